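"""Composite drought-index arithmetic, factor analysis and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from droughtgerm import index as di


def make_table(rows):
    return pd.DataFrame(rows, columns=["accession", "treatment", "replicate",
                                       "GP", "FW", "SL", "RL"])


class TestAveraging:
    @pytest.mark.parametrize(
        "values,expected", [((10.0, 20.0, 30.0), 20.0), ((92.0, 94.0, 96.0), 94.0), ((7.5,), 7.5)]
    )
    def test_replicates_average_arithmetically(self, values, expected):
        rows = [
            ("a1", trt, i + 1, v, v, v, v)
            for trt in ("control", "drought")
            for i, v in enumerate(values)
        ]
        rows += [("a2", trt, 1, 1.0, 1.0, 1.0, 1.0) for trt in ("control", "drought")]
        means = di.average_replicates(make_table(rows))
        got = means.loc[
            (means.accession == "a1") & (means.treatment == "control"), "GP"
        ].item()
        assert got == pytest.approx(expected)

    def test_accession_missing_a_treatment_is_dropped_with_warning(self):
        rows = [("a1", "control", 1, 95, 30, 10, 30), ("a1", "drought", 1, 20, 8, 2, 5),
                ("a2", "control", 1, 96, 28, 11, 31)]
        with pytest.warns(UserWarning, match="missing a treatment"):
            means = di.average_replicates(make_table(rows))
        assert set(means.accession) == {"a1"}


class TestDescriptiveStats:
    def test_fresh_weight_reduction_matches_published_value(self):
        # panel means 29.3 mg (control) vs 8.24 mg (drought)
        assert di.percent_reduction(29.3, 8.24) == pytest.approx(71.877, abs=5e-3)

    def test_cv_is_sd_over_mean(self):
        rows = []
        for i, (c, d) in enumerate([(1, 1.0), (2, 2.0), (3, 3.0)]):
            rows.append((f"a{i}", "control", 1, c, c, c, c))
            rows.append((f"a{i}", "drought", 1, d, d, d, d))
        stats = di.descriptive_stats(di.average_replicates(make_table(rows)))
        gp = stats[(stats.trait == "GP") & (stats.treatment == "control")]
        assert gp["cv_pct"].item() == pytest.approx(50.0)

    def test_identical_treatments_give_zero_reduction_and_t(self):
        rows = []
        for i in range(4):
            v = 10.0 + i
            rows.append((f"a{i}", "control", 1, v, v, v, v))
            rows.append((f"a{i}", "drought", 1, v, v, v, v))
        stats = di.descriptive_stats(di.average_replicates(make_table(rows)))
        ctl = stats[stats.treatment == "control"]
        assert np.allclose(ctl["reduction_pct"], 0.0)
        assert np.allclose(ctl["welch_t"], 0.0)


class TestDcDi:
    @pytest.mark.parametrize(
        "xd,xc,expected", [(27.1, 97.2, 27.1 / 97.2), (5.0, 5.0, 1.0), (0.0, 97.2, 0.0)]
    )
    def test_dc_is_drought_over_control(self, xd, xc, expected):
        assert di.compute_dc(xd, xc) == pytest.approx(expected)

    def test_dc_rejects_nonpositive_control(self):
        with pytest.raises(di.DroughtIndexError):
            di.compute_dc(1.0, 0.0)

    @pytest.mark.parametrize(
        "dc,xd,xm,expected",
        [(1.0, 3.0, 3.0, 1.0), (0.5, 0.0, 3.0, 0.0), (0.27881, 27.1, 27.1, 0.27881)],
    )
    def test_di_scales_dc_by_relative_performance(self, dc, xd, xm, expected):
        assert di.compute_di(dc, xd, xm) == pytest.approx(expected)

    def test_di_rejects_nonpositive_panel_mean(self):
        with pytest.raises(di.DroughtIndexError):
            di.compute_di(1.0, 1.0, 0.0)


class TestCorrelation:
    def test_three_point_closed_form(self):
        df = pd.DataFrame(
            {"GP": [1, 2, 3], "FW": [1, 2, 4], "SL": [3, 1, 2], "RL": [1, 3, 2]},
            dtype=float,
        )
        r, p = di.correlation_matrix(df)
        assert r.loc["GP", "FW"] == pytest.approx(9 / np.sqrt(84))
        assert np.allclose(r, r.T) and np.allclose(np.diag(r), 1.0)

    def test_duplicate_and_negated_columns(self):
        base = np.array([1.0, 4.0, 2.0, 5.0])
        df = pd.DataFrame({"GP": base, "FW": base, "SL": -base, "RL": base**2})
        r, _ = di.correlation_matrix(df)
        assert r.loc["GP", "FW"] == pytest.approx(1.0)
        assert r.loc["GP", "SL"] == pytest.approx(-1.0)

    def test_zero_variance_trait_is_named(self):
        df = pd.DataFrame({"GP": [1.0, 2, 3], "FW": [1.0, 1, 1],
                           "SL": [1.0, 2, 4], "RL": [2.0, 1, 3]})
        with pytest.raises(di.DroughtIndexError, match="FW"):
            di.correlation_matrix(df)


class TestFactorExtraction:
    def test_identity_correlation_gives_unit_eigenvalues(self, rng):
        # large n, independent columns: eigenvalues near (1,1,1,1)
        df = pd.DataFrame(rng.normal(size=(4000, 4)), columns=list(di.TRAITS))
        model = di.factor_extract(df, retain_rule="all")
        assert np.allclose(model.eigenvalues, 1.0, atol=0.1)
        assert np.allclose(model.contributions.sum(), 100.0)

    def test_two_trait_closed_form(self, rng):
        # 2x2 correlation matrix with off-diagonal r has eigenvalues 1 +/- r
        z = rng.normal(size=(5000, 2))
        x = z[:, 0]
        y = 0.8 * z[:, 0] + np.sqrt(1 - 0.64) * z[:, 1]
        df = pd.DataFrame({"GP": x, "FW": y})
        model = di.factor_extract(df, retain_rule="all")
        r = df.corr().iloc[0, 1]
        assert model.eigenvalues == pytest.approx([1 + r, 1 - r], abs=1e-9)

    def test_contributions_normalised_and_cumulative(self, small_study):
        table, _, _ = small_study
        means = di.average_replicates(table)
        dimat = di.di_matrix(di.drought_indices(means))
        model = di.factor_extract(dimat)
        assert model.eigenvalues.sum() == pytest.approx(4.0)
        assert model.contributions.sum() == pytest.approx(100.0)
        assert np.all(np.diff(model.cumulative) >= -1e-12)
        assert model.cumulative[-1] == pytest.approx(100.0)

    def test_scale_equivariance_of_whole_chain(self, small_study):
        # multiplying one trait's measurements in both treatments leaves
        # DC, the DI correlation matrix and hence D unchanged
        table, _, _ = small_study
        scaled = table.copy()
        scaled["FW"] = scaled["FW"] * 7.3
        out1 = di.evaluate_panel(table)[0]
        out2 = di.evaluate_panel(scaled)[0]
        assert np.allclose(out1["D"], out2["D"], atol=1e-10)


class TestMembershipWeightsD:
    @pytest.mark.parametrize(
        "scores,expected",
        [((2.0, 5.0, 8.0), (0.0, 0.5, 1.0)), ((1.0, 2.0, 4.0), (0.0, 1 / 3, 1.0)),
         ((3.0, 9.0), (0.0, 1.0))],
    )
    def test_membership_min_max(self, scores, expected):
        assert di.compute_membership(np.array(scores)) == pytest.approx(expected)

    def test_membership_rejects_constant_scores(self):
        with pytest.raises(di.DroughtIndexError):
            di.compute_membership(np.array([2.0, 2.0, 2.0]))

    def test_weights_normalise_contributions(self):
        p = np.array([82.885, 8.509, 5.507, 3.099])
        w = di.compute_weights(p)
        assert w == pytest.approx([0.82885, 0.08509, 0.05507, 0.03099])
        assert w.sum() == pytest.approx(1.0)
        assert di.compute_weights([42.0]) == pytest.approx([1.0])

    def test_d_is_weighted_sum(self):
        w = di.compute_weights([82.885, 8.509, 5.507, 3.099])
        d = di.compute_d(np.array([[1.0, 0, 0, 0], [1, 1, 1, 1], [0, 0, 0, 0]]), w)
        assert d == pytest.approx([0.82885, 1.0, 0.0])

    def test_d_dimension_mismatch(self):
        with pytest.raises(di.DroughtIndexError):
            di.compute_d(np.ones((3, 2)), np.array([1.0]))

    def test_single_retained_factor_d_ranks_like_f1(self, small_study):
        table, _, _ = small_study
        scores, model, _, _ = di.evaluate_panel(table)
        assert model.retained == [0]
        f1 = model.scores["F1"]
        assert np.all(
            np.argsort(scores["D"].to_numpy()) == np.argsort(f1.to_numpy())
        )


class TestClassification:
    @pytest.mark.parametrize(
        "d,label",
        [(0.85, "extremely strong"), (1.0, "extremely strong"), (0.7, "extremely strong"),
         (0.400, "strong"), (0.699, "strong"), (0.1, "moderate"), (0.399, "moderate"),
         (0.04, "susceptible"), (0.02, "poorest"), (0.0, "poorest")],
    )
    def test_band_membership(self, d, label):
        assert di.classify_d(d) == label

    def test_rejects_out_of_range(self):
        with pytest.raises(di.DroughtIndexError):
            di.classify_d(1.2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_partition_every_value_has_exactly_one_class(self, d):
        labels = {lab for _, lab in di.DEFAULT_BANDS}
        assert di.classify_d(d) in labels


def wpgma_oracle(dist: np.ndarray):
    """Naive O(n^3) WPGMA: merge the closest pair, new distances are plain
    averages of the two children's distances."""
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(d.shape[0]))
    heights = []
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        k = np.argmin(sub)
        i, j = np.unravel_index(k, sub.shape)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        heights.append(sub[i, j])
        for c in active:
            if c not in (a, b):
                d[a, c] = d[c, a] = 0.5 * (d[a, c] + d[b, c])
        active.remove(b)
    return sorted(heights)


class TestWpgma:
    def test_two_accessions_single_merge(self):
        z, groups, newick = di.wpgma_cluster(np.array([0.2, 0.9]), k_groups=2)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.7)
        assert newick.count(",") == 1 and newick.endswith(";")

    def test_separated_clusters_cut_cleanly(self):
        _, groups, _ = di.wpgma_cluster(np.array([0.0, 0.1, 0.9, 1.0]), k_groups=2)
        g = groups.to_numpy()
        assert g[0] == g[1] and g[2] == g[3] and g[0] != g[2]

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_merge_heights_match_bruteforce_oracle(self, n, rng):
        for _ in range(20):
            d = rng.random(n)
            z, _, _ = di.wpgma_cluster(d, k_groups=2)
            dist = np.abs(d[:, None] - d[None, :])
            assert np.allclose(sorted(z[:, 2]), wpgma_oracle(dist), atol=1e-12)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(di.DroughtIndexError):
            di.wpgma_cluster(np.array([0.1, 0.2]), k_groups=3)
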