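"""CAPS marker screening: does a SNP create or destroy a digestion site?

A SNP inside a SalI recognition site (GTCGAC) makes the two alleles
digest differently, which is exactly what a CAPS genotyping assay exploits.
"""

from droughtgerm.candidates import caps_scan, default_enzymes

#           1234567890123
sequence = "TTAGTCGACGGAA"  # SalI site at positions 4-9
snp_pos, ref, alt = 4, "G", "A"  # G->A destroys the site

report = caps_scan(sequence, snp_pos, ref, alt)
print(report.to_string(index=False))

hits = report[report.polymorphic]
for row in hits.itertuples():
    print(f"\n{row.enzyme} ({row.site}) is a CAPS candidate: "
          f"{row.ref_sites} site(s) in the reference allele vs "
          f"{row.alt_sites} in the variant allele.")
# An enzyme with equal counts in both alleles cannot distinguish the
# genotypes on a gel and is not reported as polymorphic.
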