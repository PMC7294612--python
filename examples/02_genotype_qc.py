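"""Genotype QC: allele frequencies, Hardy-Weinberg filter, cohort comparison.

Simulates genotypes at the published replication-cohort frequencies, then
compares each SNP's observed MAF against the discovery cohort's published
frequency (allele-count chi-squared) and flags rare variants (MAF ≤ 5%).
"""

from n3grs import filter_hwe, maf_table, simulate_genotypes
from n3grs.panel import FAS_N_PARTICIPANTS, compared_panel, compared_reference
from n3grs.simulate import study_like_preset

config = study_like_preset(seed=7, n_participants=122)
matrix = simulate_genotypes(config)
panel = config.panel

retained, excluded = filter_hwe(matrix, panel, alpha=0.05)
print(f"HWE filter at alpha=0.05: {len(retained)}/{len(panel)} SNPs retained")
for res in excluded:
    print(f"  excluded {res.snp_id}: chi2={res.chi_squared:.2f} p={res.p_value:.3g}")

reference = dict(zip(compared_reference().snp_id, compared_reference().maf_fas))
report = maf_table(
    matrix, panel,
    reference_mafs=reference,
    reference_n_alleles=2 * FAS_N_PARTICIPANTS,
)
print(f"\nrare SNPs (MAF <= 0.05): {int(report.rare_flag.sum())}")
print(f"SNPs differing from the discovery cohort at p < 0.05: "
      f"{int((report.cmp_p < 0.05).sum())}")
print("\nfirst rows of the QC table:")
print(report.head(5).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
# hwe_p is the 1-df chi-squared tail probability; cmp_p compares this cohort's
# allele counts with the discovery cohort's.
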