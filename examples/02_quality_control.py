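"""Genotype quality control with the chip-analysis thresholds.

Applies the four filters (SNP call rate >= 0.90, animal call rate >= 0.90,
MAF > 0.05, heterozygote-frequency deviation < 0.15) in the fixed order and
prints the per-step attrition table — the same arithmetic that takes a chip
from its raw SNP count down to the analysis set.
"""

from wssgblup import QcThresholds, SimConfig, apply_qc, simulate_dataset

ds = simulate_dataset(SimConfig(seed=2, missing_rate=0.03))
geno, report = apply_qc(ds.genotypes, QcThresholds())

print(report.summary().to_string(index=False))
print(f"\nSNPs    : {report.n_snps_in} -> {report.n_snps_out}")
print(f"animals : {report.n_animals_in} -> {report.n_animals_out}")
print("\nremoval reasons:")
print(report.removed_snps["reason"].value_counts().to_string())
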