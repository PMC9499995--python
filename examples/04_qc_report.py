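"""Quality control from spike-in counts.

Computes methylation specificity (the immunoprecipitation's
selectivity for methylated DNA), the share of reads spent on
spike-ins, and the count consistency of same-property alternative
fragments.
"""

from medipspike import SimConfig, qc_report
from medipspike.simulate import simulate_spikein_counts

cfg = SimConfig(seed=4, depth=50_000)
table, _ = simulate_spikein_counts(cfg)

report = qc_report([table], grand_total=int(table["count"].sum() / 0.01))
print(f"methylation specificity : {report.methylation_specificity:.3f}")
print(f"unmethylated fraction   : {report.unmethylated_fraction:.3f}")
print(f"spike-in read fraction  : {report.spikein_read_fraction:.3%}")
print("alternative 320 bp fragments (within-range / between-means):")
for _, row in report.alternative_ranges.iterrows():
    print(f"  G+C {row.gc_content:.0%}, CpG 1/{1 / row.cpg_fraction:.0f}: "
          f"[{row.within_min}, {row.within_max}] / "
          f"{row.between_means:.1f}")
# Specificity near 0.97 reflects ~3% non-specific recovery of
# unmethylated fragments; small between-alternative differences show
# that counts depend on designed properties, not particular sequences.
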