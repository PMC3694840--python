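"""Full synthetic run: simulate the three allele profiles on a 16-chromosome
genome, process them, and test peak–hotspot colocalization.

The printed matched fractions show the planted biology: peaks of the 8A/8D
ratio profile sit on DSB hotspot blocks (far above the random envelope),
while peaks of the inverted 8D/8A ratio sit at axis sites, away from the
blocks (at or below chance).
"""

import meichip as m

result = m.run_pipeline(m.PipelineConfig(seed=1), outdir="pipeline_out")

print(f"genome: {result.summary['genome_total_bp']:,} bp, "
      f"{result.summary['n_blocks']} hotspot blocks")
print(f"decile factors: {result.summary['norm_factors']}")
print()
print(f"{'comparison':>10} {'n_peaks':>8} {'matched@600bp':>14} "
      f"{'random':>8} {'Fisher p':>10}")
for label, row in result.summary["coloc"].items():
    print(f"{label:>10} {row['n_peaks']:>8} {row['matched_fraction']:>14.2f} "
          f"{row['null_mean_fraction']:>8.3f} {row['fisher_p']:>10.2e}")
print()
print("a matched fraction far above the random column means the ratio's "
      "peaks colocalize with the planted DSB hotspots")
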