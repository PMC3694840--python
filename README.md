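# meichip

Analysis of meiotic ChIP-chip tiling profiles: where do Spo11 and its
accessory proteins sit on the genome, and how does that occupancy shift
between phospho-site alleles of the DSB machinery?

In budding yeast meiosis, Spo11 catalyses programmed DNA double-strand
breaks (DSBs) at hotspots, while accessory proteins such as Rec114 are
anchored at the chromosome axis and contact hotspot DNA transiently.
Phospho-site mutants of Rec114 — `8A` (all eight [S/T]Q sites
non-phosphorylatable) and `8D` (phospho-mimetic) — move occupancy in
opposite directions: `8A` raises and `8D` suppresses hotspot signal
(8A > WT > 8D at hotspots), with the mirror ordering at axis sites
(8D > WT > 8A). This package implements the statistical pipeline that
detects and quantifies those shifts from tiling-array ChIP/WCE tracks,
together with a synthetic-data generator that emulates the whole study
design so every stage can be validated against known ground truth.

## What it computes

Given per-probe ChIP/WCE intensity tracks for the three alleles:

1. **Smoothing** — Nadaraya–Watson kernel regression per chromosome with
   a Gaussian kernel of sd `0.3706·h` for bandwidth `h` (the `ksmooth`
   normal-kernel convention, default `h` = 500 bp).
2. **Decile normalization** — one multiplicative factor per profile,
   `F = 1/Q₀.₁₀`, where `Q₀.₁₀` is the genome-wide first decile of the
   intensities; this superimposes the profiles on their shared,
   DSB-unspecific background peaks.
3. **Ratio profiles** — elementwise `8A/8D`, `WT/8D`, `8A/WT`, `1/8D`
   (denominator floored at 0.25): allele-differential occupancy becomes
   a positional peak signal.
4. **Peak calling** — strict local maxima above a height threshold with
   a minimum separation, ranked by apex height.
5. **Colocalization statistics** — for the top-*N* peaks vs the top-*M*
   hottest hotspot blocks: the nearest-block-edge distance per peak (the
   distance to the nearer edge even for peaks inside a block), cumulative
   distance curves, the matched fraction at 600 bp, a random-placement
   null model (uniform positions, 100 repetitions, pointwise 2%/98%
   envelopes), and a two-sided Fisher's exact test of observed vs
   chance-expected matched counts.
6. **Axis-domain classification** — binary labels at axis sites (1 iff
   the 8D/8A ratio exceeds 0.5), tracing DSB-hot vs cold axis domains.
7. **[S/T]Q / SCD scanning** — a protein-sequence utility locating
   ATM/ATR consensus motifs (S or T followed by Q) and SCD regions
   (≥ 3 motifs within ≤ 100 residues).

The synthetic generator builds a 16-chromosome, ~12.07 Mb genome with
3600 hotspot blocks whose widths follow lognormal(ln 180, 0.82) —
median 180 bp, mean ≈ 252 bp, 0.9 quantile ≈ 507 bp — heats coupled to
widths by a Gaussian copula, axis sites flanking each block, shared
background peaks near telomeres/centromeres, and multiplicative
lognormal noise. See `docs/methods.md` for the model and its knobs.

## Worked example

```python
import meichip as m

result = m.run_pipeline(m.PipelineConfig(seed=1))
row = result.summary["coloc"]["8A/8D"]
print(row["matched_fraction"], row["null_mean_fraction"], row["fisher_p"])
```

prints

```
0.85 0.0129 3.965907879459807e-39
```

— 85 of the 100 strongest 8A/8D ratio peaks fall within 600 bp of the
edge of one of the 100 hottest hotspot blocks, versus a 1.3% chance
level, with a Fisher p of ~4×10⁻³⁹: the ratio of the two mutant
profiles pinpoints the planted DSB hotspots. Running the same
comparison on the inverted ratio (`8D/8A`) gives a matched fraction of
0.00 and p = 1 — its peaks are axis sites, which deliberately avoid
hotspot centers. The scripts in `examples/` walk through each
capability (full pipeline, generator calibration, step-by-step profile
processing, SCD scanning) and print a line explaining each number.

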