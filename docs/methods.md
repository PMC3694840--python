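# Methods

## Scope and data model

The package analyses tiling ChIP/WCE occupancy profiles (one intensity
per probe position per chromosome) for three allele backgrounds of the
meiotic DSB machinery — wild type (`WT`), non-phosphorylatable
(`8A`) and phospho-mimetic (`8D`) — against a map of DSB hotspot
*blocks*: disjoint intervals with a positive heat emulating mapped
Spo11-oligo 5′-end counts. Coordinates are 0-based half-open (BED
convention) everywhere, in files and in memory. Profiles are exchanged
as bedGraph, features as BED5, genomes as two-column `chrom.sizes`.

## Profile processing

**Smoothing.** Nadaraya–Watson kernel regression with a Gaussian kernel,
evaluated at the probe positions, independently per chromosome. The
kernel sd is `0.3706·bandwidth`, which places the kernel quartiles at
±bandwidth/4 — the bandwidth convention of R's `ksmooth` "normal"
kernel, so a 500 bp bandwidth here means the same thing it does there.
Default bandwidth 500 bp; 250–1000 bp is the sensible range for
50 bp probe spacing. On uniform probe grids the estimator runs through
`scipy.ndimage.gaussian_filter1d` applied to the values and to a vector
of ones (zero-padded), whose quotient is exactly the Nadaraya–Watson
estimate with an 8 sd kernel truncation; irregular grids fall back to a
direct windowed computation with the same truncation. Smoothing is
linear, preserves constants, and never leaves the convex hull of the
input values; the unit tests pin all three properties at 1e-9 relative.

**Decile normalization.** A single correction factor per profile,
`F = 1/Q₀.₁₀` with `Q₀.₁₀` the genome-wide 0.10 quantile
(linear-interpolation convention) of the intensities; all intensities
are multiplied by `F`. We read the method's "0.1 percentile" as the
first decile, consistent with the method's own name — the 0.1th
percentile of a noisy positive profile would be an unstable extreme
order statistic. Because most probes in a ChIP/WCE track sit at
background, `F` is close to 1 and the scaling superimposes replicate
profiles on their shared DSB-unspecific background peaks; with noise
off and a sparse feature set this superimposition is exact, and the
test suite asserts it exactly. Normalization is idempotent (the second
factor is 1 to 1e-9). The pipeline smooths first and normalizes the
smoothed track, which is what makes `F` stable; both steps are exposed
separately so callers can reorder them.

**Ratio and inversion profiles.** Elementwise quotients of smoothed,
normalized profiles on identical probe grids (no implicit resampling).
The denominator is floored at 0.25 on the normalized scale to prevent
spurious ratio peaks over near-zero denominators; the floor is a guard
of this implementation, exposed as a parameter. `1/profile` is the
special case with a unit numerator.

## Peak calling

A probe is a candidate peak if its value is the strict maximum within
±`local_window` (default: the smoothing bandwidth) and at least
`min_height` (default 1.1 on the normalized scale — 10% above
background). Candidates closer than `min_separation` (default 1000 bp)
are merged keeping the higher one, ties broken leftmost, so output is
deterministic. Peak strength is the apex height, not the area: on
ratio profiles the amplitude carries the allele signal. The
local-maximum/separation/threshold scheme with all three knobs exposed
is this package's definition of "automatic" peak calling; `min_height`
filters before top-N selection.

## Colocalization statistics

The distance of a peak to a hotspot block is the distance to the
**nearest block edge**, even when the peak maps inside the block (a
peak at the center of a 180 bp block is 89–90 bp from its nearer
edge). This deliberately unusual convention is preserved because the
downstream statistics are defined in terms of it; a zero-inside variant
is not provided. A peak on a chromosome without blocks is at infinite
distance.

For a top-*N*-peaks vs top-*M*-blocks comparison (both strength-sorted),
the package reports per-peak distances, the cumulative distance curve
over a 0–5 kb grid (100 bp steps), and the matched fraction at the
match distance (default 600 bp). The chance level comes from a
random-placement null: *N* positions uniform over the genome
(chromosome chosen proportional to length), mapped to the blocks
exactly as real peaks, repeated 100 times; the mean matched fraction
and pointwise 2%/98% percentile envelopes summarize it. For sparse
non-overlapping blocks the null mean equals Σᵢ(wᵢ + 2d*)/G
analytically, and a test holds the Monte-Carlo mean to within three
standard errors of that closed form.

Significance uses the two-sided **Fisher's exact test** (via
`scipy.stats.fisher_exact`; an exact integer hypergeometric enumeration
serves as the independent oracle in the tests, swept over every 2×2
table with total ≤ 30). The tested table pairs the observed
matched/unmatched counts against the null's mean expected counts
rounded to integers — the comparison is observed-vs-chance, not
profile-vs-profile. No multiple-testing correction is applied; each
comparison is a single planned test.

**Axis-domain classifier.** At each axis site the 8D/8A ratio value at
the nearest probe is compared against a threshold (default 0.5):
strictly above → label 1, else 0 (a value exactly at the threshold is
0). Runs of 1s trace DSB-hot axis domains.

## Synthetic study design

The generator is the package's ground-truth instrument; its defaults
*are* the study conditions, and the acceptance checks run against them.

**Genome.** `"sk1-like"`: 16 chromosomes totalling 12,071,326 bp with
approximate centromere positions, emulating the budding-yeast
karyotype; `"toy"`: two chromosomes (300 + 200 kb) for desk-scale work.

**Hotspot blocks.** 3600 blocks; widths lognormal(µ = ln 180,
σ = 0.82), the unique lognormal reproducing the published block-width
summary (analytic median 180 bp, mean ≈ 252 bp, 0.9 quantile ≈ 515 bp
vs the printed 507 bp — a 1.4% calibration error accepted as within
tolerance). Heats are lognormal(ln 50, 1.2) — the source map publishes
no heat distribution, so these are free parameters chosen to span the
orders of magnitude real Spo11-oligo counts cover — coupled to widths
by a Gaussian copula with ρ = 0.5, so the hottest blocks are wider than
average (this is what puts the 500-strongest-blocks random-overlap
level at ~7%). Placement is rejection sampling: chromosome proportional
to length, center uniform, redraws on overlap within a 500 bp minimum
gap; rejection resamples the position only, leaving the width
distribution intact.

**Axis sites.** One per block, displaced 2–8 kb from the block center,
with strength tied to the parent block's heat. Axis sites live in the
loop regions *between* hotspots, so the generator selects, among
uniformly drawn candidate offsets, the position minimizing mutual
interference with hotspot centers, scored against budgets derived
exactly from the allele multipliers: the summed axis signal at any
center stays below the level that would flip the hotspot ordering
8A > WT > 8D, and the hotspot signal received at the site stays below
the level that would flip the axis ordering 8D > WT > 8A. Sites are
placed strongest-first with running load tracking, followed by a repair
pass that re-places, slightly attenuates, or slightly boosts the
strength of the few sites (typically < 5 of 3600) caught in
pathologically crowded clusters — axis occupancy reflects the local
domain, not only the parent block, so these small adjustments are part
of the model rather than a correction to it. The result is that the
noise-free ordering contract holds at *every* hotspot center and
*every* axis site genome-wide, which the acceptance tests verify
exhaustively.

**Background peaks.** DSB-unspecific peaks placed within 20 kb of
chromosome ends or centromeres, identical across alleles — the features
decile normalization aligns.

**Profiles.** Probes every 50 bp (a desk-scale stand-in for
high-density tiling arrays; configurable). The noise-free mean at probe
x is background (1.0) plus Gaussian bumps: hotspot bumps (sd 400 bp) at
block centers scaled by `hotspot_multiplier · heat′`, axis bumps
(sd 600 bp) scaled by `axis_multiplier · strength′`, and the shared
background bumps; heat′/strength′ are unit-scaled by their means.
Kernels are truncated at 6 sd so probes far from all features sit
exactly at background — this is what makes the decile factor identical
across alleles on sparse genomes and the superimposition check exact.
Default multipliers: hotspot 8A:1.25, WT:1.0, 8D:0.15 (the 8A value
realizes the reported 20–30% hotspot increase; the 8D value encodes
"strongly reduced"); axis 8D:1.4, WT:1.0, 8A:0.8 (magnitudes invented
to realize the reported axis ordering — the real axis-site differences
are only shown graphically and are not calibrated to any printed
number). Observed intensity is the mean times exp(N(0, σ²)) with
σ = 0.15: ChIP/WCE ratios are positive and right-skewed, so noise is
multiplicative lognormal. Each allele consumes an independent
seed-derived noise stream; identical seed and configuration give
bit-identical profiles.

## What the synthetic data does and does not show

Passing the recovery tests shows the pipeline correctly inverts the
generative model it was pointed at: Gaussian peaks, multiplicative
noise, known block list. Real tiling arrays add probe-specific response,
spatial correlation of noise, replication-timing and copy-number
structure, and hotspot shapes that are not Gaussian; none of these are
modeled, so recovery rates here are upper bounds, not forecasts, for
real-data performance. The `1/8D` inversion illustrates the gap: in the
synthetic model the 8D hotspot component is reduced but still positive,
so inverting 8D yields no hotspot peaks (matched fraction ~0), whereas
on the real arrays the inversion reportedly recovers a weaker but
positive correlation — capturing that would require modeling the
axis-dominated local baseline around real hotspots.

## Acceptance problem sizes

The acceptance checks run the full default design: a 12.07 Mb genome,
3600 blocks, 50 bp probes, three simulated profiles plus five ratio
tracks, top-100 peak comparisons with a 100-repetition null
(`run_pipeline` completes in a few seconds), and the
500-peaks-vs-top-500-blocks random overlap averaged over 100
repetitions. The Fisher oracle sweep enumerates all 46,375 tables with
total ≤ 30.

## Numerical choices and degenerate inputs

- Quantiles use the linear-interpolation convention throughout.
- Kernel truncations: 8 sd (smoother), 6 sd (simulated features).
- Peak ties broken leftmost; ranks are 1-based and deterministic.
- Empty chromosomes pass through smoothing; profiles need ≥ 10 probes
  to normalize; zero peaks reject colocalization statistics explicitly.
- `generate_hotspots` warns and returns a partial list when the genome
  cannot fit the requested blocks; `compare_top_n` warns and uses all
  peaks/blocks when fewer than requested exist.
- SCD tract length runs from the first motif's S/T to the last motif's
  Q inclusive (the strictest natural reading); overlapping qualifying
  windows merge into maximal regions, so nested windows are reported
  once, and a merged chain can span more than `max_tract` even though
  each constituent window satisfies the bound.

## Known limitations

- The axis-site interference budgets assume the default allele
  multipliers and peak widths; radically different multipliers would
  need the corresponding budget arguments adjusted.
- The random null places peaks uniformly; real peak callers have
  position biases (e.g. toward probe-dense regions) the null ignores.
- `value_at` evaluates at the nearest probe, so sub-probe-spacing
  positional claims are meaningless at 50 bp spacing.
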