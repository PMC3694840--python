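"""Synthetic tiling ChIP/WCE profiles for the three Rec114 phospho-alleles.

The generator emulates the occupancy structure reported for Spo11/Rec114
ChIP-chip in wild type (WT) and the rec114 phospho-site mutants:

* *hotspot* signal (Gaussian bumps at hotspot-block centers) ordered
  8A > WT > 8D — the non-phosphorylatable allele raises, and the
  phospho-mimetic allele strongly reduces, hotspot occupancy.  The 8A
  default multiplier (1.25) realizes the reported 20-30% hotspot
  increase over wild type;
* *axis* signal (bumps at axis sites flanking hotspots) ordered the other
  way round, 8D > WT > 8A;
* *background* peaks near chromosome ends and pericentric windows that
  are identical across alleles (DSB-unspecific) — the features decile
  normalization uses to superimpose profiles;
* flat background at 1.0 with multiplicative lognormal noise (intensities
  are ChIP/WCE ratios: positive and right-skewed).

Feature kernels are truncated at 6 standard deviations, so probes far
from every feature sit exactly at the background level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import Genome
from .profiles import TilingProfile

__all__ = [
    "ALLELES",
    "AxisSite",
    "AlleleEffectConfig",
    "BackgroundPeak",
    "generate_axis_sites",
    "generate_background_peaks",
    "simulate_profile",
    "simulate_alleles",
    "write_sites_bed",
]

ALLELES = ("WT", "8A", "8D")
_ALLELE_STREAM = {"WT": 0, "8A": 1, "8D": 2}

# Gaussian kernels contribute nothing beyond this many sd from a feature.
KERNEL_CUTOFF_SD = 6.0


@dataclass(frozen=True)
class AxisSite:
    """An axis-protein enrichment site flanking a hotspot block."""

    chrom: str
    pos: int
    strength: float

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("axis site position must be >= 0")
        if not self.strength > 0:
            raise ValueError("axis site strength must be positive")


@dataclass(frozen=True)
class BackgroundPeak:
    """A DSB-unspecific peak shared identically by all three alleles."""

    chrom: str
    pos: int
    amplitude: float
    sd: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0 or not self.sd > 0:
            raise ValueError("background peak amplitude and sd must be positive")


@dataclass(frozen=True)
class AlleleEffectConfig:
    """Allele-specific occupancy multipliers and array/noise geometry.

    ``hotspot_multiplier`` and ``axis_multiplier`` scale the unit-scaled
    hotspot heats / axis strengths per allele; peak widths are the
    Gaussian sd of the hotspot and axis bumps in bp; ``noise_sigma`` is
    the sd of the multiplicative lognormal noise on the log scale.
    """

    hotspot_multiplier: dict = field(
        default_factory=lambda: {"8A": 1.25, "WT": 1.0, "8D": 0.15}
    )
    axis_multiplier: dict = field(
        default_factory=lambda: {"8A": 0.8, "WT": 1.0, "8D": 1.4}
    )
    hotspot_peak_sd: float = 400.0
    axis_peak_sd: float = 600.0
    background_level: float = 1.0
    noise_sigma: float = 0.15
    probe_spacing: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for table in (self.hotspot_multiplier, self.axis_multiplier):
            for allele, m in table.items():
                if m < 0:
                    raise ValueError(f"multiplier for {allele} must be >= 0")
        if not self.hotspot_peak_sd > 0 or not self.axis_peak_sd > 0:
            raise ValueError("peak sds must be > 0")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate_axis_sites(
    genome: Genome,
    blocks,
    offset_range: tuple[int, int] = (2000, 8000),
    seed: int = 0,
    n_candidates: int = 512,
    hotspot_sd: float = 400.0,
    axis_sd: float = 600.0,
    center_budget: float = 1.25,
    site_budget: float = 0.47,
) -> list[AxisSite]:
    """One axis site per hotspot block, displaced from the block center.

    Displacement magnitudes are drawn uniformly in ``offset_range``
    (either side), clipped to the chromosome.  Axis sites sit in the loop
    regions *between* hotspots, so among ``n_candidates`` candidate
    offsets the one with the least mutual interference with hotspot
    centers is kept.  Interference is scored against explicit budgets
    derived from the default allele multipliers: the summed axis signal
    deposited at a hotspot center must stay below ``center_budget`` times
    that center's heat (so the hotspot ordering 8A > WT > 8D survives the
    axis signal's opposite ordering), and the summed hotspot signal
    received at the site must stay below ``site_budget`` times the site's
    own strength (so the axis ordering 8D > WT > 8A survives there).
    Sites are placed strongest-first with the running per-center axis
    load tracked, which keeps the ordering contract of the simulated
    profiles intact even on a densely covered genome with a heavy-tailed
    heat distribution.  ``hotspot_sd``/``axis_sd`` are the peak widths
    the score assumes (defaults match :class:`AlleleEffectConfig`).
    Site strength equals the parent block heat (axis occupancy scales
    with local DSB activity).
    """
    lo, hi = offset_range
    if not 0 < lo <= hi:
        raise ValueError("offset_range must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    blocks = list(blocks)
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(blocks):
        by_chrom.setdefault(b.chrom, []).append(i)
    centers: dict[str, np.ndarray] = {}
    heats: dict[str, np.ndarray] = {}
    axis_load: dict[str, np.ndarray] = {}
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: blocks[i].center)
        centers[chrom] = np.array([blocks[i].center for i in idxs], dtype=np.int64)
        heats[chrom] = np.array([blocks[i].heat for i in idxs], dtype=float)
        axis_load[chrom] = np.zeros(len(idxs))

    reach = KERNEL_CUTOFF_SD * max(hotspot_sd, axis_sd)
    reach_a = KERNEL_CUTOFF_SD * axis_sd
    reach_h = KERNEL_CUTOFF_SD * hotspot_sd

    # Exact hotspot signal at every center (own block plus neighbors):
    # in crowded regions a weak center sits on the shoulder of strong
    # hotspot kernels, which raises the axis signal it can absorb before
    # its allele ordering flips.
    hot_sum: dict[str, np.ndarray] = {}
    for chrom, cc in centers.items():
        hh = heats[chrom]
        d = np.abs(cc[:, None] - cc[None, :]).astype(float)
        gh = np.where(d <= reach_h, np.exp(-0.5 * (d / hotspot_sd) ** 2), 0.0)
        hot_sum[chrom] = gh @ hh

    # deterministic offsets covering the allowed band, so near-boundary
    # escape positions are always among the candidates
    grid_mags = np.arange(lo, hi + 1, 100)
    grid_offsets = np.concatenate([grid_mags, -grid_mags, [hi, -hi]])

    # The strongest sites are the most dangerous leakers, so they are
    # placed first, while every center's axis budget is still empty.
    order = sorted(range(len(blocks)), key=lambda i: -blocks[i].heat)
    positions: dict[int, int] = {}
    for i in order:
        b = blocks[i]
        L = genome.lengths[b.chrom]
        cc, hh, load = centers[b.chrom], heats[b.chrom], axis_load[b.chrom]
        mags = rng.integers(lo, hi + 1, size=n_candidates)
        signs = rng.choice((-1, 1), size=n_candidates)
        cand = np.concatenate([signs * mags, grid_offsets]) + b.center
        cand = np.clip(cand, 0, L - 1)
        j0 = int(np.searchsorted(cc, cand.min() - reach))
        j1 = int(np.searchsorted(cc, cand.max() + reach, side="right"))
        if j1 <= j0:
            positions[i] = int(cand[0])
            continue
        d = np.abs(cand[:, None] - cc[None, j0:j1]).astype(float)
        ga = np.where(d <= reach_a, np.exp(-0.5 * (d / axis_sd) ** 2), 0.0)
        gh = np.where(d <= reach_h, np.exp(-0.5 * (d / hotspot_sd) ** 2), 0.0)
        # axis signal the candidate would add at each center, on top of
        # what earlier sites already deposited, against that center's
        # budget; and hotspot signal received at the candidate against
        # the site's own budget.
        cap = center_budget * hot_sum[b.chrom][j0:j1]
        center_score = ((load[None, j0:j1] + b.heat * ga) / cap[None, :]).max(axis=1)
        site_score = (hh[None, j0:j1] * gh).sum(axis=1) / (site_budget * b.heat)
        scores = np.maximum(center_score, site_score)
        best = int(np.argmin(scores))
        load[j0:j1] += b.heat * ga[best]
        positions[i] = int(cand[best])

    # Final guarantee (see _enforce_interference_budgets): conflicted
    # sites are re-placed with full knowledge of the final configuration,
    # then strengths are attenuated (center side) or boosted (site side)
    # within both budgets — axis occupancy tracks the activity of the
    # whole local domain, not just the parent block, so mild strength
    # adjustments in crowded clusters are part of the model.
    strengths, n_stuck = _enforce_interference_budgets(
        genome, blocks, by_chrom, centers, heats, hot_sum, positions, rng,
        lo, hi, n_candidates, hotspot_sd, axis_sd, center_budget, site_budget,
        reach_a, reach_h,
    )
    if n_stuck:
        warnings.warn(
            f"axis-site interference budgets could not be met for {n_stuck} "
            "site(s); allele ordering may be blurred there",
            stacklevel=2,
        )
    return [
        AxisSite(blocks[i].chrom, positions[i], strengths[i])
        for i in range(len(blocks))
    ]


def _enforce_interference_budgets(
    genome, blocks, by_chrom, centers, heats, hot_sum, positions, rng,
    lo, hi, n_candidates, hotspot_sd, axis_sd, center_budget, site_budget,
    reach_a, reach_h,
):
    """Adjust axis-site positions/strengths until both ordering budgets hold.

    Center budget: summed axis signal at every hotspot center stays below
    ``center_budget * hot_sum`` (times a safety margin that absorbs
    probe-grid evaluation).  Site budget: hotspot signal received at a
    site stays below ``site_budget`` times the site strength.  Conflicted
    sites are first re-placed against the final configuration; remaining
    excess is resolved by attenuating the dominant contributor (center
    side) or raising a site's strength to its floor where the neighboring
    centers still have margin (site side).
    """
    safety = 0.9
    strengths = {i: float(blocks[i].heat) for i in positions}

    def site_window(chrom, x):
        cc = centers[chrom]
        j0 = int(np.searchsorted(cc, x - max(reach_a, reach_h)))
        j1 = int(np.searchsorted(cc, x + max(reach_a, reach_h), side="right"))
        d = np.abs(cc[j0:j1] - x).astype(float)
        ga = np.where(d <= reach_a, np.exp(-0.5 * (d / axis_sd) ** 2), 0.0)
        gh = np.where(d <= reach_h, np.exp(-0.5 * (d / hotspot_sd) ** 2), 0.0)
        return j0, j1, ga, gh

    def compute_state():
        loads = {c: np.zeros(len(v)) for c, v in by_chrom.items()}
        floors = {}
        windows = {}
        for i in positions:
            chrom = blocks[i].chrom
            j0, j1, ga, gh = site_window(chrom, positions[i])
            windows[i] = (j0, j1, ga, gh)
            loads[chrom][j0:j1] += strengths[i] * ga
            floors[i] = float(gh @ heats[chrom][j0:j1]) / (safety * site_budget)
        caps = {c: safety * center_budget * hot_sum[c] for c in by_chrom}
        return loads, floors, windows, caps

    n_stuck = 0
    for _round in range(4):
        loads, floors, windows, caps = compute_state()
        offenders: set[int] = {i for i in positions if strengths[i] < floors[i]}
        for chrom, idxs in by_chrom.items():
            over = loads[chrom] > caps[chrom]
            if not over.any():
                continue
            for i in idxs:
                j0, j1, ga, _ = windows[i]
                if np.any(over[j0:j1] & (strengths[i] * ga > 0.05 * caps[chrom][j0:j1])):
                    offenders.add(i)
        if not offenders:
            break

        # re-place offenders against the final loads of everyone else
        moved = False
        for i in sorted(offenders, key=lambda i: -blocks[i].heat):
            b = blocks[i]
            chrom, L = b.chrom, genome.lengths[b.chrom]
            cc, hh = centers[chrom], heats[chrom]
            j0, j1, ga, _ = windows[i]
            loads[chrom][j0:j1] -= strengths[i] * ga
            mags = rng.integers(lo, hi + 1, size=n_candidates)
            signs = rng.choice((-1, 1), size=n_candidates)
            grid = np.arange(lo, hi + 1, 25)
            cand = np.concatenate([signs * mags, grid, -grid]) + b.center
            cand = np.unique(np.clip(cand, 0, L - 1))
            k0 = int(np.searchsorted(cc, cand.min() - max(reach_a, reach_h)))
            k1 = int(
                np.searchsorted(cc, cand.max() + max(reach_a, reach_h), side="right")
            )
            d = np.abs(cand[:, None] - cc[None, k0:k1]).astype(float)
            ga_c = np.where(d <= reach_a, np.exp(-0.5 * (d / axis_sd) ** 2), 0.0)
            gh_c = np.where(d <= reach_h, np.exp(-0.5 * (d / hotspot_sd) ** 2), 0.0)
            if k1 > k0:
                cs = (
                    (loads[chrom][None, k0:k1] + b.heat * ga_c)
                    / caps[chrom][None, k0:k1]
                ).max(axis=1)
                ss = (gh_c @ hh[k0:k1]) / (safety * site_budget * b.heat)
            else:
                cs = ss = np.zeros(cand.size)
            score = np.maximum(cs, ss)
            best = int(np.argmin(score))
            old = positions[i]
            positions[i] = int(cand[best])
            strengths[i] = float(b.heat)
            jj0, jj1, ga_new, _ = site_window(chrom, positions[i])
            loads[chrom][jj0:jj1] += strengths[i] * ga_new
            if positions[i] != old:
                moved = True

        # strength fine-tuning on the final positions
        loads, floors, windows, caps = compute_state()
        n_stuck = 0
        for chrom, idxs in by_chrom.items():
            cap = caps[chrom]
            for _ in range(10 * len(idxs) + 10):
                over = loads[chrom] - cap
                j = int(np.argmax(over / cap))
                if over[j] <= 0:
                    break
                contrib = []
                for i in idxs:
                    j0, j1, ga, _ = windows[i]
                    if j0 <= j < j1:
                        contrib.append((strengths[i] * ga[j - j0], i, ga[j - j0]))
                contrib.sort(reverse=True)
                reduced = False
                for amount, i, g in contrib:
                    room = strengths[i] - floors[i]
                    if g <= 0 or room <= 0:
                        continue
                    delta = min(over[j] / g, room)
                    strengths[i] -= delta
                    j0, j1, ga, _ = windows[i]
                    loads[chrom][j0:j1] -= delta * ga
                    reduced = True
                    break
                if not reduced:
                    n_stuck += 1
                    break
        # boost under-floor sites where neighboring centers have margin
        for i in positions:
            if strengths[i] >= floors[i]:
                continue
            chrom = blocks[i].chrom
            j0, j1, ga, _ = windows[i]
            margin = caps[chrom][j0:j1] - loads[chrom][j0:j1]
            with np.errstate(divide="ignore"):
                allowance = np.where(ga > 0, margin / np.where(ga > 0, ga, 1.0), np.inf)
            s_max = strengths[i] + (allowance.min() if allowance.size else np.inf)
            if s_max >= floors[i]:
                delta = floors[i] - strengths[i]
                strengths[i] = floors[i]
                loads[chrom][j0:j1] += delta * ga
            else:
                n_stuck += 1
        if not moved and n_stuck == 0:
            break
    for i in strengths:
        strengths[i] = float(max(strengths[i], 1e-9))
    return strengths, n_stuck


def generate_background_peaks(
    genome: Genome,
    n: int,
    seed: int = 0,
    window: int = 20_000,
    amplitude_range: tuple[float, float] = (0.5, 2.0),
    sd_range: tuple[float, float] = (300.0, 800.0),
) -> list[BackgroundPeak]:
    """Place ``n`` DSB-unspecific peaks near chromosome ends and centromeres.

    Each peak falls uniformly in one of three windows per chromosome —
    within ``window`` bp of either chromosome end, or within ``window`` bp
    of the centromere — emulating the telomeric/pericentric background
    signal shared by all alleles.  The same list must be reused for every
    allele.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = genome.lengths
    probs = np.array([lengths[c] for c in names], dtype=float)
    probs /= probs.sum()
    peaks: list[BackgroundPeak] = []
    for _ in range(n):
        chrom = names[rng.choice(len(names), p=probs)]
        L = lengths[chrom]
        cen = genome.centromere(chrom)
        zone = rng.integers(0, 3)
        if zone == 0:
            lo, hi = 0, min(window, L)
        elif zone == 1:
            lo, hi = max(0, L - window), L
        else:
            lo, hi = max(0, cen - window), min(L, cen + window)
        pos = int(rng.integers(lo, hi))
        amp = float(rng.uniform(*amplitude_range))
        sd = float(rng.uniform(*sd_range))
        peaks.append(BackgroundPeak(chrom, pos, amp, sd))
    return peaks


def _add_bumps(grid: np.ndarray, mean: np.ndarray, pos: int, amp: float, sd: float):
    """Add amp*exp(-(x-pos)^2 / 2 sd^2) to ``mean``, truncated at 6 sd."""
    if amp == 0.0:
        return
    cutoff = KERNEL_CUTOFF_SD * sd
    i0 = int(np.searchsorted(grid, pos - cutoff, side="left"))
    i1 = int(np.searchsorted(grid, pos + cutoff, side="right"))
    if i1 <= i0:
        return
    d = (grid[i0:i1] - pos).astype(np.float64)
    mean[i0:i1] += amp * np.exp(-0.5 * (d / sd) ** 2)


def simulate_profile(
    genome: Genome,
    blocks,
    axis_sites,
    background_peaks,
    allele: str,
    config: AlleleEffectConfig = AlleleEffectConfig(),
) -> TilingProfile:
    """Simulate one allele's tiling ChIP/WCE profile.

    The noise-free mean at probe x is::

        background + sum_blocks  h_mult * heat' * N(x; center, hotspot_sd)
                   + sum_axis    a_mult * strength' * N(x; pos, axis_sd)
                   + sum_bg      amplitude * N(x; pos, sd)

    where ``heat'``/``strength'`` are the heats/strengths divided by their
    mean (unit scaling), and N is an unnormalized Gaussian bump.  Observed
    intensity = mean * exp(Normal(0, noise_sigma^2)); each allele consumes
    an independent, seed-derived noise stream so the three profiles are
    individually and jointly reproducible.
    """
    if allele not in ALLELES:
        raise ValueError(f"unknown allele {allele!r}; expected one of {ALLELES}")
    h_mult = config.hotspot_multiplier.get(allele, 0.0)
    a_mult = config.axis_multiplier.get(allele, 0.0)

    blocks = list(blocks)
    axis_sites = list(axis_sites)
    heats = np.array([b.heat for b in blocks], dtype=float)
    strengths = np.array([s.strength for s in axis_sites], dtype=float)
    heat_scale = heats.mean() if heats.size else 1.0
    strength_scale = strengths.mean() if strengths.size else 1.0

    rng = np.random.default_rng([config.seed, _ALLELE_STREAM[allele]])
    data = {}
    for chrom, L in genome.chromosomes:
        grid = np.arange(0, L, config.probe_spacing, dtype=np.int64)
        mean = np.full(grid.size, float(config.background_level))
        for b in blocks:
            if b.chrom == chrom:
                _add_bumps(
                    grid, mean, b.center, h_mult * b.heat / heat_scale,
                    config.hotspot_peak_sd,
                )
        for s in axis_sites:
            if s.chrom == chrom:
                _add_bumps(
                    grid, mean, s.pos, a_mult * s.strength / strength_scale,
                    config.axis_peak_sd,
                )
        for p in background_peaks:
            if p.chrom == chrom:
                _add_bumps(grid, mean, p.pos, p.amplitude, p.sd)
        if config.noise_sigma > 0:
            values = mean * np.exp(rng.normal(0.0, config.noise_sigma, grid.size))
        else:
            values = mean
        data[chrom] = (grid, values)
    return TilingProfile(genome=genome, data=data, label=allele)


def simulate_alleles(
    genome: Genome,
    blocks,
    axis_sites,
    background_peaks,
    config: AlleleEffectConfig = AlleleEffectConfig(),
) -> dict[str, TilingProfile]:
    """Simulate all three allele profiles from the same feature sets."""
    return {
        allele: simulate_profile(
            genome, blocks, axis_sites, background_peaks, allele, config
        )
        for allele in ALLELES
    }


def write_sites_bed(sites, path) -> None:
    """Write axis sites or background peaks as BED5 point features."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            score = getattr(s, "strength", None)
            if score is None:
                score = getattr(s, "amplitude")
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\tsite{i:05d}\t{score:.6g}\n")
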