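"""Tiling-profile data model, kernel smoothing, decile normalization, ratios.

A :class:`TilingProfile` holds, per chromosome, sorted probe positions and
strictly positive ChIP/WCE intensities, plus processing metadata (label,
smoothing bandwidth, normalization factor).

Processing stack
----------------
* ``smooth`` — Nadaraya–Watson kernel regression with a Gaussian kernel of
  standard deviation 0.3706·bandwidth (the "normal kernel" bandwidth
  convention of R's ``ksmooth``, where the kernel quartiles sit at
  ±0.25·bandwidth), evaluated at the probe positions, never across
  chromosome boundaries.
* ``decile_normalize`` — one multiplicative correction factor per profile,
  F = 1 / (0.10 quantile of all intensities genome-wide); after scaling,
  the first decile of the profile sits at exactly 1, which superimposes
  replicate profiles on their shared DSB-unspecific background peaks.
* ``ratio_profile`` / ``invert_profile`` — elementwise quotients of
  normalized smoothed profiles with a denominator floor that guards
  against spurious ratio peaks where the denominator is near zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .genome import Genome

__all__ = [
    "TilingProfile",
    "SmoothingParams",
    "NormalizationFactor",
    "KSMOOTH_SD_PER_BANDWIDTH",
    "smooth",
    "decile_normalize",
    "ratio_profile",
    "invert_profile",
    "read_bedgraph",
    "write_bedgraph",
]

# Gaussian sd per unit bandwidth: 0.25 / Phi^-1(0.75), i.e. kernel
# quartiles at +/- bandwidth/4.
KSMOOTH_SD_PER_BANDWIDTH = 0.3706


@dataclass
class TilingProfile:
    """Per-chromosome probe positions (bp) and positive intensities."""

    genome: Genome
    data: dict[str, tuple[np.ndarray, np.ndarray]]
    label: str = ""
    smoothed: bool = False
    bandwidth: float | None = None
    normalized: bool = False
    norm_factor: float | None = None

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, val) in self.data.items():
            if chrom not in self.genome:
                raise ValueError(f"profile chromosome {chrom!r} not in genome")
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=np.float64)
            if pos.shape != val.shape:
                raise ValueError(f"{chrom}: positions/values length mismatch")
            if pos.size:
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"{chrom}: positions not strictly increasing")
                if pos[0] < 0 or pos[-1] >= self.genome.lengths[chrom]:
                    raise ValueError(f"{chrom}: probe position outside chromosome")
                if np.any(val <= 0):
                    raise ValueError(f"{chrom}: intensities must be positive")
            clean[chrom] = (pos, val)
        self.data = clean

    @property
    def n_probes(self) -> int:
        return sum(pos.size for pos, _ in self.data.values())

    def all_values(self) -> np.ndarray:
        if not self.data:
            return np.empty(0)
        return np.concatenate([val for _, val in self.data.values()])

    def value_at(self, chrom: str, pos: int) -> float:
        """Intensity at the probe nearest ``pos`` on ``chrom``."""
        positions, values = self.data[chrom]
        if positions.size == 0:
            raise ValueError(f"no probes on {chrom}")
        i = int(np.searchsorted(positions, pos))
        candidates = [j for j in (i - 1, i) if 0 <= j < positions.size]
        j = min(candidates, key=lambda j: abs(int(positions[j]) - pos))
        return float(values[j])

    def with_values(self, new_data, **meta) -> "TilingProfile":
        kwargs = dict(
            genome=self.genome,
            data=new_data,
            label=self.label,
            smoothed=self.smoothed,
            bandwidth=self.bandwidth,
            normalized=self.normalized,
            norm_factor=self.norm_factor,
        )
        kwargs.update(meta)
        return TilingProfile(**kwargs)

    def same_grid(self, other: "TilingProfile") -> bool:
        if set(self.data) != set(other.data):
            return False
        return all(
            np.array_equal(self.data[c][0], other.data[c][0]) for c in self.data
        )


@dataclass(frozen=True)
class SmoothingParams:
    """Kernel-regression bandwidth in bp (documented valid range 250-1000)."""

    bandwidth: float = 500.0

    def __post_init__(self) -> None:
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be > 0")


@dataclass(frozen=True)
class NormalizationFactor:
    """The per-profile multiplicative decile correction factor F."""

    F: float

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise ValueError("normalization factor must be > 0")


def _nw_uniform(pos: np.ndarray, val: np.ndarray, sd: float) -> np.ndarray:
    spacing = float(pos[1] - pos[0])
    sigma = sd / spacing
    num = gaussian_filter1d(val, sigma, mode="constant", cval=0.0, truncate=8.0)
    den = gaussian_filter1d(
        np.ones_like(val), sigma, mode="constant", cval=0.0, truncate=8.0
    )
    return num / den


def _nw_general(pos: np.ndarray, val: np.ndarray, sd: float) -> np.ndarray:
    out = np.empty_like(val)
    cutoff = 8.0 * sd
    lo = np.searchsorted(pos, pos - cutoff, side="left")
    hi = np.searchsorted(pos, pos + cutoff, side="right")
    for i in range(pos.size):
        d = (pos[lo[i] : hi[i]] - pos[i]).astype(np.float64)
        w = np.exp(-0.5 * (d / sd) ** 2)
        out[i] = np.dot(w, val[lo[i] : hi[i]]) / w.sum()
    return out


def smooth(
    profile: TilingProfile,
    params: SmoothingParams = SmoothingParams(),
    allow_resmooth: bool = False,
) -> TilingProfile:
    """Nadaraya-Watson Gaussian-kernel smoothing per chromosome.

    Evaluated at the probe positions themselves; chromosomes never share
    kernel mass.  Empty chromosomes pass through empty.
    """
    if profile.smoothed and not allow_resmooth:
        raise ValueError("profile already smoothed (pass allow_resmooth=True)")
    sd = KSMOOTH_SD_PER_BANDWIDTH * params.bandwidth
    out = {}
    for chrom, (pos, val) in profile.data.items():
        if pos.size == 0:
            out[chrom] = (pos, val)
            continue
        if pos.size == 1:
            out[chrom] = (pos, val.copy())
            continue
        diffs = np.diff(pos)
        if np.all(diffs == diffs[0]):
            sm = _nw_uniform(pos, val, sd)
        else:
            sm = _nw_general(pos, val, sd)
        out[chrom] = (pos, sm)
    return profile.with_values(out, smoothed=True, bandwidth=params.bandwidth)


def decile_normalize(
    profile: TilingProfile,
) -> tuple[TilingProfile, NormalizationFactor]:
    """Scale the profile by F = 1/(0.10 quantile of all intensities).

    The 0.10 quantile uses the linear-interpolation convention, so with
    intensities 1..100 the quantile is 10.9 and F = 1/10.9.  After scaling
    the genome-wide first decile equals 1 (to 1e-9 relative), which is what
    superimposes replicate profiles on shared background peaks.
    """
    values = profile.all_values()
    if values.size < 10:
        raise ValueError("decile normalization needs at least 10 probes")
    q = float(np.quantile(values, 0.10))
    if q <= 0:
        raise ValueError("0.10 quantile is not positive; cannot normalize")
    F = 1.0 / q
    out = {c: (pos, val * F) for c, (pos, val) in profile.data.items()}
    return (
        profile.with_values(out, normalized=True, norm_factor=F),
        NormalizationFactor(F),
    )


def ratio_profile(
    numerator: TilingProfile,
    denominator: TilingProfile,
    floor: float = 0.25,
) -> TilingProfile:
    """Elementwise ``numerator / max(denominator, floor)``.

    Both profiles must be smoothed, normalized, and on identical probe
    grids; there is no implicit resampling.  The floor (on the normalized
    scale) prevents spurious ratio peaks over near-zero denominators.
    """
    for p, role in ((numerator, "numerator"), (denominator, "denominator")):
        if not p.smoothed or not p.normalized:
            raise ValueError(f"{role} must be smoothed and normalized")
    if not numerator.same_grid(denominator):
        raise ValueError("profiles are on different probe grids")
    out = {
        c: (pos, val / np.maximum(denominator.data[c][1], floor))
        for c, (pos, val) in numerator.data.items()
    }
    label = f"{numerator.label or 'num'}/{denominator.label or 'den'}"
    return TilingProfile(
        genome=numerator.genome,
        data=out,
        label=label,
        smoothed=True,
        bandwidth=numerator.bandwidth,
        normalized=True,
        norm_factor=None,
    )


def invert_profile(profile: TilingProfile, floor: float = 0.25) -> TilingProfile:
    """Return ``1 / max(value, floor)`` — the unit profile divided by this one."""
    if not profile.smoothed or not profile.normalized:
        raise ValueError("profile must be smoothed and normalized")
    out = {
        c: (pos, 1.0 / np.maximum(val, floor))
        for c, (pos, val) in profile.data.items()
    }
    return TilingProfile(
        genome=profile.genome,
        data=out,
        label=f"1/{profile.label or 'profile'}",
        smoothed=True,
        bandwidth=profile.bandwidth,
        normalized=True,
        norm_factor=None,
    )


def write_bedgraph(
    profile: TilingProfile, path, sidecar: bool = False
) -> None:
    """Write fixed-width bedGraph intervals (probe = interval start).

    Interval width is the probe spacing (1 bp for single-probe
    chromosomes), clipped to the chromosome end.  With ``sidecar=True``
    the processing metadata is written next to the track as
    ``<path>.json``.
    """
    with open(path, "w") as fh:
        for chrom in profile.genome.names:
            if chrom not in profile.data:
                continue
            pos, val = profile.data[chrom]
            if pos.size == 0:
                continue
            spacing = int(pos[1] - pos[0]) if pos.size > 1 else 1
            L = profile.genome.lengths[chrom]
            ends = np.minimum(pos + spacing, L)
            for p, e, v in zip(pos, ends, val):
                fh.write(f"{chrom}\t{p}\t{e}\t{v:.8g}\n")
    if sidecar:
        meta = {
            "label": profile.label,
            "smoothed": profile.smoothed,
            "bandwidth": profile.bandwidth,
            "normalized": profile.normalized,
            "norm_factor": profile.norm_factor,
        }
        with open(f"{path}.json", "w") as fh:
            json.dump(meta, fh, indent=1)


def read_bedgraph(path, genome: Genome, label: str = "") -> TilingProfile:
    """Read a bedGraph of fixed-width intervals into a profile.

    Each interval collapses to a probe at its start.  Intervals must be
    sorted and non-overlapping per chromosome and lie inside the genome;
    violations are reported with their line number.
    """
    data: dict[str, tuple[list[int], list[float]]] = {}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            if end > genome.lengths[chrom]:
                raise ValueError(f"{path}:{lineno}: interval past end of {chrom}")
            if chrom in last_end and start < last_end[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: intervals unsorted or overlapping on {chrom}"
                )
            last_end[chrom] = end
            pos_list, val_list = data.setdefault(chrom, ([], []))
            pos_list.append(start)
            val_list.append(value)
    arrays = {
        c: (np.array(p, dtype=np.int64), np.array(v, dtype=np.float64))
        for c, (p, v) in data.items()
    }
    return TilingProfile(genome=genome, data=arrays, label=label)
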