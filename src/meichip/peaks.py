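"""Automatic peak detection and strength ranking on smoothed profiles.

A probe is a peak candidate if its value is the strict maximum within
±``local_window`` bp and at least ``min_height`` (on the normalized
scale); candidates closer than ``min_separation`` are merged keeping the
higher one (ties: leftmost).  Peak strength is the apex height — on
allele-ratio profiles the amplitude, not the width, carries the signal.
Output is sorted by height descending with 1-based ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import TilingProfile

__all__ = ["Peak", "PeakCallParams", "call_peaks", "top_n",
           "write_peaks_bed", "read_peaks_bed"]


@dataclass(frozen=True)
class Peak:
    chrom: str
    pos: int
    height: float
    rank: int = 0

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("peak height must be positive")


@dataclass(frozen=True)
class PeakCallParams:
    """min_separation and local_window in bp; min_height on the normalized
    scale.  local_window defaults to the profile's smoothing bandwidth."""

    min_separation: float = 1000.0
    min_height: float = 1.1
    local_window: float | None = None

    def __post_init__(self) -> None:
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if not self.min_height > 0:
            raise ValueError("min_height must be > 0")
        if self.local_window is not None and not self.local_window > 0:
            raise ValueError("local_window must be > 0")


def _candidates(pos: np.ndarray, val: np.ndarray, window: float,
                min_height: float) -> list[int]:
    """Indices whose value is the strict maximum within +/- window bp."""
    lo = np.searchsorted(pos, pos - window, side="left")
    hi = np.searchsorted(pos, pos + window, side="right")
    out = []
    for i in np.nonzero(val >= min_height)[0]:
        w = val[lo[i] : hi[i]]
        if val[i] >= w.max() and np.count_nonzero(w == val[i]) == 1:
            out.append(int(i))
    return out


def call_peaks(
    profile: TilingProfile, params: PeakCallParams = PeakCallParams()
) -> list[Peak]:
    """Call peaks on a smoothed (and normalized) profile.

    Raises on unsmoothed input — local maxima of raw probe noise are
    meaningless here.
    """
    if not profile.smoothed:
        raise ValueError("peak calling requires a smoothed profile")
    window = params.local_window
    if window is None:
        window = profile.bandwidth if profile.bandwidth else 500.0

    raw: list[Peak] = []
    for chrom, (pos, val) in profile.data.items():
        if pos.size == 0:
            continue
        for i in _candidates(pos, val, window, params.min_height):
            raw.append(Peak(chrom, int(pos[i]), float(val[i])))

    # Greedy merge: strongest first (ties leftmost); drop any candidate
    # within min_separation of an already-kept peak on the same chromosome.
    raw.sort(key=lambda p: (-p.height, p.chrom, p.pos))
    kept_pos: dict[str, list[int]] = {}
    kept: list[Peak] = []
    for p in raw:
        near = any(
            abs(p.pos - q) < params.min_separation for q in kept_pos.get(p.chrom, ())
        )
        if not near:
            kept.append(p)
            kept_pos.setdefault(p.chrom, []).append(p.pos)
    return [
        Peak(p.chrom, p.pos, p.height, rank=i + 1) for i, p in enumerate(kept)
    ]


def top_n(peaks: list[Peak], n: int) -> list[Peak]:
    """First min(n, len) peaks by rank (stable)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return list(peaks[:n])


def write_peaks_bed(peaks, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.pos}\t{p.pos + 1}\tpeak_rank{p.rank}\t{p.height:.6g}\n")


def read_peaks_bed(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 BED fields")
            rank = 0
            if fields[3].startswith("peak_rank"):
                rank = int(fields[3][len("peak_rank"):])
            peaks.append(Peak(fields[0], int(fields[1]), float(fields[4]), rank))
    return peaks
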