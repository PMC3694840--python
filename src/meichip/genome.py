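"""Genome representation and synthetic DSB hotspot-block generation.

The genomic substrate of every tiling profile is an ordered set of named
chromosomes.  DSB hotspots are represented as "blocks" — short disjoint
intervals carrying a positive *heat* (emulating mapped Spo11-oligo 5'-end
counts) — following the block organisation of published budding-yeast DSB
maps, where ~3600 blocks cover the genome with narrow widths (median
~180 bp, mean ~252 bp, 0.9 quantile ~507 bp).

The synthetic generator draws block widths from a lognormal distribution
calibrated to those summary statistics (mu = ln 180, sigma = 0.82, whose
analytic median/mean/0.9-quantile are 180 / ~252 / ~515 bp) and couples
block heats to widths through a Gaussian copula, so the strongest blocks
are wider than average, as in real DSB maps.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genome",
    "HotspotBlock",
    "HotspotGeneratorConfig",
    "make_genome",
    "generate_hotspots",
    "read_blocks_bed",
    "write_blocks_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

# 16 chromosomes emulating the S. cerevisiae karyotype (lengths in bp,
# total 12,071,326 ~ 12.07 Mb) with approximate centromere midpoints.
_SK1_LIKE = [
    ("chrI", 230218, 151465),
    ("chrII", 813184, 238207),
    ("chrIII", 316620, 114385),
    ("chrIV", 1531933, 449711),
    ("chrV", 576874, 151987),
    ("chrVI", 270161, 148510),
    ("chrVII", 1090940, 497038),
    ("chrVIII", 562643, 105703),
    ("chrIX", 439888, 355629),
    ("chrX", 745751, 436425),
    ("chrXI", 666816, 440246),
    ("chrXII", 1078177, 150947),
    ("chrXIII", 924431, 268031),
    ("chrXIV", 784333, 628758),
    ("chrXV", 1091291, 326702),
    ("chrXVI", 948066, 555957),
]


@dataclass(frozen=True)
class Genome:
    """Ordered list of chromosomes with lengths (bp) and optional centromeres.

    Centromere positions default to the chromosome midpoint when not given;
    they are only used to define pericentric windows for background-peak
    placement in the synthetic-profile generator.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
        for name in self.centromeres:
            if name not in names:
                raise ValueError(f"centromere given for unknown chromosome {name!r}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def centromere(self, chrom: str) -> int:
        if chrom in self.centromeres:
            return self.centromeres[chrom]
        return self.lengths[chrom] // 2

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True, order=True)
class HotspotBlock:
    """A DSB hotspot block: 0-based half-open interval with a positive heat."""

    chrom: str
    start: int
    end: int
    heat: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid block interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if not self.heat > 0:
            raise ValueError(f"block heat must be positive, got {self.heat}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HotspotGeneratorConfig:
    """Parameters of the synthetic hotspot-block generator.

    Widths are lognormal(width_log_mu, width_log_sigma); heats are
    lognormal(heat_log_mu, heat_log_sigma); the two are coupled by a
    Gaussian copula with correlation ``heat_width_correlation``.
    """

    n_blocks: int = 3600
    width_log_mu: float = math.log(180.0)
    width_log_sigma: float = 0.82
    heat_log_mu: float = math.log(50.0)
    heat_log_sigma: float = 1.2
    heat_width_correlation: float = 0.5
    min_gap: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        if self.width_log_sigma < 0 or self.heat_log_sigma < 0:
            raise ValueError("lognormal sigma must be >= 0")
        if not 0.0 <= self.heat_width_correlation <= 1.0:
            raise ValueError("heat_width_correlation must be in [0, 1]")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")


def make_genome(spec) -> Genome:
    """Build a :class:`Genome` from a preset name or an explicit length list.

    Presets: ``"sk1-like"`` (16 chromosomes, ~12.07 Mb total) and ``"toy"``
    (two chromosomes of 300 kb and 200 kb).  An explicit spec is a sequence
    of ``(name, length)`` pairs.
    """
    if isinstance(spec, str):
        if spec == "sk1-like":
            return Genome(
                tuple((n, l) for n, l, _ in _SK1_LIKE),
                centromeres={n: c for n, l, c in _SK1_LIKE},
            )
        if spec == "toy":
            return Genome((("chr1", 300_000), ("chr2", 200_000)))
        raise ValueError(f"unknown genome preset {spec!r}")
    return Genome(tuple((str(n), int(l)) for n, l in spec))


def sample_widths_heats(
    config: HotspotGeneratorConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (width, heat) pairs from the copula-coupled lognormals."""
    rho = config.heat_width_correlation
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    widths = np.exp(config.width_log_mu + config.width_log_sigma * z1)
    heats = np.exp(config.heat_log_mu + config.heat_log_sigma * z2)
    widths = np.maximum(np.rint(widths).astype(np.int64), 1)
    return widths, heats


def generate_hotspots(
    genome: Genome,
    config: HotspotGeneratorConfig = HotspotGeneratorConfig(),
    max_attempts_per_block: int = 1000,
) -> list[HotspotBlock]:
    """Place ``config.n_blocks`` non-overlapping hotspot blocks on the genome.

    Chromosomes are chosen proportional to length and block centers uniformly
    within the chromosome; a draw whose interval (padded by ``min_gap``)
    would overlap an existing block or run past a chromosome end is rejected
    and its position resampled (width/heat are kept, so the width
    distribution is unaffected by rejection).  If the genome cannot fit all
    blocks a shorter list is returned with a warning.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_blocks == 0:
        return []
    widths, heats = sample_widths_heats(config, config.n_blocks, rng)

    names = genome.names
    lengths = genome.lengths
    probs = np.array([lengths[n] for n in names], dtype=float)
    probs /= probs.sum()
    # per-chromosome sorted occupied intervals, padded by min_gap
    starts: dict[str, list[int]] = {n: [] for n in names}
    ends: dict[str, list[int]] = {n: [] for n in names}

    blocks: list[HotspotBlock] = []
    n_failed = 0
    for i in range(config.n_blocks):
        w = int(widths[i])
        placed = False
        for _ in range(max_attempts_per_block):
            chrom = names[rng.choice(len(names), p=probs)]
            L = lengths[chrom]
            if w > L:
                continue
            center = int(rng.integers(0, L))
            start = center - w // 2
            end = start + w
            if start < 0 or end > L:
                continue
            lo = start - config.min_gap
            hi = end + config.min_gap
            j = bisect.bisect_left(starts[chrom], hi)
            if j > 0 and ends[chrom][j - 1] > lo:
                continue
            starts[chrom].insert(j, start)
            ends[chrom].insert(j, end)
            blocks.append(
                HotspotBlock(chrom, start, end, float(heats[i]), name=f"hs{i:05d}")
            )
            placed = True
            break
        if not placed:
            n_failed += 1
    if n_failed:
        warnings.warn(
            f"could only place {len(blocks)} of {config.n_blocks} blocks "
            f"({n_failed} failed after {max_attempts_per_block} attempts each)",
            stacklevel=2,
        )
    blocks.sort(key=lambda b: (genome.names.index(b.chrom), b.start))
    return blocks


def blocks_by_chrom(blocks) -> dict[str, list[HotspotBlock]]:
    """Group blocks by chromosome, sorted by start."""
    out: dict[str, list[HotspotBlock]] = {}
    for b in blocks:
        out.setdefault(b.chrom, []).append(b)
    for lst in out.values():
        lst.sort(key=lambda b: b.start)
    return out


def write_blocks_bed(blocks, path) -> None:
    """Write blocks as BED5 (chrom, start, end, name, score=heat)."""
    with open(path, "w") as fh:
        for i, b in enumerate(blocks):
            name = b.name or f"hs{i:05d}"
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{name}\t{b.heat:.6g}\n")


def read_blocks_bed(path, genome: Genome | None = None) -> list[HotspotBlock]:
    """Read a BED5 block list; validates intervals (and chromosomes if a
    genome is given), reporting the offending line number."""
    blocks: list[HotspotBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 BED fields")
            chrom, start_s, end_s, name, heat_s = fields[:5]
            try:
                start, end, heat = int(start_s), int(end_s), float(heat_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end {end} <= start {start}"
                )
            if genome is not None:
                if chrom not in genome:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > genome.lengths[chrom]:
                    raise ValueError(
                        f"{path}:{lineno}: block extends past end of {chrom}"
                    )
            try:
                blocks.append(HotspotBlock(chrom, start, end, heat, name=name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return blocks


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path) -> Genome:
    chroms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            chroms.append((fields[0], int(fields[1])))
    return Genome(tuple(chroms))
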