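"""[S/T]Q motif and SCD ([S/T]Q cluster domain) scanning for protein sequences.

ATM/ATR-family kinases phosphorylate serines/threonines that immediately
precede a glutamine.  An SCD is the classical signature of their
substrates: three or more SQ/TQ dipeptides within a tract of at most 100
residues.  The tract is measured from the first motif's S/T to the last
motif's Q, inclusive — the strictest natural reading of the definition.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ScdConfig", "ScdRegion", "find_stq_motifs", "find_scds", "scan_sequence"]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ScdConfig:
    min_motifs: int = 3
    max_tract: int = 100

    def __post_init__(self) -> None:
        if self.min_motifs < 1:
            raise ValueError("min_motifs must be >= 1")
        if self.max_tract < 2:
            raise ValueError("max_tract must be >= 2 (an SQ/TQ spans 2 residues)")


@dataclass(frozen=True)
class ScdRegion:
    """0-based half-open residue interval covering a cluster of motifs."""

    start: int
    end: int
    motif_positions: tuple[int, ...]

    @property
    def tract_length(self) -> int:
        return self.end - self.start

    @property
    def n_motifs(self) -> int:
        return len(self.motif_positions)


def find_stq_motifs(sequence: str) -> list[int]:
    """0-based positions i where sequence[i] in {S, T} and sequence[i+1] == Q.

    Case-insensitive; rejects characters outside the 20-letter amino-acid
    alphabet, naming the offending position.
    """
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise ValueError(f"illegal amino-acid character {ch!r} at position {i}")
    return [i for i in range(len(seq) - 1) if seq[i] in "ST" and seq[i + 1] == "Q"]


def find_scds(
    motif_positions, config: ScdConfig = ScdConfig()
) -> list[ScdRegion]:
    """Cluster sorted motif positions into SCD regions.

    A window of ``min_motifs`` consecutive motifs qualifies when its tract
    — from the first motif's S/T to the last motif's Q, inclusive — spans
    at most ``max_tract`` residues.  Overlapping qualifying windows are
    merged into maximal regions, so nested windows are reported once; a
    merged chain of windows can span more than ``max_tract`` even though
    each constituent window satisfies the bound.
    """
    pos = list(motif_positions)
    if any(pos[i] >= pos[i + 1] for i in range(len(pos) - 1)):
        raise ValueError("motif positions must be sorted strictly ascending")
    k = config.min_motifs
    if len(pos) < k:
        return []
    # qualifying windows of exactly k consecutive motifs
    windows = [
        (i, i + k - 1)
        for i in range(len(pos) - k + 1)
        if (pos[i + k - 1] + 1) - pos[i] + 1 <= config.max_tract
    ]
    if not windows:
        return []
    # merge windows sharing motifs into maximal regions
    regions: list[ScdRegion] = []
    cur_lo, cur_hi = windows[0]
    for lo, hi in windows[1:]:
        if lo <= cur_hi:
            cur_hi = hi
        else:
            regions.append(_make_region(pos, cur_lo, cur_hi))
            cur_lo, cur_hi = lo, hi
    regions.append(_make_region(pos, cur_lo, cur_hi))
    return regions


def _make_region(pos, lo: int, hi: int) -> ScdRegion:
    motifs = tuple(pos[lo : hi + 1])
    return ScdRegion(start=motifs[0], end=motifs[-1] + 2, motif_positions=motifs)


def scan_sequence(
    sequence: str, config: ScdConfig = ScdConfig()
) -> tuple[list[int], list[ScdRegion]]:
    """Motif positions and SCD regions of one protein sequence."""
    motifs = find_stq_motifs(sequence)
    return motifs, find_scds(motifs, config)
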