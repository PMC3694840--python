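"""End-to-end orchestration: simulate (or load) → smooth → normalize →
ratio profiles → peak calling → colocalization → axis-domain labels.

`run_pipeline` sequences the whole analysis from a single
:class:`PipelineConfig` and a global seed, writing bedGraph/BED/TSV/JSON
artifacts when an output directory is given; every artifact records the
seed and a hash of the configuration, and re-runs are byte-identical.
`scan_scd` applies the [S/T]Q / SCD scanner to a protein FASTA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import coloc as _coloc
from . import motifs as _motifs
from .genome import (
    Genome,
    HotspotGeneratorConfig,
    generate_hotspots,
    make_genome,
    write_blocks_bed,
)
from .peaks import PeakCallParams, call_peaks, write_peaks_bed
from .profiles import (
    SmoothingParams,
    decile_normalize,
    invert_profile,
    ratio_profile,
    smooth,
    write_bedgraph,
)
from .simulate import (
    AlleleEffectConfig,
    generate_axis_sites,
    generate_background_peaks,
    simulate_alleles,
    write_sites_bed,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "scan_scd"]

logger = logging.getLogger("meichip")

# numerator/denominator allele pairs evaluated by default; "1" is the
# unit profile (inversion of the denominator).
RATIO_PAIRS = (("8A", "8D"), ("WT", "8D"), ("8A", "WT"), ("1", "8D"), ("8D", "8A"))


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all stage configurations plus a single global seed.

    The global seed deterministically derives the per-stage seeds
    (hotspots, axis sites, background peaks, profile noise, random null),
    so one integer reproduces the entire run.
    """

    genome_spec: object = "sk1-like"
    hotspots: HotspotGeneratorConfig = field(default_factory=HotspotGeneratorConfig)
    alleles: AlleleEffectConfig = field(default_factory=AlleleEffectConfig)
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)
    coloc: _coloc.ColocConfig = field(default_factory=_coloc.ColocConfig)
    null: _coloc.NullModelConfig = field(default_factory=_coloc.NullModelConfig)
    axis_offset_range: tuple[int, int] = (2000, 8000)
    n_background_peaks: int = 30
    ratio_floor: float = 0.25
    top_peaks: int = 100
    top_blocks: int = 100
    axis_threshold: float = 0.5
    seed: int = 0

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        """Build a config from a (JSON-style) dict, rejecting unknown keys."""
        return _config_from_dict(PipelineConfig, d, path="")


_NESTED = {
    "hotspots": HotspotGeneratorConfig,
    "alleles": AlleleEffectConfig,
    "smoothing": SmoothingParams,
    "peak_params": PeakCallParams,
    "coloc": _coloc.ColocConfig,
    "null": _coloc.NullModelConfig,
}


def _config_from_dict(cls, d: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in d.items():
        where = f"{path}.{key}" if path else key
        if key not in names:
            raise ValueError(f"unknown configuration key: {where!r}")
        if cls is PipelineConfig and key in _NESTED and isinstance(value, dict):
            value = _config_from_dict(_NESTED[key], value, where)
        kwargs[key] = value
    return cls(**kwargs)


def _config_digest(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    genome: Genome
    blocks: list
    axis_sites: list
    background_peaks: list
    profiles: dict
    norm_factors: dict
    ratios: dict
    peaks: dict
    coloc_results: dict
    axis_labels: np.ndarray
    summary: dict


def _derive_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    names = ("hotspots", "axis", "background", "noise", "null")
    return {n: int(s) for n, s in zip(names, rng.integers(0, 2**31 - 1, len(names)))}


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    outdir=None,
    profiles: dict | None = None,
    blocks=None,
) -> PipelineResult:
    """Run the full analysis and optionally write a report bundle.

    By default the input profiles are simulated from the config; passing
    ``profiles`` (a dict of allele → raw :class:`TilingProfile`, e.g. read
    from user bedGraphs) together with ``blocks`` runs exactly the same
    downstream path on user data.
    """
    seeds = _derive_seeds(config.seed)
    genome = make_genome(config.genome_spec)

    if profiles is None:
        hot_cfg = dataclasses.replace(config.hotspots, seed=seeds["hotspots"])
        blocks = generate_hotspots(genome, hot_cfg)
        axis_sites = generate_axis_sites(
            genome, blocks, config.axis_offset_range, seed=seeds["axis"]
        )
        background = generate_background_peaks(
            genome, config.n_background_peaks, seed=seeds["background"]
        )
        allele_cfg = dataclasses.replace(config.alleles, seed=seeds["noise"])
        profiles = simulate_alleles(genome, blocks, axis_sites, background, allele_cfg)
        logger.info("simulated %d blocks, %d axis sites", len(blocks), len(axis_sites))
    else:
        if blocks is None:
            raise ValueError("user-supplied profiles also need a hotspot block list")
        axis_sites, background = [], []

    smoothed = {a: smooth(p, config.smoothing) for a, p in profiles.items()}
    normed, factors = {}, {}
    for a, p in smoothed.items():
        normed[a], nf = decile_normalize(p)
        factors[a] = nf.F
        logger.info("decile factor F[%s] = %.4f", a, nf.F)

    ratios = {}
    for num, den in RATIO_PAIRS:
        if den not in normed or (num != "1" and num not in normed):
            continue
        if num == "1":
            ratios["1/" + den] = invert_profile(normed[den], config.ratio_floor)
        else:
            ratios[f"{num}/{den}"] = ratio_profile(
                normed[num], normed[den], config.ratio_floor
            )

    called = {label: call_peaks(r, config.peak_params) for label, r in ratios.items()}

    null_cfg = dataclasses.replace(config.null, seed=seeds["null"])
    coloc_results = {}
    for label, pk in called.items():
        if not pk:
            continue
        coloc_results[label] = _coloc.compare_top_n(
            pk,
            blocks,
            min(config.top_peaks, len(pk)),
            min(config.top_blocks, len(blocks)),
            config.coloc,
            null_cfg,
            genome=genome,
        )

    if "8D/8A" in ratios and axis_sites:
        axis_labels = _coloc.axis_domain_classifier(
            ratios["8D/8A"], axis_sites, config.axis_threshold
        )
    else:
        axis_labels = np.empty(0, dtype=np.int64)

    summary = {
        "seed": config.seed,
        "config_hash": _config_digest(config),
        "genome_total_bp": genome.total_length,
        "n_blocks": len(blocks),
        "n_axis_sites": len(axis_sites),
        "norm_factors": {a: round(f, 6) for a, f in factors.items()},
        "n_peaks": {label: len(pk) for label, pk in called.items()},
        "coloc": {
            label: {
                "n_peaks": r.n_peaks,
                "n_blocks": r.n_blocks,
                "match_distance": config.coloc.match_distance,
                "matched": r.matched,
                "matched_fraction": round(r.matched_fraction, 6),
                "null_mean_fraction": round(r.null.mean_fraction, 6),
                "fisher_p": r.fisher_p,
            }
            for label, r in coloc_results.items()
        },
        "axis_label_fraction_1": (
            round(float(axis_labels.mean()), 6) if axis_labels.size else None
        ),
    }

    result = PipelineResult(
        genome=genome,
        blocks=blocks,
        axis_sites=axis_sites,
        background_peaks=background,
        profiles=profiles,
        norm_factors=factors,
        ratios=ratios,
        peaks=called,
        coloc_results=coloc_results,
        axis_labels=axis_labels,
        summary=summary,
    )
    if outdir is not None:
        _write_bundle(result, config, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, config: PipelineConfig, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    write_blocks_bed(result.blocks, outdir / "hotspot_blocks.bed")
    if result.axis_sites:
        write_sites_bed(result.axis_sites, outdir / "axis_sites.bed")
    for allele, prof in result.profiles.items():
        write_bedgraph(prof, outdir / f"profile_{allele}.bedgraph", sidecar=True)
    for label, pk in result.peaks.items():
        write_peaks_bed(pk, outdir / f"peaks_{label.replace('/', '_over_')}.bed")

    rows = []
    for label, r in result.coloc_results.items():
        rows.append(
            {
                "comparison": label,
                "n_peaks": r.n_peaks,
                "n_blocks": r.n_blocks,
                "match_distance_bp": config.coloc.match_distance,
                "matched": r.matched,
                "matched_fraction": round(r.matched_fraction, 6),
                "null_mean_fraction": round(r.null.mean_fraction, 6),
                "fisher_p": r.fisher_p,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "coloc_summary.tsv", sep="\t", index=False)

    curve_rows = []
    for label, r in result.coloc_results.items():
        for d, c, lo, hi in zip(
            r.grid, r.curve, r.null.lower_curve, r.null.upper_curve
        ):
            curve_rows.append(
                {
                    "comparison": label,
                    "distance_bp": d,
                    "cumulative_fraction": round(float(c), 6),
                    "null_lower": round(float(lo), 6),
                    "null_upper": round(float(hi), 6),
                }
            )
    pd.DataFrame(curve_rows).to_csv(outdir / "coloc_curves.tsv", sep="\t", index=False)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)


def scan_scd(
    fasta_path, config: _motifs.ScdConfig = _motifs.ScdConfig(), out_tsv=None
) -> pd.DataFrame:
    """Scan a protein FASTA for [S/T]Q motifs and SCD regions.

    Returns one row per sequence with motif count, motif positions, and
    the SCD regions found; optionally writes the table as TSV.
    """
    rows = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        motifs, regions = _motifs.scan_sequence(str(record.seq), config)
        rows.append(
            {
                "sequence": record.id,
                "length": len(record.seq),
                "n_motifs": len(motifs),
                "motif_positions": ",".join(map(str, motifs)),
                "n_scds": len(regions),
                "scd_regions": ";".join(
                    f"{r.start}-{r.end}({r.n_motifs})" for r in regions
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "sequence", "length", "n_motifs", "motif_positions",
            "n_scds", "scd_regions",
        ],
    )
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", index=False)
    return df
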