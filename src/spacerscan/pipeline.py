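"""Orchestrate simulate -> extract -> map -> analyze with machine-readable
outputs.

Every stage writes TSV with a one-line header; the run summary is JSON.
Ratios use all spacers (duplicates retained); maps and PAM matrices use
unique spacers.  All thresholds in effect are logged at run start.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis import (
    bias_summary,
    bin_hits,
    build_pam_matrix,
    count_pam_sites,
)
from .core import CrisprArrayModel, ReferenceSet, load_references, read_fastq
from .framestats import annotate_frame, atg_fraction_by_duplication, \
    p_inframe_atg_no_stop, p_no_inframe_stop
from .mapping import CATEGORIES, SpacerMapper, extract_pam
from .parser import DEFAULT_MAX_EDIT_FRACTION, collapse_duplicates, parse_reads
from .simulate import ErrorModel, SimulationConfig, simulate_run

logger = logging.getLogger("spacerscan")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "OUTPUT_FILES"]

#: Canonical analysis outputs produced by a full run (simulation inputs are
#: written in addition when the simulate stage is enabled).
OUTPUT_FILES = (
    "spacers.tsv",
    "tally.tsv",
    "hits.tsv",
    "bins_chromosome.tsv",
    "bins_plasmid.tsv",
    "pam_matrix.tsv",
    "frame_annotations.tsv",
    "duplication_bins.tsv",
    "bias_summary.json",
    "summary.json",
)

EXIT_INVALID_CONFIG = 2
EXIT_MISSING_INPUT = 3
EXIT_NO_SPACERS = 4


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 1):
        super().__init__(message)
        self.exit_code = exit_code


_KNOWN_KEYS = {
    "chromosome_fasta", "plasmid_fasta", "reads_fastq", "output_dir",
    "simulate", "seed", "repeat", "leader_anchor", "unit_length",
    "spacer_length_min", "spacer_length_max", "atg_window", "frame_offset",
    "max_edit_fraction", "max_edits", "pam_offset", "pam_width",
    "chromosome_bin_width", "plasmid_bin_width", "plasmid_copy_number",
    "n_events", "plasmid_source_prob", "pam_bias", "duplication_mean",
    "parental_read_fraction", "substitution_rate", "insertion_rate",
    "deletion_rate", "n_permutations", "chromosome_length", "plasmid_length",
    "gc_content",
}


@dataclass
class PipelineConfig:
    output_dir: str = "spacerscan_out"
    chromosome_fasta: str | None = None
    plasmid_fasta: str | None = None
    reads_fastq: str | None = None
    simulate: bool = False
    seed: int = 0
    # array model overrides (None = CrisprArrayModel defaults)
    repeat: str | None = None
    leader_anchor: str | None = None
    unit_length: int = 61
    spacer_length_min: int | None = None
    spacer_length_max: int | None = None
    atg_window: int = 30
    frame_offset: int = 0
    # thresholds
    max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION
    max_edits: int = 2
    pam_offset: int = -2
    pam_width: int = 3
    chromosome_bin_width: int = 10_000
    plasmid_bin_width: int = 50
    plasmid_copy_number: float = 40.0
    n_permutations: int = 10_000
    # simulation parameters (used when simulate=True)
    chromosome_length: int = 100_000
    plasmid_length: int = 5_300
    gc_content: float = 0.5
    n_events: int = 100
    plasmid_source_prob: float = 0.5
    pam_bias: float = 1.0
    duplication_mean: float = 3.0
    parental_read_fraction: float = 0.9
    substitution_rate: float = 0.01
    insertion_rate: float = 0.005
    deletion_rate: float = 0.005

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise PipelineError(
                f"unknown config keys: {sorted(unknown)}", EXIT_INVALID_CONFIG
            )
        try:
            return cls(**d)
        except TypeError as exc:
            raise PipelineError(str(exc), EXIT_INVALID_CONFIG) from exc

    def array_model(self) -> CrisprArrayModel:
        kwargs: dict = {
            "unit_length": self.unit_length,
            "atg_window": self.atg_window,
            "frame_offset": self.frame_offset,
        }
        if self.repeat is not None:
            kwargs["repeat"] = self.repeat
        if self.leader_anchor is not None:
            kwargs["leader_anchor"] = self.leader_anchor
        if self.spacer_length_min is not None and self.spacer_length_max is not None:
            kwargs["spacer_length_window"] = (self.spacer_length_min,
                                              self.spacer_length_max)
        try:
            return CrisprArrayModel(**kwargs)
        except ValueError as exc:
            raise PipelineError(str(exc), EXIT_INVALID_CONFIG) from exc

    def simulation_config(self) -> SimulationConfig:
        try:
            return SimulationConfig(
                seed=self.seed,
                chromosome_length=self.chromosome_length,
                plasmid_length=self.plasmid_length,
                gc_content=self.gc_content,
                n_events=self.n_events,
                plasmid_source_prob=self.plasmid_source_prob,
                pam_bias=self.pam_bias if self.pam_bias > 0 else math.inf,
                duplication_mean=self.duplication_mean,
                parental_read_fraction=self.parental_read_fraction,
                error_model=ErrorModel(
                    substitution_rate=self.substitution_rate,
                    insertion_rate=self.insertion_rate,
                    deletion_rate=self.deletion_rate,
                ),
            )
        except ValueError as exc:
            raise PipelineError(str(exc), EXIT_INVALID_CONFIG) from exc


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write every report; returns the run summary."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = config.array_model()
    logger.info(
        "thresholds: max_edit_fraction=%s max_edits=%s pam_offset=%s pam_width=%s",
        config.max_edit_fraction, config.max_edits, config.pam_offset,
        config.pam_width,
    )
    timings: dict[str, float] = {}

    # --- stage: inputs (simulate or load) ----------------------------------
    t = time.time()
    if config.simulate:
        sim = config.simulation_config()
        refs, model, events, reads = simulate_run(sim, outdir, model=model)
    else:
        if not (config.chromosome_fasta and config.plasmid_fasta and config.reads_fastq):
            raise PipelineError(
                "chromosome_fasta, plasmid_fasta and reads_fastq are required "
                "when simulate is disabled", EXIT_MISSING_INPUT,
            )
        for p in (config.chromosome_fasta, config.plasmid_fasta, config.reads_fastq):
            if not Path(p).exists():
                raise PipelineError(f"missing input: {p}", EXIT_MISSING_INPUT)
        refs = load_references(
            config.chromosome_fasta, config.plasmid_fasta,
            plasmid_copy_number=config.plasmid_copy_number,
        )
        reads = list(read_fastq(config.reads_fastq))
    timings["inputs"] = time.time() - t

    # --- stage: extract ----------------------------------------------------
    t = time.time()
    parsed, counters = parse_reads(reads, model, config.max_edit_fraction)
    rows = []
    all_spacers: list[str] = []
    for p in parsed:
        for spacer, pos in zip(p.spacers, p.spacer_positions):
            rows.append((p.read_id, p.orientation_used, p.expansion_count,
                         spacer, pos))
            all_spacers.append(spacer)
    _write_tsv(outdir / "spacers.tsv", pd.DataFrame(
        rows, columns=["read_id", "orientation", "expansion_count", "spacer",
                       "position_in_read"]))
    tally = collapse_duplicates(all_spacers)
    _write_tsv(outdir / "tally.tsv", pd.DataFrame(
        [(s, tally.counts[s]) for s in tally.unique],
        columns=["spacer", "duplication_count"]))
    timings["extract"] = time.time() - t
    if not all_spacers:
        raise PipelineError("no spacers extracted", EXIT_NO_SPACERS)

    # --- stage: map --------------------------------------------------------
    t = time.time()
    mapper = SpacerMapper(refs, max_edits=config.max_edits)
    hits = {}
    for spacer in tally.unique:
        hit = mapper.map(spacer)
        if hit.mapped:
            pam = extract_pam(hit, refs, model, offset=config.pam_offset,
                              width=config.pam_width)
            hit = dataclasses.replace(hit, pam=pam)
        hits[spacer] = hit
    hit_rows = []
    for spacer in tally.unique:
        h = hits[spacer]
        name = (refs.chromosome_label if h.source == "chromosome"
                else refs.plasmid_label if h.source == "plasmid" else h.source)
        hit_rows.append((name, h.start, h.end, spacer, h.edit_distance,
                         h.strand, h.pam, h.source, tally.counts[spacer]))
    _write_tsv(outdir / "hits.tsv", pd.DataFrame(
        hit_rows, columns=["source_name", "start", "end", "spacer",
                           "edit_distance", "strand", "pam", "category",
                           "duplication_count"]))
    timings["map"] = time.time() - t

    # --- stage: analyze ----------------------------------------------------
    t = time.time()
    # all-spacer (duplicate-weighted) category counts: the ratio rule
    all_counts = {c: 0 for c in CATEGORIES}
    unique_counts = {c: 0 for c in CATEGORIES}
    for spacer in tally.unique:
        cat = hits[spacer].source
        all_counts[cat] += tally.counts[spacer]
        unique_counts[cat] += 1

    bias = bias_summary(
        all_counts["chromosome"], all_counts["plasmid"],
        genome_length=len(refs.chromosome),
        plasmid_length=len(refs.plasmid),
        copy_number=refs.plasmid_copy_number,
    )
    with open(outdir / "bias_summary.json", "w") as fh:
        payload = bias.to_dict()
        payload["ratio_rule"] = "all_spacers_with_duplicates"
        payload["map_rule"] = "unique_spacers"
        json.dump(payload, fh, indent=2)

    # unique-spacer maps and PAM matrix
    for source, width, fname in (
        ("chromosome", config.chromosome_bin_width, "bins_chromosome.tsv"),
        ("plasmid", config.plasmid_bin_width, "bins_plasmid.tsv"),
    ):
        starts = [h.start for h in hits.values() if h.source == source]
        binned = bin_hits(starts, width, len(refs.sequence(source)), source)
        _write_tsv(outdir / fname, pd.DataFrame(
            {"bin_start": binned.bin_starts, "count": binned.counts}))

    pams = [h.pam for h in hits.values() if h.mapped and h.pam]
    if pams:
        pm = build_pam_matrix(pams)
        dfm = pd.DataFrame(pm.counts, index=list("ACGT"),
                           columns=[str(i) for i in range(pm.width)])
        dfm.loc["information_bits"] = pm.information_content
        dfm.insert(0, "row", dfm.index)
        _write_tsv(outdir / "pam_matrix.tsv", dfm)
        pam_consensus = pm.consensus
    else:
        _write_tsv(outdir / "pam_matrix.tsv", pd.DataFrame({"row": []}))
        pam_consensus = ""

    annotations = {s: annotate_frame(s, model.atg_window, model.frame_offset)
                   for s in tally.unique}
    _write_tsv(outdir / "frame_annotations.tsv", pd.DataFrame(
        [(s, tally.counts[s], a.has_inframe_atg, a.has_inframe_stop)
         for s, a in annotations.items()],
        columns=["spacer", "duplication_count", "has_inframe_atg",
                 "has_inframe_stop"]))
    bins, trend = atg_fraction_by_duplication(
        tally.counts, annotations, n_permutations=config.n_permutations,
        seed=config.seed)
    _write_tsv(outdir / "duplication_bins.tsv", pd.DataFrame(
        [(b.duplication_count, b.n_spacers, b.atg_fraction) for b in bins],
        columns=["duplication_count", "n_spacers", "atg_fraction"]))
    timings["analyze"] = time.time() - t

    k = (model.atg_window - model.frame_offset) // 3
    summary = {
        "version": __version__,
        "schema": 1,
        "counters": {
            **counters,
            "unique_spacers": len(tally.unique),
            "mapped_unique": unique_counts["chromosome"] + unique_counts["plasmid"],
            "category_counts_unique": unique_counts,
            "category_counts_all": all_counts,
        },
        "bias_summary": bias.to_dict(),
        "pam_consensus": pam_consensus,
        "plasmid_pam_sites": count_pam_sites(
            refs.plasmid, "AAG", circular=refs.plasmid_circular, both_strands=True),
        "analytic_constants": {
            "k_codons": k,
            "atg_baseline_percent": 100.0 * p_inframe_atg_no_stop(k),
            "detection_limit_percent": 100.0 * p_no_inframe_stop(k),
        },
        "trend": {
            "statistic": trend.statistic,
            "p_value": trend.p_value,
            "n_permutations": trend.n_permutations,
        },
        "config": {kk: getattr(config, kk) for kk in sorted(_KNOWN_KEYS)
                   if hasattr(config, kk)},
        "timings_sec": {**timings, "total": time.time() - t0},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
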