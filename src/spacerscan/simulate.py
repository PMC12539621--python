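"""Synthetic sequencing input: expanded reporter-array amplicons with
planted acquisition events, nanopore-style errors, and ground truth.

All randomness flows through a single numpy Generator keyed by the config
seed, with a fixed draw order (references -> events -> reads), so runs are
fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    LACZ_STUB,
    PRIMER_FWD,
    PRIMER_REV,
    DEFAULT_LEADER,
    CrisprArrayModel,
    ReadRecord,
    ReferenceSet,
    circular_window,
    revcomp,
    write_fasta,
    write_fastq,
)
from .mapping import pam_window

__all__ = [
    "ErrorModel",
    "SimulationConfig",
    "AcquisitionEvent",
    "generate_references",
    "plant_events",
    "synthesize_reads",
    "simulate_run",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ("event_id", "source", "start", "strand", "spacer", "pam",
                 "duplication_count")

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution / insertion / deletion rates (ONT-noise proxy)."""

    substitution_rate: float = 0.01
    insertion_rate: float = 0.005
    deletion_rate: float = 0.005

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(not 0.0 <= r <= 0.2 for r in rates):
            raise ValueError("error rates must be within [0, 0.2]")
        if sum(rates) >= 0.5:
            raise ValueError("summed error rates must be < 0.5")

    @property
    def total_rate(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chromosome_length: int = 100_000
    plasmid_length: int = 5_300
    gc_content: float = 0.5
    n_events: int = 100
    plasmid_source_prob: float = 0.5
    pam_bias: float = 1.0  # weight of AAG-PAM start sites; may be math.inf
    duplication_distribution: str = "geometric"
    duplication_mean: float = 3.0
    error_model: ErrorModel = field(default_factory=ErrorModel)
    parental_read_fraction: float = 0.9
    exclude_cassette_overlap: bool = True

    def __post_init__(self) -> None:
        if self.chromosome_length <= 0 or self.plasmid_length <= 0:
            raise ValueError("sequence lengths must be positive")
        if self.plasmid_length >= self.chromosome_length:
            raise ValueError("plasmid must be shorter than the chromosome")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.plasmid_source_prob <= 1.0:
            raise ValueError("plasmid_source_prob must be in [0, 1]")
        if self.pam_bias < 1.0:
            raise ValueError("pam_bias must be >= 1")
        if self.duplication_distribution not in ("geometric", "constant"):
            raise ValueError("duplication_distribution must be geometric|constant")
        if self.duplication_mean < 1.0:
            raise ValueError("duplication_mean must be >= 1")
        if not 0.0 <= self.parental_read_fraction <= 1.0:
            raise ValueError("parental_read_fraction must be in [0, 1]")


@dataclass(frozen=True)
class AcquisitionEvent:
    """Planted ground truth for one acquisition event."""

    event_id: str
    source: str  # chromosome | plasmid
    start: int  # 0-based forward-strand protospacer start
    strand: str
    spacer: str
    pam: str
    duplication_count: int


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=probs)
    return _BASE_ARR[codes].tobytes().decode("ascii")


def _cassette(model: CrisprArrayModel) -> str:
    """Parental (unexpanded) amplicon template, primer to primer."""
    return PRIMER_FWD + DEFAULT_LEADER + model.repeat + LACZ_STUB + revcomp(PRIMER_REV)


def generate_references(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    model: CrisprArrayModel | None = None,
) -> tuple[ReferenceSet, CrisprArrayModel, str]:
    """Seeded references with the reporter cassette embedded mid-chromosome.

    Returns (references, array model, parental amplicon template).  Draw
    order: chromosome background, then plasmid.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if model is None:
        model = CrisprArrayModel()
    cassette = _cassette(model)
    if config.chromosome_length < len(cassette) + 2:
        raise ValueError("chromosome too short for the reporter cassette")
    chrom_bg = _random_seq(rng, config.chromosome_length - len(cassette), config.gc_content)
    insert_at = (config.chromosome_length - len(cassette)) // 2
    chromosome = chrom_bg[:insert_at] + cassette + chrom_bg[insert_at:]
    plasmid = _random_seq(rng, config.plasmid_length, config.gc_content)
    refs = ReferenceSet(chromosome=chromosome, plasmid=plasmid)
    return refs, model, cassette


def cassette_span(config: SimulationConfig, model: CrisprArrayModel) -> tuple[int, int]:
    """Chromosomal half-open interval occupied by the reporter cassette."""
    cassette = _cassette(model)
    insert_at = (config.chromosome_length - len(cassette)) // 2
    return insert_at, insert_at + len(cassette)


def _aag_start_mask(seq: str, strand: str, m: int) -> np.ndarray:
    """Boolean mask over circular start positions whose PAM window is AAG."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    A, G, C, T = ord("A"), ord("G"), ord("C"), ord("T")
    if strand == "+":
        # PAM = seq[s-2], seq[s-1], seq[s] == A, A, G
        return (np.roll(arr, 2) == A) & (np.roll(arr, 1) == A) & (arr == G)
    # minus strand: revcomp(seq[s+m-1 : s+m+2]) == AAG  <=>  that window is CTT
    return (
        (np.roll(arr, -(m - 1)) == C)
        & (np.roll(arr, -m) == T)
        & (np.roll(arr, -(m + 1)) == T)
    )


def plant_events(
    refs: ReferenceSet,
    model: CrisprArrayModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[AcquisitionEvent]:
    """Plant acquisition events with source, PAM and duplication biases.

    Draw order per event: source, strand, start site, then (after all
    events) duplication counts in one vectorized draw.
    """
    m = model.expected_spacer_length
    w = config.pam_bias
    site_lists: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    lo, hi = cassette_span(config, model)
    lo, hi = lo - m, hi + m  # keep planted windows clear of the cassette
    for source in ("chromosome", "plasmid"):
        seq = refs.sequence(source)
        for strand in ("+", "-"):
            mask = _aag_start_mask(seq, strand, m)
            if config.exclude_cassette_overlap and source == "chromosome":
                allowed = np.ones(len(seq), dtype=bool)
                allowed[max(0, lo) : hi] = False
                positions_all = np.nonzero(allowed)[0]
                aag = np.nonzero(mask & allowed)[0]
                non_aag = np.nonzero(~mask & allowed)[0]
            else:
                positions_all = np.arange(len(seq))
                aag = np.nonzero(mask)[0]
                non_aag = np.nonzero(~mask)[0]
            site_lists[(source, strand)] = {
                "all": positions_all, "aag": aag, "non_aag": non_aag,
            }

    events: list[AcquisitionEvent] = []
    for i in range(config.n_events):
        source = "plasmid" if rng.random() < config.plasmid_source_prob else "chromosome"
        strand = "+" if rng.random() < 0.5 else "-"
        sites = site_lists[(source, strand)]
        aag, non_aag = sites["aag"], sites["non_aag"]
        if np.isinf(w) and aag.size:
            start = int(aag[rng.integers(aag.size)])
        elif aag.size == 0:
            start = int(non_aag[rng.integers(non_aag.size)])
        else:
            p_aag = (w * aag.size) / (w * aag.size + non_aag.size)
            if rng.random() < p_aag:
                start = int(aag[rng.integers(aag.size)])
            else:
                start = int(non_aag[rng.integers(non_aag.size)])
        seq = refs.sequence(source)
        spacer = circular_window(seq, start, m, strand, circular=True)
        pam = pam_window(seq, start, m, strand, circular=True)
        events.append(AcquisitionEvent(
            event_id=f"ev{i:05d}", source=source, start=start, strand=strand,
            spacer=spacer, pam=pam, duplication_count=1,
        ))

    if config.duplication_distribution == "geometric":
        dups = rng.geometric(1.0 / config.duplication_mean, size=config.n_events)
    else:
        dups = np.full(config.n_events, int(round(config.duplication_mean)))
    return [dataclasses.replace(e, duplication_count=int(d))
            for e, d in zip(events, dups)]


def apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Independently corrupt a sequence with substitutions, insertions and
    deletions.  Insertions are placed after the base they were drawn for."""
    if model.total_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.shape[0]
    draws = rng.random((n, 3))
    sub = draws[:, 0] < model.substitution_rate
    dele = draws[:, 1] < model.deletion_rate
    ins = draws[:, 2] < model.insertion_rate
    out = arr.copy()
    if sub.any():
        # substitute with one of the three other bases
        idx = np.nonzero(sub)[0]
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        base_codes = np.searchsorted(_BASE_ARR, out[idx])  # ACGT are sorted
        out[idx] = _BASE_ARR[(base_codes + shift) % 4]
    pieces: list[bytes] = []
    ins_bases = _BASE_ARR[rng.integers(0, 4, size=int(ins.sum()))]
    keep = ~dele
    if not ins.any():
        return out[keep].tobytes().decode("ascii")
    boundaries = np.nonzero(ins)[0]
    prev = 0
    for k, b in enumerate(boundaries):
        seg = out[prev : b + 1]
        pieces.append(seg[keep[prev : b + 1]].tobytes())
        pieces.append(ins_bases[k : k + 1].tobytes())
        prev = b + 1
    seg = out[prev:]
    pieces.append(seg[keep[prev:]].tobytes())
    return b"".join(pieces).decode("ascii")


def expanded_template(event: AcquisitionEvent, model: CrisprArrayModel) -> str:
    """+1 expansion amplicon: the new unit inserts at the leader side."""
    return (
        PRIMER_FWD + DEFAULT_LEADER + model.repeat + event.spacer + model.repeat
        + LACZ_STUB + revcomp(PRIMER_REV)
    )


def synthesize_reads(
    events: list[AcquisitionEvent],
    refs: ReferenceSet,
    model: CrisprArrayModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ReadRecord]:
    """Emit duplication_count reads per event plus parental reads.

    Draw order: per expanded read (in event order) orientation then errors;
    then parental reads.  With parental_read_fraction = 1 only parental
    reads are emitted.  About half of all reads are reverse-complemented.
    """
    reads: list[ReadRecord] = []
    parental = _cassette(model)
    n_expanded = 0
    if config.parental_read_fraction < 1.0:
        for event in events:
            template = expanded_template(event, model)
            for r in range(event.duplication_count):
                seq = apply_errors(template, config.error_model, rng)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                reads.append(ReadRecord(id=f"{event.event_id}_r{r}", sequence=seq))
                n_expanded += 1
        rho = config.parental_read_fraction
        n_parental = int(round(rho / (1.0 - rho) * n_expanded))
    else:
        n_parental = sum(e.duplication_count for e in events)
    for r in range(n_parental):
        seq = apply_errors(parental, config.error_model, rng)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(ReadRecord(id=f"parental_r{r}", sequence=seq))
    return reads


def write_truth(path: str | Path, events: list[AcquisitionEvent]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for e in events:
            fh.write(
                f"{e.event_id}\t{e.source}\t{e.start}\t{e.strand}\t"
                f"{e.spacer}\t{e.pam}\t{e.duplication_count}\n"
            )


def simulate_run(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    model: CrisprArrayModel | None = None,
) -> tuple[ReferenceSet, CrisprArrayModel, list[AcquisitionEvent], list[ReadRecord]]:
    """Full simulation; optionally writes the standard file set to outdir."""
    rng = np.random.default_rng(config.seed)
    refs, model, _template = generate_references(config, rng, model)
    events = plant_events(refs, model, config, rng)
    reads = synthesize_reads(events, refs, model, config, rng)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "chromosome.fasta", [("chromosome", refs.chromosome)])
        write_fasta(outdir / "plasmid.fasta", [("plasmid", refs.plasmid)])
        write_fastq(outdir / "reads.fastq", reads)
        write_truth(outdir / "truth.tsv", events)
        cfg = dataclasses.asdict(config)
        cfg["pam_bias"] = None if np.isinf(config.pam_bias) else config.pam_bias
        with open(outdir / "sim_config.json", "w") as fh:
            json.dump(cfg, fh, indent=2)
    return refs, model, events, reads
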