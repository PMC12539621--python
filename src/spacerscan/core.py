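"""Shared sequence domain types, coordinate conventions and FASTA/FASTQ I/O.

Coordinates are 0-based, half-open, always reported on the forward strand
with an explicit strand field.  Circular references are supported by
wrapping windows past the sequence end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetError",
    "CoordinateError",
    "ReferenceSet",
    "CrisprArrayModel",
    "ReadRecord",
    "revcomp",
    "circular_window",
    "load_references",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "DEFAULT_REPEAT",
    "DEFAULT_LEADER",
    "PRIMER_FWD",
    "PRIMER_REV",
    "LACZ_STUB",
]


class AlphabetError(ValueError):
    """A sequence contains symbols outside the allowed nucleotide alphabet."""


class CoordinateError(ValueError):
    """A window overruns a linear sequence or a position is out of range."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_REF_ALPHABET = frozenset("ACGT")
_READ_ALPHABET = frozenset("ACGTN")

#: E. coli K-12 Type I-E CRISPR direct repeat (29 nt).
DEFAULT_REPEAT = "GTGTTCCCCGCGCCAGCGGGGATAAACCG"

#: Leader segment placed between the forward primer site and the first
#: repeat in the reporter cassette; the anchor used for read orientation
#: is its 3' (repeat-proximal) end.
DEFAULT_LEADER = "ATAAACCGTTAGTTGAAGTAATTTAGTCATCTAAAGAGGA"

#: Amplification primers flanking the reporter leader-repeat junction.
PRIMER_FWD = "GGTCTTAATGAATGGCCGGG"
PRIMER_REV = "CATGGATCCGAAGTCGAGC"

#: First 60 bp of lacZ, used as the downstream reporter stub in the
#: simulated cassette.
LACZ_STUB = "ATGACCATGATTACGGATTCACTGGCCGTCGTTTTACAACGTCGTGACTGGGAAAACCCT"


def _validate_alphabet(seq: str, allowed: frozenset, what: str) -> None:
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(
            f"{what} contains invalid symbols {sorted(bad)!r}; "
            f"allowed: {''.join(sorted(allowed))}"
        )


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N; N maps to N)."""
    _validate_alphabet(seq, _READ_ALPHABET, "sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def circular_window(
    seq: str,
    start: int,
    length: int,
    strand: str = "+",
    circular: bool = True,
) -> str:
    """Extract a window from ``seq``, wrapping past the end when circular.

    ``start`` is a 0-based forward-strand position; negative starts wrap
    on circular sequences.  Strand ``-`` returns the reverse complement of
    the forward-strand window.
    """
    n = len(seq)
    if length < 0:
        raise CoordinateError(f"negative window length {length}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if circular:
        if n == 0:
            raise CoordinateError("empty sequence")
        start %= n
        if length > n:
            raise CoordinateError(f"window length {length} exceeds sequence length {n}")
        end = start + length
        window = seq[start:end] if end <= n else seq[start:] + seq[: end - n]
    else:
        if not 0 <= start < n:
            raise CoordinateError(f"start {start} out of range for length-{n} sequence")
        if start + length > n:
            raise CoordinateError(
                f"window [{start}, {start + length}) overruns linear sequence of length {n}"
            )
        window = seq[start : start + length]
    return revcomp(window) if strand == "-" else window


@dataclass(frozen=True)
class ReferenceSet:
    """The mapping universe: chromosome + plasmid with circularity flags."""

    chromosome: str
    plasmid: str
    chromosome_circular: bool = True
    plasmid_circular: bool = True
    plasmid_copy_number: float = 40.0
    chromosome_label: str = "chromosome"
    plasmid_label: str = "plasmid"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", self.chromosome.upper())
        object.__setattr__(self, "plasmid", self.plasmid.upper())
        if not self.chromosome or not self.plasmid:
            raise ValueError("reference sequences must be non-empty")
        _validate_alphabet(self.chromosome, _REF_ALPHABET, "chromosome")
        _validate_alphabet(self.plasmid, _REF_ALPHABET, "plasmid")
        if len(self.plasmid) >= len(self.chromosome):
            raise ValueError(
                "plasmid must be shorter than the chromosome "
                f"({len(self.plasmid)} >= {len(self.chromosome)})"
            )
        if self.plasmid_copy_number <= 0:
            raise ValueError("plasmid_copy_number must be positive")

    def sequence(self, source: str) -> str:
        if source == "chromosome":
            return self.chromosome
        if source == "plasmid":
            return self.plasmid
        raise KeyError(source)

    def is_circular(self, source: str) -> bool:
        return self.chromosome_circular if source == "chromosome" else self.plasmid_circular


@dataclass(frozen=True)
class CrisprArrayModel:
    """What the array parser looks for in an amplicon read.

    ``frame_offset`` is the frame of the spacer's first base relative to
    the reporter start codon; ``atg_window`` is the spacer prefix (bp)
    able to contribute an in-frame ATG.
    """

    repeat: str = DEFAULT_REPEAT
    leader_anchor: str = DEFAULT_LEADER[-20:]
    unit_length: int = 61
    expected_spacer_length: int | None = None
    spacer_length_window: tuple[int, int] | None = None
    atg_window: int = 30
    frame_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "repeat", self.repeat.upper())
        object.__setattr__(self, "leader_anchor", self.leader_anchor.upper())
        _validate_alphabet(self.repeat, _REF_ALPHABET, "repeat")
        _validate_alphabet(self.leader_anchor, _REF_ALPHABET, "leader_anchor")
        if not self.repeat or not self.leader_anchor:
            raise ValueError("repeat and leader_anchor must be non-empty")
        if self.expected_spacer_length is None:
            object.__setattr__(
                self, "expected_spacer_length", self.unit_length - len(self.repeat)
            )
        if self.unit_length != len(self.repeat) + self.expected_spacer_length:
            raise ValueError(
                "unit_length must equal repeat length + expected_spacer_length "
                f"({self.unit_length} != {len(self.repeat)} + {self.expected_spacer_length})"
            )
        if self.expected_spacer_length <= 0:
            raise ValueError("expected_spacer_length must be positive")
        if self.spacer_length_window is None:
            object.__setattr__(
                self,
                "spacer_length_window",
                (self.expected_spacer_length - 3, self.expected_spacer_length + 3),
            )
        lo, hi = self.spacer_length_window
        if not lo <= self.expected_spacer_length <= hi:
            raise ValueError(
                f"spacer_length_window {self.spacer_length_window} does not contain "
                f"expected_spacer_length {self.expected_spacer_length}"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if self.atg_window <= 0:
            raise ValueError("atg_window must be positive")


@dataclass(frozen=True)
class ReadRecord:
    """A basecalled read; qualities are optional and never consumed downstream."""

    id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        _validate_alphabet(self.sequence, _READ_ALPHABET, f"read {self.id!r}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file as ``[(id, uppercased sequence), ...]``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    for rid, seq in records:
        if not seq:
            raise ValueError(f"empty FASTA record {rid!r} in {path}")
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(seqrecords)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate Sanger Phred+33 FASTQ records as :class:`ReadRecord`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield ReadRecord(id=rec.id, sequence=str(rec.seq), qualities=quals)


def write_fastq(path: str | Path, records: Iterable[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.qualities or "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{quals}\n")


def load_references(
    chromosome_fasta: str | Path,
    plasmid_fasta: str | Path,
    chromosome_circular: bool = True,
    plasmid_circular: bool = True,
    plasmid_copy_number: float = 40.0,
) -> ReferenceSet:
    """Load chromosome + plasmid FASTA files into a validated ReferenceSet.

    Multi-record files are concatenation-free: only single-record files are
    accepted, matching the one-replicon-per-file deposit convention.
    """
    chrom = read_fasta(chromosome_fasta)
    plas = read_fasta(plasmid_fasta)
    if len(chrom) != 1 or len(plas) != 1:
        raise ValueError("reference FASTA files must contain exactly one record each")
    return ReferenceSet(
        chromosome=chrom[0][1],
        plasmid=plas[0][1],
        chromosome_circular=chromosome_circular,
        plasmid_circular=plasmid_circular,
        plasmid_copy_number=plasmid_copy_number,
        chromosome_label=chrom[0][0],
        plasmid_label=plas[0][0],
    )
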