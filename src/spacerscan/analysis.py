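"""Hotspot bin maps, source-bias normalization, PAM matrices and saturation.

Two tallies coexist on purpose: source *ratios* use all spacers (with
duplicates), while hotspot maps and PAM matrices use unique spacers only.
The two rules run through separate code paths so they cannot be conflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import revcomp

__all__ = [
    "BinnedCounts",
    "PamMatrix",
    "BiasSummary",
    "bin_hits",
    "plasmid_fraction",
    "molar_excess",
    "neutral_plasmid_share",
    "bias_summary",
    "build_pam_matrix",
    "count_pam_sites",
    "MG1655_GENOME_LENGTH",
    "DEFAULT_PLASMID_LENGTH",
    "DEFAULT_COPY_NUMBER",
]

#: E. coli K-12 MG1655 genome length (U00096.3), the reporter strain's parent.
MG1655_GENOME_LENGTH = 4_641_652
#: Working length of the Cas1-Cas2 expression plasmid (pBAD-derived, kan
#: marker); configurable wherever used.
DEFAULT_PLASMID_LENGTH = 5_300
DEFAULT_COPY_NUMBER = 40.0

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class BinnedCounts:
    """Unique-spacer hit counts per fixed-width bin along one replicon."""

    source: str
    bin_width: int
    length: int
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width


def bin_hits(starts, bin_width: int, length: int, source: str = "") -> BinnedCounts:
    """Assign unique hits to bins by floor(start / bin_width)."""
    if bin_width <= 0 or length <= 0:
        raise ValueError("bin_width and length must be positive")
    starts = np.asarray(list(starts), dtype=np.int64)
    n_bins = math.ceil(length / bin_width)
    if starts.size and (starts.min() < 0 or starts.max() >= length):
        raise ValueError(f"hit start outside [0, {length})")
    counts = np.bincount(starts // bin_width, minlength=n_bins) if starts.size \
        else np.zeros(n_bins, dtype=np.int64)
    return BinnedCounts(source=source, bin_width=bin_width, length=length,
                        counts=counts.astype(np.int64))


def plasmid_fraction(n_chromosome: int, n_plasmid: int) -> float:
    """Plasmid share of mapped spacers; ambiguous/unmapped are excluded upstream."""
    total = n_chromosome + n_plasmid
    if total <= 0:
        raise ValueError("plasmid_fraction undefined: no mapped spacers")
    return n_plasmid / total


def molar_excess(genome_length: float, plasmid_length: float,
                 copy_number: float) -> float:
    """Fold molar excess of chromosomal over total plasmid DNA per cell."""
    if genome_length <= 0 or plasmid_length <= 0 or copy_number <= 0:
        raise ValueError("all molar_excess inputs must be positive")
    return genome_length / (copy_number * plasmid_length)


def neutral_plasmid_share(genome_length: float, plasmid_length: float,
                          copy_number: float) -> float:
    """Expected plasmid share under neutral sampling of available DNA."""
    cp = copy_number * plasmid_length
    if genome_length <= 0 or cp <= 0:
        raise ValueError("all inputs must be positive")
    return cp / (cp + genome_length)


@dataclass
class BiasSummary:
    n_chromosome: int
    n_plasmid: int
    plasmid_fraction: float
    molar_excess: float
    neutral_plasmid_share: float
    bias_index: float  # observed odds / neutral odds; 1.0 = neutral sampling
    degenerate: str = ""  # 'zero' or 'infinite' when the fraction is 0 or 1

    def to_dict(self) -> dict:
        return {
            "n_chromosome": self.n_chromosome,
            "n_plasmid": self.n_plasmid,
            "plasmid_fraction": self.plasmid_fraction,
            "molar_excess": self.molar_excess,
            "neutral_plasmid_share": self.neutral_plasmid_share,
            "bias_index": self.bias_index,
            "degenerate": self.degenerate,
        }


def bias_summary(n_chromosome: int, n_plasmid: int, genome_length: float,
                 plasmid_length: float, copy_number: float) -> BiasSummary:
    f = plasmid_fraction(n_chromosome, n_plasmid)
    s = neutral_plasmid_share(genome_length, plasmid_length, copy_number)
    neutral_odds = s / (1.0 - s)
    if f == 0.0:
        index, flag = 0.0, "zero"
    elif f == 1.0:
        index, flag = math.inf, "infinite"
    else:
        index, flag = (f / (1.0 - f)) / neutral_odds, ""
    return BiasSummary(
        n_chromosome=n_chromosome,
        n_plasmid=n_plasmid,
        plasmid_fraction=f,
        molar_excess=molar_excess(genome_length, plasmid_length, copy_number),
        neutral_plasmid_share=s,
        bias_index=index,
        degenerate=flag,
    )


@dataclass
class PamMatrix:
    """Position-frequency + information-content matrix over PAM windows."""

    counts: np.ndarray  # 4 x W, rows A,C,G,T
    pseudocount: float = 0.0
    frequencies: np.ndarray = field(init=False)
    information_content: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = self.counts.astype(float) + self.pseudocount
        totals = c.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(totals > 0, c / np.where(totals > 0, totals, 1.0), 0.0)
        self.frequencies = freqs
        nz = freqs > 0
        plogp = np.zeros_like(freqs)
        plogp[nz] = freqs[nz] * np.log2(freqs[nz])
        entropy = -plogp.sum(axis=0)
        self.information_content = np.where(totals > 0, 2.0 - entropy, 0.0)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


def build_pam_matrix(pams, pseudocount: float = 0.0) -> PamMatrix:
    """Count matrix over equal-length PAM strings (rows A,C,G,T)."""
    pams = [p.upper() for p in pams]
    if not pams:
        raise ValueError("no PAM strings supplied")
    width = len(pams[0])
    if any(len(p) != width for p in pams):
        raise ValueError("PAM strings must all have equal length")
    counts = np.zeros((4, width), dtype=np.int64)
    for p in pams:
        for j, base in enumerate(p):
            if base in _BASE_INDEX:
                counts[_BASE_INDEX[base], j] += 1
    return PamMatrix(counts=counts, pseudocount=pseudocount)


def _count_overlapping(text: str, motif: str) -> int:
    n, pos = 0, text.find(motif)
    while pos != -1:
        n += 1
        pos = text.find(motif, pos + 1)
    return n


def count_pam_sites(sequence: str, motif: str = "AAG", circular: bool = True,
                    both_strands: bool = True) -> int:
    """Number of (position, strand) occurrences of ``motif``.

    Overlapping occurrences count; circular counting includes occurrences
    spanning the origin.  Both strands are counted by default (minus-strand
    occurrences are occurrences of revcomp(motif) on the forward text).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    sequence = sequence.upper()
    motif = motif.upper()
    text = sequence + sequence[: len(motif) - 1] if circular else sequence
    total = _count_overlapping(text, motif)
    if both_strands:
        total += _count_overlapping(text, revcomp(motif))
    return total
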