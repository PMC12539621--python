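"""Extract newly acquired spacers from amplicon reads.

Reads are first oriented by the leader anchor, repeat copies are then
located by error-tolerant matching, and the segments between adjacent
repeat copies become candidate spacers, filtered by length.  Exact
duplicate spacers are collapsed with counts (case-insensitive, in the
orientation they were extracted — spacers are directional in the array,
so no cross-strand canonicalization is applied).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import align
from .core import CrisprArrayModel, ReadRecord, revcomp

__all__ = [
    "RepeatMatch",
    "ParsedRead",
    "SpacerTally",
    "orient_read",
    "find_repeat_matches",
    "extract_spacers",
    "parse_read",
    "parse_reads",
    "collapse_duplicates",
    "DEFAULT_MAX_EDIT_FRACTION",
]

#: Matching tolerance for anchor and repeat location; chosen so nanopore
#: error is absorbed while random 29-mer false positives stay negligible.
DEFAULT_MAX_EDIT_FRACTION = 0.2


@dataclass(frozen=True)
class RepeatMatch:
    """An approximate repeat occurrence on the oriented read (half-open)."""

    read_id: str
    start: int
    end: int
    edit_distance: int


@dataclass
class ParsedRead:
    read_id: str
    orientation_used: str  # '+' forward, '-' read was reverse-complemented
    repeat_matches: list[RepeatMatch] = field(default_factory=list)
    spacers: list[str] = field(default_factory=list)
    spacer_positions: list[int] = field(default_factory=list)
    parseable: bool = True
    anchor_edit_distance: int | None = None

    @property
    def expansion_count(self) -> int:
        return max(0, len(self.repeat_matches) - 1)


@dataclass
class SpacerTally:
    """spacer sequence -> number of reads contributing that exact sequence."""

    counts: dict[str, int] = field(default_factory=dict)
    unique: list[str] = field(default_factory=list)  # first-seen order

    def add(self, spacer: str) -> None:
        spacer = spacer.upper()
        if spacer not in self.counts:
            self.counts[spacer] = 0
            self.unique.append(spacer)
        self.counts[spacer] += 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _edit_budget(pattern: str, max_edit_fraction: float) -> int:
    return math.ceil(max_edit_fraction * len(pattern))


def orient_read(
    read: ReadRecord,
    model: CrisprArrayModel,
    max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION,
) -> tuple[str, str, int] | None:
    """Orient a read so the leader anchor reads forward.

    Returns ``(oriented_sequence, orientation, anchor_edit_distance)`` where
    orientation is '+' if the read was already leader-forward and '-' if it
    was reverse-complemented.  Ties go to '+'.  Returns None when neither
    orientation matches the anchor within the edit budget (the caller logs
    and counts the read as unparseable).
    """
    anchor = model.leader_anchor
    budget = _edit_budget(anchor, max_edit_fraction)
    seq = read.sequence
    if len(seq) < len(anchor):
        return None
    # exact fast path: an exact hit cannot be beaten, and ties go forward
    if anchor in seq:
        return seq, "+", 0
    rc = revcomp(seq)
    if anchor in rc:
        return rc, "-", 0
    d_fwd = int(align.search_ends(anchor, seq).min())
    d_rev = int(align.search_ends(anchor, rc).min())
    if min(d_fwd, d_rev) > budget:
        return None
    if d_fwd <= d_rev:
        return seq, "+", d_fwd
    return rc, "-", d_rev


def find_repeat_matches(
    oriented: str,
    repeat: str,
    max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION,
    read_id: str = "",
) -> list[RepeatMatch]:
    """All non-overlapping approximate repeat occurrences, sorted by position."""
    budget = _edit_budget(repeat, max_edit_fraction)
    return [
        RepeatMatch(read_id=read_id, start=m.start, end=m.end, edit_distance=m.distance)
        for m in align.find_matches(repeat, oriented, budget)
    ]


def extract_spacers(
    matches: Sequence[RepeatMatch],
    oriented: str,
    model: CrisprArrayModel,
) -> tuple[list[str], list[int]]:
    """Inter-repeat segments passing the spacer length filter, 5'->3'.

    Returns the spacers (leader-proximal first) and their start positions
    on the oriented read.  Overlapping match pairs are skipped.
    """
    lo, hi = model.spacer_length_window
    spacers: list[str] = []
    positions: list[int] = []
    for left, right in zip(matches, matches[1:]):
        if right.start < left.end:  # overlap: malformed pair
            continue
        gap = right.start - left.end
        if lo <= gap <= hi:
            spacers.append(oriented[left.end : right.start])
            positions.append(left.end)
    return spacers, positions


def parse_read(
    read: ReadRecord,
    model: CrisprArrayModel,
    max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION,
) -> ParsedRead:
    oriented = orient_read(read, model, max_edit_fraction)
    if oriented is None:
        return ParsedRead(read_id=read.id, orientation_used="+", parseable=False)
    seq, orientation, anchor_dist = oriented
    matches = find_repeat_matches(seq, model.repeat, max_edit_fraction, read.id)
    spacers, positions = extract_spacers(matches, seq, model)
    return ParsedRead(
        read_id=read.id,
        orientation_used=orientation,
        repeat_matches=matches,
        spacers=spacers,
        spacer_positions=positions,
        anchor_edit_distance=anchor_dist,
    )


def parse_reads(
    reads: Iterable[ReadRecord],
    model: CrisprArrayModel,
    max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION,
) -> tuple[list[ParsedRead], dict[str, int]]:
    """Parse a read set, returning parsed reads plus stage counters."""
    parsed: list[ParsedRead] = []
    counters = Counter(total_reads=0, unparseable=0, parental=0, expanded=0, spacers=0)
    for read in reads:
        p = parse_read(read, model, max_edit_fraction)
        parsed.append(p)
        counters["total_reads"] += 1
        if not p.parseable:
            counters["unparseable"] += 1
        elif p.spacers:
            counters["expanded"] += 1
            counters["spacers"] += len(p.spacers)
        else:
            counters["parental"] += 1
    return parsed, dict(counters)


def collapse_duplicates(spacers: Iterable[str]) -> SpacerTally:
    """Tally exact duplicate spacers (case-insensitive)."""
    tally = SpacerTally()
    for s in spacers:
        tally.add(s)
    return tally
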