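"""Map spacers to protospacer loci on the chromosome or plasmid.

Best hit across both replicons and both strands, with circular wrap.
Exact substring hits are taken first (they cannot be beaten); otherwise a
full edit-distance scan finds the minimum-distance site.  Equal-best hits
on both replicons make a spacer ``ambiguous``; equal-best hits within one
replicon resolve to the lowest (source, start) with the multiplicity
recorded.  Coordinates are 0-based forward-strand; ``start`` is always on
the forward strand regardless of hit strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import align
from .core import CrisprArrayModel, ReferenceSet, circular_window, revcomp

__all__ = [
    "ProtospacerHit",
    "SpacerMapper",
    "map_spacer",
    "extract_pam",
    "classify_sources",
    "DEFAULT_MAX_EDITS",
]

#: Edit tolerance for mapping extracted spacers; absorbs residual read
#: errors in short spacers while keeping spurious genome hits rare.
DEFAULT_MAX_EDITS = 2

SOURCES = ("chromosome", "plasmid")
CATEGORIES = ("chromosome", "plasmid", "ambiguous", "unmapped")


@dataclass(frozen=True)
class ProtospacerHit:
    spacer: str
    source: str  # chromosome | plasmid | ambiguous | unmapped
    start: int = -1  # 0-based forward strand; -1 when unmapped/ambiguous
    strand: str = "."
    length: int = 0  # reference bases covered by the alignment
    edit_distance: int = -1
    pam: str = ""
    n_equal_best: int = 0  # multiplicity of equal-best placements

    @property
    def mapped(self) -> bool:
        return self.source in SOURCES

    @property
    def end(self) -> int:
        return self.start + self.length if self.mapped else -1


class SpacerMapper:
    """Caches wrapped/encoded reference texts for repeated mapping calls."""

    def __init__(self, refs: ReferenceSet, max_edits: int = DEFAULT_MAX_EDITS,
                 wrap: int = 63):
        self.refs = refs
        self.max_edits = max_edits
        self._texts: dict[tuple[str, str], str] = {}
        self._codes: dict[tuple[str, str], np.ndarray] = {}
        for source in SOURCES:
            seq = refs.sequence(source)
            ov = min(wrap, len(seq) - 1) if refs.is_circular(source) else 0
            fwd = seq + seq[:ov]
            rc = revcomp(seq)
            rcw = rc + rc[:ov]
            self._texts[(source, "+")] = fwd
            self._texts[(source, "-")] = rcw
            self._codes[(source, "+")] = align.encode(fwd)
            self._codes[(source, "-")] = align.encode(rcw)

    def _to_forward(self, source: str, strand: str, start: int, length: int) -> int:
        """Convert a scanned-text start to a forward-strand start (mod L)."""
        n = len(self.refs.sequence(source))
        if strand == "+":
            return start % n
        return (n - (start + length)) % n

    def _exact_hits(self, spacer: str) -> list[tuple[str, str, int, int]]:
        hits = []
        m = len(spacer)
        for (source, strand), text in self._texts.items():
            n = len(self.refs.sequence(source))
            pos = text.find(spacer)
            while pos != -1:
                if pos < n:  # matches starting in the wrap duplicate earlier ones
                    hits.append((source, strand, pos, m))
                pos = text.find(spacer, pos + 1)
        return hits

    def _scan_hits(self, spacer: str) -> tuple[int, list[tuple[str, str, int, int]]]:
        pat = align.encode(spacer)
        per_key: dict[tuple[str, str], np.ndarray] = {}
        best = len(spacer) + 1
        for key, codes in self._codes.items():
            ends = align.search_ends(pat, codes)
            per_key[key] = ends
            best = min(best, int(ends.min()))
        if best > self.max_edits:
            return best, []
        hits = []
        for (source, strand), ends in per_key.items():
            n = len(self.refs.sequence(source))
            for j in np.nonzero(ends == best)[0]:
                j = int(j)
                start = align._locate_start(pat, self._codes[(source, strand)], j + 1, best)
                if start < n:
                    hits.append((source, strand, start, j + 1 - start))
        return best, hits

    def map(self, spacer: str) -> ProtospacerHit:
        spacer = spacer.upper()
        hits = self._exact_hits(spacer)
        dist = 0
        if not hits:
            dist, hits = self._scan_hits(spacer)
            if not hits:
                return ProtospacerHit(spacer=spacer, source="unmapped")
        # normalize to forward-strand coordinates and deduplicate
        placements = sorted(
            {
                (source, self._to_forward(source, strand, start, length), strand, length)
                for source, strand, start, length in hits
            }
        )
        sources_hit = {p[0] for p in placements}
        if len(sources_hit) > 1:
            return ProtospacerHit(
                spacer=spacer, source="ambiguous", edit_distance=dist,
                n_equal_best=len(placements),
            )
        source, start, strand, length = placements[0]
        return ProtospacerHit(
            spacer=spacer, source=source, start=start, strand=strand,
            length=length, edit_distance=dist, n_equal_best=len(placements),
        )


def map_spacer(spacer: str, refs: ReferenceSet,
               max_edits: int = DEFAULT_MAX_EDITS) -> ProtospacerHit:
    """Map a single spacer (convenience wrapper around :class:`SpacerMapper`)."""
    return SpacerMapper(refs, max_edits=max_edits).map(spacer)


def pam_window(seq: str, start: int, length: int, strand: str, circular: bool,
               offset: int = -2, width: int = 3) -> str:
    """PAM window 5'->3' on the protospacer strand.

    ``offset`` is the window's first position relative to the protospacer
    start on its own strand (default -2) and ``width`` its length (default
    3, i.e. two upstream bases plus the first protospacer base).
    """
    if strand == "+":
        return circular_window(seq, start + offset, width, "+", circular)
    fwd_start = start + length - offset - width
    return circular_window(seq, fwd_start, width, "-", circular)


def extract_pam(hit: ProtospacerHit, refs: ReferenceSet,
                model: CrisprArrayModel | None = None,
                offset: int = -2, width: int = 3) -> str:
    """PAM for a mapped hit; raises on unmapped/ambiguous hits."""
    if not hit.mapped:
        raise ValueError(f"cannot extract PAM from {hit.source} hit")
    seq = refs.sequence(hit.source)
    return pam_window(
        seq, hit.start, hit.length, hit.strand,
        refs.is_circular(hit.source), offset=offset, width=width,
    )


def classify_sources(hits) -> dict[str, int]:
    """Per-category counts; total is conserved across the four categories."""
    counts = Counter({c: 0 for c in CATEGORIES})
    for h in hits:
        counts[h.source] += 1
    return dict(counts)
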