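"""Bit-parallel approximate string matching (Myers 1999, semi-global).

The search variant is used throughout: the pattern may start anywhere in
the text (first DP row all zeros) and the per-position output is the best
edit distance of any alignment ending at that text position.  Patterns are
limited to 63 symbols, which covers anchors, repeats and spacers.

N (code 4) never matches anything, in pattern or text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["Match", "encode", "search_ends", "best_match", "find_matches"]

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _build_peq(pattern_codes: np.ndarray) -> np.ndarray:
    m = pattern_codes.shape[0]
    peq = np.zeros(5, dtype=np.uint64)
    for i in range(m):
        c = pattern_codes[i]
        if c < 4:  # N in the pattern matches nothing
            peq[c] |= np.uint64(1) << np.uint64(i)
    return peq


def _ends_py(peq: np.ndarray, text: np.ndarray, m: int) -> np.ndarray:
    full = (1 << m) - 1
    hibit = 1 << (m - 1)
    peq_int = [int(x) for x in peq]
    pv, mv, score = full, 0, m
    out = np.empty(text.shape[0], dtype=np.int32)
    for i in range(text.shape[0]):
        eq = peq_int[text[i]]
        xv = eq | mv
        xh = (((eq & pv) + pv) ^ pv) | eq
        ph = mv | (~(xh | pv) & full)
        mh = pv & xh
        if ph & hibit:
            score += 1
        elif mh & hibit:
            score -= 1
        ph = (ph << 1) & full
        mh = (mh << 1) & full
        pv = mh | (~(xv | ph) & full)
        mv = ph & xv
        out[i] = score
    return out


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _ends_nb(peq, text, m, out):  # pragma: no cover - compiled
        one = np.uint64(1)
        hibit = one << np.uint64(m - 1)
        zero = np.uint64(0)
        full = ((one << np.uint64(m)) - one) if m < 64 else ~zero
        pv = full
        mv = zero
        score = m
        for i in range(text.shape[0]):
            eq = peq[text[i]]
            xv = eq | mv
            xh = (((eq & pv) + pv) ^ pv) | eq
            ph = mv | ~(xh | pv)
            mh = pv & xh
            if ph & hibit:
                score += 1
            elif mh & hibit:
                score -= 1
            ph = ph << one
            mh = mh << one
            pv = mh | ~(xv | ph)
            mv = ph & xv
            out[i] = score


def search_ends(pattern: str | np.ndarray, text: str | np.ndarray) -> np.ndarray:
    """Best edit distance of ``pattern`` against every end position of ``text``.

    ``out[j]`` is the minimum edit distance over alignments of the full
    pattern ending at text position j (inclusive).
    """
    pat = encode(pattern) if isinstance(pattern, str) else pattern
    txt = encode(text) if isinstance(text, str) else text
    m = pat.shape[0]
    if not 0 < m <= 63:
        raise ValueError(f"pattern length must be in [1, 63], got {m}")
    if txt.shape[0] == 0:
        return np.empty(0, dtype=np.int32)
    peq = _build_peq(pat)
    if _HAVE_NUMBA:
        out = np.empty(txt.shape[0], dtype=np.int32)
        _ends_nb(peq, txt, m, out)
        return out
    return _ends_py(peq, txt, m)


@dataclass(frozen=True)
class Match:
    """An approximate occurrence: 0-based half-open interval on the text."""

    start: int
    end: int
    distance: int


def _locate_start(pat: np.ndarray, txt: np.ndarray, end: int, dist: int) -> int:
    """Find the start of an alignment of ``pat`` ending at ``end`` (exclusive)
    with edit distance ``dist``, preferring lengths closest to len(pat)."""
    m = pat.shape[0]
    lo = max(0, end - m - dist)
    window = txt[lo:end][::-1]
    rev = search_ends(pat[::-1], window)
    best = int(rev.min())
    lengths = np.nonzero(rev == best)[0] + 1  # candidate match lengths
    length = int(lengths[np.argmin(np.abs(lengths - m))])
    return end - length


def best_match(pattern: str | np.ndarray, text: str | np.ndarray,
               max_distance: int | None = None) -> Match | None:
    """Best single occurrence of pattern in text, or None above threshold."""
    pat = encode(pattern) if isinstance(pattern, str) else pattern
    txt = encode(text) if isinstance(text, str) else text
    if txt.shape[0] == 0:
        return None
    ends = search_ends(pat, txt)
    j = int(np.argmin(ends))
    d = int(ends[j])
    if max_distance is not None and d > max_distance:
        return None
    start = _locate_start(pat, txt, j + 1, d)
    return Match(start=start, end=j + 1, distance=d)


def find_matches(pattern: str | np.ndarray, text: str | np.ndarray,
                 max_distance: int) -> list[Match]:
    """All non-overlapping approximate occurrences within ``max_distance``.

    Candidate end positions are every position at or under the threshold;
    matches are then selected greedily by (distance, start position), each
    selection suppressing overlapping candidates.  Returned sorted by start.
    """
    pat = encode(pattern) if isinstance(pattern, str) else pattern
    txt = encode(text) if isinstance(text, str) else text
    if txt.shape[0] == 0:
        return []
    ends = search_ends(pat, txt)
    candidates = []
    idxs = np.nonzero(ends <= max_distance)[0]
    for j in idxs:
        j = int(j)
        # keep only local minima to bound the number of start look-ups
        if j > 0 and ends[j - 1] < ends[j]:
            continue
        if j + 1 < ends.shape[0] and ends[j + 1] < ends[j]:
            continue
        if j > 0 and ends[j - 1] == ends[j]:  # leftmost point of a plateau
            continue
        d = int(ends[j])
        start = _locate_start(pat, txt, j + 1, d)
        candidates.append(Match(start=start, end=j + 1, distance=d))
    selected: list[Match] = []
    for cand in sorted(candidates, key=lambda c: (c.distance, c.start)):
        if all(cand.end <= s.start or cand.start >= s.end for s in selected):
            selected.append(cand)
    selected.sort(key=lambda c: c.start)
    return selected
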