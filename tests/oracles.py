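"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations (quadratic DP, exhaustive
enumeration, rotation scans) kept separate from the package code paths
they check.
"""

from __future__ import annotations

import itertools


def levenshtein(a: str, b: str) -> int:
    """Classic quadratic-DP edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (0 if ca == cb and ca != "N" else 1),
            ))
        prev = cur
    return prev[-1]


def semiglobal_ends(pattern: str, text: str) -> list[int]:
    """DP oracle: best edit distance of pattern vs any substring of text
    ending at each position (first row free)."""
    m = len(pattern)
    col = list(range(m + 1))
    out = []
    for cb in text:
        new = [0]
        for i, ca in enumerate(pattern, 1):
            new.append(min(
                col[i] + 1,
                new[i - 1] + 1,
                col[i - 1] + (0 if ca == cb and ca != "N" else 1),
            ))
        col = new
        out.append(col[m])
    return out


def best_occurrence(pattern: str, text: str) -> tuple[int, int, int]:
    """(distance, start, end) of the best substring match, brute force over
    all substrings (O(n^2 m)); ties resolved to length closest to m then
    leftmost end."""
    best = (len(pattern) + len(text), -1, -1)
    for end in range(1, len(text) + 1):
        for start in range(end):
            d = levenshtein(pattern, text[start:end])
            key = (d, abs((end - start) - len(pattern)), end, start)
            cur_key = (best[0], abs((best[2] - best[1]) - len(pattern)), best[2], best[1])
            if key < cur_key:
                best = (d, start, end)
    return best


STOPS = {"TAA", "TAG", "TGA"}
CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


def enumerate_frame_probs(k: int) -> tuple[float, float]:
    """Exhaustive enumeration over all 64**k codon sequences.

    Returns (P(no stop codon), P(some ATG with no stop after it)).
    """
    n_total = 64**k
    n_no_stop = 0
    n_atg_ok = 0
    for seq in itertools.product(CODONS, repeat=k):
        live = False
        stopped = False
        for codon in seq:
            if codon == "ATG":
                live = True
            elif codon in STOPS:
                live = False
                stopped = True
        if not stopped:
            n_no_stop += 1
        if live:
            n_atg_ok += 1
    return n_no_stop / n_total, n_atg_ok / n_total


def count_motif_rotations(sequence: str, motif: str, circular: bool,
                          both_strands: bool) -> int:
    """Rotation-scan oracle for motif counting."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(motif))
    motifs = [motif, rc] if both_strands else [motif]
    n = 0
    L = len(sequence)
    starts = range(L) if circular else range(L - len(motif) + 1)
    for target in motifs:
        for s in starts:
            window = "".join(sequence[(s + i) % L] for i in range(len(target)))
            if window == target:
                n += 1
    return n
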