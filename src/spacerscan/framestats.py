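"""Reading-frame analytics for the papillation reporter.

A newly inserted 61 bp repeat-spacer unit restores the reporter's frame;
whether the fusion is expressed depends on the spacer's in-frame codon
content.  Under a uniform base model over k in-frame codons:

* probability of no in-frame stop (detection limit): (61/64)^k
* probability of an in-frame ATG with no later in-frame stop:
  (1/4) * (1 - (60/64)^k)

both of which are matched by exhaustive enumeration and Monte-Carlo in the
test suite.  The second follows from scanning codons right to left: the
first codon from the right that is ATG or a stop must be an ATG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "STOP_CODONS",
    "FrameAnnotation",
    "DuplicationBin",
    "TrendResult",
    "p_inframe_atg_no_stop",
    "p_no_inframe_stop",
    "annotate_frame",
    "atg_fraction_by_duplication",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def _check_k(k: int) -> None:
    if k < 0:
        raise ValueError(f"codon count must be non-negative, got {k}")


def p_no_inframe_stop(k: int) -> float:
    """Probability that k uniform random codons contain no stop codon."""
    _check_k(k)
    return (61.0 / 64.0) ** k


def p_inframe_atg_no_stop(k: int) -> float:
    """Probability that k uniform random codons contain an ATG with no
    stop codon at any later codon position."""
    _check_k(k)
    return 0.25 * (1.0 - (60.0 / 64.0) ** k)


@dataclass(frozen=True)
class FrameAnnotation:
    spacer: str
    has_inframe_atg: bool
    has_inframe_stop: bool
    codon_count: int
    truncated: bool = False  # spacer shorter than the ATG window
    ambiguous_codons: int = 0  # codons skipped for non-ACGT symbols


def annotate_frame(spacer: str, atg_window: int = 30,
                   frame_offset: int = 0) -> FrameAnnotation:
    """Deterministic in-frame ATG/stop annotation of a spacer prefix.

    Codons are read at positions frame_offset, frame_offset+3, ... within
    the first ``atg_window`` bp (or the whole spacer if shorter, flagged
    ``truncated``).  ``has_inframe_atg`` is True iff some in-frame ATG has
    no in-frame stop after it inside the window.
    """
    spacer = spacer.upper()
    limit = min(len(spacer), atg_window)
    truncated = len(spacer) < atg_window
    atg_live = False
    has_stop = False
    skipped = 0
    count = 0
    pos = frame_offset
    while pos + 3 <= limit:
        codon = spacer[pos : pos + 3]
        pos += 3
        count += 1
        if any(b not in "ACGT" for b in codon):
            skipped += 1
            continue
        if codon == "ATG":
            atg_live = True
        elif codon in STOP_CODONS:
            atg_live = False  # a stop kills every ATG before it
            has_stop = True
    return FrameAnnotation(
        spacer=spacer,
        has_inframe_atg=atg_live,
        has_inframe_stop=has_stop,
        codon_count=count,
        truncated=truncated,
        ambiguous_codons=skipped,
    )


@dataclass(frozen=True)
class DuplicationBin:
    duplication_count: int
    n_spacers: int
    atg_fraction: float


@dataclass(frozen=True)
class TrendResult:
    """Weighted rank correlation between duplication count and ATG fraction,
    with a permutation p-value (annotations permuted against counts)."""

    statistic: float
    p_value: float
    n_permutations: int


def _weighted_rank_corr(rx: np.ndarray, ry: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx = (w * rx).sum()
    my = (w * ry).sum()
    cov = (w * (rx - mx) * (ry - my)).sum()
    vx = (w * (rx - mx) ** 2).sum()
    vy = (w * (ry - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def atg_fraction_by_duplication(
    tally: dict[str, int],
    annotations: dict[str, FrameAnnotation],
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> tuple[list[DuplicationBin], TrendResult]:
    """Group unique spacers by duplication count and test the ATG trend.

    One bin per observed duplication count.  The trend statistic is the
    rank correlation between duplication count and per-bin ATG fraction,
    weighted by bin size; its one-sided p-value comes from permuting the
    per-spacer annotations against the counts.
    """
    if not tally:
        return [], TrendResult(statistic=float("nan"), p_value=1.0,
                               n_permutations=0)
    spacers = list(tally.keys())
    missing = [s for s in spacers if s not in annotations]
    if missing:
        raise ValueError(f"{len(missing)} tallied spacers lack annotations")
    dups = np.array([tally[s] for s in spacers], dtype=np.int64)
    atg = np.array([annotations[s].has_inframe_atg for s in spacers], dtype=float)

    levels, inverse = np.unique(dups, return_inverse=True)
    n_bins = levels.shape[0]
    sizes = np.bincount(inverse, minlength=n_bins).astype(float)
    fractions = np.bincount(inverse, weights=atg, minlength=n_bins) / sizes
    bins = [
        DuplicationBin(int(levels[i]), int(sizes[i]), float(fractions[i]))
        for i in range(n_bins)
    ]

    rx = rankdata(levels)
    observed = _weighted_rank_corr(rx, rankdata(fractions), sizes)
    if n_bins < 2 or n_permutations <= 0:
        return bins, TrendResult(statistic=observed, p_value=1.0, n_permutations=0)

    rng = np.random.default_rng(seed)
    # vectorized permutation null: B (bins x spacers) indicator, columns of
    # L are permuted annotation vectors
    indicator = np.zeros((n_bins, dups.shape[0]))
    indicator[inverse, np.arange(dups.shape[0])] = 1.0
    perms = rng.permuted(
        np.tile(atg[:, None], (1, n_permutations)), axis=0
    )
    perm_fracs = (indicator @ perms) / sizes[:, None]
    perm_ranks = rankdata(perm_fracs, axis=0)
    w = sizes / sizes.sum()
    mx = (w * rx).sum()
    rxc = rx - mx
    vx = (w * rxc**2).sum()
    my = (w[:, None] * perm_ranks).sum(axis=0)
    ryc = perm_ranks - my[None, :]
    cov = (w[:, None] * rxc[:, None] * ryc).sum(axis=0)
    vy = (w[:, None] * ryc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stats = np.where((vx > 0) & (vy > 0), cov / np.sqrt(vx * vy), 0.0)
    p = (1.0 + np.sum(stats >= observed - 1e-12)) / (1.0 + n_permutations)
    return bins, TrendResult(statistic=observed, p_value=float(p),
                             n_permutations=n_permutations)
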