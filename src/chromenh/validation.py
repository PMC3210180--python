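"""Cross-validated ROC analysis of the training profile.

The anchor set is split into 10 folds; for each fold a profile is
trained on the remaining nine and used to score (a) the held-out anchor
windows (true positives) and (b) an equal number of random genomic
windows (false positives).  Pooled score lists are turned into an ROC
curve by counting, at thresholds spaced every 0.02 from 1 down to -1,
the fraction of scores at or above the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import ConfigurationError, GenomicInterval, TagCollection
from .profile import build_training_profile
from .scanner import _ProfileScorer
from .profile import bin_tags

logger = logging.getLogger(__name__)

__all__ = ["RocCurve", "make_folds", "crossval_scores", "roc_points", "auc"]


@dataclass
class RocCurve:
    """An ROC polyline from (0,0) to (1,1) with the threshold step used."""

    points: list[tuple[float, float]]
    interval: float
    n_true: int
    n_false: int

    def __post_init__(self) -> None:
        pts = self.points
        if pts[0] != (0.0, 0.0) or pts[-1] != (1.0, 1.0):
            raise ValueError("curve must start at (0,0) and end at (1,1)")
        fprs = [p[0] for p in pts]
        tprs = [p[1] for p in pts]
        if any(b < a for a, b in zip(fprs, fprs[1:])):
            raise ValueError("FPR must be non-decreasing")
        if any(b < a for a, b in zip(tprs, tprs[1:])):
            raise ValueError("TPR must be non-decreasing")
        if min(fprs) < 0 or max(fprs) > 1 or min(tprs) < 0 or max(tprs) > 1:
            raise ValueError("rates must lie in [0, 1]")


def make_folds(n_items: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Split ``range(n_items)`` into ``k`` disjoint shuffled folds.

    Fold sizes differ by at most one (the first ``n_items % k`` folds
    get the extra item); e.g. 137 items in 10 folds gives seven folds of
    14 and three of 13.
    """
    if n_items < k:
        raise ConfigurationError(f"cannot make {k} folds from {n_items} items")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    base, extra = divmod(n_items, k)
    folds = []
    pos = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(np.sort(perm[pos : pos + size]))
        pos += size
    return folds


def _random_windows(
    genome: Mapping[str, int],
    n: int,
    window_size: int,
    rng: np.random.Generator,
    exclude: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Uniform random windows proportional to chromosome length.

    Windows colliding with any excluded interval are resampled (logged).
    """
    chroms = [c for c, L in genome.items() if L >= window_size]
    if not chroms:
        raise ConfigurationError("no chromosome can hold a window")
    lengths = np.array([genome[c] - window_size + 1 for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    out: list[GenomicInterval] = []
    resampled = 0
    while len(out) < n:
        c = chroms[int(rng.choice(len(chroms), p=probs))]
        start = int(rng.integers(0, genome[c] - window_size + 1))
        w = GenomicInterval(c, start, start + window_size)
        if any(w.overlaps(e) for e in exclude):
            resampled += 1
            continue
        out.append(w)
    if resampled:
        logger.debug("resampled %d random windows colliding with anchors", resampled)
    return out


def crossval_scores(
    anchors: Sequence[GenomicInterval],
    positive_marks: Sequence[TagCollection],
    genome: Mapping[str, int],
    seed: int = 0,
    k: int = 10,
    window_size: int = 10_000,
    bin_size: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled held-out and random-window profile scores over k folds.

    For each fold, the profile trained on the other folds scores every
    held-out anchor window and an equal number of seeded random windows
    (excluding all anchor windows).  Both returned arrays have one entry
    per anchor.
    """
    anchors = list(anchors)
    folds = make_folds(len(anchors), k=k, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    half = window_size // 2
    exclude = []
    for a in anchors:
        c = a.midpoint
        if c - half >= 0 and c + half <= genome[a.chrom]:
            exclude.append(GenomicInterval(a.chrom, c - half, c + half))
    true_scores: list[float] = []
    false_scores: list[float] = []
    for fold in folds:
        held = [anchors[i] for i in fold]
        rest = [a for j, a in enumerate(anchors) if j not in set(fold.tolist())]
        training = build_training_profile(
            rest, positive_marks, window_size=window_size, bin_size=bin_size
        )
        scorer = _ProfileScorer(training)

        def _score_window(w: GenomicInterval) -> float:
            test = np.stack(
                [bin_tags(tc, w, bin_size) for tc in positive_marks]
            )
            return scorer.score(test)

        held_windows = []
        for a in held:
            c = a.midpoint
            if c - half < 0 or c + half > genome[a.chrom]:
                continue
            held_windows.append(GenomicInterval(a.chrom, c - half, c + half))
        randoms = _random_windows(genome, len(held_windows), window_size, rng, exclude)
        true_scores.extend(_score_window(w) for w in held_windows)
        false_scores.extend(_score_window(w) for w in randoms)
    return np.asarray(true_scores), np.asarray(false_scores)


def roc_points(
    true_scores: Sequence[float],
    false_scores: Sequence[float],
    interval: float = 0.02,
) -> RocCurve:
    """ROC curve from pooled score lists at fixed threshold spacing.

    For thresholds c = 1.0, 1.0 - interval, ..., -1.0 the true- and
    false-positive rates are the fractions of scores >= c; the polyline
    is closed with (0,0) and (1,1).
    """
    t = np.asarray(true_scores, dtype=float)
    f = np.asarray(false_scores, dtype=float)
    if t.size == 0 or f.size == 0:
        raise ConfigurationError("score lists must be non-empty")
    n_steps = int(round(2.0 / interval))
    thresholds = 1.0 - interval * np.arange(n_steps + 1)
    pts = [(0.0, 0.0)]
    for c in thresholds:
        fpr = float(np.mean(f >= c))
        tpr = float(np.mean(t >= c))
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    # enforce monotone closure against floating threshold jitter
    cleaned = [pts[0]]
    for p in pts[1:]:
        prev = cleaned[-1]
        cleaned.append((max(p[0], prev[0]), max(p[1], prev[1])))
    return RocCurve(points=cleaned, interval=interval,
                    n_true=int(t.size), n_false=int(f.size))


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC polyline."""
    fpr = np.array([p[0] for p in curve.points])
    tpr = np.array([p[1] for p in curve.points])
    return float(np.trapezoid(tpr, fpr))
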