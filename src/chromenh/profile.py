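"""Training-profile construction from anchor sites.

The enhancer chromatin signature is learned from anchor sites (p300-like
binding sites): each anchor gets a 10-kb window centered on its
midpoint, divided into 100 bins of 100 bp; per-mark tag counts are
summed across anchors into a 5 x 100 training profile.  Anchors are
admitted only if significantly tag-enriched (Poisson test against the
genomic background rate, Bonferroni-corrected) for every
enhancer-positive mark and for none of the enhancer-negative marks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import ConfigurationError, GenomicInterval, TagCollection
from .stats import poisson_sf

logger = logging.getLogger(__name__)

__all__ = [
    "POSITIVE_MARKS",
    "DEFAULT_NEGATIVE_MARKS",
    "BinnedWindow",
    "ChromatinProfile",
    "bin_tags",
    "mark_enrichment",
    "select_anchors",
    "build_training_profile",
    "centered_window",
]

#: the five enhancer-characteristic histone modifications, in canonical order
POSITIVE_MARKS = ("H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac", "H3K27ac")

#: enhancer-negative control modifications (configurable everywhere it matters)
DEFAULT_NEGATIVE_MARKS = ("H3K27me3", "H3K36me3", "H4K20me1")


@dataclass(frozen=True)
class BinnedWindow:
    """Per-mark binned tag counts over one anchor's window."""

    anchor: GenomicInterval
    window: GenomicInterval
    counts: dict[str, np.ndarray]


@dataclass
class ChromatinProfile:
    """Summed per-mark tag-count vectors over the training anchors."""

    marks: tuple[str, ...]
    vectors: np.ndarray  # (n_marks, n_bins)
    n_anchors: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.marks):
            raise ValueError("one vector per mark required")
        if np.any(self.vectors < 0):
            raise ValueError("profile counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.vectors.shape[1])

    def to_table(self, path: str) -> None:
        """Serialize as a tab-delimited marks x bins matrix with header."""
        with open(path, "w") as fh:
            fh.write("mark\t" + "\t".join(f"bin{i}" for i in range(self.n_bins)) + "\n")
            for mark, vec in zip(self.marks, self.vectors):
                fh.write(mark + "\t" + "\t".join(f"{v:.10g}" for v in vec) + "\n")

    @classmethod
    def from_table(cls, path: str) -> "ChromatinProfile":
        marks: list[str] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                marks.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        return cls(marks=tuple(marks), vectors=np.asarray(rows), n_anchors=0)


def centered_window(
    anchor: GenomicInterval, window_size: int = 10_000
) -> GenomicInterval:
    """The ``window_size`` span centered on the anchor midpoint."""
    c = anchor.midpoint
    start = c - window_size // 2
    return GenomicInterval(anchor.chrom, start, start + window_size)


def bin_tags(
    tags: TagCollection, window: GenomicInterval, bin_size: int = 100
) -> np.ndarray:
    """Count tag midpoints per ``bin_size`` bin across ``window``.

    A midpoint ``m`` falls in bin ``floor((m - window.start) / bin_size)``;
    midpoints outside the window are ignored.
    """
    length = len(window)
    if bin_size <= 0 or length % bin_size:
        raise ConfigurationError(
            f"bin size {bin_size} does not divide window length {length}"
        )
    n_bins = length // bin_size
    mids = tags.midpoints(window.chrom)
    edges = window.start + bin_size * np.arange(n_bins + 1, dtype=np.int64)
    idx = np.searchsorted(mids, edges, side="left")
    return np.diff(idx).astype(np.int64)


def mark_enrichment(
    tags: TagCollection, window: GenomicInterval, alpha_corrected: float
) -> tuple[float, bool]:
    """Poisson enrichment of a window against the genomic background.

    p = P(X >= observed) with X ~ Poisson(lambda0 * window length); the
    window is enriched when p <= the (already corrected) alpha.  An
    empty collection has no background rate: p is ``nan`` and the window
    is never enriched.
    """
    lam = tags.lambda0 * len(window)
    if lam <= 0:
        return float("nan"), False
    p = poisson_sf(tags.count_in(window), lam)
    return p, p <= alpha_corrected


def select_anchors(
    candidates: Sequence[GenomicInterval],
    positive_marks: Sequence[TagCollection],
    negative_marks: Sequence[TagCollection] = (),
    alpha: float = 0.05,
    window_size: int = 10_000,
) -> list[GenomicInterval]:
    """Keep candidates enriched in all positive and no negative marks.

    The Bonferroni-corrected threshold is
    ``alpha / (len(candidates) * total marks tested)``; "not enriched"
    for a negative mark means its p-value exceeds that same threshold.
    Candidate order is preserved.
    """
    if not candidates:
        raise ConfigurationError("no candidate anchor sites supplied")
    n_tests = len(candidates) * (len(positive_marks) + len(negative_marks))
    alpha_corr = alpha / n_tests
    selected = []
    for cand in candidates:
        window = centered_window(cand, window_size)
        ok = all(
            mark_enrichment(tc, window, alpha_corr)[1] for tc in positive_marks
        ) and not any(
            mark_enrichment(tc, window, alpha_corr)[1] for tc in negative_marks
        )
        if ok:
            selected.append(cand)
    if not selected:
        logger.warning(
            "no candidate passed anchor selection (%d tested); "
            "downstream training will refuse to run",
            len(candidates),
        )
    return selected


def build_training_profile(
    anchors: Sequence[GenomicInterval],
    positive_marks: Sequence[TagCollection],
    window_size: int = 10_000,
    bin_size: int = 100,
) -> ChromatinProfile:
    """Sum per-anchor binned windows into the training profile.

    Anchors whose centered window would overhang a chromosome edge are
    dropped (with a logged count) so that every summed window keeps the
    full bin geometry.
    """
    if not anchors:
        raise ConfigurationError("cannot train on an empty anchor list")
    marks = tuple(tc.mark for tc in positive_marks)
    n_bins = window_size // bin_size
    vectors = np.zeros((len(marks), n_bins))
    used = 0
    dropped = 0
    for anchor in anchors:
        c = anchor.midpoint
        start = c - window_size // 2
        chrom_len = positive_marks[0].genome.get(anchor.chrom)
        if chrom_len is None or start < 0 or start + window_size > chrom_len:
            dropped += 1
            continue
        window = GenomicInterval(anchor.chrom, start, start + window_size)
        for i, tc in enumerate(positive_marks):
            vectors[i] += bin_tags(tc, window, bin_size)
        used += 1
    if dropped:
        logger.warning("dropped %d anchors with out-of-bounds windows", dropped)
    if used == 0:
        raise ConfigurationError("no anchor window fits inside the genome")
    return ChromatinProfile(marks=marks, vectors=vectors, n_anchors=used)
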