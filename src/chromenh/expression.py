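"""Linking enhancer calls to gene expression.

Overlapping co-directional transcripts are merged into transcriptional
units (TUs); enhancer anchors are counted inside a 100-kb window around
each TU's TSS; and the counts are related to expression three ways:
mean expression binned by enhancer count within a cell type,
count asymmetry at differentially expressed genes between cell types
(Wilcoxon signed-rank), and expression divergence vs normalized count
difference across divergence deciles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import (
    ConfigurationError,
    ExpressionMatrix,
    GenomicInterval,
    Transcript,
)
from .scanner import EnhancerCall
from .stats import TestResult, oneway_anova, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptionalUnit",
    "GeneEnhancerRecord",
    "build_units",
    "probe_to_unit_expression",
    "count_enhancers_near_tss",
    "attach_expression",
    "expression_by_count",
    "differential_genes",
    "enhancer_asymmetry",
    "divergence_deciles",
]


@dataclass(frozen=True)
class TranscriptionalUnit:
    """Merged span of overlapping co-directional transcripts."""

    id: str
    interval: GenomicInterval
    member_ids: tuple[str, ...]

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass
class GeneEnhancerRecord:
    """Per-TU enhancer counts and mean expression, keyed by cell type."""

    unit: TranscriptionalUnit
    n_enh: dict[str, int] = field(default_factory=dict)
    mean_expr: dict[str, float] = field(default_factory=dict)


def build_units(transcripts: Sequence[Transcript]) -> list[TranscriptionalUnit]:
    """Merge same-strand overlapping transcripts transitively into TUs.

    TU boundaries are the outermost transcript start and end; opposite
    strands never merge.  Units are returned sorted by coordinate with
    deterministic ids ``TU_0000``, ``TU_0001``, ...
    """
    units: list[TranscriptionalUnit] = []
    merged: list[tuple[GenomicInterval, list[str]]] = []
    for strand in ("+", "-"):
        group = sorted(
            (t for t in transcripts if t.interval.strand == strand),
            key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end),
        )
        current: tuple[str, int, int, list[str]] | None = None
        for t in group:
            iv = t.interval
            if (
                current is not None
                and iv.chrom == current[0]
                and iv.start < current[2]
            ):
                current = (
                    current[0],
                    current[1],
                    max(current[2], iv.end),
                    current[3] + [t.id],
                )
            else:
                if current is not None:
                    merged.append(
                        (GenomicInterval(current[0], current[1], current[2], strand),
                         current[3])
                    )
                current = (iv.chrom, iv.start, iv.end, [t.id])
        if current is not None:
            merged.append(
                (GenomicInterval(current[0], current[1], current[2], strand),
                 current[3])
            )
    merged.sort(key=lambda m: (m[0].chrom, m[0].start, m[0].end, m[0].strand))
    for i, (iv, members) in enumerate(merged):
        units.append(
            TranscriptionalUnit(id=f"TU_{i:04d}", interval=iv,
                                member_ids=tuple(members))
        )
    return units


def probe_to_unit_expression(
    probe_expr: ExpressionMatrix,
    probe_coords: Mapping[str, GenomicInterval],
    units: Sequence[TranscriptionalUnit],
) -> ExpressionMatrix:
    """Average probe-level expression over the probes inside each TU.

    A probe contributes only when its interval lies fully inside the TU
    span; TUs without any probe are dropped with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    for i, pid in enumerate(probe_expr.unit_ids):
        iv = probe_coords.get(pid)
        if iv is None:
            raise ConfigurationError(f"no coordinates for probe {pid}")
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (i, iv))
    unit_ids: list[str] = []
    rows: list[np.ndarray] = []
    dropped = 0
    for unit in units:
        span = unit.interval
        tree = trees.get(span.chrom)
        idx = []
        if tree is not None:
            for hit in tree.overlap(span.start, span.end):
                i, iv = hit.data
                if iv.start >= span.start and iv.end <= span.end:
                    idx.append(i)
        if not idx:
            dropped += 1
            continue
        unit_ids.append(unit.id)
        rows.append(probe_expr.values[sorted(idx)].mean(axis=0))
    if dropped:
        logger.warning("%d transcriptional units had no probes and were dropped",
                       dropped)
    if not rows:
        raise ConfigurationError("no unit matched any probe")
    return ExpressionMatrix(
        unit_ids=unit_ids,
        sample_ids=list(probe_expr.sample_ids),
        group=dict(probe_expr.group),
        values=np.vstack(rows),
    )


def count_enhancers_near_tss(
    calls_by_cell: Mapping[str, Sequence[EnhancerCall]],
    units: Sequence[TranscriptionalUnit],
    window: int = 100_000,
) -> list[GeneEnhancerRecord]:
    """Count call anchors inside the ``window`` span around each TSS.

    The window is ``[tss - window/2, tss + window/2)``; an enhancer may
    count toward several nearby TUs.
    """
    half = window // 2
    anchors: dict[str, dict[str, np.ndarray]] = {}
    for cell, calls in calls_by_cell.items():
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for call in calls:
            per_chrom.setdefault(call.anchor.chrom, []).append(
                (call.anchor.start, call.anchor.end)
            )
        anchors[cell] = {
            c: np.asarray(sorted(v), dtype=np.int64) for c, v in per_chrom.items()
        }
    records = []
    for unit in units:
        rec = GeneEnhancerRecord(unit=unit)
        lo, hi = unit.tss - half, unit.tss + half
        for cell, per_chrom in anchors.items():
            arr = per_chrom.get(unit.interval.chrom)
            if arr is None or arr.size == 0:
                rec.n_enh[cell] = 0
                continue
            # anchor [s, e) overlaps [lo, hi) iff s < hi and e > lo
            rec.n_enh[cell] = int(np.sum((arr[:, 0] < hi) & (arr[:, 1] > lo)))
        records.append(rec)
    return records


def attach_expression(
    records: Sequence[GeneEnhancerRecord],
    unit_expr: ExpressionMatrix,
    cell_types: Sequence[str] | None = None,
) -> list[GeneEnhancerRecord]:
    """Fill per-cell-type mean expression; drops TUs absent from the matrix."""
    cells = list(cell_types) if cell_types is not None else unit_expr.groups
    means = {c: unit_expr.group_means(c) for c in cells}
    index = {uid: i for i, uid in enumerate(unit_expr.unit_ids)}
    kept = []
    for rec in records:
        i = index.get(rec.unit.id)
        if i is None:
            continue
        for c in cells:
            rec.mean_expr[c] = float(means[c][i])
        kept.append(rec)
    return kept


def expression_by_count(
    records: Sequence[GeneEnhancerRecord], cell_type: str, cap: int = 4
) -> pd.DataFrame:
    """Mean expression of genes binned by nearby-enhancer count.

    Bins are 0, 1, ..., cap-1 and ``>=cap``; empty bins appear with
    ``n_genes = 0`` and NaN mean.
    """
    if not records:
        raise ValueError("no records")
    counts = np.array([min(r.n_enh.get(cell_type, 0), cap) for r in records])
    exprs = np.array([r.mean_expr[cell_type] for r in records])
    rows = []
    for b in range(cap + 1):
        mask = counts == b
        label = str(b) if b < cap else f">={cap}"
        rows.append(
            {
                "count_bin": label,
                "mean_expression": float(exprs[mask].mean()) if mask.any() else float("nan"),
                "n_genes": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def differential_genes(
    expr: ExpressionMatrix, alpha: float = 1e-7
) -> tuple[set[str], set[str]]:
    """ANOVA-significant genes split by direction between two groups.

    A gene is differential when its one-way ANOVA p-value across the two
    cell-type groups is <= ``alpha`` (the threshold is taken as already
    multiplicity-adjusted); direction is the sign of mean(A) - mean(B)
    for the groups in their declared order.
    """
    groups = expr.groups
    if len(groups) != 2:
        raise ConfigurationError(f"need exactly 2 groups, have {groups}")
    a, b = groups
    va = expr.sample_columns(a)
    vb = expr.sample_columns(b)
    if va.shape[1] < 2 or vb.shape[1] < 2:
        raise ConfigurationError("each group needs >= 2 samples")
    up_a: set[str] = set()
    up_b: set[str] = set()
    for i, uid in enumerate(expr.unit_ids):
        res = oneway_anova([va[i], vb[i]])
        if res.pvalue == res.pvalue and res.pvalue <= alpha:
            if va[i].mean() > vb[i].mean():
                up_a.add(uid)
            elif vb[i].mean() > va[i].mean():
                up_b.add(uid)
    return up_a, up_b


def enhancer_asymmetry(
    de_units: set[str],
    records: Sequence[GeneEnhancerRecord],
    up_cell: str,
    other_cell: str,
) -> tuple[float, float, TestResult]:
    """Mean enhancer counts near up-regulated genes, same vs other cell.

    For every differential gene up-regulated in ``up_cell``, the pair
    (count in up_cell, count in other_cell) feeds a Wilcoxon signed-rank
    test; the two means are returned with the test result.
    """
    pairs = [
        (float(r.n_enh.get(up_cell, 0)), float(r.n_enh.get(other_cell, 0)))
        for r in records
        if r.unit.id in de_units
    ]
    if not pairs:
        raise ValueError("no differential genes among the records")
    arr = np.asarray(pairs)
    result = wilcoxon_signed_rank(pairs)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean()), result


def divergence_deciles(
    records: Sequence[GeneEnhancerRecord],
    cell_a: str,
    cell_b: str,
    totals: Mapping[str, int],
    normalization: str = "per-total",
) -> pd.DataFrame:
    """Expression divergence vs enhancer-count difference across deciles.

    Genes are sorted by expression divergence mean(A) - mean(B) and split
    into 10 equal-size bins (remainder spread over the leading bins).
    The count difference is ``n_A/total_A - n_B/total_B`` under
    ``per-total`` normalization, or the raw difference under ``none``.
    """
    if len(records) < 10:
        raise ConfigurationError("need at least 10 genes for deciles")
    if normalization not in ("per-total", "none"):
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    div = np.array([r.mean_expr[cell_a] - r.mean_expr[cell_b] for r in records])
    if normalization == "per-total":
        ta, tb = totals[cell_a], totals[cell_b]
        if ta <= 0 or tb <= 0:
            raise ConfigurationError("call totals must be positive")
        cdiff = np.array(
            [r.n_enh.get(cell_a, 0) / ta - r.n_enh.get(cell_b, 0) / tb
             for r in records]
        )
    else:
        cdiff = np.array(
            [r.n_enh.get(cell_a, 0) - r.n_enh.get(cell_b, 0) for r in records],
            dtype=float,
        )
    order = np.argsort(div, kind="stable")
    n = len(records)
    base, extra = divmod(n, 10)
    rows = []
    pos = 0
    for b in range(10):
        size = base + (1 if b < extra else 0)
        idx = order[pos : pos + size]
        pos += size
        rows.append(
            {
                "decile": b + 1,
                "mean_expression_divergence": float(div[idx].mean()),
                "mean_count_difference": float(cdiff[idx].mean()),
                "n_genes": int(size),
            }
        )
    return pd.DataFrame(rows)
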