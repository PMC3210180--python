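"""Transposable-element attribution of enhancer calls.

Calls whose 100-bp anchor overlaps a RepeatMasker interval are
TE-derived.  TE-derived calls are grouped into the six major Repbase
families (Alu, L1, LTR, DNA, L2, MIR), family contributions are
normalized by each family's genomic abundance (bp annotated), and
over-/under-representation is assessed with a chi-square goodness-of-fit
test.  Cross-cell-type sharing of calls and its hypergeometric
under-representation test live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .genomic_io import TEAnnotation
from .scanner import EnhancerCall
from .stats import TestResult, chi2_gof, hypergeom_left, spearman_rho, spearman_significance

logger = logging.getLogger(__name__)

__all__ = [
    "MAJOR_FAMILIES",
    "FamilyStats",
    "classify_family",
    "attribute_te",
    "family_representation",
    "age_correlation",
    "shared_calls",
    "underrepresentation_test",
]

#: the six major Repbase families considered
MAJOR_FAMILIES = ("Alu", "L1", "LTR", "DNA", "L2", "MIR")


@dataclass(frozen=True)
class FamilyStats:
    """Observed vs abundance-expected enhancer contribution of one family."""

    family: str
    observed: int
    genomic_bp: int
    expected: float
    ratio: float


def classify_family(te: TEAnnotation) -> str:
    """Map a RepeatMasker class/family pair onto a major family label.

    SINE/Alu -> Alu, SINE/MIR -> MIR, LINE/L1 -> L1, LINE/L2 -> L2,
    class LTR -> LTR, class DNA -> DNA; anything else -> ``Other``.
    """
    cls = te.repeat_class
    fam = te.repeat_family
    if cls == "SINE":
        if fam.startswith("Alu"):
            return "Alu"
        if fam.startswith("MIR"):
            return "MIR"
        return "Other"
    if cls == "LINE":
        if fam.startswith("L1"):
            return "L1"
        if fam.startswith("L2"):
            return "L2"
        return "Other"
    if cls == "LTR":
        return "LTR"
    if cls == "DNA":
        return "DNA"
    return "Other"


def _te_tree(tes: Sequence[TEAnnotation]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for te in tes:
        iv = te.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, te)
    return trees


def attribute_te(
    calls: Sequence[EnhancerCall], tes: Sequence[TEAnnotation]
) -> list[EnhancerCall]:
    """The TE-derived subset of calls, with ``te_link`` populated.

    A call is TE-derived when its anchor overlaps >= 1 bp of a TE
    interval; ties on overlap go to the longer TE, then the leftmost.
    Order-independent and idempotent.
    """
    trees = _te_tree(tes)
    out: list[EnhancerCall] = []
    for call in calls:
        tree = trees.get(call.anchor.chrom)
        if tree is None:
            continue
        hits = tree.overlap(call.anchor.start, call.anchor.end)
        if not hits:
            continue
        best = max(
            (h.data for h in hits),
            key=lambda te: (
                call.anchor.overlap_bp(te.interval),
                len(te.interval),
                -te.interval.start,
            ),
        )
        out.append(replace(call, te_link=best))
    return out


def family_genomic_bp(tes: Sequence[TEAnnotation]) -> dict[str, int]:
    """Total annotated bp per major family (``Other`` included)."""
    bp: dict[str, int] = {}
    for te in tes:
        fam = classify_family(te)
        bp[fam] = bp.get(fam, 0) + len(te.interval)
    return bp


def family_representation(
    te_calls: Sequence[EnhancerCall], tes: Sequence[TEAnnotation]
) -> tuple[list[FamilyStats], TestResult]:
    """Observed vs abundance-expected family contributions plus chi-square.

    Only calls linked to the six major families enter the test;
    ``expected_f = total_calls * bp_f / sum(bp over the six families)``,
    so expected counts sum to the observed total.  Families with zero
    annotated bp are excluded with a warning.
    """
    if not te_calls:
        raise ValueError("need at least one TE-derived call")
    bp = family_genomic_bp(tes)
    families = [f for f in MAJOR_FAMILIES if bp.get(f, 0) > 0]
    skipped = [f for f in MAJOR_FAMILIES if bp.get(f, 0) <= 0]
    if skipped:
        logger.warning("families with no annotated bp excluded: %s", skipped)
    observed = {f: 0 for f in families}
    for call in te_calls:
        fam = classify_family(call.te_link)
        if fam in observed:
            observed[fam] += 1
    total = sum(observed.values())
    if total == 0:
        raise ValueError("no call belongs to a major family")
    total_bp = sum(bp[f] for f in families)
    stats = []
    for f in families:
        expected = total * bp[f] / total_bp
        stats.append(
            FamilyStats(
                family=f,
                observed=observed[f],
                genomic_bp=bp[f],
                expected=expected,
                ratio=observed[f] / expected if expected > 0 else float("nan"),
            )
        )
    test = chi2_gof([s.observed for s in stats], [s.expected for s in stats])
    return stats, test


def age_correlation(
    family_ages: Mapping[str, float], observed_normalized: Mapping[str, float]
) -> TestResult:
    """Spearman correlation between family age and normalized contribution.

    The age proxy is typically mean percent divergence per family.
    Undefined (nan statistic) with fewer than 3 families in common or a
    constant vector.
    """
    fams = [f for f in family_ages if f in observed_normalized]
    if len(fams) < 3:
        return TestResult(float("nan"), float("nan"), n=len(fams))
    ages = [family_ages[f] for f in fams]
    ratios = [observed_normalized[f] for f in fams]
    rho = spearman_rho(ages, ratios)
    if rho != rho:  # nan
        return TestResult(float("nan"), float("nan"), n=len(fams))
    sig = spearman_significance(rho, len(fams))
    return TestResult(rho, sig.pvalue, df=sig.df, n=len(fams))


def mean_family_divergence(tes: Sequence[TEAnnotation]) -> dict[str, float]:
    """Mean percent divergence per major family — the default age proxy."""
    sums: dict[str, list[float]] = {}
    for te in tes:
        fam = classify_family(te)
        if fam in MAJOR_FAMILIES:
            sums.setdefault(fam, []).append(te.divergence)
    return {f: sum(v) / len(v) for f, v in sums.items()}


def shared_calls(
    calls_a: Sequence[EnhancerCall], calls_b: Sequence[EnhancerCall]
) -> tuple[list[tuple[EnhancerCall, EnhancerCall]], float]:
    """Anchor-overlap sharing between two cell types' call sets.

    Pairs are matched greedily by coordinate so each call joins at most
    one pair.  The shared fraction uses the union denominator
    ``|A| + |B| - |shared|`` and is symmetric in its arguments.
    """
    a_sorted = sorted(calls_a, key=lambda c: (c.anchor.chrom, c.anchor.start))
    b_sorted = sorted(calls_b, key=lambda c: (c.anchor.chrom, c.anchor.start))
    pairs: list[tuple[EnhancerCall, EnhancerCall]] = []
    used_b: set[int] = set()
    j = 0
    for ca in a_sorted:
        for idx, cb in enumerate(b_sorted):
            if idx in used_b:
                continue
            if ca.anchor.overlaps(cb.anchor):
                pairs.append((ca, cb))
                used_b.add(idx)
                break
    n_union = len(calls_a) + len(calls_b) - len(pairs)
    fraction = len(pairs) / n_union if n_union else 0.0
    return pairs, fraction


def shared_fraction(n_a: int, n_b: int, n_shared: int) -> float:
    """Shared fraction over the union, ``n_shared / (n_a + n_b - n_shared)``."""
    if n_shared > min(n_a, n_b):
        raise ValueError("shared count exceeds a set size")
    union = n_a + n_b - n_shared
    if union <= 0:
        raise ValueError("empty union")
    return n_shared / union


def underrepresentation_test(
    N_all_union: int, K_all_shared: int, n_te_union: int, k_te_shared: int
) -> TestResult:
    """Are TE-derived calls under-shared relative to all calls?

    Hypergeometric left tail: drawing the TE-derived union
    (``n_te_union``) from the union of all calls (``N_all_union``, of
    which ``K_all_shared`` are shared), how surprising is observing only
    ``k_te_shared`` shared TE-derived calls?
    """
    p = hypergeom_left(N_all_union, K_all_shared, n_te_union, k_te_shared)
    return TestResult(float(k_te_shared), p, n=n_te_union)
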