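"""Transcriptional units, enhancer counting and expression association."""

import math

import numpy as np
import pytest

from chromenh.genomic_io import (
    ConfigurationError,
    ExpressionMatrix,
    GenomicInterval,
    Transcript,
)
from chromenh.scanner import EnhancerCall
from chromenh.expression import (
    GeneEnhancerRecord,
    TranscriptionalUnit,
    attach_expression,
    build_units,
    count_enhancers_near_tss,
    differential_genes,
    divergence_deciles,
    enhancer_asymmetry,
    expression_by_count,
    probe_to_unit_expression,
)


def _tx(start, end, strand="+", tid="t", chrom="chr1"):
    return Transcript(GenomicInterval(chrom, start, end, strand), tid)


def _call(anchor_start, chrom="chr1"):
    return EnhancerCall(
        cell_type="A",
        dhs=GenomicInterval(chrom, anchor_start - 200, anchor_start + 300),
        anchor=GenomicInterval(chrom, anchor_start, anchor_start + 100),
        window=GenomicInterval(chrom, max(0, anchor_start - 4950),
                               anchor_start + 5050),
        score=0.7,
    )


def _unit(tss, uid="u0", strand="+", chrom="chr1"):
    start = tss if strand == "+" else tss - 999
    return TranscriptionalUnit(
        uid, GenomicInterval(chrom, start, start + 1000, strand), ("t",)
    )


class TestBuildUnits:
    def test_overlapping_codirectional_merge(self):
        units = build_units([_tx(100, 500, tid="a"), _tx(400, 900, tid="b")])
        (u,) = units
        assert (u.interval.start, u.interval.end) == (100, 900)
        assert u.tss == 100
        assert set(u.member_ids) == {"a", "b"}

    def test_opposite_strands_never_merge(self):
        units = build_units([_tx(100, 500, "+"), _tx(400, 900, "-")])
        assert len(units) == 2
        minus = next(u for u in units if u.interval.strand == "-")
        assert minus.tss == 899

    def test_transitive_chain_merges(self):
        # a overlaps b, b overlaps c, but a and c are disjoint
        units = build_units(
            [_tx(0, 300, tid="a"), _tx(250, 600, tid="b"), _tx(550, 800, tid="c")]
        )
        (u,) = units
        assert (u.interval.start, u.interval.end) == (0, 800)

    def test_agrees_with_union_find_oracle(self):
        rng = np.random.default_rng(4)
        txs = []
        for i in range(60):
            start = int(rng.integers(0, 50_000))
            txs.append(_tx(start, start + int(rng.integers(100, 5_000)),
                           strand="+" if rng.random() < 0.5 else "-",
                           tid=f"t{i}"))
        units = build_units(txs)
        # oracle: union-find over pairwise overlapping same-strand pairs
        parent = list(range(len(txs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                a, b = txs[i].interval, txs[j].interval
                if a.strand == b.strand and a.overlaps(b):
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(txs))})
        assert len(units) == n_components
        assert sum(len(u.member_ids) for u in units) == len(txs)


class TestProbeToUnit:
    def _probe_expr(self, values, coords):
        ids = [f"p{i}" for i in range(len(values))]
        m = ExpressionMatrix(
            unit_ids=ids,
            sample_ids=["s1", "s2"],
            group={"s1": "A", "s2": "B"},
            values=np.asarray(values, dtype=float),
        )
        return m, dict(zip(ids, coords))

    def test_single_probe_identity(self):
        m, coords = self._probe_expr([[2, 3]], [GenomicInterval("chr1", 150, 200)])
        unit = TranscriptionalUnit("u0", GenomicInterval("chr1", 100, 500, "+"), ("t",))
        out = probe_to_unit_expression(m, coords, [unit])
        np.testing.assert_allclose(out.values, [[2, 3]])

    def test_probe_mean(self):
        m, coords = self._probe_expr(
            [[2, 2], [4, 6]],
            [GenomicInterval("chr1", 150, 200), GenomicInterval("chr1", 300, 360)],
        )
        unit = TranscriptionalUnit("u0", GenomicInterval("chr1", 100, 500, "+"), ("t",))
        out = probe_to_unit_expression(m, coords, [unit])
        np.testing.assert_allclose(out.values, [[3, 4]])

    def test_straddling_probe_excluded(self):
        m, coords = self._probe_expr(
            [[2, 2], [100, 100]],
            [GenomicInterval("chr1", 150, 200), GenomicInterval("chr1", 450, 550)],
        )
        unit = TranscriptionalUnit("u0", GenomicInterval("chr1", 100, 500, "+"), ("t",))
        out = probe_to_unit_expression(m, coords, [unit])
        np.testing.assert_allclose(out.values, [[2, 2]])


class TestCountNearTss:
    def test_window_boundaries(self):
        unit = _unit(100_000)
        inside = count_enhancers_near_tss({"A": [_call(60_000)]}, [unit])
        assert inside[0].n_enh["A"] == 1  # window is [50,000, 150,000)
        outside = count_enhancers_near_tss({"A": [_call(150_050)]}, [unit])
        assert outside[0].n_enh["A"] == 0

    def test_enhancer_counts_toward_multiple_genes(self):
        units = [_unit(100_000, "u0"), _unit(130_000, "u1")]
        recs = count_enhancers_near_tss({"A": [_call(115_000)]}, units)
        assert [r.n_enh["A"] for r in recs] == [1, 1]

    def test_agrees_with_quadratic_oracle(self):
        rng = np.random.default_rng(14)
        units = [
            _unit(int(rng.integers(60_000, 4_000_000)), f"u{i}",
                  chrom="chr1" if rng.random() < 0.5 else "chr2")
            for i in range(200)
        ]
        calls = [
            _call(int(rng.integers(10_000, 4_000_000)),
                  chrom="chr1" if rng.random() < 0.5 else "chr2")
            for _ in range(200)
        ]
        recs = count_enhancers_near_tss({"A": calls}, units, window=100_000)
        for rec in recs:
            lo, hi = rec.unit.tss - 50_000, rec.unit.tss + 50_000
            naive = sum(
                1 for c in calls
                if c.anchor.chrom == rec.unit.interval.chrom
                and c.anchor.start < hi and c.anchor.end > lo
            )
            assert rec.n_enh["A"] == naive


def _records(counts_a, exprs_a, counts_b=None, exprs_b=None):
    out = []
    for i, (c, e) in enumerate(zip(counts_a, exprs_a)):
        rec = GeneEnhancerRecord(unit=_unit(10_000 + 1000 * i, f"u{i}"))
        rec.n_enh["A"] = c
        rec.mean_expr["A"] = e
        if counts_b is not None:
            rec.n_enh["B"] = counts_b[i]
            rec.mean_expr["B"] = exprs_b[i]
        out.append(rec)
    return out


class TestExpressionByCount:
    def test_worked_example(self):
        recs = _records([0, 0, 1, 2], [1, 1, 3, 5])
        tab = expression_by_count(recs, "A", cap=3)
        assert tab["mean_expression"].tolist()[:3] == [1.0, 3.0, 5.0]
        assert tab["n_genes"].tolist() == [2, 1, 1, 0]

    def test_all_zero_counts_single_bin(self):
        recs = _records([0, 0, 0], [1, 2, 3])
        tab = expression_by_count(recs, "A", cap=2)
        assert tab["n_genes"].tolist() == [3, 0, 0]
        assert tab["mean_expression"][0] == pytest.approx(2.0)

    def test_gene_totals_conserved(self):
        rng = np.random.default_rng(0)
        recs = _records(rng.integers(0, 8, 50).tolist(), rng.uniform(0, 10, 50))
        tab = expression_by_count(recs, "A", cap=4)
        assert tab["n_genes"].sum() == 50


class TestDifferentialGenes:
    def _matrix(self, a_rows, b_rows):
        na, nb = len(a_rows[0]), len(b_rows[0])
        samples = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
        groups = {s: ("A" if s.startswith("a") else "B") for s in samples}
        values = np.hstack([np.asarray(a_rows, float), np.asarray(b_rows, float)])
        return ExpressionMatrix([f"g{i}" for i in range(len(a_rows))],
                                samples, groups, values)

    def test_identical_groups_nothing_differential(self):
        m = self._matrix([[1, 2, 3]] * 4, [[1, 2, 3]] * 4)
        up_a, up_b = differential_genes(m, alpha=0.05)
        assert up_a == set() and up_b == set()

    def test_planted_shift_recovered_with_direction(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(50, 150, 30)
        a = base[:, None] + rng.normal(0, 1.0, (30, 10))
        b = a.copy()
        b[:10] += 40.0  # first ten genes up in B
        m = self._matrix(np.maximum(a, 0).tolist(), np.maximum(b, 0).tolist())
        up_a, up_b = differential_genes(m, alpha=1e-7)
        assert up_b == {f"g{i}" for i in range(10)}
        assert up_a == set()

    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(6)
        m = self._matrix(rng.uniform(0, 1, (5, 4)).tolist(),
                         rng.uniform(10, 11, (5, 4)).tolist())
        assert differential_genes(m, alpha=0.0) == (set(), set())

    def test_single_replicate_rejected(self):
        m = self._matrix([[1.0]] * 3, [[2.0, 3.0]] * 3)
        with pytest.raises(ConfigurationError):
            differential_genes(m)


class TestEnhancerAsymmetry:
    def test_identical_counts_undefined_test(self):
        recs = _records([1, 2, 3], [5, 5, 5], [1, 2, 3], [5, 5, 5])
        same, other, res = enhancer_asymmetry({"u0", "u1", "u2"}, recs, "A", "B")
        assert same == other
        assert math.isnan(res.statistic)

    def test_directional_signal_detected(self):
        counts_a = [4, 5, 6, 4, 5, 6, 7, 5]
        counts_b = [1, 1, 2, 0, 1, 2, 2, 1]
        recs = _records(counts_a, [9] * 8, counts_b, [1] * 8)
        same, other, res = enhancer_asymmetry(
            {f"u{i}" for i in range(8)}, recs, "A", "B"
        )
        assert same > other
        assert res.pvalue < 0.05

    def test_swapping_labels_swaps_report(self):
        recs = _records([4, 5, 6, 7], [9] * 4, [1, 0, 2, 1], [1] * 4)
        ids = {f"u{i}" for i in range(4)}
        s1, o1, r1 = enhancer_asymmetry(ids, recs, "A", "B")
        s2, o2, r2 = enhancer_asymmetry(ids, recs, "B", "A")
        assert (s1, o1) == (o2, s2)
        assert r1.pvalue == pytest.approx(r2.pvalue)


class TestDivergenceDeciles:
    def test_no_divergence_all_zero(self):
        recs = _records(list(range(12)), [5] * 12, list(range(12)), [5] * 12)
        tab = divergence_deciles(recs, "A", "B", {"A": 10, "B": 10})
        np.testing.assert_allclose(tab["mean_expression_divergence"], 0)
        np.testing.assert_allclose(tab["mean_count_difference"], 0)
        assert tab["n_genes"].sum() == 12

    def test_reversing_labels_negates_columns(self):
        rng = np.random.default_rng(8)
        ca = rng.integers(0, 5, 20).tolist()
        cb = rng.integers(0, 5, 20).tolist()
        ea = rng.uniform(0, 10, 20)
        eb = rng.uniform(0, 10, 20)
        recs = _records(ca, ea, cb, eb)
        t1 = divergence_deciles(recs, "A", "B", {"A": 10, "B": 10})
        t2 = divergence_deciles(recs, "B", "A", {"A": 10, "B": 10})
        np.testing.assert_allclose(
            t1["mean_expression_divergence"].to_numpy(),
            -t2["mean_expression_divergence"].to_numpy()[::-1],
        )
        np.testing.assert_allclose(
            t1["mean_count_difference"].to_numpy(),
            -t2["mean_count_difference"].to_numpy()[::-1],
        )

    def test_too_few_genes_rejected(self):
        recs = _records([1] * 5, [1] * 5, [1] * 5, [1] * 5)
        with pytest.raises(ConfigurationError):
            divergence_deciles(recs, "A", "B", {"A": 1, "B": 1})

    def test_attach_expression_joins_by_unit_id(self):
        recs = _records([1, 2], [0, 0])
        m = ExpressionMatrix(
            ["u0", "u1"], ["s1", "s2"], {"s1": "A", "s2": "B"},
            np.array([[1.0, 2.0], [3.0, 4.0]]),
        )
        out = attach_expression(recs, m)
        assert out[0].mean_expr == {"A": 1.0, "B": 2.0}
        assert out[1].mean_expr == {"A": 3.0, "B": 4.0}
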