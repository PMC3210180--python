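"""Synthetic genomes with planted regulatory signal.

The generator emulates the statistical structure of the real inputs the
pipeline consumes: a small multi-chromosome genome carrying planted
enhancers, CAGE-marked promoters and background open-chromatin (DHS)
sites; ChIP-Seq-like tag landscapes in which each histone modification
has a characteristic profile shape over active features on top of a
uniform Poisson background; RepeatMasker-style TE annotations with
family labels and percent divergence; transcript models; and replicated
two-cell-type expression whose per-gene means increase with the number
of planted enhancers near the TSS.

Every quantity is reproducible from ``(config, seed)``.  A truth table
mapping each DHS site to its planted label supports end-to-end
evaluation of the caller.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import (
    ConfigurationError,
    ExpressionMatrix,
    GenomicInterval,
    TagCollection,
    TEAnnotation,
    Transcript,
    write_bed,
    write_expression_table,
    write_tagalign,
)
from .genomic_io import write_rmsk_table
from .profile import DEFAULT_NEGATIVE_MARKS, POSITIVE_MARKS

__all__ = [
    "MarkShape",
    "SimConfig",
    "PlantedFeature",
    "SyntheticGenome",
    "default_enhancer_shapes",
    "default_promoter_shapes",
    "simulate_annotation",
    "simulate_tags",
    "simulate_expression",
    "planted_enhancer_counts",
    "write_inputs",
]


@dataclass(frozen=True)
class MarkShape:
    """Expected tag landscape of one assay around an active feature.

    ``amplitude`` is the expected number of extra tags per 100-bp bin at
    a component peak; the shape is a sum of Gaussian bumps with the
    given bp offsets from the feature anchor and common width (sd, bp).
    ``lambda0`` is the uniform background rate in tags/bp.
    """

    lambda0: float
    amplitude: float
    centers: tuple[float, ...] = (0.0,)
    width: float = 500.0

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ConfigurationError("background rate lambda0 must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.width <= 0:
            raise ConfigurationError("width must be > 0")

    def expected_bin_counts(self, offsets: np.ndarray) -> np.ndarray:
        """Expected extra tags per bin at the given bp offsets from anchor."""
        total = np.zeros_like(offsets, dtype=float)
        for c in self.centers:
            total += np.exp(-((offsets - c) ** 2) / (2.0 * self.width**2))
        return self.amplitude * total


def default_enhancer_shapes() -> dict[str, MarkShape]:
    """Enhancer-characteristic mark shapes.

    H3K4me1/me2 are bimodal (bumps at +/-1 kb flanking the
    nucleosome-depleted anchor); H3K4me3, H3K9ac and H3K27ac are
    unimodal and central.  Amplitudes are sized so that, at the default
    feature density, an active enhancer's per-window tag mass clearly
    exceeds the genome-wide mean rate even though that rate is itself
    inflated by the planted signal (the enrichment test measures its
    Poisson mean from the total tag count, exactly as on real data).
    """
    bg = 1e-3
    return {
        "H3K4me1": MarkShape(bg, 8.0, centers=(-1000.0, 1000.0), width=500.0),
        "H3K4me2": MarkShape(bg, 8.0, centers=(-1000.0, 1000.0), width=500.0),
        "H3K4me3": MarkShape(bg, 8.0, centers=(0.0,), width=700.0),
        "H3K9ac": MarkShape(bg, 8.0, centers=(0.0,), width=700.0),
        "H3K27ac": MarkShape(bg, 8.0, centers=(0.0,), width=700.0),
    }


def default_promoter_shapes() -> dict[str, MarkShape]:
    """Promoter-like mark shapes: unimodal, H3K4me3-dominant."""
    bg = 1e-3
    return {
        "H3K4me1": MarkShape(bg, 3.0, centers=(0.0,), width=500.0),
        "H3K4me2": MarkShape(bg, 6.0, centers=(0.0,), width=500.0),
        "H3K4me3": MarkShape(bg, 8.0, centers=(0.0,), width=500.0),
        "H3K9ac": MarkShape(bg, 6.0, centers=(0.0,), width=500.0),
        "H3K27ac": MarkShape(bg, 4.0, centers=(0.0,), width=500.0),
    }


#: TE family placement parameters: genomic frequency, mean length (bp),
#: length sd, mean percent divergence (age proxy), divergence sd.
_TE_FAMILY_PARAMS = {
    # family: (genomic_weight, mean_len, sd_len, mean_div, sd_div)
    "Alu": (0.38, 300, 60, 12.0, 3.0),
    "L1": (0.20, 4000, 1500, 18.0, 5.0),
    "LTR": (0.12, 1500, 500, 22.0, 5.0),
    "DNA": (0.12, 800, 300, 25.0, 5.0),
    "L2": (0.08, 1200, 400, 30.0, 4.0),
    "MIR": (0.10, 200, 50, 33.0, 4.0),
}

#: repeat_class/repeat_family spellings used when materializing annotations
_TE_FAMILY_LABELS = {
    "Alu": ("SINE", "Alu"),
    "MIR": ("SINE", "MIR"),
    "L1": ("LINE", "L1"),
    "L2": ("LINE", "L2"),
    "LTR": ("LTR", "ERVL"),
    "DNA": ("DNA", "hAT-Charlie"),
}

#: enhancer-donation weights: older families donate disproportionately,
#: so the planted age/contribution correlation is positive by design
_TE_ENHANCER_WEIGHTS = {
    "Alu": 0.10,
    "L1": 0.10,
    "LTR": 0.20,
    "DNA": 0.15,
    "L2": 0.20,
    "MIR": 0.25,
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults describe a 5-Mb genome with 200 planted enhancers, 200
    promoters and 400 background DHS sites, two cell types, a 0.4
    TE-anchor fraction, and replicated expression on a normalized
    intensity scale (``mu0 + beta * local enhancer count`` with Gaussian
    noise, floored at zero).
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 2_000_000}
    )
    cell_types: tuple[str, str] = ("cellA", "cellB")
    n_enhancers: int = 200
    n_promoters: int = 200
    n_background_dhs: int = 400
    #: fractions of enhancers active in cell A only / cell B only / both
    activity_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    min_separation: int = 10_000
    placement_jitter: int = 1_000
    dhs_length: int = 500
    window_size: int = 10_000
    bin_size: int = 100
    te_fraction: float = 0.4
    n_background_tes: int = 2_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2_000, 50_000)
    #: overall multiplier on all signal amplitudes (0 gives a null genome)
    amplitude_scale: float = 1.0
    enhancer_shapes: dict[str, MarkShape] = field(
        default_factory=default_enhancer_shapes
    )
    promoter_shapes: dict[str, MarkShape] = field(
        default_factory=default_promoter_shapes
    )
    negative_marks: tuple[str, ...] = DEFAULT_NEGATIVE_MARKS
    negative_lambda0: float = 1e-3
    dhs_shape: MarkShape = field(
        default_factory=lambda: MarkShape(1e-3, 10.0, centers=(0.0,), width=300.0)
    )
    cage_shape: MarkShape = field(
        default_factory=lambda: MarkShape(5e-5, 40.0, centers=(0.0,), width=50.0)
    )
    #: extra background loci offered as anchor candidates during training
    n_background_candidates: int = 50
    # expression model
    mu0: float = 100.0
    beta: float = 50.0
    sigma: float = 20.0
    replicates: tuple[int, int] = (20, 21)
    enhancer_window: int = 100_000

    def scaled_shapes(self, shapes: Mapping[str, MarkShape]) -> dict[str, MarkShape]:
        return {
            m: replace(s, amplitude=s.amplitude * self.amplitude_scale)
            for m, s in shapes.items()
        }


@dataclass(frozen=True)
class PlantedFeature:
    """A planted regulatory locus: point anchor plus activity label."""

    anchor: GenomicInterval
    activity: str  # one of the cell-type names or "both"


@dataclass
class SyntheticGenome:
    """A fully-specified synthetic annotation with its truth table."""

    genome: dict[str, int]
    enhancers: list[PlantedFeature]
    promoters: list[GenomicInterval]
    tes: list[TEAnnotation]
    genes: list[Transcript]
    dhs_sites: dict[str, list[GenomicInterval]]
    truth: dict[GenomicInterval, str]
    p300_candidates: list[GenomicInterval]
    config: SimConfig

    def active_enhancers(self, cell: str) -> list[PlantedFeature]:
        return [e for e in self.enhancers if e.activity in (cell, "both")]


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


def _point(chrom: str, pos: int) -> GenomicInterval:
    return GenomicInterval(chrom, pos, pos + 1)


def simulate_annotation(config: SimConfig, seed: int) -> SyntheticGenome:
    """Place all planted features, TEs, genes and DHS sites.

    Signal-bearing features (enhancers and promoters) sit on a jittered
    lattice guaranteeing at least ``min_separation`` between any two of
    them; background DHS sites interleave between them.  Raises
    :class:`ConfigurationError` when the genome cannot hold the request.
    """
    n_signal = config.n_enhancers + config.n_promoters
    n_total = n_signal + config.n_background_dhs
    if n_signal == 0:
        raise ConfigurationError("need at least one signal feature")
    margin = config.window_size
    chroms = sorted(config.chrom_lengths)
    usable = {c: config.chrom_lengths[c] - 2 * margin for c in chroms}
    if any(u <= 0 for u in usable.values()):
        raise ConfigurationError("chromosomes too short for the window margin")
    total_usable = sum(usable.values())

    # proportional slot allocation (largest remainder)
    raw = {c: n_total * usable[c] / total_usable for c in chroms}
    slots_per_chrom = {c: int(raw[c]) for c in chroms}
    for c in sorted(chroms, key=lambda c: raw[c] - int(raw[c]), reverse=True):
        if sum(slots_per_chrom.values()) >= n_total:
            break
        slots_per_chrom[c] += 1

    slot_list: list[tuple[str, int, float]] = []  # (chrom, slot pos, spacing)
    for c in chroms:
        k = slots_per_chrom[c]
        if k == 0:
            continue
        spacing = usable[c] / k
        for i in range(k):
            slot_list.append((c, int(margin + (i + 0.5) * spacing), spacing))
    if len(slot_list) < n_total:
        raise ConfigurationError("genome too small for requested feature count")

    # signal features occupy evenly spread slots; check the separation
    # guarantee (slot gap minus twice the jitter)
    signal_idx = sorted({(i * n_total) // n_signal for i in range(n_signal)})
    if len(signal_idx) < n_signal:
        raise ConfigurationError("cannot spread signal features over slots")
    min_spacing = min(s for (_, _, s) in slot_list)
    gap_slots = max(
        1, min(b - a for a, b in zip(signal_idx, signal_idx[1:])) if n_signal > 1 else 1
    )
    if gap_slots * min_spacing - 2 * config.placement_jitter < config.min_separation:
        raise ConfigurationError(
            "genome too small to keep planted features "
            f"{config.min_separation} bp apart"
        )

    rng = _rng(seed, 1)
    jitter = rng.integers(
        -config.placement_jitter, config.placement_jitter + 1, size=len(slot_list)
    )
    positions = [
        (c, int(p + j)) for (c, p, _), j in zip(slot_list, jitter)
    ]

    signal_set = set(signal_idx)
    signal_pos = [positions[i] for i in signal_idx]
    background_pos = [p for i, p in enumerate(positions) if i not in signal_set]
    background_pos = background_pos[: config.n_background_dhs]

    # which signal slots are enhancers vs promoters, and enhancer activity
    roles = np.array(
        ["E"] * config.n_enhancers + ["P"] * config.n_promoters, dtype=object
    )
    rng.shuffle(roles)
    a_frac, b_frac, _ = config.activity_mix
    n_a = int(round(config.n_enhancers * a_frac))
    n_b = int(round(config.n_enhancers * b_frac))
    n_both = config.n_enhancers - n_a - n_b
    if n_both < 0:
        raise ConfigurationError("activity mix fractions exceed 1")
    cell_a, cell_b = config.cell_types
    activities = np.array(
        [cell_a] * n_a + [cell_b] * n_b + ["both"] * n_both, dtype=object
    )
    rng.shuffle(activities)

    enhancers: list[PlantedFeature] = []
    promoters: list[GenomicInterval] = []
    e_i = 0
    for (chrom, pos), role in zip(signal_pos, roles):
        if role == "E":
            enhancers.append(PlantedFeature(_point(chrom, pos), str(activities[e_i])))
            e_i += 1
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            promoters.append(GenomicInterval(chrom, pos, pos + 1, strand))

    # DHS sites: active features own one per active cell type; background
    # DHS are open in both cell types
    half_dhs = config.dhs_length // 2
    truth: dict[GenomicInterval, str] = {}
    dhs_sites: dict[str, list[GenomicInterval]] = {c: [] for c in config.cell_types}

    def _dhs(chrom: str, pos: int) -> GenomicInterval:
        return GenomicInterval(chrom, pos - half_dhs, pos - half_dhs + config.dhs_length)

    for feat in enhancers:
        site = _dhs(feat.anchor.chrom, feat.anchor.start)
        truth[site] = "enhancer"
        for cell in config.cell_types:
            if feat.activity in (cell, "both"):
                dhs_sites[cell].append(site)
    for prom in promoters:
        site = _dhs(prom.chrom, prom.start)
        truth[site] = "promoter"
        for cell in config.cell_types:
            dhs_sites[cell].append(site)
    for chrom, pos in background_pos:
        site = _dhs(chrom, pos)
        truth[site] = "background"
        for cell in config.cell_types:
            dhs_sites[cell].append(site)
    for cell in config.cell_types:
        dhs_sites[cell].sort()

    tes = _simulate_tes(config, seed, enhancers, promoters)
    genes = _simulate_genes(config, seed)

    # anchor candidates for training: enhancers active in the first cell
    # type plus background loci that selection should reject
    rng_c = _rng(seed, 5)
    candidates = [
        f.anchor for f in enhancers if f.activity in (config.cell_types[0], "both")
    ]
    for _ in range(config.n_background_candidates):
        chrom = chroms[int(rng_c.integers(len(chroms)))]
        pos = int(rng_c.integers(margin, config.chrom_lengths[chrom] - margin))
        candidates.append(_point(chrom, pos))

    return SyntheticGenome(
        genome=dict(config.chrom_lengths),
        enhancers=enhancers,
        promoters=promoters,
        tes=tes,
        genes=genes,
        dhs_sites=dhs_sites,
        truth=truth,
        p300_candidates=candidates,
        config=config,
    )


def _simulate_tes(
    config: SimConfig,
    seed: int,
    enhancers: Sequence[PlantedFeature],
    promoters: Sequence[GenomicInterval],
) -> list[TEAnnotation]:
    rng = _rng(seed, 2)
    families = list(_TE_FAMILY_PARAMS)
    genomic_w = np.array([_TE_FAMILY_PARAMS[f][0] for f in families])
    genomic_w = genomic_w / genomic_w.sum()
    enh_w = np.array([_TE_ENHANCER_WEIGHTS[f] for f in families])
    enh_w = enh_w / enh_w.sum()

    anchor_pos: dict[str, np.ndarray] = {}
    for chrom in config.chrom_lengths:
        pts = [f.anchor.start for f in enhancers if f.anchor.chrom == chrom]
        pts += [p.start for p in promoters if p.chrom == chrom]
        anchor_pos[chrom] = np.sort(np.asarray(pts, dtype=np.int64))

    def _draw(family: str) -> tuple[int, float]:
        _, mean_len, sd_len, mean_div, sd_div = _TE_FAMILY_PARAMS[family]
        length = max(150, int(rng.normal(mean_len, sd_len)))
        div = max(0.1, float(rng.normal(mean_div, sd_div)))
        return length, div

    def _annot(chrom: str, start: int, end: int, family: str, div: float,
               idx: int) -> TEAnnotation:
        cls, fam = _TE_FAMILY_LABELS[family]
        strand = "+" if rng.random() < 0.5 else "-"
        return TEAnnotation(
            interval=GenomicInterval(chrom, start, end, strand),
            repeat_name=f"{family}_{idx}",
            repeat_class=cls,
            repeat_family=fam,
            divergence=round(div, 1),
        )

    tes: list[TEAnnotation] = []
    # TEs hosting enhancer anchors
    for i, feat in enumerate(enhancers):
        if rng.random() >= config.te_fraction:
            continue
        family = families[int(rng.choice(len(families), p=enh_w))]
        length, div = _draw(family)
        chrom = feat.anchor.chrom
        mid = feat.anchor.start
        offset = int(rng.integers(0, length))
        start = max(0, mid - offset)
        end = min(config.chrom_lengths[chrom], start + length)
        tes.append(_annot(chrom, start, end, family, div, i))

    # background TEs kept clear of all planted anchors so the planted
    # TE-anchor fraction stays exact
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    placed = 0
    attempts = 0
    while placed < config.n_background_tes:
        attempts += 1
        if attempts > 50 * config.n_background_tes:
            raise ConfigurationError("cannot place background TEs clear of anchors")
        family = families[int(rng.choice(len(families), p=genomic_w))]
        length, div = _draw(family)
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        L = config.chrom_lengths[chrom]
        if L <= length:
            continue
        start = int(rng.integers(0, L - length))
        end = start + length
        pts = anchor_pos[chrom]
        lo = np.searchsorted(pts, start - 200)
        hi = np.searchsorted(pts, end + 200)
        if hi > lo:
            continue
        tes.append(_annot(chrom, start, end, family, div, 10_000 + placed))
        placed += 1
    tes.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end))
    return tes


def _simulate_genes(config: SimConfig, seed: int) -> list[Transcript]:
    rng = _rng(seed, 3)
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    lo, hi = config.gene_length_range
    genes: list[Transcript] = []
    for i in range(config.n_genes):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        L = config.chrom_lengths[chrom]
        g_len = int(rng.integers(lo, hi))
        start = int(rng.integers(0, max(1, L - g_len)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Transcript(GenomicInterval(chrom, start, start + g_len, strand),
                       id=f"tx_{i:04d}")
        )
        # occasionally add an overlapping co-directional isoform
        if rng.random() < 0.2:
            shift = int(rng.integers(1, max(2, g_len // 2)))
            end2 = min(L, start + g_len + shift)
            genes.append(
                Transcript(GenomicInterval(chrom, start + shift, end2, strand),
                           id=f"tx_{i:04d}b")
            )
    return genes


def _bin_offsets(config: SimConfig) -> np.ndarray:
    half = config.window_size // 2
    return (
        -half + config.bin_size * np.arange(config.window_size // config.bin_size)
        + config.bin_size / 2.0
    )


def _signal_midpoints(
    rng: np.random.Generator,
    anchors: Sequence[tuple[str, int]],
    shape: MarkShape,
    config: SimConfig,
    chrom_lengths: Mapping[str, int],
) -> dict[str, list[np.ndarray]]:
    """Poisson tag midpoints for one mark over the given active anchors."""
    offsets = _bin_offsets(config)
    expected = shape.expected_bin_counts(offsets)
    out: dict[str, list[np.ndarray]] = {}
    if shape.amplitude <= 0 or not anchors:
        return out
    half = config.window_size // 2
    counts = rng.poisson(np.tile(expected, (len(anchors), 1)))
    for (chrom, pos), row in zip(anchors, counts):
        total = int(row.sum())
        if total == 0:
            continue
        bin_idx = np.repeat(np.arange(row.size), row)
        starts = pos - half + bin_idx * config.bin_size
        mids = starts + rng.integers(0, config.bin_size, size=total)
        mids = np.clip(mids, 0, chrom_lengths[chrom] - 1)
        out.setdefault(chrom, []).append(mids)
    return out


def _background_midpoints(
    rng: np.random.Generator, lambda0: float, chrom_lengths: Mapping[str, int]
) -> dict[str, list[np.ndarray]]:
    out: dict[str, list[np.ndarray]] = {}
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        n = int(rng.poisson(lambda0 * L))
        if n:
            out.setdefault(chrom, []).append(rng.integers(0, L, size=n))
    return out


def _merge_collection(
    mark: str,
    parts: Sequence[dict[str, list[np.ndarray]]],
    chrom_lengths: Mapping[str, int],
) -> TagCollection:
    merged: dict[str, np.ndarray] = {}
    for chrom in chrom_lengths:
        arrays = [a for part in parts for a in part.get(chrom, [])]
        merged[chrom] = (
            np.concatenate(arrays) if arrays else np.empty(0, dtype=np.int64)
        )
    return TagCollection.from_midpoints(mark, merged, chrom_lengths)


def simulate_tags(
    genome: SyntheticGenome, seed: int
) -> dict[str, dict[str, TagCollection]]:
    """Tag collections per cell type and mark (histones, DHS, CAGE).

    Positive marks carry the enhancer shape at enhancers active in that
    cell and the promoter shape at promoters; negative marks are pure
    background; the DHS assay is enriched at every open site (planted or
    background); CAGE is enriched at promoters only.  All counts are
    Poisson; everything is deterministic given the seed.
    """
    config = genome.config
    enh_shapes = config.scaled_shapes(config.enhancer_shapes)
    prom_shapes = config.scaled_shapes(config.promoter_shapes)
    missing = [m for m in POSITIVE_MARKS if m not in enh_shapes or m not in prom_shapes]
    if missing:
        raise ConfigurationError(f"missing shapes for marks: {missing}")
    dhs_shape = config.scaled_shapes({"DHS": config.dhs_shape})["DHS"]
    cage_shape = config.scaled_shapes({"CAGE": config.cage_shape})["CAGE"]

    result: dict[str, dict[str, TagCollection]] = {}
    for ci, cell in enumerate(config.cell_types):
        enh_anchors = [
            (f.anchor.chrom, f.anchor.start) for f in genome.active_enhancers(cell)
        ]
        prom_anchors = [(p.chrom, p.start) for p in genome.promoters]
        open_anchors = [
            (s.chrom, s.midpoint) for s in genome.dhs_sites[cell]
        ]
        cell_marks: dict[str, TagCollection] = {}
        for mi, mark in enumerate(POSITIVE_MARKS):
            rng = _rng(seed, 10, ci, mi)
            parts = [
                _background_midpoints(rng, enh_shapes[mark].lambda0, genome.genome),
                _signal_midpoints(rng, enh_anchors, enh_shapes[mark], config,
                                  genome.genome),
                _signal_midpoints(rng, prom_anchors, prom_shapes[mark], config,
                                  genome.genome),
            ]
            cell_marks[mark] = _merge_collection(mark, parts, genome.genome)
        for mi, mark in enumerate(config.negative_marks):
            rng = _rng(seed, 11, ci, mi)
            parts = [
                _background_midpoints(rng, config.negative_lambda0, genome.genome)
            ]
            cell_marks[mark] = _merge_collection(mark, parts, genome.genome)
        rng = _rng(seed, 12, ci)
        cell_marks["DHS"] = _merge_collection(
            "DHS",
            [
                _background_midpoints(rng, dhs_shape.lambda0, genome.genome),
                _signal_midpoints(rng, open_anchors, dhs_shape, config,
                                  genome.genome),
            ],
            genome.genome,
        )
        rng = _rng(seed, 13, ci)
        cell_marks["CAGE"] = _merge_collection(
            "CAGE",
            [
                _background_midpoints(rng, cage_shape.lambda0, genome.genome),
                _signal_midpoints(rng, prom_anchors, cage_shape, config,
                                  genome.genome),
            ],
            genome.genome,
        )
        result[cell] = cell_marks
    return result


def planted_enhancer_counts(
    genome: SyntheticGenome,
    tss_list: Sequence[tuple[str, int]],
    cell: str,
    window: int | None = None,
) -> np.ndarray:
    """Planted active-enhancer count within the TSS window, per TSS."""
    w = window if window is not None else genome.config.enhancer_window
    half = w // 2
    per_chrom: dict[str, np.ndarray] = {}
    for f in genome.active_enhancers(cell):
        per_chrom.setdefault(f.anchor.chrom, None)
    for chrom in per_chrom:
        per_chrom[chrom] = np.sort(
            np.asarray(
                [
                    f.anchor.start
                    for f in genome.active_enhancers(cell)
                    if f.anchor.chrom == chrom
                ],
                dtype=np.int64,
            )
        )
    counts = np.zeros(len(tss_list), dtype=np.int64)
    for i, (chrom, tss) in enumerate(tss_list):
        pts = per_chrom.get(chrom)
        if pts is None:
            continue
        counts[i] = np.searchsorted(pts, tss + half) - np.searchsorted(
            pts, tss - half
        )
    return counts


def simulate_expression(
    genome: SyntheticGenome,
    seed: int,
    beta: float | None = None,
    replicates: tuple[int, int] | None = None,
    sigma: float | None = None,
) -> ExpressionMatrix:
    """Replicated two-cell-type expression driven by planted enhancers.

    Unit ids follow the transcriptional units built from the simulated
    transcripts; each unit's mean in cell ``c`` is
    ``mu0 + beta * (planted enhancers active in c within the TSS
    window)`` and replicate values add Gaussian noise (floored at 0).
    """
    from .expression import build_units

    config = genome.config
    beta = config.beta if beta is None else beta
    sigma = config.sigma if sigma is None else sigma
    reps = config.replicates if replicates is None else replicates
    if beta < 0 or sigma <= 0:
        raise ConfigurationError("need beta >= 0 and sigma > 0")
    if any(r < 2 for r in reps):
        raise ConfigurationError("ANOVA needs >= 2 replicates per cell type")
    units = build_units(genome.genes)
    tss = [(u.interval.chrom, u.tss) for u in units]
    rng = _rng(seed, 4)
    cell_a, cell_b = config.cell_types
    sample_ids: list[str] = []
    group: dict[str, str] = {}
    cols: list[np.ndarray] = []
    for cell, r in zip((cell_a, cell_b), reps):
        counts = planted_enhancer_counts(genome, tss, cell)
        means = config.mu0 + beta * counts
        for j in range(r):
            sid = f"{cell}_{j:02d}"
            sample_ids.append(sid)
            group[sid] = cell
            cols.append(np.maximum(0.0, means + rng.normal(0.0, sigma, len(units))))
    return ExpressionMatrix(
        unit_ids=[u.id for u in units],
        sample_ids=sample_ids,
        group=group,
        values=np.column_stack(cols),
    )


def write_inputs(
    genome: SyntheticGenome,
    tags: Mapping[str, Mapping[str, TagCollection]],
    expr: ExpressionMatrix,
    outdir: str,
    tag_length: int = 36,
) -> None:
    """Materialize a run as the on-disk formats the readers consume.

    Writes per-cell tagAlign files for every assay, per-cell DHS BED
    files, a UCSC-rmsk-dialect TE table, a transcript BED6, and the
    tab-delimited expression matrix.
    """
    os.makedirs(outdir, exist_ok=True)
    half = tag_length // 2
    for cell, marks in tags.items():
        for mark, coll in marks.items():
            path = os.path.join(outdir, f"{cell}_{mark}.tagAlign")
            with open(path, "w") as fh:
                for chrom in sorted(coll.genome):
                    for mid in coll.midpoints(chrom):
                        start = max(0, int(mid) - half)
                        fh.write(f"{chrom}\t{start}\t{start + tag_length}\tN\t1000\t+\n")
    for cell, sites in genome.dhs_sites.items():
        write_bed(sites, os.path.join(outdir, f"{cell}_DHS_sites.bed"))
    write_rmsk_table(genome.tes, os.path.join(outdir, "repeats_rmsk.txt"))
    write_bed(
        [g.interval for g in genome.genes],
        os.path.join(outdir, "transcripts.bed"),
        names=[g.id for g in genome.genes],
        scores=[0] * len(genome.genes),
    )
    write_expression_table(expr, os.path.join(outdir, "expression.tsv"))
    with open(os.path.join(outdir, "chrom_sizes.tsv"), "w") as fh:
        for chrom in sorted(genome.genome):
            fh.write(f"{chrom}\t{genome.genome[chrom]}\n")
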