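"""End-to-end orchestration of the enhancer-prediction pipeline.

Wires the stages together for a synthetic run: anchor selection and
profile training on one cell type, sliding-window calling and CAGE
promoter filtering per cell type, truth-table evaluation, TE
attribution, and the expression analyses.  Used by the analysis
drivers, the acceptance script and the integration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genomic_io import GenomicInterval, TagCollection
from .profile import (
    ChromatinProfile,
    POSITIVE_MARKS,
    build_training_profile,
    select_anchors,
)
from .scanner import EnhancerCall, cage_enriched_bins, call_enhancers, filter_promoters
from .synthetic import SimConfig, SyntheticGenome, simulate_annotation, simulate_tags

__all__ = ["CellCallResult", "PipelineRun", "train_profile", "scan_cell",
           "evaluate_calls", "run_synthetic"]


@dataclass
class CellCallResult:
    """Calls for one cell type, before and after promoter filtering."""

    cell: str
    provisional: list[EnhancerCall]
    enhancers: list[EnhancerCall]
    promoters_removed: list[EnhancerCall]


@dataclass
class Recovery:
    """Truth-table evaluation of one cell's calls."""

    n_true_enhancer_dhs: int
    n_called: int
    n_true_positive: int
    n_prov_promoter_calls: int
    n_promoters_removed: int
    n_enhancers_removed_as_promoter: int

    @property
    def sensitivity(self) -> float:
        return self.n_true_positive / self.n_true_enhancer_dhs

    @property
    def precision(self) -> float:
        return self.n_true_positive / self.n_called if self.n_called else float("nan")

    @property
    def promoter_removal_rate(self) -> float:
        if self.n_prov_promoter_calls == 0:
            return float("nan")
        return self.n_promoters_removed / self.n_prov_promoter_calls


@dataclass
class PipelineRun:
    genome: SyntheticGenome
    tags: dict[str, dict[str, TagCollection]]
    anchors: list[GenomicInterval]
    training: ChromatinProfile
    cells: dict[str, CellCallResult] = field(default_factory=dict)


def train_profile(
    genome: SyntheticGenome,
    tags: Mapping[str, Mapping[str, TagCollection]],
    cell: str | None = None,
    alpha: float = 0.05,
) -> tuple[list[GenomicInterval], ChromatinProfile]:
    """Select enriched anchors in the training cell and sum their windows."""
    config = genome.config
    cell = cell if cell is not None else config.cell_types[0]
    positives = [tags[cell][m] for m in POSITIVE_MARKS]
    negatives = [tags[cell][m] for m in config.negative_marks]
    anchors = select_anchors(
        genome.p300_candidates, positives, negatives, alpha=alpha,
        window_size=config.window_size,
    )
    training = build_training_profile(
        anchors, positives, window_size=config.window_size,
        bin_size=config.bin_size,
    )
    return anchors, training


def scan_cell(
    genome: SyntheticGenome,
    tags: Mapping[str, Mapping[str, TagCollection]],
    training: ChromatinProfile,
    cell: str,
    cutoff: float = 0.5,
    cage_alpha: float = 0.05,
    promoter_margin: int = 1000,
) -> CellCallResult:
    """Call enhancers in one cell type and remove CAGE-adjacent promoters."""
    config = genome.config
    marks = [tags[cell][m] for m in POSITIVE_MARKS]
    provisional = call_enhancers(
        genome.dhs_sites[cell], marks, training, cutoff=cutoff,
        step=config.bin_size, window_size=config.window_size,
        bin_size=config.bin_size, cell_type=cell,
    )
    enriched = cage_enriched_bins(
        tags[cell]["CAGE"], bin_size=config.bin_size, alpha=cage_alpha
    )
    enhancers, removed = filter_promoters(
        provisional, enriched, margin=promoter_margin, bin_size=config.bin_size
    )
    return CellCallResult(cell=cell, provisional=provisional,
                          enhancers=enhancers, promoters_removed=removed)


def evaluate_calls(genome: SyntheticGenome, result: CellCallResult) -> Recovery:
    """Score a cell's calls against the planted truth table."""
    truth = genome.truth
    cell = result.cell
    n_true = sum(
        1 for s in genome.dhs_sites[cell] if truth.get(s) == "enhancer"
    )
    tp = sum(1 for c in result.enhancers if truth.get(c.dhs) == "enhancer")
    prov_prom = [c for c in result.provisional if truth.get(c.dhs) == "promoter"]
    removed_prom = [
        c for c in result.promoters_removed if truth.get(c.dhs) == "promoter"
    ]
    removed_enh = [
        c for c in result.promoters_removed if truth.get(c.dhs) == "enhancer"
    ]
    return Recovery(
        n_true_enhancer_dhs=n_true,
        n_called=len(result.enhancers),
        n_true_positive=tp,
        n_prov_promoter_calls=len(prov_prom),
        n_promoters_removed=len(removed_prom),
        n_enhancers_removed_as_promoter=len(removed_enh),
    )


def run_synthetic(
    config: SimConfig | None = None,
    seed: int = 0,
    cells: Sequence[str] | None = None,
    cutoff: float = 0.5,
) -> PipelineRun:
    """Simulate, train and call enhancers in every cell type."""
    config = config if config is not None else SimConfig()
    genome = simulate_annotation(config, seed)
    tags = simulate_tags(genome, seed)
    anchors, training = train_profile(genome, tags)
    run = PipelineRun(genome=genome, tags=tags, anchors=anchors, training=training)
    for cell in (cells if cells is not None else config.cell_types):
        run.cells[cell] = scan_cell(genome, tags, training, cell, cutoff=cutoff)
    return run
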