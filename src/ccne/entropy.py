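"""Local, cell-specific and stage-level causal network entropy.

The local entropy of a gene in a cell is the Shannon entropy (natural log) of
the normalized outgoing causal weights of its localized network, averaged over
the Q outgoing edges, and scaled by the cell's leave-one-out contribution to
the gene's expression standard deviation within its stage group:

    LH = [-(1/Q) * sum_j P_j log P_j] * |SD(E) - SD(E without cell l)|

Cells whose removal barely changes the spread, or genes with at most one
outgoing edge, score zero. The cell-specific score H^l sums the top-fraction
local entropies of the cell's column, and the stage score H_t is the mean of
H^l over the cells of a stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causal import LocalizedCausalNetwork, NeighborPlan, StageCausalEngine
from .datasets import BackgroundNetwork, ExpressionDataset

__all__ = [
    "LocalEntropyMatrix",
    "CcneScores",
    "loo_sd_term",
    "loo_sd_terms",
    "local_ccne",
    "local_entropy_matrix",
    "cell_ccne",
    "stage_ccne",
    "ccne_scores",
    "top_gene_count",
]


def loo_sd_term(gene_values, l: int) -> float:
    """|SD of all M values - SD excluding cell l| (sample SD, M >= 3)."""
    v = np.asarray(gene_values, dtype=float)
    m = v.size
    if m < 3:
        raise ValueError(f"leave-one-out SD needs a stage group of M >= 3 cells, got {m}")
    if not 0 <= l < m:
        raise IndexError(f"cell index {l} out of range for M={m}")
    full = float(np.std(v, ddof=1))
    rest = float(np.std(np.delete(v, l), ddof=1))
    return abs(full - rest)


def loo_sd_terms(gene_values) -> np.ndarray:
    """Vectorized leave-one-out SD terms for every cell of one group.

    Uses the exact sum-of-squares downdate
    SS_{-l} = SS - (x_l - mean)^2 * M/(M-1); agreement with the direct
    two-pass computation is exercised in the test suite.
    """
    v = np.asarray(gene_values, dtype=float)
    m = v.size
    if m < 3:
        raise ValueError(f"leave-one-out SD needs a stage group of M >= 3 cells, got {m}")
    mean = v.mean()
    dev = v - mean
    ss = float(np.sum(dev * dev))
    full = math.sqrt(ss / (m - 1))
    ss_loo = np.maximum(ss - dev * dev * (m / (m - 1)), 0.0)
    rest = np.sqrt(ss_loo / (m - 2))
    return np.abs(full - rest)


def local_ccne(localized: LocalizedCausalNetwork, sd_term: float) -> float:
    """Local entropy of one localized network scaled by the SD term.

    Returns 0 for Q <= 1 (a single outgoing edge carries no entropy and an
    empty star encodes no detectable causal output).
    """
    if sd_term < 0:
        raise ValueError("sd_term must be non-negative")
    q = localized.q
    if q <= 1:
        return 0.0
    w = localized.weights
    p = w / w.sum()
    ent = -(1.0 / q) * float(np.sum(p * np.log(p)))
    return ent * sd_term


def _entropy_factor(weights: np.ndarray) -> float:
    """-(1/Q) sum P log P over the strictly positive weights, 0 for Q <= 1."""
    w = weights[weights > 0]
    q = w.size
    if q <= 1:
        return 0.0
    p = w / w.sum()
    return -(1.0 / q) * float(np.sum(p * np.log(p)))


@dataclass
class LocalEntropyMatrix:
    """Gene x cell matrix of local entropies with its configuration echo."""

    frame: pd.DataFrame  # analyzed genes x all cells
    dataset: ExpressionDataset
    analyzed_genes: list[str]
    excluded_genes: list[str]
    plan: NeighborPlan
    config: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def column(self, cell_id: str) -> pd.Series:
        return self.frame[cell_id]

    def stage_frame(self, stage) -> pd.DataFrame:
        cols = [c for c in self.frame.columns if self.dataset.stage_of_cell[c] == stage]
        return self.frame[cols]


def local_entropy_matrix(
    dataset: ExpressionDataset,
    background: BackgroundNetwork,
    plan: NeighborPlan | None = None,
) -> LocalEntropyMatrix:
    """Local entropy for every (analyzed gene, cell) of the dataset.

    Genes absent from the background network are excluded from the analysis
    and recorded in ``excluded_genes``.
    """
    plan = plan or NeighborPlan()
    analyzed = background.match(dataset)
    excluded = [g for g in dataset.gene_ids if g not in set(analyzed)]
    gi = dataset.gene_index()
    out = np.zeros((len(analyzed), dataset.n_cells))
    if plan.scope == "global":
        groups = [np.arange(dataset.n_cells)]
    else:
        groups = [dataset.stage_columns(s) for s in dataset.stages_present()]
    for columns in groups:
        if len(columns) < 3:
            raise ValueError(
                "stage groups must contain at least 3 cells for leave-one-out SD"
            )
        engine = StageCausalEngine(dataset, background, plan, columns, analyzed_genes=analyzed)
        outw = engine.out_weight_arrays()
        for row, g in enumerate(analyzed):
            sd = loo_sd_terms(dataset.values[gi[g], columns])
            _, wmat = outw[g]
            if wmat.shape[0] == 0:
                continue
            ent = np.array([_entropy_factor(wmat[:, j]) for j in range(len(columns))])
            out[row, columns] = ent * sd
    frame = pd.DataFrame(out, index=analyzed, columns=dataset.cell_ids)
    return LocalEntropyMatrix(
        frame=frame,
        dataset=dataset,
        analyzed_genes=analyzed,
        excluded_genes=excluded,
        plan=plan,
        config={"plan": plan.to_dict(), "log_base": "e"},
    )


def top_gene_count(n_genes: int, top_fraction: float) -> int:
    """S = max(1, ceil(fraction * G)) genes enter each cell's score."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    return max(1, int(math.ceil(top_fraction * n_genes)))


def cell_ccne(column: pd.Series, top_fraction: float = 0.05) -> tuple[float, list[str]]:
    """Cell score: sum of the S largest local entropies of one cell's column.

    Ties at the cutoff are broken by lexicographic gene id, so the score and
    the recorded top-gene list are deterministic.
    """
    if len(column) == 0:
        raise ValueError("empty local-entropy column")
    s = top_gene_count(len(column), top_fraction)
    order = sorted(column.items(), key=lambda kv: (-kv[1], kv[0]))
    top = order[:s]
    return float(sum(v for _, v in top)), [g for g, _ in top]


@dataclass
class CcneScores:
    """Per-cell scores H^l with the aligned per-stage means H_t."""

    per_cell: pd.Series  # indexed by cell id, in dataset order
    stage_of_cell: dict
    stage_order: list
    top_fraction: float
    s: int
    top_genes: dict[str, list[str]] = field(default_factory=dict)

    def stage_values(self, stage) -> np.ndarray:
        cells = [c for c in self.per_cell.index if self.stage_of_cell[c] == stage]
        return self.per_cell[cells].to_numpy()

    @property
    def stage_means(self) -> pd.Series:
        return stage_ccne(self.per_cell, self.stage_of_cell, self.stage_order)


def stage_ccne(per_cell: pd.Series, stage_of_cell: dict, stage_order: list) -> pd.Series:
    """Arithmetic mean of per-cell scores within each stage, in stage order."""
    stages = [s for s in stage_order if any(stage_of_cell[c] == s for c in per_cell.index)]
    means = {}
    for s in stages:
        vals = [per_cell[c] for c in per_cell.index if stage_of_cell[c] == s]
        means[s] = float(np.mean(vals))
    return pd.Series([means[s] for s in stages], index=stages, name="H_t")


def ccne_scores(matrix: LocalEntropyMatrix, top_fraction: float = 0.05) -> CcneScores:
    """Cell-specific scores for every cell of a local-entropy matrix."""
    per_cell = {}
    top_genes = {}
    for c in matrix.frame.columns:
        h, top = cell_ccne(matrix.frame[c], top_fraction)
        per_cell[c] = h
        top_genes[c] = top
    ds = matrix.dataset
    return CcneScores(
        per_cell=pd.Series(per_cell, name="H_l").reindex(ds.cell_ids),
        stage_of_cell=dict(ds.stage_of_cell),
        stage_order=list(ds.stage_order),
        top_fraction=top_fraction,
        s=top_gene_count(len(matrix.analyzed_genes), top_fraction),
        top_genes=top_genes,
    )
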