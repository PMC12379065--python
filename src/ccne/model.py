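"""Model/Results interface tying the pipeline together.

``CCNEModel`` holds the data and configuration; ``fit()`` runs causal-network
inference, entropy scoring and critical-stage detection, returning a
``CCNEResults`` with the local-entropy matrix, per-cell and per-stage scores,
the detection report, and downstream helpers (signaling genes, dark genes,
plotting, file export).
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._version import __version__
from .causal import NeighborPlan
from .datasets import BackgroundNetwork, ExpressionDataset
from .detect import (
    CriticalStateReport,
    DarkGeneCall,
    SignalingGeneSet,
    detect_critical_stage,
    identify_dark_genes,
    select_signaling_genes,
)
from .entropy import LocalEntropyMatrix, ccne_scores, local_entropy_matrix

__all__ = ["CCNEModel", "CCNEResults"]


class CCNEModel:
    """Cell-specific causal network entropy model for staged expression data.

    Parameters
    ----------
    dataset : ExpressionDataset
        Gene x cell matrix with ordered stage labels.
    background : BackgroundNetwork
        Undirected prior interaction network restricting causal edges.
    plan : NeighborPlan, optional
        Neighborhood configuration (default: k = ceil(sqrt(M)) per stage,
        index-order ties, stage-scoped neighborhoods).
    top_fraction : float
        Fraction of analyzed genes summed into each cell's score.
    alpha : float
        Significance level of the stage-detection test.
    x_assignment, reference : str
        Detection-test configuration; see :func:`ccne.detect.detect_critical_stage`.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        background: BackgroundNetwork,
        plan: NeighborPlan | None = None,
        top_fraction: float = 0.05,
        alpha: float = 0.05,
        x_assignment: str = "candidate",
        reference: str = "baseline",
        log1p: bool = False,
    ) -> None:
        if log1p:
            dataset = ExpressionDataset(
                values=np.log1p(dataset.values),
                gene_ids=dataset.gene_ids,
                cell_ids=dataset.cell_ids,
                stage_of_cell=dataset.stage_of_cell,
                stage_order=dataset.stage_order,
                meta=dict(dataset.meta),
            )
        self.dataset = dataset
        self.background = background
        self.plan = plan or NeighborPlan()
        self.top_fraction = top_fraction
        self.alpha = alpha
        self.x_assignment = x_assignment
        self.reference = reference
        self.log1p = log1p

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        stage_of_cell: dict,
        stage_order: list,
        background: BackgroundNetwork | None = None,
        **kwargs,
    ) -> "CCNEModel":
        """Build from a genes x cells DataFrame; a missing background network
        defaults to the complete graph over the frame's genes."""
        ds = ExpressionDataset.from_dataframe(frame, stage_of_cell, stage_order)
        bg = background or BackgroundNetwork.complete(ds.gene_ids)
        return cls(ds, bg, **kwargs)

    def config(self) -> dict:
        return {
            "plan": self.plan.to_dict(),
            "top_fraction": self.top_fraction,
            "alpha": self.alpha,
            "x_assignment": self.x_assignment,
            "reference": self.reference,
            "log1p": self.log1p,
            "version": __version__,
        }

    def fit(self) -> "CCNEResults":
        matrix = local_entropy_matrix(self.dataset, self.background, self.plan)
        scores = ccne_scores(matrix, self.top_fraction)
        report = detect_critical_stage(
            scores,
            alpha=self.alpha,
            x_assignment=self.x_assignment,
            reference=self.reference,
            config=self.config(),
        )
        return CCNEResults(model=self, local_entropy=matrix, scores=scores, report=report)


@dataclass
class CCNEResults:
    """Fitted entropies, scores and the critical-state call."""

    model: CCNEModel
    local_entropy: LocalEntropyMatrix
    scores: "pd.api.extensions.ExtensionArray | object"
    report: CriticalStateReport
    _signaling: SignalingGeneSet | None = field(default=None, repr=False)

    # -- core accessors --------------------------------------------------
    @property
    def entropy_frame(self) -> pd.DataFrame:
        """Analyzed genes x cells local-entropy matrix (the CCNE matrix)."""
        return self.local_entropy.frame

    @property
    def per_cell(self) -> pd.Series:
        return self.scores.per_cell

    @property
    def stage_means(self) -> pd.Series:
        return self.report.stage_means

    @property
    def detected_stage(self):
        return self.report.detected_stage

    # -- downstream ------------------------------------------------------
    def signaling_genes(self, fraction: float = 0.05, stage=None) -> SignalingGeneSet:
        stage = stage if stage is not None else self.detected_stage
        if stage is None:
            raise ValueError("no critical stage detected; pass stage= explicitly")
        return select_signaling_genes(
            self.local_entropy, self.model.background, stage, fraction
        )

    def dark_genes(
        self,
        genes: list[str] | None = None,
        before_stage=None,
        critical_stage=None,
        fraction: float = 0.05,
        alpha_expr: float = 0.05,
        alpha_ccne: float = 0.05,
        test: str = "ranksums",
    ) -> list[DarkGeneCall]:
        critical_stage = (
            critical_stage if critical_stage is not None else self.detected_stage
        )
        if critical_stage is None:
            raise ValueError("no critical stage detected; pass critical_stage=")
        stages = list(self.stage_means.index)
        if before_stage is None:
            pos = stages.index(critical_stage)
            if pos == 0:
                raise ValueError("critical stage is the first stage; pass before_stage=")
            before_stage = stages[pos - 1]
        if genes is None:
            genes = self.signaling_genes(fraction, stage=critical_stage).genes
        return identify_dark_genes(
            self.model.dataset,
            self.local_entropy,
            genes,
            before_stage,
            critical_stage,
            alpha_expr=alpha_expr,
            alpha_ccne=alpha_ccne,
            test=test,
        )

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        ds = self.model.dataset
        lines = []
        lines.append("Cell-specific causal network entropy")
        lines.append("=" * 54)
        lines.append(
            f"genes analyzed: {len(self.local_entropy.analyzed_genes)}"
            f" / {ds.n_genes}    cells: {ds.n_cells}"
            f"    stages: {len(self.stage_means)}"
        )
        excl = len(self.local_entropy.excluded_genes)
        if excl:
            lines.append(f"genes outside background network (excluded): {excl}")
        plan = self.model.plan
        kdesc = plan.k if plan.k is not None else (
            f"{plan.k_fraction}*M" if plan.k_fraction else "ceil(sqrt(M))"
        )
        lines.append(
            f"neighbors k = {kdesc}, ties = {plan.tie_policy}, scope = {plan.scope};"
            f" top fraction = {self.model.top_fraction} (S = {self.scores.s})"
        )
        lines.append("-" * 54)
        lines.append(f"{'stage':<16}{'cells':>6}{'H_t':>12}{'P':>12}  flag")
        by_stage = {c.stage: c for c in self.report.candidates}
        sizes = ds.stage_sizes()
        for stage, h in self.stage_means.items():
            cand = by_stage.get(stage)
            p = f"{cand.p_value:.3g}" if cand else "-"
            mark = "  *" if cand and cand.flagged else ""
            lines.append(f"{str(stage):<16}{sizes.get(stage, 0):>6}{h:>12.5g}{p:>12}{mark}")
        lines.append("-" * 54)
        if self.detected_stage is not None:
            lines.append(
                f"detected pre-transition stage: {self.detected_stage}"
                f" (alpha = {self.report.alpha})"
            )
        else:
            lines.append(f"no pre-transition stage detected (alpha = {self.report.alpha})")
        return "\n".join(lines)

    def plot_series(self, ax=None):
        """H_t trajectory with per-stage per-cell score distributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        stages = list(self.stage_means.index)
        data = [self.scores.stage_values(s) for s in stages]
        ax.boxplot(data, positions=range(len(stages)), widths=0.5)
        ax.plot(range(len(stages)), self.stage_means.values, "o-", color="firebrick")
        ax.set_xticks(range(len(stages)))
        ax.set_xticklabels([str(s) for s in stages], rotation=45, ha="right")
        ax.set_ylabel("cell-specific CCNE $H^l$")
        ax.set_xlabel("stage")
        if self.detected_stage is not None:
            ax.axvline(stages.index(self.detected_stage), ls="--", color="gray")
        return ax

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()

    def __repr__(self) -> str:
        det = self.detected_stage
        return (
            f"<CCNEResults: {len(self.local_entropy.analyzed_genes)} genes, "
            f"{self.model.dataset.n_cells} cells, detected={det!r}>"
        )

    def save(self, outdir) -> dict:
        """Write all standard outputs; see :func:`ccne.io.write_results`."""
        from .io import write_results

        return write_results(self, outdir)


def _wrap(text: str) -> str:  # pragma: no cover - helper for docs
    return textwrap.fill(text, 78)
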