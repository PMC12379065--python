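"""Pre-transition stage detection, signaling genes, and dark genes.

A stage t is flagged as the pre-transition (critical) state when its mean
score rises above the previous stage's and a one-sample t test

    SC = sqrt(m) * (mean(X) - x) / SD(X)

declares the deviation significant (two-sided P < alpha, t distribution with
m - 1 degrees of freedom). By default X holds the per-cell scores of the
candidate stage and x is the mean score over all earlier (before-transition)
cells: treating the pooled prior mean as the test's constant keeps the
directional false-alarm rate near its nominal level, whereas testing a
single noisy stage mean against the other stage's cells roughly doubles the
variance of the statistic under the null. Both assignments are available.
The earliest flagged stage is reported as the detection, since an early
warning must precede the transition itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._version import __version__ as _pkg_version
from .datasets import BackgroundNetwork, ExpressionDataset
from .entropy import CcneScores, LocalEntropyMatrix, top_gene_count

__all__ = [
    "CriticalStateReport",
    "SignalingGeneSet",
    "DarkGeneCall",
    "one_sample_t",
    "detect_critical_stage",
    "select_signaling_genes",
    "identify_dark_genes",
]


def one_sample_t(x_vector, x: float) -> tuple[float, float]:
    """One-sample t statistic of vector X against the constant x, with its P.

    Degenerate SD(X) = 0 is reported as P = 1 when mean(X) = x and P = 0
    otherwise (with a warning); SC is then signed infinity or 0.
    """
    xv = np.asarray(x_vector, dtype=float)
    m = xv.size
    if m < 2:
        raise ValueError("one-sample t test needs m >= 2 observations")
    mean = float(xv.mean())
    sd = float(np.std(xv, ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate one-sample t test: SD(X) = 0")
        if mean == x:
            return 0.0, 1.0
        return float(np.sign(mean - x)) * float("inf"), 0.0
    sc = np.sqrt(m) * (mean - x) / sd
    p = 2.0 * float(stats.t.sf(abs(sc), df=m - 1))
    return float(sc), min(p, 1.0)


@dataclass
class StageCandidate:
    stage: object
    reference_stage: object
    h_t: float
    h_prev: float
    sc: float
    p_value: float
    m: int
    flagged: bool

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "reference_stage": self.reference_stage,
            "H_t": self.h_t,
            "H_prev": self.h_prev,
            "SC": self.sc,
            "p_value": self.p_value,
            "m": self.m,
            "flagged": self.flagged,
        }


@dataclass
class CriticalStateReport:
    """Detection result: the H_t series, all candidate tests, and the call."""

    stage_means: pd.Series
    candidates: list[StageCandidate]
    detected_stage: object | None
    alpha: float
    x_assignment: str
    reference: str
    per_cell: pd.Series
    stage_of_cell: dict
    config: dict = field(default_factory=dict)
    version: str = _pkg_version

    @property
    def flagged_stages(self) -> list:
        return [c.stage for c in self.candidates if c.flagged]

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "alpha": self.alpha,
            "x_assignment": self.x_assignment,
            "reference": self.reference,
            "stage_order": [str(s) for s in self.stage_means.index],
            "H_t": {str(s): float(v) for s, v in self.stage_means.items()},
            "candidates": [c.to_dict() for c in self.candidates],
            "detected_stage": self.detected_stage,
            "flagged_stages": self.flagged_stages,
            "per_cell_H": {c: float(v) for c, v in self.per_cell.items()},
            "stage_of_cell": {c: self.stage_of_cell[c] for c in self.per_cell.index},
            "config": self.config,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)

    @classmethod
    def from_dict(cls, d: dict) -> "CriticalStateReport":
        stages = d["stage_order"]
        means = pd.Series([d["H_t"][s] for s in stages], index=stages, name="H_t")
        cands = [
            StageCandidate(
                stage=c["stage"],
                reference_stage=c["reference_stage"],
                h_t=c["H_t"],
                h_prev=c["H_prev"],
                sc=c["SC"],
                p_value=c["p_value"],
                m=c["m"],
                flagged=c["flagged"],
            )
            for c in d["candidates"]
        ]
        return cls(
            stage_means=means,
            candidates=cands,
            detected_stage=d["detected_stage"],
            alpha=d["alpha"],
            x_assignment=d["x_assignment"],
            reference=d["reference"],
            per_cell=pd.Series(d["per_cell_H"], name="H_l"),
            stage_of_cell=d["stage_of_cell"],
            config=d.get("config", {}),
            version=d.get("version", _pkg_version),
        )

    @classmethod
    def from_json(cls, path) -> "CriticalStateReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def detect_critical_stage(
    scores: CcneScores,
    alpha: float = 0.05,
    x_assignment: str = "candidate",
    reference: str = "baseline",
    config: dict | None = None,
) -> CriticalStateReport:
    """Flag stages whose score rises significantly above the reference.

    Parameters
    ----------
    scores : CcneScores
        Per-cell and per-stage scores.
    alpha : float
        Significance level for criterion (b).
    x_assignment : {"candidate", "reference"}
        Which stage supplies the vector X of the one-sample test: the
        candidate stage (x is then the reference mean, the default) or the
        reference stage (x is then the candidate mean).
    reference : {"baseline", "previous"}
        Compare against the pool of all earlier stages (default) or against
        the immediately preceding stage only.
    """
    if x_assignment not in ("reference", "candidate"):
        raise ValueError("x_assignment must be 'reference' or 'candidate'")
    if reference not in ("previous", "baseline"):
        raise ValueError("reference must be 'previous' or 'baseline'")
    means = scores.stage_means
    stages = list(means.index)
    if len(stages) < 2:
        raise ValueError("detection needs at least 2 stages")
    candidates: list[StageCandidate] = []
    for t in range(1, len(stages)):
        stage = stages[t]
        prev_stage = stages[t - 1]
        if reference == "previous":
            ref_stages = [prev_stage]
            ref_label = prev_stage
        else:
            ref_stages = stages[:t]
            ref_label = "pooled:" + ",".join(str(s) for s in ref_stages)
        ref_cells = np.concatenate([scores.stage_values(s) for s in ref_stages])
        h_t = float(means[stage])
        h_prev = float(means[prev_stage])
        if x_assignment == "reference":
            sc, p = one_sample_t(ref_cells, h_t)
        else:
            sc, p = one_sample_t(scores.stage_values(stage), float(ref_cells.mean()))
        flagged = (h_t > h_prev) and (p < alpha)
        candidates.append(
            StageCandidate(
                stage=stage,
                reference_stage=ref_label,
                h_t=h_t,
                h_prev=h_prev,
                sc=sc,
                p_value=p,
                m=len(ref_cells) if x_assignment == "reference" else len(scores.stage_values(stage)),
                flagged=flagged,
            )
        )
    detected = next((c.stage for c in candidates if c.flagged), None)
    return CriticalStateReport(
        stage_means=means,
        candidates=candidates,
        detected_stage=detected,
        alpha=alpha,
        x_assignment=x_assignment,
        reference=reference,
        per_cell=scores.per_cell,
        stage_of_cell=dict(scores.stage_of_cell),
        config=dict(config or {}),
    )


@dataclass
class SignalingGeneSet:
    """Top genes by local entropy at the critical stage, with their subgraph."""

    critical_stage: object
    ranked: pd.Series  # mean local entropy at the critical stage, descending
    genes: list[str]
    subgraph_nodes: list[str]
    subgraph_edges: list[tuple[str, str]]


def select_signaling_genes(
    matrix: LocalEntropyMatrix,
    background: BackgroundNetwork,
    stage,
    fraction: float = 0.05,
) -> SignalingGeneSet:
    """Top-fraction genes by mean local entropy over the stage's cells.

    The selected genes are mapped back onto the background network and the
    largest connected induced subgraph is extracted (ties by node count, then
    edge count, then lexicographically smallest member).
    """
    sub = matrix.stage_frame(stage)
    if sub.shape[1] == 0:
        raise ValueError(f"no cells in stage {stage!r}")
    ranked_all = sub.mean(axis=1)
    order = sorted(ranked_all.items(), key=lambda kv: (-kv[1], kv[0]))
    n = top_gene_count(len(order), fraction)
    genes = [g for g, _ in order[:n]]
    import networkx as nx

    induced = background.graph.subgraph(genes)
    components = [sorted(c) for c in nx.connected_components(induced)]
    if not components:
        best: list[str] = []
    else:
        # largest by node count, then edge count; remaining ties go to the
        # component whose smallest member sorts first
        ranked_components = sorted(
            components,
            key=lambda c: (-len(c), -induced.subgraph(c).number_of_edges(), min(c)),
        )
        best = ranked_components[0]
    best_graph = induced.subgraph(best)
    return SignalingGeneSet(
        critical_stage=stage,
        ranked=pd.Series({g: float(ranked_all[g]) for g in genes}).sort_values(ascending=False),
        genes=genes,
        subgraph_nodes=sorted(best),
        subgraph_edges=sorted(tuple(sorted(e)) for e in best_graph.edges),
    )


@dataclass
class DarkGeneCall:
    """Per-gene verdict: expression-stable but entropy-shifted."""

    gene: str
    p_expression: float
    p_ccne: float
    q_ccne: float
    dark: bool

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "p_expression": self.p_expression,
            "p_ccne": self.p_ccne,
            "q_ccne": self.q_ccne,
            "dark": self.dark,
        }


def _two_sample_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return 1.0  # identical constant in both stages: no difference
    if test == "ranksums":
        return float(stats.ranksums(a, b).pvalue)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adj[idx] = running
    return adj


def identify_dark_genes(
    dataset: ExpressionDataset,
    matrix: LocalEntropyMatrix,
    genes: list[str],
    before_stage,
    critical_stage,
    alpha_expr: float = 0.05,
    alpha_ccne: float = 0.05,
    test: str = "ranksums",
) -> list[DarkGeneCall]:
    """Call dark genes among a candidate (signaling) gene set.

    A gene is dark when its expression does not differ significantly between
    the before-transition and pre-transition stages (two-sided rank-sum
    P >= alpha_expr, raw) while its local entropy does (Benjamini-Hochberg
    adjusted P < alpha_ccne).
    """
    if test not in ("ranksums", "ttest"):
        raise ValueError("test must be 'ranksums' or 'ttest'")
    cols_before = dataset.stage_columns(before_stage)
    cols_crit = dataset.stage_columns(critical_stage)
    if len(cols_before) < 3 or len(cols_crit) < 3:
        raise ValueError("both stages need at least 3 cells for dark-gene testing")
    gi = dataset.gene_index()
    p_expr = []
    p_ccne = []
    for g in genes:
        if g not in gi or g not in matrix.frame.index:
            raise KeyError(f"gene {g!r} not among analyzed genes")
        ev = dataset.values[gi[g]]
        p_expr.append(_two_sample_p(ev[cols_before], ev[cols_crit], test))
        row = matrix.frame.loc[g].to_numpy()
        p_ccne.append(_two_sample_p(row[cols_before], row[cols_crit], test))
    p_expr = np.asarray(p_expr)
    p_ccne = np.asarray(p_ccne)
    q_ccne = _bh_adjust(p_ccne) if len(genes) else p_ccne
    calls = []
    for i, g in enumerate(genes):
        dark = (p_expr[i] >= alpha_expr) and (q_ccne[i] < alpha_ccne)
        calls.append(
            DarkGeneCall(
                gene=g,
                p_expression=float(p_expr[i]),
                p_ccne=float(p_ccne[i]),
                q_ccne=float(q_ccne[i]),
                dark=bool(dark),
            )
        )
    return calls
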