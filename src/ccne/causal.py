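"""Cell-specific causal network inference via cross-map mutual information.

For one cell l within a stage group of M cells, the causal weight from gene
g_x to gene g_y is a pointwise mutual-information score of the overlap between
the two genes' nearest-neighbor cell sets around cell l:

    w_l(g_x, g_y) = p_xy * log(p_xy / (p_x * p_y))

where p_x = |NN_l(g_x)| / M, p_y = |NN_l(g_y)| / M and p_xy is the fraction of
cells shared by the two neighbor sets (the cross-map of g_x's neighborhood
into g_y's coordinate is realized as the common cell-index image, so the
intersection is taken over cell indices). A positive weight indicates a
functional dependency and contributes a directed edge; non-positive weights
mean no edge. With equal neighbor counts the score is symmetric in its
arguments, so both directions of a background edge receive the same weight;
both are reported.

Neighborhoods are computed within the cell's stage group by default so that
per-stage statistics are not confounded by cross-stage mixing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import BackgroundNetwork, ExpressionDataset

__all__ = [
    "NeighborPlan",
    "CellCausalNetwork",
    "LocalizedCausalNetwork",
    "neighbor_sets",
    "neighbor_matrix",
    "cross_map_weight",
    "build_cell_network",
    "localized_networks",
    "default_k",
]

TIE_POLICIES = ("index_order", "seeded_jitter")
AGGREGATIONS = ("mean", "max")
#: magnitude of the deterministic jitter (relative to the data range) used by
#: the ``seeded_jitter`` tie policy
_JITTER_SCALE = 1e-9


def default_k(m: int) -> int:
    """Default neighbor count ceil(sqrt(M)): the usual bias/variance compromise."""
    return int(math.ceil(math.sqrt(m)))


@dataclass(frozen=True)
class NeighborPlan:
    """How nearest-neighbor cell sets are formed.

    Parameters
    ----------
    k : int or None
        Neighbor count. ``None`` means ceil(sqrt(M)) per stage group, unless
        ``k_fraction`` is given.
    k_fraction : float or None
        Alternative to ``k``: neighbor count as a fraction of the group size
        (at least 1).
    tie_policy : {"index_order", "seeded_jitter"}
        Deterministic resolution of equidistant cells: stable by cell index,
        or by adding seeded jitter of relative magnitude 1e-9.
    exclude_self : bool
        A cell is never its own neighbor by default.
    multi_scale_ks : tuple of int, optional
        Strictly increasing ladder of neighbor counts; the per-edge weight is
        then the ``aggregation`` of the single-k weights (the "varying
        neighbor size" mode).
    scope : {"stage", "global"}
        Universe over which neighbors and M are taken.
    """

    k: int | None = None
    k_fraction: float | None = None
    tie_policy: str = "index_order"
    exclude_self: bool = True
    multi_scale_ks: tuple[int, ...] | None = None
    aggregation: str = "mean"
    scope: str = "stage"
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.scope not in ("stage", "global"):
            raise ValueError("scope must be 'stage' or 'global'")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k_fraction is not None and not (0 < self.k_fraction < 1):
            raise ValueError("k_fraction must lie in (0, 1)")
        if self.multi_scale_ks is not None:
            ks = tuple(int(k) for k in self.multi_scale_ks)
            if list(ks) != sorted(set(ks)) or any(k < 1 for k in ks):
                raise ValueError("multi_scale_ks must be strictly increasing positive ints")
            object.__setattr__(self, "multi_scale_ks", ks)

    def resolve_k(self, m: int) -> int:
        """Concrete neighbor count for a group of ``m`` cells (validated)."""
        if self.k is not None:
            k = self.k
        elif self.k_fraction is not None:
            k = max(1, int(math.ceil(self.k_fraction * m)))
        else:
            k = default_k(m)
        if not 1 <= k < m:
            raise ValueError(f"neighbor count k={k} must satisfy 1 <= k < M={m}")
        return k

    def ladder(self, m: int) -> tuple[int, ...]:
        """Neighbor counts actually evaluated for a group of ``m`` cells."""
        if self.multi_scale_ks is not None:
            bad = [k for k in self.multi_scale_ks if not 1 <= k < m]
            if bad:
                raise ValueError(f"multi-scale k values {bad} must satisfy 1 <= k < M={m}")
            return self.multi_scale_ks
        return (self.resolve_k(m),)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "k_fraction": self.k_fraction,
            "tie_policy": self.tie_policy,
            "exclude_self": self.exclude_self,
            "multi_scale_ks": list(self.multi_scale_ks) if self.multi_scale_ks else None,
            "aggregation": self.aggregation,
            "scope": self.scope,
            "jitter_seed": self.jitter_seed,
        }


@dataclass
class LocalizedCausalNetwork:
    """Star subnetwork: one center gene with its outgoing neighbors and weights."""

    center: str
    neighbors: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.neighbors) != len(self.weights):
            raise ValueError("neighbors and weights must align")
        if np.any(self.weights <= 0):
            raise ValueError("localized-network weights must be strictly positive")
        if self.center in self.neighbors:
            raise ValueError("center gene cannot be its own neighbor")
        if len(set(self.neighbors)) != len(self.neighbors):
            raise ValueError("duplicate outgoing neighbors")

    @property
    def q(self) -> int:
        return len(self.neighbors)


@dataclass
class CellCausalNetwork:
    """Directed weighted causal network of a single cell.

    ``edges`` maps (source, target) -> weight; only strictly positive weights
    are stored, and every directed edge is supported by a background edge.
    """

    cell_id: str
    genes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if w <= 0:
                raise ValueError(f"non-positive weight stored for edge {a}->{b}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_edges(self, gene: str) -> list[tuple[str, float]]:
        return [(b, w) for (a, b), w in self.edges.items() if a == gene]


# ---------------------------------------------------------------------------
# neighbor machinery
# ---------------------------------------------------------------------------

def _jittered(values: np.ndarray, plan: NeighborPlan) -> np.ndarray:
    rng = np.random.default_rng(plan.jitter_seed)
    span = float(np.ptp(values)) or 1.0
    return values + rng.uniform(0.0, _JITTER_SCALE * span, size=values.shape)


def neighbor_matrix(values, plan: NeighborPlan, k: int | None = None) -> np.ndarray:
    """Boolean M x M matrix B with B[l, i] True iff cell i is a neighbor of cell l.

    Neighbors of cell l are the ``k`` cells whose scalar expression is nearest
    to cell l's value in absolute difference; ties are resolved
    deterministically by the plan's tie policy. Exactly ``k`` True entries per
    row.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D per-cell expression vector")
    m = v.size
    if m < 2:
        raise ValueError("neighbor sets need a group of M >= 2 cells")
    if k is None:
        k = plan.resolve_k(m)
    if not 1 <= k < m:
        raise ValueError(f"neighbor count k={k} must satisfy 1 <= k < M={m}")
    if plan.tie_policy == "seeded_jitter":
        v = _jittered(v, plan)
    dist = np.abs(v[None, :] - v[:, None])  # dist[l, i] = |v_i - v_l|
    if plan.exclude_self:
        np.fill_diagonal(dist, np.inf)
    # stable argsort resolves exact ties by ascending cell index
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    out = np.zeros((m, m), dtype=bool)
    rows = np.repeat(np.arange(m), k)
    out[rows, order.ravel()] = True
    return out


def neighbor_sets(values, plan: NeighborPlan, k: int | None = None) -> list[set[int]]:
    """Per-cell neighbor sets (cell indices) for one gene within one group."""
    b = neighbor_matrix(values, plan, k=k)
    return [set(np.flatnonzero(row)) for row in b]


# ---------------------------------------------------------------------------
# cross-map weight
# ---------------------------------------------------------------------------

def cross_map_weight(gx_neighbors, gy_neighbors, m: int) -> float:
    """Cross-map mutual-information weight between two neighbor sets.

    w = p_xy * log(p_xy / (p_x * p_y)) with natural log and 0*log(0) := 0,
    where p_x, p_y are the neighbor-set fractions and p_xy the fraction of
    shared cells among all M cells of the group.
    """
    sx, sy = set(gx_neighbors), set(gy_neighbors)
    if not sx or not sy:
        raise ValueError("neighbor sets must be non-empty")
    if len(sx) >= m or len(sy) >= m:
        raise ValueError("neighbor sets must be smaller than the group size M")
    inter = len(sx & sy)
    if inter == 0:
        return 0.0
    p_xy = inter / m
    p_x = len(sx) / m
    p_y = len(sy) / m
    return p_xy * math.log(p_xy / (p_x * p_y))


def _weights_from_matrices(bx: np.ndarray, by: np.ndarray, m: int, k: int) -> np.ndarray:
    """Vectorized w_l for all cells at once from two neighbor boolean matrices."""
    inter = np.einsum("li,li->l", bx.astype(np.int64), by.astype(np.int64)).astype(float)
    p_xy = inter / m
    p = k / m
    with np.errstate(divide="ignore", invalid="ignore"):
        w = p_xy * np.log(p_xy / (p * p))
    w[inter == 0] = 0.0
    return w


# ---------------------------------------------------------------------------
# stage-level engine
# ---------------------------------------------------------------------------

class StageCausalEngine:
    """All cell-specific causal networks of one stage group, vectorized.

    Computes, per analyzed gene, the boolean neighbor matrix at each neighbor
    count of the plan's ladder, then evaluates every background edge for every
    cell of the group in one shot. Multi-scale plans aggregate the per-k
    weights (mean or max) before the positivity threshold is applied.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        background: BackgroundNetwork,
        plan: NeighborPlan,
        columns: np.ndarray,
        analyzed_genes: list[str] | None = None,
    ) -> None:
        self.dataset = dataset
        self.plan = plan
        self.columns = np.asarray(columns, dtype=int)
        self.m = len(self.columns)
        if self.m < 2:
            raise ValueError("stage group must contain at least 2 cells")
        self.genes = (
            analyzed_genes if analyzed_genes is not None else background.match(dataset)
        )
        gi = dataset.gene_index()
        self.ks = plan.ladder(self.m)
        self._nbr: dict[int, dict[str, np.ndarray]] = {}
        sub = dataset.values[:, self.columns]
        for k in self.ks:
            mats = {}
            for g in self.genes:
                mats[g] = neighbor_matrix(sub[gi[g]], plan, k=k)
            self._nbr[k] = mats
        # undirected pairs to evaluate
        gene_set = set(self.genes)
        self.pairs = [
            (a, b) for a, b in background.edges() if a in gene_set and b in gene_set
        ]
        self._pair_weights: dict[tuple[str, str], np.ndarray] = {}
        for a, b in self.pairs:
            per_k = np.stack(
                [
                    _weights_from_matrices(self._nbr[k][a], self._nbr[k][b], self.m, k)
                    for k in self.ks
                ]
            )
            agg = per_k.mean(axis=0) if plan.aggregation == "mean" else per_k.max(axis=0)
            self._pair_weights[(a, b)] = agg

    def weight(self, a: str, b: str) -> np.ndarray:
        """Per-cell weights for the (unordered) evaluated pair a-b."""
        if (a, b) in self._pair_weights:
            return self._pair_weights[(a, b)]
        return self._pair_weights[(b, a)]

    def network_for(self, local_index: int) -> CellCausalNetwork:
        """CellCausalNetwork of the ``local_index``-th cell of the group."""
        cell_id = self.dataset.cell_ids[self.columns[local_index]]
        edges: dict[tuple[str, str], float] = {}
        for a, b in self.pairs:
            w = float(self._pair_weights[(a, b)][local_index])
            if w > 0:
                edges[(a, b)] = w
                edges[(b, a)] = w
        return CellCausalNetwork(cell_id=cell_id, genes=list(self.genes), edges=edges)

    def out_weight_arrays(self) -> dict[str, tuple[list[str], np.ndarray]]:
        """For each gene: (outgoing neighbor genes, weights array (n_nb, M)).

        Weights may be non-positive; callers apply the positivity rule.
        """
        out: dict[str, tuple[list[str], np.ndarray]] = {g: ([], []) for g in self.genes}
        for a, b in self.pairs:
            w = self._pair_weights[(a, b)]
            out[a][0].append(b)
            out[a][1].append(w)
            out[b][0].append(a)
            out[b][1].append(w)
        return {
            g: (nbs, np.stack(ws) if ws else np.empty((0, self.m)))
            for g, (nbs, ws) in out.items()
        }


def build_cell_network(
    dataset: ExpressionDataset,
    background: BackgroundNetwork,
    cell_id: str,
    plan: NeighborPlan | None = None,
) -> CellCausalNetwork:
    """Infer the directed causal network of one cell over background edges."""
    plan = plan or NeighborPlan()
    if cell_id not in dataset.cell_ids:
        raise KeyError(f"unknown cell id {cell_id!r}")
    if plan.scope == "global":
        columns = np.arange(dataset.n_cells)
    else:
        columns = dataset.stage_columns(dataset.stage_of_cell[cell_id])
    engine = StageCausalEngine(dataset, background, plan, columns)
    local = list(columns).index(dataset.cell_ids.index(cell_id))
    return engine.network_for(local)


def localized_networks(net: CellCausalNetwork) -> list[LocalizedCausalNetwork]:
    """Decompose a cell network into one star per analyzed gene.

    Genes with no outgoing causality yield records with Q = 0.
    """
    by_center: dict[str, list[tuple[str, float]]] = {g: [] for g in net.genes}
    for (a, b), w in net.edges.items():
        by_center[a].append((b, w))
    result = []
    for g in net.genes:
        nbs = sorted(by_center[g])  # deterministic order by target gene id
        result.append(
            LocalizedCausalNetwork(
                center=g,
                neighbors=[b for b, _ in nbs],
                weights=np.array([w for _, w in nbs], dtype=float),
            )
        )
    return result
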