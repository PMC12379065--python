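"""Core data containers: expression matrices with staged cells and background networks.

The analysis operates on a gene x cell expression matrix whose cells carry an
ordered stage (time-point) label, and on an undirected background interaction
network (typically a protein-protein interaction network) that restricts which
gene pairs are ever evaluated for causal dependency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "BackgroundNetwork", "GeneMatchError"]


class GeneMatchError(ValueError):
    """Raised when the background network and dataset share too few genes."""


@dataclass
class ExpressionDataset:
    """Gene x cell expression matrix with an ordered stage assignment.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_cells)
        Non-negative, finite expression values.
    gene_ids, cell_ids : list of str
        Unique identifiers for rows and columns.
    stage_of_cell : dict
        Maps every cell id to a stage label.
    stage_order : list
        Stage labels in temporal order; every assigned stage must appear here.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    stage_of_cell: dict[str, object]
    stage_order: list[object]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.stage_order = list(self.stage_order)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("expression values must be a 2-D gene x cell matrix")
        if v.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {v.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if not np.all(np.isfinite(v)):
            i, j = np.argwhere(~np.isfinite(v))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )
        if np.any(v < 0):
            i, j = np.argwhere(v < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )
        if len(set(self.stage_order)) != len(self.stage_order):
            raise ValueError("duplicate labels in stage_order")
        missing = [c for c in self.cell_ids if c not in self.stage_of_cell]
        if missing:
            raise ValueError(f"cells without a stage assignment: {missing[:5]}")
        known = set(self.stage_order)
        for c in self.cell_ids:
            if self.stage_of_cell[c] not in known:
                raise ValueError(
                    f"cell {c!r} assigned to stage {self.stage_of_cell[c]!r} "
                    "absent from stage_order"
                )
        counts = self.stage_sizes()
        small = [s for s, n in counts.items() if n < 2]
        if small:
            raise ValueError(f"every stage needs >= 2 cells; too small: {small}")

    # -- accessors -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def stage_sizes(self) -> dict:
        sizes: dict = {s: 0 for s in self.stage_order}
        for c in self.cell_ids:
            sizes[self.stage_of_cell[c]] += 1
        return {s: n for s, n in sizes.items() if n > 0}

    def stages_present(self) -> list:
        sizes = self.stage_sizes()
        return [s for s in self.stage_order if s in sizes]

    def stage_columns(self, stage) -> np.ndarray:
        """Column indices of the cells belonging to ``stage`` (dataset order)."""
        return np.array(
            [j for j, c in enumerate(self.cell_ids) if self.stage_of_cell[c] == stage],
            dtype=int,
        )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def stage_series(self) -> pd.Series:
        return pd.Series({c: self.stage_of_cell[c] for c in self.cell_ids}, name="stage")

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        stage_of_cell: dict,
        stage_order: list,
        meta: dict | None = None,
    ) -> "ExpressionDataset":
        """Build a dataset from a genes-as-rows, cells-as-columns DataFrame."""
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(g) for g in frame.index],
            cell_ids=[str(c) for c in frame.columns],
            stage_of_cell=dict(stage_of_cell),
            stage_order=list(stage_order),
            meta=dict(meta or {}),
        )

    def subset_stages(self, stages: list) -> "ExpressionDataset":
        keep = [c for c in self.cell_ids if self.stage_of_cell[c] in set(stages)]
        cols = [self.cell_ids.index(c) for c in keep]
        return ExpressionDataset(
            values=self.values[:, cols],
            gene_ids=self.gene_ids,
            cell_ids=keep,
            stage_of_cell={c: self.stage_of_cell[c] for c in keep},
            stage_order=[s for s in self.stage_order if s in set(stages)],
            meta=dict(self.meta),
        )


@dataclass
class BackgroundNetwork:
    """Undirected gene-gene interaction graph constraining causal inference.

    Gene identifiers are matched exactly (case-sensitively) against the
    expression dataset. Self-loops and duplicate edges are dropped on
    construction.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in self.graph.nodes)
        dropped = 0
        for a, b in self.graph.edges:
            a, b = str(a), str(b)
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
        if dropped:
            warnings.warn(f"dropped {dropped} self-loop(s) from background network")
        self.graph = g

    @classmethod
    def from_edges(cls, edges) -> "BackgroundNetwork":
        g = nx.Graph()
        g.add_edges_from((str(a), str(b)) for a, b in edges)
        return cls(g)

    @classmethod
    def complete(cls, gene_ids) -> "BackgroundNetwork":
        """Uninformative prior: every gene pair is a candidate interaction."""
        return cls(nx.complete_graph([str(g) for g in gene_ids]))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self):
        return list(self.graph.edges)

    def match(self, dataset: ExpressionDataset, max_unmatched: float = 0.5) -> list[str]:
        """Genes analyzable under this background: present in both objects.

        Raises :class:`GeneMatchError` when more than ``max_unmatched`` of the
        background genes are absent from the dataset (a likely identifier
        namespace mismatch); individually unmatched genes only warn.
        """
        net_genes = self.genes()
        if not net_genes:
            return []
        data_genes = set(dataset.gene_ids)
        matched = net_genes & data_genes
        frac_unmatched = 1.0 - len(matched) / len(net_genes)
        if frac_unmatched > max_unmatched:
            raise GeneMatchError(
                f"{frac_unmatched:.0%} of background-network genes are absent from "
                "the dataset; gene identifier namespaces probably differ"
            )
        if matched != net_genes:
            warnings.warn(
                f"{len(net_genes) - len(matched)} background gene(s) not in dataset; skipped"
            )
        return [g for g in dataset.gene_ids if g in matched]
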