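"""Readers and writers for the on-disk formats, run configuration, pipeline.

Formats
-------
* expression: dense TSV/CSV (first column gene ids, header row cell ids) or
  MatrixMarket coordinate file with ``genes.tsv`` / ``barcodes.tsv`` sidecars;
* cell metadata: TSV with columns ``cell_id``, ``stage``, ``stage_order``;
* background network: two-column TSV edge list (``#`` comments allowed);
* results: TSV matrices/tables plus JSON reports, each stamped with the
  configuration hash.

Readers validate and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .causal import NeighborPlan
from .datasets import BackgroundNetwork, ExpressionDataset

logger = logging.getLogger("ccne")

__all__ = [
    "RunConfig",
    "read_expression",
    "read_metadata",
    "read_network",
    "attach_metadata",
    "write_expression",
    "write_truth",
    "write_entropy_matrix",
    "write_results",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """All pipeline tunables; round-trips losslessly through JSON."""

    k: int | None = None
    k_fraction: float | None = None
    multi_scale_ks: list[int] | None = None
    tie_policy: str = "index_order"
    neighbor_scope: str = "stage"
    aggregation: str = "mean"
    top_fraction: float = 0.05
    alpha: float = 0.05
    alpha_expr: float = 0.05
    alpha_ccne: float = 0.05
    x_assignment: str = "candidate"
    reference: str = "baseline"
    dark_gene_test: str = "ranksums"
    signaling_fraction: float = 0.05
    log1p: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def plan(self) -> NeighborPlan:
        return NeighborPlan(
            k=self.k,
            k_fraction=self.k_fraction,
            multi_scale_ks=tuple(self.multi_scale_ks) if self.multi_scale_ks else None,
            tie_policy=self.tie_policy,
            aggregation=self.aggregation,
            scope=self.neighbor_scope,
            jitter_seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _validate_matrix(values: np.ndarray, genes: list[str], cells: list[str], origin: str):
    if values.size == 0:
        raise ValueError(f"{origin}: empty expression matrix")
    if len(set(genes)) != len(genes):
        dup = pd.Series(genes)
        raise ValueError(
            f"{origin}: duplicate gene ids, e.g. {dup[dup.duplicated()].iloc[0]!r}"
        )
    if len(set(cells)) != len(cells):
        dup = pd.Series(cells)
        raise ValueError(
            f"{origin}: duplicate cell ids, e.g. {dup[dup.duplicated()].iloc[0]!r}"
        )
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{origin}: non-finite value at row {i + 1} (gene {genes[i]!r}), "
            f"column {j + 1} (cell {cells[j]!r})"
        )
    neg = values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"{origin}: negative value at row {i + 1} (gene {genes[i]!r}), "
            f"column {j + 1} (cell {cells[j]!r})"
        )


def read_expression(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a gene x cell matrix; returns a validated DataFrame (no stages yet).

    ``fmt`` is inferred from the suffix when omitted: .tsv/.txt, .csv, or .mtx
    (MatrixMarket coordinate file next to ``genes.tsv`` and ``barcodes.tsv``).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}; pass fmt=")
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        if frame.shape[1] == 0:
            raise ValueError(f"{path}: no cell columns found (malformed header?)")
        try:
            values = frame.to_numpy(dtype=float)
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: non-numeric expression values ({err})") from err
        genes = [str(g) for g in frame.index]
        cells = [str(c) for c in frame.columns]
    elif fmt == "mtx":
        from scipy.io import mmread

        mat = mmread(path)
        genes_path = path.parent / "genes.tsv"
        cells_path = path.parent / "barcodes.tsv"
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"MTX sidecar missing: {p}")
        genes = [ln.split("\t")[0] for ln in genes_path.read_text().splitlines() if ln]
        cells = [ln.split("\t")[0] for ln in cells_path.read_text().splitlines() if ln]
        values = np.asarray(mat.todense(), dtype=float)
        if values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"{path}: matrix is {values.shape} but sidecars define "
                f"{len(genes)} genes x {len(cells)} cells"
            )
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    _validate_matrix(np.asarray(values), genes, cells, str(path))
    return pd.DataFrame(values, index=genes, columns=cells)


def read_metadata(path) -> tuple[dict, list]:
    """Read the cell-stage table; returns (stage_of_cell, stage_order)."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"cell_id", "stage", "stage_order"}
    if not required <= set(meta.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"{path}: duplicate cell_id {dup!r}")
    try:
        ranks = meta["stage_order"].astype(int)
    except ValueError as err:
        raise ValueError(f"{path}: stage_order must be integers ({err})") from err
    by_stage = {}
    for stage, rank in zip(meta["stage"], ranks):
        if stage in by_stage and by_stage[stage] != rank:
            raise ValueError(
                f"{path}: stage {stage!r} has inconsistent stage_order values"
            )
        by_stage[stage] = rank
    if len(set(by_stage.values())) != len(by_stage):
        raise ValueError(f"{path}: two stages share the same stage_order rank")
    stage_order = [s for s, _ in sorted(by_stage.items(), key=lambda kv: kv[1])]
    stage_of_cell = dict(zip(meta["cell_id"], meta["stage"]))
    return stage_of_cell, stage_order


def attach_metadata(frame: pd.DataFrame, stage_of_cell: dict, stage_order: list) -> ExpressionDataset:
    """Join an expression frame with its stage table into a dataset.

    Cells in the matrix but absent from the metadata are an error; extra
    metadata rows are ignored with a warning.
    """
    cells = [str(c) for c in frame.columns]
    missing = [c for c in cells if c not in stage_of_cell]
    if missing:
        raise ValueError(f"cells missing from metadata: {missing[:5]}")
    extra = set(stage_of_cell) - set(cells)
    if extra:
        warnings.warn(f"{len(extra)} metadata row(s) without a matrix column; ignored")
    return ExpressionDataset.from_dataframe(
        frame, {c: stage_of_cell[c] for c in cells}, stage_order
    )


def read_network(path) -> BackgroundNetwork:
    """Read a two-column undirected edge list (extra columns ignored)."""
    path = Path(path)
    edges = []
    n_self = 0
    seen = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: need at least 2 columns")
        a, b = parts[0], parts[1]
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        edges.append(key)
    if n_self:
        logger.info("dropped %d self-loop(s) from %s", n_self, path)
    if not edges:
        warnings.warn(f"{path}: empty background network")
    return BackgroundNetwork.from_edges(edges)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _stamp(config_hash: str) -> str:
    return f"# ccne v{__version__} config={config_hash}\n"


def write_expression(dataset: ExpressionDataset, outdir, config_hash: str = "-") -> dict:
    """Write a dataset as expression.tsv + metadata.tsv (+ meta echo)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write(_stamp(config_hash))
        dataset.to_frame().to_csv(fh, sep="\t", index_label="gene_id")
    meta_path = outdir / "metadata.tsv"
    order_rank = {s: i for i, s in enumerate(dataset.stage_order)}
    with open(meta_path, "w") as fh:
        fh.write(_stamp(config_hash))
        fh.write("cell_id\tstage\tstage_order\n")
        for c in dataset.cell_ids:
            st = dataset.stage_of_cell[c]
            fh.write(f"{c}\t{st}\t{order_rank[st]}\n")
    return {"expression": str(expr_path), "metadata": str(meta_path)}


def write_truth(dataset: ExpressionDataset, outdir) -> str:
    """Ground-truth sidecar for simulated datasets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = {
        "critical_stage": dataset.meta.get("critical_stage"),
        "dnb_genes": dataset.meta.get("dnb_genes"),
        "spec_hash": dataset.meta.get("spec_hash"),
        "config": dataset.meta.get("config"),
        "s_of_stage": dataset.meta.get("s_of_stage"),
    }
    path = outdir / "truth.json"
    path.write_text(json.dumps(truth, indent=1))
    return str(path)


def write_entropy_matrix(results, outdir, config_hash: str = "-", mtx: bool = False) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tsv = outdir / "ccne_matrix.tsv"
    with open(tsv, "w") as fh:
        fh.write(_stamp(config_hash))
        results.entropy_frame.to_csv(fh, sep="\t", index_label="gene_id")
    paths["ccne_matrix"] = str(tsv)
    if mtx:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mtx_path = outdir / "ccne_matrix.mtx"
        mmwrite(str(mtx_path), csr_matrix(results.entropy_frame.to_numpy()))
        (outdir / "genes.tsv").write_text(
            "\n".join(results.entropy_frame.index) + "\n"
        )
        (outdir / "barcodes.tsv").write_text(
            "\n".join(results.entropy_frame.columns) + "\n"
        )
        paths["ccne_matrix_mtx"] = str(mtx_path)
    return paths


def write_results(results, outdir, cfg: RunConfig | None = None, mtx: bool = False) -> dict:
    """All standard outputs of a fitted model into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or RunConfig()
    h = cfg.hash()
    paths = write_entropy_matrix(results, outdir, h, mtx=mtx)
    scores_path = outdir / "cell_scores.tsv"
    with open(scores_path, "w") as fh:
        fh.write(_stamp(h))
        fh.write("cell_id\tstage\tH_l\ttop_genes\n")
        for c, v in results.per_cell.items():
            st = results.model.dataset.stage_of_cell[c]
            tops = ",".join(results.scores.top_genes.get(c, []))
            fh.write(f"{c}\t{st}\t{v:.17g}\t{tops}\n")
    paths["cell_scores"] = str(scores_path)
    report_path = outdir / "report.json"
    d = results.report.to_dict()
    d["config_hash"] = h
    with open(report_path, "w") as fh:
        json.dump(d, fh, indent=1, default=str)
    paths["report"] = str(report_path)
    cfg_path = outdir / "config.json"
    cfg.to_json(cfg_path)
    paths["config"] = str(cfg_path)
    return paths


def write_signaling(sig, outdir, config_hash: str = "-") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tsv = outdir / "signaling_genes.tsv"
    with open(tsv, "w") as fh:
        fh.write(_stamp(config_hash))
        fh.write("gene\tmean_local_ccne\tin_largest_subgraph\n")
        for g, v in sig.ranked.items():
            fh.write(f"{g}\t{v:.17g}\t{int(g in set(sig.subgraph_nodes))}\n")
    paths["signaling_genes"] = str(tsv)
    sub = outdir / "signaling_subgraph.tsv"
    with open(sub, "w") as fh:
        fh.write(_stamp(config_hash))
        fh.write("source\ttarget\n")
        for a, b in sig.subgraph_edges:
            fh.write(f"{a}\t{b}\n")
    paths["signaling_subgraph"] = str(sub)
    return paths


def write_dark_genes(calls, outdir, config_hash: str = "-") -> str:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "dark_genes.tsv"
    with open(path, "w") as fh:
        fh.write(_stamp(config_hash))
        fh.write("gene\tp_expression\tp_ccne\tq_ccne\tdark\n")
        for c in calls:
            fh.write(
                f"{c.gene}\t{c.p_expression:.17g}\t{c.p_ccne:.17g}"
                f"\t{c.q_ccne:.17g}\t{int(c.dark)}\n"
            )
    return str(path)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    cfg: RunConfig,
    expression_path,
    metadata_path,
    network_path=None,
    outdir="ccne_out",
) -> dict:
    """Read inputs, fit the model, write every standard output.

    Deterministic given the configuration (including seed); returns the map
    of written paths. A missing network path means a complete background over
    the dataset's genes.
    """
    from .model import CCNEModel

    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    t0 = time.time()
    frame = read_expression(expression_path)
    stage_of_cell, stage_order = read_metadata(metadata_path)
    dataset = attach_metadata(frame, stage_of_cell, stage_order)
    if network_path is not None:
        background = read_network(network_path)
    else:
        background = BackgroundNetwork.complete(dataset.gene_ids)
    logger.info(
        "loaded %d genes x %d cells, %d stages, %d background edges [%.2fs]",
        dataset.n_genes,
        dataset.n_cells,
        len(dataset.stages_present()),
        background.n_edges,
        time.time() - t0,
    )
    model = CCNEModel(
        dataset,
        background,
        plan=cfg.plan(),
        top_fraction=cfg.top_fraction,
        alpha=cfg.alpha,
        x_assignment=cfg.x_assignment,
        reference=cfg.reference,
        log1p=cfg.log1p,
    )
    results = model.fit()
    logger.info("fit complete [%.2fs]; detected=%s", time.time() - t0, results.detected_stage)
    paths = write_results(results, outdir, cfg)
    if results.detected_stage is not None:
        sig = results.signaling_genes(cfg.signaling_fraction)
        paths.update(write_signaling(sig, outdir, cfg.hash()))
        stages = list(results.stage_means.index)
        pos = stages.index(results.detected_stage)
        if pos >= 1:
            calls = results.dark_genes(
                genes=sig.genes,
                alpha_expr=cfg.alpha_expr,
                alpha_ccne=cfg.alpha_ccne,
                test=cfg.dark_gene_test,
            )
            paths["dark_genes"] = write_dark_genes(calls, outdir, cfg.hash())
    logger.info("pipeline done [%.2fs]", time.time() - t0)
    return paths
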