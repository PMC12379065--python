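"""One-sample t statistic, stage detection logic, signaling and dark genes."""

import math

import numpy as np
import pandas as pd
import pytest

from ccne.datasets import BackgroundNetwork, ExpressionDataset
from ccne.detect import (
    CriticalStateReport,
    detect_critical_stage,
    identify_dark_genes,
    one_sample_t,
    select_signaling_genes,
)
from ccne.entropy import CcneScores, LocalEntropyMatrix, local_entropy_matrix
from ccne.causal import NeighborPlan

from _reference import ref_t_sf_df2
from conftest import make_dataset


def make_scores(stage_values: dict[str, list[float]], stage_order=None) -> CcneScores:
    """CcneScores stub from explicit per-stage per-cell values."""
    per_cell = {}
    stage_of = {}
    for stage, vals in stage_values.items():
        for i, v in enumerate(vals):
            cid = f"{stage}_c{i}"
            per_cell[cid] = float(v)
            stage_of[cid] = stage
    order = stage_order or list(stage_values)
    return CcneScores(
        per_cell=pd.Series(per_cell),
        stage_of_cell=stage_of,
        stage_order=order,
        top_fraction=0.05,
        s=1,
    )


class TestOneSampleT:
    def test_centered_case(self):
        sc, p = one_sample_t([1.0, 2.0, 3.0], 2.0)
        assert sc == 0.0
        assert p == 1.0

    def test_hand_value_against_closed_form_cdf(self):
        sc, p = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert sc == pytest.approx(2.0 * math.sqrt(3.0), rel=1e-12)
        # independent oracle: closed-form t CDF for 2 degrees of freedom
        assert p == pytest.approx(2.0 * ref_t_sf_df2(2.0 * math.sqrt(3.0)), rel=1e-12)

    def test_translation_invariance(self):
        x = np.array([0.3, 1.1, 2.9, 0.7])
        a = one_sample_t(x, 0.5)
        b = one_sample_t(x + 10.0, 10.5)
        assert a[0] == pytest.approx(b[0], rel=1e-12)
        assert a[1] == pytest.approx(b[1], rel=1e-12)

    def test_degenerate_variance_convention(self):
        with pytest.warns(UserWarning, match="SD"):
            sc, p = one_sample_t([2.0, 2.0, 2.0], 2.0)
        assert (sc, p) == (0.0, 1.0)
        with pytest.warns(UserWarning, match="SD"):
            sc, p = one_sample_t([2.0, 2.0, 2.0], 1.0)
        assert p == 0.0 and sc == math.inf

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0], 0.0)


class TestDetection:
    def test_constant_series_never_detected(self):
        scores = make_scores({f"t{i}": [1.0, 1.0, 1.0] for i in range(4)})
        rep = detect_critical_stage(scores)
        assert rep.detected_stage is None

    def test_rising_stage_is_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.1, size=30).tolist()
        scores = make_scores(
            {
                "t0": base,
                "t1": base[::-1],  # identical distribution: no rise in mean
                "t2": rng.normal(3.0, 0.1, size=30).tolist(),
            }
        )
        rep = detect_critical_stage(scores)
        assert rep.detected_stage == "t2"
        cand = {c.stage: c for c in rep.candidates}
        assert cand["t2"].p_value < 1e-6
        assert cand["t2"].flagged

    def test_alpha_zero_detects_nothing(self):
        rng = np.random.default_rng(1)
        scores = make_scores(
            {"t0": rng.normal(1, 0.1, 20).tolist(), "t1": rng.normal(5, 0.1, 20).tolist()}
        )
        assert detect_critical_stage(scores, alpha=0.0).detected_stage is None

    def test_alpha_one_reduces_to_monotone_rise(self):
        rng = np.random.default_rng(2)
        scores = make_scores(
            {
                "t0": rng.normal(1, 0.3, 20).tolist(),
                "t1": (rng.normal(1, 0.3, 20) + 0.01).tolist(),
            }
        )
        rep = detect_critical_stage(scores, alpha=1.0)
        flagged_expected = rep.stage_means["t1"] > rep.stage_means["t0"]
        assert (rep.detected_stage == "t1") == flagged_expected

    def test_earliest_flagged_stage_wins(self):
        rng = np.random.default_rng(3)
        scores = make_scores(
            {
                "t0": rng.normal(1, 0.05, 25).tolist(),
                "t1": rng.normal(2, 0.05, 25).tolist(),
                "t2": rng.normal(4, 0.05, 25).tolist(),
            }
        )
        rep = detect_critical_stage(scores)
        assert rep.flagged_stages == ["t1", "t2"]
        assert rep.detected_stage == "t1"

    def test_single_stage_rejected(self):
        scores = make_scores({"t0": [1.0, 2.0]})
        with pytest.raises(ValueError):
            detect_critical_stage(scores)

    def test_spec_reference_wiring_available(self):
        rng = np.random.default_rng(4)
        scores = make_scores(
            {"t0": rng.normal(1, 0.1, 20).tolist(), "t1": rng.normal(3, 0.1, 20).tolist()}
        )
        rep = detect_critical_stage(scores, x_assignment="reference", reference="previous")
        assert rep.detected_stage == "t1"
        cand = rep.candidates[0]
        # X is then the reference stage: m must equal its cell count
        assert cand.m == 20
        assert cand.reference_stage == "t0"

    def test_report_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        scores = make_scores(
            {"t0": rng.normal(1, 0.2, 15).tolist(), "t1": rng.normal(2, 0.2, 15).tolist()}
        )
        rep = detect_critical_stage(scores)
        path = tmp_path / "report.json"
        rep.to_json(path)
        back = CriticalStateReport.from_json(path)
        assert back.detected_stage == rep.detected_stage
        assert list(back.stage_means) == list(rep.stage_means)
        for a, b in zip(back.candidates, rep.candidates):
            assert a.to_dict() == b.to_dict()
        assert back.per_cell.to_dict() == rep.per_cell.to_dict()


class TestSignalingGenes:
    def _matrix(self, frame: pd.DataFrame, ds: ExpressionDataset) -> LocalEntropyMatrix:
        return LocalEntropyMatrix(
            frame=frame,
            dataset=ds,
            analyzed_genes=list(frame.index),
            excluded_genes=[],
            plan=NeighborPlan(),
        )

    def test_full_fraction_returns_largest_component(self):
        ds = make_dataset(n_genes=5, cells_per_stage=(4,), seed=0)
        frame = pd.DataFrame(
            np.arange(20, dtype=float).reshape(5, 4), index=ds.gene_ids, columns=ds.cell_ids
        )
        bg = BackgroundNetwork.from_edges(
            [("G00", "G01"), ("G01", "G02"), ("G03", "G04")]
        )
        sig = select_signaling_genes(self._matrix(frame, ds), bg, "t0", fraction=1.0)
        assert set(sig.genes) == set(ds.gene_ids)
        assert sig.subgraph_nodes == ["G00", "G01", "G02"]

    def test_edgeless_selection_gives_single_node(self):
        ds = make_dataset(n_genes=4, cells_per_stage=(4,), seed=0)
        frame = pd.DataFrame(
            np.eye(4) * [[4.0], [3.0], [2.0], [1.0]],
            index=ds.gene_ids,
            columns=ds.cell_ids,
        )
        bg = BackgroundNetwork.from_edges([("G02", "G03")])
        bg.graph.add_nodes_from(ds.gene_ids)
        sig = select_signaling_genes(self._matrix(frame, ds), bg, "t0", fraction=0.5)
        assert sig.genes == ["G00", "G01"]  # top 2 by mean entropy
        assert len(sig.subgraph_nodes) == 1
        assert sig.subgraph_nodes == ["G00"]

    def test_ranked_by_stage_mean_with_ties_by_id(self):
        ds = make_dataset(n_genes=4, cells_per_stage=(4,), seed=0)
        frame = pd.DataFrame(
            [[2.0] * 4, [2.0] * 4, [5.0] * 4, [0.0] * 4],
            index=ds.gene_ids,
            columns=ds.cell_ids,
        )
        bg = BackgroundNetwork.complete(ds.gene_ids)
        sig = select_signaling_genes(self._matrix(frame, ds), bg, "t0", fraction=0.5)
        assert sig.genes == ["G02", "G00"]


class TestDarkGenes:
    def _setup(self, seed=0, shift_ccne=True, shift_expr=False):
        rng = np.random.default_rng(seed)
        m = 30
        genes = ["target", "ctrl", "other"]
        vals = rng.lognormal(size=(3, 2 * m))
        if shift_expr:
            vals[0, m:] += 5.0
        ds = ExpressionDataset(
            values=vals,
            gene_ids=genes,
            cell_ids=[f"c{i}" for i in range(2 * m)],
            stage_of_cell={f"c{i}": ("before" if i < m else "crit") for i in range(2 * m)},
            stage_order=["before", "crit"],
        )
        ent = np.abs(rng.normal(0.1, 0.02, size=(3, 2 * m)))
        if shift_ccne:
            ent[0, m:] += 0.5  # 5+ SD shift in the critical stage
        frame = pd.DataFrame(ent, index=genes, columns=ds.cell_ids)
        mat = LocalEntropyMatrix(
            frame=frame, dataset=ds, analyzed_genes=genes, excluded_genes=[], plan=NeighborPlan()
        )
        return ds, mat

    def test_entropy_shift_without_expression_shift_is_dark(self):
        ds, mat = self._setup(shift_ccne=True, shift_expr=False)
        calls = {c.gene: c for c in identify_dark_genes(ds, mat, ["target", "ctrl"], "before", "crit")}
        assert calls["target"].dark
        assert not calls["ctrl"].dark

    def test_strong_expression_shift_is_never_dark(self):
        ds, mat = self._setup(shift_ccne=True, shift_expr=True)
        calls = {c.gene: c for c in identify_dark_genes(ds, mat, ["target"], "before", "crit")}
        assert not calls["target"].dark
        assert calls["target"].p_expression < 0.05

    def test_identical_gene_is_not_dark(self):
        ds, mat = self._setup(shift_ccne=False)
        calls = identify_dark_genes(ds, mat, ["target"], "before", "crit")
        assert not calls[0].dark

    def test_constant_gene_convention(self):
        ds, mat = self._setup(shift_ccne=True)
        ds.values[1, :] = 1.0  # ctrl constant in both stages
        calls = {c.gene: c for c in identify_dark_genes(ds, mat, ["ctrl"], "before", "crit")}
        assert calls["ctrl"].p_expression == 1.0


def test_detection_invariant_under_global_expression_rescaling():
    ds = make_dataset(n_genes=6, cells_per_stage=(12, 12, 12), seed=13)
    # inject a genuine rise in stage t2 for one gene cluster
    cols = ds.stage_columns("t2")
    ds.values[:3, cols] *= np.abs(np.random.default_rng(1).normal(2.0, 1.0, (3, len(cols))))
    bg = BackgroundNetwork.complete(ds.gene_ids)
    mat0 = local_entropy_matrix(ds, bg)
    from ccne.entropy import ccne_scores

    rep0 = detect_critical_stage(ccne_scores(mat0))
    ds_scaled = ExpressionDataset(
        values=ds.values * 11.3,
        gene_ids=ds.gene_ids,
        cell_ids=ds.cell_ids,
        stage_of_cell=ds.stage_of_cell,
        stage_order=ds.stage_order,
    )
    rep1 = detect_critical_stage(ccne_scores(local_entropy_matrix(ds_scaled, bg)))
    assert rep0.detected_stage == rep1.detected_stage
    np.testing.assert_allclose(
        rep1.stage_means.to_numpy(), 11.3 * rep0.stage_means.to_numpy(), rtol=1e-10
    )
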