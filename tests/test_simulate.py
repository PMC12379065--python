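"""Circuit structure, bifurcation certificate, and simulator contracts."""

import numpy as np
import pytest
from scipy import optimize

from ccne.datasets import BackgroundNetwork
from ccne.simulate import (
    Edge,
    RegulatoryNetworkSpec,
    SimulationConfig,
    SimulationInstabilityError,
    build_default_circuit,
    deterministic_fixed_point,
    generate_null_sweep,
    generate_sweep,
    leading_eigenvalue,
    simulate_cells,
)


@pytest.fixture(scope="module")
def circuit():
    return build_default_circuit()


class TestCircuitStructure:
    def test_eight_nodes_five_dnb(self, circuit):
        assert circuit.n_nodes == 8
        assert len(circuit.dnb_nodes) == 5
        assert set(circuit.dnb_nodes) == {"g1", "g2", "g3", "g4", "g5"}

    def test_dnb_module_connected_and_coupled_outward(self, circuit):
        # validated on construction; a broken module must be rejected
        with pytest.raises(ValueError, match="connected"):
            RegulatoryNetworkSpec(
                node_ids=circuit.node_ids,
                edges=tuple(e for e in circuit.edges if e.target not in ("g2", "g3")),
                dnb_nodes=circuit.dnb_nodes,
                basal=circuit.basal,
                degradation=circuit.degradation,
                s_coupling=circuit.s_coupling,
            )

    def test_rates_strictly_positive(self, circuit):
        assert all(d > 0 for d in circuit.degradation)
        assert all(e.v > 0 and e.k > 0 and e.h >= 1 for e in circuit.edges)

    def test_invalid_edge_parameters_rejected(self):
        with pytest.raises(ValueError):
            Edge("a", "b", "activating", v=-1.0, k=1.0, h=2)
        with pytest.raises(ValueError):
            Edge("a", "b", "sideways", v=1.0, k=1.0, h=2)


class TestBifurcationCertificate:
    """Independent oracle: root-finding + eigen-decomposition of the drift."""

    def _core_rate(self, circuit, x1):
        self_edge = next(e for e in circuit.edges if e.source == e.target == "g1")
        return float(self_edge.response(np.array([x1]))[0])

    def test_stable_far_from_bifurcation(self, circuit):
        # documented stability margin delta = 0.5 at s = -0.5
        lam = leading_eigenvalue(circuit, -0.5)
        assert lam < -0.5

    def test_tangency_at_zero(self, circuit):
        # saddle-node condition: drift and its x1-derivative vanish together
        a0 = circuit.basal_at(0.0)[0]
        g = lambda x: a0 + self._core_rate(circuit, x) - x
        dg = lambda x: (g(x + 1e-6) - g(x - 1e-6)) / 2e-6
        xstar = optimize.brentq(dg, 0.5, 5.0)
        assert abs(g(xstar)) < 1e-9
        fp = np.array(
            deterministic_fixed_point(circuit, 0.0, x0=np.full(8, 0.1))
        )
        lam = leading_eigenvalue(circuit, 0.0, fp)
        assert abs(lam) < 0.01

    def test_eigenvalue_crosses_zero_within_one_grid_step(self, circuit):
        lam_before = leading_eigenvalue(circuit, -0.1)
        assert lam_before < 0
        # just above the bifurcation the low state is gone: the x1-drift is
        # strictly positive over the former low basin
        xs = np.linspace(0.0, 5.0, 200)
        a = circuit.basal_at(0.1)[0]
        g = a + np.array([self._core_rate(circuit, x) for x in xs]) - xs
        assert g.min() > 0

    def test_dnb_restricted_eigenvalue_matches_full(self, circuit):
        # the soft mode lives in the DNB module
        for s in (-0.5, -0.2, -0.1):
            full = leading_eigenvalue(circuit, s)
            dnb = leading_eigenvalue(circuit, s, restrict_to_dnb=True)
            assert dnb == pytest.approx(full, abs=1e-8)

    def test_monotone_softening_towards_zero(self, circuit):
        lams = [leading_eigenvalue(circuit, s) for s in (-0.5, -0.4, -0.3, -0.2, -0.1)]
        assert all(b > a for a, b in zip(lams, lams[1:]))


class TestSimulateCells:
    def test_zero_noise_cells_sit_on_fixed_point(self, circuit):
        cfg = SimulationConfig(s_values=(-0.3,), n_cells_per_s=5, sigma=0.0, seed=1)
        ds = simulate_cells(circuit, -0.3, cfg)
        fp = deterministic_fixed_point(circuit, -0.3)
        np.testing.assert_allclose(ds.values, np.tile(fp[:, None], (1, 5)), atol=1e-6)

    def test_same_seed_bitwise_identical(self, circuit):
        cfg = SimulationConfig(n_cells_per_s=10, seed=42)
        a = simulate_cells(circuit, -0.2, cfg)
        b = simulate_cells(circuit, -0.2, cfg)
        assert np.array_equal(a.values, b.values)
        assert a.cell_ids == b.cell_ids

    def test_values_non_negative(self, circuit):
        cfg = SimulationConfig(n_cells_per_s=40, sigma=0.2, seed=3)
        ds = simulate_cells(circuit, -0.5, cfg)
        assert (ds.values >= 0).all()

    def test_variance_grows_near_bifurcation(self, circuit):
        """Critical slowing down: DNB variance higher at s=-0.01 than s=-0.4."""
        var = {}
        for s in (-0.4, -0.01):
            vs = []
            for seed in range(3):
                cfg = SimulationConfig(n_cells_per_s=50, sigma=0.05, seed=seed)
                ds = simulate_cells(circuit, s, cfg)
                vs.append(ds.values[:5].var(axis=1, ddof=1).mean())
            var[s] = np.mean(vs)
        assert var[-0.01] > var[-0.4]

    def test_independent_cells_mode(self, circuit):
        cfg = SimulationConfig(n_cells_per_s=12, seed=5, independent_cells=True)
        ds = simulate_cells(circuit, -0.3, cfg)
        assert ds.values.shape == (8, 12)
        # restarted replicates must not be identical to one another
        assert np.std(ds.values[0]) > 0

    def test_divergence_raises_instability_error(self, circuit):
        cfg = SimulationConfig(n_cells_per_s=5, sigma=0.0, dt=4.0, sampling_interval=4.5, seed=0)
        with pytest.raises(SimulationInstabilityError, match="dt"):
            # start far from equilibrium so the coarse explicit step explodes
            from ccne.simulate import _integrate

            _integrate(circuit, -0.5, np.full(8, 50.0), 200, 4.0, 0.0, np.random.default_rng(0))


class TestSweeps:
    def test_sweep_shape_and_truth(self, circuit):
        cfg = SimulationConfig(n_cells_per_s=10, seed=2)
        ds = generate_sweep(circuit, cfg)
        assert ds.values.shape == (8, 80)
        assert len(ds.stage_order) == 8
        assert ds.meta["critical_stage"] == "s=-0.10"
        assert ds.meta["dnb_genes"] == ["g1", "g2", "g3", "g4", "g5"]
        sizes = ds.stage_sizes()
        assert all(v == 10 for v in sizes.values())

    def test_sweep_determinism(self, circuit):
        cfg = SimulationConfig(n_cells_per_s=8, seed=9)
        a = generate_sweep(circuit, cfg)
        b = generate_sweep(circuit, cfg)
        assert np.array_equal(a.values, b.values)

    def test_variance_monotone_along_approach(self, circuit):
        """Grid-averaged DNB variance is non-decreasing towards s -> 0-."""
        pre = ["s=-0.50", "s=-0.40", "s=-0.30", "s=-0.20", "s=-0.10"]
        acc = np.zeros(len(pre))
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(n_cells_per_s=50, seed=seed)
            ds = generate_sweep(circuit, cfg)
            for i, st in enumerate(pre):
                cols = ds.stage_columns(st)
                acc[i] += ds.values[:5, cols].var(axis=1, ddof=1).mean()
        acc /= n_seeds
        assert all(b >= a for a, b in zip(acc, acc[1:]))

    def test_null_sweep_zero_noise_constant_series(self, circuit):
        from ccne.entropy import ccne_scores, local_entropy_matrix

        cfg = SimulationConfig(
            s_values=(-0.5, -0.4, -0.3), n_cells_per_s=6, sigma=0.0, seed=0
        )
        ds = generate_null_sweep(circuit, cfg)
        mat = local_entropy_matrix(ds, BackgroundNetwork.complete(ds.gene_ids))
        scores = ccne_scores(mat)
        h = scores.stage_means.to_numpy()
        assert np.all(h == h[0])

    def test_null_sweep_flatter_than_true_sweep(self, circuit):
        """Stage-to-stage variation of H_t: null sweeps are much flatter."""
        from ccne.entropy import ccne_scores, local_entropy_matrix

        def series_cv(ds):
            mat = local_entropy_matrix(ds, BackgroundNetwork.complete(ds.gene_ids))
            h = ccne_scores(mat).stage_means.to_numpy()
            return np.std(h) / np.mean(h)

        cvs_true, cvs_null = [], []
        for seed in range(3):
            cfg = SimulationConfig(n_cells_per_s=30, seed=seed)
            cvs_true.append(series_cv(generate_sweep(circuit, cfg)))
            cvs_null.append(series_cv(generate_null_sweep(circuit, cfg)))
        assert np.mean(cvs_null) < np.mean(cvs_true)


class TestConfigValidation:
    def test_s_values_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            SimulationConfig(s_values=(-0.1, -0.2))

    def test_dt_below_sampling_interval(self):
        with pytest.raises(ValueError, match="dt"):
            SimulationConfig(dt=5.0, sampling_interval=2.0)

    def test_burn_in_floor_vs_degradation(self, circuit):
        cfg = SimulationConfig(burn_in_time=5.0)
        with pytest.raises(ValueError, match="burn_in"):
            cfg.validate_against(circuit)
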