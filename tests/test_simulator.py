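import numpy as np
import pytest

import memclust as mc
from memclust.simulate import _derive_seeds


def small_cfg(target=20.0, **kw):
    kw.setdefault("n_agents", 80)
    kw.setdefault("duration_s", 0.5)
    kw.setdefault("record_every", None)
    return mc.SimulationConfig.standard(target, **kw)


class TestConfigValidation:
    def test_non_integer_frame_count(self):
        with pytest.raises(ValueError):
            small_cfg(duration_s=0.505, dt_ms=10.0)

    def test_radius_too_large(self):
        with pytest.raises(ValueError):
            mc.SimulationConfig(
                profile=mc.DisplacementProfile("linear_converging", 3.5, l_target=100.0),
                density_radius=1500.0,
            )

    def test_mesh_must_divide_box(self):
        with pytest.raises(ValueError):
            small_cfg(mesh_spacing=700.0)

    def test_step_must_fit_mesh_cell(self):
        with pytest.raises(ValueError):
            small_cfg(mesh_spacing=250.0, d_max=30.0)

    def test_target_count_roundtrip(self):
        cfg = mc.SimulationConfig.standard(45.0)
        assert cfg.target_count == pytest.approx(45.0, rel=1e-9)


class TestInitialisation:
    def test_empty(self):
        profile = mc.DisplacementProfile("linear_converging", 3.5, l_target=100.0)
        cfg = mc.SimulationConfig(profile=profile, n_agents=0, duration_s=0.5,
                                  record_every=None)
        p = mc.initialise_pattern(cfg, np.random.RandomState(0))
        assert p.n == 0

    def test_seed_determinism(self):
        cfg = small_cfg()
        a = mc.initialise_pattern(cfg, np.random.RandomState(42))
        b = mc.initialise_pattern(cfg, np.random.RandomState(42))
        assert np.array_equal(a.positions, b.positions)

    def test_csr_calibration_full_scale(self):
        cfg = mc.SimulationConfig.standard(45.0, seed=3)
        p = mc.initialise_pattern(cfg, np.random.RandomState(_derive_seeds(3)[0]))
        counts = mc.neighbour_counts(p, 100.0)
        assert counts.mean() == pytest.approx(6.98, abs=0.35)


class TestStepFrame:
    def test_zero_dmax_is_static(self):
        profile = mc.DisplacementProfile("linear_converging", d_max=0.0, l_target=100.0)
        cfg = mc.SimulationConfig(profile=profile, n_agents=50, duration_s=0.2, record_every=None, seed=4)
        rec = mc.run_simulation(cfg)
        start = mc.initialise_pattern(cfg, np.random.RandomState(_derive_seeds(4)[0]))
        assert np.array_equal(rec.final_frame.positions, start.positions)

    def test_frozen_above_target_stay_put(self):
        """Molecules whose L already exceeds the target must not move."""
        clump = 1500.0 + np.random.RandomState(0).uniform(-20, 20, size=(30, 2))
        lone = np.array([[200.0, 200.0], [2800.0, 2800.0]])
        pattern = mc.PointPattern(np.vstack([clump, lone]), mc.Box())
        l_vals = mc.local_l_values(pattern, 100.0).l_values
        profile = mc.DisplacementProfile("linear_converging", 3.5, l_target=200.0)
        cfg = mc.SimulationConfig(profile=profile, n_agents=32, record_every=None)
        out = mc.step_frame(pattern, cfg, np.random.RandomState(7))
        frozen = l_vals >= 200.0
        assert frozen[:30].all() and not frozen[30:].any()
        assert np.array_equal(out.positions[frozen], pattern.positions[frozen])
        assert not np.allclose(out.positions[~frozen], pattern.positions[~frozen])

    def test_agent_count_conserved(self):
        cfg = small_cfg(n_agents=120)
        rec = mc.run_simulation(cfg)
        assert rec.final_frame.n == 120  # PointPattern validates in-box


class TestEngineParity:
    @pytest.mark.parametrize(
        "kw",
        [
            {},
            {"step_mode": "gaussian"},
            {"mesh_spacing": 250.0},
            {"n_agents": 400, "target": 12.0, "duration_s": 1.0},
        ],
        ids=["fixed", "gaussian", "mesh", "partial-freeze"],
    )
    def test_numba_matches_python_reference(self, kw):
        kw = dict(kw)
        target = kw.pop("target", 20.0)
        cfg = small_cfg(target, seed=13, **kw)
        a = mc.run_simulation(cfg, sim_engine="numba")
        b = mc.run_simulation(cfg, sim_engine="python")
        assert np.allclose(a.final_frame.positions, b.final_frame.positions, atol=1e-9)
        assert np.allclose(a.l_series, b.l_series, atol=1e-9)


class TestRunSimulation:
    def test_determinism_bit_identical(self):
        cfg = small_cfg(seed=99)
        a = mc.run_simulation(cfg)
        b = mc.run_simulation(cfg)
        assert np.array_equal(a.l_series, b.l_series)
        assert np.array_equal(a.final_frame.positions, b.final_frame.positions)

    def test_initial_l_is_csr_level(self):
        cfg = mc.SimulationConfig.standard(45.0, duration_s=0.1, seed=21, record_every=None)
        rec = mc.run_simulation(cfg)
        assert rec.l_series[0] == pytest.approx(100.0, abs=3.0)

    def test_csr_target_never_aggregates(self):
        """Target at the CSR calibration level (7 encircled) does not form
        clusters: the freeze-at-target ratchet lifts <L> a few percent
        above the CSR level (everyone ends with ~target neighbours) but
        nowhere near an aggregated state."""
        cfg = mc.SimulationConfig.standard(7.0, duration_s=10.0, seed=22, record_every=None)
        rec = mc.run_simulation(cfg)
        assert np.all(rec.l_series > 93.0) and np.all(rec.l_series < 130.0)
        rep = mc.analyze_pattern(rec.final_frame, min_size=20)
        assert int((rep.per_cluster["size"] >= 50).sum()) == 0

    def test_stored_frame_schedule(self):
        cfg = small_cfg(duration_s=1.0, record_every=20)
        rec = mc.run_simulation(cfg)
        assert len(rec.stored_frames) == 5  # ceil(100 / 20)
        assert rec.stored_times[0] == 0.0
        assert rec.times.size == cfg.n_frames + 1

    def test_nucleation_within_seconds(self):
        """Converged runs grow dense nucleation sites in the first seconds."""
        cfg = mc.SimulationConfig.standard(25.0, duration_s=10.0, seed=23, record_every=1000)
        rec = mc.run_simulation(cfg)
        def big_clusters(pattern):
            rep = mc.analyze_pattern(pattern, min_size=20)
            return int((rep.per_cluster["size"] >= 20).sum())
        assert big_clusters(rec.stored_frames[0]) == 0
        assert big_clusters(rec.final_frame) > 0

    def test_async_update_mode(self):
        cfg = small_cfg(n_agents=30, duration_s=0.1, update_mode="asynchronous", seed=5)
        rec = mc.run_simulation(cfg, sim_engine="python")
        sync = mc.run_simulation(
            small_cfg(n_agents=30, duration_s=0.1, seed=5), sim_engine="python"
        )
        assert rec.final_frame.n == 30
        assert not np.array_equal(rec.final_frame.positions, sync.final_frame.positions)
        with pytest.raises(ValueError):
            mc.run_simulation(cfg, sim_engine="numba")


class TestEnsemble:
    def test_single_rep_equals_run(self):
        cfg = small_cfg(seed=31)
        ens = mc.run_ensemble(cfg, 1)
        solo = mc.run_simulation(
            mc.SimulationConfig.standard(
                20.0, n_agents=80, duration_s=0.5,
                seed=mc.ensemble_seeds(31, 1)[0], record_every=None,
            )
        )
        assert np.array_equal(ens.mean_l, solo.l_series)

    def test_seed_list_mismatch(self):
        with pytest.raises(ValueError):
            mc.run_ensemble(small_cfg(), 3, seeds=[1, 2])

    def test_csr_ensemble_within_noise(self, condition_cache):
        """With the target at CSR scale the ensemble mean stays near the
        CSR level (modulo the freeze-at-target ratchet)."""
        ens = condition_cache(7.0, 3, duration_s=30.0)
        assert np.all(ens.mean_l > 95.0) and np.all(ens.mean_l < 130.0)
        assert ens.mean_l[0] == pytest.approx(100.0, abs=3.0)

    def test_frozen_state_is_absorbing(self):
        """Once every molecule sits at/above target, the pattern never changes.

        A target below the CSR level freezes (nearly) every molecule at
        frame zero; stragglers with no neighbour diffuse until they meet
        one.  From the first fully frozen frame the series is exactly
        constant."""
        cfg = mc.SimulationConfig.standard(1.0, duration_s=30.0, seed=37,
                                           record_every=None)
        rec = mc.run_simulation(cfg)
        tail = rec.l_series[-1000:]
        assert np.all(tail == tail[0])
        assert tail[0] > 90.0
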