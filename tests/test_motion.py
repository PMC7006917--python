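import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import memclust as mc
from memclust.geometry import Box

BOX = Box(3000.0, 3000.0)


def std_profile(l_target=250.0, **kw):
    return mc.DisplacementProfile("linear_converging", d_max=3.5, l_target=l_target, **kw)


class TestDisplacementRate:
    def test_immobile_at_and_above_target(self):
        p = std_profile()
        assert p.rate(250.0) == 0.0
        assert p.rate(400.0) == 0.0

    def test_d_max_at_anchor(self):
        for fam in mc.motion.PROFILE_FAMILIES:
            p = mc.DisplacementProfile(fam, d_max=3.5, d_min=0.5, l_target=250.0, l_anchor=50.0)
            assert p.rate(50.0) == pytest.approx(3.5)

    def test_linear_and_quadratic_midpoint(self):
        lin = std_profile()
        quad = mc.DisplacementProfile("quadratic", d_max=3.5, l_target=250.0)
        assert lin.rate(125.0) == pytest.approx(3.5 / 2)
        assert quad.rate(125.0) == pytest.approx(3.5 / 4)

    def test_floor_at_d_min(self):
        p = mc.DisplacementProfile("linear_floor", d_max=3.5, d_min=0.52, l_target=250.0)
        assert p.rate(250.0) == pytest.approx(0.52)
        assert p.rate(1000.0) == pytest.approx(0.52)
        assert p.rate(0.0) == pytest.approx(3.5)

    def test_tent_zero_only_at_equality(self):
        p = mc.DisplacementProfile("tent_nonconverging", d_max=3.5, l_target=250.0)
        assert p.rate(250.0) == 0.0
        assert p.rate(249.0) > 0.0
        assert p.rate(251.0) > 0.0
        # far above target the rate is clamped back to d_max
        assert p.rate(600.0) == pytest.approx(3.5)

    @given(st.sampled_from(mc.motion.PROFILE_FAMILIES), st.integers(0, 1000))
    def test_non_increasing_between_anchor_and_target(self, fam, seed):
        p = mc.DisplacementProfile(fam, d_max=3.5, d_min=0.2, l_target=250.0, l_anchor=20.0)
        ls = np.sort(np.random.RandomState(seed).uniform(20.0, 250.0, 20))
        rates = p.rate(ls)
        assert np.all(np.diff(rates) <= 1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            mc.DisplacementProfile("nope", d_max=1.0, l_target=100.0)
        with pytest.raises(ValueError):
            mc.DisplacementProfile("linear_converging", d_max=1.0, l_target=0.0)
        with pytest.raises(ValueError):
            mc.DisplacementProfile("linear_converging", d_max=1.0, d_min=2.0, l_target=100.0)


class TestProposeStep:
    def test_zero_rate_stays_and_draws_nothing(self):
        rng = np.random.RandomState(0)
        before = rng.get_state()[1].copy()
        out = mc.propose_step(np.array([5.0, 6.0]), 0.0, 10.0, rng)
        assert np.array_equal(out, [5.0, 6.0])
        assert np.array_equal(rng.get_state()[1], before)

    def test_fixed_step_length_is_exact(self):
        rng = np.random.RandomState(1)
        pos = np.zeros((500, 2))
        out = mc.propose_step(pos, np.full(500, 3.5), 10.0, rng, mode="fixed")
        lengths = np.hypot(out[:, 0], out[:, 1])
        assert np.allclose(lengths, 35.0, atol=1e-9)

    def test_gaussian_rms_step_length(self):
        rng = np.random.RandomState(2)
        pos = np.zeros((100_000, 2))
        out = mc.propose_step(pos, np.full(100_000, 3.5), 10.0, rng, mode="gaussian")
        rms = math.sqrt(float(np.mean(out[:, 0] ** 2 + out[:, 1] ** 2)))
        assert rms == pytest.approx(35.0, rel=0.01)

    def test_invalid_args(self):
        rng = np.random.RandomState(0)
        with pytest.raises(ValueError):
            mc.propose_step((0.0, 0.0), 1.0, 0.0, rng)
        with pytest.raises(ValueError):
            mc.propose_step((0.0, 0.0), 1.0, 10.0, rng, mode="levy")


class TestMeshReflection:
    MESH = mc.ActinMesh(500.0)

    def test_same_cell_unchanged(self):
        out = mc.reflect_off_mesh((100.0, 100.0), (140.0, 130.0), self.MESH)
        assert np.allclose(out, (140.0, 130.0))

    def test_single_mirror(self):
        out = mc.reflect_off_mesh((490.0, 100.0), (510.0, 100.0), self.MESH)
        assert np.allclose(out, (490.0, 100.0))

    def test_corner_double_mirror(self):
        out = mc.reflect_off_mesh((495.0, 495.0), (510.0, 510.0), self.MESH)
        assert np.allclose(out, (490.0, 490.0))

    def test_no_mesh_passthrough(self):
        out = mc.reflect_off_mesh((490.0, 100.0), (510.0, 100.0), None)
        assert np.allclose(out, (510.0, 100.0))

    def test_rejects_step_beyond_spacing(self):
        with pytest.raises(ValueError):
            mc.reflect_off_mesh((100.0, 100.0), (700.0, 100.0), self.MESH)

    @given(st.integers(0, 2000))
    def test_confined_to_cell(self, seed):
        r = np.random.RandomState(seed)
        old = r.uniform(0, 3000, 2)
        step = r.uniform(0, 499.0)
        ang = r.uniform(0, 2 * math.pi)
        prop = old + step * np.array([math.cos(ang), math.sin(ang)])
        out = mc.reflect_off_mesh(old, prop, self.MESH)
        assert np.array_equal(np.floor(old / 500.0), np.floor(out / 500.0))

    def test_mesh_validation(self):
        with pytest.raises(ValueError):
            mc.ActinMesh(0.0)
        with pytest.raises(ValueError):
            mc.ActinMesh(700.0).validate_for_box(BOX)
        mc.ActinMesh(250.0).validate_for_box(BOX)


class TestWrap:
    def test_examples(self):
        assert np.allclose(mc.wrap_torus((100.0, 100.0), BOX), (100.0, 100.0))
        assert np.allclose(mc.wrap_torus((3005.0, -3.0), BOX), (5.0, 2997.0))

    @given(st.integers(0, 5000))
    def test_idempotent(self, seed):
        p = np.random.RandomState(seed).uniform(-9000, 9000, 2)
        w = mc.wrap_torus(p, BOX)
        assert np.allclose(mc.wrap_torus(w, BOX), w)
        assert 0 <= w[0] < 3000 and 0 <= w[1] < 3000


class TestFreeDiffusionMSD:
    def test_msd_grows_linearly(self):
        """Constant-rate gaussian steps give MSD = 4 D_eff t with
        D_eff = (rate dt)^2 / (4 dt)."""
        rate, dt, n_frames, n = 0.5, 10.0, 50, 400
        profile = mc.DisplacementProfile(
            "linear_floor", d_max=rate, d_min=rate, l_target=1.0
        )
        cfg = mc.SimulationConfig(
            profile=profile,
            n_agents=n,
            dt_ms=dt,
            duration_s=n_frames * dt / 1000.0,
            step_mode="gaussian",
            seed=9,
            record_every=None,
        )
        rec0 = mc.run_simulation(cfg)
        start = mc.initialise_pattern(cfg, np.random.RandomState(
            mc.simulate._derive_seeds(cfg.seed)[0]))
        disp = mc.toroidal_displacement(start.positions, rec0.final_frame.positions, cfg.box)
        msd = float(np.mean(disp[:, 0] ** 2 + disp[:, 1] ** 2))
        expected = n_frames * (rate * dt) ** 2  # = 4 D_eff T
        assert msd == pytest.approx(expected, rel=0.15)
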