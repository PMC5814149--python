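"""Stochastic nucleator-filament simulator: oracles and invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from monoaster.filaments import FilamentSet
from monoaster.simulate import SimConfig, SimState, ran_wave, run, shadow_profile, step


def _quiet() -> SimConfig:
    """A config with everything switched off; tests turn pieces back on."""
    return SimConfig(k_act=0.0, k_seed=0.0, k_on=0.0, k_nuc=0.0, dt=0.05, t_end=10.0)


class TestStep:
    def test_empty_stays_empty(self):
        cfg = _quiet()
        state = SimState(cfg)
        rng = np.random.default_rng(0)
        for _ in range(200):
            step(state, cfg, rng)
        assert state.n_filaments == 0 and state.n_active == 0

    def test_nucleation_counts_are_poisson(self):
        """A single bound nucleator fires k_nuc*dt per step: thinning oracle."""
        cfg = replace(_quiet(), k_nuc=0.2, k_off=0.0, k_inact=0.0, theta=0.0,
                      v_p=0.0, dt=0.05)
        state = SimState(cfg)
        state.add_filaments(np.array([5.0]), np.array([10.0]), 0.0)
        state.bound_host = np.array([0], dtype=np.int64)
        state.bound_offset = np.array([2.0])
        rng = np.random.default_rng(4)
        n_steps = 100_000
        for _ in range(n_steps):
            step(state, cfg, rng)
        expected = n_steps * cfg.k_nuc * cfg.dt  # 1000
        assert abs(state.n_nucleated - expected) < 3.0 * math.sqrt(expected)

    def test_dt_stability_guard(self):
        with pytest.raises(ValueError, match="unstable"):
            SimConfig(dt=0.5, k_off=1.0, k_nuc=1.0)

    def test_obstacle_must_clear_chromatin(self):
        with pytest.raises(ValueError):
            SimConfig(obstacle=(2.0, 8.0))

    def test_nucleator_conservation(self):
        """Activated = active + inactivated at every point in time."""
        cfg = SimConfig(k_act=50.0, t_end=5.0, dt=0.05, k_seed=5.0)
        rng = np.random.default_rng(1)
        state = SimState(cfg)
        n_act = 0
        for _ in range(int(cfg.t_end / cfg.dt)):
            before = state.n_active + state.n_inactivated
            step(state, cfg, rng)
            # activation is the only source; read it back from the balance
            n_act += state.n_active + state.n_inactivated - before
        assert state.n_active + state.n_inactivated == n_act


class TestRun:
    def test_seed_determinism(self):
        cfg = SimConfig(t_end=20.0, seed=7)
        a = run(cfg)
        b = run(cfg)
        assert np.array_equal(a.density.values, b.density.values)
        assert np.array_equal(a.filaments.minus_pos, b.filaments.minus_pos)
        assert np.array_equal(a.mass, b.mass)

    def test_seeding_only_gives_exponential_density(self):
        """With branching off, coverage decays as exp(-x/ell) beyond the zone."""
        cfg = SimConfig(k_on=0.0, k_nuc=0.0, k_act=0.0, k_seed=60.0,
                        t_end=250.0, chrom_radius=3.0, seed=21, bin_width=2.0)
        vals = np.zeros(0)
        for s in range(4):
            res = run(replace(cfg, seed=cfg.seed + s))
            vals = res.density.values + (vals if vals.size else 0.0)
        x = res.density.x
        sel = (x > 6.0) & (x < 35.0) & (vals > 0)
        slope = np.polyfit(x[sel], np.log(vals[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(cfg.ell, rel=0.10)

    def test_unbound_gradient_length(self):
        """Diffusion + inactivation sets the sqrt(D/k_inact) gradient."""
        cfg = SimConfig(t_end=300.0, seed=3, k_on=0.0, k_nuc=0.0, k_seed=0.0,
                        bin_width=2.0, profile_t_start=180.0)
        res = run(cfg)
        n = res.unbound_nucleators
        sel = (n.x > 8.0) & (n.x < 55.0) & (n.values > 0)
        slope = np.polyfit(n.x[sel], np.log(n.values[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(cfg.ell_u, rel=0.10)

    def test_steady_state_lengths_are_exponential(self):
        """Removal-mode turnover yields exponential length statistics."""
        cfg = SimConfig(t_end=250.0, seed=5, k_on=0.0, k_nuc=0.0, k_seed=80.0)
        res = run(cfg)
        lengths = res.filaments.length
        lengths = lengths[lengths > 1e-6]
        assert len(lengths) > 500
        ks = stats.kstest(lengths, "expon", args=(0, lengths.mean()))
        assert ks.pvalue > 0.01

    def test_subcritical_mass_plateaus(self):
        cfg = SimConfig(t_end=300.0, seed=9)
        res = run(cfg)
        m = res.mass
        q = len(m) // 4
        t_last, m_last = res.mass_t[-q:], m[-q:]
        slope, _, _, p, se = stats.linregress(t_last, m_last)
        # last-quartile slope consistent with zero growth (relative drift tiny)
        assert abs(slope) < 3.0 * se or abs(slope) * np.ptp(t_last) < 0.1 * m_last.mean()

    def test_mass_decays_without_nucleators(self):
        cfg = replace(_quiet(), t_end=120.0, theta=0.05)
        rng_state = SimState(cfg)
        rng = np.random.default_rng(2)
        rng_state.add_filaments(np.random.default_rng(0).uniform(0, 5, 300),
                                np.random.default_rng(0).exponential(8, 300), 0.0)
        m0 = rng_state.total_polymer
        for _ in range(int(cfg.t_end / cfg.dt)):
            step(rng_state, cfg, rng)
        assert rng_state.total_polymer < 0.05 * m0


class TestShadow:
    def test_zero_width_obstacle_ratio_near_one(self):
        cfg = SimConfig(seed=13, t_end=150.0, obstacle=(15.0, 15.0),
                        domain_length=80.0)
        res = shadow_profile(cfg, window=20.0, n_seeds=2)
        assert res.window_ratio == pytest.approx(1.0, abs=0.15)

    def test_stimulated_mode_has_hard_shadow(self):
        cfg = SimConfig(seed=31, t_end=150.0, obstacle=(12.0, 16.0), domain_length=80.0)
        res = shadow_profile(cfg, window=24.0, n_seeds=2)
        assert res.window_ratio < 0.05

    def test_independent_mode_repopulates(self):
        cfg = SimConfig(seed=31, t_end=150.0, obstacle=(12.0, 16.0), domain_length=80.0,
                        independent_nucleation=True, k_nuc=0.004, k_on=0.0)
        res = shadow_profile(cfg, window=24.0, n_seeds=2)
        assert res.window_ratio > 0.4


def _supercritical(seed: int, **kw) -> SimConfig:
    base = dict(seed=seed, t_end=50.0, uniform_activation=True, k_act=400.0,
                k_on=4e-3, k_seed=0.0, domain_length=150.0, dt=0.08)
    base.update(kw)
    return SimConfig(**base)


def _pregrown(n: int = 200) -> FilamentSet:
    rng = np.random.default_rng(0)
    return FilamentSet(minus_pos=rng.uniform(0, 5, n),
                       length=np.minimum(rng.exponential(8, n), 15.0))


class TestRanWave:
    def test_no_polymerization_no_front(self):
        cfg = _supercritical(1, v_p=0.0, t_end=30.0)
        wf = ran_wave(cfg, _pregrown(), snapshot_interval=5.0)
        assert not wf.has_front or wf.speed < 0.02

    def test_front_speed_independent_of_diffusion(self):
        speeds = []
        for D in (5.0, 20.0):
            wf = ran_wave(_supercritical(8, D=D), _pregrown(), snapshot_interval=5.0)
            assert wf.has_front
            speeds.append(wf.speed)
        se = max(wf.speed_se, 0.02)
        assert abs(speeds[0] - speeds[1]) < 4.0 * se

    def test_front_speed_increases_with_polymerization_speed(self):
        speeds = []
        for v_p in (0.1, 0.2, 0.4):
            wf = ran_wave(_supercritical(15, v_p=v_p), _pregrown(), snapshot_interval=5.0)
            assert wf.has_front
            speeds.append(wf.speed)
        assert speeds[0] < speeds[1] < speeds[2]
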