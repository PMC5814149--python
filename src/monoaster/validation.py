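"""Closed-loop reproduction studies on synthetic ground truth.

Each function runs one generate-then-measure loop at a configurable problem
size and returns the summary numbers: the exactness of the length-rescaling
identity, minus-end recovery of the ablation pipeline against direct
bookkeeping, parameter and velocity recovery, length and lifetime recovery,
and the agreement between the stochastic simulator and the closed-form
steady state.  They are deterministic given their seeds and are used both by
the test suite and by the reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import ablation as ab
from .filaments import FilamentSet, count_severed_minus_ends
from .lifetimes import LifetimeSample, fit_lifetime, sample_lifetimes, simulate_speckle_lifetimes
from .model import ModelParams, RadialProfile, density_profile, fit_density, rescale_profile
from .simulate import SimConfig, ran_wave, run, shadow_profile
from .synthdata import Optics, sample_monopole

CONTROL = ModelParams(ell=8.0, ell_u=24.9, alpha=2.38, rho0=4058.0, theta=0.05)
MCAK = ModelParams(ell=24.0, ell_u=24.9, alpha=2.38, rho0=4058.0, theta=0.016)


def rescaling_identity_max_error(n_sets: int = 100, seed: int = 0) -> float:
    """Max relative error of density(ell_C) vs rescaled density(ell_M)."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 100.0, 257)
    worst = 0.0
    for _ in range(n_sets):
        p = ModelParams(
            ell=rng.uniform(4.0, 40.0),
            ell_u=rng.uniform(5.0, 50.0),
            alpha=rng.uniform(0.0, 5.0),
            rho0=rng.uniform(0.1, 1e4),
        )
        ell_to = rng.uniform(4.0, 40.0)
        direct = density_profile(replace(p, ell=ell_to), grid).values
        via = rescale_profile(density_profile(p, grid), p.ell, ell_to).values
        worst = max(worst, float(np.max(np.abs(via / direct - 1.0))))
    return worst


@dataclass
class OracleStudy:
    max_rel_error: float
    n_bins_compared: int
    n_cuts: int


def ablation_oracle_study(
    seed: int = 0,
    n_filaments: int = 10_000,
    n_cuts: int = 12,
    bin_width: float = 3.0,
    min_counts: int = 100,
) -> OracleStudy:
    """Pipeline minus-end counts vs direct severed-filament bookkeeping.

    One control-regime monopole, circular cuts at ``n_cuts`` radii; per cut,
    the wave-area curve is differenced into per-bin minus-end counts and
    compared with the ground truth in every bin holding >= ``min_counts``.
    """
    optics = Optics(pixel_size=0.35, size=420, noise="none", frame_interval=0.5)
    filaments = sample_monopole(CONTROL, n_filaments, seed=seed, x_max=58.0)
    radii = np.linspace(10.0, 28.0, n_cuts)
    v_d = 33.5 / 60.0
    worst = 0.0
    n_bins = 0
    for i, r in enumerate(radii):
        cut = ab.CutSpec(geometry="circle", radius=float(r), delta_t=2.0)
        stack = ab.simulate_cut(filaments, cut, v_d, optics, seed=seed + i)
        _, _, est = ab.analyze_cut_movie(stack, cut)
        edges = np.arange(0.0, r - v_d * cut.delta_t, bin_width)
        oracle = count_severed_minus_ends(filaments, float(r), edges)
        pipe = ab.minus_end_counts(est, edges, optics.intensity_per_um)
        big = oracle >= min_counts
        if big.any():
            worst = max(worst, float(np.abs(pipe[big] / oracle[big] - 1.0).max()))
            n_bins += int(big.sum())
    return OracleStudy(max_rel_error=worst, n_bins_compared=n_bins, n_cuts=n_cuts)


@dataclass
class RecoveryStudy:
    ell_u_median_err: float
    alpha_median_err: float
    n_profiles: int


def parameter_recovery_study(
    seed: int = 0, n_profiles: int = 50, noise: float = 0.05, n_points: int = 100
) -> RecoveryStudy:
    """fit_density round trip on noisy synthetic long-microtubule profiles."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 80.0, n_points)
    clean = density_profile(MCAK, grid).values
    e_lu, e_a = [], []
    for _ in range(n_profiles):
        noisy = clean * (1.0 + noise * rng.standard_normal(n_points))
        fit = fit_density(
            RadialProfile(x=grid, values=np.maximum(noisy, 1e-9)), ell_fixed=MCAK.ell
        )
        e_lu.append(abs(fit.params.ell_u / MCAK.ell_u - 1.0))
        e_a.append(abs(fit.params.alpha / MCAK.alpha - 1.0))
    return RecoveryStudy(
        ell_u_median_err=float(np.median(e_lu)),
        alpha_median_err=float(np.median(e_a)),
        n_profiles=n_profiles,
    )


def velocity_recovery_study(
    seed: int = 0,
    speeds_um_per_min: tuple[float, ...] = (20.0, 33.5, 46.0),
    n_filaments: int = 8000,
) -> dict[float, float]:
    """Recovered depolymerization speed per true speed, shot-noise rendering."""
    optics = Optics(pixel_size=0.35, size=420, noise="poisson", frame_interval=0.5)
    out = {}
    for v_min in speeds_um_per_min:
        v_d = v_min / 60.0
        filaments = sample_monopole(CONTROL, n_filaments, seed=seed, x_max=58.0)
        cut = ab.CutSpec(geometry="circle", radius=18.0, delta_t=2.0)
        stack = ab.simulate_cut(filaments, cut, v_d, optics, seed=seed + 1)
        _, vel, _ = ab.analyze_cut_movie(stack, cut)
        out[v_min] = vel.v_um_per_min
    return out


@dataclass
class LengthStudy:
    ell_control: float
    ell_mcak: float
    ratio: float
    n_cuts: int


def length_recovery_study(seed: int = 0, n_filaments: int = 10_000) -> LengthStudy:
    """Mean-length recovery for the short and long regimes from multi-cut decays."""
    v_d = 33.5 / 60.0
    recovered = {}
    setups = [
        (CONTROL, (12.0, 15.0, 18.0, 21.0, 24.0, 28.0), Optics(pixel_size=0.35, size=420, noise="none", frame_interval=0.5)),
        (MCAK, (18.0, 26.0, 34.0, 42.0, 50.0, 58.0, 66.0), Optics(pixel_size=0.5, size=640, noise="none", frame_interval=1.0)),
    ]
    n_total = 0
    for params, radii, optics in setups:
        x_max = min(6.0 * params.ell + 40.0, optics.field_radius - 2.0)
        ests = []
        for i, r in enumerate(radii):
            filaments = sample_monopole(params, n_filaments, seed=seed + 100 + i, x_max=x_max)
            cut = ab.CutSpec(geometry="circle", radius=r, delta_t=2.0)
            stack = ab.simulate_cut(filaments, cut, v_d, optics, seed=seed + i)
            _, _, est = ab.analyze_cut_movie(stack, cut)
            ests.append(est)
            n_total += 1
        lf = ab.length_distribution(ests, optics.intensity_per_um, y_band=(2.0, 10.0))
        recovered[params.ell] = lf.ell
    return LengthStudy(
        ell_control=recovered[CONTROL.ell],
        ell_mcak=recovered[MCAK.ell],
        ratio=recovered[MCAK.ell] / recovered[CONTROL.ell],
        n_cuts=n_total,
    )


def lifetime_recovery_study(
    seed: int = 0,
    taus: tuple[float, ...] = (40.0, 80.0, 240.0),
    n: int = 5000,
    n_reps: int = 5,
) -> dict[float, float]:
    """Median recovered tau per true tau (inverse-CDF sampling + MLE refit)."""
    out = {}
    for k, tau in enumerate(taus):
        fits = []
        for rep in range(n_reps):
            x = sample_lifetimes(tau, 2.0, n, np.random.default_rng(seed + 97 * k + rep))
            fits.append(fit_lifetime(LifetimeSample(x), t_min=2.0).tau)
        out[tau] = float(np.median(fits))
    return out


def drift_limit_error(L0: float = 8.0, v: float = 0.5) -> float:
    """Relative error of the pure-drift lifetime against L0 / v (exact)."""
    s = simulate_speckle_lifetimes(L0=L0, v=v, D=0.0, n=100, seed=0)
    return float(np.abs(s.durations / (L0 / v) - 1.0).max())


@dataclass
class GradientAgreement:
    max_dev_over_se: float
    nucleator_gradient_um: float
    expected_gradient_um: float
    alpha_fitted: float
    n_seeds: int


def simulator_model_agreement(seed: int = 0, n_seeds: int = 20) -> GradientAgreement:
    """Subcritical gradient runs vs the closed-form steady state.

    The binned filament density, averaged over seeds, is fitted with the
    model (mean length fixed to v_p/theta) and compared bin by bin against
    the seed-to-seed standard error; the unbound-nucleator gradient is fitted
    for its decay length.
    """
    cfg = SimConfig(t_end=300.0, dt=0.08, bin_width=1.0)
    dens = []
    nucs = None
    for s in range(n_seeds):
        res = run(replace(cfg, seed=seed + s))
        dens.append(res.density.values)
        nucs = res.unbound_nucleators.values + (nucs if nucs is not None else 0.0)
    x = res.density.x
    dens = np.asarray(dens)
    mean = dens.mean(axis=0)
    se = dens.std(axis=0, ddof=1) / math.sqrt(n_seeds)

    sel = (x >= 6.0) & (x <= 45.0)
    fit = fit_density(RadialProfile(x=x[sel], values=mean[sel]), ell_fixed=cfg.ell)
    curve = density_profile(fit.params, x[sel]).values
    max_dev = float(np.max(np.abs(curve - mean[sel]) / se[sel]))

    nsel = (x > 8.0) & (x < 55.0) & (nucs > 0)
    slope = np.polyfit(x[nsel], np.log(nucs[nsel]), 1)[0]
    return GradientAgreement(
        max_dev_over_se=max_dev,
        nucleator_gradient_um=float(-1.0 / slope),
        expected_gradient_um=cfg.ell_u,
        alpha_fitted=fit.params.alpha,
        n_seeds=n_seeds,
    )


def supercritical_growth_slope(seed: int = 0, n_seeds: int = 10) -> tuple[float, float]:
    """(mean, SE) of the exponential-phase log-mass slope, uniform activation."""
    slopes = []
    for s in range(n_seeds):
        cfg = SimConfig(seed=seed + s, t_end=50.0, uniform_activation=True,
                        k_act=400.0, k_on=4e-3, k_seed=5.0, domain_length=150.0,
                        dt=0.08, sample_interval=2.0)
        res = run(cfg)
        sel = (res.mass_t > 20.0) & (res.mass > 0)
        slopes.append(np.polyfit(res.mass_t[sel], np.log(res.mass[sel]), 1)[0])
    slopes = np.asarray(slopes)
    return float(slopes.mean()), float(slopes.std(ddof=1) / math.sqrt(n_seeds))


def shadow_contrast(seed: int = 0, n_seeds: int = 6) -> tuple[float, float]:
    """(stimulated, independent) normalized density behind an obstacle."""
    base = dict(t_end=200.0, dt=0.08, obstacle=(12.0, 16.0), domain_length=80.0)
    stim = shadow_profile(SimConfig(seed=seed, **base), window=24.0, n_seeds=n_seeds)
    indep = shadow_profile(
        SimConfig(seed=seed, independent_nucleation=True, k_nuc=0.004, k_on=0.0, **base),
        window=24.0, n_seeds=n_seeds,
    )
    return stim.window_ratio, indep.window_ratio


def wave_front_speeds(seed: int = 0) -> dict[str, float]:
    """Nucleation-front speeds: diffusion halved/doubled and v_p swept."""
    rng = np.random.default_rng(seed)
    pregrown = FilamentSet(
        minus_pos=rng.uniform(0, 5, 200),
        length=np.minimum(rng.exponential(8.0, 200), 15.0),
    )
    out = {}
    for label, kw in [("D5", dict(D=5.0)), ("D20", dict(D=20.0)),
                      ("vp_02", dict(v_p=0.2)), ("vp_04", dict(v_p=0.4))]:
        cfg = SimConfig(seed=seed, t_end=50.0, uniform_activation=True, k_act=400.0,
                        k_on=4e-3, k_seed=0.0, domain_length=150.0, dt=0.08, **kw)
        wf = ran_wave(cfg, pregrown, snapshot_interval=5.0)
        out[label] = wf.speed if wf.has_front else 0.0
    return out
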