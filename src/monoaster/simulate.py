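"""Stochastic agent-based simulator of the nucleator–filament system.

Inactive nucleators are activated inside a chromatin zone at the center (or
everywhere, under uniform activation), diffuse, inactivate at a constant
rate, bind and unbind filaments, and — while bound — nucleate new
microtubules at the nucleator's position with the mother's (outward)
polarity.  Filaments elongate at the plus end and turn over either by
whole-filament removal (rate theta, the clean mapping onto the steady-state
model) or by catastrophe followed by shrinkage at v_d.  Geometry is the
effective 1D radial convention of the analysis: positions are distances from
the center, with a reflecting boundary at 0.

Time stepping is fixed-step tau-leaping.  Constant per-particle rates are
guarded by the dt stability invariant; the position-dependent binding rate is
converted to a per-step probability 1 - exp(-rate*dt), which stays valid even
where local polymer density is high.  Accuracy is checked against Poisson and
closed-form oracles in the test suite.

The emergent behaviour mirrors the model module: the unbound-nucleator
gradient decays over sqrt(D / k_inact); with a finite gradient the structure
is bounded, while uniform activation with gain beta0 * ell > 1 grows without
bound as a filament-borne wave whose speed is set by microtubule dynamics,
not nucleator diffusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .filaments import FilamentSet
from .model import RadialProfile

__all__ = [
    "SimConfig",
    "SimState",
    "SimResult",
    "ShadowResult",
    "WaveFrontResult",
    "step",
    "run",
    "growth_curve",
    "shadow_profile",
    "ran_wave",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (µm, s).

    Rate values are not printed measurements; the defaults are chosen so the
    emergent steady state lands in the measured regime (mean length
    v_p/theta = 8 µm, nucleator gradient sqrt(D/k_inact) = 25 µm, subcritical
    branching) — see the methods note.
    """

    domain_length: float = 100.0
    chrom_radius: float = 5.0       # activation zone [0, chrom_radius]
    k_act: float = 200.0            # activation events/s in the zone
    D: float = 10.0                 # nucleator diffusion, µm²/s
    k_inact: float = 0.016          # inactivation rate, 1/s
    k_on: float = 1.6e-5            # binding rate per µm of local filament, 1/(µm s)
    capture_radius: float = 0.25    # binding neighborhood half-width, µm
    k_off: float = 0.5              # unbinding rate, 1/s
    k_nuc: float = 0.5              # nucleation rate per bound nucleator, 1/s
    k_seed: float = 20.0            # spontaneous chromatin seeding, filaments/s
    v_p: float = 0.4                # plus-end polymerization speed, µm/s
    turnover_mode: Literal["removal", "catastrophe"] = "removal"
    theta: float = 0.05             # whole-filament removal rate, 1/s
    k_cat: float = 0.05             # catastrophe rate, 1/s (catastrophe mode)
    v_d: float = 0.56               # shrinkage speed after catastrophe, µm/s
    dt: float = 0.08
    t_end: float = 300.0
    seed: int = 0
    uniform_activation: bool = False
    independent_nucleation: bool = False
    obstacle: tuple[float, float] | None = None
    bin_width: float = 1.0          # spatial binning of output profiles, µm
    profile_t_start: float | None = None  # start of steady-state averaging window
    sample_interval: float = 5.0    # profile/mass sampling cadence, s

    def __post_init__(self) -> None:
        for name in ("k_act", "D", "k_inact", "k_on", "k_off", "k_nuc", "k_seed",
                     "v_p", "theta", "k_cat", "v_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.chrom_radius < self.domain_length):
            raise ValueError("need 0 < chrom_radius < domain_length")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.obstacle is not None:
            a, b = self.obstacle
            # a == b is allowed: a degenerate (zero-width) obstacle blocks nothing
            if not (0 <= a <= b <= self.domain_length):
                raise ValueError("obstacle interval must satisfy 0 <= a <= b <= domain")
            if a < self.chrom_radius:
                raise ValueError("obstacle must lie strictly outside the chromatin zone")
        # fixed-step stability: constant per-particle rates must leap < 0.1
        max_rate = max(
            self.k_inact + self.k_off + self.k_nuc,   # bound nucleator
            self.k_inact,                              # unbound nucleator
            self.theta if self.turnover_mode == "removal" else self.k_cat,
        )
        if self.dt * max_rate >= 0.1:
            raise ValueError(
                f"dt={self.dt} unstable: dt * max rate = {self.dt * max_rate:.3f} >= 0.1"
            )

    @property
    def ell(self) -> float:
        """Mean filament length implied by the turnover mode, µm."""
        if self.turnover_mode == "removal":
            return self.v_p / self.theta
        return self.v_p / self.k_cat

    @property
    def ell_u(self) -> float:
        """Nucleator gradient length sqrt(D / k_inact), µm."""
        return math.sqrt(self.D / self.k_inact)


_GROWING, _SHRINKING = 0, 1


class SimState:
    """Mutable simulation state: filament and nucleator arrays.

    Filament arrays are append-only within a run; removal clears the alive
    flag so bound-nucleator host indices stay valid.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self.t = 0.0
        self.f_minus = np.empty(0)
        self.f_len = np.empty(0)
        self.f_birth = np.empty(0)
        self.f_alive = np.empty(0, dtype=bool)
        self.f_state = np.empty(0, dtype=np.int8)
        self.unbound = np.empty(0)            # positions of active unbound nucleators
        self.bound_host = np.empty(0, dtype=np.int64)
        self.bound_offset = np.empty(0)       # µm from the host's minus end
        self.n_inactivated = 0
        self.n_nucleated = 0

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_filaments(self) -> int:
        return int(self.f_alive.sum())

    @property
    def n_active(self) -> int:
        return len(self.unbound) + len(self.bound_host)

    @property
    def total_polymer(self) -> float:
        return float(self.f_len[self.f_alive].sum())

    def bound_positions(self) -> np.ndarray:
        return self.f_minus[self.bound_host] + self.bound_offset

    def add_filaments(self, minus: np.ndarray, length: np.ndarray, t: float) -> None:
        n = len(minus)
        if n == 0:
            return
        self.f_minus = np.concatenate([self.f_minus, minus])
        self.f_len = np.concatenate([self.f_len, length])
        self.f_birth = np.concatenate([self.f_birth, np.full(n, t)])
        self.f_alive = np.concatenate([self.f_alive, np.ones(n, dtype=bool)])
        self.f_state = np.concatenate([self.f_state, np.full(n, _GROWING, dtype=np.int8)])

    def filament_set(self) -> FilamentSet:
        m = self.f_alive
        return FilamentSet(
            minus_pos=self.f_minus[m].copy(),
            length=self.f_len[m].copy(),
            birth_time=self.f_birth[m].copy(),
        )

    def coverage_counts(self, bin_edges: np.ndarray) -> np.ndarray:
        """Number of alive filaments overlapping each bin (diff-array trick)."""
        nb = len(bin_edges) - 1
        bw = bin_edges[1] - bin_edges[0]
        diff = np.zeros(nb + 1)
        m = self.f_alive
        lo = np.clip((self.f_minus[m] / bw).astype(int), 0, nb)
        hi = np.clip((self.f_len[m] + self.f_minus[m]) / bw, 0, nb).astype(int) + 1
        hi = np.clip(hi, 0, nb + 1)
        np.add.at(diff, lo, 1.0)
        valid = hi <= nb
        np.add.at(diff, hi[valid], -1.0)
        return np.cumsum(diff)[:nb]


def _in_obstacle(x: np.ndarray, obstacle: tuple[float, float] | None) -> np.ndarray:
    if obstacle is None:
        return np.zeros(len(x), dtype=bool)
    a, b = obstacle
    return (x >= a) & (x < b)


def step(state: SimState, config: SimConfig, rng: np.random.Generator) -> SimState:
    """Advance the state by one fixed time step dt (in place)."""
    dt = config.dt
    L = config.domain_length

    # 1. activation
    rate = config.k_act
    n_new = rng.poisson(rate * dt)
    if n_new:
        if config.uniform_activation:
            new = rng.uniform(0.0, L, n_new)
        else:
            new = rng.uniform(0.0, config.chrom_radius, n_new)
        state.unbound = np.concatenate([state.unbound, new])

    # 2. diffusion of unbound nucleators, reflecting at both boundaries
    if len(state.unbound):
        state.unbound = state.unbound + math.sqrt(2 * config.D * dt) * rng.standard_normal(
            len(state.unbound)
        )
        state.unbound = np.abs(state.unbound)
        over = state.unbound > L
        state.unbound[over] = 2 * L - state.unbound[over]
        np.clip(state.unbound, 0.0, L, out=state.unbound)

    # 3. inactivation (both unbound and bound)
    if len(state.unbound):
        keep = rng.random(len(state.unbound)) >= config.k_inact * dt
        state.n_inactivated += int((~keep).sum())
        state.unbound = state.unbound[keep]
    if len(state.bound_host):
        keep = rng.random(len(state.bound_host)) >= config.k_inact * dt
        state.n_inactivated += int((~keep).sum())
        state.bound_host = state.bound_host[keep]
        state.bound_offset = state.bound_offset[keep]

    # 4. binding: rate = k_on * filament length within the capture neighborhood
    if len(state.unbound) and config.k_on > 0 and state.n_filaments:
        bw = max(config.capture_radius, 1e-3)
        nb = int(math.ceil(L / bw))
        edges = np.arange(nb + 1) * bw
        cover = state.coverage_counts(edges)
        local_len = cover[np.clip((state.unbound / bw).astype(int), 0, nb - 1)] * (
            2 * config.capture_radius
        )
        p_bind = -np.expm1(-config.k_on * local_len * dt)
        binds = rng.random(len(state.unbound)) < p_bind
        if binds.any():
            bx = state.unbound[binds]
            # host selection: any alive filament whose lattice reaches the
            # capture neighborhood; uniform among candidates
            minus = state.f_minus[None, :]
            plus = (state.f_minus + state.f_len)[None, :]
            cand = (
                state.f_alive[None, :]
                & (minus <= bx[:, None] + config.capture_radius)
                & (plus >= bx[:, None] - config.capture_radius)
            )
            n_cand = cand.sum(axis=1)
            ok = n_cand > 0
            hosts = np.full(len(bx), -1, dtype=np.int64)
            if ok.any():
                # uniform candidate per row, fully vectorized: pick the
                # k-th True in each row via a cumulative-count threshold
                k = (rng.random(len(bx)) * n_cand).astype(np.int64)
                cum = np.cumsum(cand, axis=1)
                hosts[ok] = (cum[ok] > k[ok, None]).argmax(axis=1)
            attached = hosts >= 0
            new_hosts = hosts[attached]
            offs = np.clip(bx[attached] - state.f_minus[new_hosts], 0.0, state.f_len[new_hosts])
            state.bound_host = np.concatenate([state.bound_host, new_hosts])
            state.bound_offset = np.concatenate([state.bound_offset, offs])
            drop = binds.copy()
            drop[np.nonzero(binds)[0][~attached]] = False
            state.unbound = state.unbound[~drop]

    # 5. unbinding and host-loss release
    if len(state.bound_host):
        host_dead = ~state.f_alive[state.bound_host]
        unbind = (rng.random(len(state.bound_host)) < config.k_off * dt) | host_dead
        if unbind.any():
            released = state.f_minus[state.bound_host[unbind]] + state.bound_offset[unbind]
            state.unbound = np.concatenate([state.unbound, np.clip(released, 0.0, L)])
            state.bound_host = state.bound_host[~unbind]
            state.bound_offset = state.bound_offset[~unbind]

    # 6. nucleation
    new_minus = []
    if len(state.bound_host) and config.k_nuc > 0 and not config.independent_nucleation:
        nuc = rng.random(len(state.bound_host)) < config.k_nuc * dt
        if nuc.any():
            pos = state.f_minus[state.bound_host[nuc]] + np.clip(
                state.bound_offset[nuc], 0.0, state.f_len[state.bound_host[nuc]]
            )
            new_minus.append(pos)
    if config.independent_nucleation and len(state.unbound) and config.k_nuc > 0:
        nuc = rng.random(len(state.unbound)) < config.k_nuc * dt
        if nuc.any():
            new_minus.append(state.unbound[nuc])
    # spontaneous seeding at chromatin
    n_seed = rng.poisson(config.k_seed * dt)
    if n_seed:
        new_minus.append(rng.uniform(0.0, config.chrom_radius, n_seed))
    if new_minus:
        pos = np.concatenate(new_minus)
        ok = ~_in_obstacle(pos, config.obstacle)  # no nucleation inside an obstacle
        pos = pos[ok]
        state.n_nucleated += len(pos)
        state.add_filaments(pos, np.zeros(len(pos)), state.t)

    # 7. plus-end growth with obstacle and domain clamping
    grow = state.f_alive & (state.f_state == _GROWING)
    if grow.any():
        state.f_len[grow] += config.v_p * dt
        if config.obstacle is not None and config.obstacle[1] > config.obstacle[0]:
            a, b = config.obstacle
            before = grow & (state.f_minus < a)
            state.f_len[before] = np.minimum(state.f_len[before], a - state.f_minus[before])
        state.f_len[grow] = np.minimum(
            state.f_len[grow], config.domain_length - state.f_minus[grow]
        )

    # 8. turnover
    alive_idx = np.nonzero(state.f_alive)[0]
    if len(alive_idx):
        if config.turnover_mode == "removal":
            gone = rng.random(len(alive_idx)) < config.theta * dt
            state.f_alive[alive_idx[gone]] = False
        else:
            growing = state.f_state[alive_idx] == _GROWING
            cat = rng.random(len(alive_idx)) < config.k_cat * dt
            state.f_state[alive_idx[cat & growing]] = _SHRINKING
            shrink = state.f_alive & (state.f_state == _SHRINKING)
            state.f_len[shrink] -= config.v_d * dt
            dead = shrink & (state.f_len <= 0)
            state.f_len[dead] = 0.0
            state.f_alive[dead] = False

    state.t += dt
    return state


@dataclass
class SimResult:
    """Output of a full simulation run."""

    filaments: FilamentSet
    density: RadialProfile            # time-averaged polymer coverage per µm
    unbound_nucleators: RadialProfile  # time-averaged unbound count per µm
    mass_t: np.ndarray                # s
    mass: np.ndarray                  # total polymer length, µm
    final_state: SimState
    config: SimConfig


def run(config: SimConfig) -> SimResult:
    """Simulate to t_end; profiles are time-averaged over the tail window.

    Deterministic given ``config.seed``.  The averaging window starts at
    ``profile_t_start`` (default: half of t_end) and samples every
    ``sample_interval`` seconds.
    """
    rng = np.random.default_rng(config.seed)
    state = SimState(config)
    n_steps = int(round(config.t_end / config.dt))
    t_start = (
        config.profile_t_start if config.profile_t_start is not None else config.t_end / 2
    )
    sample_every = max(int(round(config.sample_interval / config.dt)), 1)

    edges = np.arange(0.0, config.domain_length + config.bin_width, config.bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens_acc = np.zeros(len(centers))
    nuc_acc = np.zeros(len(centers))
    n_prof = 0
    mass_t, mass = [], []

    for i in range(n_steps):
        step(state, config, rng)
        if i % sample_every == 0:
            mass_t.append(state.t)
            mass.append(state.total_polymer)
            if state.t >= t_start:
                m = state.f_alive
                lo = np.clip(state.f_minus[m][:, None], edges[:-1], edges[1:])
                hi = np.clip((state.f_minus[m] + state.f_len[m])[:, None], edges[:-1], edges[1:])
                dens_acc += (hi - lo).sum(axis=0) / config.bin_width
                cnt, _ = np.histogram(state.unbound, bins=edges)
                nuc_acc += cnt / config.bin_width
                n_prof += 1

    n_prof = max(n_prof, 1)
    density = RadialProfile(x=centers, values=dens_acc / n_prof, kind="density")
    nucleators = RadialProfile(x=centers, values=nuc_acc / n_prof, kind="intensity")
    return SimResult(
        filaments=state.filament_set(),
        density=density,
        unbound_nucleators=nucleators,
        mass_t=np.asarray(mass_t),
        mass=np.asarray(mass),
        final_state=state,
        config=config,
    )


def growth_curve(config: SimConfig, sampling_interval: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Total polymer length vs time (the simulated mass-over-time curve)."""
    cfg = replace(config, sample_interval=sampling_interval)
    res = run(cfg)
    return res.mass_t, res.mass


@dataclass
class ShadowResult:
    """Normalized density behind an obstacle vs an obstacle-free reference."""

    distance_obstacle_radii: np.ndarray  # (x - b) / obstacle radius
    normalized: np.ndarray               # rho_obstacle(x) / rho_reference(x)
    window_ratio: float                  # windowed-sum ratio behind the obstacle
    obstacle: tuple[float, float]


def shadow_profile(
    config: SimConfig, window: float = 24.0, n_seeds: int = 8
) -> ShadowResult:
    """Shadow cast by an inert obstacle, as a normalized density ratio.

    Runs paired simulations (with the obstacle and without, same seed list),
    averages the binned density over seeds, and returns the profile behind
    the obstacle divided by the obstacle-free profile at the same positions,
    with distance rescaled by the obstacle radius.  ``window_ratio`` is the
    ratio of summed densities over [b, b + window] — near zero when
    nucleation requires physical proximity to filaments, order one when
    nucleators nucleate independently.
    """
    if config.obstacle is None:
        raise ValueError("config.obstacle must be set")
    a, b = config.obstacle
    dens_obs = None
    dens_ref = None
    for s in range(n_seeds):
        cfg_obs = replace(config, seed=config.seed + s)
        cfg_ref = replace(cfg_obs, obstacle=None)
        r_obs = run(cfg_obs)
        r_ref = run(cfg_ref)
        if dens_obs is None:
            x = r_obs.density.x
            dens_obs = np.zeros_like(r_obs.density.values)
            dens_ref = np.zeros_like(r_ref.density.values)
        dens_obs += r_obs.density.values
        dens_ref += r_ref.density.values

    sel = (x >= b) & (x <= b + window)
    radius = (b - a) / 2.0 if b > a else 1.0  # degenerate obstacle: keep µm
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dens_ref[sel] > 0, dens_obs[sel] / dens_ref[sel], np.nan)
    # unweighted mean of the pointwise-normalized profile over the window,
    # restricted to bins where the reference carries real signal
    strong = dens_ref[sel] > 0.05 * dens_ref[sel].max(initial=0.0)
    window_ratio = float(np.nanmean(ratio[strong])) if strong.any() else math.nan
    return ShadowResult(
        distance_obstacle_radii=(x[sel] - b) / radius,
        normalized=ratio,
        window_ratio=window_ratio,
        obstacle=(a, b),
    )


@dataclass
class WaveFrontResult:
    """Front of the nucleation wave after uniform activation."""

    times: np.ndarray
    front: np.ndarray        # outermost position with density above threshold
    speed: float             # µm/s, nan when no front advanced
    speed_se: float
    has_front: bool


def ran_wave(
    config: SimConfig,
    pregrown: FilamentSet,
    density_threshold: float = 2.0,
    snapshot_interval: float = 5.0,
) -> WaveFrontResult:
    """Wave-like growth of a pre-grown structure under uniform activation.

    Mimics flooding the cytoplasm with active nucleators: the pre-existing
    structure seeds an outward-travelling nucleation front whose speed is set
    by filament dynamics (v_p, turnover, gain), not nucleator diffusion.
    Subcritical parameters yield a 'no front' result rather than an error.
    """
    if not config.uniform_activation:
        raise ValueError("ran_wave requires uniform_activation=True")
    rng = np.random.default_rng(config.seed)
    state = SimState(config)
    state.add_filaments(pregrown.minus_pos.copy(), pregrown.length.copy(), 0.0)

    edges = np.arange(0.0, config.domain_length + config.bin_width, config.bin_width)
    n_steps = int(round(config.t_end / config.dt))
    every = max(int(round(snapshot_interval / config.dt)), 1)
    times, fronts = [], []
    for i in range(n_steps):
        step(state, config, rng)
        if (i + 1) % every == 0:
            m = state.f_alive
            lo = np.clip(state.f_minus[m][:, None], edges[:-1], edges[1:])
            hi = np.clip((state.f_minus[m] + state.f_len[m])[:, None], edges[:-1], edges[1:])
            dens = (hi - lo).sum(axis=0) / config.bin_width
            above = np.nonzero(dens > density_threshold)[0]
            times.append(state.t)
            fronts.append(edges[above[-1] + 1] if len(above) else 0.0)

    times = np.asarray(times)
    fronts = np.asarray(fronts)
    moved = fronts[-1] - fronts[0]
    if len(times) < 3 or moved <= config.bin_width:
        return WaveFrontResult(times, fronts, math.nan, math.nan, has_front=False)
    A = np.vstack([times, np.ones_like(times)]).T
    coef, res_, *_ = np.linalg.lstsq(A, fronts, rcond=None)
    resid = fronts - A @ coef
    dof = max(len(times) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    return WaveFrontResult(
        times=times,
        front=fronts,
        speed=float(coef[0]),
        speed_se=float(math.sqrt(max(cov[0, 0], 0.0))),
        has_front=True,
    )
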