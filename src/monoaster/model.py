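"""Steady-state model of autocatalytic, microtubule-stimulated nucleation.

A monopolar spindle is treated as an effective 1D radial structure: all
microtubules point outward, minus ends mark nucleation sites, and lengths are
exponentially distributed with mean ``ell`` (set by polymerization speed and
turnover, ell = v_p / theta).  Nucleation is stimulated by existing polymer and
licensed by a gradient of active nucleators that decays over a length
``ell_u`` away from the chromatin at the center.  The branching gain per unit
length of polymer is

    beta(x) = (alpha / ell_u) * exp(-x / ell_u),

so ``alpha`` is the total integrated gain of the gradient.  The steady-state
polymer density is the closed form

    rho(x) = rho0 * exp[ alpha * (1 - exp(-x/ell_u)) - x / ell ],

and the nucleation profile (events per unit area, up to a global amplitude A)

    nu(x) = A * beta(x) * rho(x),

which together satisfy d(rho)/dx = nu/A - rho/ell.  The local reproductive
number R(x) = beta(x) * ell is the mean number of daughters a microtubule at x
creates; the structure is bounded whenever R drops below 1 at the periphery,
which for finite ell_u always happens.  With uniform activation (ell_u
infinite at fixed gain density beta0 = alpha/ell_u) growth is unbounded iff
beta0 * ell > 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ModelParams",
    "RadialProfile",
    "FitResult",
    "density_profile",
    "nucleation_profile",
    "rescale_profile",
    "fit_density",
    "predict_counterpart",
    "reproductive_number",
    "critical_radius",
    "is_bounded",
]

ProfileKind = Literal["density", "nucleation", "intensity"]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters for one condition.

    Parameters
    ----------
    ell : float
        Mean microtubule length, µm.
    ell_u : float
        Decay length of the unbound active-nucleator gradient, µm.  Use
        ``math.inf`` for uniform activation; then ``beta0`` (gain per µm)
        must be supplied instead of being derived as alpha/ell_u.
    alpha : float
        Dimensionless branching amplitude — integrated gain of the gradient.
    rho0 : float
        Polymer density at the center, arbitrary fluorescence units.
    theta : float
        Microtubule turnover rate, 1/s (reciprocal of the mean lifetime).
    beta0 : float
        Uniform-mode gain per unit length, 1/µm.  Only meaningful when
        ``ell_u`` is infinite; otherwise derived as alpha/ell_u.
    """

    ell: float
    ell_u: float
    alpha: float
    rho0: float
    theta: float = 0.05
    beta0: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (self.ell > 0):
            raise ValueError(f"ell must be positive, got {self.ell}")
        if not (self.ell_u > 0):  # inf passes
            raise ValueError(f"ell_u must be positive (or inf), got {self.ell_u}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if not (self.rho0 > 0):
            raise ValueError(f"rho0 must be positive, got {self.rho0}")
        if not (self.theta > 0):
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.uniform_activation and math.isnan(self.beta0):
            raise ValueError("uniform activation (ell_u=inf) requires beta0")

    @property
    def uniform_activation(self) -> bool:
        return math.isinf(self.ell_u)

    def gain(self, x: np.ndarray | float) -> np.ndarray | float:
        """Branching gain per unit polymer length beta(x), 1/µm."""
        if self.uniform_activation:
            return self.beta0 * np.ones_like(np.asarray(x, dtype=float))
        return (self.alpha / self.ell_u) * np.exp(-np.asarray(x, dtype=float) / self.ell_u)

    @property
    def central_reproductive_number(self) -> float:
        """R(0) = beta(0) * ell — derived, read-only convention."""
        return float(self.gain(0.0)) * self.ell

    @property
    def mean_lifetime(self) -> float:
        """Mean microtubule lifetime 1/theta, s."""
        return 1.0 / self.theta


@dataclass
class RadialProfile:
    """A 1D profile versus distance from the structure center.

    ``x`` is a strictly increasing grid of distances (µm, may start at 0),
    ``values`` the profile in arbitrary units, ``kind`` one of density /
    nucleation / intensity, ``sd`` an optional per-point spread and ``n`` an
    optional per-point sample count.
    """

    x: np.ndarray
    values: np.ndarray
    kind: ProfileKind = "density"
    sd: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.values.shape:
            raise ValueError("x and values must be 1D arrays of equal length")
        if np.any(np.isnan(self.x)) or np.any(np.isnan(self.values)):
            raise ValueError("profile contains NaN")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.x < 0):
            raise ValueError("x must be non-negative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.x.shape:
                raise ValueError("sd must match x in length")


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if np.any(np.isnan(grid)):
        raise ValueError("grid contains NaN")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-negative and strictly increasing")
    return grid


def _log_density(params: ModelParams, x: np.ndarray) -> np.ndarray:
    """log rho(x) - log rho0; kept in log space for numerical headroom."""
    if params.uniform_activation:
        return (params.beta0 - 1.0 / params.ell) * x
    return params.alpha * (1.0 - np.exp(-x / params.ell_u)) - x / params.ell


def density_profile(params: ModelParams, grid: Sequence[float] | np.ndarray) -> RadialProfile:
    """Steady-state polymer density rho(x) on ``grid``.

    rho(0) = rho0; with alpha = 0 the profile is a pure exponential decay
    with mean ell.  Under uniform activation the profile grows exponentially
    when beta0 * ell > 1.
    """
    x = _check_grid(grid)
    values = params.rho0 * np.exp(_log_density(params, x))
    return RadialProfile(x=x, values=values, kind="density")


def nucleation_profile(
    params: ModelParams, grid: Sequence[float] | np.ndarray, amplitude: float = 1.0
) -> RadialProfile:
    """Nucleation profile nu(x) = amplitude * beta(x) * rho(x) on ``grid``.

    nu has units of events per unit area (the model's per-area convention);
    it is identically zero when alpha = 0.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    x = _check_grid(grid)
    rho = params.rho0 * np.exp(_log_density(params, x))
    values = amplitude * np.asarray(params.gain(x)) * rho
    return RadialProfile(x=x, values=values, kind="nucleation")


def rescale_profile(profile: RadialProfile, ell_from: float, ell_to: float) -> RadialProfile:
    """Parameter-free length rescaling between conditions.

    Multiplies pointwise by exp[(1/ell_from - 1/ell_to) * x]: the density of a
    condition with mean length ell_from maps onto the one with ell_to because
    the two profiles differ only in the x/ell term of the exponent.
    """
    if ell_from <= 0 or ell_to <= 0:
        raise ValueError("lengths must be positive")
    factor = np.exp((1.0 / ell_from - 1.0 / ell_to) * profile.x)
    return RadialProfile(
        x=profile.x.copy(), values=profile.values * factor, kind=profile.kind
    )


def reproductive_number(params: ModelParams, x: np.ndarray | float) -> np.ndarray | float:
    """Local reproductive number R(x) = beta(x) * ell.

    The mean number of new microtubules a microtubule at distance x creates
    over its lifetime.  R < 1 at the periphery bounds the structure.
    """
    r = np.asarray(params.gain(x)) * params.ell
    return float(r) if np.isscalar(x) or np.ndim(x) == 0 else r


def critical_radius(params: ModelParams) -> float:
    """Radius where R(x) = 1, i.e. x* = ell_u * ln(alpha * ell / ell_u).

    Coincides with the argmax of the density profile.  Returns 0.0 when
    R(0) <= 1 (the density is monotone decreasing) and inf under
    supercritical uniform activation.
    """
    if params.uniform_activation:
        return math.inf if params.beta0 * params.ell > 1 else 0.0
    r0 = params.central_reproductive_number
    if r0 <= 1:
        return 0.0
    return params.ell_u * math.log(r0)


def is_bounded(params: ModelParams) -> bool:
    """Whether steady-state growth is bounded.

    Any finite nucleator gradient is eventually subcritical; uniform
    activation is unbounded iff beta0 * ell > 1.
    """
    if params.uniform_activation:
        return params.beta0 * params.ell <= 1
    return True


@dataclass
class FitResult:
    """Result of fitting the density model to a measured radial profile."""

    params: ModelParams
    covariance: np.ndarray  # order (ell_u, alpha, rho0)
    residual_rms: float
    r_squared: float
    converged: bool
    degenerate: bool
    message: str = ""


# deterministic multi-start grid: decades of ell_u crossed with alpha levels
_ELL_U_STARTS = (5.0, 50.0)
_ALPHA_STARTS = (0.5, 2.0, 5.0)


def fit_density(
    data: RadialProfile,
    ell_fixed: float,
    xtol: float = 1e-10,
) -> FitResult:
    """Fit (ell_u, alpha, rho0) to a measured density profile, ell held fixed.

    Nonlinear least squares on linear intensities with positivity bounds,
    started from a small deterministic grid of initial points to avoid local
    minima.  ``ell_fixed`` comes from an independent measurement (laser
    ablation).  A profile with no curvature leaves alpha and ell_u confounded
    and is flagged degenerate.
    """
    if ell_fixed <= 0:
        raise ValueError("ell_fixed must be positive")
    if len(data.x) < 10:
        raise ValueError("need at least 10 grid points to fit")

    x, y = data.x, data.values
    span = float(y.max() - y.min())
    if span <= 1e-12 * max(abs(float(y.max())), 1.0):
        params = ModelParams(
            ell=ell_fixed, ell_u=1.0, alpha=0.0, rho0=max(float(y.mean()), 1e-12)
        )
        return FitResult(
            params=params,
            covariance=np.full((3, 3), np.nan),
            residual_rms=0.0,
            r_squared=0.0,
            converged=True,
            degenerate=True,
            message="flat profile: alpha and ell_u are confounded",
        )

    def resid(p: np.ndarray) -> np.ndarray:
        ell_u, alpha, rho0 = p
        m = ModelParams(ell=ell_fixed, ell_u=ell_u, alpha=alpha, rho0=rho0)
        return rho0 * np.exp(_log_density(m, x)) - y

    rho0_init = max(float(y[0]), 1e-6)
    lower = np.array([1e-3, 0.0, 1e-12])
    upper = np.array([1e4, 50.0, np.inf])

    best = None
    for lu0 in _ELL_U_STARTS:
        for a0 in _ALPHA_STARTS:
            try:
                sol = least_squares(
                    resid,
                    x0=np.array([lu0, a0, rho0_init]),
                    bounds=(lower, upper),
                    xtol=xtol,
                    ftol=xtol,
                    gtol=xtol,
                )
            except Exception:  # pragma: no cover - optimizer hard failure
                continue
            if best is None or sol.cost < best.cost:
                best = sol

    if best is None:
        raise RuntimeError("density fit failed from every starting point")

    ell_u, alpha, rho0 = best.x
    params = ModelParams(ell=ell_fixed, ell_u=float(ell_u), alpha=float(alpha), rho0=float(rho0))
    dof = max(len(x) - 3, 1)
    rms = float(np.sqrt(2 * best.cost / dof))
    ss_res = float(2 * best.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    # covariance from the Jacobian at the optimum
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * (ss_res / dof)
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
    return FitResult(
        params=params,
        covariance=cov,
        residual_rms=rms,
        r_squared=r2,
        converged=bool(best.success),
        degenerate=False,
        message=best.message,
    )


def predict_counterpart(fit: ModelParams, ell_other: float, grid: np.ndarray) -> RadialProfile:
    """Predict the density profile of the counterpart condition.

    Holds (ell_u, alpha, rho0) from the fit and swaps the mean length for the
    counterpart's independently measured value.  Algebraically identical to
    rescale_profile applied to the fitted curve.
    """
    other = replace(fit, ell=ell_other)
    return density_profile(other, grid)
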