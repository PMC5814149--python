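"""Ground-truth generators for the analysis pipeline.

Parametric monopoles with known minus-end statistics, rendering of filament
populations into fluorescence-like frames (uniform angles, straight segments,
Gaussian PSF, optional shot noise), cut-movie fixtures, and speckle-lifetime
tables.  All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .filaments import FilamentSet
from .model import ModelParams, _log_density as _model_log_density, nucleation_profile
from .lifetimes import LifetimeSample, simulate_speckle_lifetimes

__all__ = [
    "Optics",
    "sample_monopole",
    "render",
    "render_segments",
    "make_cut_fixture",
    "make_speckle_table",
]


@dataclass(frozen=True)
class Optics:
    """Rendering parameters emulating spinning-disk imaging of monopoles.

    Defaults correspond to a typical 60x/1.2 NA configuration (0.22 µm
    pixels, 0.25 µm PSF sigma); they are rendering conventions, not
    measurements.
    """

    pixel_size: float = 0.22        # µm
    psf_sigma: float = 0.25         # µm
    intensity_per_um: float = 100.0  # integrated a.u. per µm of polymer
    background: float = 10.0        # a.u. per pixel
    noise: str = "none"             # {"none", "poisson"}
    noise_scale: float = 1.0        # photons per a.u. for Poisson noise
    frame_interval: float = 0.5     # s
    size: int = 512                 # image side, px

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.psf_sigma, self.intensity_per_um,
               self.frame_interval, self.noise_scale) <= 0:
            raise ValueError("optics parameters must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise mode {self.noise!r}")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.size - 1) / 2.0, (self.size - 1) / 2.0)

    @property
    def field_radius(self) -> float:
        """Largest radius fully inside the field, µm."""
        return (self.size / 2.0 - 1) * self.pixel_size


def sample_monopole(
    params: ModelParams,
    n_filaments: int,
    seed: int,
    x_max: float | None = None,
    include_center_seeds: bool = False,
) -> FilamentSet:
    """Draw a monopole with minus ends from nu(x) and exponential lengths.

    Minus-end positions are sampled from the normalized model nucleation
    profile by inverse-CDF on a fine grid; lengths are i.i.d. exponential
    with mean ``params.ell``.  Each filament also receives a uniform angle so
    repeated renders are consistent.

    With ``include_center_seeds`` a chromatin-seeded subpopulation with minus
    ends at the origin is mixed in, weighted so the expected polymer coverage
    reproduces the model density rho(x) including its boundary value
    rho(0) = rho0 (branch-nucleated filaments alone have zero coverage at the
    origin).  Leave it off when the minus-end statistics themselves are the
    object under study.
    """
    if n_filaments < 0:
        raise ValueError("n_filaments must be non-negative")
    rng = np.random.default_rng(seed)
    if n_filaments == 0:
        z = np.empty(0)
        return FilamentSet(minus_pos=z, length=z.copy(), angles=z.copy())

    if x_max is None:
        x_max = 6.0 * max(params.ell, params.ell_u if np.isfinite(params.ell_u) else 0.0)
    grid = np.linspace(0.0, x_max, 20001)
    nu = nucleation_profile(params, grid).values
    total = np.trapezoid(nu, grid)
    if not (total > 0) or not np.isfinite(total):
        raise ValueError("nucleation profile is not normalizable on the domain")
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (nu[1:] + nu[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    # drop duplicate CDF values so interp stays monotone
    keep = np.concatenate([[True], np.diff(cdf) > 0])

    n_seed = 0
    if include_center_seeds:
        # coverage rho(x) solves rho' = nu/A - rho/ell with rho(0) = rho0; the
        # branch population contributes rho - rho0*exp(-x/ell), so seeds at the
        # origin must carry weight rho0 against the integrated branching gain
        gain = np.asarray(params.gain(grid)) * (
            params.rho0 * np.exp(_model_log_density(params, grid))
        )
        seed_fraction = params.rho0 / (params.rho0 + np.trapezoid(gain, grid))
        n_seed = rng.binomial(n_filaments, seed_fraction)
    minus = np.concatenate(
        [
            np.zeros(n_seed),
            np.interp(rng.uniform(0, 1, n_filaments - n_seed), cdf[keep], grid[keep]),
        ]
    )
    lengths = rng.exponential(params.ell, n_filaments)
    angles = rng.uniform(0.0, 2.0 * np.pi, n_filaments)
    return FilamentSet(minus_pos=minus, length=lengths, angles=angles)


def render_segments(
    r_in: np.ndarray,
    r_out: np.ndarray,
    angles: np.ndarray,
    optics: Optics,
) -> np.ndarray:
    """Noise-free, background-free frame of radial segments [r_in, r_out].

    Each segment deposits intensity_per_um per µm of length along its ray and
    is blurred with the Gaussian PSF.  Total integrated intensity equals
    intensity_per_um times total segment length for segments inside the field.
    """
    r_in = np.asarray(r_in, float)
    r_out = np.asarray(r_out, float)
    angles = np.asarray(angles, float)
    img = np.zeros((optics.size, optics.size))
    seg_len = np.maximum(r_out - r_in, 0.0)
    total = seg_len.sum()
    if total <= 0:
        return img
    ds = optics.pixel_size / 3.0
    n_pts = np.maximum(np.ceil(seg_len / ds).astype(int), 1)
    # per-segment sample points at midpoints of equal sub-intervals
    reps = np.repeat(np.arange(len(r_in)), n_pts)
    # fractional position along each segment
    offs = (np.concatenate([np.arange(k) for k in n_pts]) + 0.5) / np.repeat(n_pts, n_pts)
    radii = r_in[reps] + offs * seg_len[reps]
    w = np.repeat(seg_len / n_pts, n_pts) * optics.intensity_per_um
    cr, cc = optics.center
    rows = np.round(cr + radii * np.sin(angles[reps]) / optics.pixel_size).astype(int)
    cols = np.round(cc + radii * np.cos(angles[reps]) / optics.pixel_size).astype(int)
    inside = (rows >= 0) & (rows < optics.size) & (cols >= 0) & (cols < optics.size)
    np.add.at(img, (rows[inside], cols[inside]), w[inside])
    gaussian_filter(img, optics.psf_sigma / optics.pixel_size, mode="constant",
                    output=img, truncate=6.0)
    return img


def _apply_noise(frame: np.ndarray, optics: Optics, rng: np.random.Generator) -> np.ndarray:
    if optics.noise == "poisson":
        return rng.poisson(np.maximum(frame, 0.0) * optics.noise_scale) / optics.noise_scale
    return frame


def render(
    filaments: FilamentSet,
    optics: Optics,
    seed: int = 0,
) -> np.ndarray:
    """Render a filament population into one fluorescence frame.

    Filaments without pre-assigned angles get uniform random angles (drawn
    from ``seed``).  Background is added after PSF blurring; Poisson noise is
    applied if configured.  Filaments extending past the field are clipped.
    """
    rng = np.random.default_rng(seed)
    angles = filaments.angles
    if angles is None:
        angles = rng.uniform(0.0, 2.0 * np.pi, len(filaments))
    if len(filaments) and float(filaments.plus_pos.max(initial=0.0)) > optics.field_radius:
        import warnings

        warnings.warn("filaments extend beyond the field of view; clipped", stacklevel=2)
    frame = render_segments(filaments.minus_pos, filaments.plus_pos, angles, optics)
    frame += optics.background
    return _apply_noise(frame, optics, rng)


def make_cut_fixture(
    params: ModelParams,
    n_filaments: int,
    r_cut: float,
    v_d: float,
    optics: Optics,
    seed: int,
    t_pre: float = 1.0,
    t_post: float | None = None,
    x_max: float | None = None,
):
    """Synthetic circular-cut movie with its ground-truth filament set.

    Samples a monopole, severs it at ``r_cut`` and renders the
    depolymerization wave (speed ``v_d``, µm/s).  Returns
    (ImageStack, FilamentSet); reproducible bit-for-bit per seed.
    """
    from .ablation import CutSpec, simulate_cut  # lazy: ablation renders via this module

    filaments = sample_monopole(params, n_filaments, seed, x_max=x_max)
    cut = CutSpec(geometry="circle", radius=r_cut)
    stack = simulate_cut(
        filaments, cut, v_d, optics, seed=seed, t_pre=t_pre, t_post=t_post
    )
    return stack, filaments


def make_speckle_table(
    params: ModelParams,
    v_d: float,
    D: float,
    n: int,
    movie_length: float,
    seed: int,
) -> tuple[pd.DataFrame, LifetimeSample]:
    """Speckle lifetime table with movie-length censoring.

    Lifetimes are first-passage times of the shrinking end (drift ``v_d``,
    diffusion ``D``) to a speckle a mean length ``params.ell`` away.  Each
    speckle appears at a uniform time within the movie; tracks still alive at
    the end are censored, matching the rule that only speckles that both
    appear and disappear within the movie are analyzed.
    """
    sample = simulate_speckle_lifetimes(
        L0=params.ell, v=v_d, D=D, n=n, seed=seed, t_max=10 * movie_length
    )
    rng = np.random.default_rng(seed + 1)
    t_start = rng.uniform(0.0, movie_length, n)
    t_end = t_start + sample.durations
    censored = sample.censored | (t_end > movie_length)
    df = pd.DataFrame(
        {
            "track_id": np.arange(n),
            "t_start_s": t_start,
            "t_end_s": np.minimum(t_end, movie_length),
            "censored": censored,
        }
    )
    return df, LifetimeSample(durations=sample.durations, censored=censored)
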