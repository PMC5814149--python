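# monoaster

Quantitative toolkit for **autocatalytic, microtubule-stimulated nucleation
in monopolar spindles** (cell-free *Xenopus laevis* egg-extract systems).
It is aimed at people who quantify spindle-scale microtubule organization:
it bundles the steady-state model of branching nucleation under a nucleator
gradient, a stochastic simulator of the nucleator–filament system, the
laser-ablation depolymerization-wave analysis that measures nucleation
profiles from movies, first-passage fitting of speckle lifetimes, and
synthetic-data generators with exact ground truth for validating all of the
above.

## The model

A monopole is a radially symmetric aster: minus ends point to the center,
plus ends grow outward at speed *v_p*, and whole-filament turnover at rate Θ
gives exponentially distributed lengths with mean ℓ = *v_p*/Θ. New
microtubules are nucleated **on** existing microtubules by nucleators that
are activated at the chromatin, diffuse (coefficient *D*), and inactivate at
rate *k_i*; the resulting gradient of active nucleators decays over
ℓ_u = √(*D*/*k_i*). With branching gain per unit polymer length
β(x) = (α/ℓ_u)·e^(−x/ℓ_u), the steady-state polymer density is

    ρ(x) = ρ(0) · exp[ α (1 − e^(−x/ℓu)) − x/ℓ ],

the nucleation profile is ν(x) ∝ β(x)·ρ(x), and the local reproductive
number R(x) = β(x)·ℓ (daughters per microtubule) controls everything:
R(0) > 1 gives an initially amplifying structure whose density peaks exactly
where R(x) = 1, while R < 1 everywhere gives a monotonically decaying one.
Because β(x) does not depend on microtubule dynamics, two conditions that
differ only in ℓ are related by the parameter-free rescaling
ρ_C = ρ_M · exp[(1/ℓ_M − 1/ℓ_C) x] — the package treats this identity, and
its closed-loop measurement from synthetic movies, as first-class tests.

The ablation analysis implements the measurement side: subtracting movie
frames δt apart turns the synchronized depolymerization after a laser cut
(front speed *v_d*) into a travelling peak; Gaussian fits of the angularly
integrated differentials give the front position (hence *v_d*) and the area
Ã(t, r), whose decay with distance from the cut counts the severed minus
ends; dividing by 2πr yields the per-area nucleation profile, and the decay
of the minus-end density with cut radius yields the length distribution.
Speckle lifetimes are fitted with the first-passage density
𝒫(t) ∝ t^(−3/2) e^(−t/τ), where τ/4 is the mean lifetime and Θ its inverse.

## Worked example

```python
import numpy as np
from monoaster import ablation, model, synthdata

# fit the long-microtubule (MCAK-inhibited) density profile, ell fixed from ablation
params = model.ModelParams(ell=24.0, ell_u=24.9, alpha=2.38, rho0=4058.0, theta=0.016)
grid = np.linspace(0.0, 80.0, 100)
fit = model.fit_density(model.density_profile(params, grid), ell_fixed=24.0)
print(f"fitted ell_u = {fit.params.ell_u:.1f} um, alpha = {fit.params.alpha:.2f}")
print(f"R(0) = {model.reproductive_number(fit.params, 0.0):.2f}, "
      f"density peak at {model.critical_radius(fit.params):.1f} um")

# forward-generate a cut movie and run the ablation pipeline on it
optics = synthdata.Optics(pixel_size=0.35, size=420, noise="poisson")
ctrl = model.ModelParams(ell=8.0, ell_u=24.9, alpha=2.38, rho0=4058.0)
stack, truth = synthdata.make_cut_fixture(ctrl, 10_000, r_cut=15.0,
                                          v_d=33.5 / 60.0, optics=optics,
                                          seed=1, x_max=58.0)
cut = ablation.CutSpec(geometry="circle", radius=15.0, delta_t=2.0)
track, vel, est = ablation.analyze_cut_movie(stack, cut)
print(f"depolymerization velocity = {vel.v_um_per_min:.1f} um/min")
print(f"area decay length = {est.decay_length:.1f} um; "
      f"nucleation value at r = {est.per_area_value:.1f} a.u.")
```

prints

```
fitted ell_u = 24.9 um, alpha = 2.38
R(0) = 2.29, density peak at 20.7 um
depolymerization velocity = 33.5 um/min
area decay length = 6.6 um; nucleation value at r = 478.0 a.u.
```

The fitted R(0) = 2.29 means a microtubule at the center of the
MCAK-inhibited monopole spawns ~2.3 daughters, so the density grows out to
20.7 µm before the nucleator gradient makes branching subcritical; the
recovered wave speed matches the 33.5 µm/min used to render the movie, and
the 6.6 µm area-decay length reflects how the severed population's minus
ends are distributed below the cut.

A `monoaster` command-line tool exposes the same operations on files
(`simulate`, `make-fixture`, `ablate-analyze`, `fit-model`, `rescale`,
`lifetimes-fit`, `profile-predict`); every run writes a JSON manifest with
input hashes and the seed.

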