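# Methods

## Steady-state model

The model treats a monopole as an effective 1D radial system: every
microtubule points outward, minus ends are immobile (no motor transport),
and lengths are exponential with mean ℓ because whole-filament turnover is a
Poisson process at rate Θ while plus ends grow at constant v_p (ℓ = v_p/Θ).
Nucleators are activated at the chromatin, diffuse with coefficient D and
inactivate at rate k_i, giving an active-nucleator gradient with decay
length ℓ_u = √(D/k_i). Branching gain per unit polymer length is
β(x) = (α/ℓ_u) e^(−x/ℓ_u); α is the **integrated** gain ∫β dx, which makes
it dimensionless and condition-independent. The density solves
dρ/dx = β ρ − ρ/ℓ with ρ(0) = ρ0, i.e.

ρ(x) = ρ0 exp[α(1 − e^(−x/ℓu)) − x/ℓ],  ν(x) = A β(x) ρ(x).

Consequences used as tests: the two-condition rescaling
ρ_C = ρ_M exp[(1/ℓ_M − 1/ℓ_C)x] is exact; the density peak sits at
x* = ℓ_u ln(αℓ/ℓ_u), which is also the root of the reproductive number
R(x) = β(x)ℓ = 1; finite ℓ_u always yields a bounded structure; a uniform
gain β0 (the ℓ_u → ∞ limit at fixed β0 = α/ℓ_u) grows without bound iff
β0ℓ > 1. The convention R(0) = αℓ/ℓ_u is exposed read-only; α itself is the
fitted quantity.

ρ(0) is in camera units and treated as an arbitrary amplitude. Θ and the
mean lifetime are reciprocal by definition.

**Fitting.** `fit_density` estimates (ℓ_u, α, ρ0) with ℓ fixed from an
independent measurement (ablation), by bounded nonlinear least squares on
linear intensities, multi-started from a deterministic 2×3 grid over decades
of ℓ_u and α (tolerances 1e−10). A flat profile leaves α and ℓ_u confounded
and returns a degenerate flag instead of numbers that look meaningful.

## Stochastic simulator

`simulate` is a fixed-step tau-leaping scheme (not exact Gillespie): binding
rates are position-dependent (k_on × filament length within the capture
radius), and fixed steps keep the coupling to continuous filament growth
simple. Constant per-particle rates are guarded by dt·(total rate) < 0.1;
the position-dependent binding probability is computed as 1 − exp(−rate·dt)
so it remains a probability even in dense regions. Accuracy is verified
against Poisson-thinning, pure-exponential-decay and diffusion–decay
oracles in the test suite. Local filament length is accumulated on a grid
of capture-radius-sized bins via a difference array, and binding hosts are
drawn uniformly among filaments overlapping the capture neighborhood.

Nucleators follow activation (in the chromatin zone, or everywhere in
uniform-activation mode) → diffusion (reflecting boundaries) → inactivation
→ binding/unbinding → nucleation. A nucleation event creates a zero-length
filament at the nucleator's position with outward polarity; the nucleator
stays bound (it is not consumed — unbinding and inactivation are separate
processes, and nucleator identity is conserved through every transition).
Turnover is either whole-filament removal at Θ (clean mapping to the model;
default for steady-state studies) or catastrophe-then-shrink at v_d
(realistic for ablation/lifetime fixtures). Obstacles are intervals that
block plus-end extension and nucleation inside them but not diffusion; a
zero-width interval blocks nothing. The obstacle summary statistic is the
unweighted mean of the pointwise-normalized density over a window behind
the obstacle (profiles normalized to the obstacle-free reference, then
averaged), with distance rescaled by the obstacle radius.

**Rates.** The measured microtubule and nucleator scales fix v_p = 0.4 µm/s (24 µm/min range,
chosen so v_p/Θ = 8 µm at Θ = 0.05 s⁻¹), D = 10 µm²/s and
k_i = 0.016 s⁻¹ (ℓ_u = 25 µm). Binding/unbinding/nucleation rates are not
published; the defaults (k_on = 1.6·10⁻⁵ µm⁻¹s⁻¹, k_off = k_nuc = 0.5 s⁻¹,
k_act = 200 s⁻¹, k_seed = 20 s⁻¹) were chosen once so that binding is weak
(trapping shifts the nucleator gradient by < 1%), the emergent branching
amplitude is subcritical at ℓ = 8 µm, and steady state holds ~10²–10³
filaments in a 100 µm domain. α is never computed from the microscopic
rates by formula; it is measured by fitting the simulated density, exactly
as for data.

## Ablation analysis

`differential_intensity` subtracts raw frames δt apart (default 2 s) from
the cut onward, keeping signed values (clipping is for visualization only).
`angular_integrate` sums the differentials in 0.5 µm radial bins around the
intensity-weighted centroid (line cuts integrate along the cut direction
instead, and a linear cut in a bipolar geometry is analyzed as two waves,
one per side). `fit_wave` fits one Gaussian per differential frame,
initialized at the running maximum. Because the physical peak is a boxcar
of width v_d·δt convolved with the PSF — flat-topped, not Gaussian — the
profile is first convolved with a 1 µm Gaussian: convolution conserves the
area and brings the shape close enough to Gaussian that the fitted area is
unbiased. Frames are rejected when the peak falls below 2% of the track
maximum or 5× the local noise, or when the center comes within a peak-width
of the origin (there the ring wave folds onto itself and the angular
integral stops resolving it); large fit residuals flag merged/distorted
peaks without aborting the track.

The depolymerization velocity is the |slope| of center vs time;
the distance-from-cut coordinate uses this fitted velocity (d = v_d t), not
per-frame centers, to suppress jitter. The area decay Ã(d) is fitted with a
weighted exponential (Poisson-like weights with a 5% floor); the normalized
slope at the cut × the angularly integrated pre-cut fluorescence gives the
minus-end linear density at the cut, and ÷2πr the per-area nucleation
value. Per-depth minus-end **counts** use the exact observation identity
Ã/scale = ∫ N(<u) du over the known subtraction window: the window operator
is inverted by nonnegative least squares on a 0.5 µm sub-grid, which
removes both the flat-top bias and the interpolation error of naive
differencing. The method resolves minus ends only up to v_d·δt below the
cut; comparisons stop there.

The length distribution comes from the decay of the minus-end count in a
fixed depth band with cut radius r (∝ e^(−r/ℓ) for exponential lengths,
fitted across ≥4 radii); a relative rms residual above 20% flags a
non-exponential ground truth, and a radii span below 2ℓ triggers a warning.

## Lifetimes

`fit_lifetime` is a maximum-likelihood fit of the truncated density
c·t^(−3/2)e^(−t/τ) on [t_min, ∞), with the normalization in closed form via
the upper incomplete gamma (Γ(−1/2,·) expressed through erfc). MLE avoids
the binning choices of histogram fits; a histogram-free KS statistic against
the fitted form flags model mismatch at 1%. t_min defaults to two frame
intervals; its choice is not printed anywhere authoritative, so the fit
reports τ at alternative truncations as a sensitivity diagnostic. The rule
mean lifetime = τ/4 is applied as a definition, not re-derived. Only
uncensored tracks (appear **and** disappear within the movie) enter the fit.
The first-passage simulator is Euler–Maruyama with a Brownian-bridge
within-step absorption correction, which removes the O(√dt) bias of
discrete-time absorption; with D = 0 it degenerates to the exact L0/v.

## Synthetic data

`sample_monopole` draws minus ends from the normalized ν(x) by inverse CDF
on a 20001-point grid and lengths i.i.d. exponential; angles are uniform
and fixed per filament so repeated renders are consistent. Branch-nucleated
filaments alone have zero coverage at the origin, while ρ(0) = ρ0 belongs
to the chromatin-seeded population; `include_center_seeds` mixes in that
population with the weight that makes the expected coverage equal ρ(x)
exactly. Rendering draws straight segments (no curvature) at
intensity-per-µm resolution of a third of a pixel, convolves with a
Gaussian PSF (defaults 0.22 µm pixels, 0.25 µm PSF — typical 60×/1.2 NA
values, not measurements) and adds background and optional Poisson noise.
Cut movies render the static content (unsevered filaments + distal
fragments) once and only the shrinking proximal fragments per frame.

What the generators deliberately do **not** emulate: photobleaching, stage
drift, 3D sectioning, out-of-focus light, filament curvature, motor-driven
poleward flux, and the mixed polarity of real bipolar spindles. Passing the
closed-loop tests therefore shows the estimators are correct for an ideal
radially organized structure imaged with shot noise — not that they are
robust to every real-microscope artifact.

## Problem sizes of the reproduction studies

The studies in `monoaster.validation` (run by `scripts/acceptance.py` and
the recovery tests) use: 100 random parameter sets for the rescaling
identity; one 10⁴-filament monopole with 12 circular cuts (10–28 µm) for
minus-end recovery; 50 noisy profiles (5% multiplicative noise, 100 points)
for parameter recovery; three rendered shot-noise movies at 20/33.5/46
µm/min for velocity; 6–7 cuts per condition for the 8 vs 24 µm length
contrast; 5000 lifetimes × 3 τ values × 5 replicates; 20 simulator seeds
for the gradient/steady-state comparison, 10 for the supercritical growth
slope and 6 paired runs per nucleation mode for the obstacle shadow. These
sizes give each statistic comfortable resolution relative to its recovery
band while keeping a full reproduction run in the minutes range on one
core.

## Known limitations

- The 1D obstacle is absolute (filaments cannot grow around it), so the
  independent-nucleation shadow recovers over ~ℓ rather than the faster
  2D recovery around a finite obstacle.
- The minus-end deconvolution needs the absolute intensity scale, which is
  known for synthetic data but arbitrary for real movies; there the profile
  is meaningful up to one global amplitude, as in the per-cut slope method.
- `fit_density` on profiles without curvature cannot separate α from ℓ_u
  (flagged, not guessed).
- The simulator's mean-field correspondence assumes weak nucleator binding;
  strong-trapping regimes would renormalize the gradient length.
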