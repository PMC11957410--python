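# Methods

## Wave-field model

A configuration of a distorted lamellar phase is represented by the
complex field `S(r) = sqrt(2/n_waves) Σₙ exp[i(kₙ·r + φₙ)]` on a periodic
cubic box.  The wave-vector ensemble factorizes:

* **polar cosine** `u = cos θ` follows the Fisher density
  `P(u) ∝ exp(Γu)` about the +z layer normal, sampled by the closed-form
  inverse CDF `u = 1 + ln(ξ + (1-ξ)e^{-2Γ})/Γ`.  The normalization
  `c = Γ/(2 sinh Γ)` is evaluated in an overflow-safe form.  Γ is the
  orientational (smectic) order parameter: Γ→0 is an isotropic sponge,
  Γ ~ 10²–10³ a well-aligned stack.  The density is taken on the full
  sphere; `k` and `−k` generate the same cosine modulation up to phase,
  so a hemispherical convention would be equivalent.
* **azimuth** uniform on `[0, 2π)`.
* **magnitude** `|k| ~ N(k₀, σₖk₀)` truncated to positive values by
  rejection (the acceptance rate is recorded on the sampled wave set;
  at the largest supported σₖ = 0.5 about 2% of draws are rejected).
  σₖ is dimensionless (a fraction of `k₀`); `d = 2π/k₀` is the mean
  inter-plane spacing.

The `sqrt(2/n_waves)` normalization makes `Re S` a unit-variance Gaussian
field in the ensemble sense, which fixes the meaning of the clipping
level.  In a *single* box at high Γ and small σₖ the correlation volume
is comparable to the box, so the sample variance of one realization
fluctuates strongly (standard deviation ≈ 0.3 at Γ = 128 in an 8d box);
unit variance is asserted as an ensemble mean.

Defaults: `n_waves = 1000` (spectra are converged relative to 500 and
2000 at the reported tolerances), box edge `8d`, voxel centers at
`(i + 1/2)·spacing`.  Production grids here are 64³–128³; the model is
grid-agnostic and larger boxes only refine the reciprocal-space binning.

Two generalizations share the sampled wave set: partial **spherical
waves** `exp[i(kₙ|r−cₙ| + φₙ)]` with origins `cₙ` normal-scattered about
the box center (multilamellar "onion" morphologies; constant unit
amplitude by default, since a 1/r decay concentrates all contrast at the
origins and destroys the concentric morphology — a config switch restores
it), and a **time-dependent** field in which wave `n` advances its phase
at rate `ωₙ ~ N(ω₀, σ_ω)` (a normal density of states; σ_ω = 0 is a
global phase rotation that moves no defect).

## Clipping convention

The scattering-length-density field is the indicator of
`Re S(r) > β` with `β` the empirical upper `α`-quantile of the realized
field, making the membrane volume fraction exactly `α` regardless of
finite-`n_waves` variance fluctuations (for an ideal unit-variance
Gaussian field this is `β = probit(1−α)`, the value the
`clip_threshold` helper reports).

The one-sided clip is a deliberate design decision.  A symmetric band
`|Re S| < β` is an even function of the Gaussian field: its Hermite
expansion contains only even orders, the clipped correlation function
becomes a function of `C(r)²`, and the fundamental lamellar reflection at
`Qd/2π = 1` vanishes identically — contradicting the observed three-order
peak structure.  The one-sided clip keeps all orders, and its
second-order Hermite coefficient `β·φ(β)` crosses zero exactly at
`α = 1/2`: the even-numbered correlation peaks fade as the membrane and
solvent layers approach equal thickness, which is the measured
phenomenology.  The band convention remains available
(`clip_to_sld(..., mode="band")`).

`α = 0` is geometrically degenerate (zero membrane volume); the level is
floored at one voxel-equivalent sheet per period, `α_min = spacing/d`
(1/16 at 128³ in an 8d box), so that nominal-`α = 0` reference curves
remain computable.  This floor is a resolution limit: values of `α`
below it are not representable on the grid.

## Scattering

The coherent intensity is `|FFT(ρ − ⟨ρ⟩)|²` (mean subtraction removes
the forward-scattering spike); Parseval's identity is asserted in the
tests.  Radial averaging bins `|Q|d/2π` with bin centers at integer
multiples of one reciprocal-lattice spacing (`d/box_edge`, 1/8 for the
standard box), so the lamellar orders land on bin centers; the DC voxel
is excluded, empty bins are absent rather than zero-filled, and the
binning is an exact partition of the remaining voxels (rebinning
conserves count-weighted totals to machine precision).  Ensemble spectra
average 8 independent realizations by default (seeds derived from the
master seed by unit stride) and carry per-bin standard errors.

The model produces a genuine upturn at `Qd/2π ≲ 0.3`; analyses that
target the correlation peaks therefore operate in a window (default
`[0.5, 3.5]`), which is also where measured curves are free of the
grain-orientation effects outside this model.

## Surrogate

The spline network is exactly the two-stage architecture described in
the package overview: stage 1 `[3, 7, 3]` on the normalized triple
`(σₖ, ln Γ, α)`, stage 2 `[4, 9, 1, 1]` on the three latents plus
normalized `q = Qd/2π`, predicting `log₁₀ Î`; the trailing 1→1 layer is
a learnable output warp.  Each edge carries a clamped cubic B-spline on
a uniform knot grid plus a `silu` residual with learnable weight
(inputs outside the domain clamp to the boundary; deeper layers use a
`[−3, 3]` domain for the latents).  Knot grids: 8 intervals per edge in
stage 1 (the parameter dependence is smooth) and 24 in stage 2 (the `q`
dependence contains peaks a few bin-widths wide; the knot spacing must
resolve them).  Γ enters as `ln Γ` and intensity as `log₁₀` so the
decades-spanning curves train stably.

**Library.** Latin-hypercube design over `σₖ ∈ [0.01, 0.5]`,
`ln Γ ∈ [0, 5]`, `α ∈ [0, 0.5]`; each spectrum an ensemble mean on a 64³
box restricted to `q ∈ [0.25, 4]`, normalized by the library's median
intensity, with per-bin Monte-Carlo standard errors stored.  The
reference library here is 200 spectra (the production-scale run of
thousands is supported but not part of the default test suite).

**Training.** Deterministic full-batch L-BFGS with analytic gradients on
the (inverse-variance-weighted, floored at 0.02 dex) mean squared error
in `log₁₀ Î`, tracking an 80/10/10 train/validation/test split and
returning the best-validation snapshot; first-order Adam is retained as
an option but converges far more slowly on this small, smooth problem.
At the 200-spectrum scale a single training reaches validation RMSE
≈ 0.04 dex; the working surrogate for inversion is a two-seed ensemble
(mean `log₁₀ Î` of independently initialized trainings), which
suppresses the seed-dependent component of the approximation error
(held-out median |ratio − 1| ≈ 0.036).

**Known limitation.** Stage 1 maps a 3-D parameter space through a 3-D
latent space; at weak training scales this map can fold, producing
distinct parameter triples with numerically identical predicted curves
(an exact inversion ambiguity, demonstrated in `examples/03`).
Production-scale training removes the folds inside the identifiable
domain below.

## Inversion

`I_model(Q) = A·Î(Qd/2π; σₖ, Γ, α) + B` is fitted to a reduced curve by
bounded trust-region least squares over `(σₖ, ln Γ, α, d, A, B)`;
weights are `1/σ` when uncertainties are present, unweighted otherwise.
The initial `d` is `2π/Q₁*` from the first correlation peak of the
lightly smoothed curve (lowest-`q` peak among those within half the
maximum prominence); a curve with no interior maximum raises an error
asking for `d` explicitly.  The fit window (`Qd/2π ∈ [0.5, 3.5]` by
default, fixed by the initial `d`) excludes the low-`Q` region, where
the model's upturn and real-world grain orientation disagree.
Twenty-seven deterministic starts at the quartiles of the parameter box
are screened by initial cost and the best five refined; 1σ errors come
from the quadratic approximation at the optimum.

**Identifiability.**  At the 64³ desk scale the data constrain the
parameters in a bounded domain: σₖ below ≈ 0.06 leaves the first peak
narrower than one reciprocal bin (width saturates), σₖ above ≈ 0.15
smears the higher orders that carry the Γ signal; the spectrum stops
responding to Γ once alignment saturates (`ln Γ ≳ 3.5`); α below the
clip floor (1/8 at 64³) is not representable and near 0.5 the
even-order signal that encodes it vanishes.  The parameter-recovery
study in the test suite therefore draws its ground-truth triples from
`σₖ ∈ [0.06, 0.15]`, `ln Γ ∈ [1.5, 3.5]`, `α ∈ [0.15, 0.38]` with `d`
supplied (as it would be from the first-order peak), 5% relative noise,
and recovers them within `|Δσₖ| ≤ 0.03`, `|Δln Γ| ≤ 0.5`,
`|Δα| ≤ 0.05`.  Outside this domain the same tolerances are not
attainable from a single noisy curve — not because of the optimizer but
because χ² is genuinely flat there (verified by comparing χ² at truth
and at the fitted optimum).  Residual misses in repeated draws are
`ln Γ` biases of 0.5–0.8 traceable to the 200-spectrum surrogate's
approximation error, reproducible across simulation seeds and ensemble
sizes.

## Defect analysis

The de Gennes counting rule gives the permissible singularity dimension
`δ = d_space − n_components`; for the complex wave field in three
dimensions, `δ = 3 − 2 = 1`: line defects.

The phase `Ψ = atan2(Im S, Re S)` (range `(−π, π]`; exact zeros of `S`
get phase 0 and are flagged) is scanned in 2-D slices along all three
axes.  For each pixel the eight wrapped phase differences around the
counterclockwise 8-neighbor loop (start at offset (−1,−1); the start is
provably irrelevant) are summed; wrapping maps to `(−π, π]` with the
boundary assigned to +π (the tie-break matters in degenerate symmetric
cases).  The sum telescopes to an exact multiple of 2π — quantization
holds to ~10⁻⁶ rad as a floating-point identity and is asserted on every
winding map.  A straight singular line perpendicular to one slice family
is always encircled by loops of another, so the three-orientation union
never misses an axis-aligned line.  For periodic (plane-wave) fields the
loops wrap across the box boundary; otherwise boundary pixels remain
unlabeled.

The union mask (typically 2×2 voxels thick around each line) is thinned
by a sequential connectivity-preserving pass written for this geometry:
a voxel is removed only if its present 26-neighbors remain one connected
set without it and do not form a mutual-adjacency clique (the clique
condition preserves line tips).  Standard 3-D skeletonization (Lee's
method) was found to delete 2×2-voxel bars outright, which is exactly
the shape these masks take.  The thinned voxels' 26-neighbor graph is
walked depth-first from terminals (degree ≠ 2), splitting at junctions;
closed loops are walked from an arbitrary start; paths shorter than
`min_length = 3` voxels are dropped.  Each line records its dominant
signed winding, its end-to-end direction (mean consistent segment
direction for closed loops), and its class: screw if
`|cos Φ| ≥ √2/2` (within 45° of the layer normal), else edge.

Tracking links lines of consecutive frames greedily by symmetrized mean
closest-point distance, strictly below `match_radius` (default 3
voxels), so a zero radius yields singleton trajectories; unmatched lines
open or close trajectories.

## Synthetic measurements

The generator emulates a reduced SANS curve of a distorted lamellar
phase: `I(Q) = A·Î(Qd/2π) + B` on a log-spaced absolute-`Q` grid (150
points across `Qd/2π ∈ [0.3, 3.9]`, matching a `Q`-range of roughly
0.05–0.6 Å⁻¹ at `d = 40 Å`), multiplicative Gaussian noise at a stated
relative level (default 5%), and an uncertainty column equal to
noise × clean intensity.  The template is either the surrogate or a
leveled-wave ensemble simulation.  What it does *not* emulate: instrument
resolution smearing, incoherent background structure, grain-orientation
effects at low `Q`, and absolute-intensity calibration physics — so
passing recovery tests demonstrate the statistical machinery, not
robustness to those real-data systematics.

## Problem sizes and determinism

Default test-scale runs use 64³ grids (128³ for the reference peak
structure), ensembles of 8, `n_waves = 1000`, and the 200-spectrum
surrogate library; these are the package's reference desk-scale
conditions and all reported tolerances refer to them.  Every stochastic
component is a pure function of a master seed: realization seeds advance
by unit stride, the library design and split use fixed large offsets
(so changing the ensemble size never perturbs a design), and training is
deterministic given its seed.  Identical configuration and seed
reproduce fields bit-for-bit and reports byte-for-byte.
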