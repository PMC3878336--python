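# Methods

## Problem and model

Confocal stacks of thick specimens lose signal with depth: excitation and
emission photons are absorbed or scattered out of the detection pinhole's
path.  Both effects are multiplicative per unit length, so the surviving
fraction along a ray follows Beer-Lambert attenuation with a spatially
variant coefficient field `alpha(x)` (per voxel-length, >= 0).  A single
recording cannot separate true fluorophore concentration from attenuation;
recording the same (registered) sample from two opposite sides provides a
second measurement per voxel and makes the joint estimation well-posed
wherever fluorophores exist.

The measurement model for view `i` (1 = top, lens at `z = 0`; 2 = bottom,
lens at `z = nz-1`) is

    F_i(x) = beta_i * I(x) * C_i(x)^2
    C_i(x) = sum_r  s_i(r) * exp( - integral of alpha along the ray from x in direction r )

with `C_i` the transmission averaged over the objective's cone of rays
(`s_i` is the normalized cone quadrature, so `C_i = 1` when `alpha = 0`),
squared because excitation and emission traverse the same cone.  `beta_1 = 1`
and `beta_2 > 0` is a global bleaching factor: the second recording is
acquired after the first has already bleached the fluorophores, a zeroth
order approximation of the true (nonlinear, dye-specific) bleaching.

Estimation minimizes

    E = sum_i sum_x (I_i - F_i)^2 / (m^2 I_i + sigma^2)
      + lambda * sum_x psi(|grad alpha|^2)
      + mu * sum_x sqrt(alpha^2 + eps_sp^2)

subject to `alpha >= 0`, `I >= 0`, `beta_2 > 0`.  The data weights are the
per-voxel variance of a Poisson-Gaussian noise model (`m` intensity levels
per photon-equivalent, read-out noise `sigma`), evaluated at the *recorded*
intensities and fixed per run.  `psi` is the identity (Tikhonov-Miller,
smooth fields) or the smoothed total-variation loss
`psi(t) = sqrt(t + eps_tv^2)` (piecewise-constant fields, sharp boundaries).
The sparsity term drives `alpha` to zero where the data carry no
information.  Default stabilizers `eps_sp = eps_tv = 1e-10`.

A convention worth emphasizing: when the absolute noise scale is unknown one
parameter may be fixed arbitrarily, and we follow the usual choice of fixing
the *model* `sigma := 1` during reconstruction even when the simulated
read-out noise has `sigma = 10`.  The weights then act as a relative
down-weighting of bright voxels, and the useful magnitudes of `lambda` and
`mu` (1e4..1e9) are calibrated against this convention.  Reconstructing with
the simulation's `sigma = 10` instead shrinks the data term ~100x and makes
the same `lambda` values over-regularize.

## Discretization of the ray integrals

The line integral of `alpha` along a ray is discretized as a
slice-synchronized shear sweep: each step advances exactly one z-slice and
applies a constant in-plane bilinear shift, accumulating

    S = W alpha + W^2 alpha + ...,   L = step_len * (alpha/2 + S),  T = exp(-L)

where `W` is the one-step shift operator (zero outside the volume — the
natural boundary condition) and `step_len = 1/|r_z|` the per-step path
length in voxel units.  Two properties motivated this choice over direct
trilinear sampling at fixed 1-voxel steps:

* `L` is a *linear operator* applied to `alpha` whose transpose is the same
  sweep run backwards (a constant-offset bilinear gather with zero padding
  transposes to the gather with negated offsets).  The attenuation gradient
  of the discrete energy is therefore the *exact* adjoint backprojection of
  the forward model — analytic gradients match central finite differences to
  rounding error, which is the property the quasi-Newton optimizer needs.
* cost is one volume pass per ray instead of one per ray and step.

The repeated interpolation acts like an incrementally widening ray: the
effective footprint grows ~sqrt(depth) voxels.  This mirrors the widening
conic rays of earlier cone-integration schemes, but it also *blurs the
angular identity* of rays at depth, with consequences discussed under
Limitations.  A direct-sampling `transmittance()` point evaluator (trilinear
samples at 1-voxel steps) is kept as the reference implementation and agrees
with the sweep within a few percent on smooth fields.

The cone quadrature places rings of directions every `ray_spacing` degrees
(default 6, the value used throughout) from the axis to `half_angle`
(default 30 degrees; the optics' half-angle is not fixed by the model and is
configurable), weights each ring by the solid angle of its annular patch
(uniform weighting is available), and normalizes weights to 1.

Smoothness terms use forward-difference gradients with Neumann boundaries
and their exact adjoint (backward-difference divergence) for both TM and TV,
so every prior gradient is the exact derivative of the discrete energy sum.
Central differences would be an equally valid discretization but would break
exact adjointness with the divergence used in the gradient.

## Optimization

`alpha` is optimized by box-constrained L-BFGS-B (`alpha >= 0` enforced by
the optimizer, `beta_2 > 0` by clamping at 1e-6).  For fixed `alpha` the
data term has closed-form minimizers in `I` (per voxel) and in `beta_2`
(scalar); an inner fixed-point loop alternates the two until the relative
`beta_2` change drops below 1e-6 (at most 10 sweeps).  The inner refresh
runs at *every* energy evaluation (variable projection): the outer objective
is then a consistent function of `alpha` alone, line searches are monotone,
and the `alpha`-gradient is the exact envelope derivative at the inner
optimum.  Each half-step of the alternation is an exact coordinate
minimizer, so the data energy never increases across the inner loop.

Initialization: `alpha = 0`, `beta_2 = 1`, `I` from the closed-form update
with unit cone transmissions — the exact optimum of the attenuation-free
model.  Stopping: `max_outer_iterations` (default 50) or a relative
total-energy change below `energy_tol`.  If L-BFGS-B terminates early on its
internal tolerances the driver restarts it from the current iterate with a
fresh Hessian (up to 3 restarts).  All reductions are single-threaded and
deterministic: identical inputs reproduce bit-identical states.

The `reconstruct_baseline_ref7` preset is the pure-Gaussian special case
(`m = 0`, `sigma = 1`, no sparsity, bleaching estimation disabled) — the
energy older two-view Gaussian approaches minimized.  Note it shares this
package's numerics and optimizer; it reproduces the older *model*, not the
behaviour of any historical implementation of it.

## Synthetic data

`make_dataset` chains phantom -> PSF smoothing -> two-view simulation ->
noise.  Defaults are the benchmark conditions of the evaluation suite:

| quantity | default | note |
| --- | --- | --- |
| sphere absorption | 0.006 / voxel | constant inside the sphere |
| core intensity | 4094 | inner 60 % of the radius |
| texture | std = 0.3 * field max | Gaussian noise smoothed with sigma = 4 voxels, added within each field's support, clamped at 0 |
| sphere radius | 0.4 * grid extent | free geometry parameter; chosen so the object fills most of the frame |
| Shepp-Logan | standard 10-ellipsoid tabulation | painted in order (homogeneous regions), intensities scaled to [0, 65535] |
| region attenuations | [0, 0.01] | lookup written in `SHEPP_LOGAN_ATTENUATIONS`, deliberately decorrelated from intensity |
| PSF | Gaussian sigma (2, 1, 1) voxels | band-limits the ground truth for Nyquist-safe sampling; axial 2x worse than lateral |
| bleaching | beta_2 = 0.8 | 20 % signal loss in the bottom view |
| noise | m = 0.05, sigma = 10 | variance m^2 I + sigma^2, exactly the model's weight denominator |

The Poisson branch uses gain `1/m^2` photon-equivalents per level
(`out = m^2 Poisson(v/m^2) + N(0, sigma^2)`), the parameterization that
makes simulator and data weights self-consistent.  The PSF is applied to the
ground-truth fields themselves, so reported RMSEs measure reconstruction
error rather than blur.  The generators emulate attenuation, bleaching and
mixed noise; they do not model refraction, scattering-in, spatially varying
PSFs or registration error, so passing tests say nothing about those
effects on real data.

## Problem sizes

Unit and property tests run on grids up to 6^3 (gradient checks against
finite differences, adjoint identities against dense matrices) and 16^3-24^3
(optimizer behaviour).  The evaluation-style tests use 40^3-80^3 phantoms
with the benchmark parameter settings; the reproduction script
(`scripts/acceptance.py`) simulates at 80^3, the processing resolution
typical for real recordings.  These sizes
were chosen so a full run completes on a single CPU core in minutes; the
attenuation strength of the sphere (optical depth ~0.4 through the centre
at 80^3) scales with the grid, so error magnitudes quoted at different
resolutions are not directly comparable.

## Known limitations

* **Shell ambiguity.**  For a z-symmetric object, the component of the
  attenuation field lying where `I = 0` (e.g. the non-fluorescing shell of
  the sphere phantom) enters the two views almost symmetrically and can be
  absorbed into `I` and `beta_2`; it is constrained only through the angular
  diversity of the cone rays.  Because the shear-sweep numerics blur ray
  identity at depth, this constraint is weak: TV + sparsity reconstructions
  recover core and background attenuation to ~1e-4..7e-4 RMS but set the
  shell mostly to zero, and TM reconstructions spread it smoothly instead.
  Evaluations built on other cone-integration numerics can land elsewhere in
  this null space and report different attenuation errors: the numerical
  approximation of the cone integrals, not the energy formulation, dominates
  such differences.
* The exponential-decay model holds for absorption and mild random
  refraction only; structured refraction (lens-like tissue) violates it.
* Samples exceeding the recorded volume violate the zero-outside-attenuation
  boundary condition; high sparsity weights and early stopping mitigate the
  resulting boundary artifacts (fewer than ten iterations already give
  qualitatively good reconstructions).
* The energy is non-convex; all statements about convergence are empirical.
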