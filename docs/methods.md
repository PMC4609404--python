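# Methods

`dictsir` reconstructs 2-D fan-beam CT images from sparse-view, low-dose
projection data by penalized weighted least squares with a learned-patch
(dictionary) prior, and — its central feature — selects the regularization
parameter automatically from a single infinite-regularization pass.

## Measurement model and geometry

A scan is described by a flat, equispaced virtual detector through the
isocenter, a point source at distance `R = source_factor × N·h` from the
center (default `source_factor = 2`, i.e. twice the image edge), `V` views
at a fixed angular step, and `D` detector elements whose span is sized (with
a 10% margin) so the fan covers the circumscribed circle of the `N × N`
pixel grid from every view. The system matrix `A = {a_ij}` holds the exact
Euclidean intersection length of ray `i` with pixel `j` (Siddon traversal,
vectorized per view); forward projection is `l = A μ` and the adjoint is
`Aᵀ`. Exact intersection lengths were chosen over interpolation footprints
because the data model is a line integral of the attenuation map; the
detector convention (flat vs. arc) is a config choice with the flat detector
as the simpler default.

Photon statistics follow the usual transmission model
`y_i ~ Poisson(b_i e^{−l_i} + r_i)` with log-transformed measurement
`l̂_i = ln(b_i/(y_i − r_i))` and statistical weight
`ω_i = (y_i − r_i)²/y_i`. The simulator's default regime is the one used
throughout the validation experiments: entrance intensity `b0 = 10⁶`
photons, zero read-out mean (`r = 0`), and additive zero-mean Gaussian noise
applied directly to each line integral with standard deviation equal to a
stated fraction of that ray's noiseless value ("0.2% noise" means
`σ_i = 0.002 · l_i`; rays with `l_i = 0` stay exact). Full Poisson
resampling of the counts exists as an option but the reproduction
experiments use the Gaussian convention. Under it the weighted relative
data-fidelity error defined below has a clean noise floor: its expected
value at the true image is exactly `(noise level)²`.

### Attenuation scale

The Shepp-Logan phantom is dimensionless (values 0–1). The experiments
assign `0.07` attenuation units per phantom unit so that line integrals
peak near 5, the regime of a head scan. This matters: with unit-value
pixels the weights `ω = b0·e^{−l}` would span tens of orders of magnitude
and every weighted-fidelity quantity would be dominated by background rays.
NMAD and SNR are invariant to jointly scaling the reconstruction and the
reference, so the published image-quality comparisons are unaffected by
this choice.

## Reconstruction

All iterative methods stop on the relative-change rule
`err = |δ_t − δ_{t−1}|/δ_t < stop_tol` (default `10⁻³`), where

    δ = Σ_i (ω_i/2)([Aμ]_i − l̂_i)² / Σ_i (ω_i/2) l̂_i²

is the weighted relative data-fidelity error of the current iterate, and
all enforce nonnegativity.

**SART** performs view-by-view simultaneous updates with row/column-sum
normalization (relaxation 1.0, no decay), up to 300 sweeps by default. On
the 120-view protocol it converges to a solution with bulk streak error of
about 4% NMAD — the minimum-norm character of the unregularized solution,
not a convergence artifact (longer runs, relaxation changes and
support-masking experiments do not move it appreciably).

**GPBB** minimizes `Σ ω_i/2 ([Aμ]_i − l̂_i)² + β·TV_ε(μ)` by projected
gradient with Barzilai–Borwein step lengths and a monotone backtracking
safeguard, starting from the SART image. `β` defaults to
`4×10⁻³ · mean(ω)` so it scales with the photon statistics, `ε = 10⁻⁶`
smooths the isotropic TV, and the iteration cap is 200. Because BB steps
make `δ` non-monotone, the stopping rule requires three consecutive
sub-tolerance changes.

**Dictionary SIR.** The regularizer is `Σ_s ‖E_s μ − D α_s‖²` over all
overlapping 8×8 patches (stride 1). Patches are coded with their mean
removed and restored on reassembly. The separable paraboloid surrogate of
the data term decouples the update per pixel; with data curvature
`p_j = Σ_i a_ij ω_i Σ_k a_ik`, patch coverage `q_j`, data target `c_j` and
patch-model target `d_j` (the patch-average of the sparse approximations),
the classic update is `μ_j ← [(p_j c_j + 2λ q_j d_j)/(p_j + 2λ q_j)]₊`.
Reweighting the patch penalty per pixel by `r_j = p_j/(2 q_j)` gives both
quadratics the same curvature and yields the adaptive-weight (AWR) closed
form `μ_j ← [(c_j + λ d_j)/(1 + λ)]₊`, whose `λ → ∞` limit is the pure
patch-model update `μ_j ← [d_j]₊`. The data step cycles over 10 ordered
view subsets with the subset gradient scaled by the subset count.

**Dictionary handling.** In *global* mode the dictionary is trained
beforehand on a separate reference image. In *adaptive* mode it is trained
(K-SVD) on the pass's own starting image — adapted to the data being
reconstructed — and held fixed for the pass while the sparse codes refresh
every outer iteration. Holding the dictionary fixed within a pass keeps
each pass an alternating minimization of one fixed objective; retraining
every outer iteration was tried and rejected because it turns the objective
into a moving target: the iteration then drifts (the patch average acts as
a diffusion), `δ` grows without bound and the stopping rule never binds.
Defaults: K = 512 atoms, 16 000 training patches (seeded subsample), 20
K-SVD iterations, training sparsity 5, seeded and reproducible.

**K-SVD** alternates batch OMP coding with per-atom rank-1 SVD updates of
the restricted residual, re-seeding unused and near-duplicate atoms from
the worst-represented signals. Batch OMP is the Gram/Cholesky ("batch
OMP") formulation with a numba-compiled inner loop; a single-vector
textbook OMP serves as the reference implementation in the tests.

**Coding tolerance — the regularization mechanism.** Sparse coding stops
per patch at `max(tol_abs, 10⁻³‖x‖)` residual or 32 atoms. The absolute
tolerance is what regularizes: it is re-calibrated every outer iteration to
the *artifact floor* of the current iterate — the amplitude of the
streak/noise content of nominally flat regions, estimated by a three-class
multi-Otsu split of the log patch norms (background / artifact-bearing
flats / anatomy edges) with a separation guard that falls back to faithful
coding when no unambiguous artifact band exists. Flat-but-streaky patches
then collapse to their mean (artifacts vanish) while anatomy patches are
represented nearly exactly; as the image gets cleaner the tolerance
anneals toward zero, so the alternation reaches a fixed point instead of
smoothing indefinitely. A fixed relative tolerance was tried first and
regularizes nothing (it encodes faint streaks faithfully); a fixed absolute
tolerance over-smooths once the artifacts are gone.

## Automatic selection of λ

One pass with `λ = ∞` — the patch-model projection of the data-consistent
warm start under a dictionary trained on it, coded faithfully (relative
tolerance only, the regime the annealed pass reaches at its own fixed
point) — yields

    δ_∞ = δ(patch-model image),    δ_G = 10⁶ · δ_∞ .

`δ_∞` isolates the dictionary model's intrinsic misfit plus the
projection-noise floor, and grows with the noise level exactly as the
proper `λ` must. The shipped piecewise-quadratic map

    λ* =  1.74485 δ_G² + 0.58883 δ_G − 6.88253   if δ_G > 1.96
    λ* = −0.21545 δ_G² + 1.08602 δ_G − 0.32634   if δ_G ≤ 1.96

is calibrated for `δ_G` roughly in [0.4, 10]; outside that range the
package warns and extrapolates, clamping nonpositive results to a small
positive floor (the high branch is negative for small `δ_G`). The
coefficients are data (a `LambdaModel` value), not code, so a model
refitted for a different protocol (`scripts/fit_lambda_model.py`) drops in.

The two-pass workflow is: SART warm start → pass 1 at `λ = ∞` (measures
`δ_∞`, trains the dictionary) → `λ* = f(δ_G)` → pass 2 at `λ*` from the
same warm start with the same dictionary. Exactly two dictionary passes
are executed, against the ten-or-more reconstructions an empirical search
for `λ` typically costs.

The `λ = ∞` pass is a single outer iteration by construction: iterating
`μ ← [d(μ)]₊` has no useful fixed point (each application compounds the
patch-average smoothing), so the projection of the converged warm start is
the quantity that characterizes the model-vs-data misfit.

## Evaluation

NMAD% = `100 Σ|μ − μ^truth| / Σ μ^truth` (denominator deliberately the
plain sum, matching the convention of the quantities reproduced) and
SNR = `10 log₁₀(Σ μ_truth² / Σ (μ − μ_truth)²)` dB, with `∞` as the
sentinel for identical images. Display export windows linearly to 8 bit;
round-half-to-even puts exact window midpoints at 128 (or 127 when floating
point lands a hair under the boundary).

## Validation protocol and problem sizes

The acceptance study uses the 256×256 Shepp-Logan phantom, 120 views at 3°
over 360°, 512 detectors, source at twice the image edge, noise levels
0.0% and 0.2% — with the two printed selector operating points evaluated
exactly. The selector's noise-monotonicity check runs the same protocol at
128×128, and the λ-balance property (fidelity non-decreasing, patch
penalty non-increasing in λ) on a 32×32 instance with a fixed global
dictionary — sizes chosen so the full suite completes on a single CPU in
minutes while preserving the regimes of interest (the 256² protocol is the
one place where SART is genuinely underdetermined and streak-limited).

What the synthetic study does *not* emulate: polychromatic spectra, scatter,
detector cross-talk, arc detectors, 3-D cone-beam geometry, and clinical
anatomy. Passing tests demonstrate the mechanics and the selector's
behavior under the stated noise model, not clinical image quality; the
selector's quadratic coefficients were fitted elsewhere and their
transferability to other geometries, patch configurations or dictionary
sizes is not established (the monotone `δ_∞`–`λ` relation is the part that
generalizes; refit the map when the configuration changes).

## Known limitations

* The SART baseline converges to a ~4% NMAD streak floor under the 120-view
  protocol in these conventions; published SART figures for the same
  protocol vary with unstated projector and iteration choices.
* At 0.2% noise the two-pass result lands near 1.5–1.6% NMAD, limited by
  the noise amplification of its SART warm start.
* The artifact-floor estimator assumes a multi-modal patch-norm
  distribution; on images whose artifacts rival anatomy in amplitude it
  conservatively disables the lossy coding (the pass then preserves its
  warm start rather than denoising it).
* `δ_G` far outside [0.4, 10] (e.g. heavy noise) extrapolates the high
  branch to very large λ*; pass 2 then relies almost entirely on the
  annealed patch model.
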