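# Methods

## Model

Parathyroid hormone (PTH) acts on osteoblasts and osteocytes through PTH1R, a
G-protein-coupled receptor that interconverts between signalling-competent
(active) and desensitised (inactive) conformations whether or not ligand is
bound. `pthpulse` implements the classic two-state receptor scheme with four
species — active free receptor R_a, active complex C_a, inactive complex C_i,
inactive free receptor R_i — connected by first-order conformational
conversions (rates k1, k−1 between the free forms and k2, k−2 between the
complexes) and by ligand binding/unbinding (kr, k−r for the active branch,
kd, k−d for the inactive branch). Written in fractions of the total receptor
pool, the state x = (r_a, c_a, c_i, r_i) obeys a linear ODE dx/dt = K(L)x
whose coefficient matrix depends on the plasma PTH concentration L(t). The
columns of K(L) sum to zero, so the pool is conserved exactly.

Because every stimulus in the package is piecewise constant (square waves),
the system is never time-stepped: propagation across a constant-ligand
segment is the matrix exponential of K·Δt, equilibria are null-space solves,
and the periodic regime under a square wave is the eigenvalue-1 fixed point
of the one-period monodromy map (the product of the segment exponentials).
Contraction of that map — all other monodromy eigenvalues strictly inside
the unit circle — is asserted on every solve. An adaptive stiff-capable ODE
integrator (`scipy.integrate.solve_ivp`, LSODA) appears only as an
independent oracle in the test suite.

### Kinetic parameters

Conversion rates are the experimentally derived GPCR values
k1 = 0.012, k−1 = 0.104, k2 = 0.222, k−2 = 0.055 min⁻¹, and the
active-complex dissociation constant is Kr = 1 nM. The binding off-rates
are not separately identified by these constants; the defaults
k−r = k−d = 10 min⁻¹ put binding on a much faster timescale than the
conformational conversions (the quasi-equilibrium regime the two-state
literature assumes) and are exposed as calibration knobs.

The inactive-complex constant Kd is **derived from detailed balance** by
default: the four reactions form a thermodynamic cycle, and requiring zero
net circulation at equilibrium fixes Kd = Kr·K2/K1 (K1 = k−1/k1,
K2 = k−2/k2). This is not cosmetic: the exact-adaptation property below
holds *exactly, at every ligand level*, if and only if the cycle is
detailed-balanced. With the frequently quoted Kd = 10³ nM the cycle carries
a steady flux and the "adapted" activity drifts by tens of percent across
the physiological ligand range; that mode remains available
(`detailed_balance: false`) but is not the default.

## Activity and cellular responsiveness

Signalling output is summarised by the scaled activity
α = s·(a1·r_a + a2·c_a + a3·c_i + a4·r_i) with non-negative weights. The
weight of the active complex is always constructed from the exact-adaptation
condition

    a2 = (((a1·K1 + a4)/(K1+1))·(K2+1) − a3)/K2,

the unique grouping for which uniform weights return themselves (a constant
activity trivially adapts). Under detailed balance this makes the
steady-state activity identical to the basal activity α0 for **any**
constant stimulus, so the cell responds only to change: a frequency
detector.

For a square wave (tonic γ0, peak γ1, on-phase τ1, period T) at the
periodic steady state, each pulse elicits an activity burst followed by a
refractory undershoot while the receptor pool resensitises. The package
quantifies stimulation by the **burst area**

    α_T = ∫₀ᵀ max(α(t) − α0, 0) dt,

computed exactly (spectral representation per segment; sign changes of the
excess are root-found and the positive stretches integrated in closed
form). The signed integral is also available but is not a useful readout:
an exactly adapting system has zero DC gain, so the signed per-period
integral cancels to second order in the pulse amplitude — the burst is
repaid by the undershoot — and any functional built on it is cubically
small for weak pulses. The burst area is first-order in the stimulus and is
what makes pulse patterns discriminable.

The responsiveness of a pattern is

    α_R = (α_T / α_T_step) · (α_T / T),

where α_T_step = τ_a·α_M_step references a single sustained step from γ0 to
γ1: α_M_step is the peak *excess* activity of the step transient and τ_a the
adaptation time — the first time after the peak at which the excess has
decayed below 1/e of its maximum (the fraction is configurable; 2% and 5%
variants give systematically longer τ_a and a correspondingly smaller α_R
scale; the criterion used is recorded in every result and manifest).
τ_a·α_M_step approximates the integrated excess of the whole step response,
so the first factor measures how much of the "one-shot" response a single
pulse recovers, and the second is the per-period average. α_R vanishes for
constant stimuli, is invariant to the phase origin of the wave, and scales
linearly with the activity weights.

With the default kinetics the adaptation time is ≈10 min and the
resensitisation of the free-receptor pool is slower (k−1⁻¹ ≈ 10 min,
k1⁻¹ ≈ 83 min), which places the optimal glandular pattern at pulses of
≈12.5 min separated by ≈75 min — pulse long enough to fire the burst
completely, off-phase long enough to resensitise, but not longer, because
the period average penalises idle time.

## Stimuli

Glandular secretion is a square wave; its AUC over a window s splits in
closed form into a tonic part γ0·s and a pulsatile part (γ1−γ0)·τ1·s/T,
with pulsatile fraction r. A subcutaneous injection of dose D produces a
plasma concentration given by the one-compartment first-order-absorption
(Bateman) solution; for use in the periodic model it is reduced to an
equal-peak, equal-AUC rectangle riding on the tonic baseline
(τ1 = AUC/peak, independent of dose under linear PK). Combined
gland + injection stimulation is evaluated two ways: **model 2** adds the
responsivenesses of the two waves computed independently; **model 1**
simulates the summed ligand (baseline counted once) over one dosing period
and attributes the activity integral to the injection window
[0, τ1_inj] and the gland elsewhere, crediting the bursts of gland pulses
that fall inside the injection window back to the gland (estimated from the
gland-only pattern — with rectified integrals they do not cancel). The two
models agree exactly at dose zero and to within 5–26% at clinical doses;
the residual is genuine receptor cross-desensitisation between the drug
plateau and the gland bursts, largest for high-tonic states.

### PK preset

The shipped parameters describe PTH(1–34) (teriparatide) subcutaneous
kinetics in the flip-flop regime: elimination t½ = 5 min
(k_e = 0.1386 min⁻¹), absorption-limited decay with k_a = 0.0149 min⁻¹
(t½ ≈ 47 min, giving a plasma peak at ≈18 min), F = 0.95, V_d = 13.1 L,
molar mass 4117.8 g/mol. k_a and V_d were calibrated so that the
square-wave reduction of a once-daily dose reproduces the published
reduction geometry (on-phase 87.9 min; peak 1.44 pmol/L per µg). Doses in
µg convert to pmol at the configuration boundary.

## Optimisation problems

All pattern problems conserve exposure: total AUC equals a reference A_ref
and the pulsatile share stays at r. Substituting the square-wave closed
form eliminates both constraints (γ0 = γ0_ref and
T = s·τ1·(γ1−γ0)/(r·A_ref)), leaving an unconstrained search over
(γ1, τ1); a design is feasible iff the amplitude exceeds the mean pulsatile
concentration r·A_ref/s (else the implied period would not contain the
pulse). Searches run a Nelder–Mead simplex on log-transformed variables
(xatol = fatol = 1e-6, ≤2000 iterations) from a fixed 3×3 multistart grid
(γ1 ∈ {1.5, 3, 6}·γ0 nudged into feasibility, τ1 ∈ {5, 10, 20} min), with
box penalties instead of hard failures inside the search — fully
deterministic. Target problems minimise (α_R − target)² and are declared
infeasible when the final residual exceeds 1e-2 (configurable); all local
optima found are recorded. An exhaustive grid scan with lexicographic
tie-breaking serves as the independent oracle in the tests.

Injection problems are one-dimensional in the per-injection dose D: the PK
model fixes (γ1, τ1), and conserving the daily drug AUC fixes the dosing
interval T(D). The responsiveness along this constraint is a nearly flat
ridge in D (burst area and step reference both scale with the dose until
concentrations approach Kr), so the located maximum should be read as "the
flat top of the ridge" rather than a sharp optimum. The dose normalising a
disease deficit is solved at a fixed once-daily period.

## Scenarios

The registry covers healthy secretion, healthy with 20%-reduced tonic
secretion, idiopathic osteoporosis (OP), postmenopausal osteoporosis (PMO),
glucocorticoid-induced osteoporosis (GIO), primary hyperparathyroidism
(HP), the initial and steady-state phases of a hypocalcemic clamp and a
hypercalcemic clamp. Tonic levels γ0 and pulsatile mean concentrations
q = r·A/s were reconstructed by inverting published pattern-optimisation
outputs for these states (two independent rows per state over-determine the
pair; the reduced-tonic state reproduces 0.8·γ0_healthy to four digits,
validating the inversion). Pulse shape (τ1, T) is calibrated within
physiological burst bands (2–8 min pulses, 4–15 bursts/hour where
pulsatility is active) so that each baseline α_R matches its published
value, with the healthy anchor (τ1 = 2, T = 10 min) fixing the activity
scale s = 1489.5 such that healthy α_R = 0.939. The hypercalcemic state is
the exception: its near-absent pulsatility caps α_R at ≈0.10 in this model,
below the literature value 0.174; it is shipped at its ceiling and remains
the lowest-responsiveness state. Calibrated quantities are therefore the
healthy anchor and the per-scenario periods; genuinely *predicted*
quantities include the optimal pattern geometry, the baseline-to-maximum
ratio (31%), all fold-changes between states, feasibility of restoring each
disease to the healthy level, and the whole injection branch.

## Synthetic stimulus generator

`generate_test_stimulus` draws square waves uniformly from physiological
ranges (γ0 ∈ [1, 10] pmol/L, γ1/γ0 ∈ [1, 10], τ1 ∈ [1, 30] min,
T ∈ [τ1+1, 120] min), deterministically for a fixed seed. It emulates the
geometry of secretory patterns only — plateau levels are exact and noise-free,
there is no assay noise, no burst-to-burst amplitude variability, and no
slow circadian modulation of the tonic level. Passing property tests on
these fixtures therefore validates the *mathematics* of the pipeline
(conservation, exactness of propagation, constraint satisfaction), not the
fidelity of any clinical time series.

## Numerical choices and limitations

- Spectral (eigendecomposition) representations are used for in-segment
  evaluation and integration; spurious positive real parts of eigenvalues
  (≤ machine noise) are clamped to zero. Propagators use `scipy.linalg.expm`.
- Periodic fixed points are solved directly (replace one redundant row by
  the conservation constraint); residual tolerance 1e-10, contraction of the
  monodromy map asserted.
- Burst-area integrals locate excess sign changes on a ≥128-point grid per
  segment refined by Brent root-finding; accuracy is limited only by root
  bracketing (validated against dt = 10⁻³ min quadrature at 1e-6 relative).
- Degenerate stimuli (γ1 = γ0) return α_R = 0 with a flag rather than an
  error; uniform activity weights make the step response identically zero
  and are rejected in `step_response`.
- The model has no receptor synthesis/degradation, no downstream cAMP
  dynamics, a single ligand, and square-wave stimuli only; responsiveness
  values are relative scores on the configured activity scale, not absolute
  signalling rates. Superposition model 1's window attribution is an
  approximation (see above). The once-daily injection problems inherit the
  linearity of single-dose PK; repeated-dose accumulation is negligible at
  daily spacing but would matter for intervals below ~4 absorption
  half-lives, where this PK layer underestimates peaks.
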