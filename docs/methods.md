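# Methods

## Relaxation model

The orientational correlation function of each backbone N–H vector is
factorized into overall tumbling and internal motion, C(t) =
C_overall(t)·C_int(t). Internal motion uses the additive (cross-term-free)
extended model-free form

    C_int(t) = S²_f S²_s + (1 − S²_f) e^(−t/τ_f) + S²_f (1 − S²_s) e^(−t/τ_s)

with a fast (ps) and an optional slow (ns–sub-µs) process; S²_total =
S²_f·S²_s. Products of multi-exponentials are handled exactly as mode sums
(pairwise-summed decay rates, multiplied amplitudes), so every spectral
density in the package is a finite Lorentzian sum

    J(ω) = (2/5) Σ_k a_k τ_k / (1 + (ω τ_k)²).

Rates follow the standard Redfield expressions for the ¹H–¹⁵N dipolar
interaction plus axially symmetric ¹⁵N CSA:

    R₁ = (D²/4)[J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H+ω_N)] + C² J(ω_N)
    R₂ = (D²/8)[4J(0) + J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H) + 6J(ω_H+ω_N)]
         + (C²/6)[4J(0) + 3J(ω_N)] + R_ex
    η_xy = (DC√3/6)·P₂(cos β)·[4J(0) + 3J(ω_N)]

with D = (µ₀/4π)γ_Hγ_Nħ/r³ and C = Δσ·ω_N/√3. Defaults: 850 MHz ¹H
frequency (19.97 T), r_NH = 1.02 Å, Δσ = −170 ppm, β = 17°. The bond length,
CSA and β are conventional backbone-amide values; they scale all rates
globally and therefore drop out of every calibrated S² output (verified by a
scale-invariance test). The field is the single source of truth: ω_N is
derived from the gyromagnetic-ratio ratio, never entered independently.

## Gel model (exchange-modulated tumbling)

The gel sample is modelled as a two-state Markov-modulated isotropic
rotational diffusion: state F (free inside a gel cavity) with rank-2
orientational decay rate 1/τ_gel, and state B (transiently bound to the gel
matrix) with tumbling fully suppressed — decay rate exactly 0, no
large-number surrogate. Exchange follows the generator K = [[−k_fb, k_bf],
[k_fb, −k_bf]] with k_fb = p_b·k_ex and k_bf = (1−p_b)·k_ex, so

    C_overall(t) = 1ᵀ exp[(K − diag(1/τ_gel, 0)) t] p_eq ,

eigendecomposed into exactly two Lorentzian modes. This discrete-state
reduction reproduces the stochastic-Liouville picture of the cartoon model
exactly and needs no trajectory simulation. Internal motion is assumed
identical in both states. A bound state with p_b > 0 and k_ex = 0 is
rejected as infeasible (its non-decaying correlation would make J(0)
infinite). Negative mode amplitudes from the eigendecomposition are
permitted in principle (intermediate exchange); J(ω) ≥ 0 is asserted on a
frequency grid in the tests.

Reference parameter set (defaults everywhere, including the synthetic-data
generator): τ_P = 10 ns in the gel-free sample, τ_gel = 16 ns for the
unbound protein in the gel, p_b = 0.25 %, k_ex = 5×10⁵ s⁻¹. The exchange
rate is quoted without units in its source context; s⁻¹ is the only
dimensionally consistent choice and is used throughout. With these values a
rigid residue gains ΔR₂ ≈ 19.7 s⁻¹ (≈ 16.7 s⁻¹ at S² = 0.85, i.e. the
15–20 s⁻¹ range typical of ordered secondary structure) and ΔR₁ ≈
−0.33 s⁻¹ — the viscosity-induced slowdown moves R₁ down its dispersion
curve at this field, hence the opposite signs.

ΔR₂, ΔR₁ and Δη_xy are computed with the exchange-broadening term R_ex
stripped before differencing. Since R_ex enters both conditions additively
and identically, (x + R_ex) − (y + R_ex) = x − y is an algebraic identity;
implementing it as such makes the cancellation exact to the bit. When the
subtraction is instead performed on stored rate tables (R_ex already baked
into the floats), the identity holds to IEEE rounding (~10⁻¹⁴ s⁻¹), which
is measurement-wise zero.

### Time-scale sensitivity map

`sweep_timescale_map` evaluates ΔR₂ over (S², τ_int) for single-time-scale
internal motion. Two convergence scales emerge: free-protein R₂ curves for
different S² merge once τ_int exceeds a few × τ_P (tens of ns), because
faster internal motion is averaged by tumbling; ΔR₂ curves merge only once
τ_int exceeds the bound-state lifetime 1/k_bf ≈ 2 µs, converging to the
rigid-limit ΔR₂ independent of S². Under the reference parameters the
cross-S² spread of ΔR₂ is 19 % of the rigid limit at τ_int = 1 µs and first
falls below 5 % near τ_int ≈ 10 µs. That two-orders-of-magnitude gap between
the convergence points is the quantitative statement of the method's
extended observation window. The sweep returns raw ΔR₂ (normalization
conventions differ between presentations; the caller decides) and the
free-R₂ reference normalized to its rigid-rotor value.

## Lean model-free analysis

"Lean" model-free uses R₁ and R₂ only (no heteronuclear NOE):

1. **Global tumbling.** τ_P solves ⟨R₂/R₁⟩ = f(τ_P) for a rigid rotor,
   where the mean is taken after excluding residues whose ratio deviates
   more than 1.5 SD from the median (exclusion iterated once); the root is
   bracketed on [1, 100] ns. When the trimmed set retains residues with
   residual internal motion the estimate carries a small (~2–3 %) negative
   bias, which propagates into a uniform few-percent scale on the fitted S²;
   this does not affect gNASR outputs (independently calibrated) and only
   mildly affects the MF comparison.
2. **Per-residue fit.** With two observables and two parameters the problem
   is exactly determined. Both rates are linear in S² at fixed τ_int, so S²
   is eliminated through R₁ and the R₂ residual is solved as a bracketed
   1-D root in τ_int (machine-precision recovery on noise-free data); a
   χ²-grid plus local refinement serves as fallback. Bounds: S² ∈ [0, 1],
   τ_int ∈ [0, 5 ns]; ties broken by lowest χ², then lowest τ_int. A best
   τ_int below 1 ps (or a degenerate rigid solution) triggers a one-parameter
   refit with τ_int = 0 (`S2-only`). Residues whose residual χ² exceeds
   `chi2_max` (default 10) are flagged `excluded` — with two observables an
   unmodelled R_ex cannot be separated from dynamics, so such residues are
   flagged, never fitted. Uncertainties default to 2 % of each rate when the
   table carries none.

Because only sub-τ_P motions modulate free-protein rates appreciably, the
lean-MF S² tracks S²_fast: a residue with S²_fast = 0.85 carrying an
additional slow process (S²_slow = 0.6, τ_slow = 200 ns) still fits to S² ≈
0.83–0.86. The same residue's ΔR₂, calibrated, gives S²(gNASR) ≈ 0.68 — a
gap ≥ 0.15 that is the method's detection signal.

## Calibration and comparison

S²(gNASR) = d·ΔR₂ with d = 0.85 / mean(ΔR₂ over the calibration mask); the
masked mean is a plain mean (the mask itself, not trimming, selects the
stable centres of helices and sheets). Errors propagate by quadrature
through the difference and linearly through d; the uncertainty of d itself
is not propagated by default. Calibrated values above 1 are retained and
flagged, never clamped — they are evidence of noise or a misspecified mask.
A non-positive masked mean raises a calibration error: it is the designed
failure mode for swapped free/gel inputs. Δη_xy is calibrated identically
(channel `eta`), giving an intrinsically exchange-free cross-check; on
noise-free synthetic data the two channels agree with Pearson r > 0.9999.

`compare_profiles` reports per-residue differences, RMSD and Pearson r, and
flags residues with S²(gNASR) < S²(MF) − 0.1 as candidate slow-motion sites.
Residues `excluded` by the model-free fit are dropped first: their reported
S² is not a valid comparison baseline (an exchange-broadened residue would
otherwise be mistaken for a slow-motion site).

## Synthetic data

The generator emulates a small GTPase (170 residues by default): flexible
termini ramping to S²_fast = 0.2, sheets/helices with S²_fast ∈ [0.82, 0.88]
and τ_fast ∈ [20, 80] ps, loops with S²_fast ∈ [0.5, 0.8], slow loops adding
S²_slow ∈ [0.5, 0.8] with τ_slow log-uniform in [50 ns, 1 µs] (Switch-I- and
Switch-II-like segments at residues 30–36 and 60–64), and a short
exchange-broadened patch (R_ex ∈ [2, 10] s⁻¹). Helix/sheet interiors
(segments trimmed by two residues at each edge) form the calibration mask
and are rigid apart from fast librations by construction, so the calibration
premise holds exactly in every bundle. A `representative_slow_architecture`
variant pins the slow loops at the reference slow process — S²_slow = 0.6,
τ_slow = 200 ns on an otherwise ordered backbone — the localized-dip picture
used for blind-spot and detection benchmarks; slow motions drawn near the
weak end of the default ranges (S²_slow → 0.8, τ_slow → 1 µs) produce gaps
below the 0.1 flagging margin by construction and are a documented
limitation, not a detection failure.

Rates are forward-simulated with the package's own relaxation and exchange
models, then perturbed by independent Gaussian relative noise (default 2 %,
the typical experimental precision); error columns are set to
noise_level·rate. Randomness uses per-residue substreams seeded by (seed,
residue), so editing the architecture never reshuffles other residues. The
generator does not emulate spectral artifacts (peak overlap, baseline
errors) — the pipeline's inputs are fitted rates, so passing tests
demonstrate correctness of the rate-to-S² analysis, not robustness of
spectral fitting.

## Numerical choices

* Mode sums are validated to Σa_k = 1 within 10⁻⁹ at construction; zero or
  negative decay rates are rejected.
* The independent validation oracle computes J(ω) = (2/5)∫C(t)cos(ωt)dt by
  piecewise adaptive quadrature over log-spaced decade segments (oscillatory
  QAWO rule per segment), with C_overall(t) from `scipy.linalg.expm` of the
  two-state generator — sharing no code path with the eigendecomposition it
  validates. Agreement is ~10⁻¹¹ relative; the test threshold is 10⁻⁶.
* τ_P root-finding uses `brentq` at relative tolerance ~10⁻¹⁵; the
  R₂/R₁-vs-τ_P relation is monotone on the [1, 100] ns bracket at this
  field.
* Benchmarks use the 170-residue default chain; the full test suite and the
  acceptance script each complete in well under a minute.

## Known limitations

* Isotropic overall tumbling only; no anisotropic diffusion tensors.
* Bound-state internal motion is assumed identical to free-state motion.
* The lean model-free variant cannot fit R_ex (flagging instead); hetNOE is
  not used.
* Residue pairing is strictly by residue number — tables must come from the
  same construct.
* Gel-type specificity (polyacrylamide vs agarose) enters only through the
  tumbling/binding parameters, not through distinct physics.
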