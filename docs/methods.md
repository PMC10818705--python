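# Methods

## Kinetic model

Each electron-transfer (ET) step is treated with the semiclassical
high-temperature rate law

    k = k0 · exp(−β (r − r0)) · exp(−(ΔG° + λ)² / (4 λ k_B T)),

which factors into a distance-decayed electronic-coupling term and a
classical Franck–Condon (activation) term. Assumptions: nonadiabatic
transfer, a single classical reorganization coordinate, temperature-
independent λ, and purely exponential coupling decay with distance (no
pathway or packing-density model; the through-bond distances are inserted
directly into the through-space-style decay). Nuclear tunnelling
corrections in the inverted region are not included; none of the default
driving forces reach it.

The hopping scheme is a linear three-state chain D ⇌ I → A, where D is the
photogenerated Ru(III) oxidant state, I the tyrosyl-radical intermediate
state, and A the product state with oxidized Cu. Forward and reverse rates
of the first step come from the same Marcus expression with the sign of
ΔG° flipped, so detailed balance holds exactly by construction. The second
step is treated as irreversible for the overall rate because its driving
force in the regime of interest (≈ −0.6 eV) makes the back reaction
negligible; the back rate is nevertheless computed and stored
(`RateSet.k2r`) for transparency. The overall hopping rate is the
slow eigenvalue of this scheme,

    λ∓ = [S ∓ √(S² − 4 k1f k2f)] / 2,  S = k1f + k1r + k2f,

evaluated in the cancellation-safe form λ− = k1f·k2f / λ+. The
steady-state-intermediate estimator k1f·k2f / (k1r + k2f) is retained as an
alternative; the two agree to better than 5% whenever k2f > 100·max(k1f,
k1r), which includes the entire experimentally relevant driving-force
regime. An exact matrix-exponential propagator of the full master equation
(including k2r) lives in the synthetic-data module and serves as an
independent oracle for both estimators.

The tyrosine deprotonation pre-equilibrium that precedes the first ET step
is not modelled kinetically: pH enters only through the measured formal
potentials, exactly as in the hopping-map analysis this package
implements. Met122 is not treated as a redox relay (its potential,
≈1.6 V, is out of reach of the Ru(III) oxidant), and protein dynamics are
outside the model.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| λ (`lambda_reorg`) | 0.8 | eV | reorganization energy of each step |
| β (`beta`) | 1.1 | Å⁻¹ | coupling decay constant |
| T (`temperature`) | 298 | K | temperature |
| k0 | 10¹³ | s⁻¹ | activationless rate at contact |
| r0 | 3 | Å | van der Waals contact distance |
| r(D–I), r(I–A), r(D–A) | 16.5, 18.3, 34.8 | Å | through-bond distances |
| E(Ru III/II) | 1.0 | V vs NHE | photosensitizer couple |

λ, β, T and the distances are the values used for the published map of
this system. k0 and r0 are not printed there; the defaults are the
convention of the hopping-map literature (activationless rate of 10¹³ s⁻¹
at van der Waals contact) and are exposed as configurable parameters.
k_B = 8.617333×10⁻⁵ eV/K; all energies in eV, potentials in V, and all
couples are one-electron, so ΔG°(eV) = −ΔE(V) numerically.

The default map axes span ΔG1 ∈ [−0.4, +0.4] eV and ΔGtotal ∈
[−1.0, −0.4] eV on a 201×201 grid, covering the driving-force regime the
measured potentials occupy; generation is vectorized and deterministic
(bit-identical across runs).

Two reporting conventions follow the precision of the measured tables:
potential spreads are rounded to 0.01 V, and percent rate differences are
additionally exposed rounded to the nearest 10%.

With these defaults the calculated overall rates from the measured
potentials are log₁₀ k = 3.38 at pH 6 and 4.14 at pH 9 (Tyr109Met122
intermediate). The choice of overall-rate definition (eigenvalue vs
steady state vs half-life) and of the unstated prefactor conventions
shifts such values by up to a few tenths of a log unit, which is why
map-level comparisons are made on the log scale.

## Trace fitting

Transient-absorbance traces are fit to
ΔA(t) = a₁e^(−k₁t) + a₂e^(−k₂t) + c by Levenberg–Marquardt
(lmfit). Initialization is deliberately derivative-free: the 10–90%
transit times of the signal envelope bound the fast and slow timescales, a
small log-spaced grid of rate pairs inside those bounds is screened with
amplitudes obtained by linear least squares (variable projection), and the
best pair seeds the nonlinear refinement. Rates are reported ordered
k₁ ≥ k₂; per-fit standard errors come from the local curvature of the
objective, but replicate-level errors are the sample standard deviation
across fits, matching experimental practice. Non-convergence raises;
fitted rates within a factor of 2 of each other trigger an
identifiability warning rather than a silent guess, and the same threshold
governs the phase-ambiguity warning in assignment. Phase assignment is
strictly by rate magnitude (the quenched excited-state decay is always the
fast phase; the slow phase is k_obs); amplitude signs are diagnostic only.
The default fit window drops samples before 2% of the trace span to
exclude the excitation artifact of real measurements and is configurable
(`window_start`); fits are invariant to time-unit rescaling.

## Synthetic data

`simulate_trace` generates traces from the biexponential closed form —
the same model class the analysis fits, which is also how rate constants
are extracted from the real measurements — with a fast emission/bleach
component (negative-going at 628 nm; the redox component inverts at
490 nm), a slower redox component, an offset, and pointwise Gaussian noise
from a PCG64 generator keyed by the config seed (platform-stable).
Defaults: excited-state rate 2×10⁵ s⁻¹ (the quenched *Ru(II) decay at
10 mM quencher), redox rate 1.2×10⁴ s⁻¹ (the observed Cu(I)-oxidation
rate near pH 7), amplitudes −0.010 / +0.008 absorbance (order-of-magnitude
plausible; absolute experimental amplitudes are not published), t_max =
10 redox lifetimes, 500 linearly spaced points, σ = 5×10⁻⁴ (redox-phase
SNR 16). Slow recombination between the Ru(III) label and the reduced
quencher (>0.5 ms timescale) is excluded from the default model.

What the generator does **not** emulate: instrument response and laser
artifact shape, shot-to-shot energy jitter, correlated (1/f) detector
noise, baseline drift, and the recombination tail. Passing closed-loop
tests therefore demonstrates correctness of the estimator on the assumed
model class with white noise, not robustness to every instrumental
pathology of real traces.

`recovery_study` runs the full simulate → fit → assign loop over a grid of
true rates and SNRs (100 replicates per cell by default, each with a
deterministic child seed derived from (seed, cell, replicate) via
`SeedSequence`). Two choices mirror experimental practice: the
excited-state rate scales with each cell's redox rate so the base
config's ratio (≈17) is preserved — experimenters tune the quencher
concentration so the photophysics stays well-separated from the ET step,
and at a fixed 2×10⁵ s⁻¹ a 10⁵ s⁻¹ cell would be unidentifiable by the
package's own factor-of-2 criterion — and fits start at t = 0 because
synthetic traces carry no excitation artifact. Under these conditions the
median |relative error| of the recovered slow rate is ≈2.5% per cell at
SNR 16 (relative RMSE < 5%), as the acceptance suite verifies.

## Numerical notes and edge cases

- The slow eigenvalue is computed as a product/quotient, never as a
  difference of near-equal terms; the discriminant S² − 4k1f·k2f ≥
  (k1f − k2f)² ≥ 0 is clamped at 0 against rounding.
- Distances at or inside contact (r < r0), non-positive λ, T, k0, rates,
  mV-scale potentials, non-monotone time axes, and duplicate table keys
  are all rejected with typed errors (`ConfigError`, `DataError`,
  `UnitsError`, `TraceFormatError`, `ConvergenceError`), which the CLI
  maps to exit codes 2/3/3/3/4.
- Degenerate (single-exponential) input to the biexponential fit produces
  an identifiability warning and either collapsed rates or a vanishing
  amplitude — never a silently invented second phase.
- Map grids, pipeline summaries, and recovery reports are deterministic
  for a fixed config/seed; pipeline reruns are byte-identical.

## Known limitations

- The hopping chain is exactly two steps; longer chains are out of scope.
- No global multi-wavelength fitting or instrument-response deconvolution.
- The pH dependence of the first step is purely thermodynamic (via the
  measured potentials); a kinetic deprotonation model would be needed to
  describe buffer and isotope effects.
- Calculated overall rates carry the ambiguity of the unstated k0/r0
  convention; they are meaningful on the log scale, not to three digits.
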