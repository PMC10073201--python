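# Methods notes

## Model and assumptions

The DVC triad is modelled as three coupled phase oscillators with a sine
interaction function — the leading term of any odd 2π-periodic coupling —
plus a single symmetry-breaking phase lag γ in the AP–NTS channel.  The
model is deterministic and nuclei-wide: single-cell heterogeneity,
oscillation amplitude and stochastic phase diffusion are deliberately out of
scope.  The bilateral NTS is treated as one oscillator (identical halves,
symmetric coupling to the AP), which is also what makes the surgical
disconnection analogue a parameter operation: removing one half maps
K_an → K_an/2 with everything else unchanged.  NTS–4Vep coupling is fixed at
zero; the 4Vep communicates with the rest of the network only through the
AP.

Phases are tracked unwrapped in radians internally.  Every user-facing phase
difference and period is in hours, with the single conversion factor
24/(2π) h·rad⁻¹; PDs are reported on the half-open interval (−12, 12] h
(+12 h and −12 h are the same antiphase relation; the wrap keeps +12).
Positive PD means the AP peaks first.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| τ_a, τ_n, τ_v | 25.7, 22.5, 23.4 | h | intrinsic periods |
| K_an, K_na | 0.031, 0.041 | rad/h | reciprocal attractive AP–NTS coupling |
| K_av, K_va | −0.045, −0.007 | rad/h | repulsive AP–4Vep coupling |
| γ | 0.770 | rad | AN phase lag (≈ 2.9 h on a 24 h cycle) |
| s_n(t), s_v(t) | 1 | — | per-channel global coupling, `max(s₀ − ct, 0)` |

s = 1 reproduces the fitted coupling exactly; the schedule multiplies K_an
and K_na by s_n and K_av and K_va by s_v.  The sign structure matters:
attractive AN coupling with a lag sets a small positive AN-PD, while the
weak repulsive AV channel with small detuning sets a near-antiphase AV-PD.

## Numerics

*Integration.*  `solve_ivp` RK45 with rtol 1e-3, atol 1e-6 (exposed per
call), dense hourly output.  The three-phase system is integrated in a
frame co-rotating at the mean intrinsic frequency: unwrapped phases
otherwise reach hundreds of radians within a fortnight of simulated time
and the *relative* tolerance then dwarfs the phase differences of interest.
The rotation is restored exactly on output.  Validation work that compares
two separately integrated systems (PD-reduction equivalence, estimator
round trips) uses rtol ≤ 1e-9 so the comparison probes the model, not the
integrator.

*Fixed points and the fold.*  Steady states solve the sine-linear system
A·(sin(θ_an−γ), sin θ_av)ᵀ = (ω_an, ω_av)ᵀ/s with
A = [[K̃_an, K_av], [K_an, K̃_av]].  Solving once at s = 1 gives (U, V);
fixed points exist iff max(|U|, |V|) ≤ s, so s_fold = max(|U|, |V|) in
closed form, and continuation is exact per-s branch enumeration
(4 arcsin-branch combinations) rather than predictor–corrector.  Stability
comes from the 2×2 Jacobian eigenvalues with a 1e-9 neutrality tolerance;
the closed form doubles as an oracle for the grid search the acceptance
script performs.  Degenerate det A = 0 raises a named error; zero detuning
gives s_fold = 0.

*Sweep classification.*  Long-run PD behaviour is classified on
block-extended simulations (400 h blocks, up to 3200 h): "locked" when the
state parks within 0.2 rad of the stable fixed point at near-zero velocity;
otherwise "drifting", refined to "near-threshold" when, after the first
block, more than 25% of samples move slower than 0.005 rad/h while the PD
still advances — the plateau-and-slip signature of the saddle-node ghost.
Near the fold slips recur on ~500 h timescales, which is why short windows
cannot classify reliably.

## Synthetic recordings

The generator emulates hourly-binned, ~150 h nuclei-wide PER2::LUC traces
via the simplest non-negative observation model,
B_i(t) = A·e^(−t/τ_d)·(1 + cos θ_i) + trend(t) + ε, with amplitude 100 a.u.,
damping time 150 h, zero polynomial trend and Gaussian noise (σ = 2 a.u.,
SNR ≈ 50) by default — values chosen so the 48 h detrend removes the
envelope cleanly and ridge extraction is unambiguous, since no amplitude
statistics are available for the real traces.  Ensembles (default n = 11)
jitter τ_a and τ_v with SD 1.75 h and 2.03 h (the fitted spreads), never
τ_n (its measured spread is far smaller), and draw per-member coupling
schedules from a menu of constant values in [0, 1] and linear decays
reaching zero between 100 and 200 h.  One ensemble seed fans out to
per-member substream seeds, each logged on the recording, so any member
regenerates bit-identically.

What passing on these synthetics does *not* show: robustness to the real
data's non-stationary amplitude, non-Gaussian noise, missing samples or
single-cell desynchrony — none of which the observation model contains.

## Wavelet stage

Detrending subtracts a least-squares line plus the Blackman-windowed-sinc
low-pass (cutoff period 48 h, kernel half-width 2 cutoffs, even-reflection
padding) — the line removal prevents boundary kinks when reflecting a
trending record.  The Morlet transform uses base angular frequency 2π so
scale equals period, a linear grid of 101 periods on [10, 48] h, and an
amplitude normalisation making a unit cosine score power ≈ 1 on the ridge
with ridge phase zero at each peak.  The ridge is the per-time argmax of
power (threshold 0 keeps all points), sharpened below the 0.38 h grid
spacing by parabolic interpolation across the argmax.  Samples within one
ridge period of a record edge are flagged as cone-of-influence and excluded
from averaged statistics.  Because the Gaussian envelope spans about one
period, the ridge smooths frequency modulation on that scale — a 4 h/150 h
chirp reads back with ≤ 0.7 h lag — and on locked, noise-free renders the
round trip recovers periods within 1% and PDs within 0.25 h once a
max-period (48 h) is trimmed from each edge.

## Plateau detection and estimation

The constant-PD detector differentiates the unwrapped PD after a 3 h moving
average (1 h sampling is too coarse for a raw derivative against a
0.01 rad/h threshold), keeps maximal sub-threshold runs ≥ 24 h, and reports
each run's mean PD θ* and collective period τ* (mean of the two oscillators'
mean ridge periods; a >4% period mismatch inside a segment triggers a
warning, not an error).  Multiple plateaus in one trace are all reported and
the trace flagged multistable; such traces are excluded from fitting because
the steady state is ambiguous.

Estimation inverts the two-oscillator reductions channel-wise: K̃_av =
ω_av/sin θ*_av and ΔK_av = 2(Ω* − ⟨ω⟩)/sin θ*_av for the AV pair; for the
AN pair the lag degeneracy is broken by the perturbation decay rate λ
(fit of a·e^(λt) + b to the approach window, from the first sample within
0.5 rad of the plateau to the plateau start), giving K̃_an = √(λ² + ω²_an)
and γ = θ* − arcsin(ω_an/K̃_an) on the stable branch (principal arcsin,
cos > 0, consistent with λ < 0).  The ΔK_an expression uses sin(θ*_an − γ):
deriving the mean-frequency relation from the phase equations gives
Ω_an = ⟨ω⟩_an + ((K_na − K_an)/2)·sin(θ_an − γ), an AN-channel-only
identity.  Sign conventions: ΔK_ch = K_(follower→AP-partner) − K_(AP→...),
concretely ΔK_an = K_na − K_an and ΔK_av = K_va − K_av, with
K_ij = (K̃ − ΔK)/2.

The validation protocol (`two_oscillator_round_trip`) measures θ*, τ* and λ
from simulations exactly as from data, but probes each plateau from both
sides (±1 h launches around a pilot run's plateau) and averages: the sine
nonlinearity biases a one-sided exponential fit by ~7% with opposite sign on
the two approaches, so the average cancels the leading-order bias.  Recovery
accuracy on the fitted parameters is ~1.5% for the couplings and <0.01 rad
for γ.  Singular plateaus (θ* at 0 or ±12 h) raise a named error; λ = 0 is
flagged as marginal rather than inverted blindly.

## Design choices that were genuinely open

* θ* as the plain segment mean (not a tail mean): simple and unbiased once
  segments are long; launch distance and record length in validation runs
  are chosen so approach-tail bias stays below the reporting precision.
* Per-channel schedules (s_n, s_v) with the single-s analysis as the special
  case s_n = s_v = s; the sweep and fold analysis use the single-s form.
* The fit-selection rule (top-stability unimodal traces) is implemented as
  a configurable count; the synthetic cohort exercises it qualitatively.
* Initial phases for scenario runs start at (or perturbed from) the
  relevant fixed point when the scenario concerns the locked regime, and at
  generic values when it concerns transients.

## Known limitations

* The sweep classifier's plateau-fraction threshold (25% of samples below
  0.005 rad/h) is heuristic; arbitrarily close to the fold any finite
  record under-samples slips.
* The wavelet stage assumes uniform sampling and a single dominant ridge;
  multi-component or amplitude-collapsing traces are read best-effort.
* Estimation requires a genuine locking plateau; near- or sub-threshold
  traces (no plateau, or plateau-then-slip) are detected as such and
  excluded rather than fitted.
* Problem sizes used throughout (150–450 h records, ≤ 3200 h sweeps,
  11-member cohorts, 300-point continuation grids) are the package's
  defaults; all are configurable.
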