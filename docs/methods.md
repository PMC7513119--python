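# Methods

## Signal model and preprocessing

Inputs are single-channel ECG segments in µV with a known sampling rate,
each annotated with a shock time, the start of the pre-shock
compression-free pause, and two binary outcomes: *electrical* success
(post-shock rhythm with sustained QRS complexes ≥ 30 bpm within a minute)
and *clinical* success (discharge alive with Cerebral Performance Category
1–3). Typical acquisition hardware samples at 125–250 Hz with a bandwidth
around 0.5–21 Hz and ≈4.8 µV/LSB resolution; the package treats 250 Hz as
the analysis rate.

Preprocessing emulates an AED front end: an order-8 elliptic band-pass
(0.5–30 Hz, 1 dB pass ripple, 30 dB stop attenuation), implemented in
second-order sections and applied **causally** by default — an AED filters
in real time, so zero-phase filtering is available (`zero_phase=True`) but
off. Resampling is polyphase FIR at the rational rate ratio with a Kaiser
(β = 5) anti-aliasing design; the output length is pinned to
`round(n · fs_out / fs_in)`. The analysis window of length `wl` ends
exactly 1 s before the shock (guard interval) and must lie inside the
annotated pause; violations raise `WindowError` naming the deficit.
An optional 4.8 µV quantizer reproduces the recorder's amplitude staircase
for robustness experiments; it is never applied by default.

WFDB input is not supported; records are CSV (`t_s,ecg_uV`) plus a JSON
shock sidecar, or in-memory `EcgRecord` objects.

## Entropies with absolute tolerance

For a series `x(1..N)`, delay-embedded vectors
`x_i = (x(i), x(i+τ), …, x(i+(m−1)τ))` are compared with the Chebyshev
distance `d_ij = max_k |x(i+kτ) − x(j+kτ)|`.

**Template convention.** Both scales use the same `N − mτ` templates;
each is compared against the remaining `N − mτ − 1` vectors (self-matches
excluded). `φ_m` is the mean per-template fraction (SampEn) or mean fuzzy
membership (FuzzyEn) of matches; the entropy is `ln φ_m − ln φ_{m+1}`.
Sharing one template set guarantees `φ_{m+1} ≤ φ_m`, hence non-negative
SampEn. (Published presentations vary between `N−m+1`, `N−m` and `N−m−1`
counts; the difference is O(1/N) and irrelevant at the working lengths of
120–300 samples, but the shared-template convention is the one that makes
the conditional-probability reading exact.)

**SampEn** counts hard matches `d ≤ r`. A distance exactly equal to `r`
counts as a full match; a half-weight-at-tie variant
(`half_weight_ties=True`) exists because the Heaviside step can also be
written with value ½ at 0, but ties have measure zero on real signals.
When no pair matches at one scale the estimate is undefined: the result
carries a NaN value and names the failing scale rather than raising — with
small absolute `r` and short windows this is a real operating condition,
and callers (e.g. the grid search) decide how to treat it.

**FuzzyEn** first removes each embedding vector's own mean (matching is
then local-shape based) and replaces the step by `exp(−(d/r)^n)` with
`n = 2` (Gaussian membership). Every pair contributes a positive weight,
so FuzzyEn is finite for any finite input — its practical advantage at
small `r` and short windows. As `n → ∞` without baseline removal it
converges to SampEn wherever pair distances stay away from `r` (verified
on amplitude-quantized signals, where distances are bounded away from a
mid-step threshold; for continuous-valued signals the boundary layer at
`d ≈ r` makes the `n = 50` agreement only ≈1e-2 nats).

**The tolerance is absolute (µV).** Nothing is normalized by the signal's
standard deviation. This is the core modelling choice: at fixed `r`,
scaling the waveform changes the entropy, so the statistic encodes
amplitude *and* regularity. The exact invariance that does hold — and is
tested to 1e-12 — is joint rescaling: `E(kx, kr) = E(x, r)`.

**Working rate.** Entropies are computed at `fs* = 60 Hz` on the
band-passed signal (`prepare_series` performs band-pass at the native rate,
then resampling), so a 2–5 s window yields N = 120–300 samples. The
embedding delay `τ` (default 1) enters as the stride of the delay
embedding; no further generalization is attempted.

**Numerics.** The reference path is a vectorised O(N²) pair sweep
(O(N²) memory, accumulated one coordinate at a time). For large N, SampEn
switches to exact dual-tree pair counting (`scipy.spatial.cKDTree`,
Chebyshev metric), which agrees with the direct path to 1e-12 and makes
the N = 1e5 analytic-limit check feasible. Fuzzy memberships clamp the
exponent at 700 so weights stay normal floats; the diagonal is masked
(not subtracted) so tiny off-diagonal memberships survive cancellation.

**Default operating points** (5 s windows): electrical criterion —
SampEn(m=1, r=50 µV), FuzzyEn(m=3, r=80 µV); survival criterion —
SampEn(m=2, r=25 µV), FuzzyEn(m=3, r=15 µV). Exposed as module constants;
everything is overridable.

## The predictor bank

Twenty-five literature predictors plus the two entropies form the
27-feature vector. Amplitude/slope/SNEO features are computed at the
native 250 Hz; spectral features from a 2048-point FFT of the
Hamming-windowed, mean-subtracted window (coherent-gain compensated so a
bin-centred tone of amplitude A peaks at ≈A µV; the mean is removed so a
residual DC offset cannot leak through window side lobes into the band);
the analysis band defaults to 2–30 Hz (below the AED filter edge, above
drift). The mean-slope identity `E|d/dt A sin 2πft| = 4fA`, the
Teager–Kaiser identity `ψ = A² sin²(2πf/fs)` for tones and `E[ψ] = σ²`
for white noise anchor the time-domain tests.

Several features are pinned down only in their original references; the
definitions used here are explicit, configurable defaults chosen to match
each feature's name and amplitude-scaling degree:

* **PPA**: mean peak-to-peak excursion over non-overlapping 1 s
  sub-windows. **RMS1/RMS2**: raw and mean-subtracted RMS.
* **AMSA** `Σ|A(f)|·f` and **PSA** `Σ|A(f)|·f²` over the band; **CF/CP**
  power- and squared-power-weighted centroids; **SFM** geometric/arithmetic
  power-mean ratio; **SEN** band-power Shannon entropy normalized to [0,1].
* **Hu**: rescaled-range slope over dyadic blocks with the
  Anis–Lloyd–Peters small-sample correction (uncorrected R/S reads ≈0.58
  for white noise at these lengths; corrected, it centres on 0.5).
* **ScE**: slope of `log L(τ)` vs `log τ` where `L(τ)` is the mean
  absolute increment at lag τ (≈0 for white noise, ≈1 for smooth signals).
* **LAC**: log mean |autocorrelation| over lags 1–25 samples.
* **DFA1/DFA2**: detrended-fluctuation slopes over box sizes 8–32 and
  32–128 samples. Box sizes below ~8 samples were deliberately excluded:
  first-order DFA is biased high there (white noise would read ≈0.6
  rather than 0.5).
* **MSI**: median Euclidean step between successive Poincaré-plot points
  `(x(n), x(n+1))`, in µV.
* **WE**: Shannon entropy of relative energies across a 5-level db4
  wavelet decomposition (6 sub-bands). Periodization boundary mode keeps
  the transform exactly orthogonal, so sub-band energies partition the
  signal energy and the `ln 6` upper bound is exact.

Every feature's amplitude-scaling degree (0, 1 or 2) is recorded in
`HOMOGENEITY_DEGREE` and verified programmatically; the entropies are
excluded from that table because amplitude dependence at fixed `r` is
their purpose. Non-finite feature values (e.g. scale-free features of a
constant window) are flagged, never dropped.

## Evaluation

Success is the positive class and corresponds to the **larger** predictor
value; negatively-associated predictors are negated before ROC
construction with the sign recorded on the curve. The ROC has one vertex
per distinct score plus both endpoints, ties share a vertex, and the
trapezoidal AUC therefore equals the tie-corrected rank statistic
`U/(n₁n₂)` (cross-checked against scikit-learn and a brute-force pairwise
oracle). Four operating points are reported per curve: Se at Sp = 90 and
Sp at Se = 90 (linear interpolation along the curve's upper envelope —
where several vertices share a specificity the best sensitivity among
them is the attainable one), the balanced-accuracy/Youden optimum, and
the vertex closest to (0, 1).

Mann–Whitney comparisons use the exact null distribution for tie-free
samples up to n = 20 per group and the tie-corrected normal approximation
otherwise (no continuity correction, so identical groups give p = 1).

The `(m, r)` grid is 3 × 20: m ∈ {1, 2, 3}, r = 5, 10, …, 100 µV. AUC is
computed per cell per criterion; ties in the optimum break toward smaller
r, then smaller m; per-cell per-class median entropies are retained for
tolerance-sweep plots. No multiple-testing correction is applied across
the grid — the surface is descriptive. The window-length sweep re-extracts
windows at each `wl` with the same guard, recomputes features, and drops
(with a count) shocks whose records cannot supply a window.

## Pre-shock pause dynamics

Entropy trajectories slide a 3 s window in 0.5 s hops from the pause
onset, up to `min(pause − 3 s, 16 s)`; the record is band-passed once at
its native rate and each window is then resampled to 60 Hz, so a
trajectory value equals the entropy of the hand-cut window exactly.

Group trends are ordinary least squares of entropy on time (slope
reported per minute). Pooling is per-point across all selected
trajectories by default — the population-level trend; a per-shock
alternative (`pooling="per_shock"`, coefficients averaged with
between-shock standard errors) is provided because trajectory points
within a shock are serially dependent and a hierarchical reading may be
preferred. Coefficient differences between outcome groups use the
pooled-residual-variance extension of the two-sample t-test
(`s² = (SSE₁+SSE₂)/(n₁+n₂−4)`), which is algebraically identical to the
interaction/main-effect t of a dummy-coded joint regression — an identity
the tests verify to 1e-10. `time_to_cross` converts two intercepts and a
negative slope into the pause duration needed for one level to decay to
the other: `60·(a_hi − a_lo)/|b|` seconds.

## Synthetic cohorts

No public pre-shock OHCA waveform corpus exists, so the package ships a
generator that makes **no claim of biophysical VF realism**: it targets
exactly the statistical handles the method responds to.

A record is `A(t)·[sin(φ(t)) + 0.25 sin(2φ(t) + θ)]/1.03 +
0.6·irr·A(t)·η(t)` where `φ` is a carrier at the dominant frequency
(uniform in 3.5–6.5 Hz per class, inside the 3–7 Hz range typical of
human VF) jittered by an Ornstein–Uhlenbeck phase process with standard
deviation proportional to the irregularity knob `irr ∈ [0, 1]`; `A(t)`
is a slow (0.3 Hz, ±25%) multiplicative envelope around the amplitude
scale with an optional exponential decay (min⁻¹) emulating deterioration
across a pause; `η` is unit-RMS 2–12 Hz Gaussian noise. Records are 30 s
at 250 Hz with a 22 s compression-free pause before the shock by default,
mirroring the pause durations under which AEDs operate.

Cohort class defaults — success: amplitude log-normal around 300 µV
(log-sd 0.25), irregularity 0.70 ± 0.10; failure: 110 µV and 0.35 ± 0.10 —
encode the separation the method exploits (large irregular VF is
amenable). Each record's stream derives from
`SeedSequence(cohort_seed, spawn_key=(index,))`, so cohorts are pure
functions of their spec and order-independent. A `null=True` spec draws
both classes from the success distribution for calibration checks, and
`label_noise` flips labels independently.

What the generator does **not** emulate: CPR artifacts, rhythm
transitions, electrode noise, device quantization (available separately),
inter-patient spectral structure, or any physiological coupling between
waveform and survival beyond the imposed amplitude/irregularity link.
Passing tests therefore demonstrate the machinery's correctness and the
method's sensitivity to the intended waveform properties — not clinical
performance on real OHCA data.

Surrogates are iAAFT (rank-exact amplitude distribution, power spectrum
matched within iteration tolerance; 19 surrogates by default for a 0.05
one-sided rank level). On linear Gaussian processes the original's
FuzzyEn falls inside the surrogate distribution, as the null calibration
test checks.

## Problem sizes and numerical tolerances

Synthetic experiments in the tests and the acceptance script use cohorts
of 120–200 shocks with 5 s windows (N = 300 at 60 Hz), the full 3 × 20
grid, 1000-replicate null calibration for the coefficient comparison and
200-replicate slope-recovery checks — sizes chosen to make Monte-Carlo
error small relative to the asserted tolerances while keeping a full run
in the minutes range on one CPU. Implementation-equivalence checks
(vectorised vs brute force, tree vs direct, two-fit vs joint regression)
are asserted at 1e-10 to 1e-12; statistical calibrations at 3 Monte-Carlo
standard errors or binomial-appropriate margins.

## Known limitations

* The exact definitions of CP, PSA, LAC, ScE, MSI, WE, the PPA
  sub-windowing and the two RMS variants differ between published
  implementations; the ones here are documented defaults behind config
  knobs, not verified against any particular original code.
* The causal band-pass leaves a multi-second transient; analysis windows
  cut near a record's start inherit it. Records should begin several
  seconds before the first analysis window (the generator's do).
* Device bandwidth narrower than 0.5–30 Hz is not compensated before
  re-filtering; whatever signal is provided is filtered as-is.
* SampEn is undefined (flagged, not raised) when no matches exist at some
  scale — increasingly likely for small `r` and 2 s windows; FuzzyEn is
  the robust choice there.
* Pooled-point pause regressions ignore within-shock serial correlation;
  their standard errors are anti-conservative for strongly overlapping
  windows. The per-shock pooling mode is the conservative alternative.
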