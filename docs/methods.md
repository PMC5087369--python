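# Methods

## Model

A single-lead QRS window is a uniformly sampled series `y(n)`, `n = 1..p`, in
microvolts (default 2 kHz, so one sample is 0.5 ms and a typical 100 ms
complex has p = 200). The approximation model is a Gaussian RBF network with
a *shared* spread,

    ŷ(n) = Σⱼ₌₁..M wⱼ exp(−(n − cⱼ)²/(2σ²)),

with integer centers cⱼ restricted to sample locations 1..p. Sharing σ is
what gives the residual its meaning: the network can only synthesize
structure at least as smooth as the basis, so the residual e = y − ŷ
collects the sharper components — the abnormal intra-QRS potential (AIQP)
estimate. The two summary statistics are AIQP = RMS(e) and
AQR = RMS(e)/RMS(y). The estimator is linear given the centers, so the
residual scales exactly with the signal amplitude and AQR is amplitude-
invariant (this is tested to 1e-9).

## Center selection (orthogonal least squares)

All p sample locations are candidates; none are sub-sampled. At step L each
remaining candidate's RBF column is orthogonalized against the L−1 selected
columns, and its error reduction ratio

    [err] = g² (sᵀs) / (yᵀy),   g = sᵀy / sᵀs,

is the fraction of signal energy that column would newly explain. The
largest [err] wins; ties within 1e-12 relative resolve to the smaller
sample index (deterministic across platforms). The per-step quantities
(chosen center, [err], h = sᵀs, g, and the triangular Gram–Schmidt
coefficients) are recorded in an `OLSTrace` so the energy balance
Σ g²h + eᵀe = yᵀy can be verified on any fit; the suite enforces it at
1e-9 relative.

Numerical choices:

* **Orthogonalization** is classical Gram–Schmidt against the cached
  selected vectors with one re-orthogonalization pass (CGS2). A single
  classical pass loses orthogonality near the numerical rank of the
  Gaussian design (which these spreads approach quickly) and the energy
  balance degrades to ~1e-6; the second pass restores it to machine
  precision without changing which candidate wins a step. No pivoted QR is
  used — it could reorder ties.
* **Dependence guard**: a candidate whose orthogonalized vector retains
  less than 1e-12 of its own squared norm is numerically dependent and is
  excluded from the step; if the whole pool degenerates before M centers
  are placed, a `PartialSelectionError` reports how many were. The guard
  value matters: at σ = 10 the usable rank of the 200-sample design is only
  ~45, and a stricter guard (1e-10) would cut the conventional
  `AQR(2:40, 10)` grid off at M ≈ 38–41. 1e-12 keeps the grid feasible
  while still keeping the gain divisions well away from 0/0.
* **Final weights** are re-solved over the selected design matrix by
  SVD-based least squares with a machine-precision rank cutoff
  (`lstsq(rcond=None)`), not back-substituted through the triangular
  factors. The two agree in exact arithmetic; the direct solve is more
  robust, and an aggressive cutoff (e.g. 1e-10 relative) measurably
  inflates the residual of near-interpolating fits (AQR 1.6e-4 vs 2.5e-5
  at M = p, σ = 10).
* **M = p**: with one neuron per sample every location is a center, so
  greedy selection is unnecessary and is bypassed; the fit is a regularized
  interpolation and its trace records the natural-order decomposition with
  dependent columns contributing zero. The Eq.-22-style energy balance is a
  property of the *greedy* decomposition and is asserted on those fits; the
  interpolation path is covered by its own limit test (AQR < 1e-4).

Selection is nested in M (the first M centers of a longer run are the
M-center selection), which the grid code exploits: one selection per spread,
one weight re-solve per grid cell. Grid cells whose selection degenerates
are *missing*, never zero — zeros would bias the discriminant — and subjects
with missing cells are dropped from the feature table with a logged notice.

## Preprocessing

* **Signal averaging**: beats are aligned to the first beat by the integer
  lag maximizing cross-correlation, rejected when the peak normalized
  correlation falls below 0.98, and averaged. Shifts are applied
  circularly, which is harmless for beat windows with near-baseline edges.
* **Bandpass**: 40–250 Hz Butterworth of analog-prototype order 4 (8 poles
  after the bandpass transform — conventions differ, so this is stated
  explicitly). Default is zero-phase forward–backward filtering (squared
  magnitude response: edge gain 1/2 instead of 1/√2); a segment-wise
  bidirectional mode (forward over the first half, backward over the
  second) is available as `mode="segmented"` for compatibility with SAECG
  systems that avoid smearing filter ringing across the QRS. Edges are
  reflection-padded by three filter lengths.
* **QRS bounds** are detected on the XYZ vector magnitude by a sustained
  threshold crossing: threshold = noise mean + 3·SD over a user-given
  noise window, sustained for 5 ms. Onset is the first such excursion's
  start, offset the last one's end.
* **VLP indices**: fQRSD (onset→offset, ms), RMS40 (RMS over the 40 ms
  ending at the offset), LAS40 (time from the last sample above 40 µV to
  the offset; equal to fQRSD when nothing in the QRS exceeds the
  threshold). The 40 µV threshold is a parameter; the conventional value
  is the default. The measured noise RMS is reported, but gating records
  on it (e.g. at 0.7 µV) is left to the user.

## Synthetic data — what it emulates and what it does not

The generator produces the study conditions every test runs under.

* **QRS**: a sum of four Gaussian lobes (Q dip, dominant R, S dip, late
  shoulder) on p = 200 samples; RMS ≈ 607 µV, inside the 380–730 µV range
  of realistic signal-averaged complexes. The lobe widths deliberately mix
  4.75–13.5 samples: a complex made of a few equally smooth bumps is
  synthesized almost exactly by a 20-neuron network, leaving no inherent
  error, whereas realistic complexes leave several microvolts. With these
  defaults the (20, 10) fit of the clean complex leaves 6.66 µV (AQR
  1.1%), the regime in which the misjudgment phenomenon — an added AIQP
  lowering the residual by partial phase cancellation — actually occurs
  and in which the (20, 10) and (20, 12) configurations misjudge
  *different* repetitions.
* **AIQP**: white Gaussian noise filtered forward through the same
  4th-order 40–250 Hz Butterworth, 512 samples of padding on each side so
  the transient never reaches the window, then rescaled so each
  realization's RMS is *exactly* the requested value (5 µV is the
  protocol's standard amplitude) rather than merely in expectation. A long
  realization keeps ≈ 9% of its power outside the band (< 20% bound,
  consistent with 4th-order rolloff).
* **Cohorts**: 42 normal / 30 VT by default. Each subject-lead draws a
  jittered morphology (5% relative SD on every lobe parameter) and a QRS
  RMS uniform in 380–730 µV; VT subjects draw a subject-level AIQP
  amplitude from N(10, 2²) µV clipped at 0 (normals: none) realized
  independently per lead. Seeding uses spawned substreams, so repetition i
  and subject j see the same draws regardless of how many others run.

What it does **not** emulate: P/T waves, beat-trigger jitter, baseline
wander, electrode noise above the stated floor, inter-lead correlation of
morphology, or any physiological model of conduction. Passing tests show
the *estimator chain* behaves as designed under controlled conditions, not
that clinical accuracy figures transfer to real cohorts.

## Classification

Fisher's LDA with VT as the positive class: w ∝ pinv(Sw)(μ_vt − μ_normal),
pooled within-class covariance, orientation fixed so VT scores higher. With
60 correlated AQR features and 72 subjects Sw is singular; the
pseudo-inverse (relative tolerance 1e-10) is used and the collinear columns
are named in a warning. The reported operating point maximizes *training*
TPA (ties → higher specificity, then the larger cutoff); no cross-validation
is performed because the reported quantities are apparent (training-set)
performance. AUC is the normalized Mann–Whitney statistic with ties
credited ½, identical to the trapezoidal area under the empirical ROC.

## Known limitations

* The optimum (M, σ) is subject-dependent and unknown; single AQR cells
  over- or under-estimate the AIQP, which is precisely why grid
  combinations are used.
* Apparent performance with 60 features on 72 subjects is optimistic
  (training TPA of the simulated cohort saturates at 100%); the package
  reports it as such and leaves validation designs to the user.
* The greedy selector's partial-selection behavior near the design's
  numerical rank means very large M at large σ may be unattainable; the
  grid code records such cells as missing.
* Circular shifts in beat alignment assume windows with quiet edges.

## Problem sizes

Defaults used by the tests and the acceptance script: p = 200 windows,
50-repetition studies, 200-instance oracle comparisons (p ≤ 32, M ≤ 6),
a 72-subject cohort with 60 features, and 2¹⁵-sample spectra — sizes chosen
so the whole suite completes in well under a minute of CPU per module while
keeping every Monte-Carlo margin comfortable.
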