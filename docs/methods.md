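# Methods

This note documents the models and procedures the package implements, the
choices made where a convention had to be fixed, and what the synthetic data
do and do not establish.

## Task and generative agent

Each trial offers a guaranteed ("safe") water volume on one port and a
probabilistic ("risky") one on the other. Volumes are drawn independently and
uniformly from {6, 12, 24, 48} μL for each side; the risky probability is
uniform on {0, 0.1, …, 1}; the safe side is right with probability 0.5. The
flash count cueing probability is `round(10p)` and the click rate cueing
volume numerically equals the volume in μL; both mappings are recorded in
`TaskConfig` and overridable. The empirical joint offer distribution of the
original experiment is not tabulated anywhere, so uniform sampling is the
default and the offer generator accepts any configuration on the same grid.

The agent chooses right with probability
`lapse/2 + (1−lapse)·σ(w_ev·ΔEV + w_rs·x_rs + w_rws·x_rws + w_lr·x_lr + w₀)`.
The lapse is a uniform mixture *outside* the logistic so that planted weights
remain identifiable by a plain logistic fit (the fitted model has no lapse
term). Regressor coding, shared verbatim between simulator and fitter
(`choice_model.history_regressors`):

- `ΔEV` — right minus left expected value, in μL (unnormalized by default;
  a z-scoring option exists).
- `x_lr` — +1/−1 for a previous right/left choice.
- `x_rs` — (+1 if the previous choice was safe else −1) × (+1 if safe is
  right now else −1): positive means repeating the previous risk category is
  the rightward action.
- `x_rws` — 1 only if the previous trial was a *rewarded risky choice*,
  signed by the current risky side. A risky loss contributes 0.

Positive weights therefore mean "repeat / approach right". The first trial
of a session enters no conditional quantity. Safe choices are always
rewarded with the safe volume; risky choices pay with the offered
probability. Inter-trial intervals are log-normal (median 3 s, log-sd 0.5),
floored at 4 s after a choice-report-laser trial, matching the perturbation
protocol in which illumination persists 4 s into the ITI.

Three simulation-only hooks exist for validation studies and default to off:
an alternative risky win-stay weight applied after choice-report-laser trials
(planted ablation), a win-stay increment linear in (1 − p) of the won gamble
(planted graded bias), and an exponential ITI decay of side hysteresis
(planted ITI confound).

## Behavioral estimators

Efficiency compares the mean expected value of the chosen option (ratEV)
with that of a random chooser (randEV, the mean of the two offers' average)
and a maximizer (maxEV): `0.5·(ratEV−randEV)/(maxEV−randEV) + 0.5`. It is
undefined when every offer pair is symmetric (maxEV = randEV), and the
implementation raises in that case. The training criterion is the median of
all session efficiencies minus 1.5 times the IQR of the second half of
sessions; quartiles use linear interpolation (type 7), stated explicitly
because the criterion value depends on the convention.

Bias estimates are differences of conditional probabilities keyed on the
previous trial, with the 95% half-width
`z·sqrt(p₁(1−p₁)/n₁ + p₂(1−p₂)/n₂)`, z = 1.9600. "Following a risky reward"
conditions on the previous trial being a rewarded risky *choice*, not merely
a risky offer. The risky win-stay value is `P(safe|post-safe-reward) −
P(safe|post-risky-reward)`; the per-condition deltas against the
unconditional safe rate are also carried (`delta1`, `delta2`) for
figure-style summaries. Spatial win-stay and lose-switch are corrected by the
session-wide repeat and switch rates respectively; the baseline is
configurable via the returned estimate since the reference is a convention.
The graded bias bins post-risky-win trials by the exact previous risky
probability level (p > 0 only, since p = 0 cannot yield a win) and reports
the OLS slope across levels.

Laser comparisons group current trials by the *previous* trial's laser
epoch. ITI-matched controls restrict control trials to a previous ITI ≥ 4 s,
the same floor the perturbation imposes; with a hysteresis decay that is
essentially complete by 4 s this removes the apparent laser effect, while a
slower decay leaves a small residual because post-laser ITIs concentrate at
exactly 4 s whereas matched-control ITIs have a tail.

## Choice-model and psychometric fitting

The logistic model is fitted by maximum likelihood (statsmodels `Logit`),
with standard errors from the observed information. Perfect separation —
detected by non-convergence, non-finite standard errors, or coefficient
blow-up (|β| > 100, far beyond any behaviorally plausible weight) — triggers
a logged ridge fallback (penalized GLM, L2), which returns finite weights
without standard errors.

The psychometric curve uses trials where exactly one side is certain (both-
certain offers excluded), binned into 11 equal-width bins of VS − VR. The
4-parameter sigmoid is fitted by minimizing the MSE against the binned
proportions under box constraints y0, a ∈ [0, 0.5], b ≥ 0, with 20 random
L-BFGS-B starts (ftol 1e−9) and the best start returned; per-trial
likelihood fitting is intentionally not the default, matching the binned
definition of the curve.

## Neural analyses

Spike counts are binned at 50 ms and converted to Hz, then smoothed with a
centered 5-point moving mean whose window shrinks symmetrically at the edges
(so endpoints are preserved and pre-smoothing counts conserve total spikes).
Units enter analysis if they fire more than two spikes on at least half of
trials (strictly more: exactly two fails). Selectivity per task variable is
an unpaired t-test on per-trial counts in an analysis window — [0, 1] s after
trial initiation for reward history, [0, 1] s after center-port exit for
choice variables (windows are configurable; nothing canonical fixes them) —
and risky/safe choice selectivity uses rewarded trials only, so reward
delivery is matched between conditions. d′ per bin is
`|μ₁−μ₂|/sqrt((σ₁²+σ₂²)/2)`; since the absolute value is positively biased,
the mean of the same statistic over label shuffles (15 by default; tests use
100+ for tighter nulls) is subtracted, and negative corrected values are kept
(clipping would re-bias the null). Bins where both conditions have zero
variance return 0.

## Tensor decomposition

Session tensors stack per-unit trial × bin rate matrices into
neuron × time × trial arrays, each neuron divided by its maximum rate (+ε) so
the neuron factor is not dominated by high-rate units (factor units are
arbitrary anyway; the scale is a gain on the other modes). Rank-1 CP is
fitted by alternating least squares with closed-form mode updates; initial
factors are half-normal (nonnegative), which for nonnegative rate tensors
avoids sign-straddling local optima without constraining the updates — a
singular normal-equation matrix (possible when the requested rank exceeds the
effective rank) falls back to the minimum-norm solution. The best of
`n_inits` random starts by reconstruction error is returned, canonicalized to
‖w‖ = ‖b‖ = 1 with scale and any sign flips absorbed into the trial factor
and mean(w), mean(b) ≥ 0. The ALS error trace is non-increasing by
construction and asserted in tests.

The similarity index between two solutions is, per matched component, the
product over the three modes of the absolute cosine similarity — greedy
matching for rank > 1, which approximates the permutation-optimal score and
can understate similarity in adversarial cases; selected rank is the largest
with mean consecutive-initialization similarity > 0.9 (0 if none). Triggered
averages of the trial factor at lags 0–7 subtract the mean of the identical
computation on shuffled reward labels (100 shuffles by default here, where no
canonical count exists). "Reward history" for the trial-factor correlation
means the previous trial's reward indicator; an exponential-kernel history is
available but off by default.

## Unit tracking

The per-channel scale is the closed-form least-squares minimizer
`α = (x·y)/(x·x)`, which is the exact optimum of the 1-D problem that was
originally solved numerically. Session-1 templates are scaled onto session-2
(directional, kept as the convention). A non-positive α means an inverted
waveform and yields d₂ = ∞, an automatic non-match. Candidate pairs must
pass d₁ < 0.8 and d₂ < 1 and show a positive PSTH correlation with p < 0.05;
assignment is one-to-one, greedy by ascending d₁. Pairs passing the waveform
criteria but failing the PSTH check are flagged (`psth_discordant`) in place
of a manual-review stage. Null calibration computes the empirical d₁/d₂
distributions over ≥100 cross-animal pairs and reports the requested-FPR
quantiles; the operating thresholds stay at (0.8, 1).

## Synthetic data: what it emulates and what it does not

The Poisson population plants, per unit: a trial-initiation transient whose
amplitude grows after unrewarded trials (reward-history units), additive
choice-report bumps for side/risk/reward preference, and a shared across-
trial gain `g_k = 1 − γ·1{previous rewarded} + noise` — a rank-1 structure
the tensor analyses should and do recover. Waveform templates combine a
per-unit random trough/after-hump shape with log-normal channel amplitudes;
drift multiplies channels by `exp(N(0, 0.1))` (≈10% session-to-session gain
drift) and adds shape noise of s.d. 0.02 in template units. These generators
are stationary Poisson/Gaussian idealizations: no bursting or refractoriness,
no slow drift within sessions, no correlated noise between units beyond the
planted gain, no electrode movement mid-session. Passing recovery tests
therefore shows the estimators are correct and calibrated under the model
that matches their assumptions, not that real recordings satisfy those
assumptions.

## Problem sizes and numerical conventions

Parameter-recovery and estimator-consistency checks use 10⁵ simulated trials
(weights within 3 s.e.); CI-coverage checks use 100 runs of 10⁴ trials each,
about the pooled scale at which the bias CIs are used on real data (~27
sessions of ~370 trials). Tensor recovery uses 60 × 60 × 300 tensors with
Poisson noise (mode congruence > 0.99); d′ calibration uses 500 null
simulations (mean corrected d′ within ±0.02 of 0); tracking calibration uses
200 true-drift and 200 cross-animal pairs (≥95% recall and rejection at the
default thresholds). All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
outputs.

## Known limitations

- The offer generator's uniform joint distribution is a stand-in for the
  unpublished empirical offer frequencies; estimators do not depend on it,
  but absolute bias magnitudes do.
- The greedy component matching in the similarity index is an approximation
  for rank > 1 (rank-selection edge cases near the 0.9 boundary may differ
  from a permutation-optimal score).
- Waveform matching is directional (session 1 → 2); reversing direction can
  change d₁/d₂ slightly, though decisions agree in expectation.
- The behavioral estimators assume a single continuous session; no
  mixed-effects pooling across animals is provided.
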