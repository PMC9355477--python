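# Methods

`swirpupil` models the pupillometric and statistical pipeline of a
speech-in-noise recall experiment: adult hearing-aid users listen to 28
blocks of 7 sentences in 16-talker babble at an individualized
signal-to-noise ratio (SNR), repeat each sentence-final word, and
free-recall the seven words at the end of each block (the SWIR task).
The quantity of interest is the *pupil baseline* — an index of tonic
physiological arousal — and how it changes over the session while recall
performance stays flat (task habituation rather than disengagement).

This note documents the model, the defaults and their units, what the
synthetic generator does and does not emulate, the numerical choices,
and known limitations.

## Pupil preprocessing

Input is a 1,200 Hz pupil-diameter stream per eye with a validity flag
per sample. All sample windows are half-open `[start, end)`; indices are
0-based; diameters are in mm.

1. **Eye selection.** The right eye is analyzed unless the left eye has
   strictly more valid samples.
2. **Blink detection.** A centered 1 s sliding window (1,200 samples,
   clipped at the trace edges) provides a local mean and sample SD over
   the *valid* samples; a sample is blink-flagged when its diameter is
   strictly below `mean − 3·SD`. Detection is single-pass: the window
   statistics always use the original validity mask. Windows with fewer
   than two valid samples flag nothing, and a 1e-9 mm guard absorbs
   prefix-sum rounding on megasample traces so a constant window can
   never flag (the strict inequality's intent).
3. **Margins.** Each flagged run is widened by 77 samples (≈64 ms)
   before and 181 samples (≈151 ms) after — the sample counts are
   authoritative, the millisecond figures are rounded documentation —
   then overlapping intervals are merged and all covered samples are
   marked invalid.
4. **Interpolation.** Invalid stretches are replaced by linear
   interpolation between the nearest valid neighbours; leading/trailing
   gaps take the nearest valid value. The pre-interpolation validity
   mask is preserved, because the next step must see what was actually
   measured.
5. **Sentence filter.** Each sentence's epoch is
   `[onset − 1 s, offset + 1 s)` (baseline window through the end of the
   post-sentence noise). A sentence with strictly less than 60% valid
   samples — counted after margin widening, before interpolation — is
   discarded. Exactly 60% is retained.
6. **Participant filter.** A participant with strictly more than 15% of
   sentences discarded is excluded. Exactly 15% is retained.

The window alignment (centered rather than causal) and the epoch used by
the 60% rule are configurable; the defaults above are this package's
choices where the protocol leaves them open, and the test suite pins
them against an independent per-sample brute-force oracle.

A practical note on the 3-SD rule: if the dip samples of a blink remain
"valid" and occupy a fraction f of the window, they inflate the window SD
so strongly that the rule only fires for f < 0.1, i.e. dips shorter than
~100 ms, *regardless of dip depth*. Real trackers mark the occluded core
of a blink invalid, which removes it from the window statistics; the rule
then catches the depressed-but-valid transition samples around the core,
and the 77/181-sample margins remove the rest. The synthetic generator
reproduces exactly this situation.

## Baselines and recall

The *sentence baseline* is the mean interpolated diameter over
`[onset − 1 s, onset)` — the onset sample itself is excluded. The *pupil
baseline* of a block is the mean of its retained sentence baselines;
blocks with zero retained sentences become missing rows, never zeros
(zeros would bias the model). Recall is scored per block as
`100 · matches / 7`, case-insensitive exact matching against the word
the participant *repeated* (so a misperceived word that is consistently
recalled counts), duplicates counted once, order ignored. An epoch
grand-average (mean ± normal-approximation 95% CI across all sentence
epochs, aligned at sentence onset, −1 s to the next noise onset) gives
the familiar time-course figure.

## Session timeline

Defaults, in seconds: noise leads the first sentence of a block by 3 and
the others by 1, trails every sentence by 1; a 4 s silent response
interval separates sentences (2 s after the seventh), followed by a 4 s
retention interval, the recall beep, a 10 s recall window and a 7.5 s
break. Sentence audio duration defaults to 1.8 s. The recall-window and
break durations and the sentence duration are not fixed by the protocol
(free recall is untimed; breaks were "approximately 5–10 s"); they only
move the clock, not any analyzed quantity.

## Adaptive SNR procedures

The babble is fixed at 70 dB SPL, so SNR moves with the speech level.

* **Modified HINT staircase**: −0.8 dB after a correct sentence
  repetition, +3.2 dB after an incorrect one, both doubled on trials
  1–5; the update applies after every trial including the first; the
  resulting SNR is the post-final-update value (a mean-of-last-k
  alternative is available). All arithmetic is carried in integer tenths
  of a dB, so accumulated SNRs are exact. The weighted 1-up/1-down rule
  equilibrates where `0.8·p = 3.2·(1 − p)`, i.e. delivered
  intelligibility p = 0.8.
* **Training adjustment**: over four 7-sentence lists, +0 dB for 6–7
  correct last words, +1 dB for 4–5, +2 dB for 0–3, applied after each
  list.

A caveat worth stating precisely: with these large asymmetric steps the
stationary distribution of the staircase is wide (SD ≈ 2 dB) and the
logistic psychometric function is concave at p = 0.8, so although the
*average delivered intelligibility* converges to 0.8 exactly, the
*dB-domain mean* of the converged SNR sits ≈ 0.5–0.8 dB above the
inverse-logistic 80% point (a Jensen gap of order `(−p″/p′)·var/2`) for
any listener slope. Simulations of this staircase should compare
delivered intelligibility, not the raw dB mean, against the 80% target;
the test suite demonstrates both faces of this.

The simulated listener is logistic in SNR:
`P(correct) = expit((snr − srt)·slope)` with defaults srt = −3 dB and
slope = 0.5/dB (≈ 12.5%/dB at midpoint), typical of sentence-level
speech audiometry in noise.

## The mixed-model workflow

The analysis table has one row per participant × block: pupil baseline
(mm) or recall (%), with Block (1..28), Reading-Span score RS (%) and
SNR (dB) as predictors. Predictors are **centered at their grand means
and not divided by their SDs**. The unscaled-centered convention is
forced by the arithmetic of the published post-hoc slopes: with
coefficients b_SNR = −0.09 and b_RS×SNR = −0.01, the reported group
slopes −0.19 and 0.01 equal `b_SNR + b_RS×SNR · m_g` only when m_g is a
group mean of *unscaled* centered RS (±9.57 ≈ half-normal mean
0.7979 × 11.99), and the tested SNR grid −5..7 matches the raw SNR range
2.60–13.4 minus its mean 6.65. A configuration flag restores full
standardization.

**Maximal model.** Fixed: Block, RS, SNR and all interactions up to the
three-way. Random, by participant: intercept and slopes for Block, RS
and SNR with unstructured covariance. Because RS and SNR are
participant-level covariates, their random slopes are exactly collinear
with the random intercept inside every participant — the maximal model
is structurally unidentifiable, which is why such fits produce singular
warnings. These aliased slopes are removed before fitting; the maximal
*identifiable* model keeps the random intercept and Block slope.

**Estimation** is REML via statsmodels `MixedLM` (Powell search with a
default-optimizer fallback; agreement with lme4 on fixed effects and
REML log-likelihood is pinned by a test). A fit is flagged singular when
any random SD falls below 1e-6 × outcome SD or any random-effect
correlation reaches |r| ≥ 0.999, and non-convergence is treated the same
way. Note that REML point estimates of a truly zero variance component
are positive in roughly half of replicates, so the singular flag on any
single stochastic fit is advisory; the elimination loop, not the flag,
is the reliability mechanism.

**Backward elimination.** Random structure first: aliased slopes go
immediately; a slope whose own variance has collapsed (or any slope,
when no converged fit exists) is stripped next, because it *is* the
singularity; then the slope with the largest REML likelihood-ratio
p ≥ 0.1 is repeatedly dropped (df = number of covariance parameters
removed, plain chi-square, lmerTest's convention). A boundary
random-effect correlation (|r| → 1) deliberately does not trigger
stripping: in the recall model the true between-participant intercept
variance is ≈ 0 (participant variation enters through the fixed RS
term), the maximal fit then sits on the correlation boundary, and the
REML LRT — which remains valid there — is what correctly keeps the
Block slope. Elimination refits are warm-started from the previous
covariance estimate. Fixed effects second: the droppable
term (one not contained in a retained interaction) with the largest
Wald p ≥ 0.05 is repeatedly dropped with a refit each time. Marginality
is enforced among fixed terms only — a random slope may outlive its
fixed counterpart, as in the recall model (Block random slope, no fixed
Block). The full trail is recorded.

Two operating characteristics of this procedure are worth knowing.
First, a surviving null interaction (≈5% each) locks its constituent
terms in via marginality, so null *base* terms appear in final models at
~10–15%, not 5%; only the three-way interaction's retention rate is a
clean read of the per-term type-I level. Second, p-values use the Wald
z (infinite-df) reference, consistent with chi-square reporting and
slightly anti-conservative at small participant counts; no
Satterthwaite or Kenward–Roger correction is applied, deliberately.

**Derived statistics.**

* *Type II Wald chi-square*: each term is tested from a model containing
  all terms except its higher-order relatives (the full fit when none
  exist); all terms are single-coefficient, so chi2 = (β/SE)² on 1 df.
* *Marginal/conditional R²* (variance-partition form): with σ²_f the
  variance of the fixed-effect predictor, σ²_r the mean over
  observations of `z′Gz`, and σ²_e the residual variance, marginal =
  σ²_f/(σ²_f+σ²_r+σ²_e) and conditional = (σ²_f+σ²_r)/(σ²_f+σ²_r+σ²_e).
* *VIF*: 1/(1−R²_j) from regressing each fixed column on the others;
  perfect collinearity reports infinity.
* *Median split*: scores strictly above the sample median are "high"
  working-memory capacity; ties and the median itself are "low", so an
  odd sample splits (n+1)/2 low vs (n−1)/2 high (21 → 11/10).
* *Simple slopes*: `slope_g = b_SNR + b_RS×SNR · m_g` at each group's
  mean centered RS, SE by the delta method (exact here — the slope is
  linear in the estimates); the group difference is
  `b_RS×SNR · (m_high − m_low)` with a Wald z test.
* *SNR-grid contrasts*: at each centered SNR s in −5..7 (step 1), the
  predicted group difference `(b_RS + b_RS×SNR·s)(m_high − m_low)` with
  per-point unadjusted Wald tests (two groups per point).

## The synthetic generator

The generator is first-class code: it defines the conditions under which
every downstream stage is validated.

* Covariates: RS ~ Normal(41.72, 11.99) % clipped to [0, 100] (clipping,
  not truncation-renormalization — at these parameters clips are rare);
  SNR ~ Normal(6.65, 3.08) dB; age and PTA drawn similarly for
  completeness.
* Pupil baselines: `mu_ij = 3.48 − 0.01·Block_c + 0.01·RS_c − 0.09·SNR_c
  − 0.01·RS_c·SNR_c + u0_i + u1_i·Block_c` (mm, centered predictors),
  with u0 ~ N(0, 0.3), u1 ~ N(0, 0.003) and block-level residual
  N(0, 0.1). The fixed effects are the published coefficient table; the
  variance components are not published — the defaults are chosen so
  that (a) the implied conditional R² is high, as reported, and (b) the
  Block random slope is detectable at study scale (the residual-induced
  per-participant slope noise is σ/√ΣBlock_c² ≈ 0.0023 mm/block against
  τ_block = 0.003).
* Traces: the block mean held over the block at 1,200 Hz, plus an
  optional linear within-block memory ramp (default 0.02 mm per sentence
  index — the load of holding words for recall; the linear form is this
  package's choice), Gaussian measurement noise, and Poisson blinks
  (default 15/min, 0.1–0.4 s) whose occluded core is marked invalid and
  whose 20 ms transition edges stay valid, as a real tracker behaves.
  The noise is an AR(1)/Ornstein–Uhlenbeck process (marginal SD 0.05 mm,
  autocorrelation time 50 ms; 0 restores white noise): pupil traces are
  smooth, and white noise at 1,200 Hz would put ~0.13% of samples beyond
  the 3-SD threshold as isolated singletons, each dragging 259 margin
  samples with it — roughly 30% of every trace — which no real recording
  shows and which the published ~1.65% sentence-discard rate rules out.
* Recall: per block Binomial(7, p) with
  `logit p = logit(0.581) + 0.03·RS_c + (g_block + u_block,i)·Block_c`;
  the fixed Block term is zero by default (performance is stable over
  the session) and the per-participant slope heterogeneity defaults to
  SD 0.02/block on the logit scale, mirroring the finding that the
  recall model retains a Block random slope but no fixed Block effect.
  At p ≈ 0.58 the binomial SD of a block score is ≈ 18.6 percentage
  points, matching the reported recall SD of 18.31.
* Every dataset ships a `SyntheticTruth` ledger (random effects, true
  block means, blink intervals, recall probabilities); recovery tests
  never let the fitting side see it.

What the generator does **not** emulate: task-evoked pupil dilations
within a trial, gaze- or luminance-dependent diameter changes, pupil
foreshortening, slow drift or fatigue trends beyond the linear Block
effect, correlation between RS and SNR (the study sample showed high-WM
participants clustered at low SNRs, which shaped its grid-contrast
significance pattern; the generator draws the two independently), and
any acoustics. Passing tests therefore demonstrate that the pipeline
recovers what this statistical structure encodes — not that the
preprocessing would be optimal for any particular eye tracker's noise.

## Numerical choices and problem sizes

* Window statistics use prefix sums after subtracting the global valid
  mean (cancellation-safe), with the 1e-9 mm guard described above.
* Staircase arithmetic in integer tenths of dB.
* Sample indices from times by nearest-integer rounding; all windows
  half-open.
* REML fits: Powell first, statsmodels' default optimizer sequence as
  fallback; optimizer failure is recorded as a singular non-converged
  fit rather than raised mid-elimination.
* Parameter-recovery checks run at 500 participants × 28 blocks (the
  fixed-effect SEs there are 3–10× smaller than the recovery
  tolerances); elimination operating characteristics at 100 replicates
  of 100 participants; distributional checks at n = 10,000. These sizes
  make the Monte-Carlo error a small fraction of every asserted
  tolerance while keeping the default suite comfortably runnable.

## Known limitations

* Wald-z p-values (no small-sample df correction) are mildly
  anti-conservative at n ≈ 21 participants.
* The singular-fit flag depends on the optimizer's boundary behaviour;
  it is a trigger for simplification, not a test statistic.
* Recall is generated binomially but modelled as Gaussian, exactly as
  the original workflow does; at 7 trials per block the Gaussian
  approximation is crude near the 0/100% edges.
* The blink detector inherits the 3-SD rule's blindness to long
  valid-flagged dips (f ≥ 0.1 of the window); see above.
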