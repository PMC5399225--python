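# Methods

`batkit` implements the analytic chain of an exposure-based, multimodal
adult-attachment test: per-session physiological, behavioral and
linguistic streams are segmented by a themed stimulus timeline, reduced to
per-theme features, collapsed into a composite effects index per
participant, and analysed with correlation screens and cross-set
stability ANOVAs.  Because no raw recordings of this kind are publicly
deposited, the package ships a synthetic-cohort generator with planted
effects; every claim the test suite makes is a claim about recovery of
known, planted structure.

## Session model and segmentation

A session walks through `n_themes` (default 14) narrative *themes*; each
theme shows a stimulus for 15 s (*exposure*), collects a spoken answer for
25 s (*response*), and pauses 5 s (interstitial, discarded).  Theme 1 is a
neutral baseline; themes 4, 7 and 13 are the attachment-deactivating
(reassuring) themes on which the analyses focus.  All windows are
half-open `[start, end)` in 0-based ms, so a sample on a boundary belongs
to the later window.

Two score treatments individualize per-theme features: `minus_baseline`
(theme k − theme 1) removes each participant's resting level, and
`minus_previous` (theme k − theme k−1) isolates the increment over
carry-over from earlier themes.  Both are linear and agree on theme 2 by
construction; theme 1 never carries treated variants.

## Cardiac features

The interbeat-interval series is cleaned by a reproducible artifact rule:
drop intervals outside 300–2000 ms or deviating more than 25 % from the
running median of five (edge windows replicate the boundary value).  The
upstream tooling this substitutes for does not publish its algorithm, so
the rule is a documented convention, not a reimplementation.

Time-domain HRV uses the conventional definitions — SDNN with the sample
(n−1) standard deviation, RMSSD over successive differences, NN50 counting
differences strictly greater than 50 ms, pNN50 as its percentage.  These
are verified against a brute-force reimplementation to 1e−9.

Frequency-domain HRV resamples the RR tachogram by cubic spline at 4 Hz,
linearly detrends it, and integrates a Welch periodogram over the
conventional bands (VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.40 Hz).
Normalized units are band/(LF+HF)×100, so `lf_nu + hf_nu = 100` is an
identity wherever LF+HF > 0.  A window of at least 30 s is required; per
theme the spectral features are computed on the combined
exposure+response window (40 s by default), since 15 s alone is below the
spectral-resolution minimum for the LF band.

The Baevsky stress index is `SI = AMo / (2 · Mo · MxDMn)` with a 50 ms
histogram aligned at 0 ms, Mo the modal-bin midpoint in seconds, AMo the
modal-bin share in percent, and MxDMn the interval range in seconds; ties
between modal bins break toward the lower bin.  Bin alignment changes SI
materially, so fixing it makes results bit-reproducible.  The formula
variant and units are a stated convention (the classical AMo(%) /
(2·Mo(s)·MxDMn(s)) form).

## Electrodermal features

The decomposition is a smoothing surrogate for deconvolution methods:
tonic is a 30 s moving median of the 0.5 s moving-average-smoothed
signal, and phasic is defined as raw − tonic, so tonic + phasic
reconstructs the input exactly.  The 30 s median width was chosen because
a skin-conductance response with a 1 s rise and 4 s decay spans roughly
15 s; a median window must be long relative to that for isolated
responses to stay phasic (measured tonic leakage is ~1 % at 30 s versus
~13 % at 10 s).  Deconvolution-based decomposition is an explicit
non-goal.

SCRs are detected trough-to-peak on the phasic component with a minimum
amplitude of 0.01 µS (a common threshold in the psychophysiology
literature).  The per-window aggregate `scr_sum` is the sum of detected
amplitudes; sum rather than mean or count is a configurable choice, since
the aggregation the original analysis used is not specified.  Tonic level
is computed but excluded from the composite index because it is only
meaningful over much longer recordings.

## Composite effects index

Features are z-scored across participants within a stimuli set (sample
SD; zero-variance or under-observed cells are dropped and logged), then
summed into a desirable group (HF power in normalized units, SDNN, RMSSD,
NN50, pNN50, the breathy-voice feature H1−H2, the positive-expression
composite, head size) and an undesirable group (Baevsky SI, mean HR,
gaze-away fraction, the tense-voice feature Rd, the negative-expression
composite, SCR), over the requested themes, available phases and
variants; the index is the desirable sum minus the undesirable sum.

Design choices:

* Redundant features are excluded so information is not double counted:
  LF in normalized units and the LF/HF ratio (determined by HF nu), HF in
  percent and absolute power (HF nu controls for VLF), mean/median RR
  (redundant with HR), individual expression channels (contained in the
  two composites), phasic maximum (redundant with SCR sum) and tonic
  level.  Word-category features stay out of the index entirely because
  they have no single desirable direction.
* The raw variant is summed together with both treatments by default; a
  flag restricts the sum to treated variants only.
* Missing contributions enter as 0 — the cohort mean after z-scoring —
  with a per-participant missingness count, keeping the index defined
  under partial modality coverage.
* H1−H2 is grouped desirable (higher = breathier = more relaxed) and Rd
  undesirable; the grouping ships as an editable JSON ledger.

With no missing values the index necessarily averages 0 across
participants; it is invariant to location shifts of any raw feature and
to participant order.

## Statistics

The exploratory screen correlates every feature (averaged over the theme
scope that matches each ground-truth measure: partner questionnaire →
theme 7; the general projective measure → mean of 4, 7, 13; the
mother/father/partner interview models → themes 13, 4, 7) with that
measure, pairwise-complete.  Pearson is used when at least 30
participants carry the measure, Spearman otherwise — generalising the
small-sample rationale to an explicit cutoff.  Spearman P-values are
exact by full permutation enumeration for n ≤ 8 (the null distribution is
cached for tie-free ranks) and t-approximate beyond; 9!–10! enumeration
would add cost without materially changing any decision.  No
multiple-testing correction is applied by default — the composite index
is the answer to multiplicity — but Bonferroni and Benjamini-Hochberg
modes exist.  An expected-sign table tags significant correlations as
theory-consistent or not.

Cross-set stability uses a one-way within-subject ANOVA per feature
(complete cases, features averaged over themes 4/7/13 per set).
Mauchly's test uses the second-order chi-square approximation (as in
SPSS and ezANOVA); when it rejects at .05 both degrees of freedom are
multiplied by the Greenhouse-Geisser epsilon, which equals 1 exactly at
k = 2.  The implementation is closed-form and is verified against
pingouin to 1e−6 on random tables.  The multiple-comparison ledger makes
the no-Bonferroni argument concrete: 46 features × 3 sets = 138 F tests,
and .05/138 ≈ .0003 would be an unusable alpha at this sample size.

## Synthetic cohorts: what is emulated and what is not

Each participant gets a latent standard-normal security trait z, fixed
across sets.  Per modality m, an expressed trait
`u_m = r_m z + sqrt(1 − r_m²) ε` carries the planted signal, so the
population trait–feature correlation is approximately the configured
`effect_size` r_m (default 0.5 on all modalities) independent of modality
gain.  On the deactivating themes u_m shifts:

* RR dynamics: `RR(t) = 800 + A_LF sin(2π·0.1t) + A_HF sin(2π·0.25t) + N(0,10)` ms,
  with A_HF = 25·(1+0.30u), A_LF = 25·(1−0.15u), mean RR +20u ms.  The
  oscillators sit squarely inside the standard LF/HF bands so spectral
  extraction is verifiable; the asymmetric gains keep every desirable
  time-domain feature (SDNN included) shifting upward while LF share
  falls.
* EDA: linear tonic drift plus Poisson-arriving bi-exponential SCR pulses
  (1 s rise, 4 s decay; base rate 0.10/s, base amplitude 0.30 µS), with
  rate and amplitude scaled by (1−0.30u).
* Expressions (evidence units, frame noise SD 0.5): positive composite
  +0.5u, negative −0.5u, individual channels with proportional shares;
  gaze-away is Bernoulli with a −1.0u logit shift from a 0.2 base rate;
  head size 100·(1+0.05u).
* Voice: H1−H2 = 1+0.5u, Rd = 1−0.5u (response-level noise SD 0.2).
* Word frequencies: Dirichlet over ten categories plus a bulk remainder,
  with ±0.4u log-weight shifts on attunement- vs distress-flavoured
  categories.

Ground-truth instruments are 0.8z + 0.6·noise; the interview-based scores
default to 40 % coverage, mirroring the fact that only a subset of a real
cohort completes the long-form interviews (which also exercises the
small-n Spearman path).  Missingness can additionally drop whole
modalities per participant per set.

Rates are wristband-class: EDA at 4 Hz, video analysis at 10 Hz (a
tractability choice; consumer webcams run faster, but per-phase means at
10 Hz are already estimated to ±0.04 evidence units).

What the generator does **not** emulate: real effect sizes (none are
published at feature level; defaults are chosen for testability),
non-stationary baselines, motion artifacts beyond the cleaning rule's
reach, correlated modality dropout, respiratory coupling, or any actual
stimulus content.  Passing tests therefore demonstrate that the pipeline
recovers structure it was designed to detect under its own stated model —
internal validity — not that the instrument measures attachment in
humans.

## Problem sizes and numerical conventions

The recovery experiments use cohorts of n = 200 over 20 seeds (planted
effect 0.5), the null index calibration n = 60 over 50 seeds, and the
cross-set stability null n = 10 × 3 sets over 50 seeds with 46 feature
keys (matching the study-scale feature count); the reproduction script
uses 5/20/20 seeds for the same experiments.  Degenerate inputs follow
one convention throughout: features that cannot be computed are missing
with a reason code (never zero), zero-variance cells are dropped from
z-scoring, and modal-bin and ranking ties break toward the lower bin /
lexicographic id.

## Known limitations

* The artifact rule, EDA decomposition and SCR aggregation are documented
  surrogates for unpublished proprietary algorithms; absolute feature
  values are not comparable to those tools, though directions and
  rank-orders are.
* The per-theme feature schema is the closure of what this package
  computes; a schema audit reports achieved counts rather than asserting
  any external total.
* Raw video, audio and transcription are out of scope: expression
  evidence, gaze, paralinguistic vectors and word-category frequencies
  are inputs, not computed from media.
* Stimulus-selection thresholds (minimum fitness per theme) are not
  published; they default to 0 and are configurable, preserving the
  gating mechanism without inventing values.
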