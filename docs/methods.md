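# Methods

This note documents the models, defaults and numerical choices behind
`typoclust`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, and where
the open design decisions were resolved.

## 1. Synthetic cohort generator

The generator emulates a fear-elicitation study: `n_volunteers` participants
(default 47), each exposed to `stimuli_per_volunteer` audiovisual stimuli
(default 14, half labeled fear), with BVP, GSR and SKT recorded at 100 Hz.
Volunteers are drawn from `n_typologies` latent typologies (default 4)
assigned round-robin and shuffled by seed, so every typology holds at least
`floor(N/G)` members; `typology_weights` overrides this to engineer
under-sized groups for exercising the merge rule.

Signal models, chosen as the minimal processes that carry the feature
classes the extractor measures:

* **BVP** — a two-harmonic pulse `sin φ + 0.3 sin(2φ + 1)` driven by an
  instantaneous rate with slow sinusoidal variability (3 % at 0.25 Hz, 2 % at
  0.1 Hz), a 0.05 Hz drift of amplitude 0.5, and white noise (σ = 0.05).
  Volunteer base rates are N(70, 5²) bpm; fear adds the typology's
  `hr_shift` (bpm).
* **GSR** — tonic level N(8, 1.5²) µS with a small random drift, plus
  Poisson-arriving skin-conductance responses shaped
  `exp(−t/3) − exp(−t/0.7)` (seconds). The base arrival rate is U(1, 3)
  events/min with log-normal amplitudes around U(0.3, 0.5) µS; fear adds
  `scr_rate_shift` (events/min) and `scr_amp_shift` (µS).
* **SKT** — baseline N(33, 0.5²) °C, linear drift N(0, 0.02²) °C/min, three
  slow sinusoids (≤ 0.07 Hz) and white noise; fear adds `skt_slope_shift`
  (°C/min).

What the generator deliberately does **not** reproduce: sensor artifacts,
motion noise, respiration coupling, inter-stimulus carry-over, or any
distributional claim about real recordings. Consequently, pipeline tests on
synthetic cohorts demonstrate *algorithmic* correctness (recovery of known
structure, directionality of effects), not field performance on real data.

Default effect sizes span a palette of plausible sympathetic responses
(heart-rate shifts of ±4–30 bpm, 0.5–8 extra SCRs/min, 0.05–1.2 µS amplitude
shifts, ∓0.04–0.5 °C/min slopes). Tests that require *well-separated*
typologies use the strong end of that palette explicitly.

## 2. Preprocessing

* BVP FIR stage: windowed-sinc (Hamming) with 101 taps at 100 Hz; the design
  cutoff of `firwin` is the half-amplitude point, placing −6 dB at 3.5 Hz.
  The filter is applied with its group delay compensated (reflection
  padding), so the stage is zero-phase while keeping the single-pass
  magnitude response.
* Drift removal: the low-frequency drift is *estimated* by a zero-phase
  order-2 Butterworth low-pass at 0.2 Hz and subtracted. Forward–backward
  filtering uses Gustafsson initial conditions; plain padded filtfilt leaves
  ~1e−7 relative asymmetry with poles this close to the unit circle, while
  the Gustafsson method is symmetric to ~1e−14.
* GSR/SKT: order-4 zero-phase Butterworth at 2 Hz, then a 1 s moving average
  (100 samples) and a 0.5 s moving median (51 samples — odd, for a centered
  window), edges reflected. The stage order (low-pass → average → median)
  means a single-sample spike is smeared by the linear stages before the
  median sees it; it is suppressed to below 2 % of its height rather than
  removed exactly, and a step input is monotone only up to the low-pass
  stage's ~5e−5 Gibbs ringing.
* Windows: 20 s length, 10 s overlap, starting at t = 0; trailing samples
  that do not fill a window are dropped. Other sampling rates are polyphase
  resampled to 100 Hz before filtering.

Exact FIR/Butterworth orders are not dictated by the methodology; the values
above are the package defaults and are configurable in `FilterConfig`.

## 3. Feature registry

The 57-feature registry (31 BVP = 4 time + 12 frequency + 15 non-linear;
20 GSR = 9 + 3 + 8; 6 SKT = 4 + 2) is this package's concrete compilation of
standard HRV, electrodermal and temperature descriptors; the registry module
is the single source of truth for names and order and is exported by
`registry()`. Notable conventions:

* BVP inter-beat intervals come from peak detection (min distance 0.3 s,
  prominence 0.5 σ); HRV band powers (VLF/LF/HF) from a 4 Hz interpolated
  tachogram. With 20 s windows the VLF/LF estimates are coarse — they are
  retained as registry members, not as calibrated HRV measurements.
* GSR is decomposed into a tonic level (double 2 s moving average) and a
  phasic residual; SCRs are peaks with prominence ≥ max(0.01 µS, 2 × median
  |phasic|). The mean skin-conductance level feature is the plain window
  mean.
* Sample entropy, approximate entropy (m = 2, r = 0.2 σ, Chebyshev) and DFA
  run on 4× decimated windows (2000 → 500 samples) for tractability; this
  preserves their ordering across conditions, which is all downstream stages
  use. Degenerate inputs (constant windows, too few beats) map to 0 rather
  than NaN so vectors stay finite.
* Z-scoring is per volunteer with the sample (n−1) standard deviation;
  constant columns map to 0 with a warning. At enrollment time a new
  volunteer is normalized with their own window statistics — no labels are
  needed, mirroring the individualized normalization of the training side.

## 4. Typology clustering (M1)

`D′` columns (mean/std per feature per class; 228 for 57 features and two
classes) are standardized across volunteers before Ward clustering —
without this, high-variance columns would dominate the Euclidean geometry.
The Dunn index uses the classical definition (minimum inter-cluster point
distance over maximum cluster diameter); an all-singleton partition has zero
diameter and scores +∞ by convention, which can only win when the allowed
`k` reaches the number of volunteers — cohorts should therefore have
N > k_max (the defaults satisfy this).

Ties in the `k` search go to the smallest `k`; all other ties (nearest
centroid, nearest merge target) go to the lowest index. The minimum-size
rule merges the smallest violating cluster into the cluster with the nearest
centroid, recomputing centroids after each merge, until every cluster holds
at least `ceil(0.15 N)` volunteers; a merge that would collapse the
partition to a single cluster raises instead of silently degenerating.
The 15 % threshold is applied to volunteers (the rows of `D′`).

## 5. Enrollment (M2)

Internal clusters are searched in [4, 6] with the same Dunn-guided Ward
procedure, on the TC's (volunteer-normalized) observations without further
column standardization, so IC centroids live in the same R^57 as incoming
observations. The minimum-size rule is *not* applied to ICs — it exists to
guarantee enough training data per TC model, which ICs do not affect. The
enrollment score is the literal sum (not mean) of each observation's
distance to the nearest IC centroid of a TC; both reductions rank TCs
identically for a fixed observation set.

## 6. Classifier

The cost-weighted vote `p = c·k⁺/(c·k⁺ + k⁻)` is this package's concrete
reading of a "misclassification cost" hyperparameter for KNN: `c = 1`
reduces exactly to the unweighted vote, and `p` is monotone in `c`.
Hyperparameters (cost ∈ [0.5, 2.5] continuous, neighbors ∈ [20, 100]
integer, metric ∈ {Euclidean, Manhattan}) are tuned by a Gaussian-process
surrogate (Matérn ν = 2.5) with expected-improvement acquisition over 30
evaluations (a third random initialization), each scored by stratified
5-fold CV F1. Feature selection: mRMR uses the mutual-information-difference
scheme on 8-bin quantile-discretized variables (up to 30 features); SFS is
scikit-learn's sequential forward selector with an F1 tolerance stop;
mRMR-Boruta screens with a random-forest shadow-feature test (15 rounds,
one-sided binomial p < 0.05) before mRMR ranking.

LASO splits one volunteer's stimuli in half, stratified by label (odd class
counts are balanced by seeded assignment of the leftovers), so windows of a
stimulus never straddle the train/test boundary. Evaluation harness fits
clip the neighbor count to the available training size for small scopes.

## 7. Fusion and evaluation

Entropy uses the natural log with probabilities clipped to [1e−12,
1 − 1e−12]; only comparisons and ratios of entropies are consumed, so the
base cannot change a fused label. Per-stimulus probabilities are the means
of window probabilities. The decision threshold is exactly 0.5 → positive;
type-2 entropy ties go to the personalized model; type-3 entropies are
floored at 1e−12 before inversion. Per-cluster type-1 contribution indices
are configuration, selected on validation data by sweeping α over
{0, 0.05, …, 1}.

Accuracy and F1 (of the fear class, zero-division → 0) are computed per
window, averaged across volunteers within a scope, and reported on the
percent scale; cluster-level figures combine into a single number weighted
by volunteer counts, `m_avg = Σ n_c m_c / Σ n_c`. The three validation
indices are: performance (a TC's model on its own volunteers' held-out
halves), robustness (the same model on all other volunteers' held-out
halves), and the M1-vs-M2 assignment-agreement percentage. The 70–30
volunteer partition is seeded, stratified by generator typology when ground
truth is available.

## 8. Problem sizes

Tests and the acceptance script run scaled-down cohorts — 12–16 volunteers,
6–12 stimuli of 30–40 s — chosen so latent structure is identifiable (the
number of volunteers always exceeds the cluster-search upper bound) while a
full pipeline run stays in the seconds range; the generator's defaults keep
the full study geometry (47 × 14 × 60 s) for users who want it.

## 9. Known limitations

* The feature registry reproduces the documented counts and group structure,
  not any specific laboratory's exact feature set.
* Dunn-guided Ward clustering is a fixed choice; no alternative linkage or
  validity index is offered, and the Dunn index's preference for compact,
  well-separated partitions is inherited.
* No online re-clustering: enrollment never updates TCs or ICs.
* Fusion combines exactly two models (personalized + general) and is not
  trainable.
* Synthetic-cohort results bound what the tests can claim; real recordings
  will add artifacts and label noise the generator does not model.
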