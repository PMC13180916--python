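# Methods

`cogspeech` implements a multidomain speech-analysis pipeline for
screening cognitive decline: feature extraction from three spoken tasks,
CSF-based ATN biomarker labeling, wrapper feature selection with
machine-learning model training, and Shapley-based auditing. This note
records the models and procedures, the parameters that matter, what the
synthetic generators do and do not emulate, and the design decisions
taken where the design was genuinely open.

## Tasks and data model

Each subject contributes three recordings with annotated transcripts:

- **IMG** — picture description (Cookie-Theft-style scene),
- **SVF** — one-minute semantic verbal fluency (animal naming),
- **PPE** — a positive personal experience narrative.

Transcripts carry universal POS tags, and optionally constituency trees
(Penn bracketing) and dependency arcs (CoNLL-U). Audio is mono PCM WAV
resampled to 16 kHz on load. Subject records carry diagnosis (SCD,
naMCI, aMCI, ADD, non-AD dementia), age, sex, education, MMSE, seven
cognitive composite scores and optional CSF analytes.

Content words are {NOUN, PROPN, VERB, ADJ, ADV}; everything else is
treated as functional. Token normalization is lowercase plus
leading/trailing punctuation stripping; accent folding is configurable
and off by default because the Spanish norm lexicons carry accents.

## Acoustic features

Low-level descriptors (LLDs) are computed on 20 ms frames with a 10 ms
hop and smoothed with a symmetric 3-frame moving average (the window
shrinks at the edges; NaN frames — unvoiced pitch — stay NaN). The
inventory follows a minimal prosodic/spectral parameter set: log-F0,
jitter, shimmer, loudness, HNR, formants 1–3 (frequency, bandwidth,
relative energy), alpha ratio, Hammarberg index, spectral slopes in
0–500 and 500–1500 Hz, H1−H2, H1−A3, spectral flux and MFCC 1–4.
Algorithmic choices, all unit-tested on synthetic signals:

- **F0**: normalized autocorrelation with a bias-corrected (unbiased)
  normalization, computed on a 50 ms window centered on each 10 ms hop —
  a 20 ms frame cannot resolve the 27.5 Hz floor (period ≈ 36 ms).
  Search range 27.5–600 Hz; among local maxima within 90% of the global
  peak the shortest lag wins (guards against subharmonic octave errors);
  parabolic interpolation refines the lag. Reported as
  12·log2(f0/27.5) semitones. A frame is voiced when the
  autocorrelation peak exceeds 0.45 and frame RMS exceeds 1e−5.
  Recovery error on synthetic tones 80–400 Hz is <0.1% at SNR ≥ 20 dB.
- **Jitter/shimmer**: cycle markers are peaks of the zero-phase
  band-passed fundamental (0.6–1.5·F0), refined parabolically; jitter =
  mean |ΔT|/mean T over consecutive cycle lengths, shimmer = mean
  |Δ amplitude| in dB. The raw waveform is not peak-picked directly
  because a harmonic complex can carry several competing maxima per
  period.
- **Loudness**: power-law-compressed frame RMS (rms^0.6), a perceptual
  approximation chosen so that digital silence maps to exactly 0 (a dB
  scale has no finite floor).
- **Formants**: LPC order 12 at 16 kHz (autocorrelation method,
  Levinson-Durbin) with root solving; bandwidth from root radius;
  relative energy as band power (±100 Hz) over total, in dB.
- **Spectral balance**: alpha ratio = 10·log10(E(50–1000)/E(1000–5000));
  Hammarberg = peak dB 0–2 kHz − peak dB 2–5 kHz; slopes by linear fit
  to the log-power spectrum within band (dB per kHz).
- **MFCC**: 26 triangular mel filters, orthonormal DCT-II,
  coefficients 1–4.

Functionals per LLD: mean, coefficient of variation (0 when the mean is
0), linear-interpolation quartiles, IQR, mean of positive and of
negative consecutive differences (0 when none), biased sample skewness
and excess kurtosis. SD is sample (n−1). All features are computed over
voiced frames, except loudness (all frames); alpha ratio, both slopes
and Hammarberg are additionally summarized over unvoiced frames.
Whole-signal statistics (12-bin chromagram, RMS, zero-crossing rate,
onset strength, spectral bandwidth/centroid; mean/SD/skew/kurtosis each)
and one autocorrelation tempo estimate complete the set, along with
voiced/unvoiced segment-duration statistics from the voice-activity
segmentation.

Voice-activity detection is a pluggable contract `(clip) →
Segmentation`. The built-in backend marks frames voiced when energy
exceeds 0.1× the median of the top-decile frame energies and
periodicity exceeds 0.45, then merges intervals bridging gaps < 0.1 s.
External diarization output can replace it.

Bit-compatibility with any specific feature-extraction toolkit is not
claimed; the definitions above are the contract.

## Lexical features

POS-category proportions (nouns, verbs, adjectives, adverbs,
auxiliaries, adpositions over non-punctuation words) and the
adjective:noun, adjective:verb, noun:verb cross-ratios — IMG and PPE
only, zero denominators flagged missing.

**MTLD** is bidirectional: a factor completes when the running
type-token ratio drops strictly below the threshold (the completing
token starts a fresh window); the trailing partial factor counts
(1 − TTR_end)/(1 − threshold); score = mean of N/factors over the
forward and reverse passes. A text that never dips below threshold is
scored N (documented convention). Thresholds 0.65/0.70/0.75, computed
on all words and again on content-only tokens (nouns, verbs,
adjectives, adverbs). **MATTR** uses a 10-token window with a 5-token
stride over full windows (whole-sequence TTR when shorter), content-only
per the study protocol, with an all-token variant also emitted since
the protocol leaves it open. Richness indices with N tokens, V types,
natural logs: Guiraud V/√N, Herdan lnV/lnN, Maas (lnN−lnV)/(lnN)²,
Uber (lnN)²/(lnN−lnV) (missing when V = N). Word-frequency statistics
are mean/SD of log10 frequency over in-lexicon content tokens, with an
out-of-vocabulary count.

## Syntactic features (IMG and PPE)

From constituency trees: the **Yngve score** numbers each node's
children right-to-left from 0 and scores a word as the sum along its
root-to-leaf path (left-branching memory load); the **Frazier score**
ascends from a word's preterminal while the current node is the
leftmost child of its parent, scoring each parent 1 — 1.5 for
sentence-type labels (configurable, default {S, ROOT, SBAR, sentence}).
A parentless preterminal (single-word tree) scores itself once. This is
the Roark-lineage scoring, fixed against hand-worked values
(the/dog/barks → 2.5/0/1). Depth features are the maximum and mean
root-to-leaf edge counts. From dependency arcs: the maximum and mean
out-degree of each sentence's root token. All scores are unweighted
means over sentences; sentences without parses are skipped.

## Semantic features

Age-of-acquisition statistics (mean/SD over in-lexicon words plus
coverage) apply to all tasks. For IMG and SVF, static word embeddings
are trained on the cohort's own transcripts with function words
excluded: a positive-PMI co-occurrence matrix (symmetric window,
default 5) factorized by dense truncated SVD with rows scaled by √σ.
This count-based estimator factorizes the same shifted-PMI objective
that skip-gram approximates, and it is exactly reproducible (dense
LAPACK SVD, fixed component signs) — iterative sparse solvers were
rejected because their restart draws come from process-global state on
degenerate spectra. Defaults d = 100, window 5; the training manifest
records corpus hash, dimensions and seed.

Distance features: mean/SD Euclidean distance and cosine similarity
over consecutive in-vocabulary content-token pairs and over all
unordered pairs (both emitted; the protocol's phrase "pairwise
distances" is ambiguous between the two).

Spectral clustering runs per task on the whole vocabulary: affinity
(1 + cosine)/2, sparsified to the symmetrized 10-nearest-neighbor
graph, sklearn spectral clustering with seeded k-means label
assignment, labels canonicalized by first vocabulary occurrence.
k is not fixed by the protocol; default k = 10 per task,
config-exposed. Cluster centroids are mean embedding vectors. Subject
trajectories over the cluster sequence of in-vocabulary tokens
(out-of-vocabulary tokens dropped, not nearest-mapped) yield: distinct
clusters visited, transitions (consecutive pairs differing), words per
visited cluster (mean/SD), revisits (transitions into an
already-visited cluster), and mean/SD Euclidean/cosine statistics over
pairs of visited-cluster centroids.

## Task-specific features

**IMG** — content information units (CIUs) with normalized image
coordinates in [0,1]² (origin top-left) and quadrant labels. Mentions
are found by leftmost-longest keyword matching (multiword keys
supported). Features: distinct CIU count; mean Euclidean distance
between consecutive *distinct* mentions (self-transitions travel 0 and
are excluded from that mean, matching the travel metaphor); mean/SD of
|Δx| and |Δy|; words per CIU by onset-to-onset attribution (tail tokens
to the last mention); concreteness (mention tokens / total words);
consecutive and non-consecutive repetition counts; same-quadrant
transition count and the cross:same ratio (missing when the denominator
is 0, not infinity); per-quadrant coverage. The Cookie-Theft CIU
inventory ships as an editable resource; tests rely on the synthetic
scene generator, so the resource is not load-bearing.

**SVF** — the animal sequence is the ordered list of lexicon matches
with variants canonicalized. Repetition gaps count animal mentions
strictly between a repeat and its *most recent* prior occurrence,
measured in the animal-only subsequence (intrusions excluded) — the
protocol is ambiguous here; this is the documented choice.

**PPE** — sentiment is a backend contract returning a
positive/negative/neutral triple (sums to 1) plus six emotion scores.
The shipped backend is deterministic keyword counting over configurable
valence/emotion lists (neutral = 1 for keyword-free text); transformer
backends can be registered under the same contract.

## ATN labeling

CSF thresholds, strict inequalities: A+ iff Aβ1-42/Aβ1-40 < 0.069;
T+ iff P-tau181 > 54 pg/mL; N+ iff T-tau > 412 pg/mL. Missing analytes
yield null flags.

## Modeling

**Split.** 80/20 stratified by diagnosis. After each candidate split,
per-group Mann–Whitney U tests (age, education) and chi-square tests
(sex) compare train vs test at Bonferroni-corrected α = 0.05; failing
splits reshuffle with an incremented seed (default 25 retries), after
which the best-seen split is returned with a warning. The split result
carries a provenance token; evaluation refuses overlapping train/test
ids.

**Objectives.** Balanced accuracy (BA, the mean of sensitivity and
specificity) for classification, MAE for regression, both via 5-fold
CV (stratified for classification).

**NSGA-II selection** (sklearn `SelectorMixin` estimator): boolean-mask
chromosomes, objectives (maximize BA or minimize MAE, minimize feature
count), inner model SVM (RBF, standardized). Binary tournament on
(rank, crowding), uniform crossover p = 0.9, per-bit mutation 1/n,
elitist environmental selection; all-zero masks are repaired by
activating one random feature; objective evaluations are cached by
mask. Defaults 100×50 (tests and acceptance use 40×20). The chosen
mask is the front member with the best performance, ties toward fewer
features — this knee rule is this package's convention.

**VLPSO selection**: a compact but faithful variable-length particle
swarm. Features are ranked by relevance (ANOVA F or |r|); the swarm is
split into divisions whose lengths cover increasing prefixes of the
ranking; positions in [0,1] select a feature above 0.6; comprehensive
learning (per-dimension exemplars from tournament-selected personal
bests, learning probabilities on the standard CLPSO curve); inertia
0.9→0.4, c = 1.49445, velocity clamp ±0.2; when the global best
stagnates for 7 iterations the division lengths are renewed around the
best particle's length. Inner model KNN (k = 5); fitness is BA with a
fewer-features tie-break.

**TPE search**: the first `n_random` of `n_iter` configurations are
uniform; afterwards each parameter is proposed by maximizing the
density ratio between the top-γ (0.25) observed configurations and the
rest (Gaussian KDE for numeric parameters — log space where declared —
count-weighted for categorical). Defaults 1000/500 per the study
protocol, reduced in tests. Search spaces per family ship as a
versioned YAML resource.

**Models**: RF and SVM (sklearn), XGB (xgboost), KNN, plus decision
tree and logistic/linear regression as clinical baselines.
Distance/margin models are standardized inside a Pipeline. Evaluation
reports Acc/Pre/Sen/Spe/AUC/BA (AUC rank-based with midrank ties;
sensitivity on the clinically positive class) or MAE/R²/Pearson r. No
resampling for class imbalance — BA is the optimization target.

## Explainability and auditing

Decision trees and random forests get **exact path-dependent tree
Shapley values** implemented here (polynomial-time path algorithm with
cover weighting); base value + per-feature attributions reproduce the
model output per sample to machine precision, verified against
exhaustive-subset Shapley enumeration on small trees. XGB models use
the booster's native contribution computation (margin space). SVM, KNN
and linear models use seeded permutation-sampling Shapley values
against a background sample capped at 100 rows.

Domain importance divides each domain's summed mean-|φ| by its feature
count, so large domains do not accumulate importance by size alone.

The bias audit: chi-square goodness-of-fit of misclassified samples'
sex counts against full-dataset proportions; Welch t-tests of age and
education, misclassified vs correctly classified; per-domain per-sample
total |φ| compared between sexes by Welch t-tests; flags at unadjusted
α = 0.05. The sex test compares against the full dataset (which
contains the misclassified subset), making it conservative by
construction — its null flag rate sits below α, while the t-based tests
are calibrated (verified by null simulation).

## Synthetic generators

All generators are seeded through named substreams of one master seed.

- `gen_transcript`: Zipfian token stream (configurable exponent and
  vocabulary) with per-type POS from a profile, random binary
  constituency trees and star-ish dependency arcs. Emulates type–token
  structure; it does not emulate Spanish morphology, syntax or
  discourse coherence.
- `gen_svf_sequence`: exact planted repetition structure (gap multiset
  realized in a feasible order), plus intrusions.
- `gen_audio_clip`: harmonic complexes (1/h rolloff) with known F0 and
  voicing pattern, optional white noise at a stated SNR. No formant
  structure, no prosody.
- `gen_ciu_scene`: synthetic CIU lexicon with coordinates and a token
  stream realizing a requested trajectory; truth is an independent
  recount.
- `gen_cohort_table`: group-shifted Gaussian features (effect size d
  per unit effect level), standard-normal noise features, composites as
  a seeded linear combination of informative features with noise scaled
  to a target R², CSF analytes as lognormal mixtures placed strictly on
  the intended side of the ATN thresholds, demographics with optional
  group confounds. The closed-form Bayes AUC for the extreme group
  contrast is Φ(‖δ‖/√2).
- `simulate_speech_cohort` routes group differences through the real
  extraction path: impaired groups draw from a smaller vocabulary with
  a steeper Zipf exponent and produce more fluency repetitions.

Passing tests on these generators demonstrate algorithmic correctness
and statistical behavior under known truth; they do not demonstrate
clinical validity on real speech, which differs in noise structure,
disfluency, annotation error and demographic correlation.

## Problem sizes and numerical conventions

Selection-recovery checks use n = 400 subjects, 5 informative features
at d = 1.2 among 45 noise features, NSGA-II 40×20, TPE 50 iterations,
over 20 seeds; the Pareto-front equality check enumerates all 2¹²−1
masks of a 12-feature problem. The regression check plants R² = 0.7
(expected test r = √0.7 ≈ 0.84) with 20 features. The end-to-end
determinism check runs 30 subjects with reduced selection budgets;
byte-identical artifacts are required across repeated runs, which is
why all CSV/JSON writers use deterministic float repr and sorted keys.

Quantiles are linear-interpolation; SD is sample (n−1); skewness and
kurtosis are biased sample moments with kurtosis reported as excess;
degenerate denominators yield missing values (NaN), never infinities.

## Known limitations

- No ASR, POS tagging or parsing: annotation files are inputs.
- The acoustic LLDs are this package's documented definitions, not a
  re-implementation of any proprietary toolkit's internals.
- The embedding trainer is count-based (PPMI+SVD), not stochastic
  skip-gram; for the corpus sizes involved this is the more stable
  estimator, and it is the reference implementation for tests.
- The ATN prediction tasks on fully synthetic cohorts carry only the
  signal the generator plants; absolute performance numbers on real
  cohorts are out of reach by construction.
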