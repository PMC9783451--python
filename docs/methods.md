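# Methods

This note documents the models, parameter choices, and numerical
conventions behind `morphsong`, and what the synthetic cohort does and does
not emulate.

## Song feature extraction

Spectra are Welch-averaged, Hann-tapered periodograms (`scipy.signal.welch`,
`detrend=False`, density scaling), default window 256 samples with 50%
overlap; bin spacing is `sample_rate / window_size`. A single full-length
window reduces to a plain tapered periodogram, so the classic
"plot-spectrum" analysis is a special case. The nine characteristics per
recording:

1. **Dominant frequency** — the bin of maximum power; exact ties break to
   the lowest frequency (deterministic, documented).
2. **Amplitude** — 20·log10(waveform RMS / reference). The default
   reference is digital full scale (dBFS); pass a calibration constant in
   `SongAnalysisConfig.db_reference` for SPL-calibrated recordings.
3. **Relative amplitudes A–F** — each band's RMS amplitude
   (√∫band PSD df over the half-open interval [lo, hi)) divided by the sum
   of the six band amplitudes. Scale-invariant, sums to 1.
4. **Frequency evenness** — −SD of the six proportions, sample SD (n−1)
   by default (`evenness_ddof=0` gives the population version). Range
   (−1, 0]; 0 iff perfectly even; −√(1/6) ≈ −0.408 in the one-band limit.

The exact Hz edges of the receptor-motivated bands are configuration. The
defaults (0, 3, 5.5, 8, 11, 16, 20 kHz) place the ancestral carrier,
mid-frequency rattling power, and the two purring frequency regimes in
separate bands while spanning the hearing range; every output row records
the band table used. Band "amplitude" is spectral RMS integration — a
level-meter reading on a band-filtered signal would differ by the meter's
ballistics, which we do not model.

WAV input is mono PCM 16/24/32-bit or float32; stereo is rejected rather
than silently mixed. Song selection (which bout, which song) is manual
curation: the library analyzes the segment it is given and does no bout
detection or denoising.

## Wing morphometrics

Landmarks are 14 ordered (x, y) points per right wing, 1-based at every
interface, read from tpsDIG-dialect TPS files (LM=, optional IMAGE=/ID=/
SCALE=; coordinates multiplied by SCALE; bottom-left origin, y upward).

Structure sizes are measured on **calibrated raw coordinates**, never on
Procrustes-aligned ones, because superimposition removes exactly the size
information these measures carry: harp width = |x₅ − x₁₄|, mirror size =
centroid size of landmarks 6–11 (reported only when the mirror is present;
absence is an informative value, not an error).

GPA centers and scales every configuration to unit centroid size, rotates
each to the current mean by SVD (reflections disallowed), and iterates
until the mean-shape change falls below `tol` (default 1e-10, usually 2–3
iterations). There are no semilandmarks. Output orientation is fixed only
up to one global rotation of the whole aligned set (the initial reference
is the first specimen); shape PCA scores are therefore reproducible up to
component sign, and the PCA sign convention (largest-magnitude loading
positive) removes the remaining ambiguity within a run. Shape PCA is
covariance-based on the flattened aligned coordinates; the first 10
components feed the trait matrix.

## Morph discovery

The trait matrix joins 9 calling-song + 9 courtship-song traits with 15
wing traits (harp width, mirror size, three 0/1 structure flags, shape
PC1–10) = 33 columns, inner-joined on individual, complete-case filtered
(dropped IDs reported), then z-scored per column. A missing mirror
contributes 0 to the mirror-size column before scaling so that an entire
mirror-less morph is not discarded; binary flags enter as 0/1 — the
matrix is fully numeric, as Euclidean-distance clustering requires.

**Ward.D2** agglomeration is implemented via the Lance–Williams recurrence
on squared dissimilarities with merge heights reported on the distance
scale; exact ties break to the lexicographically lowest active pair, so
results are deterministic given row order. Heights are monotone
non-decreasing; tests verify equality with an independent reference
implementation to 1e-8. Cutting the tree reuses
`scipy.cluster.hierarchy.fcluster` on the merge matrix.

**Gap statistic.** For k = 1..k_max, W_k is the pooled within-cluster
dispersion of the Ward.D2 cut; by default W uses unsquared pairwise
Euclidean distances (Σ_r Σ_{i,i'∈r} d_ii' / 2n_r), with the
sum-of-squares convention available via `power=2`. Reference datasets are
drawn uniformly **in the PCA rotation of the centered data** and rotated
back (`reference="pca"`, B=100 default, seeded). We deliberately prefer
this to the axis-aligned uniform box (`reference="original"`, also
available): the 33 traits are strongly correlated (band proportions sum to
1; calling and courtship songs share a carrier), so within-cluster data
occupy a low-dimensional slab, and an axis-aligned box overstates the null
dispersion at every k — the gap curve then rises monotonically and the
selected k drifts toward k_max regardless of the true structure. The
rotated reference matches the long-standing default of the standard R
implementation of the method. Best-k rules: `firstSEmax` (default; first
local maximum, then the smallest k within one s_k of it), `globalSEmax`,
`Tibs2001SEmax`, `firstmax`, `globalmax`; s_k carries the √(1 + 1/B)
inflation.

Individuals lacking the complete trait set are assigned by nearest
centroid on z-scored diagnostic traits (default: mirror presence, harp
width, calling amplitude, calling evenness, calling dominant frequency,
file gaps). This is an explicit operationalization of "manual
classification by the characteristics that defined the clusters"; the
diagnostic set is configurable and ties go to the first-listed morph with
a warning.

## Form–function statistics

- Pearson correlations use pairwise-complete observations; p-values come
  from t = r√((n−2)/(1−r²)) on n−2 df. Cells with fewer than 4 complete
  pairs or zero variance are NA **with a recorded reason** — within-morph
  grids legitimately contain NA where a structure is fixed or absent in a
  morph. Raw p-values by default; Holm adjustment is a flag.
- Welch's t and Levene's test (Brown–Forsythe median centering by default)
  delegate to `scipy.stats` behind this module's interface; fractional
  Welch–Satterthwaite df are recomputed explicitly.
- MANOVA uses between/within SSCP matrices with Pillai's trace and its
  standard approximate F (Wilks' Λ via config); with one response it
  collapses exactly to the one-way ANOVA F.
- The **decoupling summary** classifies each wing×song trait pair per
  morph as '+', '−', 'ns', or 'NA' at α = 0.05 and flags a pair as
  decoupled when at least one morph is significant and the per-morph
  statuses are not all identical — the operational signature of different
  morphs routing the same song character through different structures. No
  formal slope-heterogeneity test is performed.

## Receiver models

The female response-threshold curve is a node table (Hz → dB SPL)
interpolated linearly in log-frequency, the audiogram convention; queries
outside the node range are errors, not extrapolations. The packaged
`synthetic_threshold_curve()` is an invented stand-in shaped like cricket
behavioral audiograms (most sensitive near 4–5 kHz); any quantitative
receiver claim requires a user-supplied digitized curve, and the package
treats threshold differences between the purring frequency regimes as an
ordering check only. `detectability_margin` = song SPL − threshold at the
dominant frequency; the pipeline maps dBFS amplitudes onto the SPL scale
with a single configurable offset (default +70 dB), which affects margins
but cancels in all within-cohort comparisons.

Phonotaxis outcomes are modeled with Firth's Jeffreys-prior-penalized
logistic regression: Newton iteration on the hat-adjusted score
U*(β) = Xᵀ(y − p + h(½ − p)) with step-halving on the penalized
log-likelihood, convergence at max|U*| < 1e-6, non-convergence flagged.
Estimates are finite under complete separation — required because speaker
contact never occurs for white noise. Pairwise stimulus contrasts are Wald
tests on the penalized fit (treatment coding, optional Holm). A random
female-ID effect is **not** modeled; with every female hearing every
stimulus in a balanced design, fixed-effect contrasts answer the same
ordering question, at the cost of ignoring between-female heterogeneity.

## Synthetic cohort

The generator is phenomenological, not biomechanical: a song is a
raised-cosine pulse-train envelope (duty 0.6; pulse rate 30 Hz calling,
×1.8 courtship) on a carrier sinusoid, mixed with 0.5–18 kHz noise at the
archetype's `noise_mix` amplitude fraction, rescaled to the drawn RMS.
File gaps gate the envelope six times per pulse (75% duty). Wings are a
fixed 14-landmark template whose harp landmarks are placed to hit the
drawn harp width exactly and whose mirror hexagon is scaled to the drawn
centroid size (collapsed to a vestigial 0.15 mm cluster when absent), plus
isotropic Gaussian landmark noise (SD 0.03 mm).

Archetype defaults (the study conditions of every default analysis):

| parameter | ancestral | purring | rattling |
|---|---|---|---|
| carrier (kHz), mean ± SD | 4.8 ± 0.25 | 7.6 ± 2.5 (scraper) / 13.6 ± 2.5 (no scraper) | 6.5 ± 0.3 |
| noise mix | 0.05 | 0.75 | 0.30 |
| amplitude (dBFS) | −12 ± 1.5 | −32 ± 2.5 | −18 ± 2 |
| P(mirror), P(scraper) | 1, 1 | 0, 0.85 | 1, 0.92 |
| harp width (mm) | 2.6 ± 0.15 | 1.4 ± 0.15 | 2.5 ± 0.15 |
| mirror size (mm) | 1.9 ± 0.10 | — | 1.8 ± 0.12 |
| file gaps | no | no | yes |

The purring carrier medians are the published scraper-state medians; the
2.5 kHz within-state SD encodes the morph's characteristically variable
dominant frequency and is consistent with the magnitude of the published
scraper/scraperless test statistic at plausible group sizes. The rattling
archetype couples its carrier to mirror size (+3 kHz/mm), reproducing the
positive mirror-size/frequency association unique to that morph; purring
couples frequency to scraper state. Ancestral males get no coupling —
their morphology is nearly invariant, so their correlation cells are weak
or NA, as in real data. Remaining means (ancestral carrier, dBFS levels,
structure sizes, prevalences within the clustered sample) are plausible
values for this species chosen once as the generator's conditions; they
are not published measurements. Amplitudes keep waveform peaks below full
scale — clipping distorts band proportions and was excluded by design.

Default cohort: n = 59 with morph proportions 0.40/0.33/0.27. Each
individual draws from an RNG stream keyed (seed, index), so cohorts are
byte-reproducible and stable under changes of n; batch archetype
synthesis (`synthesize_archetype_songs`) instead draws its carrier,
noise-mix, and amplitude vectors from one stream per batch so their sample
distributions are transparent. Phonotaxis trials are Bernoulli draws per
female × stimulus (defaults 0.9/0.6/0.3/0.02 for
ancestral/rattling/purring/white-noise), with contact drawn conditionally
on response.

What the generator does **not** emulate: biomechanical resonance, real
pulse/syllable microstructure, background noise and recording-distance
variation, measurement error in landmark placement beyond isotropic noise,
population structure beyond a coarse site label, and repeated-measures
structure in phonotaxis. Passing tests therefore demonstrate that the
analysis recovers known structure of this idealized form, not that it is
robust to every artifact of field recordings.

## Numerical and design notes

- Problem sizes in the test suite and acceptance script (0.5 s songs,
  59-individual cohorts, B = 50 gap references, 10 cohort seeds, 5,000
  null replicates for type-I calibration) are chosen to make every check
  rerunnable on a single CPU in seconds to minutes while keeping the
  binomial/Monte-Carlo error of each assertion well inside its bound.
- Dominant-frequency ties, Ward merge ties, and classification ties all
  break deterministically (lowest bin / lowest pair index / first-listed
  morph) so reruns are bit-identical.
- The pipeline rewrites all enabled-stage outputs on every invocation, in
  stage order; a rerun therefore never mixes stale and fresh outputs.
  Reports serialize with sorted keys and 10-decimal rounding so identical
  config + seed yields byte-identical files.
- Known limitations: the 15-wing-trait complement of the 33-trait matrix
  is a package convention (explicitly configurable); the gap statistic's
  selected k on real data will depend on the reference-space choice
  exposed in the API; Firth contrasts ignore female-level random
  variation; and the detectability stage's absolute margins are only as
  meaningful as the supplied threshold curve.
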