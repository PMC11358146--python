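# Methods

`musicstates` analyses continuous-music-listening fMRI at two coupled levels:
time-resolved brain-network states from ROI BOLD timeseries, and emotion
dynamics from continuous self-report ratings, joined by a bootstrap mediation
model. This note documents the models, the conventions chosen where several
were defensible, the synthetic-data generator, and what the test suite does
and does not establish about real data.

## Stimulus schedule and condition labels

The run is a fixed sequence of 13 classical pieces (3 happy, 3 sad, 7
neutral; the run opens with a neutral piece and every emotional piece is
followed by a neutral one) separated by a constant 2 s silence; it ends at
507 s. Schedules are validated on parse: events must be ordered,
non-overlapping, labelled from the three-way valence set, and separated by a
single constant gap (inferred, not configured).

A volume acquired at TR `tr_s` covers clock time
`[dummy_offset_s + v*tr_s, dummy_offset_s + (v+1)*tr_s)`; it takes the label
of the event whose half-open window `[start, end)` contains the volume
midpoint, else `silence`. Midpoint assignment against half-open windows is
unambiguous for a 2 s TR against integer-second piece boundaries. Time zero
is the start of the analysed series (after dummy scans), so `dummy_offset_s`
defaults to 0. Neutral events directly preceded by a sad (happy) event carry
the derived label `neutral_following_sad` (`neutral_following_happy`) over
*all* of their volumes, because per-song-type statistics average over whole
songs of a type.

Rating traces are assumed uniformly sampled; volume ratings are the nearest
sample to the volume midpoint, ties toward the earlier sample. Whether
variability statistics should be computed on raw-resolution or TR-resampled
traces is an open modelling choice; this package computes them on the TR grid
by default (both grids coincide for the synthetic cohorts, which generate
ratings directly on the TR grid). Traces with missing samples are rejected,
not imputed.

## Emotion dynamics

For ratings x_1..x_n over the entire task (silence volumes included by
default; `exclude_silence` restricts to music):

    STD   = sqrt( sum_i (x_i - mean)^2 / n )          (population denominator)
    RMSSD = sqrt( sum_{i<n} (x_{i+1} - x_i)^2 / (n-1) )

STD measures the overall spread of emotional state (low = blunting); RMSSD
measures moment-to-moment lability (low = inflexibility). No Bessel
correction is applied to STD — the population form is the definition used
here. Both are in rating units (the -6..+6 scale).

## LEiDA: leading-eigenvector dynamics

1. **Phases.** Each ROI column is demeaned and Hilbert-transformed; the
   analytic-signal angle is the instantaneous phase theta(t) in (-pi, pi].
   No temporal filtering is applied by default (an optional band-pass stage
   exists for users replicating filtered variants); no edge tapering is done,
   and all volumes enter the analysis. Accuracy tests for phase extraction
   exclude 10% edge volumes, where any FFT-based analytic signal is
   unreliable.
2. **Phase locking.** dPL(t)_ij = cos(theta_i(t) - theta_j(t)): symmetric,
   unit diagonal, entries in [-1, 1].
3. **Leading eigenvector.** V1(t) is the unit eigenvector of dPL(t)'s largest
   eigenvalue. Sign convention: the majority of elements negative; on a tie,
   flip so the element sum is <= 0; on a zero sum, force the first nonzero
   element negative. Under this convention the globally synchronised mode is
   all-negative, and the positive-projection set of V1 is the community that
   detaches from global coherence. Because dPL(t) = C C^T with
   C = [cos theta, sin theta] (rank <= 2), the series route solves an exact
   2x2 eigenproblem per volume instead of an N x N one; the generic matrix
   route uses a dense symmetric eigensolver, and the two agree to solver
   precision. A top eigenvalue degenerate within tolerance is flagged with a
   warning; the deterministic solver output is kept.
4. **Clustering and model selection.** Eigenvectors pooled over subjects are
   k-means clustered (Euclidean — monotone in cosine distance on unit
   vectors) for k = 5..10, with 50 random restarts by default and a fixed
   derived seed per k. The Dunn index — minimum pairwise inter-cluster point
   distance over maximum intra-cluster diameter, the point-based variant —
   selects k (ties toward smaller k). Assignments are split back per subject
   in order; labels are 1-based.
5. **State metrics.** occurrence(s) = fraction of volumes in s;
   lifetime(s) = mean maximal-run length, reported in TRs with a seconds
   column (x tr_s) alongside; switching(i, j) = transitions i->j over all
   transitions out of i, self-transitions included, so rows are stochastic
   (off-diagonal entries are the between-state switching probabilities).
   Absent states yield occurrence 0 and NaN-flagged lifetime/switching rows.
   Per-song-type metrics are computed per song (runs truncated at song
   boundaries) and then averaged across the songs of the type.

## Network labelling

Each centroid (full signed vector, not binarised — a config flag enables the
binarised variant) is Pearson-correlated with each of the 7 binary Yeo
network membership columns; two-sided p-values are thresholded at
alpha = 0.01/k. A state significant for no network is flagged as the
global-coherence candidate. The packaged 105-ROI membership table is a
heuristic, name-based mapping of Harvard-Oxford-style cortical/subcortical
labels onto the 7 networks (documented in the file header); users with a
proper winner-take-all atlas mapping should supply their own file.

## Statistics

* **Partial correlation** residualises both variables on the covariates
  (age, binary-coded gender, music background in the pipeline) plus an
  intercept, correlates the residuals, and tests two-sided against t with
  n - 2 - q degrees of freedom. All p-values in the package are two-sided.
* **FDR** is Benjamini-Hochberg step-up, applied within each metric family
  (e.g. MASQ-AD against every state's occurrence is one family).
* **Mediation** z-scores IV, mediator and DV; a = slope of M on IV, b and the
  direct effect c' come from the joint regression of DV on (M, IV), the total
  effect c from DV on IV, so c = c' + a*b holds exactly. The indirect effect
  ab gets a percentile bootstrap CI (case resampling, 5,000 draws by default,
  fixed seed; paths re-standardised within each resample). The percentile
  (not bias-corrected) interval is the deliberate default. Degenerate
  resamples are redrawn and counted; more than 10% aborts. "Full mediation"
  = CI excluding zero + significant c + non-significant c'. Covariates are
  not inside the mediation regressions by default; a flag residualises all
  three variables first. If IV and mediator are numerically collinear the
  shared path is credited to the mediator (b = r_MD / r_IM, c' = 0).
* **Median split** labels scores >= median as the high group.
* The pipeline's mediation IV is the occupancy of the state with the
  smallest p in the MASQ-AD-by-occurrence family — the data-driven analogue
  of "the state whose occupancy tracks anhedonia".

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, so recovery
is a meaningful end-to-end test.

**States.** Each subject follows a Markov chain over `planted_k` states;
state 1 is the global-coherence mode and the others are ROI communities (at
the default 105-ROI, k=8 scale: the 7 Yeo networks from the packaged
fixture; otherwise disjoint contiguous blocks). Dwell times are 2 TRs plus a
shifted geometric with mean `dwell_mean_trs` (default 10): an instantaneous-
phase state must persist for about two carrier cycles to exist at the
sampling resolution, and one-volume states are unobservable. A per-subject
loading tilts switch probabilities into a designated dorsal-attention-like
state, creating the between-subject occupancy variance the mediation chain
needs.

**Signals.** All ROIs share a 0.1 Hz carrier (upper edge of the BOLD band;
rounded to an integer number of cycles per acquisition so the series is
circularly continuous and the FFT-based analytic signal has no boundary
transient). The active community is anti-phase (pi-shifted): in the
noiseless limit the sampled dPL has exactly two phase blocks and V1's
positive set *is* the community, which makes the oracle analytic. The pi
shift is realised as a signed amplitude envelope whose raised-cosine crossing
falls between volumes — the sign at every sample still equals the active
community, but the signal stays band-limited, so instantaneous phase remains
defined across switches. Per-ROI phase jitter is an AR(1) process (lag-1
correlation 0.8, marginal SD `phase_noise_sd`, default 0.3 rad): BOLD phase
fluctuations are slow relative to a 2 s TR. The state sequence is closed
cyclically (the final run takes the first run's state) so the periodic
extension seen by the FFT contains no spurious switch. BOLD = envelope x
cos(carrier + jitter).

**Behaviour.** Standardized anhedonia loads on z-scored attentional-state
occupancy with coefficient `a_true` (default 0.54) and residual SD
sqrt(1 - a^2), then maps affinely onto the 14..70 questionnaire range (mean
34, SD 9, rounded and clipped). The per-subject rating amplitude is
base x (1 + 0.35 x (b_true x z(masq) + sqrt(1 - b^2) x noise)) with
`b_true` = -0.62 — negative, i.e. higher anhedonia flattens the ratings.
With sqrt(1 - coef^2) residuals on both paths the planted standardized
coefficients are exact by construction, not approximations. Ratings follow
the 13-piece schedule (+amplitude on happy, -amplitude on sad, 0 on
neutral/silence; base amplitude 3.0, matching typical mean ratings of about
+3.5 for happy and -2.5 for sad pieces), with Gaussian noise (SD 0.5) and
clipping to [-6, 6]. Ages, genders and music-background scores are drawn
from plausible cohort distributions.

**What the generator does not emulate** — and hence what green tests do not
establish about real data: hemodynamic-response convolution, scanner noise
spectra and drifts, head motion and denoising residuals, spatially
correlated neural noise, overlapping or hierarchical communities, button-box
response dynamics (ratings appear directly on the TR grid), and missing
data. Parameter recovery here shows the *pipeline* is correct, not that real
cohorts carry this much signal.

## Problem sizes and numerical choices in the test suite

* Planted-repertoire recovery runs 20 generator seeds of 20 subjects x 200
  volumes x 105 ROIs with planted k = 6 at 0.3 rad phase noise, clustering
  with 10 restarts; bootstrap-calibration runs use 500 simulations of n = 200
  with 1,000 resamples. The full-scale smoke run uses the default cohort (31
  x 250 x 105) with the default 50 restarts. These sizes are the package's
  validation design.
* The null-coverage simulation sets the IV->M path to zero with a real M->DV
  path (0.4): that is the regime where the percentile interval is
  near-nominal. With both paths zero the indirect-effect distribution is
  degenerate at the origin and the percentile interval is far conservative —
  a property of the method, not a defect of the implementation.
* Determinism is byte-level: one seed fixes the Markov chains, noise,
  k-means initialisations (per-k seeds spawned from the run seed) and
  bootstrap draws; numeric serialisation uses fixed float formats.
* Dunn computation accumulates pairwise distances in row chunks, so pooled
  eigenvector sets of ~10^4 vectors need no quadratic full matrix in memory.

## Known limitations

* The point-based Dunn index keys on extreme points; on data with heavy
  transition smearing (e.g. unfiltered real BOLD with short state dwells) its
  k selection is far less stable than on the generator's band-limited
  signals.
* State labels from k-means are arbitrary across runs with different seeds;
  only the fixed-seed pipeline is bit-reproducible.
* The heuristic Yeo membership fixture is for demonstration and testing; it
  is not a validated atlas mapping.
* The mediation model is the three-variable single-mediator form; no
  multiple mediators, moderation, or Sobel-type tests.
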