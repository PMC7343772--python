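# Methods

This note documents the models, estimators, parameter choices and numerical
decisions behind `dynconn`, and what the synthetic experiments do and do not
demonstrate.

## Signal model and preprocessing

The pipeline assumes event-related, multichannel voltage recordings (µV) at a
fixed sampling rate, with the analysis conventions:

* sampling rate 500 Hz; epochs −650..2500 ms around stimulus onset
  (1575 samples); baseline −650..0 ms; amplitude rejection at ±75 µV with
  *inclusive* retention (a trial whose extremum is exactly 75 µV survives);
* analysis bands δ 1–4, θ 4–8, α 8–13, β 13–30 and full 1–30 Hz;
* 63 contiguous, non-overlapping 50 ms micro-time windows of 25 samples,
  numbered from 1 at the epoch origin (window 14 is the first post-stimulus
  window, 0–50 ms).

**Filtering.** Band filters are linear-phase Hamming windowed-sinc FIRs with
transition bandwidth `min(max(0.25·edge, 2 Hz), headroom)` and
`numtaps ≈ 3.3·fs/transition`. They are applied as the filter's real
amplitude response in the frequency domain after reflection padding. This is
the exact zero-phase counterpart of the windowed-sinc filter; zero phase is
essential because the downstream estimators operate on instantaneous phase,
and the frequency-domain application avoids `filtfilt`'s transient-length
constraint, which a 1 Hz transition at 500 Hz (≈1650 taps) would violate on
1575-sample epochs. Filtering should be done on continuous recordings before
epoching where possible; the epoch-level entry point reflection-pads each
trial and accepts the residual edge leakage (the synthetic cohorts arrive
pre-epoched).

## Phase-coupling estimators

Instantaneous phase comes from the Hilbert analytic signal `z(t)`, computed
over the *whole epoch* (not per window) to confine edge artifacts to the
epoch boundaries; windows index into the epoch-length phase series.

* `PLI = |⟨sign Δθ(t)⟩|` with strict signum (`sign(0) = 0`), making exactly
  zero-lag coupling invisible.
* `WPLI = |⟨Im S⟩| / ⟨|Im S|⟩` with `S = z_x z̄_y`; when the denominator is 0
  (no lagged component at all) the value is defined as 0 and flagged.

Implementation detail: for wrapped differences in (−π, π),
`sign(Δθ) = sign(Im S)`, so both estimators share the analytic cross-spectrum;
the definitional phase-series form is kept as the public primitive and the
two routes are cross-checked in the tests.

**Trial pooling.** A single 25-sample window is far too short for a stable
estimate, so sign/cross-spectrum samples are pooled across all retained
trials within a window before the modulus (effective count 25 × trials).
Per-trial estimation followed by averaging is a biased-up alternative; the
pooled choice is recorded in the configuration.

## Weighted graph measures

Connectivity matrices are analyzed as weighted undirected graphs with raw
weights in [0, 1] — no thresholding, since binarization is what makes network
summaries threshold-sensitive. Distances use `d = 1/w` (`w = 0` ⇒ no edge).
The nine measures and their conventions:

| measure | definition | notes |
|---|---|---|
| `Cr` | `4c(1−c)`, `c` = λ_max normalized between the unit path `2cos(π/(n+1))` and unit complete graph `n−1` | `c` clipped to [0, 1]: weak graphs can fall below the path reference |
| `GD` | mean off-diagonal weight | |
| `SGC` | entropy of `p_ij = w_ij/Σw` over the `n(n−1)/2` edges, / `log M` | base-invariant |
| `K` | mean over non-isolated nodes of `(1/s_i) Σ_j w_ij s_j` | neighbour *strengths*, the weighted generalization of neighbour degree |
| `Ce` | `4e(1−e)`, `e` = `Ge` normalized between unit path and unit complete graph, clipped | |
| `Ge` | mean inverse shortest-path distance, `1/∞ = 0` | |
| `C`  | Onnela geometric-mean triangle intensity on `w/max(w)`; nodes with < 2 positive-weight neighbours contribute 0; mean over all nodes | |
| `L`  | mean shortest-path distance over connected pairs; disconnected pairs excluded with a warning | dense phase-coupling matrices make this an edge case |
| `SW` | `(C/C_rand)/(L/L_rand)` over surrogates with off-diagonal weights uniformly permuted (symmetry preserved), default 20, seeded | the permutation draws from the *sorted* weight vector, so the index is exactly invariant to node relabelling; `SW = 0` for triangle-free graphs; zero/infinite surrogate `C`/`L` raises |

Shortest paths use a vectorized Floyd–Warshall (exact for non-negative
lengths), batched over surrogate ensembles for speed; the test suite checks
it against explicit simple-path enumeration on small graphs. The surrogate
count (20) trades variance against runtime over 63 windows × 5 bands; it is
configurable.

## Feature schemes and classification

Feature matrices are pivots of the long metric table along three axes
(estimator / windows / bands), with a fixed band-major → window → metric
column order for reproducibility. Under estimator *fusion* each subject
contributes a PLI-derived and a WPLI-derived row with the same label — the
sample-doubling that motivates the combined method. Row/column counts follow
`rows = 2·S·(1 or 2)`, `cols = 9·W·B`.

Classification uses an SVM with a polynomial kernel of order 1 (affine:
`(γ x·y + 1)¹`, i.e. linear plus constant offset), `C = 1.0` (configurable;
no hyper-parameter search by design), 5-fold stratified CV repeated 50 times
with reshuffled folds. Per repetition, accuracy is the pooled correct
fraction over the five test folds; the report carries max/mean/SD over
repetitions and mean pooled sensitivity/specificity (positive class = first
class of the task). Feature standardization is fit inside each training fold
only — scaling is not part of the replicated protocol, but fitting it on the
full matrix would leak test statistics.

Because fusion places two rows per subject, row-random folds can split a
subject across train and test. The default remains row-random (the
replicated protocol); a subject-grouped fold policy is provided as the
leakage-free variant and both can be reported.

"Maximum accuracy" is the best single repetition (not the best fold).

## Statistics

* ERP pointwise tests: Welch two-sample t per time point, uncorrected at
  α = 0.05 (display convention).
* Metric trajectories: paired t per window (within-subject design).
* Whole-network test: the per-subject network summary per window is the mean
  edge weight; a Wilcoxon rank-sum compares conditions per window, with BH-FDR
  across the 63 windows at α = 0.01. (Per-edge pooled summaries are a
  selectable variant; the mean-edge-weight default is recorded in the
  configuration.)
* Edgewise maps: Welch t per edge per window, BH-FDR within each window's
  `n(n−1)/2` edges at α = 0.01 — the FDR family matches the display
  granularity of per-window connectivity maps. Node degrees of the
  significant subgraph are the mask row sums.
* Degenerate inputs (zero variance in both groups, all-tied ranks) yield
  p = 1 with a log message rather than NaN.

A note on BH arithmetic: for p = (0.001, 0.008, 0.039, 0.041) at q = 0.05 the
step-up thresholds are (0.0125, 0.025, 0.0375, 0.05) and p₍₄₎ ≤ 0.05, so all
four hypotheses are rejected — the test suite asserts this together with a
genuinely partial case.

## Synthetic cohorts: what they emulate and what they don't

Each channel is a sum of narrowband components — white Gaussian noise passed
through the *same* band filters used in analysis, one component per sub-band,
each scaled to 5 µV SD — plus 2 µV white sensor noise. A coupling entry
replaces the target channel's band component inside the specified window
range with `c · lagged_copy(source) + (1−c) · own`, where the lagged copy is
an exact phase rotation through the analytic signal. Consequences: the
coupled pair's PLI/WPLI is monotone in `c`, equals 1 at `c = 1` with no
sensor noise, and uncoupled pairs sit at the estimator's small-sample floor.
An optional instantaneous mixing matrix emulates volume conduction: it
inflates amplitude correlations but, being zero-lag, cannot raise PLI/WPLI
above the permutation-surrogate floor.

Defaults mirror the emulated study scale: 25 subjects per class, 98 trials,
500 Hz, −650..2500 ms epochs. Determinism: one master seed; per-(class,
subject) streams derive via `SeedSequence(master, spawn_key=(class, subject))`.

Not emulated: 1/f background spectra beyond filtered noise, realistic head
geometry or a forward model, ERP-like evoked components, artifacts other than
amplitude excursions, and inter-subject variability structure. Passing the
recovery tests therefore shows the *pipeline* is correct and sensitive under
its own assumptions — not that real cortical coupling of a given strength
would be recovered at the same rates.

**Problem sizes.** The recovery experiments (test suite and
`scripts/acceptance.py`) use 25 subjects/class with coupling strength 0.9 in
the alpha band, windows 14–25, at 20 trials/subject and 8 channels — sizes
chosen so the whole study runs in minutes on a single core while keeping the
subject-level statistics at full scale; trial and channel counts enter the
estimators only through variance, and 20 × 25 pooled samples per window are
ample at this coupling strength. Edge recovery is scored as the mean, over
the injected windows, of the Jaccard overlap between the FDR-significant
edge set and the injected edge set.

## Known limitations

* The rank-sum network summary (mean edge weight) is one of several
  defensible choices; strongly localized effects dilute in it (the edgewise
  maps are the sensitive instrument for those).
* Epoch-level filtering of pre-epoched data tolerates some edge leakage;
  first and last windows of an epoch are the least reliable.
* `L` with disconnected pairs reports the mean over connected pairs only,
  which is optimistic for fragmented graphs; phase-coupling matrices are
  generically dense, so this rarely binds.
* EDF files can be read (via MNE) but not written; the canonical on-disk
  format is the delimited-text matrix with a JSON sidecar.
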