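# Methods

## The inference problem

A calcium-imaged neuron is called *selective* for one of two task states —
open-arm (OA) versus closed-arm (CA) occupancy of an elevated zero maze —
when its selectivity index

    SI = (avg(OA) − avg(CA)) / (avg(OA) + avg(CA))

falls outside the central 95% of a null distribution obtained by shuffling
the neural data 1,000 times (OA-selective above the 97.5th percentile,
CA-selective below the 2.5th, nonselective otherwise; comparisons are
strict, and quantiles are order statistics — rank ⌈0.975·n⌉ and
⌊0.025·n⌋+1 — so the decision is an exact integer-rank comparison).
avg(S) is the mean per-frame activity over the frames spent in state S
(area under the curve per unit time), which makes matched and nonmatched
comparisons duration-invariant.

The label a neuron receives depends on five analysis choices:

| dimension | levels |
|---|---|
| neural datatype | events, 2 s-convolved events, 4 s-convolved events, traces |
| behavioral datatype | head centroid, body centroid |
| bin width | native (50 ms), 1 s moving average |
| OA/CA sample matching | matched, nonmatched |
| shuffle method | randperm, partial ECM, full ECM, circshift |

of which the 8 randperm-on-traces cells are invalid (there is no event
train to permute), leaving 120 settings.  The package quantifies how much
the label depends on these choices (pairwise label-consistency matrices
with bootstrap CIs and effect tiers at CI-lower-bound thresholds 0.9/0.8),
attributes disagreement to changes in the SI value versus changes in the
null width (robust-regression congruence of per-neuron SI and null-SD
values, slope CI at 99%), and selects the setting with the best
accuracy/robustness trade-off, validated by stratified bootstrap and
holdout cross-validation and cross-checked against a regression (LM /
Poisson GLM) route.

## Shuffle methods

* **randperm** — event frames are uniformly repositioned; for convolved
  datatypes the events are permuted first and re-convolved.  Destroys all
  temporal structure; for stationary, state-independent activity it is
  exactly calibrated (the true event placement is exchangeable with the
  null's).
* **circshift** — the signal is rotated by a shift uniform on {1,…,T−1}
  (single direction with wrap-around; the direction is a free choice).
* **full ECM** — the signal is cut at every event onset (the pre-first-event
  segment is one more shufflable segment; the trailer runs to session end)
  and the segments are permuted.
* **partial ECM** — fixed chunks of 2/4/3 s (2 s-convolved / 4 s-convolved /
  events and traces) anchored at event onsets are permuted among the chunk
  slots, zeros elsewhere.  Chunks are truncated at the next event onset so
  they never overlap, and a permuted chunk placed into a shorter slot is
  truncated at the next slot; the choice matters only when inter-event
  intervals are shorter than the chunk.

The last three preserve local temporal structure and are therefore *not*
expected to hold a 5% false-positive rate on autocorrelated data — that
difference in behavior between shuffles is precisely what the
consistency analysis measures.

## Matched closed-arm sampling

The matched rule equalizes OA/CA sample sizes: for every OA bout, a
uniformly random contiguous closed-arm segment of equal frame count is
drawn from a uniformly chosen CA bout long enough to contain it; the
matched CA activity is the per-frame mean over all segments, averaged over
draws.  Both the true SI and each null iteration use 1,000 draws:
the engine folds matched draws into precomputed segment-coverage weights,
so the draw count costs nothing, and using fewer draws inside the null
(an apparent shortcut) measurably widens the matched null through pure
estimator noise and distorts the matched/nonmatched comparison.  Sub-segment sampling (rather than requiring whole CA bouts of
exactly equal duration) is used because equal-duration whole bouts
essentially never exist.  If some OA bout is longer than every CA bout the
neuron set falls back to nonmatched with an `unmatched_bout` flag.

## The batch engine and common random numbers

Labeling 692 neurons under 120 settings with a permutation null each is
computationally dominated by constructing shuffled signals.  The engine
(`caselect.engine`) batches all iterations of one neuron into a matrix and
evaluates every state quantity as a linear functional of the shuffled
signal (state sums and 1 s-binned state sums via precomputed indicator /
binning-adjoint weight vectors; matched segment sums via per-iteration
segment-coverage counts), which reduces each (datatype, shuffle) block to
one matmul and two einsums.  The engine is verified against the plain
per-iteration reference implementation to float accumulation error across
the entire grid (`tests/test_engine.py`).

Shuffle plans are drawn independently per (neuron, method, datatype) and
matched-sampling plans independently per setting; realizations are shared
only across settings that differ in behavioral datatype, bin width or
matching for a fixed (datatype, method).  This residual common-random-number
sharing is a compute-bound compromise: it slightly inflates the measured
consistency of setting pairs that differ only in those three dimensions
(both members see the same shuffle noise), but it does not touch the
within-level pair sets of the behavioral/bin/matching levels themselves.
Earlier, broader sharing (across datatypes, and of matched plans across
settings) was found to bias the analysis — it hid the realization
instability of structure-preserving shuffles and erased the matched
estimator's noise penalty — and was removed.

## Synthetic sessions

No public dataset accompanies the study design, so `caselect.synthetic`
generates sessions with known ground truth.  What it emulates, and why:

* **Behavior.**  Alternating OA/CA bouts with exponential dwell times
  (mean 8 s OA / 24 s CA, i.e. 25% open-arm time — the minority-OA pattern
  typical of the assay); the body advances around the 40 cm-inner-diameter
  ring one quadrant per bout; behavior is sampled at 18.96 Hz and aligned
  to the 20 Hz neural clock by nearest-neighbor matching (ties to the
  earlier sample), exercising the two-clock alignment path.  The head
  follows its own schedule, crossing each boundary a variable
  stretch-attend duration (mean `head_lead_s`, default 1 s) before the
  body does, and is displaced radially so the head-to-body distance has
  median 4.04 cm; zone transitions therefore appear in head coordinates
  before they appear in body coordinates.
* **Neurons.**  Discrete events are Bernoulli per 50 ms frame with
  probability `rate_state / 20 Hz`; amplitudes are lognormal(0, 0.4)
  (tests that depend on amplitudes also pass with constant amplitudes);
  the raw trace is the event train convolved with exp(−t/0.7 s) (GCaMP6f-like
  decay) plus sinusoidal drift (amplitude 0.4, period 400 s), a slow random
  walk and white noise (SD 0.12) — deliberately messy, because the
  instability of the raw-trace datatype under drift and noise is one of the
  structural findings the pipeline must be able to reproduce.
* **Ground truth.**  The rate-driving state is the *head-centric* exposure
  state: threat exposure begins when the head extends into an open arm.
  Lead durations vary per transition (uniform on 0.3–1.7 × `head_lead_s`,
  the variability of stretch-attend postures), so body-centric analysis is
  misaligned with the neural state by a variable, unpredictable amount.
  During the head-lead (risk-assessment) epochs rates are multiplied by
  `transition_gain` (default 1.5), reflecting the engagement of mPFC at
  exploratory boundary crossings.  Event rates also carry a slow
  multiplicative modulation (Ornstein–Uhlenbeck on the log rate, timescale
  120 s, SD 0.25), the slow network fluctuation that makes
  autocorrelation-preserving shuffles behave differently from full
  randomization.
* **Cohort composition.**  The default study cohort has 692 neurons: 7
  extreme OA-selective and 13 extreme CA-selective template-grade neurons
  (|SI| ∈ [0.90, 0.98]) at sparse rates (0.05–0.12 events/s), 13 exactly
  flat template-grade neurons (0.2–0.5 events/s), and 659 others drawn
  from a bimodal mixture: a near-flat majority (SI ~ N(0, 0.08), rates
  log-uniform 0.03–0.3) and a clearly selective minority (45%,
  |SI| ~ U(0.35, 0.65), rates log-uniform 0.1–0.4) — the separated
  selective subpopulation typical of this assay.  No firing statistics are
  published for this preparation; these are plausible sparse-cortical
  values chosen to exercise every detection regime.
* The true SI recorded per neuron is the analytic
  (rate_OA − rate_CA)/(rate_OA + rate_CA); transition bursts and slow
  modulation perturb realized state-conditional means only slightly.

What the generator does **not** emulate: spike-to-calcium nonlinearity and
indicator saturation, pose-estimation noise in the tracked coordinates
(angles are exact; only the radial coordinate is jittered), within-bout
pauses or direction reversals, and correlated activity across neurons.
Passing tests therefore show that the pipeline's logic behaves as intended
under controlled, realistic-order-of-magnitude conditions — not that any
particular parameter setting is optimal for a given real dataset.

## Optimization, validation, GLM

Template neurons are identified from raw event rates under head-centric
states (the least-processed datatype): normalized rate difference
d > 0.85 (OA template), d < −0.85 (CA), |d| ≤ 0.05 (nonselective);
silent neurons never qualify.  Accuracy of a setting = percent of
templates labeled with their template type.  Robustness: each parameter
level's average robustness is the mean consistency over setting pairs that
both contain the level; a setting's combined robustness is the plain mean
of its five levels × 100 (consistent with the published scale of these
scores).  Ranking is lexicographic — accuracy first, robustness second —
and the optimal set is {accuracy = 100 and robustness > 95th percentile}.

Bootstrap validation resamples neurons with replacement within strata
(each template type, the nontemplates; counts preserved) and re-ranks;
holdout validation splits 60/40 per stratum (training share rounded to
nearest — the rule that reproduces a (4, 8, 8)/395 vs (3, 5, 5)/264
partition of (7, 13, 13, 659)) and reports the Spearman correlation
between training- and testing-side rankings (average ranks for ties).
Inside each resampling iteration, pairwise consistencies are recomputed on
the resampled neurons from cached agreement indicators (recomputing nulls
inside every iteration is neither feasible nor required — the resampling
targets cohort variability, not shuffle variability).

The GLM route regresses per-frame activity on the binary state indicator
with no history terms.  With one binary regressor both links have closed
forms (identity: state mean difference; log: log rate ratio), which the
implementation uses directly; for continuous datatypes the log-link fit is
the quasi-likelihood solution of the same score equations.  Significance
is a permutation test on the regressor (100 frame-level permutations,
p = fraction of shuffled |β₁| at or above the observed; p ≥ 0.05 ⇒
nonselective).  Frame-level permutation is anticonservative for
autocorrelated activity — the same phenomenon that separates randperm from
circshift on the SI side — so SI–GLM agreement is expected to be high for
strongly selective neurons and imperfect near threshold.

## Numerical and procedural choices

* Drift removal: 2nd-order Butterworth low-pass at 0.01 Hz, applied
  forward-backward (zero phase) with three cutoff-periods of reflect
  padding, then rectification.  The cutoff separates minutes-scale drift
  from seconds-scale transients; results that depend on the exact cutoff
  should be treated as sensitivity analyses.
* Kernel truncation at 5τ (< 1% residual mass).
* 1 s binning is a centered moving average over round(rate) frames (for
  even windows the extra frame falls on the earlier side), renormalized at
  the edges.
* Boundary exclusion masks frames whose body center lies within one median
  head-to-body length (arc distance along the ring's center line) of an
  OA–CA boundary; masking affects only which frames enter state averages —
  shuffles and binning operate on the full series.  Bouts are maximal
  same-state runs over the valid frames (runs merge across masked gaps).
* Silent neurons (zero activity in both states) are labeled nonselective
  with a flag, never NaN; silent shuffle iterations contribute SI = 0 with
  a flag.  Null SD is the sample standard deviation (ddof = 1).
* Bootstrap CIs are percentile CIs; slope CIs use 99% coverage as a
  conservative multiplicity heuristic; the congruence regression includes
  an intercept but is judged on the slope (bisquare IRLS, c = 4.685, MAD
  scale, verified against statsmodels RLM).
* Ties in rankings share a rank; single winners (bootstrap/holdout
  frequency tables) break ties toward the smaller setting id.

## A structural property of the robustness metric

A finding worth stating plainly: on synthetic cohorts, the combined-
robustness metric systematically favors *conservative* analysis choices.
Any level that widens the null or attenuates the SI (matched sampling,
body-centric states, heavier smoothing, structure-preserving shuffles on
weakly structured data) shrinks the set of detected neurons, and whenever
the population's selectivity density decreases with |SI| — as it does for
any realistic population — the conservative variant's flip-prone band
sits in a lower-density region, so its labels agree more across settings.
Accuracy, which is lexicographically senior, is the intended counterweight
(an over-conservative setting should start missing template neurons), but
extreme-by-definition templates are detectable by almost every setting.
Consequently the most powerful calibrated pipeline is *not* guaranteed to
top the robustness ranking on synthetic data even when it is, by
construction, the most truthful one; the margins between the reliable
(randperm, nonmatched, head) block and its conservative neighbors are
small and can invert.  This is a property of the selection metric under
these study conditions, not an implementation artifact — the engine is
verified against the reference implementation to float precision — and it
bounds what the self-consistency checks in `tests/test_acceptance.py` can
guarantee.

## Problem sizes

Defaults follow the study design: 1,000 shuffle iterations, 1,000
bootstrap resamples, 500 bootstrap-validation and 200 CV iterations.  The
grid-wide stage (120 settings × 692 neurons) in `scripts/acceptance.py`
and the test suite runs 100 null iterations per neuron, 100 validation and
100 CV iterations, and evaluates the congruence/mechanism and boundary
analyses on a 16-setting subgrid — the package's desk-scale problem sizes,
chosen so the whole study runs on a single core in minutes while leaving
every estimator's structure unchanged.  Single-setting analyses (null
calibration, GLM comparison) use the full 1,000 iterations.
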