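# Methods

## The exposure account of citation counts

`citexposure` implements two generative models of how citations
accumulate over the life cycle of a cohort of articles (a *reference
class* of size `R` that collectively receives `C` citations, one per
*epoch*), plus the statistics used to compare the distributions they
predict with observed citation-count distributions.

Both models share one idea: the probability that an article is cited is
proportional to its accumulated *exposure*, not to any notion of its
quality. Highly cited articles then emerge from chance alone, because
early random advantages compound (the Matthew effect).

### Stochastic urn model (`citexposure.urn`)

Every article starts with `u = 1` exposure unit (a level playing
field). Each epoch one article is cited with probability
`u_i / Σu`, and its `u` grows by 1. The model has no free parameters.
After one citation in a 100-article ecology the cited article's
probability is `2/101 ≈ 0.0198` and every other article's is
`1/101 ≈ 0.0099`; iterating for `C` epochs yields right-skewed count
distributions.

With equal starting units the process is a classic two-color-per-article
Pólya urn. For `R = 2` the final count of either article is exactly
uniform on `{0, …, C}` — the test suite verifies this against exhaustive
path enumeration (C ≤ 6, agreement to 1e-12) and by Monte Carlo at
C = 50. Two optional mechanisms extend the basic process without
changing it:

* `initial_units` — an uneven starting field (some articles begin with
  more exposure), used to study how starting-point advantages are
  magnified over time;
* `exogenous_rate` — after each epoch, with this probability one
  uniformly chosen article gains an exposure unit *without* being cited
  (talks, social media, preprints). Default 0: the demonstration and
  fitting experiments use citation-driven exposure only.

Sampling inverts the cumulative sum of `u` against one uniform draw per
epoch, i.e. the naive per-epoch law is executed literally; a full-scale
run (R = 739, C = 57,310) takes well under a second.

### Memory-theoretic model (`citexposure.memory`)

The same exposure logic implemented inside an instance-based (episodic
trace) model of memory:

* **Representation.** Each article is a prototype vector of
  `n_features` features over {−1, +1}. A fraction `Sim` of the feature
  positions (rounded half away from zero to `round(Sim·n)` positions)
  carries one pattern common to all articles, modelling the conceptual
  overlap of a research domain; the rest are independent fair coins.
  `Sim = 0` gives statistically orthogonal articles, `Sim = 1`
  identical ones.
* **Encoding.** A trace of an article keeps each feature independently
  with probability `L` and loses it (0) otherwise. `L` is the single
  information-loss parameter: it does not distinguish shallow encoding
  from forgetting. Memory starts with one trace per article and gains
  the trace of the cited article each epoch, ending with `C + R` traces.
* **Retrieval.** Each epoch a probe representing the citing context is
  matched against all traces. Similarity is
  `S = Σ probe_i·trace_i / N_R` with `N_R` the number of positions
  where probe *or* trace is nonzero (`S = 0` if `N_R = 0`); activation
  is `S³`; one trace with positive activation is sampled by Luce's
  choice rule (probability `a_i / Σ_{a_j>0} a_j`) and its article is
  cited.

**Probe construction.** The citing context is modelled as a lossy
encoding (same retention `L`) of a uniformly chosen article's
prototype. Contexts therefore resemble article topics; encoding noise
plus the shared feature segment produce cross-article retrieval, and —
because cited articles accumulate traces — cumulative advantage.
This is a modelling choice on a point the model description leaves
open; the package treats it as part of the model definition.

**Defaults and units.** `L ∈ [0, 1]` (retention probability, default
0.5), `Sim ∈ [0, 1]` (shared-feature fraction, default 0.1 — the value
held fixed in all fitting experiments), `n_features = 20`. The feature
count is not critical as long as probes remain discriminative; 20 keeps
a 57,310-epoch run tractable on one CPU (the per-epoch match is a dense
product against all current traces, so a run costs O(C·(R + C/2)·n)).

**Degenerate epochs.** If a probe activates no trace (possible at very
low `L`), a fresh probe is drawn, up to `max_probe_retries = 10` times;
failing that the epoch cites a uniformly random article. Fallbacks are
counted on the run result and logged; at the parameter ranges studied
here they essentially never occur. Every run emits exactly `C`
citations regardless.

**Qualitative behaviour** (verified by paired sign tests in the suite):
lower `L` increases the skew of the final distribution — when most
traces are poorly encoded, the few articles that are well encoded by
chance gain a large retrieval advantage; higher `Sim` increases both
skew and the number of *uncited* articles, because generic probes are
increasingly captured by the already-popular articles' traces.

## Fit statistics (`citexposure.stats`)

* **A statistic** — probability that a random draw from the observed
  sample exceeds a random draw from the predicted one, ties counted
  half: `A = [#(o>p) + ½#(o=p)] / (n·m)`, computed from midranks in
  O((n+m) log(n+m)). `A = 0.5` under identity, and `A ≈ Φ(d/√2)` for
  normal populations separated by Cohen's `d` (d = 0.10 ↦ A ≈ 0.528).
  The tie-corrected Mann–Whitney `U = A·n·m` is exposed for downstream
  tests; no p-values or Bayes factors are computed here.
* **Overlapping index (OV)** — the integral of the pointwise minimum of
  Gaussian KDEs of the two samples. Bandwidth is the normal-reference
  rule `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)` (falling back to the sd
  when the IQR is 0; a zero-spread sample is an error). Counts are
  treated as continuous values. Both densities are evaluated on one
  1024-point grid spanning the pooled range padded by three bandwidths,
  and integrated by the trapezoid rule. Against the closed-form
  equal-variance normal overlap `2Φ(−Δ/2σ)` the estimate is accurate
  to well under 0.02 at n = 10⁵.
* **Upper bound (UB)** — two finite samples from the *same* population
  do not overlap perfectly, so raw OV is sample-size dependent. UB is
  the mean OV over all `m(m−1)/2` unordered pairs of same-model runs.
* **Adjusted overlap** — `OV_adj = 100·OV/UB` (%), the chance-corrected
  score; it can exceed 100 and is reported as-is. Percentages are
  reported to 2 decimals and A to 3 in CLI reports.

## Experiment protocols (`citexposure.experiments`)

* **Sweeps** — `sweep_L` (default levels 0.35/0.55/0.75/0.95, Sim fixed
  at 0.1) and `sweep_Sim` (0.1/0.25/0.50/0.75, L fixed at 0.5) run the
  memory model per (level, replicate) and tabulate skewness (g1 =
  m3/m2^{3/2}), uncited proportion and maximum count; replicate `r`
  uses seed `base + r`, shared across levels so level contrasts are
  paired.
* **Fitting** — `fit_L` grid-searches `L` (0.1 grid steps by default),
  running 10 replicates per level against an observed counts table
  whose row count and sum fix `R` and `C`. Each replicate is scored by
  A and OV; the replicates' pairwise OV gives UB; the level score is
  mean OV_adj. `best_L` maximizes mean OV_adj, ties broken by
  |mean A − 0.5|, then by the smaller L. OV_adj was chosen over raw OV
  so that the sample-size ceiling cancels; the fit is *approximate* by
  construction — neighbouring L levels predict similar distributions,
  so best-fit values should be read at ±one grid step.
* **Aggregation** — `aggregate_quantile_median` sorts each run's counts
  and takes the elementwise median across runs, the standard way to
  pool ~100 runs into one predicted distribution.
* **Trajectories** — simulators can record per-article citation
  probabilities every `track_every` epochs (for the urn, `u/Σu` after
  the update; for the memory model, each article's share of the
  positive normalized activations under that epoch's probe; epoch 0 is
  the 1/R starting point). `trajectories` extracts the series of the
  articles sitting at nearest-rank quantiles of the *final* counts
  (ties to the lowest article index) — the conventional quantile set is
  1.0, 0.99, 0.95, …, 0.01, 0.00 — and can apply a trailing moving
  average (window in epochs, e.g. 100) to smooth the epoch-to-epoch
  noise of realised probabilities.

## Synthetic observed data (`citexposure.io.generate_fixture`)

Real citation-count tables are heavy-tailed: many barely cited
articles, very few highly cited ones. The fixture generator emulates
this by drawing `R` negative-binomial counts (mean `C/R`, shape
`dispersion`; small shape ⇒ heavy tail, default 0.3) and repairing the
vector to an exact total `C` by uniformly random unit
increments/decrements (never below zero). It reproduces the marginal
shape of real data but none of its structure — no per-article
covariates, no year effects, no dependence between articles — so tests
that pass against fixtures demonstrate that the machinery works, not
that the models fit any particular real corpus.

## Problem sizes, tolerances, determinism

All randomness flows through `numpy.random.default_rng(seed)`;
replicate `r` of any multi-run protocol uses `base_seed + r`. Identical
parameters and seed reproduce results bit-for-bit.

The test suite runs scaled ecologies chosen to preserve each effect
while keeping a desk-scale runtime: run-to-run consistency and the
L/Sim sign tests at R = 200, C = 10,000 (10 seed pairs for the skew
contrast, 20 for the smaller uncited-count contrast); parameter
recovery at R = 100, C = 8,000 — the ~80 citations-per-article density
of the real cohorts, which is what makes L identifiable — with 10
replicates per grid level; the urn overlap ceiling at the full
R = 739, C = 57,310 scale, which the urn model reaches in seconds.
Statistical assertions use fixed seeds and conventional levels
(chi-square and sign tests at α = 0.01–0.05) so they are deterministic
in practice.

## Known limitations

* The probe-construction rule is one reasonable formalization of
  "citing context"; other choices (e.g. mixture probes spanning several
  articles) would change quantitative details.
* KDE overlap on counts ignores discreteness; with few distinct values
  the bandwidth rule can undersmooth. The adjusted overlap inherits
  noise from both OV and UB.
* `L` is weakly identifiable at desk scales: the distributions the
  memory model predicts for `L` between roughly 0.3 and 0.7 differ by
  less than the run-to-run noise of the overlap score, so the `fit_L`
  profile is nearly flat there and its argmax is unstable — repeated
  recovery experiments on self-generated data place `best_L` within
  one 0.1 grid step of the generating value only in a modest majority
  of trials (the suite's recovery test documents this; it is expected
  to fail when the argmax wanders beyond one step). Fitted values
  should be read as indicative, not point estimates.
* The memory model's per-epoch full rematch makes runtime quadratic in
  C; the implementation vectorizes the match but is faithful to the
  per-epoch recompute (an optimization must be distribution-identical
  to it).
* No attempt is made to fit `Sim`, and similarity structure is
  synthetic; embedding real article texts is out of scope.
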