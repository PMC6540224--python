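# Methods

## Problem setting

Virtual screening ranks a large compound library against a protein target and
forwards the top of the ranking to experiment. Benchmarks of the DUD type pair
a few dozen known actives with property-matched decoys (decoys are >95% of
each dataset), dock every molecule, and ask how strongly the top of the
ranking is enriched in actives. No single scoring function wins consistently,
which motivates consensus strategies that combine several scores into one
ranking.

`efoscreen` implements an enrichment-factor-optimization (EFO) consensus: it
searches linear combinations of 1–3 docking/rescoring scores whose induced
ranking maximizes a cluster-based quality function, validates every candidate
score subset by repeated stratified train/test splits, and reports enrichment
factors (EF) and ROC AUC.

## The model

Given a score table with N molecules (A actives) and named score columns, a
consensus model of order k is

    s(x) = Σ_j w_j · (x_j − μ_j) / σ_j,     ‖w‖₂ = 1,

where the μ_j, σ_j are per-column mean and population SD estimated on the
fitting rows and stored in the model, and w is a unit-norm coefficient vector.
Rankings are invariant to positive rescaling of w, so the unit sphere removes
the nuisance scale; the *sign* of w is meaningful — it orients each score so
that larger combined score means "more likely active" — and is therefore kept
as optimized rather than canonicalized away. Energy-like scores (more
negative = better) are handled entirely through negative coefficients; there
are no per-column orientation flags.

## Quality function

Models are compared by

    Q = a_C + (1 − r̄/N),

where a_C is the number of actives among the top C ranked molecules (the
"cluster", C = 100 by default, matching ~3% of a typical DUD dataset) and r̄
is the mean rank of all actives. The fractional term lies in [0, 1), so a_C
dominates lexicographically: maximizing Q first packs actives into the top
cluster, then pulls the remaining actives up the full ranking. Sample
skewness of the active ranks is reported as an additional asymmetry
diagnostic but kept out of Q so that Q stays strictly monotone in a_C.

## Optimization

Q depends on w only through the induced ranking, so it is piecewise constant
with zero gradient almost everywhere. The optimizer is therefore
derivative-free:

* k = 1: exact — the two points of the unit "sphere" (±1) are enumerated.
* k ≥ 2: accept-if-better Gaussian pattern search on the unit sphere.
  Proposals are w′ ∝ w + σ·g with g ~ N(0, I); σ starts at 0.5 and is halved
  after 100 consecutive rejections; a start terminates when σ·√k < 0.001
  (the run header logs this interpretation of the "RMS = 0.001" stopping
  setting) or after 5000 iterations. Each subset is optimized from 12
  seeded random starts plus one warm start.

The warm start pads the best (k−1)-score model over any sub-subset with a
zero coefficient. Because accept-if-better refinement never decreases Q, the
best training Q is non-decreasing in k by construction; this also makes the
k-monotonicity property deterministic rather than statistical. The warm
start can be disabled (`warm_start=False` / `--no-warm-start`).

All randomness derives from a single seed: each subset's starts use a seed
mixed from the master seed and a CRC of the subset's column names, so results
are bit-reproducible and independent of enumeration order.

Ties between equal combined scores are broken by lexicographic molecule id in
all reported metrics (with a logged warning when a tie group straddles a
selection boundary). Inside the optimizer's hot loop, active/decoy score
ties are instead resolved in favour of the active (strict comparison); for
continuous scores ties have probability zero, and every reported quantity is
recomputed through the exact id-tie-broken path, so the two conventions
cannot disagree on any reported number.

## Prefilters

Before subset enumeration two filters reduce the score set, in this order:

1. **Interrelation (VIF) filter.** VIF_i = 1/(1 − R²_i) from OLS of the
   standardized column i on all other standardized columns; perfectly
   collinear fits are capped at the serializable sentinel 10⁶. While any
   VIF exceeds 5, the worst offender is removed and VIFs are recomputed
   (greedy elimination with recomputation — the standard multicollinearity
   protocol; a one-pass variant would depend on the initial VIF order).
   Ties are broken by removing the column with the lower single-score EF5%
   (so of two redundant scores the more enriching one survives), then by
   keeping the earlier lexicographic name.
2. **Effectiveness filter.** A column is kept only if ranking by +column or
   −column achieves EF ≥ 2.0 at the top 5%. The two orientations are tried
   because energy-convention scores enrich through the negated column.

VIF is computed once on the full table, not per training split: the filter
decides the identity of the candidate score set, and a per-split filter would
make "the model" ill-defined across validation repeats.

A statistical caveat documented here because it is easy to trip over: a
*pure-noise* column passes the EF5% ≥ 2 test by luck with probability ≈ 8.7%
at N = 3000, A = 80 (hypergeometric tail over both orientations), so the
effectiveness filter removes a planted null column in roughly 91% of random
tables, not "always".

## Validation protocol

Candidate subsets (all C(n, k) over the filtered columns) are evaluated by
R = 5 repeated stratified 80/20 train/test splits. Stratification is a
necessity, not a refinement: an unstratified 20% draw from a 2–3%-active
table can contain zero actives, leaving EF undefined. Repeat r draws its
rows with seed (master seed + r). For each repeat, each subset's
coefficients and standardization are re-fitted on the training rows only and
scored on the held-out rows; subsets are ranked by average test Q (ties:
higher average test EF1%, then lexicographic). The winner is refitted on the
full table, and its full-data EF profile is reported next to the validation
averages so that optimistic train/validation mismatch is visible. The gap
between the two shrinks as the ranking fraction widens, since the quality
function concentrates its pressure on the top cluster.

EF uses s_f = ceil(f·N) molecules at fraction f — the ceiling guarantees a
non-empty selection for any N. AUC is the rank-sum statistic with half
credit for ties (sklearn's implementation, equivalent to the trapezoidal ROC
with ties pooled). When the quality function is evaluated on a table smaller
than the cluster size (possible for small test sets), C is clamped to N.

## Synthetic benchmark generator

The generator emulates the *structure* of a DUD-style rescoring table, not
any physics: a single latent "binding propensity" t = u + Δ·label
(u ~ N(0,1)) drives every column, score_j = λ_j·t + σ_j·ε_j. Defaults are
N = 3000 molecules, A = 80 actives (2.7%, matching the >95%-decoy regime),
K = 11 score columns with loadings tapering from −1.0 to −0.2 and unit
noise, and effect size Δ = 2 (single-score AUCs ≈ 0.75–0.9, typical of
competent docking scores). Negative loadings implement the energy
convention, so the pipeline must discover orientation through coefficient
signs. Optional bait columns stress the prefilters: a near-duplicate of
column 1 (r ≥ 0.999) and a zero-loading noise column. Molecular weight
(200–600 Da) and heavy-atom count (15–45) are drawn independently of
activity, purely to exercise normalization.

What the generator does *not* reproduce: pose geometry, score-specific error
distributions, property-matched decoy bias, or multiple binding modes.
Passing recovery tests therefore demonstrates the correctness of the search
and validation machinery under a known ground truth — not that any specific
EF level will be reached on real docking data.

`theoretical_best_subset` returns the k columns with the largest |λ|/σ and
the linear-discriminant direction implied by the generative model (under the
equal-covariance Gaussian model the LDA direction maximizes every monotone
early-recognition criterion, including Q), mapped onto the standardized
columns the pipeline combines.

## Problem sizes used in tests and the acceptance script

Run times scale with (subsets × splits × optimizer iterations × N), so the
test suite and the acceptance script exercise the full pipeline at reduced,
proportionally scaled sizes chosen once: recovery fixtures use N = 1000
molecules with 80 actives and K = 5 scores, with cluster size 33 (the same
3.3% of the dataset as 100/3000; the cluster must be recalibrated for
datasets far from the ~3000-molecule scale), while metric oracles, null
calibration, filter behaviour and split integrity run at N up to 3000. The
acceptance script additionally runs one full-scale (N = 3000, A = 80,
K = 11) two-score screen with the default settings.

Recovery fixtures are "planted" so that the ground-truth best subset is
statistically identifiable by the validation protocol itself: the k signal
columns carry clearly higher |λ|/σ than the distractors, and the distractors
still pass the EF5% filter so the competition is real. Selection resolution
is bounded by the number of test-set actives (16 per 20% split at A = 80)
and the 5 repeats, which is why the recovery fixtures keep A = 80 while N is
reduced.

## Known limitations

* Q's asymmetry term is the mean normalized active rank, a deliberate,
  documented surrogate for the original asymmetry-based parameterization;
  skewness is reported alongside but not folded into Q.
* The subset-selection step has limited resolution when candidate subsets
  differ only marginally in out-of-sample quality (a few test actives decide
  the comparison); with ~16 test actives and 5 repeats, subsets whose true
  quality gap is small are selected essentially at random. This is a
  property of the validation protocol, not of the optimizer.
* Models with k > 3 are out of scope (combinatorial cost outgrows the
  benefit); non-linear combinations and per-pose treatment are likewise not
  implemented.
* Scores are assumed complete; missing values are a load error by design.
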