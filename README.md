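# efoscreen

Consensus scoring for structure-based virtual screening by **enrichment
factor optimization (EFO)**: search linear combinations of 1–3
docking/rescoring scores that maximize a cluster-based enrichment objective,
validate every candidate score subset by repeated stratified train/test
splits, and report enrichment factors and ROC AUC on active/decoy
benchmarks.

## Who this is for

Computational chemists benchmarking docking protocols on DUD-style datasets
(a few dozen actives hidden among >95% decoys), who have a per-molecule
table of heterogeneous scores — force-field interaction terms, empirical
scores such as ChemPLP/PLP/X-Score, lipophilicity-based interaction scores,
contact counts — and want a principled, validated way to combine them into
one ranking instead of trusting any single function.

## The method

For a score subset S of size k ∈ {1, 2, 3}, a consensus model ranks
molecules by

&nbsp;&nbsp;&nbsp;&nbsp;s(x) = Σ_{j∈S} w_j (x_j − μ_j)/σ_j,&nbsp;&nbsp;‖w‖₂ = 1,

and the coefficients w are fitted by maximizing the quality function

&nbsp;&nbsp;&nbsp;&nbsp;Q = a_C + (1 − r̄/N),

where a_C is the number of actives in the top-C cluster (C = 100 by
default) and r̄ the mean rank of the actives. Q is rank-based and
piecewise constant, so the optimizer is a derivative-free accept-if-better
Gaussian pattern search on the unit sphere (12 random starts, ≤5000
iterations, step-size tolerance 0.001), exact for k = 1. Before the
exhaustive subset search, interrelated scores are discarded (variance
inflation factor > 5, greedy with recomputation) and ineffective ones
dropped (best-orientation EF at the top 5% < 2.0). Every surviving
k-subset is then re-fitted on five stratified 80/20 training splits and
ranked by its average test Q; the winner is refitted on the full table.
Enrichment factor at fraction f is EF_f = (a_f/s_f)/(A/N) with
s_f = ⌈fN⌉ (EF = 1 for a random ranking); AUC uses the rank-sum statistic
with half credit for ties. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Generate a DUD-like synthetic benchmark (3000 molecules, 80 actives, 11
correlated energy-convention scores with a planted signal) and screen it:

```sh
efoscreen simulate --out bench.csv --seed 7
efoscreen screen --table bench.csv --out-prefix run --k 2 --seed 1
```

which prints (output of this exact command):

```
INFO efoscreen.pipeline: VIF filter: 11/11 columns survive (removed: none)
INFO efoscreen.pipeline: effectiveness filter: 10 columns survive
selected score_01+score_02 (full-data EF1% = 13.75, AUC = 0.854)
wrote run.model.json, run.validation.csv, run.filters.json
```

Reading the numbers: the prefilters kept 10 of the 11 scores, the
exhaustive search over all 45 pairs selected the two most informative ones,
`score_01+score_02`; ranking all 3000 molecules by the fitted combination
puts 13.75× more actives in the top 1% than a random ranking would
(11 of the 80 actives in the top 30 molecules), and the overall
active/decoy separation is AUC 0.854. `run.validation.csv` holds the
per-subset validation table (average and per-repeat test EF/Q/AUC),
`run.model.json` the unit-norm coefficients, standardization parameters and
the echoed configuration, and `run.filters.json` the VIF/effectiveness
filter reports. Apply the frozen model to any table with the same score
columns, or rescore an exported ranking:

```sh
efoscreen apply --model run.model.json --table bench.csv --out ranked.csv
efoscreen metrics --table ranked.csv --score-col combined_score
```

The same pipeline is available as a scikit-learn estimator:

```python
from efoscreen import EFORanker, read_score_table

table = read_score_table("bench.csv")
ranker = EFORanker(k=2, random_state=0).fit(table.scores, table.labels)
ranker.subset_, ranker.coef_      # selected scores, unit-norm coefficients
scores = ranker.decision_function(table.scores)
```

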