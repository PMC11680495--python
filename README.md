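# densefc

Network-level statistics for **dense-sampling (precision) functional
connectivity studies** — repeated-measures designs in which a modest cohort
is scanned at many sessions so that *within-person* state variables (here:
daily positive and negative affect) can be related to functional
connectivity, separately from stable between-person differences.

The package implements, end to end:

- **Connectome construction** — Pearson correlation between parcellated BOLD
  timeseries, Fisher z-transformed (`z = atanh(r)`), with edge-level
  averaging of subcortical affective ROIs (amygdala + nucleus accumbens →
  one `SUBCTX` node) and partition of all node pairs into
  within-/between-network cells (28 analysis nodes in 9 networks →
  45 cells over 378 edges).
- **Edgewise linear mixed models** — at every edge
  `z ~ affect + age + sex + session + condition + motion + drowsiness + (1|subject)`,
  with affect *subject-mean centered* (so its coefficient reflects
  within-person day-to-day variation) and all other covariates grand-mean
  centered. The edge statistic is `t = beta/se` of the affect term. A
  profiled-REML solver vectorized across edges makes a full 378-edge refit
  take milliseconds, which is what makes permutation inference affordable;
  it is validated against `statsmodels` MixedLM in the test suite.
- **cNBS inference** — the constrained network-based statistic: a cell's
  observed effect is the mean edge `t` over its member edges, compared with
  a permutation null built by shuffling each subject's connectivity across
  that subject's sessions (session blocks move together, conditions stay
  matched, nothing crosses subjects). One-tailed p for directional
  hypotheses, two-tailed for the exploratory all-cells family, standardized
  effect sizes `SES = (observed − null mean)/null SD`, and
  Benjamini–Hochberg FDR within each family. Small relabeling spaces are
  enumerated exactly.
- **mv-cNBS** — multivariate pooling of a cell grouping (whole brain /
  within-network / between-network) via the Euclidean norm of the
  cell-effect vector scaled by the number of cells, tested against the same
  permutation null.
- **Variance partitioning** — stepwise conditional-R²
  (Nakagawa–Schielzeth) ledgers: predictor blocks enter in a fixed order
  (subject, demographics, condition, motion, drowsiness, affect), each
  block's Δr²c is floored at zero and expressed as percent of the total
  explained variance.
- **Synthetic cohort generator** — behavior tables and connectomes with the
  study's variance structure (dominant subject-specific connectomes,
  condition effects concentrated in the visual network, small within-person
  affect effects, PANAS-X/motion/drowsiness distributions) and a recorded
  ground truth, so every stage is testable by parameter recovery without
  any imaging data.

## Worked example

```python
from densefc import (CohortParams, generate_behavior, generate_connectomes,
                     build_observation_table, cnbs_test, stepwise_ledger)
from densefc.atlas import toy_labels

params = CohortParams(n_subjects=12, n_sessions=4, node_labels=toy_labels(),
                      affect_beta={"NET1-NET1": 0.05}, condition_effect={},
                      seed=7)
behavior = generate_behavior(params)                  # 48 session reports
connectomes, truth = generate_connectomes(params, behavior)
table = build_observation_table(connectomes, behavior)  # 144 obs × 36 edges

results, null = cnbs_test(table, affect="positive", B=1000, seed=7,
                          tails="greater")
print(results[["cell", "observed_t", "ses", "p", "q"]].head(4))
```

prints

```
     cell  observed_t       ses        p        q
NET1-NET1   22.957560 11.511759 0.000999 0.005994
NET2-NET2    0.228124  0.463996 0.324675 0.769231
NET3-NET3   -0.388558 -0.734199 0.765235 0.769231
NET1-NET2   -0.021644  0.123029 0.440559 0.769231
```

The cell carrying the injected 0.05 z-units-per-PANAS-point slope is
detected at the permutation floor `p = 1/1001` with a large standardized
effect size; null cells sit near SES 0 with uniform-looking p. The
variance ledger for the injected cell,

```python
ledger = stepwise_ledger(table, outcome="NET1-NET1", affect="positive")
print(ledger.steps[["block", "r2c_after", "percent"]])
```

```
       block    r2c_after   percent
     subject 1.000002e-08  0.000001
demographics 2.150567e-03  0.229510
   condition 8.703203e-02  9.058635
      motion 1.079308e-01  2.230341
  drowsiness 1.450117e-01  3.957302
      affect 9.370227e-01 84.524211
```

attributes the explained variance to affect, as injected: the slope was
chosen an order of magnitude above realistic values so the example is
unambiguous (for this draw the cell-mean subject variance even sits at the
ML boundary). With the generator's defaults — a small affect slope and
dominant subject intercepts — the ledger instead shows the signature seen
in real cohorts: subject identity explaining most variance and affect a
few percent at most.

## Command line

```bash
densefc simulate --seed 7 --out sim/
densefc build-table --labels sim/labels.tsv --behavior sim/behavior.csv \
        --connectomes sim/connectomes.csv --out obs.csv
densefc infer --table obs.csv --labels sim/labels.tsv \
        --family hypothesized --permutations 1000 --seed 7 --out cnbs.csv
densefc run-all --config config.yaml --out results/
```

`run-all` executes behavior prep → connectome assembly → edge models →
cNBS/mv-cNBS → variance ledgers and stamps outputs with the config hash;
two runs with the same config are byte-identical.

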