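# Methods

## Study design and data model

The package targets repeated-measures ("dense sampling" / precision fMRI)
cohorts: N subjects × K sessions, each session containing C passive-viewing
conditions with two functional runs per condition. Behavior is measured at
the session level (PANAS-X positive and negative affect over the past 24 h)
and at the run level (framewise displacement; three post-scan drowsiness
items). The connectivity observation unit is the (subject, session,
condition) triple: the two runs of a condition are concatenated in time,
Pearson correlations between parcellated node timeseries are Fisher
z-transformed (`z = atanh(r)`, with |r| clipped at 1−1e−12 and a warning,
so degenerate synthetic inputs stay finite), and the four subcortical
affective ROIs (bilateral amygdala and nucleus accumbens) are collapsed
into one `SUBCTX` node by averaging edge z-values (averaging the raw
timeseries before correlation is available behind
`average_subcortex`/`compute_fc` composition, but edge-level averaging is
the default because the collapsed quantity is a regional *connectivity*
summary). The single salience parcel is merged with the cingulo-opercular
network (`SAL/CO`). The default parcellation is 27 cortical ROIs in what
become 8 cortical networks, plus `SUBCTX`: 28 nodes, 9 networks, 378
edges, partitioned into 9 within- + 36 between-network cells. A
single-node network (here `SUBCTX`) has an empty within-network cell; it
remains in the partition for bookkeeping but carries no statistic and is
excluded from inference and from mv-cNBS groupings.

## Behavioral preparation

Drowsiness: per run the endorsed item of highest severity counts
(difficulty staying awake 3, sleepy 2, tired 1, none 0); the condition
score is the sum over the condition's two runs (0–6). The per-run
aggregation is *max*, not sum, because a 0–6 condition range is only
consistent with a per-run maximum. Any run endorsing difficulty staying
awake flags its observation for the sleep-exclusion sensitivity rerun
(`exclude_sleep`); exclusion is plain row filtering — centering is not
recomputed on the reduced sample.

Centering: affect is centered on each subject's own mean, so its
coefficient isolates within-person variation; age, sex (0 female /
1 male), session index (numeric 1..K, reflecting the single signed session
trend such cohorts show), motion and drowsiness are grand-mean centered.
Motion and drowsiness are averaged within session for the behavioral
association models but kept per-condition for the connectivity models.

Behavioral association models (`outcome ~ predictor + (1|subject)`) use
statsmodels MixedLM with REML, Wald 95% CIs and two-tailed normal p —
these fits are few and speed-irrelevant. Singular fits are returned
flagged, never silently.

## Edgewise mixed model and solver

Per edge: `z ~ affect + age + sex + session + condition + motion +
drowsiness + (1|subject)`, condition treatment-coded with the low-demand
video as reference; one valence per model. The edge statistic is the
affect coefficient's `t = beta/se`; no degrees-of-freedom p is attached
because inference is permutation-based downstream. Random slopes are
deliberately out of scope: four sessions per subject cannot support them.

The solver profiles the (RE)ML criterion over the single variance ratio
`rho = sigma_b^2/sigma_e^2`. Using within/between-subject sufficient
statistics, the generalized-least-squares pieces for *all* edges at a
candidate rho cost one p×p solve plus a p×E product, so the criterion is
minimized per edge with a coarse log-grid (25 points over rho ∈ [1e−8,
1e4]) followed by 26 golden-section refinements — edge-specific optima,
fully vectorized. SEs are the exact GLS expression
`sqrt(sigma_e^2 · diag((X'V0^-1X)^-1))` at the fitted ratio. REML is used
for coefficient inference; all variance-ledger fits use ML so r²c is
comparable across models with different fixed effects. The test suite
validates estimates, variance components and SEs against statsmodels
MixedLM (whose SEs come from a numerical Hessian and agree to ~1e−3) and
against the closed-form GLS SE (agreement ~1e−6).

Degenerate cases: a rank-deficient design raises an error naming the
collinear columns (on cohorts of only two subjects, subject-level
covariates are inherently collinear — the tiny enumeration-oracle analyses
therefore drop `age_c`/`sex_c` via the `drop` argument); an outcome with
numerically zero residual variance is flagged non-converged with NaN
statistics and is dropped (with its count logged) from cell means rather
than silently biasing them.

## cNBS permutation inference

A cell's observed effect is the arithmetic mean of its member edges'
t-values. The null relabels, independently per permutation and per
subject, that subject's session blocks of connectivity: all condition rows
of a session move together, the condition alignment is preserved, no data
crosses subjects, and predictor columns never move. Edges are refit in
full on each relabeled table (same specification and convergence policy as
the observed fit), and each cell's mean permuted t is recorded — this
preserves exchangeability of exactly the statistic being tested.

Relabelings are sampled uniformly with replacement from the product of
per-subject session permutations (identity allowed); when that product
space is no larger than the requested number of permutations (and at most
1e5) it is enumerated exactly instead, which is both cheaper and exact.
Sampled p-values use the add-one estimator `(1 + #extreme)/(1 + B)`, which
never returns zero; enumerated p-values are exact counts. Directional
hypothesis cells use one-tailed p (default tail "greater", configurable
per cell — the tail is exposed as configuration rather than inferred from
the observed sign); the exploratory all-cells family is two-tailed, with
extremity measured as |value − null mean|. SES = (observed − null
mean)/null SD (SD with ddof=1); a degenerate null yields an absent SES
with a warning. Benjamini–Hochberg FDR (statsmodels) is applied within
each family separately.

mv-cNBS pools a grouping of cells as the Euclidean norm of the cell-effect
vector divided by the number of cells K; `norm/sqrt(K)` is available via
`normalization="rms"`. Either reading yields a valid permutation test
since the identical formula is applied to observed and null. The pooled
statistic is non-negative, so the test is inherently one-sided; the SES is
reported as absent when the observed pooled effect falls below the null
mean.

## Variance ledgers

For an outcome (the mean Fisher z over a declared edge set per
observation; `whole_brain` = all 378 edges — edge-averaging before
modeling, the simplest reading, rather than averaging edge-level ledgers),
six nested ML models are fit in the fixed order subject → demographics →
condition → motion → drowsiness → affect. Conditional R² is
Nakagawa–Schielzeth: `(var_f + sigma_b^2)/(var_f + sigma_b^2 +
sigma_e^2)` with `var_f` the sample variance (ddof=1) of the fixed-effect
linear predictor; step 1's fixed part is the intercept alone, so its Δ is
the intraclass share. The session covariate enters with the condition
block (both are scan-context terms; the stepwise block list names six
blocks only). Negative Δr²c is floored at zero and floored increments are
normalized to percent of their sum; any non-converged step flags the
ledger and suppresses percents. The ledger report drops zero-contribution
blocks, as a stacked-proportion figure would.

## Synthetic cohort generator

The generator exists so that calibration, recovery and determinism can be
measured with known truth. Defaults encode the target cohort: 24 subjects
(12F/12M, age 41.15 ± 3.60) × 4 sessions × 3 conditions × 2 runs; PA
26.51 ± 6.48 and NA 11.86 ± 3.67 truncated to the PANAS-X range [10, 50]
by resampling, drawn independently per valence (the cohort showed no
within-person PA–NA coupling) with session trends −0.75 (PA) and −0.47
(NA) points/session; FD 0.08 ± 0.03 mm truncated below at 0.01; the three
drowsiness items as independent per-run Bernoulli flags with rates (tired
0.42, sleepy 0.25, awake-difficulty 0.10), chosen so the condition score
mean is ≈2 and roughly a fifth of observations carry an awake-difficulty
flag. The split of affect variance into between- and within-subject parts
is not identified by published descriptives, so it is exposed as
`affect_icc` (default 0.5, an equal split).

Edge z-values are subject intercept (base 0.30 within- / 0.10
between-network + N(0, subject_sd) per subject and edge, default 0.15) +
condition offsets (a zero-sum linear contrast of amplitude
`condition_effect[network]` across conditions on that network's
within-cell edges; default 0.15 on the visual network) + affect slope ×
true subject-centered affect (scalar or per-cell map; default 0.004
z/point, i.e. a within-person effect of a few percent) + uniform nuisance
effects (motion 0.3 z/mm, drowsiness 0.01 z/point, sex 0.02; age 0) +
N(0, noise_sd = 0.10). With these defaults subject identity accounts for
roughly two-thirds of edge variance, in the range such cohorts report.
All injected effects are returned in a `GroundTruth` object and
serializable to JSON.

`null_mode=True` zeroes the affect slope, the session trends *and* the
nuisance effects on connectivity, because a covariate effect that travels
with a session block would mildly break exchangeability under the
session-permutation null; null-calibration datasets are exactly null.

Timeseries generation (for testing the connectome-construction path) draws
Gaussian node signals with the target correlation via Cholesky, two runs
of 200 volumes per condition; a non-positive-definite target raises an
error naming the observation. No hemodynamics, autocorrelation or motion
artifacts are simulated — Gaussian channels suffice for the statistics
under test, which also bounds what passing tests show about real BOLD
data: they validate the statistical machinery, not robustness to imaging
artifacts.

Randomness: one root seed with named integer substreams per stage
(behavior / connectomes / timeseries-per-observation), so partial reruns
are reproducible; identical parameters and seed give bit-identical
outputs, and the full pipeline writes byte-identical result bundles.

## Problem sizes used in the validation runs

Type-I calibration uses 200 exactly-null cohorts of 12 subjects × 4
sessions × 3 conditions on a 9-node/3-network parcellation with B=200
one-tailed permutations — small enough to refit ~40k mixed-model tables in
minutes, large enough for a binomial check of the 0.05 level.
Enumeration-oracle agreement uses 2 subjects × 3 sessions ((3!)² = 36
relabelings) against B=10,000 samples. CI coverage uses 100 cohorts of 50
subjects × 8 sessions per slope in {0, 0.02, 0.05} z/point; cell-level
power monotonicity uses 40 cohorts of 12 × 4 with B=100 per slope.
Variance-share recovery uses 200 cohorts of 12 × 4 with the subject share
configured at 0.8. `scripts/acceptance.py` recomputes the same quantities
at comparable sizes from a user-supplied seed.

## Known limitations

- Only random intercepts; no random affect slopes (underdetermined at few
  sessions per subject).
- The permutation scheme assumes every subject has the same session
  structure available; a single-session subject is left unpermuted with a
  warning rather than dropped.
- The exploratory family's two-sided extremity is measured about the null
  mean; other two-sided definitions (e.g. doubling the smaller tail)
  differ for skewed nulls.
- Real-data ingestion starts at parcellated timeseries or connectomes;
  imaging formats and preprocessing are out of scope.
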