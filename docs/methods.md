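# Methods

## Constraint model and classification

The unit of analysis is one canonical transcript per gene with counts of
distinct predicted loss-of-function (pLoF) variants: `obs_lof` observed in a
large adult reference cohort and `exp_lof` expected under a neutral
mutational model. Expected counts are *inputs* — this package never re-fits
a sequence-context mutation model. The constraint summary is the ratio
LOE = obs/exp with a 90% confidence interval [LOELF, LOEUF]; missense
analogues (MOE/MOELF/MOEUF) are treated identically.

Classification uses the conventional 0.35 cut-off with strict inequalities,
evaluated as a cascade:

| call | rule |
|---|---|
| constrained | LOEUF < 0.35 |
| likely constrained | otherwise, LOE < 0.35 |
| not constrained | otherwise, LOELF > 0.35 |
| likely not constrained | otherwise |

A gene sitting exactly on 0.35 therefore falls to the less-constrained
side. Genes without defined LoF metrics (non-coding genes such as *RMRP*)
classify as *undefined*, are never dropped silently from panel censuses
(they occupy an explicit `undefined` column so group totals are conserved),
and are excluded from distributional statistics. Missense classification
reuses the same cascade and threshold on the missense metrics; the 0.35
value is a reference point there, not a claim that missense constraint has
the same calibration.

## Poisson o/e confidence bounds

When constraint tables are synthesized (or a source table lacks CI columns),
bounds come from the exact (Garwood) Poisson interval for the rate ratio:
`lower = Q_gamma(alpha/2; obs)/exp` (0 when obs = 0) and
`upper = Q_gamma(1 - alpha/2; obs + 1)/exp`, with alpha = 0.10 by default.
The closed form is testable (`upper = -ln(0.05)/exp` at obs = 0) and
mirrors the role the precomputed bounds play in real metrics files; it is
not the likelihood-grid procedure the reference cohort used. Exact
intervals are conservative: realised coverage is above nominal and
approaches it as the expected count grows (about 91.0% at an expected count
of 50, 92–93% near 10–20). The coverage tests therefore run at expected
count 50, where the interval is effectively calibrated.

## Fisher exact test with conditional-MLE odds ratio

Published odds ratios in this literature are R `fisher.test` output, so the
contract here is digit-level agreement with R, not merely asymptotic
equivalence:

* **p-value** — sum of conditional hypergeometric probabilities not
  exceeding the observed table's, with ties included at relative tolerance
  1e-7. Verified against exhaustive exact-rational enumeration on every 2×2
  table with total ≤ 40.
* **odds ratio** — the conditional MLE: the noncentrality psi solving
  E_psi[X] = a under the Fisher noncentral hypergeometric law given both
  margins. This differs from the sample cross-product ratio (e.g. 18.1 vs
  18.8 on the 34/19/2/21 table) and is what R reports.
* **confidence interval** — inversion of one-sided exact tests at
  alpha/2 per side. The inversion is solved, as in R, by Brent's `zeroin`
  on psi in (0, 1] or on 1/psi, with R's default convergence tolerance
  (eps^0.25 on the transformed scale). The tolerance matters: near the
  endpoint the objective is extremely flat, so a machine-precision root can
  differ from R's printed endpoint by a few tenths on large odds ratios.
  Because the published numbers carry that behaviour, the root finder is a
  faithful port (validated to ~1e-9 relative agreement with R across random
  tables) rather than a generic optimizer call. scipy's
  `contingency.odds_ratio(kind="conditional")`, which inverts to machine
  precision, serves as an independent cross-check of the point estimate in
  the tests.

Degenerate tables are signalled, not raised: a = support minimum gives
OR = 0 with a zero lower bound; a = support maximum gives +inf upper bound;
margin-determined tables give p = 1.

## Mann-Whitney U and size-corrected regression

The two-sided Mann-Whitney U uses exact enumeration when both samples have
n ≤ 8 and the pooled values are tie-free, else the normal approximation
with midrank tie and continuity correction (via scipy). Published p-values
at cohort scale come from the approximation, so cross-study agreement is
only meaningful to ~2 significant figures. Two identical constant samples
return p = 1 by definition.

Size-corrected group contrasts are OLS of the metric on an intercept, a
binary group indicator, and CDS length (statsmodels). The reported `r` is
the multiple correlation of the whole fit (sqrt of R²) — published "r"
values for such regressions are not explicitly defined, and multiple R is
the interpretation adopted here; the group inference itself (coefficient
and two-sided t-test p) does not depend on that choice.

## Size-matched gene sets and the resampling null

Targets are sorted by CDS length and cut into nine equal-count bins
(remainder to the smallest-length bins — the construction is not specified
beyond equal counts, so the deterministic choice is documented here). Each
bin's interval is the closed range of its targets' lengths; a universe gene
is a candidate for the lowest-index bin containing its length (resolving
overlaps at shared boundary lengths); the per-bin draw is the minimum
candidate count, giving the maximum subset with equal bins and no repeated
gene. Target genes are *not* excluded from the sampling universe. The
subset re-validates its own invariants after construction.

The resampling null draws k genes without replacement from the matched pool
per iteration (vectorised random-key argpartition, equivalent to uniform
subsets) and records the mean statistic. The empirical p-value uses the
add-one rule (1 + hits)/(iterations + 1), so "no instance seen in a million
samples" becomes a valid bound rather than zero.

## Cohort harmonization

Label cleaning is table-driven (packaged YAML, case- and
whitespace-insensitive; unmapped labels become `other` with a warning). The
packaged map covers common Sequence Ontology terms and the synonym spellings
seen in published supplements; it does not claim parity with any study's
full internal renaming list and is user-extensible. Rules with scientific
content:

* a variant is pLoF iff its ontology is frameshift, nonsense, or essential
  splice donor/acceptor — *regardless of reported pathogenicity*;
  `splice_region` is not pLoF;
* cross-study patient deduplication removes rows from the designated
  *secondary* study whose trimmed patient ID matches the St. Jude pattern
  and re-occurs in the primary study; nothing else is compared across
  studies;
* the only default variant exclusion is the APC c.3920T>A (p.Ile1307Lys)
  risk allele; HGVS strings are compared whitespace-stripped, with no
  attempt at full HGVS parsing or validation;
* unreported zygosity defaults to monoallelic (source studies under-report
  carrier state); the assumption count is logged.

Carrier counts for a gene use only studies whose panel covers the gene:
carriers are distinct patients with a qualifying variant, the denominator
is the covered studies' total patient count, and distinct variants are
unique HGVS strings. The full pass is idempotent.

## Nested downsampling

Curves count *distinct* LoF variants (recurrent variants once), not
carriers. The cohort-size ladder is the canonical 38-step vector shipped as
package data, truncated at the cohort size with the full cohort appended so
the last point is the actually observed count. Sampling is nested — each
smaller sample is drawn without replacement from the previous larger one —
making curves monotone by construction; the mean curve over seeds equals
the hypergeometric closed form E[distinct at n] = Σ_v (1 − C(N−k_v, n)/C(N, n)),
which the tests verify to 3 standard errors at 1000 seeds. One seed per
curve is the default (replicate bands are a caller loop); patients with
multiple variants contribute all of them.

## Synthetic data: what it emulates and what it does not

The universe generator draws CDS lengths log-normal (median 1,400 bp,
log-sd 0.75 — an exome-like spread), sets `exp_lof` = rate × length with
rate 0.012 expected distinct LoF per bp (a median gene then has ~17,
matching the order of magnitude of real per-gene expectations at reference
cohort depth), and draws `obs_lof ~ Poisson(depletion × exp_lof)`. The
default risk-group depletion of 0.25 mirrors the reported pCPS-panel mean
LOE of ~27%; the missense rate (0.14/bp) and milder missense depletion
(0.8) reproduce the weaker missense signal. Overdispersion is available but
off by default — the Poisson is the natural observation model behind an
o/e ratio.

The cohort generator plants per-gene carriers (Bernoulli, or exact counts
for rebuilding published tables), synthesizes plausible-looking HGVS tokens
with a recurrent-variant fraction of 0.2, and writes raw labels drawn from
messy synonym pools. The default case cohort is 4,574 patients over 11
studies; the overlap fixture reuses 259 of 914 secondary-study SJ-format
IDs in the primary study.

What the generator does **not** emulate: realistic site-frequency spectra
(beyond the recurrent-variant knob), sequence context, coverage or calling
artifacts, correlated gene sizes within pathways, and the true baseline
constraint distribution of the human exome — synthetic "neutral" genes have
o/e ≈ 1, whereas most real genes are somewhat depleted, so synthetic mean
LOEUF values exceed real ones. Passing tests therefore demonstrate that the
machinery recovers planted structure under the stated model, not that any
particular real panel is constrained; real-data conclusions require the
external per-gene metrics file, which the readers support directly.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep Monte-Carlo
error well inside the asserted bands: 5,000-gene universes with an 85-gene
planted panel and 10⁴-iteration resampling nulls (20 seeds) for recovery
checks; 10⁵ draws for interval coverage; 1,000 seeds on a 100-patient toy
cohort for downsampling means; exhaustive enumeration up to table total 40
for the exact test. Root finding uses R's uniroot tolerance (see above);
level classification treats NaN as undefined rather than erroring; RNG
streams are per-stage, derived from the master seed by hashing the stage
name, so adding a pipeline stage never perturbs another stage's draws.

## Known limitations

* The conditional-MLE CI reproduces R's root-finder behaviour by design;
  users wanting machine-precision inversion should use scipy's
  `odds_ratio` interval instead.
* The harmonizer's label map is intentionally small and extensible; exact
  replication of any one study's cleaning requires supplying that mapping.
* Carrier denominators assume each study's panel coverage applies to all of
  its patients uniformly; per-patient assay differences are out of scope.
* The packaged 85-gene panel annotation is a synthetic stand-in with the
  correct group partition (53/23/9 across monoallelic-LoF, biallelic, and
  gain-of-function groups) for testing; curated clinical annotations should
  be supplied for real analyses.
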