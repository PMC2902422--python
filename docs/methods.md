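# Methods

## The Bayesian interpreter

A VA case is a vector of responses in {yes, no, unknown} over a fixed
indicator list (default 100). The interpreter holds a probability base
`P(indicator | cause)` (rows = indicators, columns = causes; every entry
in [0, 1], no indicator impossible under all causes) and a prior cause
distribution, normally the population CSMF. Assuming conditional
independence of indicators given the cause, each *yes* response multiplies
every cause's probability by `P(indicator | cause)` followed by
renormalization.

*Negative responses.* By default, "no" and "unknown" do not update the
posterior: in VA interviews the absence of a report is weak evidence of
the absence of a symptom (recall failure, proxy respondents, skipped
sections). A switch (`update_on_no=True`) enables `1 − P` updating for
"no" responses for users who trust their negative data; both code paths
are verified against the same exhaustive joint-distribution oracle.

*Numerics.* Updates are accumulated in log space and normalized with
`logsumexp`, so products over ~100 indicators cannot underflow. A cause
with `P(indicator|cause) = 0` for an observed indicator is eliminated
exactly (log 0 = −inf); if every cause is eliminated the case is flagged
uninterpretable and reported indeterminate — batch interpretation logs a
warning and continues.

*Reporting.* Up to three causes are reported with likelihoods in percent
of the posterior. The top cause requires posterior ≥ `tau_top` (default
0.4); additional causes require ≥ `tau_rel` × top posterior (default
0.5). These cutoffs are configurable: the upstream tool's exact thresholds
are not published, and these defaults reproduce its qualitative behaviour
— one to three causes for clear cases, indeterminate for diffuse ones.
Ties are broken by cause-list order (stable sort), so results are
deterministic.

*Prevalence switches.* Before interpretation, priors of HIV/AIDS- and
malaria-related causes are scaled by a high/low multiplier (defaults 1.0
and 0.1) and the prior renormalized. The mechanism is deliberately the
simplest multiplicative adjustment consistent with a binary high/low
switch. The shipped configuration is malaria **low**, HIV/AIDS **high**,
matching an urban East-African surveillance population with <0.5% malaria
prevalence and >12% HIV prevalence.

*Cause list.* The default model vocabulary has 27 causes. Descriptions of
the upstream tool variously state 27 and 30 causes; the cause list here is
fully configurable, so nothing depends on that count.

## Cause harmonization

Physicians code against an abridged 60-code ICD-10 list; the model against
its 27 causes. Both are collapsed into 14 broad groups (the comparison
vocabulary) by total mapping tables; "indeterminate" passes through as a
15th category so every case stays in every table. The exact code lists
used in field practice are not published in full, so the shipped maps are
reconstructions covering the commonly coded causes (eclampsia and the
obstetric haemorrhages → maternity-related; rabies, tetanus, typhoid →
other acute/infectious; kidney disease and cancers →
noncommunicable/chronic; malaria, meningitis, TB, HIV/AIDS, pneumonia
stand alone). Both maps are plain `source_code,group` CSVs and are
user-replaceable; the pipeline validates totality and never drops an
unmapped code silently. The medical fidelity of the reconstruction is
explicitly *not* a claim this package makes — the analysis logic is.

## Agreement statistics

Percent agreement is the diagonal share of the cross-tabulation of the two
methods' groups (indeterminate included by default; an exclusion switch
reproduces the dropped-indeterminates sensitivity analysis). Cohen's κ is
the unweighted multi-category statistic, κ = (pₒ − pₑ)/(1 − pₑ), with the
Fleiss–Cohen–Everitt (1969) large-sample variance and a normal 95% CI
clipped to [−1, 1]; the implementation is tested to 1e-9 against
statsmodels' independent one on random tables. Weighted κ is out of scope
(a single unweighted κ per stratum is what the comparison needs).
Rank-k agreement compares physicians against the model's k-th cause,
optionally restricted to cases with at least k causes. Sensitivity /
specificity against physician review are deliberately not offered:
physician coding is not a gold standard.

## CSMF analysis

CSMF tables report per-group counts and fractions. The default denominator
is **all cases** with indeterminate as an explicit category (stratum
percentages then refer to the full stratum); `determined_only` removes
indeterminate cases from the denominator, which some summary figures
implicitly use. A rollup aggregates the 14 groups into infectious /
noncommunicable / injuries / maternal-perinatal-nutrition / indeterminate
(other/unspecified joins indeterminate — it denotes deaths without a
determinable specific cause). Comparisons report per-group absolute
differences and **CSMF accuracy**, `1 − Σ|a − b| / (2(1 − min b))`, the
standard community summary (1 = identical, 0 = worst possible against
reference `b`); it is an extension beyond the original comparison, used
here for synthetic-recovery checks.

## The synthetic cohort generator

Real labelled VA data cannot be shared, so validation runs on synthetic
cohorts whose truth is known. The generator emulates the study template:

| parameter | default | meaning |
|---|---|---|
| `n_cases` | 1,823 | cohort size (study template) |
| age mix | 8% <4w, 23.4% 4w–<5y, 4.6% 5–<18y, 64% ≥18y | reproduces 31.4% under-5 / 64% adult |
| stratum CSMFs | see `DEFAULT_STRATUM_CSMF` | truth per age stratum, mixture = overall CSMF |
| `n_indicators` | 100 | indicator count |
| `informativeness` | 0.9 | signature strength; 0 makes every indicator useless |
| `base_rate` | 0.05 | off-signature P(yes) |
| `missingness` | 0.1 | per-indicator P(response masked to unknown) |
| `injury_sparsity` | 5.0 | missingness multiplier for injury deaths |
| `theta` | 0.75 | per-coder probability of the true cause |
| `gamma` | 0.66 | probability a consensus meeting succeeds |
| `seed` | 0 | byte-identical output per seed |

Causes are sampled per age stratum (so perinatal deaths are neonates and
maternal deaths adults); the stratum CSMFs were chosen once as realistic
for a high-mortality urban informal settlement — infectious causes near
60% overall, dominated by HIV/AIDS, TB and pneumonia, with substantial
diarrheal and malnutrition mortality under five and injuries/chronic
disease in adults. Indicators are emitted as independent Bernoullis given
the cause from a generated base in which each cause owns a random
signature subset of indicators at probability `base_rate +
informativeness·(1 − base_rate)`, off-signature cells jittered around
`base_rate` in proportion to informativeness. The injury-sparsity
multiplier mimics structured questionnaires that capture little about
injury circumstances. γ = 0.66 reflects consensus meetings that resolve
roughly two-thirds of initially unresolved cases; θ is a free simulation
parameter (no published estimate of coder accuracy exists) and is swept in
tests rather than trusted.

*What the generator does not emulate:* indicator dependence given cause
(an optional probe exists in design but the default generator matches the
engine's independence assumption — recovery results are therefore
best-case, not evidence about misspecified real data); free-text
narratives; recall decay with interview delay; coder-specific biases or
correlated physician errors. Passing recovery tests show the pipeline's
statistics are computed correctly, not that the interpreter would agree
with physicians at any particular level on real data.

## Pipeline and reproducibility

`simulate → interpret → panel → compare` runs from one `RunConfig`; every
output CSV/report embeds the seed and a hash of the scientific
configuration, per-stage RNG streams are derived from the single seed, and
reruns are byte-identical. Strata are under-5 (<5 years), adult (≥18
years) and "other" (5–17 years, kept so totals always reconcile rather
than analyzed on its own). Degenerate strata where κ is undefined (all
mass in one margin) are reported as "n/a" rather than aborting the run.

Problem sizes in the shipped tests and acceptance script — 200 random
instances for the exact-posterior oracle, 1,000 draws for the
two-hypothesis identity and the κ oracle, cohorts of 1,823 and 2,000 for
the template and recovery runs — were chosen as the smallest sizes at
which the checks are statistically meaningful; the full suite runs in
well under a minute on one CPU.
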