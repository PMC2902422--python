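# vacompare

Tools for interpreting **verbal autopsies** (VA) — structured interviews
with the caregivers of a deceased person, used where deaths are not
medically certified — and for comparing the two standard ways of turning
them into causes of death: a Bayesian probabilistic interpreter (in the
style of InterVA) and review by a panel of physicians.

It is aimed at demographic-surveillance and burden-of-disease analysts who
need case-level cause assignments, cause-specific mortality fractions
(CSMF), and defensible agreement statistics between methods — plus a
synthetic-cohort generator with known truth for validating the whole
pipeline where real, labelled VA data cannot be shared.

## The model

Each death carries ~100 binary indicators \(I_1 \dots I_n\) (symptoms,
signs, history), answered yes / no / unknown. Given a probability base
\(P(I_j \mid C_k)\) over causes \(C_1 \dots C_m\) and a prior \(P(C_k)\)
equal to the population CSMF, the interpreter assumes the indicators are
conditionally independent given the cause and updates over each reported
("yes") indicator:

\[
P(C_k \mid \text{evidence}) \propto P(C_k) \prod_{j \,:\, I_j = \text{yes}} P(I_j \mid C_k),
\]

which for a single indicator reduces to the familiar two-hypothesis form
\(P(C \mid I) = \frac{P(I|C)P(C)}{P(I|C)P(C) + P(I|\lnot C)P(\lnot C)}\)
with \(P(I \mid \lnot C_k) = \sum_{k'\neq k} P(I|C_{k'})P(C_{k'}) / (1 - P(C_k))\).
Up to three causes are reported with likelihoods in percent (top posterior
≥ 0.4; further causes ≥ half the top), otherwise the case is
*indeterminate*. Priors for HIV/AIDS- and malaria-related causes can be
down-weighted through high/low prevalence switches before interpretation.

The physician arm is modelled as three independent coders who each assign
a cause (correct with probability θ), reconciled by the standard rule: any
cause held by two coders is final; three-way disagreement goes to a
consensus meeting that succeeds with probability γ, else the case is
indeterminate.

Both arms are harmonized into **14 broad cause groups** (HIV/AIDS,
pulmonary TB, pneumonia, malaria, meningitis, diarrheal diseases, measles,
other acute/infectious, maternity-related, preterm/perinatal,
malnutrition, noncommunicable/chronic, injuries, other/unspecified) and
compared by percent agreement, Cohen's κ (with the Fleiss–Cohen–Everitt
large-sample 95% CI), stratified CSMF tables and CSMF accuracy.

## Worked example

```bash
python examples/interpret_single_case.py
```

```
posterior over causes (sums to 1):
pulmonary_tb    0.7524
hiv_aids        0.2469
injuries        0.0008

rank 1: pulmonary_tb  likelihood 75.2%
```

An adult reported coughing blood and losing weight (no recent accident).
Those two indicators are likely under TB, possible under HIV/AIDS and
nearly impossible under injuries, so the prior (0.2, 0.3, 0.5) becomes the
posterior above; HIV/AIDS at 0.247 falls below half the top cause's 0.752
and is not reported as a second cause.

The other examples run the full synthetic pipeline
(`simulate_and_compare.py`), compare CSMFs with the broad rollup
(`csmf_comparison.py`), and sweep physician coding accuracy against
panel-vs-model κ (`coder_accuracy_sweep.py`). The same stages are
available as a CLI: `vacompare simulate | interpret | panel | map | agree
| csmf | compare`.

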