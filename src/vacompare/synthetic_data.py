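"""Synthetic VA cohorts with known truth.

The source data (an urban-slum demographic surveillance cohort of 1,823
deaths) are not public, so this module generates cohorts with the same
structure and a known true cause for every death:

* a true cause sampled from an age-stratum-specific CSMF (the stratum mix
  reproduces the study template: 31.4% under five, 64% adults);
* ~100 binary indicators emitted conditionally independently given the
  cause from a generated P(indicator|cause) base, in which each cause has
  a "signature" subset of indicators with elevated probability;
* missingness masking responses to "unknown", inflated for injury deaths
  (structured VA questionnaires capture little about injuries);
* a three-physician coding panel: each coder reports the true cause with
  probability theta, otherwise a draw from a confusion kernel; any cause
  held by two coders is final, otherwise a consensus meeting succeeds with
  probability gamma (uniform choice among the three votes) or the case is
  declared indeterminate.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes_engine import (
    AGE_GROUPS,
    INDETERMINATE,
    NO,
    UNKNOWN,
    YES,
    CaseIndicators,
    CauseAssignment,
    validate_probability_base,
)
from .cause_mapping import GROUPS

#: Age-stratum mix of the study template (31.4% under 5, 4.6% 5-17, 64% adult).
DEFAULT_AGE_MIX: dict[str, float] = {
    "<4w": 0.080,
    "4w-<5y": 0.234,
    "5-<18y": 0.046,
    ">=18y": 0.640,
}

#: True CSMFs per age stratum over the 14 broad groups (absent = 0); values
#: chosen as realistic for a high-mortality urban informal settlement, with
#: the burden dominated by HIV/AIDS, TB, pneumonia, diarrheal disease in
#: children and injuries/chronic disease in adults.
DEFAULT_STRATUM_CSMF: dict[str, dict[str, float]] = {
    "<4w": {
        "preterm_perinatal": 0.55,
        "pneumonia": 0.20,
        "diarrheal": 0.05,
        "meningitis": 0.05,
        "other_acute_infectious": 0.05,
        "malnutrition": 0.02,
        "hiv_aids": 0.03,
        "other_unspecified": 0.05,
    },
    "4w-<5y": {
        "hiv_aids": 0.10,
        "pulmonary_tb": 0.02,
        "pneumonia": 0.20,
        "malaria": 0.05,
        "meningitis": 0.04,
        "diarrheal": 0.18,
        "measles": 0.03,
        "other_acute_infectious": 0.08,
        "preterm_perinatal": 0.08,
        "malnutrition": 0.07,
        "noncommunicable_chronic": 0.04,
        "injuries": 0.06,
        "other_unspecified": 0.05,
    },
    "5-<18y": {
        "hiv_aids": 0.08,
        "pulmonary_tb": 0.05,
        "pneumonia": 0.10,
        "malaria": 0.06,
        "meningitis": 0.06,
        "diarrheal": 0.06,
        "other_acute_infectious": 0.10,
        "malnutrition": 0.03,
        "noncommunicable_chronic": 0.16,
        "injuries": 0.25,
        "other_unspecified": 0.05,
    },
    ">=18y": {
        "hiv_aids": 0.30,
        "pulmonary_tb": 0.12,
        "pneumonia": 0.08,
        "malaria": 0.02,
        "meningitis": 0.02,
        "diarrheal": 0.03,
        "other_acute_infectious": 0.04,
        "maternity_related": 0.03,
        "noncommunicable_chronic": 0.17,
        "injuries": 0.17,
        "other_unspecified": 0.02,
    },
}


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth cause for one simulated death."""

    case_id: str
    cause: str
    age_group: str


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the study template: 1,823 deaths, 100 indicators,
    strongly informative signatures (0.9) over a 0.05 background rate, 10%
    indicator missingness inflated fivefold for injury deaths, coder
    accuracy 0.75 and consensus success 0.66.
    """

    n_cases: int = 1823
    cause_labels: tuple[str, ...] = GROUPS
    age_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_MIX))
    stratum_csmf: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STRATUM_CSMF.items()}
    )
    n_indicators: int = 100
    informativeness: float = 0.9
    base_rate: float = 0.05
    missingness: float = 0.1
    injury_sparsity: float = 5.0
    injury_cause: str = "injuries"
    theta: float = 0.75
    gamma: float = 0.66
    confusion: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if not 0.0 <= self.theta <= 1.0 or not 0.0 <= self.gamma <= 1.0:
            raise ValueError("theta and gamma must lie in [0, 1]")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        if self.injury_sparsity < 1.0:
            raise ValueError("injury_sparsity is a multiplier >= 1")
        if abs(sum(self.age_mix.values()) - 1.0) > 1e-9:
            raise ValueError("age mix must sum to 1")
        if set(self.age_mix) - set(AGE_GROUPS):
            raise ValueError(f"age mix keys must be among {AGE_GROUPS}")
        for stratum, dist in self.stratum_csmf.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"stratum CSMF for {stratum!r} must sum to 1")
            if set(dist) - set(self.cause_labels):
                raise ValueError(f"stratum CSMF for {stratum!r} names unknown causes")

    def overall_csmf(self) -> pd.Series:
        """Overall true CSMF implied by the age mix and stratum CSMFs.

        Zero-mass causes get a tiny floor and renormalization so the result
        is usable directly as an engine prior (priors must be positive).
        """
        total = pd.Series(0.0, index=list(self.cause_labels))
        for stratum, w in self.age_mix.items():
            for cause, p in self.stratum_csmf[stratum].items():
                total[cause] += w * p
        floored = total.clip(lower=1e-6)
        return floored / floored.sum()


def generate_probability_base(
    n_causes: int,
    n_indicators: int,
    informativeness: float = 0.9,
    base_rate: float = 0.05,
    seed: int = 0,
    cause_labels: Sequence[str] | None = None,
    indicator_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate a synthetic P(indicator|cause) base with cause signatures.

    Indicators are randomly partitioned round-robin among causes; a cause's
    signature indicators get probability ``base_rate + informativeness *
    (1 - base_rate)`` while off-signature cells stay near ``base_rate``
    with jitter proportional to ``informativeness`` (so informativeness 0
    yields exactly constant rows and an engine posterior equal to the
    prior).
    """
    if n_indicators < n_causes:
        raise ValueError("need at least one indicator per cause to form signatures")
    if not 0.0 <= informativeness < 1.0:
        raise ValueError("informativeness must lie in [0, 1)")
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must lie in (0, 1)")
    if cause_labels is None:
        cause_labels = [f"cause_{k + 1:02d}" for k in range(n_causes)]
    if indicator_labels is None:
        indicator_labels = [f"s{j + 1:03d}" for j in range(n_indicators)]
    if len(cause_labels) != n_causes or len(indicator_labels) != n_indicators:
        raise ValueError("label lists must match n_causes / n_indicators")

    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.5, 0.5, size=(n_indicators, n_causes))
    values = np.clip(base_rate * (1.0 + informativeness * jitter), 1e-6, 1.0)
    signature_owner = rng.permutation(np.arange(n_indicators) % n_causes)
    hot = base_rate + informativeness * (1.0 - base_rate)
    values[np.arange(n_indicators), signature_owner] = hot
    base = pd.DataFrame(values, index=list(indicator_labels), columns=list(cause_labels))
    validate_probability_base(base)
    return base


def simulate_cohort(
    cfg: SimulationConfig, base: pd.DataFrame | None = None
) -> tuple[list[CaseIndicators], list[TruthRecord], pd.DataFrame]:
    """Draw a cohort: (cases, truth records, probability base used).

    The base defaults to :func:`generate_probability_base` under the
    config's own parameters and seed.
    """
    if base is None:
        base = generate_probability_base(
            n_causes=len(cfg.cause_labels),
            n_indicators=cfg.n_indicators,
            informativeness=cfg.informativeness,
            base_rate=cfg.base_rate,
            seed=cfg.seed,
            cause_labels=cfg.cause_labels,
        )
    validate_probability_base(base)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    indicators = list(base.index)
    causes = list(base.columns)
    cause_pos = {c: i for i, c in enumerate(causes)}

    strata = list(cfg.age_mix)
    stratum_p = np.array([cfg.age_mix[s] for s in strata])
    cases: list[CaseIndicators] = []
    truth: list[TruthRecord] = []
    width = max(5, len(str(max(cfg.n_cases, 1))))
    for i in range(cfg.n_cases):
        cid = f"case_{i + 1:0{width}d}"
        stratum = strata[rng.choice(len(strata), p=stratum_p)]
        dist = cfg.stratum_csmf[stratum]
        labels = list(dist)
        cause = labels[rng.choice(len(labels), p=np.array(list(dist.values())))]
        p_yes = base.to_numpy()[:, cause_pos[cause]]
        yes = rng.random(len(indicators)) < p_yes
        miss_rate = cfg.missingness * (cfg.injury_sparsity if cause == cfg.injury_cause else 1.0)
        masked = rng.random(len(indicators)) < min(miss_rate, 0.95)
        responses = {
            ind: (UNKNOWN if masked[j] else (YES if yes[j] else NO))
            for j, ind in enumerate(indicators)
        }
        sex = "M" if rng.random() < 0.56 else "F"
        site = "korogocho" if rng.random() < 0.66 else "viwandani"
        cases.append(
            CaseIndicators(case_id=cid, age_group=stratum, responses=responses, sex=sex, site=site)
        )
        truth.append(TruthRecord(case_id=cid, cause=cause, age_group=stratum))
    return cases, truth, base


def reconcile_panel(
    votes: Sequence[str], gamma: float, rng: np.random.Generator
) -> str:
    """Apply the panel rule to three coders' causes.

    Any cause held by at least two coders is final.  If all three differ, a
    consensus meeting succeeds with probability gamma (final cause drawn
    uniformly from the three votes); otherwise the case is indeterminate.
    """
    if len(votes) != 3:
        raise ValueError("the panel rule is defined for exactly three coders")
    a, b, c = votes
    if a == b or a == c:
        return a
    if b == c:
        return b
    if rng.random() < gamma:
        return votes[rng.integers(3)]
    return INDETERMINATE


def simulate_physician_panel(
    truth: Sequence[TruthRecord],
    theta: float,
    gamma: float,
    seed: int,
    cause_labels: Sequence[str] | None = None,
    confusion: Mapping[str, Mapping[str, float]] | None = None,
) -> list[CauseAssignment]:
    """Three noisy coders plus the 2-of-3 / consensus / indeterminate rule.

    Each coder independently reports the true cause with probability theta,
    otherwise a draw from the confusion kernel (default: uniform over the
    other causes).  The reconciled final cause is reported with a nominal
    100% likelihood, matching the single-cause physician output.
    """
    if not 0.0 <= theta <= 1.0 or not 0.0 <= gamma <= 1.0:
        raise ValueError("theta and gamma must lie in [0, 1]")
    if cause_labels is None:
        cause_labels = sorted({t.cause for t in truth}) or list(GROUPS)
    labels = list(cause_labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    def miscode(true_cause: str) -> str:
        if confusion is not None:
            dist = confusion[true_cause]
            keys = list(dist)
            return keys[rng.choice(len(keys), p=np.array(list(dist.values())))]
        others = [c for c in labels if c != true_cause]
        return others[rng.integers(len(others))]

    out: list[CauseAssignment] = []
    for rec in truth:
        votes = [
            rec.cause if rng.random() < theta else miscode(rec.cause) for _ in range(3)
        ]
        final = reconcile_panel(votes, gamma, rng)
        causes = () if final == INDETERMINATE else ((final, 100.0),)
        out.append(CauseAssignment(case_id=rec.case_id, causes=causes, method="physician"))
    return out


def truth_assignments(truth: Sequence[TruthRecord]) -> list[CauseAssignment]:
    """Truth records as assignments (for harmonization/agreement helpers)."""
    return [
        CauseAssignment(case_id=t.case_id, causes=((t.cause, 100.0),), method="truth")
        for t in truth
    ]
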