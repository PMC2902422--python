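"""InterVA-style Bayesian cause-of-death assignment for verbal autopsies.

A verbal-autopsy (VA) interview yields ~100 binary indicators (symptoms,
signs, medical history) for one death.  Given a conditional probability
base P(indicator | cause) and a prior cause distribution (the population
cause-specific mortality fractions), the engine updates the prior by
Bayes' theorem over the observed indicators — assuming the indicators are
conditionally independent given the cause — and reports up to three ranked
probable causes with likelihoods in percent, or "indeterminate" when no
cause is sufficiently supported.

The probability base is a plain :class:`pandas.DataFrame` (rows =
indicators, columns = causes); the prior and posterior are
:class:`pandas.Series` indexed by cause.  Updates are performed in log
space so that products over ~100 indicators cannot underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: Response tokens for a single indicator.
YES, NO, UNKNOWN = "Y", "N", "."
RESPONSES = frozenset({YES, NO, UNKNOWN})

#: Age groups used on VA case records (the model's own age banding).
AGE_GROUPS = ("<4w", "4w-<5y", "5-<18y", ">=18y")

#: Reserved label: never a column of the probability base.
INDETERMINATE = "indeterminate"

#: Default reporting thresholds (configurable everywhere they appear).
TAU_TOP = 0.4
TAU_REL = 0.5

_NORM_TOL = 1e-9


class ConfigurationError(ValueError):
    """An input object (base, prior, settings, labels) is inconsistent."""


class UninterpretableCaseError(ValueError):
    """Every cause has posterior probability zero under the observed pattern."""


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------

def validate_probability_base(base: pd.DataFrame) -> None:
    """Check a P(indicator|cause) grid: probabilities, unique labels, no dead rows."""
    if base.index.has_duplicates or base.columns.has_duplicates:
        raise ConfigurationError("probability base has duplicate indicator or cause labels")
    if INDETERMINATE in base.columns:
        raise ConfigurationError(f"'{INDETERMINATE}' is reserved and cannot be a cause column")
    if len(base.columns) < 2:
        raise ConfigurationError("probability base needs at least 2 causes")
    values = base.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any() or (values > 1).any():
        raise ConfigurationError("probability base entries must lie in [0, 1]")
    dead = base.index[(values == 0).all(axis=1)]
    if len(dead):
        raise ConfigurationError(
            f"indicator rows that are zero for every cause can never be observed: {list(dead)}"
        )


def validate_prior(prior: pd.Series) -> None:
    """Check a prior cause distribution: positive entries summing to one."""
    if prior.index.has_duplicates:
        raise ConfigurationError("prior has duplicate cause labels")
    v = prior.to_numpy(dtype=float)
    if (v <= 0).any() or (v > 1).any():
        raise ConfigurationError("prior entries must lie in (0, 1]")
    if abs(v.sum() - 1.0) > _NORM_TOL:
        raise ConfigurationError(f"prior must sum to 1 (got {v.sum()!r})")


def uniform_prior(causes: Sequence[str]) -> pd.Series:
    """Uniform prior over a cause list."""
    causes = list(causes)
    return pd.Series(1.0 / len(causes), index=causes, dtype=float)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseIndicators:
    """One death's observed indicator responses.

    ``responses`` maps every indicator label to ``"Y"`` (reported present),
    ``"N"`` (reported absent) or ``"."`` (not asked / unknown).
    """

    case_id: str
    age_group: str
    responses: Mapping[str, str]
    sex: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ConfigurationError(
                f"case {self.case_id!r}: unknown age group {self.age_group!r}; "
                f"expected one of {AGE_GROUPS}"
            )
        bad = {v for v in self.responses.values()} - RESPONSES
        if bad:
            raise ConfigurationError(
                f"case {self.case_id!r}: invalid responses {sorted(bad)}; expected Y/N/."
            )

    def yes_indicators(self) -> list[str]:
        return [k for k, v in self.responses.items() if v == YES]

    def no_indicators(self) -> list[str]:
        return [k for k, v in self.responses.items() if v == NO]


@dataclass(frozen=True)
class CauseAssignment:
    """Up to three ranked (cause, likelihood %) pairs for one case.

    An empty cause tuple means the method declared the case indeterminate.
    ``method`` tags the origin: ``"model"``, ``"physician"`` or ``"truth"``.
    """

    case_id: str
    causes: tuple[tuple[str, float], ...] = ()
    method: str = "model"

    def __post_init__(self) -> None:
        if len(self.causes) > 3:
            raise ConfigurationError(f"case {self.case_id!r}: at most 3 causes may be reported")
        pcts = [p for _, p in self.causes]
        if any(b > a for a, b in zip(pcts, pcts[1:])):
            raise ConfigurationError(f"case {self.case_id!r}: likelihoods must not increase by rank")

    @property
    def indeterminate(self) -> bool:
        return not self.causes

    def cause_at(self, rank: int) -> str | None:
        """1-based rank; None when the case has no cause at that rank."""
        if 1 <= rank <= len(self.causes):
            return self.causes[rank - 1][0]
        return None


@dataclass(frozen=True)
class PrevalenceSettings:
    """High/low prevalence switches for HIV/AIDS and malaria.

    InterVA lets the user declare the local prevalence of these two
    diseases before a run; a "low" setting multiplicatively down-weights
    the prior of every affected cause (default x0.1) before
    renormalization, a "high" setting leaves it at full weight (x1.0).
    """

    malaria: str = "low"
    hiv: str = "high"
    multiplier_high: float = 1.0
    multiplier_low: float = 0.1
    malaria_causes: tuple[str, ...] = ("malaria",)
    hiv_causes: tuple[str, ...] = ("hiv_aids",)

    def __post_init__(self) -> None:
        for level in (self.malaria, self.hiv):
            if level not in ("high", "low"):
                raise ConfigurationError(f"prevalence level must be 'high' or 'low', got {level!r}")
        if self.multiplier_high <= 0 or self.multiplier_low <= 0:
            raise ConfigurationError("prevalence multipliers must be positive")

    def multiplier(self, level: str) -> float:
        return self.multiplier_high if level == "high" else self.multiplier_low


def prevalence_for_causes(
    cause_labels: Iterable[str],
    malaria: str = "low",
    hiv: str = "high",
    multiplier_high: float = 1.0,
    multiplier_low: float = 0.1,
) -> PrevalenceSettings:
    """Build settings whose affected-cause lists are picked from *cause_labels*.

    Causes containing ``"hiv"`` are treated as HIV/AIDS-related and causes
    containing ``"malaria"`` as malaria-related, which matches both the
    14-group vocabulary and the shipped 27-cause model list.
    """
    labels = list(cause_labels)
    return PrevalenceSettings(
        malaria=malaria,
        hiv=hiv,
        multiplier_high=multiplier_high,
        multiplier_low=multiplier_low,
        malaria_causes=tuple(c for c in labels if "malaria" in c.lower()),
        hiv_causes=tuple(c for c in labels if "hiv" in c.lower()),
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def adjust_priors(prior: pd.Series, settings: PrevalenceSettings) -> pd.Series:
    """Scale the priors of HIV/AIDS- and malaria-related causes, renormalize."""
    validate_prior(prior)
    factors = pd.Series(1.0, index=prior.index)
    for causes, level in (
        (settings.malaria_causes, settings.malaria),
        (settings.hiv_causes, settings.hiv),
    ):
        for cause in causes:
            if cause not in prior.index:
                raise ConfigurationError(f"prevalence-affected cause {cause!r} not in cause list")
            factors[cause] *= settings.multiplier(level)
    adjusted = prior * factors
    return adjusted / adjusted.sum()


def complement_likelihood(
    base: pd.DataFrame, prior: pd.Series, indicator: str, cause: str
) -> float:
    """P(indicator | not cause), marginalizing the prior over the other causes.

    P(I|!Ck) = sum_{k' != k} P(I|Ck') P(Ck') / (1 - P(Ck)).
    """
    if indicator not in base.index:
        raise ConfigurationError(f"unknown indicator {indicator!r}")
    if cause not in base.columns:
        raise ConfigurationError(f"unknown cause {cause!r}")
    p_c = float(prior[cause])
    if p_c >= 1.0 - 1e-15:
        raise ConfigurationError(f"P({cause!r}) = 1: complement likelihood undefined")
    row = base.loc[indicator]
    others = [c for c in base.columns if c != cause]
    return float((row[others] * prior[others]).sum() / (1.0 - p_c))


def posterior_distribution(
    case: CaseIndicators,
    base: pd.DataFrame,
    prior: pd.Series,
    update_on_no: bool = False,
) -> pd.Series:
    """Bayes-update the prior over the case's observed indicators.

    Each "yes" indicator multiplies every cause's probability by
    P(indicator|cause) followed by renormalization; "no" and "unknown"
    responses do not update unless ``update_on_no`` is set, in which case
    "no" multiplies by 1 - P(indicator|cause).  For a single observed
    indicator this reduces exactly to the two-hypothesis form
    P(C|I) = P(I|C)P(C) / (P(I|C)P(C) + P(I|!C)P(!C)).
    """
    missing = set(base.index) - set(case.responses)
    if missing:
        raise ConfigurationError(
            f"case {case.case_id!r}: no response for indicators {sorted(missing)[:5]}..."
        )
    if not prior.index.equals(base.columns):
        prior = prior.reindex(base.columns)
        if prior.isna().any():
            raise ConfigurationError("prior and probability base cover different causes")

    with np.errstate(divide="ignore"):
        log_post = np.log(prior.to_numpy(dtype=float))
        yes = case.yes_indicators()
        if yes:
            log_post += np.log(base.loc[yes].to_numpy(dtype=float)).sum(axis=0)
        if update_on_no:
            no = case.no_indicators()
            if no:
                log_post += np.log1p(-base.loc[no].to_numpy(dtype=float)).sum(axis=0)

    if np.all(np.isneginf(log_post)):
        raise UninterpretableCaseError(
            f"case {case.case_id!r}: observed pattern has probability 0 under every cause"
        )
    log_post -= logsumexp(log_post)
    return pd.Series(np.exp(log_post), index=base.columns)


def select_causes(
    posterior: pd.Series,
    case_id: str = "",
    tau_top: float = TAU_TOP,
    tau_rel: float = TAU_REL,
    method: str = "model",
) -> CauseAssignment:
    """Report up to three ranked causes, or indeterminate.

    The top cause is reported only if its posterior reaches ``tau_top``;
    ranks 2-3 are added while their posterior is at least ``tau_rel`` times
    the top posterior.  Likelihoods are the posterior probabilities in
    percent.  Ties are broken by cause-list order (stable sort).
    """
    p = posterior.to_numpy(dtype=float)
    order = np.argsort(-p, kind="stable")
    top = p[order[0]]
    if top < tau_top:
        return CauseAssignment(case_id=case_id, causes=(), method=method)
    picked = [order[0]]
    for idx in order[1:3]:
        if p[idx] >= tau_rel * top:
            picked.append(idx)
    causes = tuple((str(posterior.index[i]), 100.0 * p[i]) for i in picked)
    return CauseAssignment(case_id=case_id, causes=causes, method=method)


def interpret_cohort(
    cases: Sequence[CaseIndicators],
    base: pd.DataFrame,
    prior: pd.Series,
    settings: PrevalenceSettings | None = None,
    tau_top: float = TAU_TOP,
    tau_rel: float = TAU_REL,
    update_on_no: bool = False,
) -> list[CauseAssignment]:
    """Interpret a cohort: prevalence-adjust the prior once, then per case
    compute the posterior and select causes.  Uninterpretable cases become
    indeterminate assignments with a logged warning; the batch never aborts.
    """
    validate_probability_base(base)
    validate_prior(prior)
    if settings is not None:
        prior = adjust_priors(prior, settings)
    out: list[CauseAssignment] = []
    for case in cases:
        try:
            post = posterior_distribution(case, base, prior, update_on_no=update_on_no)
        except UninterpretableCaseError as exc:
            logger.warning("flagging case as indeterminate: %s", exc)
            out.append(CauseAssignment(case_id=case.case_id, causes=(), method="model"))
            continue
        out.append(select_causes(post, case_id=case.case_id, tau_top=tau_top, tau_rel=tau_rel))
    return out
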