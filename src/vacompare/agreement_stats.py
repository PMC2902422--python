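"""Case-by-case agreement between two cause-of-death assignment methods.

Percent agreement and multi-category (unweighted) Cohen's kappa, with the
Fleiss–Cohen–Everitt large-sample standard error and a normal 95% CI.
"indeterminate" is a regular category by default (the study compares all
cases); an exclusion switch reproduces the dropped-indeterminates
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes_engine import INDETERMINATE, CauseAssignment
from .cause_mapping import CauseMap, harmonize_cohort


@dataclass(frozen=True)
class ContingencyTable:
    """Square cross-tabulation of two methods' harmonized groups."""

    counts: pd.DataFrame  # rows = method A, columns = method B, same labels
    stratum: str = "overall"

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.counts.columns):
            raise ValueError("contingency table must be square with shared labels")
        v = self.counts.to_numpy()
        if (v < 0).any() or not np.issubdtype(v.dtype, np.integer):
            raise ValueError("contingency table entries must be non-negative integers")

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def without(self, label: str) -> "ContingencyTable":
        """Drop one label from both axes."""
        keep = [l for l in self.counts.index if l != label]
        return ContingencyTable(self.counts.loc[keep, keep], stratum=self.stratum)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T, stratum=self.stratum)


@dataclass(frozen=True)
class AgreementResult:
    n_agree: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_agree / self.n_total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with observed/expected agreement and a 95% CI."""

    po: float
    pe: float
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    n: int


def cross_tabulate(
    a: Sequence[tuple[str, str]],
    b: Sequence[tuple[str, str]],
    stratum: str = "overall",
    labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate two (case id, group) lists over the same case ids."""
    da, db = dict(a), dict(b)
    if len(da) != len(a) or len(db) != len(b):
        raise ValueError("duplicate case ids within one method's assignments")
    if set(da) != set(db):
        off = sorted(set(da) ^ set(db))
        raise ValueError(f"case ids differ between methods: {off[:10]}")
    if labels is None:
        seen = set(da.values()) | set(db.values())
        labels = sorted(seen - {INDETERMINATE}) + ([INDETERMINATE] if INDETERMINATE in seen else [])
    labels = list(labels)
    pos = {g: i for i, g in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for cid, ga in da.items():
        counts[pos[ga], pos[db[cid]]] += 1
    df = pd.DataFrame(counts, index=labels, columns=labels)
    return ContingencyTable(df, stratum=stratum)


def percent_agreement(
    t: ContingencyTable, exclude_indeterminate: bool = False
) -> AgreementResult:
    """Diagonal fraction of the table, optionally after dropping the
    indeterminate row/column from both axes."""
    if exclude_indeterminate and INDETERMINATE in t.counts.index:
        t = t.without(INDETERMINATE)
    total = t.n
    if total == 0:
        raise ValueError("agreement undefined on an empty table")
    agree = int(np.trace(t.counts.to_numpy()))
    return AgreementResult(n_agree=agree, n_total=total)


def cohen_kappa(t: ContingencyTable, ci_level_z: float = 1.96) -> KappaResult:
    """Unweighted multi-category Cohen's kappa.

    kappa = (po - pe) / (1 - pe) with pe the margin-product chance
    agreement; the standard error is the Fleiss–Cohen–Everitt (1969)
    asymptotic formula (not the null-hypothesis SE), and the CI is
    kappa +/- 1.96 SE clipped to [-1, 1].
    """
    n = t.n
    if n == 0:
        raise ValueError("kappa undefined on an empty table")
    if len(t.counts) < 2:
        raise ValueError("kappa needs at least 2 categories")
    p = t.counts.to_numpy(dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if abs(1.0 - pe) < 1e-15:
        raise ValueError("chance agreement is 1: kappa undefined")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance.
    diag = np.diag(p)
    a = float((diag * (1.0 - (row + col) * (1.0 - kappa)) ** 2).sum())
    weights = (col[:, None] + row[None, :]) ** 2  # cell (i,j): (p+i + pj+)^2
    off = p * weights
    np.fill_diagonal(off, 0.0)
    b = (1.0 - kappa) ** 2 * float(off.sum())
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = max((a + b - c) / (n * (1.0 - pe) ** 2), 0.0)
    se = float(np.sqrt(var))
    return KappaResult(
        po=po,
        pe=pe,
        kappa=kappa,
        se=se,
        ci_low=max(kappa - ci_level_z * se, -1.0),
        ci_high=min(kappa + ci_level_z * se, 1.0),
        n=n,
    )


def rank_k_agreement(
    physician: Sequence[tuple[str, str]],
    model: Sequence[CauseAssignment],
    cmap: CauseMap,
    k: int = 1,
    restrict_to_rank: bool = False,
    stratum: str = "overall",
) -> tuple[AgreementResult, KappaResult]:
    """Agreement between physician groups and the model's rank-k cause.

    With ``restrict_to_rank`` the comparison is limited to cases for which
    the model reported at least k causes (the study's analysis of the 152
    two-cause cases); otherwise absent ranks count as indeterminate.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k!r}")
    if restrict_to_rank:
        model = [a for a in model if len(a.causes) >= k]
        keep = {a.case_id for a in model}
        physician = [(cid, g) for cid, g in physician if cid in keep]
        if not model:
            raise ValueError(f"no cases with at least {k} model causes")
    groups = harmonize_cohort(model, cmap, rank=k)
    table = cross_tabulate(physician, groups, stratum=stratum)
    return percent_agreement(table), cohen_kappa(table)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def agreement_rows(
    rows: Sequence[tuple[str, AgreementResult, KappaResult]]
) -> pd.DataFrame:
    """Tidy frame of per-stratum agreement results (one row per stratum)."""
    return pd.DataFrame(
        [
            {
                "stratum": s,
                "n": agr.n_total,
                "n_agree": agr.n_agree,
                "percent_agree": round(agr.percent, 2),
                "kappa": round(k.kappa, 3) if k else float("nan"),
                "kappa_ci_low": round(k.ci_low, 3) if k else float("nan"),
                "kappa_ci_high": round(k.ci_high, 3) if k else float("nan"),
            }
            for s, agr, k in rows
        ]
    )


def format_agreement_report(
    rows: Sequence[tuple[str, AgreementResult, KappaResult]],
    title: str = "Case-by-case agreement between methods",
) -> str:
    """Plain-text report mirroring a stratum / cases-in-agreement / kappa table."""
    lines = [title, "=" * len(title), ""]
    header = f"{'Stratum':<28}{'Cases in agreement':>22}    {'Kappa (95% CI)':<24}"
    lines += [header, "-" * len(header)]
    for stratum, agr, kap in rows:
        agree = f"{agr.n_agree} ({agr.percent:.2f}%)"
        ci = (
            f"{kap.kappa:.3f} ({kap.ci_low:.3f} - {kap.ci_high:.3f})"
            if kap is not None
            else "n/a"
        )
        lines.append(f"{stratum:<28}{agree:>22}    {ci:<24}")
    return "\n".join(lines) + "\n"
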