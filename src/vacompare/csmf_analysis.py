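"""Cause-specific mortality fractions (CSMF) by method and stratum.

The CSMF of a cause group is the fraction of deaths attributed to it.  The
default denominator is all cases in the stratum, with "indeterminate" as
an explicit category; a determined-only convention drops indeterminate
cases from the denominator.  A rollup step aggregates the 14 broad groups
into the major categories (infectious, noncommunicable, injuries,
maternal/perinatal/nutrition, indeterminate), and two tables can be
compared side by side, summarized by CSMF accuracy

    1 - sum_g |a_g - b_g| / (2 (1 - min_g b_g)),

which is 1 for identical tables and 0 at the worst possible error
relative to reference table *b*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes_engine import INDETERMINATE
from .cause_mapping import GROUPS

ALL_CASES = "all_cases"
DETERMINED_ONLY = "determined_only"

#: Broad rollup of the 14 groups used for headline comparisons.
DEFAULT_ROLLUP: dict[str, str] = {
    "hiv_aids": "infectious",
    "pulmonary_tb": "infectious",
    "pneumonia": "infectious",
    "malaria": "infectious",
    "meningitis": "infectious",
    "diarrheal": "infectious",
    "measles": "infectious",
    "other_acute_infectious": "infectious",
    "maternity_related": "maternal_perinatal_nutrition",
    "preterm_perinatal": "maternal_perinatal_nutrition",
    "malnutrition": "maternal_perinatal_nutrition",
    "noncommunicable_chronic": "noncommunicable",
    "injuries": "injuries",
    "other_unspecified": INDETERMINATE,
    INDETERMINATE: INDETERMINATE,
}


@dataclass(frozen=True)
class CSMFTable:
    """Per-group death counts and fractions for one method and stratum."""

    table: pd.DataFrame  # index = group, columns = count, fraction
    stratum: str = "overall"
    method: str = ""
    denominator: str = ALL_CASES

    @property
    def n(self) -> int:
        return int(self.table["count"].sum())

    def fraction(self, group: str) -> float:
        return float(self.table.loc[group, "fraction"])

    def count(self, group: str) -> int:
        return int(self.table.loc[group, "count"])


@dataclass(frozen=True)
class CSMFComparison:
    table: pd.DataFrame  # count/fraction per method plus abs_diff
    csmf_accuracy: float
    stratum: str = "overall"


def csmf(
    groups: Sequence[tuple[str, str]],
    denominator: str = ALL_CASES,
    stratum: str = "overall",
    method: str = "",
    group_order: Sequence[str] | None = None,
) -> CSMFTable:
    """Count and fraction of deaths per cause group.

    ``group_order`` fixes the row set (zero-count groups included), which
    makes tables from different methods directly comparable.
    """
    if not groups:
        raise ValueError("CSMF undefined on an empty case list")
    if denominator not in (ALL_CASES, DETERMINED_ONLY):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    counts = Counter(g for _, g in groups)
    if denominator == DETERMINED_ONLY:
        counts.pop(INDETERMINATE, None)
        if not counts:
            raise ValueError("no determined cases left under determined_only")
    if group_order is None:
        observed = set(counts)
        group_order = [g for g in (*GROUPS, INDETERMINATE) if g in observed]
        group_order += sorted(observed - set(group_order))
    elif denominator == DETERMINED_ONLY:
        group_order = [g for g in group_order if g != INDETERMINATE]
    n = sum(counts.values())
    df = pd.DataFrame(
        {
            "count": [counts.get(g, 0) for g in group_order],
            "fraction": [counts.get(g, 0) / n for g in group_order],
        },
        index=pd.Index(group_order, name="group"),
    )
    return CSMFTable(df, stratum=stratum, method=method, denominator=denominator)


def rollup(t: CSMFTable, rollup_map: Mapping[str, str] | None = None) -> CSMFTable:
    """Aggregate groups into broader categories; totals are preserved."""
    rmap = DEFAULT_ROLLUP if rollup_map is None else rollup_map
    missing = [g for g in t.table.index if g not in rmap]
    if missing:
        raise ValueError(f"rollup map does not cover groups: {missing}")
    target = [rmap[g] for g in t.table.index]
    agg = t.table.groupby(target, sort=False).sum()
    agg.index.name = "group"
    return CSMFTable(agg, stratum=t.stratum, method=t.method, denominator=t.denominator)


def csmf_accuracy(a: pd.Series, b: pd.Series) -> float:
    """CSMF accuracy of fractions *a* against reference fractions *b*."""
    if set(a.index) != set(b.index):
        raise ValueError("CSMF accuracy needs identical group sets")
    b = b.reindex(a.index)
    denom = 2.0 * (1.0 - float(b.min()))
    if denom == 0.0:  # reference concentrated on a single group
        return 1.0 if np.allclose(a, b) else 0.0
    return 1.0 - float((a - b).abs().sum()) / denom


def compare_csmf(a: CSMFTable, b: CSMFTable) -> CSMFComparison:
    """Side-by-side comparison of two CSMF tables over the same groups.

    Table *b* is the reference for the CSMF-accuracy summary (use the true
    CSMF, or the physician table when no truth exists).
    """
    if a.stratum != b.stratum:
        raise ValueError(f"stratum mismatch: {a.stratum!r} vs {b.stratum!r}")
    if set(a.table.index) != set(b.table.index):
        only_a = sorted(set(a.table.index) - set(b.table.index))
        only_b = sorted(set(b.table.index) - set(a.table.index))
        raise ValueError(f"group sets differ (only a: {only_a}, only b: {only_b})")
    bt = b.table.reindex(a.table.index)
    name_a = a.method or "a"
    name_b = b.method or "b"
    df = pd.DataFrame(
        {
            f"count_{name_a}": a.table["count"],
            f"fraction_{name_a}": a.table["fraction"],
            f"count_{name_b}": bt["count"],
            f"fraction_{name_b}": bt["fraction"],
        }
    )
    df["abs_diff"] = (df[f"fraction_{name_a}"] - df[f"fraction_{name_b}"]).abs()
    acc = csmf_accuracy(a.table["fraction"], bt["fraction"])
    return CSMFComparison(table=df, csmf_accuracy=acc, stratum=a.stratum)


def plot_csmf_comparison(comparison: CSMFComparison, path) -> None:
    """Grouped bar chart of two methods' CSMFs (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac_cols = [c for c in comparison.table.columns if c.startswith("fraction_")]
    ax = comparison.table[frac_cols].plot.bar(figsize=(10, 4))
    ax.set_ylabel("CSMF")
    ax.set_title(f"Cause-specific mortality fractions ({comparison.stratum})")
    ax.legend([c.removeprefix("fraction_") for c in frac_cols])
    plt.tight_layout()
    plt.savefig(path)
    plt.close()
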