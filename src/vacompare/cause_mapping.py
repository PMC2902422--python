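"""Harmonization of cause-of-death vocabularies into 14 broad groups.

Physicians code deaths with an abridged 60-code ICD-10 list while the
Bayesian interpreter assigns one of 27 model causes.  Case-by-case
comparison requires a common vocabulary, so both schemes are collapsed
into 14 broad cause groups (HIV/AIDS, pulmonary TB, pneumonia, malaria,
meningitis, diarrheal disease, measles, other acute/infectious,
maternity-related, preterm/perinatal, malnutrition,
noncommunicable/chronic, injuries, other/unspecified).  "indeterminate"
is a pass-through 15th category, never one of the groups.

Default maps for both schemes ship as package-data CSVs and are fully
user-replaceable (columns ``source_code,group``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bayes_engine import INDETERMINATE, CauseAssignment

#: The 14 broad cause groups used for every cross-method comparison.
GROUPS = (
    "hiv_aids",
    "pulmonary_tb",
    "pneumonia",
    "malaria",
    "meningitis",
    "diarrheal",
    "measles",
    "other_acute_infectious",
    "maternity_related",
    "preterm_perinatal",
    "malnutrition",
    "noncommunicable_chronic",
    "injuries",
    "other_unspecified",
)


class UnmappedCodeError(KeyError):
    """A source code is absent from the mapping (never silently dropped)."""

    def __init__(self, code: str, scheme: str = "") -> None:
        self.code = code
        suffix = f" in {scheme!r} map" if scheme else ""
        super().__init__(f"no group mapping for cause code {code!r}{suffix}")


@dataclass(frozen=True)
class CauseMap:
    """A total function from one scheme's cause codes to broad groups."""

    scheme: str
    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"cause map {self.scheme!r} is empty")
        for code, group in self.entries.items():
            if not str(group).strip():
                raise ValueError(f"cause map {self.scheme!r}: empty group for code {code!r}")
            if group == INDETERMINATE:
                raise ValueError(
                    f"cause map {self.scheme!r}: {INDETERMINATE!r} is a pass-through, not a target group"
                )

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.entries.values())))

    def __len__(self) -> int:
        return len(self.entries)


def load_mapping(path, scheme: str | None = None) -> CauseMap:
    """Read a ``source_code,group`` CSV; duplicate source codes are rejected."""
    df = pd.read_csv(path, comment="#", dtype=str)
    expected = {"source_code", "group"}
    if not expected.issubset(df.columns):
        raise ValueError(f"mapping file {path} must have columns {sorted(expected)}")
    dups = df["source_code"][df["source_code"].duplicated()]
    if len(dups):
        raise ValueError(f"duplicate source codes in {path}: {sorted(set(dups))}")
    name = scheme if scheme is not None else str(path)
    return CauseMap(scheme=name, entries=dict(zip(df["source_code"], df["group"])))


def _load_packaged(filename: str, scheme: str) -> CauseMap:
    ref = resources.files("vacompare.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return load_mapping(path, scheme=scheme)


def default_physician_map() -> CauseMap:
    """Reconstructed 60-code abridged ICD-10 list -> 14 groups."""
    return _load_packaged("physician_map.csv", "physician")


def default_interva_map() -> CauseMap:
    """Reconstructed 27-cause model list -> 14 groups."""
    return _load_packaged("interva_map.csv", "interva")


def identity_map(labels: Iterable[str], scheme: str = "identity") -> CauseMap:
    """Map each label to itself — used when a method already emits group labels."""
    return CauseMap(scheme=scheme, entries={c: c for c in labels if c != INDETERMINATE})


def map_cause(code: str, cmap: CauseMap) -> str:
    """Group label for one cause code; "indeterminate" maps to itself."""
    if code == INDETERMINATE:
        return INDETERMINATE
    try:
        return cmap.entries[code]
    except KeyError:
        raise UnmappedCodeError(code, cmap.scheme) from None


def harmonize_cohort(
    assignments: Sequence[CauseAssignment],
    cmap: CauseMap,
    rank: int = 1,
) -> list[tuple[str, str]]:
    """Map each case's rank-th cause into its broad group.

    Cases that are indeterminate, or that carry no cause at the requested
    rank, yield ``"indeterminate"``.
    """
    if rank not in (1, 2, 3):
        raise ValueError(f"rank must be 1, 2 or 3, got {rank!r}")
    out: list[tuple[str, str]] = []
    for a in assignments:
        cause = a.cause_at(rank)
        out.append((a.case_id, INDETERMINATE if cause is None else map_cause(cause, cmap)))
    return out
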