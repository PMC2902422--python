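"""CSV/YAML readers and writers for every pipeline artifact.

All files are plain CSV with optional ``#``-prefixed header comments that
record the seed and a hash of the generating configuration; readers skip
comments, so every writer's output round-trips through its reader.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .bayes_engine import (
    AGE_GROUPS,
    CaseIndicators,
    CauseAssignment,
    validate_prior,
    validate_probability_base,
)
from .synthetic_data import TruthRecord

_CASE_META = ["id", "age_group", "sex", "site"]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed: int | None, cfg_hash: str | None) -> str:
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    return "".join(line + "\n" for line in lines)


def _write_df(df: pd.DataFrame, path, seed=None, cfg_hash=None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, index=index)


# -- probability base and prior ---------------------------------------------

def write_probability_base(base: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    df = base.copy()
    df.index.name = "indicator"
    _write_df(df, path, seed, cfg_hash, index=True)


def read_probability_base(path) -> pd.DataFrame:
    base = pd.read_csv(path, comment="#", index_col=0)
    validate_probability_base(base)
    return base


def write_prior(prior: pd.Series, path, seed=None, cfg_hash=None) -> None:
    df = pd.DataFrame({"cause": prior.index, "probability": prior.to_numpy()})
    _write_df(df, path, seed, cfg_hash)


def read_prior(path) -> pd.Series:
    df = pd.read_csv(path, comment="#")
    prior = pd.Series(df["probability"].to_numpy(), index=df["cause"])
    validate_prior(prior)
    return prior


# -- cases and truth ----------------------------------------------------------

def write_cases(cases: Sequence[CaseIndicators], path, seed=None, cfg_hash=None) -> None:
    if not cases:
        _write_df(pd.DataFrame(columns=_CASE_META), path, seed, cfg_hash)
        return
    indicators = list(cases[0].responses)
    rows = [
        {
            "id": c.case_id,
            "age_group": c.age_group,
            "sex": c.sex,
            "site": c.site,
            **{ind: c.responses[ind] for ind in indicators},
        }
        for c in cases
    ]
    _write_df(pd.DataFrame(rows), path, seed, cfg_hash)


def read_cases(path) -> list[CaseIndicators]:
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    indicators = [c for c in df.columns if c not in _CASE_META]
    missing = set(_CASE_META[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"case file {path} lacks required columns {sorted(missing)}")
    return [
        CaseIndicators(
            case_id=row["id"],
            age_group=row["age_group"],
            responses={ind: row[ind] for ind in indicators},
            sex=row.get("sex", ""),
            site=row.get("site", ""),
        )
        for _, row in df.iterrows()
    ]


def write_truth(truth: Sequence[TruthRecord], path, seed=None, cfg_hash=None) -> None:
    df = pd.DataFrame(
        [{"id": t.case_id, "age_group": t.age_group, "cause": t.cause} for t in truth]
    )
    if df.empty:
        df = pd.DataFrame(columns=["id", "age_group", "cause"])
    _write_df(df, path, seed, cfg_hash)


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, comment="#", dtype=str)
    return [
        TruthRecord(case_id=r["id"], cause=r["cause"], age_group=r["age_group"])
        for _, r in df.iterrows()
    ]


# -- assignments --------------------------------------------------------------

def write_assignments(
    assignments: Sequence[CauseAssignment], path, seed=None, cfg_hash=None
) -> None:
    rows = []
    for a in assignments:
        if a.indeterminate:
            rows.append(
                {"id": a.case_id, "rank": "", "cause": "", "likelihood_pct": "",
                 "indeterminate": True, "method": a.method}
            )
        else:
            for rank, (cause, pct) in enumerate(a.causes, start=1):
                rows.append(
                    {"id": a.case_id, "rank": rank, "cause": cause,
                     "likelihood_pct": round(pct, 4), "indeterminate": False,
                     "method": a.method}
                )
    df = pd.DataFrame(rows, columns=["id", "rank", "cause", "likelihood_pct",
                                     "indeterminate", "method"])
    _write_df(df, path, seed, cfg_hash)


def read_assignments(path) -> list[CauseAssignment]:
    df = pd.read_csv(path, comment="#", dtype={"id": str, "cause": str, "method": str})
    out: list[CauseAssignment] = []
    for cid, grp in df.groupby("id", sort=False):
        method = str(grp["method"].iloc[0])
        if bool(grp["indeterminate"].iloc[0]):
            out.append(CauseAssignment(case_id=str(cid), causes=(), method=method))
        else:
            grp = grp.sort_values("rank")
            causes = tuple(
                (str(r["cause"]), float(r["likelihood_pct"])) for _, r in grp.iterrows()
            )
            out.append(CauseAssignment(case_id=str(cid), causes=causes, method=method))
    return out


# -- harmonized groups --------------------------------------------------------

def write_groups(groups: Sequence[tuple[str, str]], path, seed=None, cfg_hash=None) -> None:
    df = pd.DataFrame(groups, columns=["id", "group"])
    _write_df(df, path, seed, cfg_hash)


def read_groups(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, comment="#", dtype=str)
    return list(zip(df["id"], df["group"]))


# -- run configuration --------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run settings (paths, thresholds, prevalence, strata, seed)."""

    out_dir: str = "va_run"
    seed: int = 0
    n_cases: int = 1823
    tau_top: float = 0.4
    tau_rel: float = 0.5
    update_on_no: bool = False
    malaria: str = "low"
    hiv: str = "high"
    multiplier_high: float = 1.0
    multiplier_low: float = 0.1
    theta: float = 0.75
    gamma: float = 0.66
    informativeness: float = 0.9
    base_rate: float = 0.05
    missingness: float = 0.1
    injury_sparsity: float = 5.0
    exclude_indeterminate: bool = False

    def as_dict(self) -> dict:
        return dict(vars(self))

    def hash(self) -> str:
        # scientific settings only: where outputs land does not change them
        settings = {k: v for k, v in self.as_dict().items() if k != "out_dir"}
        return config_hash(settings)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig().as_dict())
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return RunConfig(**data)


def stratum_of(age_group: str) -> str:
    """Analysis stratum for an age group: under-5, adult, or other (5-17)."""
    if age_group in ("<4w", "4w-<5y"):
        return "under_5"
    if age_group == ">=18y":
        return "adult"
    if age_group == "5-<18y":
        return "other"
    raise ValueError(f"unknown age group {age_group!r}; expected one of {AGE_GROUPS}")
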