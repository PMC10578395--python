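"""Scoring the BMQ-AET and applying data-quality exclusion rules.

The 10-item BMQ-AET has two 5-item subscales — necessity beliefs and
concerns — each scored 1-5 per item with no reverse coding, so subscale
totals run 5-25 and the differential (necessity - concerns) runs -20 to
+20.  Quality rules flag "speed responders": respondents finishing in
under a third of the sample median time, or giving one identical response
to all 10 items of the pre- or the post-administration (straight-lining).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DataError

__all__ = [
    "BMQScores",
    "ExclusionLog",
    "score_bmq",
    "score_cohort",
    "flag_speed_responders",
    "apply_exclusions",
    "bc_subgroup_report",
]

NECESSITY_INDEX = (0, 1, 2, 3, 4)  # convention: first five items = necessity

KNOWN_RULES = ("under_18", "speed", "bc_diagnosis")


@dataclass(frozen=True)
class BMQScores:
    necessity: int
    concerns: int

    @property
    def differential(self) -> int:
        return self.necessity - self.concerns


def score_bmq(
    items: Sequence[int], necessity_index: Sequence[int] = NECESSITY_INDEX
) -> BMQScores:
    """Score one 10-item administration into subscale totals.

    ``necessity_index`` gives the (0-based) positions of the necessity
    items; the remaining five are concerns.
    """
    arr = np.asarray(items)
    if arr.shape != (10,):
        raise DataError(f"expected 10 item responses, got shape {arr.shape}")
    if not np.all((arr >= 1) & (arr <= 5)) or not np.all(arr == arr.astype(int)):
        raise DataError(f"item responses must be integers in [1, 5]: {list(items)}")
    nec_idx = list(necessity_index)
    if len(set(nec_idx)) != 5 or not all(0 <= i < 10 for i in nec_idx):
        raise DataError("necessity_index must be 5 distinct positions in 0..9")
    con_idx = [i for i in range(10) if i not in nec_idx]
    return BMQScores(int(arr[nec_idx].sum()), int(arr[con_idx].sum()))


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add subscale and differential columns for both administrations.

    Appends pre_/post_ necessity, concerns and differential columns
    computed from the item columns; the input table is not modified.
    """
    out = cohort.copy()
    for phase in ("pre", "post"):
        cols = [f"{phase}_item_{i}" for i in range(1, 11)]
        missing = [c for c in cols if c not in out.columns]
        if missing:
            raise DataError(f"cohort missing item columns: {missing}")
        vals = out[cols].to_numpy()
        if not ((vals >= 1) & (vals <= 5)).all():
            raise DataError(f"{phase} item responses outside [1, 5]")
        nec = vals[:, list(NECESSITY_INDEX)].sum(axis=1)
        con = vals[:, [i for i in range(10) if i not in NECESSITY_INDEX]].sum(axis=1)
        out[f"{phase}_necessity"] = nec
        out[f"{phase}_concerns"] = con
        out[f"{phase}_differential"] = nec - con
    return out


def flag_speed_responders(cohort: pd.DataFrame) -> pd.DataFrame:
    """Boolean flags for the three speed-responder criteria.

    The time criterion compares each completion time with one third of
    the median over the *full* pre-exclusion sample (strict inequality).
    Straight-lining is judged within the pre and the post administration
    separately.
    """
    times = cohort["completion_minutes"].to_numpy(dtype=float)
    if np.any(times <= 0):
        raise DataError("completion times must be positive")
    median = float(np.median(times))
    pre = cohort[[f"pre_item_{i}" for i in range(1, 11)]].to_numpy()
    post = cohort[[f"post_item_{i}" for i in range(1, 11)]].to_numpy()
    flags = pd.DataFrame(
        {
            "fast_time": times < median / 3,
            "straightline_pre": (pre == pre[:, :1]).all(axis=1),
            "straightline_post": (post == post[:, :1]).all(axis=1),
        },
        index=cohort.index,
    )
    flags["speed"] = flags.any(axis=1)
    return flags


@dataclass
class ExclusionLog:
    """Which rules fired for whom, and the resulting sample sizes."""

    n_before: int
    n_after: int
    rules: tuple[str, ...]
    counts: dict = field(default_factory=dict)
    flagged_ids: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_before": self.n_before,
                "n_after": self.n_after,
                "rules": list(self.rules),
                "counts": self.counts,
                "flagged_ids": {k: list(map(int, v)) for k, v in self.flagged_ids.items()},
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def apply_exclusions(
    cohort: pd.DataFrame, rules: Iterable[str] = ("under_18",)
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop rows failing any selected rule; log every flag.

    Rules: ``under_18`` (age < 18), ``speed`` (any speed-responder
    criterion), ``bc_diagnosis`` (self-reported breast-cancer diagnosis).
    The input table is untouched; the operation is idempotent.
    """
    rules = tuple(rules)
    unknown = set(rules) - set(KNOWN_RULES)
    if unknown:
        raise ValueError(f"unknown exclusion rules: {sorted(unknown)}")
    flags = {}
    flags["under_18"] = cohort["age"].to_numpy() < 18
    speed = flag_speed_responders(cohort)
    flags["speed"] = speed["speed"].to_numpy()
    flags["bc_diagnosis"] = cohort["bc_flag"].to_numpy().astype(bool) \
        if "bc_flag" in cohort.columns else np.zeros(len(cohort), bool)

    drop = np.zeros(len(cohort), dtype=bool)
    for r in rules:
        drop |= flags[r]
    filtered = cohort.loc[~drop].copy()
    ids = cohort["participant_id"] if "participant_id" in cohort.columns else cohort.index
    log = ExclusionLog(
        n_before=len(cohort),
        n_after=len(filtered),
        rules=rules,
        counts={
            **{r: int(flags[r].sum()) for r in KNOWN_RULES},
            "fast_time": int(speed["fast_time"].sum()),
            "straightline_pre": int(speed["straightline_pre"].sum()),
            "straightline_post": int(speed["straightline_post"].sum()),
            "removed": int(drop.sum()),
        },
        flagged_ids={r: np.asarray(ids)[flags[r]].tolist() for r in rules},
    )
    return filtered, log


def bc_subgroup_report(scored: pd.DataFrame, column: str = "pre_differential") -> dict:
    """Convenience two-sample t-test comparing the breast-cancer subgroup.

    Welch is deliberately not used: the pooled-variance Student t matches
    the conventional reporting style for these subgroup checks.
    """
    grp = scored["bc_flag"].astype(bool)
    a = scored.loc[grp, column]
    b = scored.loc[~grp, column]
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "column": column,
        "n_bc": int(grp.sum()),
        "n_other": int((~grp).sum()),
        "mean_bc": float(a.mean()),
        "sd_bc": float(a.std(ddof=1)),
        "mean_other": float(b.mean()),
        "sd_other": float(b.std(ddof=1)),
        "t": float(t),
        "df": int(len(scored) - 2),
        "p": float(p),
    }
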