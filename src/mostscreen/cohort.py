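"""Synthetic participant cohorts for factorial screening experiments.

Generates participant-level tables with the statistical structure the
analysis assumes: a baseline necessity-concerns differential, simple
randomization to conditions, a configurable linear truth model for the
post-intervention differential (main effects, interactions, baseline and
age covariates, Gaussian noise), item-level Likert responses consistent
with the subscale totals, completion times, and optional contamination by
"speed responders" (implausibly fast or straight-lining respondents).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import DataError, FactorialDesign, TermSpec, build_model_matrix, randomize

__all__ = [
    "TruthModel",
    "CohortConfig",
    "generate_cohort",
    "items_from_score",
    "inject_speed_responders",
]

# BMQ-AET scale geometry: two 5-item subscales on a 1-5 Likert scale
ITEMS_PER_SUBSCALE = 5
SUBSCALE_MIN = 5
SUBSCALE_MAX = 25
DIFF_MIN = -20
DIFF_MAX = 20


@dataclass(frozen=True)
class TruthModel:
    """Generative linear model for the post-intervention differential.

    ``term_effects`` are in outcome units per unit effect code — the same
    half-difference convention the analysis model reports, so fitted
    b-weights estimate these values directly.
    """

    intercept: float = 0.0
    term_effects: Mapping[TermSpec, float] = field(default_factory=dict)
    baseline_coef: float = 0.0
    age_coef: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Sample size, covariate distributions, and contamination rates.

    Baseline defaults echo the worked example's descriptives (differential
    mean 1.52, SD 5.36); ``subscale_sum`` anchors how a differential is
    split into necessity and concerns totals (~18 + ~16.5).
    """

    n: int
    baseline_mean: float = 1.52
    baseline_sd: float = 5.36
    subscale_sum: int = 34
    age_mean: float = 46.0
    age_sd: float = 15.0
    age_range: tuple[float, float] = (18.0, 90.0)
    completion_median: float = 9.45
    completion_log_sd: float = 0.35
    speed_fraction: float = 0.0
    bc_fraction: float = 0.049
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("speed_fraction", "bc_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.baseline_sd < 0 or self.age_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def items_from_score(subscale_total: int) -> tuple[int, ...]:
    """Deterministically split a subscale total into 5 Likert items.

    Every item gets ``total // 5``; the remainder is given one unit each
    to the first ``total % 5`` items.  Scoring the result recovers the
    total exactly.
    """
    t = int(subscale_total)
    if not SUBSCALE_MIN <= t <= SUBSCALE_MAX:
        raise DataError(f"subscale total {t} outside [{SUBSCALE_MIN}, {SUBSCALE_MAX}]")
    base, rem = divmod(t, ITEMS_PER_SUBSCALE)
    return tuple(base + 1 if i < rem else base for i in range(ITEMS_PER_SUBSCALE))


def _items_matrix(totals: np.ndarray) -> np.ndarray:
    """Vectorized items_from_score over an array of totals."""
    base, rem = np.divmod(totals.astype(int), ITEMS_PER_SUBSCALE)
    idx = np.arange(ITEMS_PER_SUBSCALE)
    return base[:, None] + (idx[None, :] < rem[:, None])


def _split_differential(diff: np.ndarray, target_sum: int) -> tuple[np.ndarray, np.ndarray]:
    """Necessity/concerns totals realizing each differential exactly.

    Totals are placed near ``target_sum`` and clipped into the feasible
    band so that both stay within [5, 25] while necessity - concerns
    equals the requested differential (always feasible for diff in
    [-20, 20]).
    """
    nec = np.rint((target_sum + diff) / 2).astype(int)
    nec = np.clip(nec, np.maximum(SUBSCALE_MIN, SUBSCALE_MIN + diff),
                  np.minimum(SUBSCALE_MAX, SUBSCALE_MAX + diff)).astype(int)
    con = nec - diff.astype(int)
    return nec, con


def _shift_necessity(nec_pre: np.ndarray, con_pre: np.ndarray,
                     post_diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Post totals: hold concerns at baseline, move necessity to realize
    the post differential; spill across the 5..25 bounds if needed."""
    con = con_pre.copy()
    nec = con + post_diff
    over = nec > SUBSCALE_MAX
    con[over] -= nec[over] - SUBSCALE_MAX
    nec[over] = SUBSCALE_MAX
    under = nec < SUBSCALE_MIN
    con[under] += SUBSCALE_MIN - nec[under]
    nec[under] = SUBSCALE_MIN
    return nec, con


def generate_cohort(
    design: FactorialDesign,
    truth: TruthModel,
    config: CohortConfig,
) -> pd.DataFrame:
    """Simulate one cohort of ``config.n`` participants.

    Returns a table with participant_id, age, bc_flag, condition_id,
    pre_item_1..10, post_item_1..10, and completion_minutes.  The first
    five items of each administration are the necessity subscale, the last
    five the concerns subscale.  Identical inputs (including seed) yield
    an identical table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd if config.age_sd > 0 else -np.inf
    b = (hi - config.age_mean) / config.age_sd if config.age_sd > 0 else np.inf
    if config.age_sd > 0:
        age = stats.truncnorm.rvs(
            a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
        )
    else:
        age = np.full(n, config.age_mean)
    age = np.round(age).astype(int)

    base_cont = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    base_diff = np.clip(np.rint(base_cont), DIFF_MIN, DIFF_MAX).astype(int)
    nec_pre, con_pre = _split_differential(base_diff, config.subscale_sum)

    condition = randomize(n, design.n_conditions, rng)
    codes = design.codes.loc[condition].reset_index(drop=True)

    lin = np.full(n, truth.intercept, dtype=float)
    if truth.term_effects:
        terms = list(truth.term_effects)
        M = build_model_matrix(codes, terms, design)
        lin += M.to_numpy() @ np.array([truth.term_effects[t] for t in terms])
    lin += truth.baseline_coef * base_diff + truth.age_coef * age
    if truth.noise_sd > 0:
        lin += rng.normal(0.0, truth.noise_sd, size=n)
    post_diff = np.clip(np.rint(lin), DIFF_MIN, DIFF_MAX).astype(int)
    nec_post, con_post = _shift_necessity(nec_pre, con_pre, post_diff)

    completion = rng.lognormal(
        mean=np.log(config.completion_median), sigma=config.completion_log_sd, size=n
    )
    bc_flag = rng.random(n) < config.bc_fraction

    data = {
        "participant_id": np.arange(1, n + 1),
        "age": age,
        "bc_flag": bc_flag.astype(int),
        "condition_id": condition,
    }
    pre_items = np.hstack([_items_matrix(nec_pre), _items_matrix(con_pre)])
    post_items = np.hstack([_items_matrix(nec_post), _items_matrix(con_post)])
    for i in range(10):
        data[f"pre_item_{i + 1}"] = pre_items[:, i]
    for i in range(10):
        data[f"post_item_{i + 1}"] = post_items[:, i]
    data["completion_minutes"] = np.round(completion, 3)
    return pd.DataFrame(data)


InjectionMode = Literal["fast_time", "straightline_pre", "straightline_post", "mixed"]

_MODES = ("fast_time", "straightline_pre", "straightline_post", "mixed")


def inject_speed_responders(
    cohort: pd.DataFrame,
    fraction: float,
    mode: InjectionMode = "mixed",
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Contaminate a seeded random subset of rows as speed responders.

    ``fast_time`` sets the completion time below one third of the current
    median; the straight-lining modes set all 10 pre (or post) items to
    one common value; ``mixed`` picks one of the three per contaminated
    row.  Returns the contaminated copy and a boolean truth-flag Series
    (aligned to the cohort index) for filter-validation.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    out = cohort.copy()
    n = len(out)
    flags = pd.Series(False, index=out.index, name="injected_speed")
    n_inject = int(round(fraction * n))
    if n_inject == 0:
        return out, flags
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chosen = rng.choice(n, size=n_inject, replace=False)
    flags.iloc[chosen] = True
    median_time = float(out["completion_minutes"].median())
    pre_cols = [f"pre_item_{i}" for i in range(1, 11)]
    post_cols = [f"post_item_{i}" for i in range(1, 11)]
    for pos in chosen:
        m = mode if mode != "mixed" else _MODES[rng.integers(0, 3)]
        row = out.index[pos]
        if m == "fast_time":
            out.loc[row, "completion_minutes"] = round(
                median_time / 3 * rng.uniform(0.2, 0.95), 3
            )
        elif m == "straightline_pre":
            out.loc[row, pre_cols] = int(rng.integers(1, 6))
        else:
            out.loc[row, post_cols] = int(rng.integers(1, 6))
    return out, flags
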