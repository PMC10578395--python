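"""Effect-coded factorial regression for screening experiments.

The analysis model regresses the post-intervention outcome on all (or a
selected subset of) ±1-coded factorial terms plus continuous covariates
(baseline score, age).  Because of effect coding, each factorial b-weight
is *half* the difference between the outcome means at the term's +1 and
-1 levels in a balanced design; screening decisions work on these
half-difference coefficients directly.

Standardized coefficients are post-hoc: beta = b * sd(x) / sd(y) with
sample standard deviations from the analyzed data.  For a balanced ±1
column sd(x) is ~1, so beta is b in outcome-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignConfigError, FactorialDesign, TermSpec, build_model_matrix

__all__ = [
    "EffectEstimate",
    "EffectTable",
    "ModelFit",
    "fit_ols",
    "coefficient_inference",
    "standardize",
    "fit_full_model",
    "fit_parsimonious",
]

#: default covariate columns of a scored participant table
DEFAULT_COVARIATES = ("pre_differential", "age")

_RANK_TOL = 1e-10


class RankDeficiencyError(np.linalg.LinAlgError):
    """Model matrix is (numerically) rank deficient."""


@dataclass(frozen=True)
class EffectEstimate:
    """One row of a coefficient table.

    ``term`` is a TermSpec for factorial effects or a string for
    covariates.  ``b_weight`` is in outcome units (half-difference
    convention for factorial terms); ``beta`` and the confidence interval
    are on the standardized scale.
    """

    term: TermSpec | str
    b_weight: float
    beta: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    t_stat: float | None = None
    p_value: float | None = None

    @property
    def is_factorial(self) -> bool:
        return isinstance(self.term, TermSpec)


@dataclass
class EffectTable:
    """Intercept plus a list of effect estimates.

    This is the interface between model fitting and the decision engine:
    it can come from :func:`fit_full_model` / :func:`fit_parsimonious` or
    be entered directly from a printed coefficient table
    (:meth:`from_records`), which makes published screening analyses
    reproducible without the raw data.
    """

    intercept: float
    estimates: list[EffectEstimate]
    model_label: str = "full"

    def factorial_effects(self) -> list[EffectEstimate]:
        return [e for e in self.estimates if e.is_factorial]

    def covariate_effects(self) -> list[EffectEstimate]:
        return [e for e in self.estimates if not e.is_factorial]

    def __getitem__(self, term: TermSpec | str) -> EffectEstimate:
        for e in self.estimates:
            if e.term == term:
                return e
        raise KeyError(term)

    def to_frame(
        self,
        design: FactorialDesign | None = None,
        all_terms: Sequence[TermSpec] | None = None,
    ) -> pd.DataFrame:
        """Coefficient table as a DataFrame.

        With ``all_terms``, terms absent from the fit (screened to zero in
        a parsimonious model) are included with coefficient exactly 0.
        """
        rows = []
        seen = set()
        for e in self.estimates:
            label = e.term.label(design) if e.is_factorial else e.term
            seen.add(e.term)
            rows.append(
                dict(term=label, b_weight=e.b_weight, beta=e.beta,
                     ci_low=e.ci_low, ci_high=e.ci_high, t=e.t_stat,
                     p=e.p_value, model=self.model_label)
            )
        for t in all_terms or ():
            if t not in seen:
                rows.append(
                    dict(term=t.label(design), b_weight=0.0, beta=0.0,
                         ci_low=None, ci_high=None, t=None, p=None,
                         model=self.model_label)
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_records(
        cls,
        intercept: float,
        records: Mapping[str, Mapping[str, float]],
        design: FactorialDesign,
        covariates: Mapping[str, Mapping[str, float]] | None = None,
        model_label: str = "external",
    ) -> "EffectTable":
        """Build from printed values: {term label: {b, beta, p, ...}}."""
        ests = []
        for label, vals in records.items():
            ests.append(
                EffectEstimate(
                    term=design.parse_term(label),
                    b_weight=vals.get("b", vals.get("b_weight", 0.0)),
                    beta=vals.get("beta"),
                    ci_low=vals.get("ci_low"),
                    ci_high=vals.get("ci_high"),
                    t_stat=vals.get("t"),
                    p_value=vals.get("p"),
                )
            )
        for name, vals in (covariates or {}).items():
            ests.append(
                EffectEstimate(
                    term=name,
                    b_weight=vals.get("b", 0.0),
                    beta=vals.get("beta"),
                    p_value=vals.get("p"),
                )
            )
        return cls(intercept=intercept, estimates=ests, model_label=model_label)


@dataclass
class ModelFit:
    """A fitted effect-coded regression with inference and scaling info."""

    table: EffectTable
    residual_df: int
    outcome_sd: float
    predictor_sds: dict
    n: int
    covariates: tuple[str, ...]
    residual_var: float
    terms: list[TermSpec] = field(default_factory=list)

    # convenience pass-throughs so a ModelFit can stand in for its table
    @property
    def intercept(self) -> float:
        return self.table.intercept

    @property
    def estimates(self) -> list[EffectEstimate]:
        return self.table.estimates

    def to_frame(self, design=None, all_terms=None) -> pd.DataFrame:
        return self.table.to_frame(design, all_terms)


def fit_ols(y: np.ndarray, X: pd.DataFrame | np.ndarray):
    """Ordinary least squares of y on X (X must carry the intercept).

    Returns ``(coef, residual_var, coef_cov)`` with
    ``coef_cov = residual_var * (X'X)^-1``.  Raises RankDeficiencyError,
    naming the implicated columns, when the smallest singular value of X
    is below 1e-10 relative to the largest.
    """
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xv.shape[0] <= Xv.shape[1]:
        raise ValueError("need more observations than parameters")
    u, s, vt = np.linalg.svd(Xv, full_matrices=False)
    if s[-1] < _RANK_TOL * s[0]:
        null = np.abs(vt[-1])
        names = (
            list(X.columns)
            if isinstance(X, pd.DataFrame)
            else [str(i) for i in range(Xv.shape[1])]
        )
        offenders = [n for n, w in zip(names, null) if w > 1e-6]
        raise RankDeficiencyError(f"rank-deficient model matrix; columns {offenders}")
    res = sm.OLS(y, Xv).fit()
    return res.params, res.mse_resid, res.cov_params()


def coefficient_inference(
    coef: np.ndarray,
    coef_cov: np.ndarray,
    residual_df: int,
    level: float = 0.90,
) -> pd.DataFrame:
    """Per-coefficient t statistic, two-sided p, and CI half-width.

    The returned ``ci_halfwidth`` is on the raw coefficient scale;
    standardizing both the estimate and the half-width by the same
    sd(x)/sd(y) factor gives the interval on the beta scale.
    """
    if residual_df < 1:
        raise ValueError("inference needs at least 1 residual degree of freedom")
    se = np.sqrt(np.diag(np.asarray(coef_cov)))
    t = np.asarray(coef) / se
    p = 2 * stats.t.sf(np.abs(t), residual_df)
    tcrit = stats.t.ppf((1 + level) / 2, residual_df)
    return pd.DataFrame({"se": se, "t": t, "p": p, "ci_halfwidth": tcrit * se})


def standardize(b_weight: float, predictor_sd: float, outcome_sd: float) -> float:
    """Standardized coefficient beta = b * sd(x) / sd(y)."""
    if outcome_sd <= 0:
        raise ValueError("outcome SD must be positive")
    return b_weight * predictor_sd / outcome_sd


def _prepare(
    scored: pd.DataFrame,
    design: FactorialDesign,
    terms: Sequence[TermSpec],
    covariates: Sequence[str],
    outcome: str,
):
    required = {"condition_id", outcome, *covariates}
    missing = required - set(scored.columns)
    if missing:
        raise DesignConfigError(f"scored table missing columns: {sorted(missing)}")
    codes = design.codes.loc[scored["condition_id"]].reset_index(drop=True)
    M = build_model_matrix(codes, terms, design)
    X = pd.concat(
        [pd.Series(1.0, index=M.index, name="Intercept"), M], axis=1
    )
    for c in covariates:
        X[c] = scored[c].to_numpy()
    y = scored[outcome].to_numpy(dtype=float)
    return y, X


def _assemble_fit(
    y, X, terms, design, covariates, level, model_label
) -> ModelFit:
    coef, resid_var, cov = fit_ols(y, X)
    n, p = X.shape
    df = n - p
    inf = coefficient_inference(coef, cov, df, level)
    sd_y = float(np.std(y, ddof=1))
    sds = {c: float(np.std(X[c].to_numpy(), ddof=1)) for c in X.columns[1:]}
    ests = []
    labels = [t.label(design) for t in terms]
    for j, name in enumerate(X.columns):
        if j == 0:
            continue
        term = terms[labels.index(name)] if name in labels else name
        sd_x = sds[name]
        b = float(coef[j])
        beta = standardize(b, sd_x, sd_y)
        hw = standardize(float(inf["ci_halfwidth"][j]), sd_x, sd_y)
        ests.append(
            EffectEstimate(
                term=term,
                b_weight=b,
                beta=beta,
                ci_low=beta - hw,
                ci_high=beta + hw,
                t_stat=float(inf["t"][j]),
                p_value=float(inf["p"][j]),
            )
        )
    table = EffectTable(intercept=float(coef[0]), estimates=ests, model_label=model_label)
    return ModelFit(
        table=table,
        residual_df=df,
        outcome_sd=sd_y,
        predictor_sds=sds,
        n=n,
        covariates=tuple(covariates),
        residual_var=float(resid_var),
        terms=list(terms),
    )


def fit_full_model(
    scored: pd.DataFrame,
    design: FactorialDesign,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    outcome: str = "post_differential",
    level: float = 0.90,
) -> ModelFit:
    """Fit the saturated factorial model: all 2**k - 1 terms + covariates."""
    terms = design.all_terms()
    y, X = _prepare(scored, design, terms, covariates, outcome)
    return _assemble_fit(y, X, terms, design, covariates, level, "full")


def fit_parsimonious(
    scored: pd.DataFrame,
    selected_terms: Sequence[TermSpec],
    design: FactorialDesign,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    outcome: str = "post_differential",
    level: float = 0.90,
) -> ModelFit:
    """Refit with only the selected factorial terms plus covariates.

    Terms not selected are simply omitted (their coefficients are zero by
    construction in the exported table).
    """
    all_terms = set(design.all_terms())
    unknown = [t for t in selected_terms if t not in all_terms]
    if unknown:
        raise DesignConfigError(f"selected terms not in design: {unknown}")
    terms = list(selected_terms)
    y, X = _prepare(scored, design, terms, covariates, outcome)
    return _assemble_fit(y, X, terms, design, covariates, level, "parsimonious")
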