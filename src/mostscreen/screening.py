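"""Stepped component-screening decisions and parsimonious predictions.

Screening follows a decision-priority perspective with the all-active-
components criterion: pick the component configuration with the best
expected outcome, irrespective of cost.  The procedure is stepped and
deterministic:

1. every component with an important (p < threshold) positive main effect
   is screened in, negative screened out;
2. important interactions are then examined in an order driven by the
   effect-hierarchy principle — interactions sharing a component with an
   important main effect first, then ascending interaction order, ties by
   canonical factor order.  Each interaction fixes its still-undecided
   components at the levels that maximize the parsimonious-model
   prediction over the effects whose components are already in play;
   decided components are never flipped (a conflicting pull is logged);
3. components never touched by an important effect stay at the low level.

Predictions over candidate conditions come in two modes.
``table5_compatible`` evaluates intercept + sum(beta * code product) with
standardized coefficients, the convention used in published prediction
tables for this kind of screening report; ``unstandardized`` uses raw
b-weights (plus covariate terms if values are supplied) and is the
default for new analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import HIGH, LOW, FactorialDesign, TermSpec
from .model import EffectEstimate, EffectTable, ModelFit

__all__ = [
    "ImportantEffect",
    "ScreeningResult",
    "PredictionRow",
    "PredictionTable",
    "classify_effects",
    "order_interactions",
    "resolve_interaction",
    "predict_condition",
    "build_prediction_table",
    "run_screening",
]


@dataclass(frozen=True)
class ImportantEffect:
    """A factorial effect passing the importance threshold."""

    term: TermSpec
    beta: float | None
    b_weight: float
    p_value: float

    @property
    def coefficient(self) -> float:
        return self.beta if self.beta is not None else self.b_weight

    @property
    def direction(self) -> str:
        sign = "positive" if self.coefficient > 0 else "negative"
        if self.term.order == 1:
            return sign
        return "synergistic" if sign == "positive" else "antagonistic"


@dataclass
class DecisionEntry:
    """One step of the decision log (machine-checkable)."""

    step: str                      # "main_effects" | term label | "defaults"
    effect: str | None
    resolved: dict                 # component -> chosen level (+1/-1)
    candidates: list = field(default_factory=list)  # [(combo dict, y_hat)]
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "effect": self.effect,
            "resolved": self.resolved,
            "candidates": [
                {"levels": combo, "y_hat": y} for combo, y in self.candidates
            ],
            "note": self.note,
        }


@dataclass
class ScreeningResult:
    screened_in: tuple[str, ...]
    screened_out: tuple[str, ...]
    decision_log: list[DecisionEntry]
    levels: dict  # component -> +1/-1

    def log_json(self, path=None) -> str:
        payload = json.dumps([e.to_dict() for e in self.decision_log], indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def classify_effects(
    table: EffectTable | ModelFit, threshold: float = 0.1
) -> list[ImportantEffect]:
    """Factorial terms with p strictly below the importance threshold.

    Covariates never count; effects at or above the threshold are treated
    as unimportant (their coefficients are zero downstream).
    """
    out = []
    for e in table.estimates:
        if not isinstance(e.term, TermSpec):
            continue
        if e.p_value is not None and e.p_value < threshold:
            out.append(
                ImportantEffect(
                    term=e.term, beta=e.beta, b_weight=e.b_weight, p_value=e.p_value
                )
            )
    return out


def order_interactions(
    important: Sequence[ImportantEffect],
    main_effect_components: Iterable[str],
    factor_order: Sequence[str],
) -> list[ImportantEffect]:
    """Processing order for important interactions (effect hierarchy).

    Interactions containing a component that has an important main effect
    come first, ascending by interaction order; then the remaining
    interactions ascending by order; ties broken by canonical factor
    order of the components.
    """
    mains = set(main_effect_components)
    pos = {name: i for i, name in enumerate(factor_order)}

    def key(eff: ImportantEffect):
        overlap = bool(mains & set(eff.term.components))
        return (
            0 if overlap else 1,
            eff.term.order,
            tuple(pos[c] for c in eff.term.components),
        )

    return sorted((e for e in important if e.term.order >= 2), key=key)


def _coef(est: EffectEstimate, mode: str) -> float:
    if mode == "table5_compatible":
        if est.beta is None:
            raise ValueError(f"no standardized coefficient for term {est.term}")
        return est.beta
    return est.b_weight


def predict_condition(
    table: EffectTable | ModelFit,
    codes: Mapping[str, int],
    mode: str = "table5_compatible",
    covariate_offset: float | None = None,
    covariate_values: Mapping[str, float] | None = None,
) -> float:
    """Linear predictor of the parsimonious model at one condition.

    ``codes`` maps every component appearing in the table's factorial
    terms to its ±1 level.  ``covariate_offset`` adds a constant in
    outcome units; ``covariate_values`` (unstandardized mode) multiplies
    supplied covariate values by their fitted slopes.
    """
    y = table.intercept
    for est in table.estimates:
        if isinstance(est.term, TermSpec):
            try:
                prod = int(np.prod([codes[c] for c in est.term.components]))
            except KeyError as exc:
                raise ValueError(f"missing code for component {exc}") from None
            y += _coef(est, mode) * prod
        elif covariate_values is not None and est.term in covariate_values:
            y += est.b_weight * covariate_values[est.term]
    if covariate_offset is not None:
        y += covariate_offset
    return float(y)


def _candidate_combos(free: Sequence[str]):
    """Level combinations over free components, all-high first and the
    last component varying fastest (mirrors condition enumeration)."""
    m = len(free)
    for i in range(2**m):
        bits = [(i >> (m - 1 - j)) & 1 for j in range(m)]
        yield {c: (HIGH if b == 0 else LOW) for c, b in zip(free, bits)}


def resolve_interaction(
    effect: ImportantEffect,
    decisions: Mapping[str, int],
    parsimonious: EffectTable | ModelFit,
    mode: str = "table5_compatible",
) -> tuple[dict, DecisionEntry]:
    """Fix an interaction's undecided components at their best levels.

    Candidates are scored with the parsimonious model restricted to the
    effects whose components are all *in play* (already decided or part
    of this interaction); effects involving still-undecided outside
    components contribute nothing, i.e. those components sit at a neutral
    reference.  Already-decided components are never flipped.  Ties go to
    the first candidate in all-high-first order, which implements the
    all-active-components preference for switching components on.
    """
    decisions = dict(decisions)
    label = " × ".join(effect.term.components)
    free = [c for c in effect.term.components if c not in decisions]
    if not free:
        entry = DecisionEntry(
            step=label, effect=label, resolved={},
            note=f"confirmatory: all components already decided "
                 f"({effect.direction} interaction consistent with current levels)",
        )
        return decisions, entry

    in_play = set(decisions) | set(effect.term.components)
    sub = EffectTable(
        intercept=parsimonious.intercept,
        estimates=[
            e for e in parsimonious.estimates
            if isinstance(e.term, TermSpec) and set(e.term.components) <= in_play
        ],
        model_label="restricted",
    )
    best = None
    candidates = []
    for combo in _candidate_combos(free):
        codes = {**decisions, **combo}
        y = predict_condition(sub, codes, mode=mode)
        candidates.append((combo, y))
        if best is None or y > best[1]:
            best = (combo, y)
    decisions.update(best[0])
    entry = DecisionEntry(
        step=label,
        effect=label,
        resolved=dict(best[0]),
        candidates=candidates,
        note=f"{effect.direction} interaction; undecided components set to the "
             f"level combination with the highest predicted outcome",
    )
    return decisions, entry


@dataclass(frozen=True)
class PredictionRow:
    condition_id: int
    levels: dict
    y_hat: float
    y_hat_with_offset: float | None = None


@dataclass
class PredictionTable:
    rows: list[PredictionRow]
    argmax_id: int

    def to_frame(self, design: FactorialDesign | None = None) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"condition_id": r.condition_id}
            if design is not None:
                for f in design.factors:
                    rec[f.name] = (
                        f.high_label if r.levels[f.name] == HIGH else f.low_label
                    )
            rec["y_hat"] = r.y_hat
            if r.y_hat_with_offset is not None:
                rec["y_hat_with_offset"] = r.y_hat_with_offset
            recs.append(rec)
        return pd.DataFrame(recs)


def build_prediction_table(
    parsimonious: EffectTable | ModelFit,
    design: FactorialDesign,
    fixed_levels: Mapping[str, int] | None = None,
    mode: str = "table5_compatible",
    covariate_offset: float | None = None,
) -> PredictionTable:
    """Predicted outcome for every condition over the free components.

    Components in ``fixed_levels`` are pinned (typically screened-out
    components at the low level); the remaining components are enumerated
    over all 2^m combinations.  Rows carry the condition ids of the full
    design; the argmax tie-break is the lowest condition id.
    """
    fixed = dict(fixed_levels or {})
    free = [f.name for f in design.factors if f.name not in fixed]
    rows = []
    for combo in _candidate_combos(free):
        codes = {**fixed, **combo}
        cid = design.condition_id_for(codes)
        y = predict_condition(parsimonious, codes, mode=mode)
        rows.append(
            PredictionRow(
                condition_id=cid,
                levels={f.name: codes[f.name] for f in design.factors},
                y_hat=y,
                y_hat_with_offset=(
                    y + covariate_offset if covariate_offset is not None else None
                ),
            )
        )
    rows.sort(key=lambda r: r.condition_id)
    best = max(rows, key=lambda r: (r.y_hat, -r.condition_id))
    return PredictionTable(rows=rows, argmax_id=best.condition_id)


def run_screening(
    full_fit: EffectTable | ModelFit,
    parsimonious_fit: EffectTable | ModelFit,
    design: FactorialDesign,
    threshold: float = 0.1,
    mode: str = "table5_compatible",
) -> ScreeningResult:
    """Stepped screening over all components (see module docstring).

    Importance is judged on the full model; interaction resolution uses
    the parsimonious refit's coefficients.
    """
    important = classify_effects(full_fit, threshold)
    mains = [e for e in important if e.term.order == 1]
    decisions: dict[str, int] = {}
    log: list[DecisionEntry] = []

    resolved = {}
    for e in mains:
        comp = e.term.components[0]
        decisions[comp] = HIGH if e.coefficient > 0 else LOW
        resolved[comp] = decisions[comp]
    log.append(
        DecisionEntry(
            step="main_effects",
            effect=None,
            resolved=resolved,
            note=(
                "components with important positive main effects screened in, "
                "negative screened out"
                if mains
                else "no important main effects"
            ),
        )
    )

    main_components = {e.term.components[0] for e in mains}
    for eff in order_interactions(important, main_components, design.factor_names):
        decisions, entry = resolve_interaction(eff, decisions, parsimonious_fit, mode)
        log.append(entry)

    untouched = {f.name: LOW for f in design.factors if f.name not in decisions}
    if untouched:
        decisions.update(untouched)
        log.append(
            DecisionEntry(
                step="defaults",
                effect=None,
                resolved=untouched,
                note="components absent from every important effect default "
                     "to the low level",
            )
        )

    screened_in = tuple(f.name for f in design.factors if decisions[f.name] == HIGH)
    screened_out = tuple(f.name for f in design.factors if decisions[f.name] == LOW)
    return ScreeningResult(
        screened_in=screened_in,
        screened_out=screened_out,
        decision_log=log,
        levels=decisions,
    )
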