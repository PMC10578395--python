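"""Two-level factorial designs for component screening experiments.

A screening experiment crosses ``k`` two-level intervention components
(factors) into ``2**k`` experimental conditions.  Levels are effect coded
as -1 (off/basic) and +1 (on/enhanced), so that in a balanced design each
regression coefficient equals half the difference between the two level
means of its term.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorDef",
    "TermSpec",
    "FactorialDesign",
    "PowerSpec",
    "enumerate_conditions",
    "build_model_matrix",
    "required_sample_size",
    "randomize",
]

HIGH = 1
LOW = -1


class DesignConfigError(ValueError):
    """Raised for invalid factor/term configuration."""


class DataError(ValueError):
    """Raised for malformed participant-level data."""


@dataclass(frozen=True)
class FactorDef:
    """One two-level intervention component.

    Parameters
    ----------
    name:
        Unique factor name, e.g. ``"diagrams"``.
    low_label, high_label:
        Level labels mapped to the -1 / +1 effect codes
        (e.g. ``"Off"`` / ``"On"`` or ``"Basic"`` / ``"Enhanced"``).
    abbrev:
        Short label used when printing terms (e.g. ``"D"``).
    """

    name: str
    low_label: str = "Off"
    high_label: str = "On"
    abbrev: str | None = None

    def code_for(self, label: str) -> int:
        if label == self.high_label:
            return HIGH
        if label == self.low_label:
            return LOW
        raise DataError(
            f"unknown level {label!r} for factor {self.name!r} "
            f"(expected {self.low_label!r} or {self.high_label!r})"
        )

    @property
    def short(self) -> str:
        return self.abbrev or self.name


@dataclass(frozen=True)
class TermSpec:
    """A main effect (one component) or interaction (two or more).

    ``components`` are factor names in canonical (design) order.
    """

    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.components)) != len(self.components):
            raise DesignConfigError(f"duplicate components in term {self.components}")
        if not self.components:
            raise DesignConfigError("a term needs at least one component")

    @property
    def order(self) -> int:
        return len(self.components)

    def label(self, design: "FactorialDesign | None" = None, sep: str = " × ") -> str:
        if design is None:
            return sep.join(self.components)
        shorts = {f.name: f.short for f in design.factors}
        return sep.join(shorts[c] for c in self.components)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return ":".join(self.components)


class FactorialDesign:
    """Full ``2**k`` factorial design over an ordered list of factors.

    Condition ids run 1..2**k with condition 1 assigning every factor its
    high level and the *last* factor varying fastest (high before low), so
    ids are citable against the conventional printed condition table.
    """

    def __init__(self, factors: Sequence[FactorDef]):
        factors = list(factors)
        if not factors:
            raise DesignConfigError("at least one factor required")
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise DesignConfigError(f"duplicate factor names: {names}")
        self.factors: list[FactorDef] = factors
        self._by_name = {f.name: f for f in factors}
        self._codes = self._enumerate_codes()

    # -- enumeration -------------------------------------------------------

    def _enumerate_codes(self) -> pd.DataFrame:
        k = self.k
        rows = []
        for cid in range(1, 2**k + 1):
            bits = (cid - 1) >> np.arange(k - 1, -1, -1) & 1  # MSB = first factor
            rows.append(np.where(bits == 0, HIGH, LOW))
        df = pd.DataFrame(rows, columns=[f.name for f in self.factors])
        df.insert(0, "condition_id", np.arange(1, 2**k + 1))
        return df.set_index("condition_id")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_conditions(self) -> int:
        return 2**self.k

    @property
    def codes(self) -> pd.DataFrame:
        """±1 code table, one row per condition, indexed by condition_id."""
        return self._codes

    @property
    def conditions(self) -> pd.DataFrame:
        """Level-label table, one row per condition."""
        out = self._codes.copy()
        for f in self.factors:
            out[f.name] = np.where(out[f.name] == HIGH, f.high_label, f.low_label)
        return out

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    # -- coding ------------------------------------------------------------

    def effect_code(self, condition: Mapping[str, str]) -> np.ndarray:
        """Map a {factor: level-label} assignment to a ±1 vector."""
        missing = [f.name for f in self.factors if f.name not in condition]
        if missing:
            raise DataError(f"condition missing factors: {missing}")
        return np.array([f.code_for(condition[f.name]) for f in self.factors])

    def condition_codes(self, condition_id: int) -> pd.Series:
        return self._codes.loc[condition_id]

    def condition_id_for(self, codes: Mapping[str, int]) -> int:
        """Inverse of enumeration: ±1 assignment -> condition id."""
        cid = 0
        for f in self.factors:
            cid = (cid << 1) | (0 if codes[f.name] == HIGH else 1)
        return cid + 1

    # -- terms -------------------------------------------------------------

    def term(self, *components: str) -> TermSpec:
        """Canonicalize a term: sort components into design order."""
        unknown = [c for c in components if c not in self._by_name]
        if unknown:
            raise DesignConfigError(f"unknown factors in term: {unknown}")
        order = {f.name: i for i, f in enumerate(self.factors)}
        return TermSpec(tuple(sorted(set(components), key=order.__getitem__)))

    def parse_term(self, text: str) -> TermSpec:
        """Parse a printed term label like ``"D × B"`` or ``"diagrams:benefits"``."""
        lookup = {f.short: f.name for f in self.factors}
        lookup.update({f.name: f.name for f in self.factors})
        parts = [p.strip() for p in text.replace("×", ":").replace("x", ":").split(":")]
        try:
            return self.term(*(lookup[p] for p in parts if p))
        except KeyError as exc:
            raise DesignConfigError(f"unknown component {exc} in term {text!r}") from None

    def all_terms(self, max_order: int | None = None) -> list[TermSpec]:
        """All main effects and interactions up to ``max_order`` (default k)."""
        max_order = self.k if max_order is None else max_order
        names = self.factor_names
        out = []
        for r in range(1, max_order + 1):
            out.extend(TermSpec(c) for c in itertools.combinations(names, r))
        return out

    def model_matrix(
        self, codes: pd.DataFrame, terms: Sequence[TermSpec]
    ) -> pd.DataFrame:
        return build_model_matrix(codes, terms, design=self)

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Export the condition table (labels and ±1 codes) to CSV."""
        labels = self.conditions
        codes = self._codes.add_suffix("_code")
        labels.join(codes).to_csv(path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FactorialDesign({self.factor_names}, n_conditions={self.n_conditions})"


def enumerate_conditions(factors: Sequence[FactorDef]) -> FactorialDesign:
    """Build the full 2**k design over ``factors`` (see FactorialDesign)."""
    return FactorialDesign(factors)


def build_model_matrix(
    codes: pd.DataFrame,
    terms: Sequence[TermSpec],
    design: FactorialDesign | None = None,
) -> pd.DataFrame:
    """Model matrix with one ±1 product column per term.

    ``codes`` holds one ±1 column per factor (rows = conditions or
    participants); an interaction column is the elementwise product of its
    components' columns.  Column order follows ``terms``.
    """
    cols = {}
    for t in terms:
        missing = [c for c in t.components if c not in codes.columns]
        if missing:
            raise DesignConfigError(f"term {t} references unknown factors {missing}")
        cols[t.label(design)] = codes[list(t.components)].prod(axis=1).to_numpy()
    return pd.DataFrame(cols, index=codes.index)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the screening-experiment sample-size calculation.

    effect_size_d is the smallest standardized mean difference (Cohen's d
    on the outcome) between a component's two levels that the experiment
    should detect.
    """

    effect_size_d: float
    power: float = 0.9
    alpha: float = 0.1
    attrition_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.effect_size_d > 0:
            raise ValueError("effect_size_d must be positive")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.attrition_rate < 1:
            raise ValueError("attrition_rate must be in [0, 1)")


def required_sample_size(spec: PowerSpec) -> tuple[int, int]:
    """Total n for a two-level factorial screening experiment.

    Uses the normal-approximation two-group formula applied to any one
    effect-coded contrast, which splits the whole sample into two halves
    of size n/2 each:

        n_per_level = ceil( 2 * (z_{1-alpha/2} + z_{power})**2 / d**2 )

    Returns ``(n_analysis, n_recruit)`` where ``n_analysis = 2 *
    n_per_level`` and ``n_recruit`` inflates for the expected fraction of
    unusable responses by nearest-integer rounding of
    ``n_analysis / (1 - attrition_rate)``.
    """
    z = stats.norm.ppf(1 - spec.alpha / 2) + stats.norm.ppf(spec.power)
    per_level = math.ceil(2 * z * z / spec.effect_size_d**2)
    n_analysis = 2 * per_level
    n_recruit = int(math.floor(n_analysis / (1 - spec.attrition_rate) + 0.5))
    return n_analysis, n_recruit


def randomize(
    n_participants: int,
    n_conditions: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Simple (unconstrained) randomization to conditions 1..n_conditions.

    Each participant is assigned independently and uniformly; per-condition
    counts are binomial, not forced equal.  Reproducible for a fixed seed.
    """
    if n_participants < 1 or n_conditions < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.integers(1, n_conditions + 1, size=n_participants)
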