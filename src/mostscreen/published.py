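"""Reference values from the five-component AET-leaflet screening experiment.

The package's worked example is a 2^5 factorial screening experiment on an
information leaflet about adjuvant endocrine therapy (AET), with five
candidate components — diagrams of the drug mechanism, benefit infographics,
side-effect information, answers to common concerns, and breast-cancer
survivor (patient) input — and the BMQ-AET necessity-concerns differential
as outcome.  The constants here are the published coefficient tables and
descriptive statistics of that experiment, entered as data.  They drive the
coefficient-table input mode of the pipeline (screening decisions without
raw data) and parameterize the synthetic-cohort generator's default truth
model.

p-values printed as "<.001" are stored as 0.0005; betas printed as
"<0.001" carry the sign of their b-weight.
"""

from __future__ import annotations

from .cohort import CohortConfig, TruthModel
from .design import FactorDef, FactorialDesign, PowerSpec, enumerate_conditions
from .model import EffectTable

__all__ = [
    "LEAFLET_FACTORS",
    "leaflet_design",
    "full_model_table",
    "parsimonious_table",
    "default_truth_model",
    "default_cohort_config",
    "PLANNED_POWER_SPEC",
    "BASELINE_DIFFERENTIAL_MEAN",
    "BASELINE_DIFFERENTIAL_SD",
    "FOLLOWUP_DIFFERENTIAL_SD",
    "MEDIAN_COMPLETION_MINUTES",
]

#: order matches the printed condition table (condition 1 = all high,
#: patient input varying fastest)
LEAFLET_FACTORS = (
    FactorDef("diagrams", "Off", "On", "D"),
    FactorDef("benefits", "Basic", "Enhanced", "B"),
    FactorDef("side_effects", "Basic", "Enhanced", "SE"),
    FactorDef("concerns", "Off", "On", "C"),
    FactorDef("patient_input", "Off", "On", "P"),
)

BASELINE_DIFFERENTIAL_MEAN = 1.52
BASELINE_DIFFERENTIAL_SD = 5.36
FOLLOWUP_DIFFERENTIAL_SD = 5.72
MEDIAN_COMPLETION_MINUTES = 9.45

#: planning inputs: smallest effect of interest d = 0.15, 90% power,
#: two-sided alpha 0.1, 5% anticipated nonsense responses
PLANNED_POWER_SPEC = PowerSpec(
    effect_size_d=0.15, power=0.9, alpha=0.1, attrition_rate=0.05
)

# term -> (b_weight, beta, p) for the saturated model (n = 1,603)
_FULL = {
    "D": (0.028, 0.005, 0.770),
    "B": (-0.047, -0.008, 0.627),
    "SE": (0.018, 0.003, 0.853),
    "C": (-0.005, -0.0009, 0.956),
    "P": (0.362, 0.063, 0.0005),
    "D:B": (0.267, 0.047, 0.006),
    "D:SE": (-0.163, -0.029, 0.093),
    "B:SE": (-0.102, -0.018, 0.293),
    "D:C": (0.031, 0.005, 0.746),
    "B:C": (-0.080, -0.014, 0.409),
    "SE:C": (-0.072, -0.013, 0.456),
    "D:P": (0.134, 0.023, 0.168),
    "B:P": (0.002, 0.0004, 0.983),
    "SE:P": (-0.121, -0.021, 0.210),
    "C:P": (-0.035, -0.006, 0.721),
    "D:B:SE": (-0.045, -0.008, 0.644),
    "D:B:C": (-0.042, -0.007, 0.663),
    "D:SE:C": (0.144, 0.025, 0.138),
    "B:SE:C": (0.032, 0.006, 0.744),
    "D:B:P": (0.086, 0.015, 0.375),
    "D:SE:P": (0.130, 0.023, 0.179),
    "B:SE:P": (0.061, 0.011, 0.527),
    "D:C:P": (0.167, 0.029, 0.085),
    "B:C:P": (0.047, 0.008, 0.630),
    "SE:C:P": (-0.002, -0.0004, 0.980),
    "D:B:SE:C": (-0.219, -0.038, 0.024),
    "D:B:SE:P": (-0.096, -0.017, 0.324),
    "D:B:C:P": (-0.157, -0.027, 0.107),
    "D:SE:C:P": (0.070, 0.012, 0.469),
    "B:SE:C:P": (0.107, 0.019, 0.269),
    "D:B:SE:C:P": (0.095, 0.017, 0.327),
}
_FULL_INTERCEPT = 2.322
_FULL_COVARIATES = {
    "pre_differential": dict(b=0.784, beta=0.735, p=0.0005),
    "age": dict(b=0.003, beta=0.010, p=0.566),
}

# parsimonious refit: only the p < .1 terms plus covariates
_PARSIMONIOUS = {
    "P": (0.361, 0.063, 0.0005),
    "D:B": (0.266, 0.047, 0.006),
    "D:SE": (-0.163, -0.028, 0.091),
    "D:C:P": (0.160, 0.028, 0.096),
    "D:B:SE:C": (-0.224, -0.039, 0.020),
}
_PARSIMONIOUS_INTERCEPT = 2.319
_PARSIMONIOUS_COVARIATES = {
    "pre_differential": dict(b=0.785, beta=0.736, p=0.0005),
    "age": dict(b=0.005, beta=0.014, p=0.397),
}


def leaflet_design() -> FactorialDesign:
    """The 2^5 design of the worked example (32 conditions)."""
    return enumerate_conditions(LEAFLET_FACTORS)


def _table(records, intercept, covariates, design, label) -> EffectTable:
    recs = {
        k: dict(b=b, beta=beta, p=p) for k, (b, beta, p) in records.items()
    }
    return EffectTable.from_records(
        intercept, recs, design, covariates=covariates, model_label=label
    )


def full_model_table(design: FactorialDesign | None = None) -> EffectTable:
    """Published saturated-model coefficient table (31 terms + covariates)."""
    design = design or leaflet_design()
    return _table(_FULL, _FULL_INTERCEPT, _FULL_COVARIATES, design, "full")


def parsimonious_table(design: FactorialDesign | None = None) -> EffectTable:
    """Published parsimonious prediction model (5 important terms + covariates)."""
    design = design or leaflet_design()
    return _table(
        _PARSIMONIOUS, _PARSIMONIOUS_INTERCEPT, _PARSIMONIOUS_COVARIATES,
        design, "parsimonious",
    )


def default_truth_model(design: FactorialDesign | None = None) -> TruthModel:
    """Truth model for the synthetic cohort: parsimonious b-weights.

    The residual SD is set so that, combined with the baseline carry-over,
    the follow-up differential SD lands near the published 5.72.
    """
    design = design or leaflet_design()
    effects = {design.parse_term(k): b for k, (b, _, _) in _PARSIMONIOUS.items()}
    return TruthModel(
        intercept=_PARSIMONIOUS_INTERCEPT,
        term_effects=effects,
        baseline_coef=_PARSIMONIOUS_COVARIATES["pre_differential"]["b"],
        age_coef=_PARSIMONIOUS_COVARIATES["age"]["b"],
        noise_sd=3.85,
    )


def default_cohort_config(n: int = 1604, seed: int = 0) -> CohortConfig:
    """Cohort configuration echoing the worked example's descriptives."""
    return CohortConfig(
        n=n,
        baseline_mean=BASELINE_DIFFERENTIAL_MEAN,
        baseline_sd=BASELINE_DIFFERENTIAL_SD,
        seed=seed,
    )
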