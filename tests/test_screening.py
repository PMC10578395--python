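"""Decision engine: classification, ordering, resolution, predictions."""

import numpy as np
import pytest

import mostscreen as ms
from mostscreen.model import EffectEstimate, EffectTable
from mostscreen.screening import ImportantEffect

# printed prediction table of the worked example (condition -> y_hat)
EXPECTED_PREDICTIONS = {
    5: 2.524, 6: 2.342, 7: 2.390, 8: 2.320,
    13: 2.352, 14: 2.170, 15: 2.374, 16: 2.304,
    21: 2.240, 22: 2.170, 23: 2.374, 24: 2.192,
    29: 2.412, 30: 2.342, 31: 2.390, 32: 2.208,
}


class TestClassifyEffects:
    def test_worked_example_important_set(self, design, full_table):
        important = {e.term.label(design) for e in ms.classify_effects(full_table)}
        assert important == {"P", "D × B", "D × SE", "D × C × P", "D × B × SE × C"}

    def test_threshold_strict(self, design):
        table = EffectTable(
            intercept=0.0,
            estimates=[
                EffectEstimate(design.term("diagrams"), 0.2, beta=0.05, p_value=0.1),
                EffectEstimate(design.term("benefits"), 0.2, beta=0.05, p_value=0.0999),
            ],
        )
        picked = ms.classify_effects(table, threshold=0.1)
        assert [e.term.components for e in picked] == [("benefits",)]

    def test_all_unimportant_gives_empty(self, design):
        table = EffectTable(
            intercept=0.0,
            estimates=[EffectEstimate(design.term("diagrams"), 0.2, p_value=0.5)],
        )
        assert ms.classify_effects(table) == []

    def test_covariates_never_important(self, design, full_table):
        # baseline covariate has p < .001 but is not a screening effect
        terms = [e.term for e in ms.classify_effects(full_table)]
        assert all(isinstance(t, ms.TermSpec) for t in terms)


class TestOrderInteractions:
    def test_worked_example_sequence(self, design, full_table):
        important = ms.classify_effects(full_table)
        ordered = ms.order_interactions(important, {"patient_input"}, design.factor_names)
        assert [e.term.label(design) for e in ordered] == [
            "D × C × P", "D × B", "D × SE", "D × B × SE × C",
        ]

    def test_no_main_effects_pure_ascending(self, design, full_table):
        important = ms.classify_effects(full_table)
        ordered = ms.order_interactions(important, set(), design.factor_names)
        assert [e.term.order for e in ordered] == [2, 2, 3, 4]

    def test_same_order_ties_broken_canonically(self, design):
        effs = [
            ImportantEffect(design.term("side_effects", "concerns"), 0.03, 0.1, 0.05),
            ImportantEffect(design.term("diagrams", "benefits"), 0.03, 0.1, 0.05),
        ]
        ordered = ms.order_interactions(effs, set(), design.factor_names)
        assert ordered[0].term.components == ("diagrams", "benefits")


class TestResolveInteraction:
    def test_synergistic_three_way_with_one_resolved(self, design, pars_table):
        eff = ImportantEffect(
            design.term("diagrams", "concerns", "patient_input"), 0.028, 0.160, 0.096
        )
        decisions, entry = ms.resolve_interaction(eff, {"patient_input": 1}, pars_table)
        assert decisions == {"patient_input": 1, "diagrams": 1, "concerns": 1}
        assert len(entry.candidates) == 4

    def test_antagonistic_two_way(self, design, pars_table):
        eff = ImportantEffect(
            design.term("diagrams", "side_effects"), -0.028, -0.163, 0.091
        )
        decisions, _ = ms.resolve_interaction(eff, {"diagrams": 1}, pars_table)
        assert decisions["side_effects"] == -1

    def test_fully_resolved_is_confirmatory(self, design, pars_table):
        eff = ImportantEffect(
            design.term("diagrams", "side_effects"), -0.028, -0.163, 0.091
        )
        start = {"diagrams": 1, "side_effects": -1}
        decisions, entry = ms.resolve_interaction(eff, start, pars_table)
        assert decisions == start
        assert "confirmatory" in entry.note


class TestPredictCondition:
    @pytest.mark.parametrize("cid,expected", sorted(EXPECTED_PREDICTIONS.items()))
    def test_reproduces_printed_predictions(self, design, pars_table, cid, expected):
        codes = design.condition_codes(cid).to_dict()
        y = ms.predict_condition(pars_table, codes, mode="table5_compatible")
        assert round(y, 3) == expected

    def test_zero_coefficients_give_intercept(self, design):
        table = EffectTable(intercept=2.0, estimates=[
            EffectEstimate(design.term("diagrams"), 0.0, beta=0.0, p_value=0.5)
        ])
        for cid in (1, 17, 32):
            codes = design.condition_codes(cid).to_dict()
            assert ms.predict_condition(table, codes) == 2.0

    def test_unstandardized_matches_matrix_oracle(self, design, default_cohort):
        fit = ms.fit_parsimonious(
            default_cohort,
            [design.term("patient_input"), design.term("diagrams", "benefits")],
            design, covariates=(),
        )
        terms = fit.terms
        M = ms.build_model_matrix(design.codes, terms, design)
        b = np.array([fit.table[t].b_weight for t in terms])
        for cid in range(1, 33):
            oracle = fit.intercept + float(M.loc[cid].to_numpy() @ b)
            y = ms.predict_condition(
                fit, design.condition_codes(cid).to_dict(), mode="unstandardized"
            )
            assert y == pytest.approx(oracle, abs=1e-12)

    def test_missing_code_rejected(self, pars_table):
        with pytest.raises(ValueError, match="missing code"):
            ms.predict_condition(pars_table, {"diagrams": 1})

    def test_covariate_offset_shifts_constant(self, design, pars_table):
        codes = design.condition_codes(5).to_dict()
        base = ms.predict_condition(pars_table, codes)
        shifted = ms.predict_condition(pars_table, codes, covariate_offset=1.791)
        assert shifted == pytest.approx(base + 1.791)


class TestPredictionTable:
    def test_sixteen_rows_match_printed_table(self, design, pars_table):
        pt = ms.build_prediction_table(
            pars_table, design, fixed_levels={"side_effects": -1}
        )
        got = {r.condition_id: round(r.y_hat, 3) for r in pt.rows}
        assert got == EXPECTED_PREDICTIONS
        assert pt.argmax_id == 5

    def test_all_zero_ties_break_to_lowest_id(self, design):
        table = EffectTable(intercept=1.0, estimates=[
            EffectEstimate(design.term("diagrams"), 0.0, beta=0.0, p_value=0.9)
        ])
        pt = ms.build_prediction_table(table, design)
        assert len(pt.rows) == 32
        assert len({r.y_hat for r in pt.rows}) == 1
        assert pt.argmax_id == 1

    def test_row_ids_map_to_full_design(self, design, pars_table):
        pt = ms.build_prediction_table(
            pars_table, design, fixed_levels={"side_effects": -1}
        )
        for r in pt.rows:
            assert design.condition_id_for(r.levels) == r.condition_id
            assert r.levels["side_effects"] == -1


class TestRunScreening:
    def test_worked_example_decisions(self, design, full_table, pars_table):
        res = ms.run_screening(full_table, pars_table, design)
        assert set(res.screened_in) == {"diagrams", "benefits", "concerns", "patient_input"}
        assert res.screened_out == ("side_effects",)
        steps = [e.step for e in res.decision_log]
        assert steps == [
            "main_effects",
            "diagrams × concerns × patient_input",
            "diagrams × benefits",
            "diagrams × side_effects",
            "diagrams × benefits × side_effects × concerns",
        ]

    def test_deterministic(self, design, full_table, pars_table):
        a = ms.run_screening(full_table, pars_table, design)
        b = ms.run_screening(full_table, pars_table, design)
        assert a.screened_in == b.screened_in
        assert a.log_json() == b.log_json()

    def test_empty_important_set_screens_all_out(self, design):
        null = EffectTable(intercept=2.0, estimates=[
            EffectEstimate(t, 0.01, beta=0.002, p_value=0.6) for t in design.all_terms()
        ])
        res = ms.run_screening(null, null, design)
        assert res.screened_in == ()
        assert set(res.screened_out) == set(design.factor_names)

    def test_single_negative_main_effect(self, design):
        ests = [EffectEstimate(t, 0.0, beta=0.0, p_value=0.9) for t in design.all_terms()]
        ests[2] = EffectEstimate(design.term("side_effects"), -0.3, beta=-0.05, p_value=0.01)
        table = EffectTable(intercept=2.0, estimates=ests)
        res = ms.run_screening(table, table, design)
        assert res.screened_in == ()
        assert res.levels["side_effects"] == -1

    def test_argmax_matches_screening_configuration(self, design, full_table, pars_table):
        res = ms.run_screening(full_table, pars_table, design)
        pt = ms.build_prediction_table(
            pars_table, design,
            fixed_levels={c: res.levels[c] for c in res.screened_out},
        )
        best = next(r for r in pt.rows if r.condition_id == pt.argmax_id)
        assert best.levels == res.levels

    def test_monotone_in_main_effect(self, design, full_table, pars_table):
        """Raising a screened-in component's main effect keeps it in."""
        def boosted(table, delta):
            ests = []
            for e in table.estimates:
                if e.term == design.term("patient_input"):
                    ests.append(EffectEstimate(
                        e.term, e.b_weight + delta, beta=e.beta + delta / 5.72,
                        p_value=e.p_value))
                else:
                    ests.append(e)
            return EffectTable(table.intercept, ests, table.model_label)

        for delta in (0.1, 0.5, 2.0):
            res = ms.run_screening(
                boosted(full_table, delta), boosted(pars_table, delta), design
            )
            assert "patient_input" in res.screened_in
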