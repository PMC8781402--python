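"""State/action encoding, discretizers and cohort selection."""

import numpy as np
import pandas as pd
import pytest

from htndtr import cohort_builder as cb
from htndtr.errors import ConfigurationError


class TestStateEncoding:
    def test_space_size_and_bijection(self):
        seen = set()
        for c in range(2):
            for g in range(2):
                for p in range(3):
                    for b in range(3):
                        for m in range(3):
                            v = cb.StateVector(c, g, p, b, m)
                            i = cb.encode_state(v)
                            assert 0 <= i < cb.N_STATES
                            assert cb.decode_state(i) == v
                            seen.add(i)
        assert len(seen) == cb.N_STATES == 108

    @pytest.mark.parametrize(
        "vector,index",
        [((0, 0, 0, 0, 0), 0), ((1, 1, 2, 2, 2), 107), ((0, 1, 0, 0, 0), 27)],
    )
    def test_known_indices(self, vector, index):
        assert cb.encode_state(cb.StateVector(*vector)) == index

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            cb.encode_state(cb.StateVector(2, 0, 0, 0, 0))
        with pytest.raises(ConfigurationError):
            cb.decode_state(108)


class TestActions:
    def test_action_space_composition(self):
        assert len(cb.ACTIONS) == cb.N_ACTIONS == 14
        tiers = [a.tier for a in cb.ACTIONS]
        assert tiers == [1] * 4 + [2] * 6 + [3] * 4
        # all 2-subsets and all 3-subsets of the 4 classes appear once
        duals = {a.drug_classes for a in cb.ACTIONS if a.tier == 2}
        triples = {a.drug_classes for a in cb.ACTIONS if a.tier == 3}
        assert len(duals) == 6 and len(triples) == 4

    @pytest.mark.parametrize(
        "classes,action_id",
        [
            ({"ARB"}, 1),
            ({"CCB"}, 2),
            ({"ACEi"}, 3),
            ({"D"}, 4),
            ({"CCB", "ARB"}, 5),  # order-insensitive
            ({"D", "CCB"}, 6),
            ({"ACEi", "CCB"}, 7),
            ({"D", "ARB"}, 8),
            ({"D", "ACEi"}, 9),
            ({"ARB", "ACEi"}, 10),
            ({"D", "CCB", "ARB"}, 11),
            ({"D", "CCB", "ACEi"}, 12),
            ({"CCB", "ARB", "ACEi"}, 13),
            ({"D", "ARB", "ACEi"}, 14),
        ],
    )
    def test_encode_action_table(self, classes, action_id):
        assert cb.encode_action(classes).action_id == action_id

    @pytest.mark.parametrize(
        "classes", [set(), {"D", "ACEi", "ARB", "CCB"}, {"BB"}]
    )
    def test_encode_action_invalid(self, classes):
        with pytest.raises(ConfigurationError):
            cb.encode_action(classes)


class TestDiscretizers:
    @pytest.mark.parametrize(
        "sbp,dbp,level",
        [
            (150, 85, 1),
            (118, 78, 0),
            (135, 102, 2),  # diastolic dominates under the max rule
            (139, 89, 0),
            (140, 80, 1),
            (160, 80, 2),
            (125, 95, 1),
        ],
    )
    def test_bp(self, sbp, dbp, level):
        assert cb.discretize_bp(sbp, dbp) == level

    @pytest.mark.parametrize(
        "bmi,level", [(17.0, 0), (18.5, 1), (24.99, 1), (25.0, 2), (27.9, 2)]
    )
    def test_bmi(self, bmi, level):
        assert cb.discretize_bmi(bmi) == level

    @pytest.mark.parametrize("age,flag", [(50, 1), (55, 0), (63, 0), (54.9, 1)])
    def test_age(self, age, flag):
        assert cb.discretize_age(age) == flag

    @pytest.mark.parametrize(
        "years,level", [(3.0, 0), (4.0, 0), (4.1, 1), (8.0, 1), (9.5, 2)]
    )
    def test_period(self, years, level):
        assert cb.discretize_period(years) == level

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            cb.discretize_bp(-1, 80)
        with pytest.raises(ConfigurationError):
            cb.discretize_bmi(0.0)
        with pytest.raises(ConfigurationError):
            cb.discretize_period(-0.1)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        sbp = rng.uniform(100, 200, 200)
        dbp = rng.uniform(60, 120, 200)
        vec = cb.discretize_bp(sbp, dbp)
        assert all(
            vec[i] == cb.discretize_bp(sbp[i], dbp[i]) for i in range(200)
        )


class TestComplicationDetection:
    def _claims(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "date", "icd10_code"])

    def test_prefix_scan(self):
        claims = self._claims([(1, "2005-06-01", "I13")])
        assert cb.detect_complication(claims, "2005-05-31") == 0
        assert cb.detect_complication(claims, "2005-06-01") == 1
        assert cb.detect_complication(claims, "2006-01-01") == 1

    def test_non_complication_codes_ignored(self):
        claims = self._claims(
            [(1, "2004-01-01", "I10"), (1, "2004-01-01", "E11")]
        )
        assert cb.detect_complication(claims, "2010-01-01") == 0
        assert cb.detect_complication(claims.iloc[:0], "2010-01-01") == 0

    @pytest.mark.parametrize("code", ["I11", "I12", "I13"])
    def test_each_complication_code(self, code):
        claims = self._claims([(1, "2004-01-01", code)])
        assert cb.detect_complication(claims, "2004-02-01") == 1


class TestSelectCohort:
    @staticmethod
    def _tables(claims, supply_days, complete=True):
        claims_df = pd.DataFrame(
            [(1, "2004-01-01", c) for c in claims],
            columns=["patient_id", "date", "icd10_code"],
        )
        rx = pd.DataFrame(
            {
                "patient_id": [1],
                "start_date": ["2004-01-01"],
                "days_supply": [supply_days],
                "drug_classes": ["ARB"],
            }
        )
        checkups = pd.DataFrame(
            {
                "patient_id": [1],
                "date": ["2004-01-01"],
                "systolic_bp": [150],
                "diastolic_bp": [85],
                "bmi": [26.0],
                "fpg": [np.nan if not complete else 140.0],
                "tc": [180.0],
                "smoke": [0],
                "family_history": [1],
                "age_years": [60.0],
            }
        )
        return claims_df, rx, checkups

    def test_all_criteria_met(self):
        assert cb.select_cohort(*self._tables(["I10", "E11"], 90)) == {1}

    def test_missing_diabetes_claim(self):
        assert cb.select_cohort(*self._tables(["I10"], 90)) == set()

    def test_supply_boundary_exactly_30_days(self):
        assert cb.select_cohort(*self._tables(["I10", "E14"], 30)) == set()
        assert cb.select_cohort(*self._tables(["I10", "E14"], 31)) == {1}

    def test_incomplete_checkup_excluded(self):
        tables = self._tables(["I10", "E11"], 90, complete=False)
        assert cb.select_cohort(*tables) == set()

    def test_malformed_icd10_dropped_with_warning(self, caplog):
        claims, rx, checkups = self._tables(["I10", "E11"], 90)
        claims.loc[len(claims)] = (1, "2004-01-01", "not-a-code")
        with caplog.at_level("WARNING"):
            assert cb.select_cohort(claims, rx, checkups) == {1}
        assert any("malformed" in r.message for r in caplog.records)


class TestBuildVisitStates:
    def test_round_trip_recovers_simulated_states(
        self, small_dataset, small_visits
    ):
        """Re-discretizing emitted records must reproduce every planted
        state index and action (>= 10,000 visits)."""
        sim_states = small_dataset.trajectories.states.reshape(-1)
        sim_actions = small_dataset.trajectories.actions.reshape(-1)
        v = small_visits.sort_values(["patient_id", "date"])
        assert len(v) >= 10_000
        assert np.array_equal(v["state_index"].to_numpy(), sim_states)
        assert np.array_equal(
            v["action_id"].to_numpy(dtype=np.int64), sim_actions
        )

    def test_visit_without_covering_prescription(self):
        checkups = pd.DataFrame(
            {
                "patient_id": [1, 1],
                "date": ["2004-01-01", "2004-07-01"],
                "systolic_bp": [150, 150],
                "diastolic_bp": [85, 85],
                "bmi": [26.0, 26.0],
                "fpg": [140.0, 140.0],
                "tc": [180.0, 180.0],
                "smoke": [0, 0],
                "family_history": [0, 0],
                "age_years": [60.0, 60.5],
            }
        )
        claims = pd.DataFrame(
            {
                "patient_id": [1, 1],
                "date": ["2003-06-01", "2003-06-01"],
                "icd10_code": ["E11", "I10"],
            }
        )
        rx = pd.DataFrame(
            {
                "patient_id": [1],
                "start_date": ["2004-01-01"],
                "days_supply": [60],
                "drug_classes": ["ARB+CCB"],
            }
        )
        visits = cb.build_visit_states(checkups, claims, rx)
        assert visits.loc[0, "action_id"] == 5
        assert pd.isna(visits.loc[1, "action_id"])  # supply lapsed

    def test_overlapping_supply_nearest_start_wins(self):
        checkups = pd.DataFrame(
            {
                "patient_id": [1],
                "date": ["2004-03-01"],
                "systolic_bp": [150],
                "diastolic_bp": [85],
                "bmi": [26.0],
                "fpg": [140.0],
                "tc": [180.0],
                "smoke": [0],
                "family_history": [0],
                "age_years": [60.0],
            }
        )
        claims = pd.DataFrame(
            {
                "patient_id": [1, 1],
                "date": ["2003-06-01", "2003-06-01"],
                "icd10_code": ["E11", "I10"],
            }
        )
        rx = pd.DataFrame(
            {
                "patient_id": [1, 1],
                "start_date": ["2004-01-01", "2004-02-15"],
                "days_supply": [180, 30],
                "drug_classes": ["ARB", "CCB"],
            }
        )
        visits = cb.build_visit_states(checkups, claims, rx)
        assert visits.loc[0, "action_id"] == 2  # later covering start

    def test_lapsed_recent_window_falls_back_to_earlier_cover(self):
        checkups = pd.DataFrame(
            {
                "patient_id": [1],
                "date": ["2004-04-01"],
                "systolic_bp": [150],
                "diastolic_bp": [85],
                "bmi": [26.0],
                "fpg": [140.0],
                "tc": [180.0],
                "smoke": [0],
                "family_history": [0],
                "age_years": [60.0],
            }
        )
        claims = pd.DataFrame(
            {
                "patient_id": [1, 1],
                "date": ["2003-06-01", "2003-06-01"],
                "icd10_code": ["E11", "I10"],
            }
        )
        rx = pd.DataFrame(
            {
                "patient_id": [1, 1],
                "start_date": ["2004-01-01", "2004-03-01"],
                "days_supply": [180, 7],  # recent one lapsed by Apr 1
                "drug_classes": ["ARB", "CCB"],
            }
        )
        visits = cb.build_visit_states(checkups, claims, rx)
        assert visits.loc[0, "action_id"] == 1
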