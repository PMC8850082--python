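from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oxbalance as ox
from oxbalance.scoring import (
    DegenerateDistributionError,
    weighted_quantile_cut,
)


def oracle_quantile_cut(values, weights, p: Fraction):
    """Exact-arithmetic oracle: smallest value whose cumulative normalized
    weight strictly exceeds p, walking the sorted values one by one."""
    pairs = sorted(zip(values, weights))
    total = sum(Fraction(w) for _, w in pairs)
    cum = Fraction(0)
    for v, w in pairs:
        cum += Fraction(w)
        if cum / total > p:
            return v
    return pairs[-1][0]


class TestQuantileCuts:
    @pytest.mark.parametrize(
        "values,weights",
        [
            (list(range(1, 10)), [1] * 9),
            (list(range(1, 9)), [1] * 8),
            ([0.5, 1.5, 1.5, 2.5, 9.0], [1, 2, 1, 3, 1]),
            ([3, 1, 4, 1, 5, 9, 2, 6], [2, 1, 1, 1, 1, 1, 1, 1]),
            (list(range(30)), list(range(1, 31))),
        ],
    )
    @pytest.mark.parametrize("p", [Fraction(1, 4), Fraction(1, 3), Fraction(1, 2),
                                   Fraction(2, 3), Fraction(3, 4)])
    def test_matches_exact_oracle(self, values, weights, p):
        got = weighted_quantile_cut(values, float(p), weights)
        assert got == oracle_quantile_cut(values, weights, p)

    def test_tertiles_of_nine_split_evenly(self):
        # frozen from the exact oracle: cuts (4, 7) give thirds {1,2,3},
        # {4,5,6}, {7,8,9} under the <t1 / [t1,t2) / >=t2 convention
        assert ox.compute_tertiles(range(1, 10)) == (4, 7)

    def test_unweighted_equals_equal_weights(self):
        rng = np.random.default_rng(0)
        v = rng.gamma(2, 5, size=57)
        assert ox.compute_tertiles(v) == ox.compute_tertiles(v, np.ones(57))

    def test_mass_on_one_value_is_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            ox.compute_tertiles([5.0, 5.0, 5.0, 5.0])

    def test_heavy_ties_are_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            ox.compute_tertiles([1, 2, 2, 2, 2, 2, 2, 3])


class TestComponentPoints:
    @pytest.mark.parametrize(
        "component,sex,value,expected",
        [
            ("vitamin_c", "female", 120.0, 2),
            ("iron", "male", 25.0, 0),
            ("alcohol", "male", 45.0, 0),
            ("alcohol", "female", 0.0, 2),
            ("alcohol", "female", 14.9, 1),
            ("alcohol", "female", 15.0, 0),   # threshold is inclusive
            ("alcohol", "male", 29.9, 1),
            ("vitamin_c", "female", 38.01, 1),  # exactly t1 -> middle group
            ("vitamin_c", "female", 98.49, 2),  # exactly t2 -> top group
            ("iron", "male", 12.88, 1),         # prooxidant at t1 -> middle
            ("iron", "male", 5.0, 2),
            ("bmi", "female", 22.0, 2),
            ("cotinine", "female", 0.5, 0),
        ],
    )
    def test_worked_examples(self, schema, cutpoints, component, sex, value, expected):
        spec = schema.component(component)
        assert ox.assign_component_points(value, sex, spec, cutpoints) == expected

    def test_missing_cutpoint_is_configuration_error(self, schema):
        empty = ox.CutpointSet(entries={})
        with pytest.raises(ox.SchemaError):
            ox.assign_component_points(1.0, "male", schema.component("zinc"), empty)

    def test_negative_value_rejected(self, schema, cutpoints):
        with pytest.raises(ox.SchemaError):
            ox.assign_component_points(-1.0, "male", schema.component("zinc"), cutpoints)


FEMALE_RECORD = {
    "fiber": 17.0, "carotene": 50.0, "riboflavin": 1.5, "niacin": 25.0,
    "vitamin_b6": 1.0, "total_folate": 400.0, "vitamin_b12": 5.0,
    "vitamin_c": 120.0, "vitamin_e": 5.0, "calcium": 900.0,
    "magnesium": 200.0, "zinc": 8.0, "copper": 1.0, "selenium": 70.0,
    "total_fat": 60.0, "iron": 10.0, "physical_activity": 900.0,
    "alcohol": 0.0, "bmi": 22.0, "cotinine": 0.5,
}
# hand lookup against the packaged female boundaries:
# dietary 2+0+1+2+0+2+2+2+1+2+1+1+1+1 (antioxidants) + 1+1 (fat, iron) = 20
# lifestyle 2 (PA) + 2 (nondrinker) + 2 (BMI) + 0 (cotinine) = 6
FEMALE_RECORD_EXPECTED = {"obs_dietary": 20, "obs_lifestyle": 6, "obs_total": 26}


class TestComputeObs:
    def test_hand_built_female_record(self, schema, cutpoints):
        cohort = pd.DataFrame([{"sex": "female", **FEMALE_RECORD}])
        scores = ox.compute_obs(cohort, schema, cutpoints)
        for col, expected in FEMALE_RECORD_EXPECTED.items():
            assert scores.loc[0, col] == expected

    def _extreme_cohort(self, schema, cutpoints, best: bool):
        rows = []
        for sex in ("male", "female"):
            row = {"sex": sex}
            for comp in schema:
                if comp.rule == "fixed_alcohol":
                    row[comp.name] = 0.0 if best else 100.0
                    continue
                t1, t2 = cutpoints.lookup(comp.name, sex)
                high, low = t2 * 2, t1 / 2
                if comp.polarity == "antioxidant":
                    row[comp.name] = high if best else low
                else:
                    row[comp.name] = low if best else high
            rows.append(row)
        return pd.DataFrame(rows)

    def test_all_minimum_scores_zero(self, schema, cutpoints):
        scores = ox.compute_obs(self._extreme_cohort(schema, cutpoints, False),
                                schema, cutpoints)
        assert (scores[["obs_total", "obs_dietary", "obs_lifestyle"]] == 0).all().all()

    def test_all_maximum_scores_forty(self, schema, cutpoints):
        scores = ox.compute_obs(self._extreme_cohort(schema, cutpoints, True),
                                schema, cutpoints)
        assert (scores["obs_total"] == 40).all()
        assert (scores["obs_dietary"] == 32).all()
        assert (scores["obs_lifestyle"] == 8).all()

    def test_leave_one_out_consistency(self, schema, cutpoints, small_cohort):
        full = ox.compute_obs(small_cohort, schema, cutpoints)
        for name in ("selenium", "alcohol", "cotinine"):
            reduced = ox.compute_obs(small_cohort, schema.drop(name), cutpoints)
            assert schema.drop(name).max_total == 38
            assert (
                full["obs_total"] - reduced["obs_total"] == full[f"pts_{name}"]
            ).all()


@st.composite
def cohort_records(draw, n_max=12):
    n = draw(st.integers(1, n_max))
    schema = ox.load_default_schema()
    pos = st.floats(0.001, 1e4, allow_nan=False, allow_infinity=False)
    rows = []
    for i in range(n):
        row = {"sex": draw(st.sampled_from(["male", "female"]))}
        for comp in schema:
            row[comp.name] = draw(pos)
        rows.append(row)
    return pd.DataFrame(rows)


class TestScoreProperties:
    @given(cohort=cohort_records())
    def test_decomposition_and_bounds(self, cohort):
        scores = ox.compute_obs(cohort)
        assert (scores["obs_total"]
                == scores["obs_dietary"] + scores["obs_lifestyle"]).all()
        assert scores["obs_total"].between(0, 40).all()
        assert scores["obs_dietary"].between(0, 32).all()
        assert scores["obs_lifestyle"].between(0, 8).all()

    @given(cohort=cohort_records(), comp_idx=st.integers(0, 19))
    def test_polarity_flip_reverses_points(self, cohort, comp_idx):
        import dataclasses

        schema = ox.load_default_schema()
        comp = schema.components[comp_idx]
        if comp.rule == "fixed_alcohol":
            return  # alcohol's fixed rule has no tertile polarity to flip
        flipped_comp = dataclasses.replace(
            comp,
            polarity=("prooxidant" if comp.polarity == "antioxidant"
                      else "antioxidant"),
        )
        flipped = dataclasses.replace(
            schema,
            components=tuple(flipped_comp if c.name == comp.name else c
                             for c in schema.components),
        )
        base = ox.compute_obs(cohort, schema)
        alt = ox.compute_obs(cohort, flipped)
        assert (alt[f"pts_{comp.name}"] == 2 - base[f"pts_{comp.name}"]).all()


class TestQuartiles:
    def test_eight_values_split_into_pairs(self):
        q = ox.assign_quartiles(np.arange(1, 9), ["female"] * 8)
        assert q.value_counts().to_dict() == {"Q1": 2, "Q2": 2, "Q3": 2, "Q4": 2}
        assert list(q[:2]) == ["Q1", "Q1"]
        assert list(q[-2:]) == ["Q4", "Q4"]

    def test_identical_values_error(self):
        with pytest.raises(DegenerateDistributionError):
            ox.assign_quartiles([3.0] * 10, ["male"] * 10)

    def test_labels_monotone_in_score_within_sex(self, small_cohort, schema,
                                                 cutpoints):
        scores = ox.compute_obs(small_cohort, schema, cutpoints)
        q = ox.assign_quartiles(scores["obs_total"].to_numpy(),
                                small_cohort["sex"].to_numpy())
        codes = q.cat.codes.to_numpy()
        obs = scores["obs_total"].to_numpy()
        for sex in ("male", "female"):
            m = (small_cohort["sex"] == sex).to_numpy()
            order = np.argsort(obs[m], kind="stable")
            assert (np.diff(codes[m][order]) >= 0).all()

    def test_sex_specific_by_default(self):
        # same OBS values, different quartiles per sex when distributions shift
        obs = np.r_[np.arange(1, 9), np.arange(5, 13)]
        sex = ["female"] * 8 + ["male"] * 8
        q = ox.assign_quartiles(obs, sex)
        assert q[7] == "Q4" and q[8] == "Q1"  # value 8 top for women, 5 bottom for men


class TestOBSScorerEstimator:
    def test_transform_matches_function(self, small_cohort, schema, cutpoints):
        scorer = ox.OBSScorer(schema=schema, cutpoints=cutpoints).fit(small_cohort)
        expected = ox.compute_obs(small_cohort, schema, cutpoints)
        pd.testing.assert_frame_equal(scorer.transform(small_cohort), expected)

    def test_recompute_cutpoints_from_data(self, small_cohort):
        scorer = ox.OBSScorer(recompute_cutpoints=True).fit(small_cohort)
        assert scorer.cutpoints_.provenance == "computed_from_data"
        male_fiber = small_cohort.loc[small_cohort.sex == "male", "fiber"]
        assert scorer.cutpoints_.lookup("fiber", "male") == \
            ox.compute_tertiles(male_fiber.to_numpy())

    def test_sklearn_param_interface(self):
        from sklearn.base import clone

        scorer = ox.OBSScorer(recompute_cutpoints=True, add_quartiles=True)
        cloned = clone(scorer)
        assert cloned.get_params()["recompute_cutpoints"] is True
        assert cloned.get_params()["add_quartiles"] is True
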