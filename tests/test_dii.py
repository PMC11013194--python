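"""DII scoring engine: reference tables, screening, scoring, tertiles, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microdii.dii import (
    FoodParameterSpec,
    IntakeTable,
    PUBLISHED_RANGE,
    assign_tertiles,
    compute_dii,
    dietary_statistics,
    energy_correct,
    harmonize_parameters,
    load_reference,
    screen_energy,
)

from conftest import normal_cdf_oracle


class TestReferenceTables:
    def test_common_subset_has_27_parameters(self):
        assert len(load_reference("common27")) == 27

    def test_full_index_has_45_parameters(self):
        assert len(load_reference("full45")) == 45

    def test_common_names_subset_of_full(self):
        common = {s.name for s in load_reference("common27")}
        full = {s.name for s in load_reference("full45")}
        assert common < full
        # the two instruments share 60% of the full index
        assert len(common) / len(full) == pytest.approx(0.6)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FoodParameterSpec("x", "g", 1.0, 0.0, 0.1)  # sd must be > 0
        with pytest.raises(ValueError):
            FoodParameterSpec("x", "", 1.0, 1.0, 0.1)  # units non-empty


class TestHarmonize:
    def test_single_table_identity(self, toy_intakes, toy_reference):
        merged = harmonize_parameters([toy_intakes], toy_reference)
        pd.testing.assert_frame_equal(merged.values, toy_intakes.values)
        assert merged.n_common == 3

    def test_intersection_restricts_columns(self, toy_intakes, toy_reference):
        other = IntakeTable(
            values=toy_intakes.values[["fiber", "vitamin_c"]].rename(
                index=lambda s: s + "x"
            ),
            energy_kcal=toy_intakes.energy_kcal.rename(index=lambda s: s + "x"),
        )
        merged = harmonize_parameters([toy_intakes, other], toy_reference)
        assert set(merged.parameters) == {"fiber", "vitamin_c"}
        assert merged.n_common == 2
        assert len(merged.subjects) == 6

    def test_disjoint_parameter_sets_error(self, toy_intakes, toy_reference):
        other = IntakeTable(
            values=toy_intakes.values[["fiber"]].rename(index=lambda s: s + "x"),
            energy_kcal=toy_intakes.energy_kcal.rename(index=lambda s: s + "x"),
        )
        only_fat = IntakeTable(
            values=toy_intakes.values[["saturated_fat"]],
            energy_kcal=toy_intakes.energy_kcal,
        )
        with pytest.raises(ValueError, match="empty intersection"):
            harmonize_parameters([other, only_fat], toy_reference)

    def test_alias_and_unit_conversion(self, toy_reference):
        values = pd.DataFrame(
            {"Fiber (mg)": [18800.0]}, index=pd.Index(["A"], name="subject_id")
        )
        table = IntakeTable(
            values=values,
            energy_kcal=pd.Series([2000.0], index=values.index),
            units={"Fiber (mg)": "mg"},
        )
        merged = harmonize_parameters(
            [table],
            toy_reference,
            alias_map={"Fiber (mg)": "fiber"},
            unit_conversions={("mg", "g"): 0.001},
        )
        assert merged.values.loc["A", "fiber"] == pytest.approx(18.8)

    def test_unmappable_name_error(self, toy_intakes, toy_reference):
        bad = IntakeTable(
            values=toy_intakes.values.rename(columns={"fiber": "mystery"}),
            energy_kcal=toy_intakes.energy_kcal,
        )
        with pytest.raises(ValueError, match="mystery"):
            harmonize_parameters([bad], toy_reference)


class TestEnergyScreen:
    @pytest.mark.parametrize(
        "kcal,retained",
        [(3001.5, True), (500.0, True), (5000.0, True), (5200.0, False), (499.9, False)],
    )
    def test_plausibility_window_boundaries(self, toy_intakes, kcal, retained):
        table = IntakeTable(
            values=toy_intakes.values,
            energy_kcal=pd.Series([kcal, 2000.0, 2000.0], index=toy_intakes.values.index),
        )
        kept, flagged = screen_energy(table)
        assert ("A" in kept.subjects) is retained
        assert ("A" in flagged) is not retained


class TestEnergyCorrect:
    def test_density_arithmetic(self, toy_intakes):
        corrected = energy_correct(toy_intakes, per_kcal=1000.0)
        # 30 g at 1800 kcal -> 16.67 g / 1000 kcal
        assert corrected.values.loc["C", "fiber"] == pytest.approx(30.0 / 1800.0 * 1000.0)

    def test_zero_intake_stays_zero(self, toy_intakes):
        toy_intakes.values.loc["A", "fiber"] = 0.0
        corrected = energy_correct(toy_intakes)
        assert corrected.values.loc["A", "fiber"] == 0.0

    def test_identity_when_per_kcal_equals_energy(self, toy_intakes):
        table = IntakeTable(
            values=toy_intakes.values,
            energy_kcal=pd.Series(2000.0, index=toy_intakes.values.index),
        )
        corrected = energy_correct(table, per_kcal=2000.0)
        pd.testing.assert_frame_equal(corrected.values, table.values)


class TestComputeDii:
    def test_zero_score_at_global_means(self, toy_intakes, toy_reference):
        results = compute_dii(toy_intakes, toy_reference)
        # subject A consumes exactly the global means
        assert results[0].total_score == pytest.approx(0.0, abs=1e-12)

    def test_single_parameter_against_cdf_oracle(self):
        spec = FoodParameterSpec("p", "g", 100.0, 20.0, 0.5)
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = float(rng.uniform(20, 180))
            table = IntakeTable(
                values=pd.DataFrame({"p": [x]}, index=pd.Index(["A"])),
                energy_kcal=pd.Series([2000.0], index=["A"]),
            )
            [res] = compute_dii(table, [spec])
            expected = (2.0 * normal_cdf_oracle((x - 100.0) / 20.0) - 1.0) * 0.5
            assert res.total_score == pytest.approx(expected, abs=1e-6)

    def test_worked_value(self):
        # x=120, mu=100, sd=20, S=0.5 -> (2*Phi(1)-1)*0.5 ~ 0.3413
        spec = FoodParameterSpec("p", "g", 100.0, 20.0, 0.5)
        table = IntakeTable(
            values=pd.DataFrame({"p": [120.0]}, index=pd.Index(["A"])),
            energy_kcal=pd.Series([2000.0], index=["A"]),
        )
        [res] = compute_dii(table, [spec])
        assert res.total_score == pytest.approx(0.341345, abs=1e-5)

    def test_additivity_and_boundedness(self, toy_intakes, toy_reference):
        for res in compute_dii(toy_intakes, toy_reference):
            assert res.total_score == pytest.approx(
                sum(res.contributions.values()), abs=1e-10
            )
            for spec in toy_reference:
                assert abs(res.contributions[spec.name]) <= abs(spec.effect_score)

    def test_monotone_in_intake_with_effect_sign(self, toy_reference):
        for spec in toy_reference:
            intakes = np.linspace(0.1, 3.0, 7) * spec.global_mean
            scores = []
            for x in intakes:
                table = IntakeTable(
                    values=pd.DataFrame({spec.name: [x]}, index=pd.Index(["A"])),
                    energy_kcal=pd.Series([2000.0], index=["A"]),
                )
                scores.append(compute_dii(table, [spec])[0].total_score)
            diffs = np.diff(scores)
            assert (np.sign(diffs) == np.sign(spec.effect_score)).all()

    def test_missing_values_contribute_zero(self, toy_intakes, toy_reference):
        toy_intakes.values.loc["B", "fiber"] = np.nan
        results = {r.subject: r for r in compute_dii(toy_intakes, toy_reference)}
        assert results["B"].n_parameters == 2
        assert results["B"].contributions["fiber"] == 0.0
        assert results["A"].n_parameters == 3

    def test_random_profiles_within_published_range(self):
        reference = load_reference("full45")
        rng = np.random.default_rng(3)
        n = 200
        values = {
            s.name: np.maximum(
                s.global_mean + s.global_sd * rng.normal(0, 1, n), 0.0
            )
            for s in reference
        }
        table = IntakeTable(
            values=pd.DataFrame(values, index=[f"s{i}" for i in range(n)]),
            energy_kcal=pd.Series(2000.0, index=[f"s{i}" for i in range(n)]),
        )
        lo, hi = PUBLISHED_RANGE
        for res in compute_dii(table, reference):
            assert lo <= res.total_score <= hi

    def test_instrument_invariance_after_harmonization(self, toy_reference):
        values = pd.DataFrame(
            {"fiber": [12.0], "saturated_fat": [30.0], "vitamin_c": [80.0]},
            index=pd.Index(["A"]),
        )
        energy = pd.Series([2000.0], index=["A"])
        canonical = IntakeTable(values=values, energy_kcal=energy)
        dialect = IntakeTable(
            values=values.rename(columns={"fiber": "Dietary Fiber (g)"}),
            energy_kcal=energy,
        )
        merged = harmonize_parameters(
            [dialect], toy_reference, alias_map={"Dietary Fiber (g)": "fiber"}
        )
        a = compute_dii(canonical, toy_reference)[0].total_score
        b = compute_dii(merged, toy_reference)[0].total_score
        assert a == b


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    intake=st.floats(0.0, 1e4),
    mean=st.floats(0.1, 1e3),
    sd=st.floats(0.1, 1e3),
    s=st.floats(-1.0, 1.0),
)
def test_contribution_bounded_by_effect_score(intake, mean, sd, s):
    """|contribution| <= |S| for any intake: the centered percentile is in (-1, 1)."""
    spec = FoodParameterSpec("p", "g", mean, sd, s)
    table = IntakeTable(
        values=pd.DataFrame({"p": [intake]}, index=pd.Index(["A"])),
        energy_kcal=pd.Series([2000.0], index=["A"]),
    )
    [res] = compute_dii(table, [spec])
    assert abs(res.total_score) <= abs(s) + 1e-12


class TestTertiles:
    def test_cohort_split_47(self):
        scores = [(f"s{i}", float(i)) for i in range(47)]
        tert = dict(assign_tertiles(scores))
        sizes = pd.Series(tert).value_counts().sort_index()
        assert list(sizes) == [15, 16, 16]
        # the 15 lowest scores land in tertile 1
        assert all(tert[f"s{i}"] == 1 for i in range(15))

    def test_exact_division(self):
        tert = dict(assign_tertiles([(f"s{i}", float(i)) for i in range(6)]))
        assert list(pd.Series(tert).value_counts().sort_index()) == [2, 2, 2]

    def test_ties_stable_and_deterministic(self):
        scores = [(f"s{i}", 1.0) for i in range(6)]
        first = assign_tertiles(scores)
        second = assign_tertiles(scores)
        assert first == second
        assert [t for _, t in first] == [1, 1, 2, 2, 3, 3]

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            assign_tertiles([("a", 1.0), ("b", 2.0)])


class TestDietaryStatistics:
    def test_cohort_race_table_chi_square(self, toy_intakes):
        """The cohort's race/ethnicity x tertile table gives chi-square p ~ 0.31."""
        counts = np.array([[2, 4, 1], [9, 6, 6], [4, 6, 9]])
        levels = ["Hispanic", "NH Black", "Other"]
        rows, tert = [], {}
        k = 0
        for i, level in enumerate(levels):
            for t in (1, 2, 3):
                for _ in range(counts[i, t - 1]):
                    rows.append({"subject": f"s{k}", "race": level})
                    tert[f"s{k}"] = t
                    k += 1
        demo = pd.DataFrame(rows).set_index("subject")[["race"]]
        values = pd.DataFrame({"fiber": np.ones(47)}, index=demo.index)
        table = IntakeTable(
            values=values, energy_kcal=pd.Series(2000.0, index=demo.index)
        )
        report = dietary_statistics(table, tert, demographics=demo)
        p = report.chi_square.loc[report.chi_square["variable"] == "race", "p"].item()
        assert round(p, 2) == 0.31

    def test_perfect_monotone_pair_has_unit_spearman(self):
        idx = [f"s{i}" for i in range(9)]
        x = np.arange(1.0, 10.0)
        table = IntakeTable(
            values=pd.DataFrame({"a": x, "b": x**2}, index=idx),
            energy_kcal=pd.Series(2000.0, index=idx),
        )
        tert = {s: 1 + i // 3 for i, s in enumerate(idx)}
        report = dietary_statistics(table, tert)
        assert report.spearman_rho.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(report.spearman_rho, report.spearman_rho.T)
        assert np.allclose(np.diag(report.spearman_rho), 1.0)

    def test_identical_groups_t_statistic_zero(self):
        idx = [f"s{i}" for i in range(9)]
        table = IntakeTable(
            values=pd.DataFrame({"a": np.ones(9)}, index=idx),
            energy_kcal=pd.Series(2000.0, index=idx),
        )
        tert = {s: 1 + i // 3 for i, s in enumerate(idx)}
        report = dietary_statistics(table, tert)
        row = report.ttest.iloc[0]
        assert row["t"] == 0.0
        assert row["p"] == 1.0

    def test_proportional_rows_give_null_chi_square(self):
        # two categorical levels distributed identically across tertiles
        rows, tert = [], {}
        k = 0
        for level in ("u", "v"):
            for t in (1, 2, 3):
                for _ in range(4):
                    rows.append({"subject": f"s{k}", "cat": level})
                    tert[f"s{k}"] = t
                    k += 1
        demo = pd.DataFrame(rows).set_index("subject")[["cat"]]
        table = IntakeTable(
            values=pd.DataFrame({"a": np.arange(24.0)}, index=demo.index),
            energy_kcal=pd.Series(2000.0, index=demo.index),
        )
        report = dietary_statistics(table, tert, demographics=demo)
        assert report.chi_square["statistic"].item() == pytest.approx(0.0, abs=1e-12)
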