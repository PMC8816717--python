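"""Cohort statistics, GAPT, mechanism classification, aging, dynaplot."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import silamdyn as sd
from silamdyn import (
    MECHANISM_PALETTE,
    abundance_tests,
    aging_trend,
    build_results,
    classify_mechanism,
    compute_gapt,
    dynaplot,
    turnover_tests,
    two_sample_pvalue,
)


def _long(values_by_protein, column="incorporation"):
    rows = []
    for pid, (control, disease) in values_by_protein.items():
        for i, v in enumerate(control):
            rows.append((pid, f"C{i+1}", "control", v))
        for i, v in enumerate(disease):
            rows.append((pid, f"D{i+1}", "disease", v))
    return pd.DataFrame(rows, columns=["protein_id", "mouse_id", "cohort", column])


class TestTwoSampleTest:
    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_scipy_on_random_instances(self, equal_var):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1, n2 = rng.integers(2, 8, size=2)
            a = rng.normal(0, 1 + rng.random(), n1)
            b = rng.normal(rng.random(), 1 + rng.random(), n2)
            want = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
            got, degen = two_sample_pvalue(a, b, equal_var=equal_var)
            assert not degen
            assert got == pytest.approx(want, abs=1e-10)

    def test_identical_constant_samples(self):
        p, degen = two_sample_pvalue([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert p == 1.0 and not degen

    def test_degenerate_separated_constants(self):
        p, degen = two_sample_pvalue([0.2, 0.2, 0.2], [0.4, 0.4, 0.4])
        assert degen and p < 1e-300

    def test_requires_two_per_cohort(self):
        with pytest.raises(ValueError):
            two_sample_pvalue([0.1], [0.2, 0.3])


class TestTurnoverTests:
    def test_identical_cohorts_give_unity_p(self):
        df = _long({"P": ([0.30, 0.31, 0.29], [0.30, 0.31, 0.29])})
        out = turnover_tests(df)
        assert out["delta"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_textbook_oracle(self):
        c, d = [0.25, 0.30, 0.35], [0.40, 0.45, 0.50]
        out = turnover_tests(_long({"P": (c, d)}))
        assert out["delta"].iloc[0] == pytest.approx(0.15)
        assert out["p_value"].iloc[0] == pytest.approx(
            stats.ttest_ind(c, d, equal_var=True).pvalue, abs=1e-12
        )
        welch = turnover_tests(_long({"P": (c, d)}), equal_var=False)
        assert welch["p_value"].iloc[0] == pytest.approx(
            stats.ttest_ind(c, d, equal_var=False).pvalue, abs=1e-12
        )

    def test_degenerate_shift_flagged(self):
        out = turnover_tests(_long({"P": ([0.2, 0.2, 0.2], [0.4, 0.4, 0.4])}))
        assert bool(out["degenerate"].iloc[0])
        assert out["delta_pp"].iloc[0] == pytest.approx(20.0)


class TestGapt:
    def test_identical_cohorts(self):
        df = turnover_tests(
            _long({f"P{i}": ([0.2 + i / 100] * 3, [0.2 + i / 100] * 3) for i in range(5)})
        )
        g = compute_gapt(df)
        assert g.percent_change == 0.0 and g.p_value == pytest.approx(1.0)

    def test_uniform_scaling_recovered_exactly(self):
        rng = np.random.default_rng(1)
        data = {}
        for i in range(50):
            c = rng.uniform(0.05, 0.6)
            data[f"P{i:02d}"] = ([c] * 3, [0.939 * c] * 3)
        g = compute_gapt(turnover_tests(_long(data)))
        assert g.percent_change == pytest.approx(-6.1, abs=1e-9)

    def test_paired_variant_detects_small_uniform_shift(self):
        rng = np.random.default_rng(2)
        data = {
            f"P{i}": ([v := rng.uniform(0.1, 0.5)] * 3, [0.97 * v] * 3) for i in range(40)
        }
        comp = turnover_tests(_long(data))
        unpaired = compute_gapt(comp, paired=False)
        paired = compute_gapt(comp, paired=True)
        assert paired.p_value < unpaired.p_value

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_gapt(turnover_tests(_long({"P": ([0.1, 0.2], [0.1, 0.2])})).iloc[:0])


class TestClassifyMechanism:
    @pytest.mark.parametrize(
        "dt, pt, da, pa, expected, uncoupled",
        [
            (+0.05, 0.001, +0.4, 0.001, "synthesis_up", False),
            (-0.05, 0.001, -0.4, 0.001, "synthesis_down", False),
            (+0.05, 0.001, -0.4, 0.001, "degradation_up", False),
            (-0.05, 0.001, +0.4, 0.001, "degradation_down", False),
            (+0.05, 0.001, 0.0, 0.8, "repair_up", False),
            (-0.05, 0.001, 0.0, 0.8, "repair_down", False),
            (+0.05, 0.5, +0.4, 0.5, "unchanged", False),
            (+0.05, 0.5, +0.4, 0.001, "synthesis_up", True),
            (+0.05, 0.5, -0.4, 0.001, "synthesis_down", True),
        ],
    )
    def test_regime_mapping(self, dt, pt, da, pa, expected, uncoupled):
        labels, flags = classify_mechanism([dt], [pt], [da], [pa])
        assert labels[0] == expected
        assert bool(flags[0]) is uncoupled

    def test_antisymmetric_under_cohort_relabeling(self):
        rng = np.random.default_rng(3)
        dt = rng.normal(0, 0.1, 200)
        da = rng.normal(0, 1.0, 200)
        pt = rng.uniform(0, 0.05, 200)
        pa = rng.uniform(0, 0.05, 200)
        fwd, _ = classify_mechanism(dt, pt, da, pa)
        rev, _ = classify_mechanism(-dt, pt, -da, pa)
        flip = {
            "synthesis_up": "synthesis_down",
            "synthesis_down": "synthesis_up",
            "degradation_up": "degradation_down",
            "degradation_down": "degradation_up",
            "repair_up": "repair_down",
            "repair_down": "repair_up",
            "unchanged": "unchanged",
        }
        assert all(r == flip[f] for f, r in zip(fwd, rev))

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            classify_mechanism([0.1], [0.01], [0.1], [0.01], alpha=1.5)


class TestNoiseFreeRecovery:
    def test_full_pipeline_reproduces_generative_labels(
        self, archetype_truth, schedule, noise_free_cohorts
    ):
        evidence, groups = noise_free_cohorts
        merged = sd.merge_fractions(
            sd.aggregate_to_protein(sd.compute_incorporation(evidence))
        )
        profiles = sd.integrate_abundance(sd.fraction_completeness_filter(groups))
        res = build_results(turnover_tests(merged), abundance_tests(profiles))
        truth = sd.truth_to_frame(archetype_truth).set_index("protein_id")
        joined = res.set_index("protein_id").join(truth["mechanism_label"])
        assert len(joined) == len(archetype_truth)
        assert (joined["mechanism_class"] == joined["mechanism_label"]).all()


class TestAging:
    def test_all_decreasing(self):
        ages = [113, 186, 285, 503]
        rows = [
            (a, f"P{p:03d}", 0.4 - 0.05 * i)
            for p in range(360)
            for i, a in enumerate(ages)
        ]
        series = pd.DataFrame(rows, columns=["age_days", "protein_id", "incorporation"])
        trend = aging_trend(series)
        assert trend.fraction_decreasing == 1.0
        assert trend.p_value == pytest.approx(2 * 0.5**360, rel=1e-6)
        assert (trend.slopes["slope_per_day"] < 0).all()

    def test_null_series_shows_no_trend(self):
        rng = np.random.default_rng(4)
        ages = [113, 285, 503]
        rows = [
            (a, f"P{p:03d}", rng.uniform(0.1, 0.5)) for p in range(300) for a in ages
        ]
        trend = aging_trend(pd.DataFrame(rows, columns=["age_days", "protein_id", "incorporation"]))
        assert abs(trend.fraction_decreasing - 0.5) < 0.07
        assert trend.p_value > 0.05

    def test_incomplete_proteins_dropped(self):
        rows = [(1, "A", 0.3), (2, "A", 0.2), (1, "B", 0.3)]
        trend = aging_trend(pd.DataFrame(rows, columns=["age_days", "protein_id", "incorporation"]))
        assert trend.n_proteins == 1

    def test_requires_two_ages(self):
        with pytest.raises(ValueError):
            aging_trend(pd.DataFrame({"age_days": [1], "protein_id": ["A"], "incorporation": [0.1]}))


class TestDynaplot:
    def _results(self):
        data = {
            "P1": ([0.30] * 3, [0.42] * 3),  # turnover up
            "P2": ([0.30] * 3, [0.30] * 3),  # unchanged
        }
        merged = _long(data)
        ab = _long({"P1": ([100.0] * 3, [220.0] * 3), "P2": ([100.0] * 3, [100.0] * 3)}, column="abundance")
        return build_results(turnover_tests(merged), abundance_tests(ab))

    def test_colors_follow_classification(self, tmp_path):
        res = self._results()
        table = dynaplot(res, figure_path=tmp_path / "d.svg")
        for _, row in table.iterrows():
            assert row["color"] == MECHANISM_PALETTE[row["mechanism_class"]]
        assert (tmp_path / "d.svg").read_text().startswith("<?xml")

    def test_unchanged_protein_sits_at_origin(self):
        table = dynaplot(self._results())
        row = table[table.protein_id == "P2"].iloc[0]
        assert row["mechanism_class"] == "unchanged"
        assert row["turnover_delta_pp"] == pytest.approx(0.0)
        assert row["log2_abundance_ratio"] == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dynaplot(self._results().iloc[:0])
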