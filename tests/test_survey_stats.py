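"""Frequency-matrix statistics: totals, skewness, quadrants, spectra, TP curve."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from csb2scan.sequence_model import TPTable
from csb2scan.survey_stats import (
    FrequencyMatrix,
    cumulative_tp_curve,
    position_spectrum,
    quadrant_counts,
    sample_skewness,
    survey_report,
    totals_by_total_g,
)

random_matrices = st.dictionaries(
    st.tuples(st.integers(1, 8), st.integers(1, 8)),
    st.integers(0, 50),
    min_size=1,
    max_size=20,
).map(
    lambda cells: FrequencyMatrix.from_counts(
        {f"G{m}AG{n}": c for (m, n), c in cells.items()}
    )
)


class TestFrequencyMatrix:
    def test_add_and_totals(self):
        fm = FrequencyMatrix.from_counts({"G5AG7": 3, "G13": 2, "G9TG6": 1})
        assert fm.total_hits == 6
        assert fm.cell(5, 7, "A") == 3
        assert fm.continuous[13] == 2
        assert fm.counts_by_name() == {"G5AG7": 3, "G9TG6": 1, "G13": 2}

    def test_modal_cell(self):
        fm = FrequencyMatrix.from_counts({"G6AG7": 10, "G5AG7": 4})
        assert fm.modal_cell("A") == (6, 7)

    def test_tsv_and_json_round_trip(self, tmp_path):
        fm = FrequencyMatrix.from_counts({"G6AG7": 7, "G6AG8": 5, "G13": 1, "G9CG6": 2})
        fm.to_tsv(tmp_path / "m.tsv")
        fm.to_json(tmp_path / "m.json")
        assert FrequencyMatrix.from_tsv(tmp_path / "m.tsv").counts_by_name() == fm.counts_by_name()
        assert FrequencyMatrix.from_json(tmp_path / "m.json").counts_by_name() == fm.counts_by_name()


class TestTotalsByTotalG:
    def test_single_cell(self):
        fm = FrequencyMatrix.from_counts({"G5AG7": 10})
        assert totals_by_total_g(fm) == {12: 10}

    def test_anti_diagonal_pooling(self):
        fm = FrequencyMatrix.from_counts({"G5AG7": 1, "G6AG6": 2})
        assert totals_by_total_g(fm) == {12: 3}

    @settings(max_examples=50, derandomize=True)
    @given(random_matrices)
    def test_conserves_total_hits(self, fm):
        assert sum(totals_by_total_g(fm).values()) == fm.total_hits


class TestSampleSkewness:
    def test_symmetric_data_is_zero(self):
        assert sample_skewness([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_oracle(self):
        # independent evaluation of N/((N-1)(N-2)) * sum(((x-mean)/s)^3)
        xs = [1.0, 2.0, 10.0]
        n, mean = 3, sum(xs) / 3
        s = (sum((x - mean) ** 2 for x in xs) / (n - 1)) ** 0.5
        expected = n / ((n - 1) * (n - 2)) * sum(((x - mean) / s) ** 3 for x in xs)
        assert sample_skewness(xs) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.652, abs=5e-4)

    def test_antisymmetry_under_mirroring(self):
        xs = [0.3, 1.1, 4.2, 9.9, 2.2]
        assert sample_skewness([-x for x in xs]) == pytest.approx(-sample_skewness(xs), rel=1e-12)

    def test_matches_scipy_adjusted_estimator(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            xs = rng.gamma(2.0, size=rng.integers(3, 40))
            assert sample_skewness(xs) == pytest.approx(
                sps.skew(xs, bias=False), rel=1e-10
            )
            assert sample_skewness(xs, adjusted=False) == pytest.approx(
                sps.skew(xs, bias=True), rel=1e-10
            )

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            sample_skewness([1.0, 2.0])
        with pytest.raises(ValueError):
            sample_skewness([3.0, 3.0, 3.0])


class TestQuadrantCounts:
    def test_all_mass_at_pivot(self):
        fm = FrequencyMatrix.from_counts({"G6AG7": 9})
        q = quadrant_counts(fm, pivot=(6, 7))
        assert q.on_axes == 9
        assert all(v == 0 for v in q.strict.values())

    def test_single_off_pivot_cell(self):
        fm = FrequencyMatrix.from_counts({"G6AG7": 1, "G5AG8": 4})
        q = quadrant_counts(fm, pivot=(6, 7))
        assert q.strict["first_shorter_second_longer"] == 4

    def test_inclusive_folds_axis_cells(self):
        fm = FrequencyMatrix.from_counts({"G6AG7": 2, "G6AG9": 3, "G5AG7": 5})
        q = quadrant_counts(fm, pivot=(6, 7))
        assert q.on_axes == 10
        assert q.inclusive["first_shorter_second_longer"] == 10
        assert q.inclusive_fractions["first_shorter_second_longer"] == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(random_matrices)
    def test_strict_quadrants_plus_axes_conserve_total(self, fm):
        interrupted_total = sum(fm.interrupted["A"].values())
        assume(interrupted_total > 0)
        q = quadrant_counts(fm, pivot=(4, 4))
        assert sum(q.strict.values()) + q.on_axes == interrupted_total

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError):
            quadrant_counts(FrequencyMatrix())


class TestPositionSpectrum:
    def test_single_variant_all_mass_at_minus_one(self):
        fm = FrequencyMatrix.from_counts({"G6AG7": 12})
        spec = position_spectrum(fm)
        assert spec.counts == {-1: 12}

    def test_equal_run_variants_at_zero(self):
        fm = FrequencyMatrix.from_counts({"G6AG6": 2, "G7AG7": 3})
        assert position_spectrum(fm).counts == {0: 5}

    def test_fractions_sum_to_one(self):
        fm = FrequencyMatrix.from_counts({"G6AG7": 5, "G9AG6": 5, "G6AG9": 10})
        spec = position_spectrum(fm)
        assert sum(spec.fractions.values()) == pytest.approx(1.0)
        assert spec.counts == {-2: 10, -1: 5, 2: 5}

    def test_continuous_tracts_excluded(self):
        fm = FrequencyMatrix.from_counts({"G13": 100, "G6AG7": 1})
        assert position_spectrum(fm).total == 1


class TestCumulativeTPCurve:
    def test_single_point_curve(self):
        fm = FrequencyMatrix.from_counts({"G5AG7": 8})
        curve = cumulative_tp_curve(fm, TPTable.from_mapping({"G5AG7": 17.0}))
        assert len(curve.points) == 1
        assert curve.points[0].cumulative_fraction == 1.0
        assert curve.fraction_within(17, 43) == 1.0

    def test_two_variant_split(self):
        fm = FrequencyMatrix.from_counts({"G3AG9": 5, "G5AG7": 5})
        curve = cumulative_tp_curve(fm, TPTable.from_mapping({"G3AG9": 11.0, "G5AG7": 17.0}))
        assert [p.variant for p in curve.points] == ["G3AG9", "G5AG7"]
        assert curve.fraction_within(17, 43) == 0.5
        assert curve.fraction_within(0, 100) == 1.0

    def test_cumulative_fraction_monotone_to_one(self):
        fm = FrequencyMatrix.from_counts({"G5AG7": 3, "G3AG9": 9, "G7AG6": 1})
        table = TPTable.from_mapping({"G5AG7": 17.0, "G3AG9": 11.0, "G7AG6": 17.0})
        curve = cumulative_tp_curve(fm, table)
        fracs = [p.cumulative_fraction for p in curve.points]
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(1.0)

    def test_missing_variants_excluded_with_warning(self):
        fm = FrequencyMatrix.from_counts({"G5AG7": 5, "G12AG12": 5})
        with pytest.warns(UserWarning, match="G12AG12"):
            curve = cumulative_tp_curve(fm, TPTable.from_mapping({"G5AG7": 17.0}))
        assert curve.excluded == ["G12AG12"]
        assert curve.known_hits == 5

    def test_empty_intersection_is_error(self):
        fm = FrequencyMatrix.from_counts({"G12AG12": 5})
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                cumulative_tp_curve(fm, TPTable.from_mapping({"G5AG7": 17.0}))


class TestSurveyReport:
    def test_report_structure_on_synthetic_matrix(self):
        fm = FrequencyMatrix.from_counts(
            {"G4AG7": 3, "G5AG7": 13, "G6AG7": 37, "G6AG8": 35, "G6AG9": 10, "G13": 2}
        )
        report = survey_report(fm, tp_table=TPTable.from_mapping({"G5AG7": 17.0}))
        assert report["total_hits"] == 100
        assert report["quadrants"]["pivot"] == [6, 7]
        assert report["position_spectrum"]["counts"] == {"-2": 13, "-1": 85}
        assert "skewness_row_totals_by_m" in report
        # population structure: nearly everything first-run-short / second-run-long
        frac = report["quadrants"]["inclusive_fractions"]["first_shorter_second_longer"]
        assert frac == 1.0
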