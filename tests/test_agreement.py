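"""Agreement statistics against hand derivations and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from eitbp.core import DataError
from eitbp.agreement import (
    ErrorGridDefinition,
    bland_altman_repeated,
    concordance_from_deltas,
    default_error_grid,
    density_bands,
    error_grid_classify,
    four_quadrant_concordance,
    icc_31_absolute,
    koo_category,
    summarize,
    trend_profile,
)
from eitbp.model import FoldResult


class TestIcc:
    def test_identical_series_give_one(self):
        assert icc_31_absolute([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_hand_derived_shifted_series(self):
        # two-way ANOVA by hand: MSR = 10/3, MSC = 2, MSE = 0 -> 10/13
        assert icc_31_absolute([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(
            10 / 13, abs=1e-12
        )

    def test_constant_series_rejected(self):
        with pytest.raises(DataError):
            icc_31_absolute([5, 5, 5], [5, 5, 5])

    def test_scale_sensitivity_of_absolute_agreement(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(100, 15, 50)
        est = ref + rng.normal(0, 3, 50)
        assert icc_31_absolute(ref, 2 * est) < icc_31_absolute(ref, est)

    def test_matches_pingouin_two_way_anova_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 50))
            a = rng.normal(100, 15, n)
            b = a + rng.normal(2, 8, n)
            df = pd.DataFrame(
                {
                    "targets": np.tile(np.arange(n), 2),
                    "raters": np.repeat(["ref", "est"], n),
                    "score": np.r_[a, b],
                }
            )
            oracle = (
                pg.intraclass_corr(df, "targets", "raters", "score")
                .query("Type=='ICC(A,1)'")["ICC"]
                .iloc[0]
            )
            assert icc_31_absolute(a, b) == pytest.approx(oracle, abs=1e-10)


class TestKoo:
    @pytest.mark.parametrize(
        "icc,category",
        [
            (0.49, "poor"),
            (0.530, "moderate"),
            (0.563, "moderate"),
            (0.521, "moderate"),
            (0.5, "moderate"),
            (0.75, "good"),
            (0.9, "excellent"),
            (0.95, "excellent"),
            (-0.2, "poor"),
        ],
    )
    def test_rubric(self, icc, category):
        assert koo_category(icc) == category

    def test_above_one_rejected(self):
        with pytest.raises(DataError):
            koo_category(1.2)


class TestBlandAltman:
    def test_constant_difference_zero_width(self):
        res = bland_altman_repeated([1, 2, 3], [4, 5, 6])
        assert res.bias == 3.0
        assert res.loa_lower == res.loa_upper == 3.0

    def test_single_subject_sample_sd(self):
        res = bland_altman_repeated([1, 2], [0, 3])  # differences -1, +1
        assert res.bias == 0.0
        assert res.loa_upper == pytest.approx(1.96 * np.sqrt(2), abs=1e-12)
        assert res.loa_lower == pytest.approx(-1.96 * np.sqrt(2), abs=1e-12)

    def test_one_beat_per_subject_equals_simple_variant(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(100, 10, 8)
        est = ref + rng.normal(2, 4, 8)
        rep = bland_altman_repeated(ref, est, subjects=np.arange(8))
        simple = bland_altman_repeated(ref, est)
        assert rep.bias == pytest.approx(simple.bias, abs=1e-12)
        assert rep.loa_upper == pytest.approx(simple.loa_upper, abs=1e-12)

    def test_loa_width_shrinks_with_within_subject_noise(self):
        rng = np.random.default_rng(4)
        subjects = np.repeat(np.arange(6), 40)
        offsets = np.repeat(rng.normal(0, 2, 6), 40)
        ref = rng.normal(100, 10, len(subjects))
        widths = []
        for noise_sd in (8.0, 1.0):
            est = ref + offsets + rng.normal(0, noise_sd, len(subjects))
            res = bland_altman_repeated(ref, est, subjects)
            widths.append(res.loa_upper - res.loa_lower)
        assert widths[1] < widths[0]

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            bland_altman_repeated([], [])


class TestFourQuadrant:
    def test_all_concordant_without_exclusion(self):
        rate, n, nx = concordance_from_deltas([5, -5, 8], [4, -6, 7], 0.0)
        assert (rate, n, nx) == (100.0, 3, 0)

    def test_one_discordant_pair(self):
        rate, n, nx = concordance_from_deltas([10, -10], [10, 10], 0.0)
        assert rate == 50.0

    def test_hand_enumerated_exclusion_zone(self):
        # max systolic change 50 -> threshold 5: (3,4) and (-2,-1) excluded;
        # (10,8) and (15,12) concordant, (-20,5) discordant -> 2/3
        dref = [10, -20, 15, 3, -2]
        dest = [8, 5, 12, 4, -1]
        rate, n_used, n_exc = concordance_from_deltas(dref, dest, 5.0)
        assert rate == pytest.approx(100 * 2 / 3)
        assert (n_used, n_exc) == (3, 2)

    def test_deltas_stay_within_subject(self):
        ref = np.array([100.0, 110.0, 10.0, 20.0])
        est = np.array([100.0, 111.0, 10.0, 21.0])
        subjects = np.array(["a", "a", "b", "b"])
        rate, n_used, _ = four_quadrant_concordance(
            ref, est, subjects, exclusion_frac=0.0
        )
        # only 2 within-subject pairs, not 3 (no cross-subject -90 jump)
        assert n_used == 2
        assert rate == 100.0

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_to_positive_rescaling(self, scale):
        dref = np.array([10.0, -20.0, 15.0, 3.0, -2.0])
        dest = np.array([8.0, 5.0, 12.0, 4.0, -1.0])
        base = concordance_from_deltas(dref, dest, 5.0)
        scaled = concordance_from_deltas(scale * dref, scale * dest, scale * 5.0)
        assert base == scaled

    def test_all_excluded_rejected(self):
        with pytest.raises(DataError):
            concordance_from_deltas([1, -1], [0.5, -0.5], 10.0)


def unit_square_grid() -> ErrorGridDefinition:
    return ErrorGridDefinition(
        target="SAP",
        zones=[
            ("A", Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])),
            ("E", Polygon([(-10, -10), (10, -10), (10, 10), (-10, 10)])),
        ],
        domain=(0.0, 1.0),
    )


class TestErrorGrid:
    def test_identity_line_is_zone_a(self):
        grid = default_error_grid("SAP")
        ref = np.linspace(40, 200, 30)
        labels, hist = error_grid_classify(ref, ref, grid)
        assert np.all(labels == "A")
        assert hist["A"] == 100.0

    def test_boundary_point_contained(self):
        labels, _ = error_grid_classify([1.0], [0.5], unit_square_grid())
        assert labels[0] == "A"

    def test_gross_deviation_is_at_least_zone_c(self):
        grid = default_error_grid("SAP")
        labels, _ = error_grid_classify([100.0], [180.0], grid)
        assert labels[0] in ("C", "D", "E")

    def test_histogram_sums_to_100_and_is_order_invariant(self):
        grid = default_error_grid("MAP")
        rng = np.random.default_rng(5)
        ref = rng.uniform(40, 150, 200)
        est = ref + rng.normal(0, 15, 200)
        _, hist = error_grid_classify(ref, est, grid)
        assert sum(hist.values()) == pytest.approx(100.0, abs=0.01)
        perm = rng.permutation(200)
        _, hist2 = error_grid_classify(ref[perm], est[perm], grid)
        assert hist == hist2

    def test_point_outside_all_zones_rejected(self):
        with pytest.raises(DataError, match="outside all"):
            error_grid_classify([50.0], [50.0], unit_square_grid())

    def test_no_grid_for_dap(self):
        with pytest.raises(DataError):
            default_error_grid("DAP")


class TestTrendProfile:
    def test_sorted_with_segment_markers(self):
        t = np.array([3.0, 1.0, 2.0])
        df, bounds = trend_profile([100, 90, 95], [99, 91, 96], t, segment_bounds=[1.5])
        assert list(df["time"]) == [1.0, 2.0, 3.0]
        assert list(bounds) == [1.5]

    def test_empty_input_empty_profile(self):
        df, bounds = trend_profile([], [], [])
        assert len(df) == 0


def perfect_folds(n_subjects=3, n=40):
    rng = np.random.default_rng(6)
    folds = []
    for s in range(n_subjects):
        ref = np.column_stack(
            [rng.uniform(90, 150, n), rng.uniform(70, 110, n), rng.uniform(50, 90, n)]
        )
        folds.append(
            FoldResult(
                test_subject_id=f"s{s}",
                predictions_mmHg=ref.copy(),
                references_mmHg=ref,
                t_start=np.arange(n, dtype=float),
                val_loss=0.0,
                config=None,
            )
        )
    return folds


class TestSummarize:
    def test_perfect_predictions_degenerate_report(self):
        reports = summarize(perfect_folds())
        for target in ("SAP", "MAP", "DAP"):
            rep = reports[target]
            assert rep.icc == pytest.approx(1.0)
            assert rep.bias_mmHg == 0.0
            assert rep.loa_lower_mmHg == rep.loa_upper_mmHg == 0.0
            assert rep.concordance_pct == 100.0
        assert reports["SAP"].zone_fractions_pct["A"] == 100.0
        assert reports["DAP"].zone_fractions_pct is None

    def test_zone_fractions_sum_to_100(self):
        rng = np.random.default_rng(7)
        folds = perfect_folds()
        for f in folds:
            f.predictions_mmHg = f.references_mmHg + rng.normal(
                0, 20, f.references_mmHg.shape
            )
        reports = summarize(folds)
        for target in ("SAP", "MAP"):
            assert sum(reports[target].zone_fractions_pct.values()) == pytest.approx(
                100.0, abs=0.01
            )

    def test_report_files_written(self, tmp_path):
        summarize(perfect_folds(), out_dir=tmp_path)
        assert (tmp_path / "agreement_report.json").exists()
        assert (tmp_path / "agreement_report.csv").exists()
        assert (tmp_path / "scatter_density.png").exists()

    def test_empty_folds_rejected(self):
        with pytest.raises(DataError):
            summarize([])


class TestDensityBands:
    def test_bands_range_and_peak(self):
        rng = np.random.default_rng(8)
        x = np.r_[rng.normal(0, 0.1, 500), rng.uniform(-3, 3, 50)]
        y = np.r_[rng.normal(0, 0.1, 500), rng.uniform(-3, 3, 50)]
        bands = density_bands(x, y)
        assert bands.min() >= 1 and bands.max() == 5
        # densest band sits in the clustered center
        assert np.median(np.abs(x[bands == 5])) < np.median(np.abs(x[bands == 1]))
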