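"""qPCR normalization, effect thresholds, quadrants, pathway positioning,
R-squared, and kinetics comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exitscreen import (
    PathwayPosition,
    assign_point_of_action,
    classify_quadrant,
    coefficient_of_determination,
    compare_kinetics,
    normalize_qpcr,
    rescale_to_max,
    threshold_call,
)
from exitscreen.errors import (
    DegenerateControlsError,
    DegeneratePanelError,
    GridError,
    InvalidReferenceError,
    UndefinedRSquaredError,
)
from exitscreen.readouts import recover_points_of_action, simulate_biochem_panel


class TestNormalizeQpcr:
    def test_mean_of_reference_genes(self):
        assert normalize_qpcr(6.0, (2.0, 3.0, 4.0)) == 2.0

    def test_equal_references_divide_through(self):
        assert normalize_qpcr(5.0, (2.5, 2.5, 2.5)) == 2.0

    def test_matches_direct_formula_on_random_panels(self, rng):
        for _ in range(100):
            raw = rng.uniform(0.1, 10)
            refs = rng.uniform(0.1, 5, 3)
            assert normalize_qpcr(raw, refs) == pytest.approx(raw / refs.mean())

    def test_scale_equivariance(self, rng):
        raw, refs = 3.7, np.array([1.2, 0.8, 2.0])
        for c in (0.1, 1.0, 57.0):
            assert normalize_qpcr(c * raw, c * refs) == pytest.approx(
                normalize_qpcr(raw, refs)
            )

    def test_geometric_mean_option(self):
        from scipy.stats import gmean

        refs = (1.0, 2.0, 4.0)
        assert normalize_qpcr(4.0, refs, method="geometric") == pytest.approx(
            4.0 / gmean(refs)
        )

    def test_nonpositive_reference_raises(self):
        with pytest.raises(InvalidReferenceError):
            normalize_qpcr(1.0, (1.0, 0.0, 2.0))


class TestRescaleToMax:
    def test_examples(self):
        np.testing.assert_allclose(rescale_to_max([2.0, 4.0]), [50.0, 100.0])
        np.testing.assert_allclose(rescale_to_max([7.0]), [100.0])

    def test_max_is_exactly_100(self, rng):
        for _ in range(50):
            values = rng.uniform(0.01, 20, int(rng.integers(1, 30)))
            assert rescale_to_max(values).max() == 100.0

    def test_all_zero_panel_raises(self):
        with pytest.raises(DegeneratePanelError):
            rescale_to_max([0.0, 0.0])


class TestThresholdCall:
    def test_above_direction(self):
        controls = [40.0, 50.0, 60.0]  # mean 50, sd 10
        flags = threshold_call([71.0, 69.0, 70.0], controls, k=2, direction="above")
        assert list(flags) == [True, False, True]  # threshold inclusive at 70

    def test_below_direction(self):
        controls = [40.0, 50.0, 60.0]
        flags = threshold_call([29.0, 31.0, 30.0], controls, k=2, direction="below")
        assert list(flags) == [True, False, True]

    def test_matches_brute_force_on_random_panels(self, rng):
        for _ in range(100):
            controls = rng.normal(50, 5, 8)
            values = rng.normal(50, 15, 20)
            k = float(rng.uniform(0.5, 3))
            cut = controls.mean() + k * controls.std(ddof=1)
            np.testing.assert_array_equal(
                threshold_call(values, controls, k, "above"), values >= cut
            )

    def test_degenerate_controls_raise(self):
        with pytest.raises(DegenerateControlsError):
            threshold_call([1.0], [5.0, 5.0], 2)
        with pytest.raises(DegenerateControlsError):
            threshold_call([1.0], [5.0], 2)


class TestQuadrants:
    @pytest.mark.parametrize(
        "rex1_up, second, quadrant",
        [(True, True, 1), (True, False, 2), (False, True, 3), (False, False, 4)],
    )
    def test_truth_table(self, rex1_up, second, quadrant):
        assert classify_quadrant(rex1_up, second) == quadrant
        assert classify_quadrant(rex1_up, second, "nanog_up") == quadrant

    def test_every_gene_lands_in_exactly_one_quadrant(self, rng):
        counts = [0] * 4
        for _ in range(100):
            q = classify_quadrant(bool(rng.integers(2)), bool(rng.integers(2)))
            counts[q - 1] += 1
        assert sum(counts) == 100


class TestPointOfAction:
    @pytest.mark.parametrize(
        "erk_reduced, ras_reduced, position",
        [
            (True, True, PathwayPosition.UPSTREAM_OF_RAS),
            (True, False, PathwayPosition.BETWEEN_RAS_AND_ERK),
            (False, None, PathwayPosition.DOWNSTREAM_OF_ERK),
        ],
    )
    def test_truth_table(self, erk_reduced, ras_reduced, position):
        assert assign_point_of_action("g", erk_reduced, ras_reduced).position is position

    def test_ras_value_for_downstream_gene_warns_and_is_ignored(self):
        with pytest.warns(UserWarning, match="ignored"):
            p = assign_point_of_action("g", False, True)
        assert p.position is PathwayPosition.DOWNSTREAM_OF_ERK

    def test_missing_ras_for_upstream_gene_raises(self):
        with pytest.raises(ValueError):
            assign_point_of_action("g", True, None)

    def test_recovery_exact_for_strongly_planted_panels(self):
        rng = np.random.default_rng(42)
        planted = {
            f"g{i}": pos
            for i, pos in enumerate(
                [p for p in PathwayPosition for _ in range(10)]
            )
        }
        panel = simulate_biochem_panel(planted, rng, effect_sds=6.0)
        recovered = recover_points_of_action(panel)
        assert {g: p.position for g, p in recovered.items()} == planted


class TestRSquared:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert coefficient_of_determination(x, 2 * x) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert coefficient_of_determination(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sums_of_squares_oracle(self, rng):
        x = rng.normal(0, 1, 50)
        y = 0.7 * x + rng.normal(0, 0.5, 50)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        sxx = np.sum((x - x.mean()) ** 2)
        syy = np.sum((y - y.mean()) ** 2)
        assert coefficient_of_determination(x, y) == pytest.approx(
            sxy**2 / (sxx * syy)
        )

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=100, derandomize=True)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.9, 2.2, 4.0, 5.5])
        y = np.array([1.0, 0.4, 2.5, 3.1, 2.9])
        assert coefficient_of_determination(a * x + b, y) == pytest.approx(
            coefficient_of_determination(x, y)
        )

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedRSquaredError):
            coefficient_of_determination([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareKinetics:
    times = [0.0, 10.0, 20.0, 30.0, 60.0]

    def test_identical_series_not_flagged(self):
        c = [5.0, 100.0, 60.0, 30.0, 10.0]
        call = compare_kinetics(self.times, c, list(c))
        assert not call.delayed and not call.reduced
        assert not call.premature and not call.elevated

    def test_shifted_and_halved_series_delayed_and_reduced(self):
        c = [5.0, 100.0, 60.0, 30.0, 10.0]
        kd = [2.5, 2.5, 50.0, 30.0, 15.0]
        call = compare_kinetics(self.times, c, kd)
        assert call.delayed and call.reduced
        assert call.peak_time_control == 10.0 and call.peak_time_kd == 20.0

    def test_dusp_depletion_phenotype_annotated_not_flagged(self):
        c = [5.0, 50.0, 100.0, 30.0, 10.0]
        kd = [5.0, 130.0, 90.0, 20.0, 10.0]
        call = compare_kinetics(self.times, c, kd)
        assert not call.delayed and not call.reduced
        assert call.premature and call.elevated

    def test_peaks_match_brute_force_scan(self, rng):
        for _ in range(100):
            c = rng.uniform(0, 100, 5)
            k = rng.uniform(0, 100, 5)
            call = compare_kinetics(self.times, c, k)
            assert call.peak_amp_control == max(c)
            assert call.peak_time_kd == self.times[int(np.argmax(k))]

    def test_mismatched_grid_raises(self):
        with pytest.raises(GridError):
            compare_kinetics(
                self.times,
                [1, 2, 3, 4, 5],
                [1, 2, 3, 4, 5],
                times_knockdown=[0, 1, 2, 3, 4],
            )
        with pytest.raises(GridError):
            compare_kinetics([0, 1], [1, 2], [1, 2])
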