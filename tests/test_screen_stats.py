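"""Plate statistics, SD-unit scoring, and the replicate decision cascades."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exitscreen import (
    HitStatus,
    HitThresholds,
    WellSummary,
    call_1i,
    call_counter,
    call_primary,
    call_validation,
    combine_validation,
    plate_statistics,
    score_well,
)
from exitscreen.errors import InsufficientReferenceError


def _summary(ratio, well="w", defective=False):
    return WellSummary(
        well=well,
        n_total=1000,
        n_gated=1000,
        n_high=0,
        n_low=0,
        ratio_high_low=ratio,
        log2_ratio=float(np.log2(ratio)),
        defective=defective,
    )


class TestPlateStatistics:
    def test_mean_and_sample_sd(self):
        stats = plate_statistics([_summary(r) for r in (1.0, 2.0, 3.0)])
        assert stats.mean == 2.0 and stats.sd == 1.0 and stats.n == 3

    def test_defective_wells_excluded(self):
        summaries = [_summary(float(r)) for r in range(1, 11)]
        summaries[3] = _summary(100.0, defective=True)
        stats = plate_statistics(summaries)
        assert stats.n == 9
        kept = [r for i, r in enumerate(range(1, 11)) if i != 3]
        assert stats.mean == pytest.approx(np.mean(kept))

    def test_two_pass_oracle_on_simulated_plate(self):
        rng = np.random.default_rng(2)
        ratios = rng.lognormal(0, 0.4, 86)
        stats = plate_statistics([_summary(r) for r in ratios])
        assert stats.mean == pytest.approx(ratios.mean())
        assert stats.sd == pytest.approx(ratios.std(ddof=1))

    def test_fewer_than_three_reference_wells_raises(self):
        with pytest.raises(InsufficientReferenceError):
            plate_statistics([_summary(1.0), _summary(2.0)])

    def test_log2_scale_uses_log_ratio(self):
        stats = plate_statistics(
            [_summary(r) for r in (1.0, 2.0, 4.0)], scale="log2_ratio"
        )
        assert stats.mean == pytest.approx(1.0)  # mean of log2 {0,1,2}


class TestScoreWell:
    def test_score_of_mean_is_zero_and_sd_units(self):
        stats = plate_statistics([_summary(r) for r in (1.0, 2.0, 3.0)])
        assert score_well(_summary(2.0), stats) == 0.0
        assert score_well(_summary(4.0), stats) == 2.0

    def test_matches_oracle_arithmetic_on_random_wells(self):
        rng = np.random.default_rng(3)
        ratios = rng.lognormal(0, 0.5, 500)
        stats = plate_statistics([_summary(r) for r in ratios])
        for r in ratios[:50]:
            assert score_well(_summary(r), stats) == pytest.approx(
                (r - ratios.mean()) / ratios.std(ddof=1)
            )

    def test_scores_standardize_reference_population(self):
        rng = np.random.default_rng(4)
        ratios = rng.lognormal(0, 0.5, 96)
        stats = plate_statistics([_summary(r) for r in ratios])
        z = np.array([score_well(_summary(r), stats) for r in ratios])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)


def literal_primary_status(z1, z2):
    """Independent transcription of the published replicate rules: a hit needs
    an average of 2 SD with both plates at 1.5 SD, or an average above 2.5 SD
    with one plate at 1.5 SD, or an average above 1.9 SD with both plates at
    1.9 SD; evaluated in both directions."""
    for status, sign in (("positive_up", 1.0), ("positive_down", -1.0)):
        a, b = sign * z1, sign * z2
        avg = (a + b) / 2
        fired = (
            (avg >= 2.0 and a >= 1.5 and b >= 1.5)
            or (avg >= 2.5 and (a >= 1.5 or b >= 1.5))
            or (avg >= 1.9 and a >= 1.9 and b >= 1.9)
        )
        if fired:
            return status
    return "negative"


class TestCallPrimary:
    @pytest.mark.parametrize(
        "z1, z2, status, rule",
        [
            (1.9, 1.9, HitStatus.POSITIVE_UP, "R4"),
            (3.6, 1.6, HitStatus.POSITIVE_UP, "R3"),
            (2.6, 1.4, HitStatus.NEGATIVE, None),
            (-2.2, -2.4, HitStatus.POSITIVE_DOWN, "R2"),
            (2.5, 1.5, HitStatus.POSITIVE_UP, "R2"),
            (0.0, 0.0, HitStatus.NEGATIVE, None),
        ],
    )
    def test_cascade_examples(self, z1, z2, status, rule):
        d = call_primary(z1, z2)
        assert d.status is status and d.rule_fired == rule

    def test_single_valid_replicate_uses_lone_rule(self):
        assert call_primary(2.1, None).rule_fired == "R1"
        assert call_primary(None, -2.1).status is HitStatus.POSITIVE_DOWN
        assert call_primary(1.9, None).status is HitStatus.NEGATIVE

    def test_both_defective_is_no_call(self):
        d = call_primary(None, None)
        assert d.status is HitStatus.NO_CALL and d.rule_fired is None

    def test_agrees_with_literal_rules_on_grid(self):
        grid = np.round(np.arange(-3.0, 3.01, 0.1), 10)
        for z1 in grid:
            for z2 in grid:
                assert call_primary(z1, z2).status.value == literal_primary_status(
                    z1, z2
                ), (z1, z2)

    def test_status_equals_or_of_rules(self):
        # rule precedence must not change the decision, only the label
        rng = np.random.default_rng(0)
        t = HitThresholds()
        for _ in range(2000):
            z1, z2 = rng.uniform(-4, 4, 2)
            d = call_primary(z1, z2, t)
            any_up = literal_primary_status(z1, z2) == "positive_up"
            assert (d.status is HitStatus.POSITIVE_UP) == any_up

    @given(
        z1=st.floats(-4, 4),
        z2=st.floats(-4, 4),
        bump=st.floats(0, 2),
    )
    @settings(max_examples=300, derandomize=True)
    def test_raising_a_replicate_never_loses_an_up_hit(self, z1, z2, bump):
        before = call_primary(z1, z2)
        if before.status is HitStatus.POSITIVE_UP:
            after = call_primary(z1 + bump, z2)
            assert after.status is HitStatus.POSITIVE_UP


class TestValidationRules:
    @pytest.mark.parametrize(
        "z1, z2, positive",
        [((1.5), 1.1, True), (1.3, 1.1, False), (1.25, 1.25, True)],
    )
    def test_average_threshold(self, z1, z2, positive):
        d = call_validation(z1, z2)
        assert (d.status is HitStatus.POSITIVE_UP) == positive
        assert d.average == pytest.approx((z1 + z2) / 2)

    def test_matches_threshold_oracle_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            z1, z2 = rng.uniform(-2, 3, 2)
            d = call_validation(z1, z2)
            assert (d.status is HitStatus.POSITIVE_UP) == ((z1 + z2) / 2 >= 1.25)

    def test_combine_both_positive_is_high_confidence(self):
        r = call_validation(1.5, 1.3, gene_id="g")
        o = call_validation(1.4, 1.2, gene_id="g")
        c = combine_validation(r, o)
        assert c.high_confidence and c.rule_fired == "V1"

    def test_rescue_rule_fires_across_screens(self):
        # scored below the per-screen cut in both screens, but 0.9 and 1.1
        # average SD units satisfies the 0.8/1.0 cross-screen rescue
        r = call_validation(0.9, 0.9, gene_id="g")
        o = call_validation(1.1, 1.1, gene_id="g")
        assert r.status is HitStatus.NEGATIVE
        c = combine_validation(r, o)
        assert c.high_confidence and c.rule_fired == "V2"
        # and in the swapped assignment
        assert combine_validation(o, r).high_confidence

    def test_rescue_needs_one_screen_at_one_sd(self):
        r = call_validation(0.9, 0.9)
        o = call_validation(0.9, 0.9)
        assert not combine_validation(r, o).high_confidence

    def test_no_call_screen_marks_incomplete(self):
        r = call_validation(None, None)
        o = call_validation(2.0, 2.0)
        c = combine_validation(r, o)
        assert c.incomplete and not c.high_confidence


class TestCounterAndOneI:
    def test_counter_inclusive_threshold(self):
        assert call_counter(1.25, 1.25) is True
        assert call_counter(1.4, 1.2) is True
        assert call_counter(1.2, 1.2) is False

    def test_counter_no_call_warns_and_passes_gene(self):
        with pytest.warns(UserWarning, match="not callable"):
            assert call_counter(None, None) is False

    @pytest.mark.parametrize("avg, positive", [(1.6, True), (1.4, False), (1.5, True)])
    def test_one_i_threshold(self, avg, positive):
        d = call_1i(avg, avg)
        assert (d.status is HitStatus.POSITIVE_UP) == positive
        assert (d.rule_fired == "I1") == positive
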