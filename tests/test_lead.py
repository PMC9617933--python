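import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbsteer.lead import (
    DIRECTIONAL,
    RING,
    DomainError,
    ExplorationPoint,
    LeadGeometry,
    SafetyError,
    StimSetting,
    directional_point_to_setting,
    fit_exploration_point,
    format_configuration,
    largest_remainder,
    parse_configuration,
    ring_point_to_setting,
    setting_from_percents,
    setting_to_vector,
    steering_angle_linear,
    vertical_centroid,
)


class TestGeometry:
    def test_layout(self, geometry):
        assert geometry.n_electrodes == 8
        assert geometry.electrode_levels == (0, 1, 1, 1, 2, 2, 2, 3)
        assert geometry.level_electrodes(1) == (1, 2, 3)
        assert geometry.electrode_angle(0) is None
        assert geometry.electrode_angle(1) == 0.0
        assert geometry.electrode_angle(6) == 240.0

    def test_bad_segment_spacing_rejected(self):
        with pytest.raises(ValueError):
            LeadGeometry(segment_angles=(0.0, 90.0, 240.0))


class TestRingMapping:
    def test_interpolated_level_split(self):
        s = ring_point_to_setting(ExplorationPoint(RING, 0.3, 5.1), a_max=5.5)
        assert s.percents[:8] == (-70, -10, -10, -10, 0, 0, 0, 0)
        assert s.percents[8] == 100

    def test_pure_bottom_ring(self):
        s = ring_point_to_setting(ExplorationPoint(RING, 0.0, 3.0))
        assert s.percents[:8] == (-100, 0, 0, 0, 0, 0, 0, 0)

    def test_equal_thirds_rounding(self):
        s = ring_point_to_setting(ExplorationPoint(RING, 2.0, 2.3))
        assert s.percents[:8] == (0, 0, 0, 0, -34, -33, -33, 0)

    def test_out_of_bounds_position(self):
        with pytest.raises(DomainError):
            ExplorationPoint(RING, 3.2, 1.0)

    def test_amplitude_limit(self):
        with pytest.raises(SafetyError):
            ring_point_to_setting(ExplorationPoint(RING, 1.0, 6.0), a_max=5.0)

    def test_zero_amplitude_is_all_zero(self):
        s = ring_point_to_setting(ExplorationPoint(RING, 1.0, 0.0))
        assert all(f == 0.0 for f in s.fractions)


class TestDirectionalMapping:
    def test_on_segment_single_level(self):
        s = directional_point_to_setting(ExplorationPoint(DIRECTIONAL, 0.0, 2.0), 1.0)
        assert s.percents[:8] == (0, -100, 0, 0, 0, 0, 0, 0)

    def test_equal_vertical_and_angular_split(self):
        s = directional_point_to_setting(ExplorationPoint(DIRECTIONAL, 60.0, 2.0), 1.5)
        assert s.percents[:8] == (0, -25, -25, 0, -25, -25, 0, 0)

    def test_ring_level_share_undirected(self):
        s = directional_point_to_setting(ExplorationPoint(DIRECTIONAL, 0.0, 2.0), 0.6)
        assert s.percents[:8] == (-40, -60, 0, 0, 0, 0, 0, 0)

    def test_angle_normalized_modulo_360(self):
        p = ExplorationPoint(DIRECTIONAL, 480.0, 2.0)
        assert p.coord1 == 120.0

    def test_bad_base_vertical(self):
        with pytest.raises(DomainError):
            directional_point_to_setting(
                ExplorationPoint(DIRECTIONAL, 0.0, 2.0), 3.5
            )


class TestVector:
    def test_monopolar_vector(self):
        s = ring_point_to_setting(ExplorationPoint(RING, 0.0, 3.0))
        assert tuple(setting_to_vector(s)) == (-1, 0, 0, 0, 0, 0, 0, 0, 1)

    def test_split_vector(self):
        s = ring_point_to_setting(ExplorationPoint(RING, 0.3, 4.0))
        np.testing.assert_allclose(
            setting_to_vector(s), [-0.7, -0.1, -0.1, -0.1, 0, 0, 0, 0, 1.0]
        )

    def test_zero_amplitude_vector(self):
        s = ring_point_to_setting(ExplorationPoint(RING, 1.0, 0.0))
        assert not setting_to_vector(s).any()


class TestLargestRemainder:
    def test_ties_to_lowest_index(self):
        assert list(largest_remainder(np.array([1 / 3] * 3))) == [34, 33, 33]

    def test_exact_shares_unchanged(self):
        assert list(largest_remainder(np.array([0.7, 0.1, 0.1, 0.1]))) == [
            70, 10, 10, 10,
        ]

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8).map(
            lambda xs: np.array(xs) / np.sum(xs)
        )
    )
    def test_always_sums_to_100(self, shares):
        assert largest_remainder(shares).sum() == 100


class TestRoundTrip:
    @given(
        p=st.integers(0, 30).map(lambda i: i / 10),
        amp=st.integers(1, 50).map(lambda i: i / 10),
    )
    @settings(max_examples=150)
    def test_ring_percent_sum_and_centroid(self, p, amp):
        s = ring_point_to_setting(ExplorationPoint(RING, p, amp))
        assert sum(pct for pct in s.percents[:8]) == -100
        assert abs(vertical_centroid(s) - p) <= 0.02

    @given(
        theta=st.integers(0, 359),
        # Keep the segmented levels' share large enough that integer-percent
        # rounding cannot rotate the recovered angle by more than ~3 deg.
        base=st.integers(4, 26).map(lambda i: i / 10),
        amp=st.integers(1, 50).map(lambda i: i / 10),
    )
    @settings(max_examples=150)
    def test_directional_round_trip(self, theta, base, amp):
        s = directional_point_to_setting(
            ExplorationPoint(DIRECTIONAL, float(theta), amp), base
        )
        assert sum(pct for pct in s.percents[:8]) == -100
        assert abs(vertical_centroid(s) - base) <= 0.02
        if any(f < 0 for f in s.fractions[1:7]):
            recovered = steering_angle_linear(s)
            err = abs(recovered - theta) % 360.0
            assert min(err, 360.0 - err) <= 3.0

    def test_monotone_steering_between_levels(self):
        prev = None
        for p in np.arange(1.0, 2.01, 0.1):
            s = ring_point_to_setting(ExplorationPoint(RING, float(p), 2.0))
            upper = -sum(s.fractions[4:7])
            if prev is not None:
                assert upper > prev
            prev = upper


class TestConfigurationDialect:
    def test_parse_grouped_labels(self):
        parsed = parse_configuration("E1: −70%, E2, E3, E4: −10%")
        assert parsed == {"E1": -70, "E2": -10, "E3": -10, "E4": -10}

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_configuration("E9: -100%")
        with pytest.raises(ValueError):
            parse_configuration("E1, E2")

    def test_format_parse_round_trip(self):
        text = "E2: -8%, E4: -22%, E5: -18%, E7: -52%"
        setting = setting_from_percents(parse_configuration(text), amplitude=2.9)
        assert parse_configuration(format_configuration(setting)) == parse_configuration(text)

    def test_case_balances_monopolar(self):
        s = setting_from_percents({"E1": -100}, amplitude=3.0)
        assert s.fractions[8] == 1.0


class TestStimSettingInvariants:
    def test_cathode_sum_enforced(self):
        with pytest.raises(ValueError):
            StimSetting(amplitude=2.0, fractions=(-0.5, 0, 0, 0, 0, 0, 0, 0, 1.0))

    def test_fraction_magnitude_enforced(self):
        with pytest.raises(ValueError):
            StimSetting(amplitude=2.0, fractions=(-1.5, 0.5, 0, 0, 0, 0, 0, 0, 1.0))


class TestFitExplorationPoint:
    def test_exact_ring_row(self):
        s = setting_from_percents(
            {"E1": -70, "E2": -10, "E3": -10, "E4": -10}, amplitude=3.7
        )
        point, residual = fit_exploration_point(s, RING)
        assert residual == 0
        assert math.isclose(point.coord1, 0.3, abs_tol=1e-6)

    def test_two_level_directional_row(self):
        s = setting_from_percents(
            {"E2": -8, "E4": -22, "E5": -18, "E7": -52}, amplitude=2.9
        )
        point, residual = fit_exploration_point(s, DIRECTIONAL)
        assert residual <= 1
        assert 260.0 <= point.coord1 <= 280.0
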