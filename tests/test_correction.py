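"""Closed-form bias model: worked examples and algebraic invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kymoflow.correction import (
    BidirectionalPair,
    Direction,
    InconsistentObservationError,
    RBCState,
    ScanParameters,
    SingularityError,
    apparent_size,
    apparent_velocity,
    apparent_velocity_from_angle,
    apparent_velocity_from_geometry,
    bidirectional_residual,
    real_size,
    real_velocity,
    relative_error,
    time_to_scan_rbc,
    vaa_from_var,
)

A = Direction.ANTEROGRADE
R = Direction.RETROGRADE


def scan(v_scan: float, direction: Direction, t_line: float = 10.0) -> ScanParameters:
    return ScanParameters(v_scan, direction, t_line=t_line, x_pixel=0.2, n_pixels=2)


# strategy for physically meaningful operating points, away from the pole
valid_point = st.tuples(
    st.floats(1.0, 100.0),  # v_scan
    st.floats(0.001, 0.98),  # v_real as fraction of v_scan
    st.sampled_from([A, R]),
)


class TestTransitTimeAndSize:
    @pytest.mark.parametrize(
        "d_real, v_scan, v_real, direction, expected_ms",
        [
            (6.0, 10.0, 0.0, A, 0.6),  # stationary cell: transit = size / scan speed
            (6.0, 10.0, 0.0, R, 0.6),
            (6.0, 10.0, 5.0, A, 1.2),  # closing speed 5 mm/s
            (6.0, 10.0, 5.0, R, 0.4),  # closing speed 15 mm/s
        ],
    )
    def test_transit_time(self, d_real, v_scan, v_real, direction, expected_ms):
        t = time_to_scan_rbc(RBCState(d_real, v_real), scan(v_scan, direction))
        assert t == pytest.approx(expected_ms)

    @pytest.mark.parametrize(
        "d_real, v_scan, v_real, direction, expected_um",
        [
            (6.0, 10.0, 0.0, A, 6.0),  # still cell casts a true-size shadow
            (6.0, 37.0, 0.0, R, 6.0),
            (6.0, 10.0, 5.0, A, 12.0),  # stretched while being overtaken
            (6.0, 10.0, 5.0, R, 4.0),  # compressed on head-on passage
        ],
    )
    def test_apparent_size(self, d_real, v_scan, v_real, direction, expected_um):
        d = apparent_size(RBCState(d_real, v_real), scan(v_scan, direction))
        assert d == pytest.approx(expected_um)

    @pytest.mark.parametrize(
        "d_app, v_real, direction, expected",
        [(12.0, 5.0, A, 6.0), (4.0, 5.0, R, 6.0), (7.0, 0.0, A, 7.0)],
    )
    def test_real_size_inverts(self, d_app, v_real, direction, expected):
        assert real_size(d_app, v_real, scan(10.0, direction)) == pytest.approx(expected)

    def test_anterograde_pole_raises(self):
        with pytest.raises(SingularityError):
            time_to_scan_rbc(RBCState(6.0, 10.0), scan(10.0, A))
        with pytest.raises(SingularityError):
            apparent_size(RBCState(6.0, 12.0), scan(10.0, A))
        # retrograde has no pole
        assert apparent_size(RBCState(6.0, 12.0), scan(10.0, R)) == pytest.approx(
            6.0 * 10.0 / 22.0
        )

    @settings(max_examples=200, derandomize=True)
    @given(valid_point, st.floats(0.5, 12.0))
    def test_size_round_trip_and_ordering(self, point, d_real):
        v_scan, frac, direction = point
        v_real = frac * v_scan
        s = scan(v_scan, direction)
        d_app = apparent_size(RBCState(d_real, v_real), s)
        if direction is A:
            assert d_app > d_real
        else:
            assert d_app < d_real
        assert real_size(d_app, v_real, s) == pytest.approx(d_real, rel=1e-9)


class TestVelocityModel:
    def test_camera_model(self):
        s = scan(10.0, A, t_line=1.0)
        assert apparent_velocity_from_geometry(2.0, s) == pytest.approx(2.0)
        assert apparent_velocity_from_geometry(0.0, s) == 0.0

    def test_angle_form_matches_unit_grid(self):
        # 45-degree stripe on a grid scaled to 1 um per 1 ms is 1 mm/s
        s = ScanParameters(10.0, A, t_line=1.0, x_pixel=1.0, n_pixels=2)
        assert apparent_velocity_from_angle(math.pi / 4, s) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "v_real, v_scan, direction, expected",
        [(5.0, 10.0, A, 10.0), (5.0, 10.0, R, 10.0 / 3.0), (0.0, 10.0, A, 0.0), (0.0, 10.0, R, 0.0)],
    )
    def test_forward_model(self, v_real, v_scan, direction, expected):
        assert apparent_velocity(v_real, scan(v_scan, direction)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "v_app, v_scan, direction, expected",
        [(10.0, 10.0, A, 5.0), (10.0 / 3.0, 10.0, R, 5.0)],
    )
    def test_correction(self, v_app, v_scan, direction, expected):
        assert real_velocity(v_app, scan(v_scan, direction)) == pytest.approx(expected)

    def test_slow_flow_limit(self):
        # when v_real << v_scan the bias vanishes
        s = scan(1000.0, A)
        assert apparent_velocity(0.1, s) == pytest.approx(0.1, rel=1e-3)
        assert relative_error(0.1, s) == pytest.approx(0.0, abs=1e-3)

    def test_retrograde_apparent_at_scan_speed_is_inconsistent(self):
        with pytest.raises(InconsistentObservationError):
            real_velocity(10.0, scan(10.0, R))
        with pytest.raises(InconsistentObservationError):
            real_velocity(12.0, scan(10.0, R))

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(1.0, 100.0), st.floats(1e-4, 0.99), st.sampled_from([A, R]))
    def test_velocity_round_trip(self, v_scan, frac, direction):
        # retrograde has no pole, so probe far beyond the scan speed there
        v_real = frac * v_scan if direction is A else frac * 100.0 * v_scan
        s = scan(v_scan, direction)
        v_app = apparent_velocity(v_real, s)
        assert real_velocity(v_app, s) == pytest.approx(v_real, rel=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(valid_point)
    def test_apparent_brackets_real(self, point):
        v_scan, frac, _ = point
        v_real = frac * v_scan
        v_aa = apparent_velocity(v_real, scan(v_scan, A))
        v_ar = apparent_velocity(v_real, scan(v_scan, R))
        assert v_ar < v_real < v_aa

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(2.0, 50.0), st.floats(0.01, 0.9), st.floats(1.01, 1.08))
    def test_monotonicity_in_v_real(self, v_scan, frac, bump):
        v1 = frac * v_scan
        v2 = min(bump * v1, 0.98 * v_scan)
        if v2 <= v1:
            return
        assert apparent_velocity(v2, scan(v_scan, A)) > apparent_velocity(v1, scan(v_scan, A))
        assert apparent_size(RBCState(6, v2), scan(v_scan, A)) > apparent_size(
            RBCState(6, v1), scan(v_scan, A)
        )
        assert apparent_size(RBCState(6, v2), scan(v_scan, R)) < apparent_size(
            RBCState(6, v1), scan(v_scan, R)
        )


class TestBidirectionalIdentity:
    @pytest.mark.parametrize(
        "v_aa, v_ar, v_scan, expected",
        [
            (10.0, 10.0 / 3.0, 10.0, 0.0),
            (20.0 / 19.0, 20.0 / 21.0, 20.0, 0.0),  # v_real = 1 at v_scan = 20
            (5.0, 5.0, 10.0, -0.2),  # equal apparents are inconsistent
        ],
    )
    def test_residual(self, v_aa, v_ar, v_scan, expected):
        pair = BidirectionalPair(v_aa=v_aa, v_ar=v_ar, v_scan=v_scan)
        assert bidirectional_residual(pair) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=300, derandomize=True)
    @given(valid_point)
    def test_model_pairs_have_zero_residual(self, point):
        v_scan, frac, _ = point
        v_real = frac * v_scan
        pair = BidirectionalPair(
            v_aa=apparent_velocity(v_real, scan(v_scan, A)),
            v_ar=apparent_velocity(v_real, scan(v_scan, R)),
            v_scan=v_scan,
        )
        assert abs(bidirectional_residual(pair)) < 1e-9

    @pytest.mark.parametrize(
        "v_ar, v_scan, expected",
        [(10.0 / 3.0, 10.0, 10.0), (0.001, 10.0, pytest.approx(0.001, rel=1e-3))],
    )
    def test_vaa_from_var(self, v_ar, v_scan, expected):
        assert vaa_from_var(v_ar, v_scan) == pytest.approx(expected)

    def test_vaa_from_var_pole(self):
        with pytest.raises(SingularityError):
            vaa_from_var(5.0, 10.0)
        assert vaa_from_var(4.999, 10.0) > 2000.0  # diverges toward the pole

    @settings(max_examples=200, derandomize=True)
    @given(valid_point)
    def test_vaa_from_var_consistent_with_forward_models(self, point):
        # composing the retrograde inversion with the anterograde forward
        # model must equal the direct paired-scan relation
        v_scan, frac, _ = point
        v_real = frac * v_scan
        v_ar = apparent_velocity(v_real, scan(v_scan, R))
        composed = apparent_velocity(real_velocity(v_ar, scan(v_scan, R)), scan(v_scan, A))
        assert vaa_from_var(v_ar, v_scan) == pytest.approx(composed, rel=1e-9)


class TestRelativeError:
    @pytest.mark.parametrize(
        "v_real, v_scan, direction, expected",
        [(5.0, 10.0, A, -1.0), (5.0, 10.0, R, 1.0 / 3.0)],
    )
    def test_examples(self, v_real, v_scan, direction, expected):
        assert relative_error(v_real, scan(v_scan, direction)) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(2.0, 50.0), st.floats(0.01, 0.95))
    def test_signs_and_asymmetry(self, v_scan, frac):
        v_real = frac * v_scan
        err_a = relative_error(v_real, scan(v_scan, A))
        err_r = relative_error(v_real, scan(v_scan, R))
        assert err_a < 0 < err_r  # overestimate vs underestimate
        assert abs(err_a) > abs(err_r)


class TestScanParameters:
    def test_derived_quantities(self, antero_scan):
        assert antero_scan.t_pixel == pytest.approx(0.02)
        assert antero_scan.sweep_time == pytest.approx(0.6)
        assert antero_scan.segment_length == pytest.approx(6.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(v_scan=0.0),
            dict(x_pixel=-1.0),
            dict(n_pixels=1),
            dict(t_line=0.1),  # shorter than the sweep itself
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(v_scan=10.0, direction=A, t_line=1.0, x_pixel=0.2, n_pixels=30)
        base.update(kwargs)
        with pytest.raises(ValueError):
            ScanParameters(**base)

    def test_direction_coercion_from_string(self):
        s = ScanParameters(10.0, "retrograde", 1.0, 0.2, 30)
        assert s.direction is R
        with pytest.raises(ValueError):
            ScanParameters(10.0, "sideways", 1.0, 0.2, 30)
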