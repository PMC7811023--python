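"""Local/non-local polar writhe, trajectory series and jump detection."""

import numpy as np
import pytest

from polarwrithe import (DiscreteCurve, SelfIntersectionError, detect_jumps,
                         gauss_writhe, local_writhe, nonlocal_writhe,
                         pair_nonlocal_writhe, polar_writhe, split_sections,
                         writhe_series)
from polarwrithe import fixtures as fx

from helpers import rot_z, trefoil


def helix_wpl(a, p, turns):
    return turns * (1.0 - p / np.hypot(a, p))


class TestLocalWrithe:
    def test_straight_line_zero(self):
        pts = np.linspace([0, 0, 0], [1.0, 2.0, 3.0], 50)
        sec = split_sections(DiscreteCurve(pts))[0]
        assert local_writhe(sec) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("a,p,turns", [(1.0, 1.0, 3.0), (1.0, 0.3, 5.0),
                                           (2.0, 1.5, 2.0)])
    def test_helix_closed_form(self, a, p, turns):
        curve = fx.make_helix(a, p, turns, 10000)
        res = polar_writhe(curve)
        assert res.n_sections == 1
        assert res.wpl == pytest.approx(helix_wpl(a, p, turns), abs=1e-3)
        assert res.wpnl == 0.0

    def test_helix_high_resolution_accuracy(self):
        res = polar_writhe(fx.make_helix(1.0, 1.0, 3.0, 10000))
        assert res.wpl == pytest.approx(helix_wpl(1, 1, 3), abs=1e-4)

    def test_mirror_flips_sign(self):
        curve = fx.make_helix(1.0, 1.0, 3.0, 3000)
        mirror = curve.transformed(rotation=np.diag([-1.0, 1.0, 1.0]))
        assert polar_writhe(mirror).wpl == pytest.approx(
            -polar_writhe(curve).wpl, abs=1e-9)


class TestNonlocalWrithe:
    def test_paraboloid_pair_minus_one(self):
        secs = split_sections(fx.make_paraboloid(np.pi, 1.0, 2000))
        pw = pair_nonlocal_writhe(secs[0], secs[1])
        assert pw.contribution == pytest.approx(-1.0, abs=1e-3)

    @pytest.mark.parametrize("h", [0.25, 0.5, 1.0, 2.0])
    def test_height_independence(self, h):
        secs = split_sections(fx.make_paraboloid(4 * np.pi, h, 2000))
        pw = pair_nonlocal_writhe(secs[0], secs[1])
        assert pw.contribution == pytest.approx(-4.0, abs=1e-4)

    @pytest.mark.parametrize("theta", [0.7, np.pi, 2 * np.pi, 5.0])
    def test_total_is_minus_theta_over_pi(self, theta):
        total, _ = nonlocal_writhe(split_sections(
            fx.make_paraboloid(theta, 1.0, 2000)))
        assert total == pytest.approx(-theta / np.pi, abs=1e-4)

    def test_disjoint_height_ranges_contribute_zero(self):
        lower = split_sections(fx.make_helix(1, 1, 1, 200))[0]
        upper_curve = fx.make_helix(1, 1, 1, 200).transformed(
            translation=[0, 0, 100.0])
        upper = split_sections(upper_curve)[0]
        pw = pair_nonlocal_writhe(lower, upper)
        assert pw.overlap is None and pw.contribution == 0.0

    def test_pair_decomposition_sums_to_total(self):
        secs = split_sections(fx.make_loop_transition(0.2, 2001))
        total, pairs = nonlocal_writhe(secs)
        assert len(pairs) == 3
        assert total == pytest.approx(sum(p.contribution for p in pairs))

    def test_single_section_zero(self):
        total, pairs = nonlocal_writhe(split_sections(fx.make_helix(1, 1, 2, 300)))
        assert total == 0.0 and pairs == []

    def test_coincident_strands_error_reports_height(self):
        pts = np.array([[0, 0, 0.0], [0, 0, 0.5], [0, 0, 1.0],
                        [1e-12, 1e-12, 0.75], [1e-12, 1e-12, 0.25]])
        with pytest.raises(SelfIntersectionError, match="height"):
            polar_writhe(DiscreteCurve(pts))


class TestPolarWrithe:
    def test_decomposition_identity(self):
        for curve in (fx.make_paraboloid(2 * np.pi, 1, 800),
                      trefoil(800), fx.make_loop_transition(0.2, 801)):
            res = polar_writhe(curve)
            assert res.wp == res.wpl + res.wpnl  # exact by construction
            assert res.wpnl == pytest.approx(
                sum(p.contribution for p in res.wpnl_pairs))

    @pytest.mark.parametrize("theta", [np.pi, 2 * np.pi, 4 * np.pi])
    def test_writhe_free_height(self, theta):
        res = polar_writhe(fx.make_paraboloid(theta, 0.37, 2000))
        assert abs(res.wp) < 0.05

    def test_straight_line_all_zero(self):
        pts = np.linspace([0, 0, 0], [0, 0, 1.0], 20)
        res = polar_writhe(DiscreteCurve(pts))
        assert res.wpl == res.wpnl == res.wp == 0.0

    def test_translation_and_z_rotation_invariance(self):
        curve = fx.make_paraboloid(2 * np.pi, 0.8, 1200)
        ref = polar_writhe(curve).wp
        moved = curve.transformed(rotation=rot_z(1.234),
                                  translation=[3.0, -2.0, 7.0])
        assert polar_writhe(moved).wp == pytest.approx(ref, abs=1e-9)

    def test_reflection_antisymmetry(self):
        curve = fx.make_loop_transition(0.4, 1001)
        mirrored = curve.transformed(rotation=np.diag([-1.0, 1.0, 1.0]))
        assert polar_writhe(mirrored).wp == pytest.approx(
            -polar_writhe(curve).wp, abs=1e-9)

    def test_reversal_invariance(self):
        for curve in (fx.make_paraboloid(2 * np.pi, 1, 900),
                      fx.make_loop_transition(0.2, 901)):
            assert polar_writhe(curve.reversed()).wp == pytest.approx(
                polar_writhe(curve).wp, abs=1e-9)

    def test_closed_trefoil_matches_gauss(self):
        curve = trefoil(2000)
        wp = polar_writhe(curve).wp
        wr = gauss_writhe(curve).wr
        assert wp == pytest.approx(wr, abs=1e-2)

    def test_refinement_convergence(self):
        vals = [polar_writhe(fx.make_paraboloid(2 * np.pi, 1.0, n)).wp
                for n in (500, 1000, 2000)]
        assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0])


class TestWindingProperty:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(theta=st.floats(0.5, 10.0), h=st.floats(0.3, 2.5))
    def test_paraboloid_winding_law(self, theta, h):
        """The mutual winding of the paraboloid's two sections is -theta/pi
        for every winding angle and height."""
        total, _ = nonlocal_writhe(split_sections(
            fx.make_paraboloid(theta, h, 1200)))
        assert total == pytest.approx(-theta / np.pi, abs=2e-4)


class TestSeriesAndJumps:
    def test_loop_transition_monotone_wp(self):
        from scipy.stats import spearmanr
        frames = [fx.make_loop_transition(tau, 801)
                  for tau in np.linspace(3.0, 0.2, 25)]
        series = writhe_series(frames)
        rho = spearmanr(series.data["wp"], series.data["frame"]).statistic
        assert rho > 0.99

    def test_single_frame_matches_direct(self):
        curve = fx.make_paraboloid(np.pi, 1.0, 500)
        series = writhe_series([curve])
        assert len(series) == 1
        assert series.data.loc[0, "wp"] == pytest.approx(
            polar_writhe(curve).wp)
        assert series.data.loc[0, "frame"] == 1

    def test_reversed_frame_order_reverses_series(self):
        frames = [fx.make_loop_transition(tau, 501) for tau in (3.0, 1.5, 0.2)]
        a = writhe_series(frames).data["wp"].to_numpy()
        b = writhe_series(frames[::-1]).data["wp"].to_numpy()
        np.testing.assert_allclose(a, b[::-1], atol=1e-12)

    def test_failing_frame_recorded_as_missing(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        flat = DiscreteCurve(np.column_stack([np.cos(t), np.sin(t),
                                              np.zeros(40)]), closed=True)
        series = writhe_series([fx.make_helix(1, 1, 1, 200), flat,
                                fx.make_helix(1, 1, 1, 200)])
        wp = series.data["wp"]
        assert np.isnan(wp[1]) and np.isfinite(wp[0]) and np.isfinite(wp[2])

    def test_crossing_family_jump_event(self):
        lams = [0.30, 0.40, 0.48, 0.52, 0.60, 0.70]
        frames = [fx.make_crossing_family(l, 1200) for l in lams]
        series = writhe_series(frames)
        events = detect_jumps(series, "wp")
        assert len(events) == 1
        ev = events[0]
        assert ev.frame == 4 and ev.classification == "self-crossing"
        assert abs(ev.delta) == pytest.approx(2.0, abs=0.05)

    def test_constant_series_no_events(self):
        frames = [fx.make_paraboloid(np.pi, 1.0, 400)] * 4
        series = writhe_series(frames)
        assert detect_jumps(series, "wp") == []

    def test_overthetop_jump_only_in_wp_star(self):
        lams = [0.40, 0.48, 0.52, 0.60]
        frames = [fx.make_overthetop_family(l, 1200) for l in lams]
        series = writhe_series(frames, include_wpstar=True)
        assert detect_jumps(series, "wp") == []
        events = detect_jumps(series, "wp_star")
        assert len(events) == 1
        assert events[0].classification == "over-the-top"
        assert abs(events[0].delta) == pytest.approx(2.0, abs=0.05)
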