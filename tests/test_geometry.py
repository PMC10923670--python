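"""Wall-profile laws, landmarks and channel construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hemoflow as hf
from hemoflow.geometry import (
    AneurysmSpec,
    StenosisSpec,
    aneurysm_half_height,
    build_channel,
    lesion_landmarks,
    lesion_windows,
)


class TestStenosisProfile:
    def test_throat_depth_at_center(self):
        spec = StenosisSpec(D=2.0, eps=0.5, centers=(7.0,), Ls=1.0)
        # cos(0) = 1 at the lesion centre: half-height = D/2 - eps
        assert hf.stenosis_half_height(7.0, spec) == pytest.approx(0.5)

    def test_healthy_at_lesion_edges(self):
        spec = StenosisSpec(D=2.0, eps=0.5, centers=(7.0,), Ls=1.0)
        assert hf.stenosis_half_height(6.5, spec) == pytest.approx(1.0)
        assert hf.stenosis_half_height(7.5, spec) == pytest.approx(1.0)

    def test_zero_depth_is_straight_channel(self):
        spec = StenosisSpec(D=2.0, eps=0.0)
        x = np.linspace(0, 16, 301)
        assert np.allclose(hf.stenosis_half_height(x, spec), 1.0)

    def test_continuity_at_interval_ends(self):
        spec = StenosisSpec(D=2.0, eps=0.7, centers=(5.0, 9.0), Ls=1.4)
        for edge in (4.3, 5.7, 8.3, 9.7):
            left = hf.stenosis_half_height(edge - 1e-12, spec)
            right = hf.stenosis_half_height(edge + 1e-12, spec)
            assert abs(left - right) < 1e-9

    def test_closing_channel_rejected(self):
        with pytest.raises(ValueError, match="eps"):
            StenosisSpec(D=2.0, eps=1.0)

    def test_overlapping_lesions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StenosisSpec(centers=(7.0, 7.5), Ls=1.0)

    @given(eps=st.floats(0.01, 0.95))
    @settings(max_examples=30, deadline=None)
    def test_throat_height_strictly_decreases_with_eps(self, eps):
        spec = StenosisSpec(D=2.0, eps=eps, centers=(7.0,))
        tighter = StenosisSpec(D=2.0, eps=min(eps + 0.02, 0.99), centers=(7.0,))
        assert hf.stenosis_half_height(7.0, tighter) < hf.stenosis_half_height(7.0, spec)


class TestAneurysmProfile:
    def test_ratio_is_one_at_lesion_ends(self):
        spec = AneurysmSpec(R0=1.0, eps=1.0, l0_list=(6.5,), la=1.0)
        assert hf.aneurysm_radius_ratio(6.5, spec) == pytest.approx(1.0)
        assert hf.aneurysm_radius_ratio(7.5, spec) == pytest.approx(1.0)

    def test_midpoint_value(self):
        # polynomial at t=1/2: 5.5 - 11.75 + 9 - 2.25 = 0.5, scaled by eps/(2 R0)
        spec = AneurysmSpec(R0=1.0, eps=1.0, l0_list=(6.5,), la=1.0)
        assert hf.aneurysm_radius_ratio(7.0, spec) == pytest.approx(1.25)

    def test_one_sixth_landmark_value(self):
        spec = AneurysmSpec(R0=1.0, eps=1.0, l0_list=(6.5,), la=1.0)
        t = 1.0 / 6.0
        expected = 1.0 + 0.5 * (11 * t - 47 * t**2 + 72 * t**3 - 36 * t**4)
        got = hf.aneurysm_radius_ratio(6.5 + 1.0 / 6.0, spec)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(1.4167, abs=2e-4)

    def test_bulge_outward_everywhere(self):
        spec = AneurysmSpec(R0=1.0, eps=0.5)
        x = np.linspace(0, 16, 2001)
        assert np.all(hf.aneurysm_radius_ratio(x, spec) >= 1.0 - 1e-12)

    @given(eps=st.floats(0.05, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_apex_height_strictly_increases_with_eps(self, eps):
        lo = AneurysmSpec(R0=1.0, eps=eps, l0_list=(6.5,))
        hi = AneurysmSpec(R0=1.0, eps=eps + 0.05, l0_list=(6.5,))
        x = np.linspace(6.5, 7.5, 501)
        assert np.max(aneurysm_half_height(x, hi)) > np.max(aneurysm_half_height(x, lo))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AneurysmSpec(la=0.0)
        with pytest.raises(ValueError):
            AneurysmSpec(R0=-1.0)


class TestLandmarks:
    def test_stenosis_throat_at_center(self):
        marks = lesion_landmarks(StenosisSpec(eps=0.5, centers=(7.0, 9.0)))
        assert [m["apex_x"] for m in marks] == pytest.approx([7.0, 9.0], abs=1e-6)
        assert [m["apex_half_height"] for m in marks] == pytest.approx([0.5, 0.5])

    def test_aneurysm_maximizer_matches_bruteforce_bisection(self):
        # oracle: root of the derivative polynomial 11 - 94 t + 216 t^2 - 144 t^3
        # bracketed on a dense grid, refined by bisection
        dpoly = lambda t: 11 - 94 * t + 216 * t**2 - 144 * t**3
        grid = np.linspace(0.0, 0.5, 20001)
        vals = 11 * grid - 47 * grid**2 + 72 * grid**3 - 36 * grid**4
        t0 = grid[np.argmax(vals)]
        a, b = t0 - 1e-4, t0 + 1e-4
        for _ in range(60):
            mid = 0.5 * (a + b)
            if dpoly(a) * dpoly(mid) <= 0:
                b = mid
            else:
                a = mid
        t_star = 0.5 * (a + b)
        spec = AneurysmSpec(R0=1.0, eps=1.0, l0_list=(6.5,), la=1.0)
        marks = lesion_landmarks(spec)
        assert marks[0]["apex_x"] == pytest.approx(6.5 + t_star, abs=1e-5)

    def test_aneurysm_midpoint_excursion_is_quarter_eps(self):
        # direct evaluation of the bulge polynomial at the midpoint gives a
        # wall excursion of eps/4 (in units of R0: h_a - 1 = eps/(4 R0))
        spec = AneurysmSpec(R0=1.0, eps=1.0, l0_list=(6.5,), la=1.0)
        marks = lesion_landmarks(spec)
        assert marks[0]["ratio_at_midpoint"] - 1.0 == pytest.approx(0.25)


class TestBuildChannel:
    def test_no_lesion_is_rectangle(self):
        geom = build_channel(StenosisSpec(eps=0.0))
        pts, tags = geom.boundary_polyline()
        assert np.allclose(np.abs(pts[:, 1] - 1.0), 1.0)
        assert tags.count("inlet") == 1 and tags.count("outlet") == 1

    def test_two_stenoses_give_two_throat_records(self):
        geom = build_channel(StenosisSpec(eps=0.5, centers=(7.0, 9.0)))
        assert len(geom.lesions) == 2
        assert all(l["kind"] == "stenosis" for l in geom.lesions)

    def test_aneurysm_max_height_matches_dense_profile_max(self):
        spec = AneurysmSpec(eps=0.5)
        geom = build_channel(spec, n_samples=1025)
        dense = aneurysm_half_height(np.linspace(0, 16, 20001), spec)
        assert np.max(geom.half) == pytest.approx(np.max(dense), abs=1e-4)

    def test_mirror_symmetric_and_ccw(self):
        geom = build_channel(StenosisSpec(eps=0.5))
        pts, _ = geom.boundary_polyline()
        nxt = np.roll(pts, -1, axis=0)
        area2 = np.sum(pts[:, 0] * nxt[:, 1] - pts[:, 1] * nxt[:, 0])
        assert area2 > 0  # counter-clockwise
        assert np.allclose(geom.upper_wall(geom.x_samples) - 1.0, 1.0 - geom.lower_wall(geom.x_samples))

    def test_coarse_sampling_rejected_with_lesion_name(self):
        with pytest.raises(ValueError, match="lesion 0"):
            build_channel(StenosisSpec(), n_samples=17)

    def test_exports_are_plain_text(self, tmp_path):
        geom = build_channel(StenosisSpec())
        geom.to_csv(tmp_path / "poly.csv")
        geom.to_geo(tmp_path / "chan.geo")
        body = (tmp_path / "poly.csv").read_text()
        assert body.startswith("x,y")
        geo = (tmp_path / "chan.geo").read_text()
        assert 'Physical Curve("inlet")' in geo

    def test_lesion_windows(self):
        geom = build_channel(StenosisSpec(eps=0.5, centers=(7.0, 9.0)))
        w = lesion_windows(geom)
        assert w["between"] == pytest.approx((7.0, 9.0), abs=1e-6)
        assert w["lesion_span"] == pytest.approx((6.5, 9.5), abs=1e-6)
        assert w["interior"] == (2.0, 14.0)
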