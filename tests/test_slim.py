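import numpy as np
import pytest
from scipy.optimize import brentq

from slimloc import (
    MicArrayGeometry,
    SimScene,
    USVSegment,
    exact_delays,
    four_mic_geometry,
    intersect_curves,
    localize_delays,
    localize_usv,
    manifold_offset,
    origin_curve,
    pair_frame,
    render_scene,
)
from slimloc.errors import InfeasibleDelayError, InsufficientPairsError
from slimloc.slim import curve_residuals

from conftest import random_sources, rendered_scene


def brute_force_offset(D, R, delta_p):
    """Numerically solve |dist to mic1 - dist to mic2| = delta_p at radial offset R.

    Mics at (-D/2, 0) and (+D/2, 0) in the (axis, radial) plane; the locus point
    sits at (x, R). Independent of the closed form under test.
    """

    def path_diff(x):
        d1 = np.hypot(x + D / 2, R)
        d2 = np.hypot(x - D / 2, R)
        return d1 - d2 - delta_p

    lim = 1e6
    return brentq(path_diff, -lim, lim, xtol=1e-10)


class TestManifoldOffset:
    def test_zero_delay_gives_perpendicular_bisector(self):
        for r in (0.0, 50.0, 500.0):
            assert manifold_offset(300.0, r, 0.0) == 0.0

    def test_r_zero_reduces_to_half_path_difference(self):
        assert manifold_offset(300.0, 0.0, 100.0) == pytest.approx(50.0)
        assert manifold_offset(300.0, 0.0, -80.0) == pytest.approx(-40.0)

    def test_worked_example_matches_brute_force(self):
        val = manifold_offset(300.0, 120.0, 100.0)
        assert val == pytest.approx(65.57, abs=0.01)
        assert val == pytest.approx(brute_force_offset(300.0, 120.0, 100.0), abs=1e-6)

    def test_sign_follows_path_difference(self):
        assert manifold_offset(300.0, 100.0, 50.0) > 0
        assert manifold_offset(300.0, 100.0, -50.0) < 0

    def test_monotone_in_radial_distance(self):
        rs = np.linspace(0, 400, 100)
        vals = manifold_offset(300.0, rs, np.full_like(rs, 100.0))
        assert np.all(np.diff(vals) > 0)

    def test_infeasible_path_difference_rejected(self):
        with pytest.raises(InfeasibleDelayError):
            manifold_offset(300.0, 50.0, 300.0)
        with pytest.raises(InfeasibleDelayError):
            manifold_offset(300.0, 50.0, -310.0)

    def test_oracle_equivalence_random_configurations(self, rng):
        # spot-check against the brute-force locus search (full sweep in the
        # acceptance suite)
        for _ in range(200):
            D = rng.uniform(100, 500)
            R = rng.uniform(0, 300)
            delta_p = rng.uniform(-0.95, 0.95) * D
            assert manifold_offset(D, R, delta_p) == pytest.approx(
                brute_force_offset(D, R, delta_p), abs=1e-4
            )


class TestOriginCurve:
    def test_zero_delay_is_straight_bisector(self, geom4):
        pf = pair_frame(geom4, 0, 1)  # mics share y, so bisector is x = const
        curve = origin_curve(geom4, pf, 0.0)
        pts = curve.valid_points
        assert len(pts) > 10
        # pair 0-1 runs along x; the bisector is the vertical line x = midpoint_x
        assert np.allclose(pts[:, 0], pf.midpoint[0], atol=1e-9)

    def test_curve_passes_through_true_source(self, geom4, rng):
        for src in random_sources(geom4, 10, rng):
            delays = exact_delays(src, geom4)
            for (i, j), dt in delays.items():
                pf = pair_frame(geom4, i, j)
                curve = origin_curve(geom4, pf, dt, y_step_mm=0.25)
                pts = curve.valid_points
                dmin = np.min(np.linalg.norm(pts - src, axis=1))
                assert dmin < 0.5  # within one sample step of the truth

    def test_all_points_satisfy_path_difference_residual(self, geom4, rng):
        src = random_sources(geom4, 1, rng)[0]
        for (i, j), dt in exact_delays(src, geom4).items():
            pf = pair_frame(geom4, i, j)
            curve = origin_curve(geom4, pf, dt)
            res = curve_residuals(curve, geom4)
            assert np.all(res[curve.validity_mask] < 0.1)

    def test_low_mic_height_approaches_planar_hyperbola(self):
        # with H -> 0 and the source in the plane, the origin curve collapses to
        # the classic 2D hyperbola branch
        g = MicArrayGeometry(
            mic_positions=np.array(
                [(-150.0, 0.0, 1e-6), (150.0, 0.0, 1e-6), (0.0, 200.0, 1e-6)]
            ),
            platform_half_extent=(200.0, 150.0),
        )
        src = (60.0, 40.0)
        dt = exact_delays(src, g)[(0, 1)]
        pf = pair_frame(g, 0, 1)
        curve = origin_curve(g, pf, dt, y_step_mm=0.25)
        pts = curve.valid_points
        # planar hyperbola: x^2/a^2 - y^2/b^2 = 1 with 2a = |path difference|
        delta_p = -g.speed_of_sound * dt
        a = abs(delta_p) / 2
        b2 = (150.0) ** 2 - a**2
        lhs = pts[:, 0] ** 2 / a**2 - pts[:, 1] ** 2 / b2
        assert np.allclose(lhs, 1.0, atol=1e-3)

    def test_infeasible_delay_flags_empty_curve(self, geom4):
        pf = pair_frame(geom4, 0, 1)
        dt = (pf.D / geom4.speed_of_sound) * 1.5
        curve = origin_curve(geom4, pf, dt)
        assert curve.infeasible
        assert len(curve.polyline) == 0

    def test_swapped_pair_yields_same_locus(self, geom4):
        src = (70.0, -40.0)
        d = exact_delays(src, geom4)
        dt_ij = d[(0, 1)]
        c1 = origin_curve(geom4, pair_frame(geom4, 0, 1), dt_ij, y_step_mm=0.25)
        c2 = origin_curve(geom4, pair_frame(geom4, 1, 0), -dt_ij, y_step_mm=0.25)
        # both curves pass through the source
        for c in (c1, c2):
            assert np.min(np.linalg.norm(c.valid_points - np.array(src), axis=1)) < 0.5


class TestIntersectCurves:
    def test_exact_curves_intersect_at_source(self, geom4):
        src = (50.0, -30.0)
        dens = localize_delays(exact_delays(src, geom4), geom4)
        assert np.linalg.norm(dens.estimate - np.array(src)) <= 1.5
        assert dens.la == 4 * dens.la_raw

    def test_insufficient_curves_rejected(self, geom4):
        delays = {(0, 1): exact_delays((0.0, 0.0), geom4)[(0, 1)]}
        with pytest.raises(InsufficientPairsError):
            localize_delays(delays, geom4)

    def test_jittered_delays_increase_la(self, geom4, rng):
        # LA responds to delay noise once the curve scatter exceeds the ridge
        # resolution (below it the statistic sits on its quantization plateau)
        src = (20.0, 60.0)
        clean = exact_delays(src, geom4)
        base = localize_delays(clean, geom4).la
        fs = geom4.sampling_rate
        las = []
        for _ in range(7):
            noisy = {k: v + rng.uniform(-8, 8) / fs for k, v in clean.items()}
            las.append(localize_delays(noisy, geom4).la)
        assert np.median(las) > base

    def test_six_curves_beat_three_on_noisy_arrivals(self, geom4, rng):
        # identical noisy arrival times; the 6-pair estimator uses a strict
        # superset of the 3-pair estimator's information
        src3 = lambda p: np.array([p[0], p[1], 0.0])
        errs = {6: [], 3: []}
        for src in random_sources(geom4, 40, rng):
            d = np.linalg.norm(geom4.mic_positions - src3(src), axis=1)
            arrivals = d / geom4.speed_of_sound + rng.normal(
                0, 1.0 / geom4.sampling_rate, 4
            )
            all_pairs = {
                (i, j): arrivals[j] - arrivals[i] for i, j in geom4.pairs()
            }
            sub = {k: v for k, v in all_pairs.items() if max(k) <= 2}
            errs[6].append(
                np.linalg.norm(localize_delays(all_pairs, geom4).estimate - src)
            )
            errs[3].append(
                np.linalg.norm(localize_delays(sub, geom4).estimate - src)
            )
        assert np.median(errs[6]) < np.median(errs[3])


class TestLocalizeUSV:
    def test_clean_simulated_chirp_within_5_mm(self, geom4):
        rec, seg, scene = rendered_scene(geom4, (50.0, -30.0), snr_db=20, seed=3)
        res = localize_usv(rec, seg, geom4)
        assert res.localized
        assert np.linalg.norm(res.position - np.array([50.0, -30.0])) < 5.0
        assert res.n_windows_used <= res.n_windows_total

    def test_zero_noise_error_bounded_by_grid(self, geom4):
        rec, seg, _ = rendered_scene(geom4, (-80.0, 40.0), snr_db=None)
        res = localize_usv(rec, seg, geom4)
        assert np.linalg.norm(res.position - np.array([-80.0, 40.0])) < np.sqrt(2) * 1.5

    def test_short_usv_uses_single_padded_window(self, geom4):
        rec, seg, _ = rendered_scene(geom4, (0.0, 0.0), snr_db=None, duration_ms=20.0)
        res = localize_usv(rec, seg, geom4)
        assert res.n_windows_total == 1
        assert res.localized

    def test_estimate_projected_into_bounds(self, geom4):
        rec, seg, _ = rendered_scene(geom4, (10.0, 10.0), snr_db=20, seed=0)
        res = localize_usv(rec, seg, geom4)
        bx, by = geom4.bounds()
        assert abs(res.position[0]) <= bx and abs(res.position[1]) <= by


class TestEquivariance:
    def test_rigid_transform_of_geometry_moves_estimate_rigidly(self, geom4):
        src = np.array([40.0, 25.0])
        est0 = localize_delays(exact_delays(src, geom4), geom4).estimate

        theta = np.pi / 2  # rotate the whole rig a quarter turn
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        mics = geom4.mic_positions.copy()
        mics[:, :2] = mics[:, :2] @ rot.T
        # platform must stay axis-aligned for the grid: quarter turn swaps extents
        g2 = MicArrayGeometry(
            mic_positions=mics,
            platform_half_extent=geom4.platform_half_extent[::-1],
        )
        src2 = rot @ src
        est2 = localize_delays(exact_delays(src2, g2), g2).estimate
        assert np.linalg.norm(est2 - rot @ est0) < 1.5
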