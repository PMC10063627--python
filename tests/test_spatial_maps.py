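import numpy as np
import pytest
from scipy import stats

from slimloc import (
    PolarMap,
    RelativePosition,
    conditional_density,
    occurrence_map,
    permutation_significance,
    property_map,
    relative_position,
)
from slimloc.errors import IncompatibleMapsError, SlimlocError, ValidationError



def sample_from_prior(rng, n, max_r=250.0):
    """Events uniform over the polar analysis domain."""
    return [
        RelativePosition(rng.uniform(0, max_r), rng.uniform(0, 180)) for _ in range(n)
    ]


class TestRelativePosition:
    def test_receiver_directly_ahead(self):
        rp = relative_position((0, 0), (0, -10), (0, 50))
        assert rp.distance == pytest.approx(50.0)
        assert rp.angle == pytest.approx(0.0)

    def test_receiver_directly_behind(self):
        rp = relative_position((0, 0), (0, -10), (0, -80))
        assert rp.angle == pytest.approx(180.0)

    def test_left_right_mirrored_to_same_bin(self):
        left = relative_position((0, 0), (0, -10), (-60, 0))
        right = relative_position((0, 0), (0, -10), (60, 0))
        assert left.angle == pytest.approx(right.angle)
        assert left.angle == pytest.approx(90.0)

    def test_mirroring_idempotent_over_random_positions(self, rng):
        for _ in range(50):
            r = rng.uniform(5, 200)
            a = rng.uniform(-180, 180)
            rad = np.radians(a)
            receiver = (r * np.cos(rad), r * np.sin(rad))
            mirrored = (r * np.cos(-rad), r * np.sin(-rad))
            rp1 = relative_position((0, 0), (-10, 0), receiver)
            rp2 = relative_position((0, 0), (-10, 0), mirrored)
            assert rp1.angle == pytest.approx(rp2.angle, abs=1e-9)

    def test_coincident_markers_rejected(self):
        with pytest.raises(SlimlocError):
            relative_position((5, 5), (5, 5), (0, 0))


class TestOccurrenceMap:
    def test_all_events_in_one_bin(self):
        events = [RelativePosition(30.0, 10.0)] * 10
        m = occurrence_map(events)
        assert m.counts.sum() == 10
        assert m.counts.max() == 10
        assert m.n_events == 10

    def test_empty_event_list(self):
        m = occurrence_map([])
        assert m.counts.sum() == 0
        assert m.n_events == 0

    def test_uniform_bin_area_sampling_is_uniform(self, rng):
        # draw events uniformly over the bin *grid* (uniform in angle and
        # radius), so expected counts are equal across bins
        events = sample_from_prior(rng, 10_000)
        m = occurrence_map(events)
        chi2, p = stats.chisquare(m.counts.ravel())
        assert p > 1e-4

    def test_bad_edges_rejected(self):
        with pytest.raises(ValidationError):
            occurrence_map([], angle_edges=np.array([0.0, 10.0, 5.0]))

    def test_out_of_range_events_counted_as_dropped(self):
        events = [RelativePosition(500.0, 10.0), RelativePosition(30.0, 10.0)]
        m = occurrence_map(events)
        assert m.n_events == 1
        assert m.n_dropped == 1


class TestConditionalDensity:
    def test_prior_against_itself_is_unity(self, rng):
        prior = occurrence_map(sample_from_prior(rng, 5_000))
        cond = conditional_density(prior, prior)
        unmasked = ~np.isnan(cond.density)
        assert np.allclose(cond.density[unmasked], 1.0)

    def test_zero_prior_bin_masked(self):
        voc = occurrence_map([RelativePosition(30.0, 10.0)])
        prior = occurrence_map([RelativePosition(200.0, 170.0)])
        cond = conditional_density(voc, prior)
        assert np.isnan(cond.density).sum() > 0
        assert not np.isinf(cond.density[~np.isnan(cond.density)]).any()

    def test_events_from_prior_give_flat_density(self, rng):
        frames = sample_from_prior(rng, 50_000)
        idx = rng.choice(len(frames), 50_000, replace=True)
        voc = occurrence_map([frames[i] for i in idx])
        prior = occurrence_map(frames)
        cond = conditional_density(voc, prior)
        vals = cond.density[~np.isnan(cond.density)]
        assert np.std(vals) / np.mean(vals) < 0.1

    def test_concentrated_vocs_give_single_peak(self, rng):
        prior = occurrence_map(sample_from_prior(rng, 20_000))
        voc = occurrence_map([RelativePosition(30.0, 10.0)] * 100)
        cond = conditional_density(voc, prior)
        dens = np.nan_to_num(cond.density)
        assert (dens > 0).sum() == 1

    def test_mismatched_edges_rejected(self, rng):
        a = occurrence_map(sample_from_prior(rng, 100))
        b = occurrence_map(
            sample_from_prior(rng, 100), radius_edges=np.linspace(0, 300, 13)
        )
        with pytest.raises(IncompatibleMapsError):
            conditional_density(a, b)


class TestPermutationSignificance:
    def test_extreme_concentration_is_maximally_significant(self, rng):
        prior = sample_from_prior(rng, 20_000)
        voc = [RelativePosition(30.0, 10.0)] * 200
        m = permutation_significance(voc, prior, n_perm=1000, rng=0)
        ia = np.searchsorted(m.angle_edges, 10.0, side="right") - 1
        ir = np.searchsorted(m.radius_edges, 30.0, side="right") - 1
        assert m.p_values[ia, ir] <= 1 / 1000
        assert m.signs[ia, ir] > 0

    def test_sign_convention_enriched_positive_depleted_negative(self, rng):
        prior = sample_from_prior(rng, 20_000)
        # enrich one bin, deplete by construction elsewhere
        voc = [RelativePosition(30.0, 10.0)] * 300 + sample_from_prior(rng, 300)
        m = permutation_significance(voc, prior, n_perm=200, rng=1)
        ia = np.searchsorted(m.angle_edges, 10.0, side="right") - 1
        ir = np.searchsorted(m.radius_edges, 30.0, side="right") - 1
        assert m.signs[ia, ir] > 0
        sig_neg = (m.p_values < 0.05) & (m.signs < 0)
        assert sig_neg.sum() >= 1

    def test_null_calibration_modest(self, rng):
        # full-scale calibration in the acceptance suite
        prior = sample_from_prior(rng, 10_000)
        idx = rng.choice(len(prior), 1_000, replace=False)
        voc = [prior[i] for i in idx]
        m = permutation_significance(voc, prior, n_perm=200, rng=2)
        frac = (m.p_values < 0.05).mean()
        assert frac < 0.15

    def test_p_values_super_uniform_under_null(self, rng):
        prior = sample_from_prior(rng, 10_000)
        pvals = []
        for rep in range(4):
            idx = rng.choice(len(prior), 800, replace=False)
            m = permutation_significance(
                [prior[i] for i in idx], prior, n_perm=250, rng=rep
            )
            pvals.extend(m.p_values.ravel())
        pvals = np.asarray(pvals)
        # super-uniform: P(p <= t) <= ~t for all t
        for t in (0.01, 0.05, 0.1, 0.25):
            assert (pvals <= t).mean() <= t + 3 * np.sqrt(t * (1 - t) / len(pvals))

    def test_small_prior_resamples_with_replacement(self, rng):
        prior = sample_from_prior(rng, 50)
        voc = sample_from_prior(rng, 200)
        m = permutation_significance(voc, prior, n_perm=100, rng=3)
        assert m.flags["resampled_with_replacement"]


class TestPropertyMap:
    def test_constant_property(self, rng):
        events = sample_from_prior(rng, 500)
        m = property_map(events, np.full(500, 3.25))
        occupied = m.counts > 0
        assert np.allclose(m.values[occupied], 3.25)
        assert np.isnan(m.values[~occupied]).all()

    def test_property_equal_to_distance_recovers_radial_centers(self, rng):
        events = sample_from_prior(rng, 50_000)
        values = [e.distance for e in events]
        m = property_map(events, values)
        centers = 0.5 * (m.radius_edges[:-1] + m.radius_edges[1:])
        occupied = m.counts > 0
        dev = np.abs(m.values - centers[None, :])
        assert np.nanmax(dev[occupied]) < 5.0

    def test_disjoint_populations_separate_exactly(self):
        a = [RelativePosition(30.0, 10.0)] * 20
        b = [RelativePosition(200.0, 170.0)] * 20
        m = property_map(a + b, [1.0] * 20 + [9.0] * 20)
        vals = m.values[m.counts > 0]
        assert set(np.round(vals, 9)) == {1.0, 9.0}

    def test_weights_peak_normalized(self, rng):
        m = property_map(sample_from_prior(rng, 1_000), np.ones(1_000))
        assert m.weights.max() == pytest.approx(1.0)
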