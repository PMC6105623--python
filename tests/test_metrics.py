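"""Motility metrics against hand oracles and brute-force enumerations."""

import numpy as np
import pytest

import lymphtrack as lt
from lymphtrack.metrics import LN2, MetricError

from conftest import make_track


def straight_track(track_id="s", n=10, step=1.0, dt=30.0):
    return make_track(track_id, [[step * k, 0.0, 0.0] for k in range(n)], dt=dt)


class TestInstantaneousSpeeds:
    def test_constant_motion_gives_constant_speed(self):
        ts = lt.TrackSet((straight_track(n=5, step=1.0),))
        assert np.allclose(lt.instantaneous_speeds(ts), 2.0)  # 1 μm / 30 s

    def test_stationary_track_gives_zero(self):
        ts = lt.TrackSet((make_track("z", np.zeros((5, 3))),))
        assert np.all(lt.instantaneous_speeds(ts) == 0.0)

    def test_pooled_sample_size_count_oracle(self, rng):
        ts = lt.TrackSet(tuple(
            make_track(f"t{i}", rng.normal(size=(n, 3))) for i, n in enumerate((10, 20, 30))))
        assert lt.instantaneous_speeds(ts).size == 9 + 19 + 29

    def test_single_point_tracks_raise(self):
        ts = lt.TrackSet((make_track("p", np.zeros((1, 3))),))
        with pytest.raises(MetricError):
            lt.instantaneous_speeds(ts)


class TestECDF:
    def test_single_value_steps_to_one(self):
        f = lt.ecdf([5.0])
        assert f(4.999) == 0.0 and f(5.0) == 1.0

    def test_median_proportion_is_half(self):
        assert lt.ecdf([1, 2, 3, 4])(2) == 0.5

    def test_matches_brute_force_counting(self, rng):
        x = rng.normal(size=200)
        f = lt.ecdf(x)
        for v in rng.normal(size=50):
            assert f(v) == np.sum(x <= v) / len(x)

    def test_non_decreasing_with_range(self, rng):
        f = lt.ecdf(rng.normal(size=101))
        assert np.all(np.diff(f.y) >= 0)
        assert f.y[0] == pytest.approx(1 / 101) and f.y[-1] == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(MetricError):
            lt.ecdf([])


class TestDisplacementAndMeandering:
    def test_net_displacement_345(self):
        tr = make_track("d", [[0, 0, 0], [3, 4, 0]])
        assert lt.net_displacement(tr) == 5.0

    def test_straight_track_k_steps(self):
        assert lt.net_displacement(straight_track(n=8, step=2.0)) == 14.0

    def test_start_equals_end_gives_zero(self):
        tr = make_track("o", [[1, 2, 3], [4, 5, 6], [1, 2, 3]])
        assert lt.net_displacement(tr) == 0.0

    def test_meandering_straight_is_one(self):
        assert lt.meandering_index(straight_track()) == pytest.approx(1.0)

    def test_meandering_closed_loop_is_zero(self):
        tr = make_track("loop", [[0, 0, 0], [3, 0, 0], [3, 4, 0], [0, 0, 0]])
        assert lt.meandering_index(tr) == 0.0

    def test_meandering_right_angle_is_five_sevenths(self):
        tr = make_track("L", [[0, 0, 0], [3, 0, 0], [3, 4, 0]])
        assert lt.meandering_index(tr) == pytest.approx(5.0 / 7.0)

    def test_meandering_identical_points_signalled(self):
        tr = make_track("still", np.ones((4, 3)))
        with pytest.raises(MetricError, match="zero path"):
            lt.meandering_index(tr)


class TestMSD:
    def test_ballistic_msd_and_alpha(self):
        ts = lt.TrackSet(tuple(straight_track(f"b{i}", n=20, step=3.0) for i in range(5)))
        curve = lt.msd_curve(ts, lt.MetricsConfig(msd_max_fraction=0.25))
        v = 3.0 / 30.0  # μm/s
        assert np.allclose(curve.msd, (v * curve.taus) ** 2)
        assert curve.alpha == pytest.approx(2.0, abs=1e-9)

    def test_stationary_population_signalled(self):
        ts = lt.TrackSet((make_track("z", np.zeros((20, 3))),))
        with pytest.raises(MetricError):
            lt.msd_curve(ts)

    def test_pair_counts_match_brute_force(self, rng):
        """All-ordered-pairs pooling, including across gaps, by enumeration."""
        tracks = []
        for i in range(4):
            n = int(rng.integers(4, 9))
            frames = np.sort(rng.choice(12, size=n, replace=False))
            tracks.append(make_track(f"g{i}", rng.normal(size=(n, 3)), frames=frames))
        ts = lt.TrackSet(tuple(tracks))
        curve = lt.msd_curve(ts, lt.MetricsConfig(msd_max_fraction=1.0))
        for k, tau in enumerate(curve.taus):
            total, count = 0.0, 0
            for tr in ts:
                for a in range(len(tr)):
                    for b in range(len(tr)):
                        if np.isclose(tr.t[b] - tr.t[a], tau):
                            total += float(np.sum((tr.xyz[b] - tr.xyz[a]) ** 2))
                            count += 1
            assert curve.n_pairs[k] == count
            if count:
                assert curve.msd[k] == pytest.approx(total / count)

    def test_first_lag_equals_mean_squared_step(self, brownian_population):
        ts, _ = brownian_population
        curve = lt.msd_curve(ts)
        sq_steps = np.concatenate([
            np.sum(tr.step_vectors()[0] ** 2, axis=1) for tr in ts if len(tr) > 1])
        assert curve.msd[0] == pytest.approx(np.mean(sq_steps))

    def test_brownian_population_matches_6_d_tau(self, brownian_population):
        ts, d = brownian_population
        curve = lt.msd_curve(ts)
        assert 0.9 <= curve.alpha <= 1.1
        expected = 6.0 * d * curve.taus / 60.0
        assert np.all(np.abs(curve.msd / expected - 1.0) < 0.10)


class TestArrestCoefficient:
    @pytest.mark.parametrize("speeds,expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((10.0, 10.0), 0.0),
        ((1.0, 2.0, 4.0, 8.0), 0.5),
    ])
    def test_fraction_below_threshold(self, speeds, expected):
        # build a track whose k-th step moves speeds[k] μm/min along x
        steps = np.concatenate([[0.0], np.cumsum([s / 2.0 for s in speeds])])
        tr = make_track("a", [[x, 0, 0] for x in steps])
        assert lt.arrest_coefficient(tr) == expected

    def test_no_usable_steps_signalled(self):
        with pytest.raises(MetricError):
            lt.arrest_coefficient(make_track("p", np.zeros((1, 3))))


class TestTurnSpeeds:
    def test_straight_track_turns_zero(self):
        out = lt.turn_speeds(lt.TrackSet((straight_track(n=6),)))
        assert np.allclose(out, 0.0)

    def test_right_angle_each_step_is_180_deg_per_min(self):
        # square-wave path turning 90° every 30 s
        xyz = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0], [2, 2, 0]]
        out = lt.turn_speeds(lt.TrackSet((make_track("sq", xyz),)))
        assert np.allclose(out, 180.0)

    def test_two_point_track_contributes_nothing(self):
        ts = lt.TrackSet((straight_track("long", n=5), make_track("short", np.zeros((2, 3)))))
        assert lt.turn_speeds(ts).size == 3

    def test_zero_length_steps_skipped(self):
        xyz = [[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]]
        ts = lt.TrackSet((make_track("z", xyz),))
        with pytest.raises(MetricError):
            # the only interior angles involve a zero-length displacement
            lt.turn_speeds(ts)


class TestKS:
    def test_identical_samples_d_zero(self, rng):
        x = rng.normal(size=40)
        assert lt.ks_two_sample(x, x).d == 0.0

    def test_disjoint_supports_d_one(self):
        assert lt.ks_two_sample([1, 2, 3], [10, 11]).d == 1.0

    def test_offset_triples_d_one_third(self):
        assert lt.ks_two_sample([1, 2, 3], [2, 3, 4]).d == pytest.approx(1 / 3)

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=30), rng.normal(loc=0.5, size=45)
        assert lt.ks_two_sample(a, b).d == lt.ks_two_sample(b, a).d

    def test_matches_brute_force_sup_over_ecdfs(self, rng):
        a, b = rng.normal(size=25), rng.normal(loc=0.3, size=35)
        fa, fb = lt.ecdf(a), lt.ecdf(b)
        grid = np.concatenate([a, b])
        brute = max(abs(fa(v) - fb(v)) for v in grid)
        assert lt.ks_two_sample(a, b).d == pytest.approx(brute)


class TestSurfaceMetrics:
    SPHERE = lt.SurfaceModel("m", (lt.Sphere((0.0, 0.0, 0.0), 10.0),))

    def test_point_on_surface_distance_zero(self):
        assert lt.distance_to_surface((10.0, 0.0, 0.0), self.SPHERE) == 0.0

    def test_point_30_from_centre_of_10_sphere(self):
        assert lt.distance_to_surface((30.0, 0.0, 0.0), self.SPHERE) == 20.0

    def test_point_inside_floored_to_zero(self):
        assert lt.distance_to_surface((1.0, 1.0, 1.0), self.SPHERE) == 0.0

    def test_proximity_all_on_surface(self):
        ts = lt.TrackSet((make_track("a", [[10, 0, 0], [0, 10, 0]]),))
        _, frac = lt.proximity_fraction(ts, self.SPHERE)
        assert np.all(frac == 1.0)

    def test_proximity_half_within_default_20um(self):
        tracks = tuple(
            make_track(f"c{i}", [[10.0 + d, 0.0, 0.0]], )
            for i, d in enumerate((5.0, 15.0, 25.0, 35.0)))
        _, frac = lt.proximity_fraction(lt.TrackSet(tracks), self.SPHERE)
        assert frac.tolist() == [0.5]

    def test_segmented_speeds_partition_pooled_speeds(self, rng):
        tracks = tuple(
            make_track(f"t{i}", rng.normal(scale=30.0, size=(10, 3)))
            for i in range(8))
        ts = lt.TrackSet(tracks)
        close, far = lt.segment_speeds_by_distance(ts, self.SPHERE)
        pooled = lt.instantaneous_speeds(ts)
        assert sorted(np.concatenate([close, far])) == pytest.approx(sorted(pooled))

    def test_close_step_count_oracle(self):
        # 3 steps starting within 20 μm of the sphere, 2 starting beyond
        xs = [12.0, 15.0, 18.0, 45.0, 60.0, 80.0]
        tr = make_track("seg", [[x, 0, 0] for x in xs])
        close, far = lt.segment_speeds_by_distance(lt.TrackSet((tr,)), self.SPHERE)
        assert close.size == 3 and far.size == 2

    def test_all_steps_on_surface_far_empty(self):
        tr = make_track("on", [[10, 0, 0], [0, 10, 0], [-10, 0, 0]])
        close, far = lt.segment_speeds_by_distance(lt.TrackSet((tr,)), self.SPHERE)
        assert far.size == 0 and close.size == 2


class TestContacts:
    def test_colocated_five_frames_one_event(self):
        subj = lt.TrackSet((make_track("s", np.zeros((5, 3))),))
        part = lt.TrackSet((make_track("p", np.full((5, 3), 2.0)),))
        events = lt.contact_events(subj, part)
        assert len(events) == 1
        ev = events[0]
        assert ev.duration == 5 * 30.0 and ev.partner_id == "p"

    def test_never_within_threshold_empty(self):
        subj = lt.TrackSet((make_track("s", np.zeros((4, 3))),))
        part = lt.TrackSet((make_track("p", np.full((4, 3), 100.0)),))
        assert lt.contact_events(subj, part) == []

    def test_no_temporal_overlap_signalled(self):
        subj = lt.TrackSet((make_track("s", np.zeros((3, 3)), t0=0.0),))
        part = lt.TrackSet((make_track("p", np.zeros((3, 3)), t0=900.0),))
        with pytest.raises(MetricError):
            lt.contact_events(subj, part)

    def test_rate_two_events_in_ten_minutes(self):
        events = [None, None]
        assert lt.contact_rate(events, 600.0) == 1.0

    def test_rate_zero_events(self):
        assert lt.contact_rate([], 600.0) == 0.0

    def test_rate_zero_duration_signalled(self):
        with pytest.raises(MetricError):
            lt.contact_rate([], 0.0)


class TestRegionAssignment:
    RM = lt.RegionModel({
        "SPF": [lt.Box((50.0, 50.0, 10.0), (100.0, 100.0, 20.0))],
        "FM": [lt.Box((50.0, 50.0, 35.0), (100.0, 100.0, 30.0))],
        "GC": [lt.Sphere((50.0, 50.0, 80.0), 25.0)],
    })

    def test_track_inside_gc(self):
        tr = make_track("g", [[50, 50, 80], [55, 50, 80]])
        assert lt.assign_tracks_to_regions(lt.TrackSet((tr,)), self.RM)["g"] == "GC"

    def test_majority_in_spf(self):
        # 3 of 5 points in the SPF slab, 2 in FM
        zs = [5.0, 10.0, 15.0, 30.0, 40.0]
        tr = make_track("m", [[50, 50, z] for z in zs])
        assert lt.assign_tracks_to_regions(lt.TrackSet((tr,)), self.RM)["m"] == "SPF"

    def test_outside_everything_is_other(self):
        tr = make_track("o", [[500, 500, 500], [510, 500, 500]])
        assert lt.assign_tracks_to_regions(lt.TrackSet((tr,)), self.RM)["o"] == "other"

    def test_tie_broken_by_first_point(self):
        tr = make_track("t", [[50, 50, 30.0], [50, 50, 10.0]])  # 1 FM then 1 SPF
        assert lt.assign_tracks_to_regions(lt.TrackSet((tr,)), self.RM)["t"] == "FM"

    def test_matches_point_membership_oracle(self, rng):
        tracks = tuple(
            make_track(f"r{i}", rng.uniform(0, 100, size=(9, 3)))
            for i in range(20))
        ts = lt.TrackSet(tracks)
        got = lt.assign_tracks_to_regions(ts, self.RM)
        for tr in ts:
            labels = []
            for p in tr.xyz:
                lab = "other"
                for name, prims in self.RM.regions.items():
                    if any(prim.contains(p[None, :])[0] for prim in prims):
                        lab = name
                        break
                labels.append(lab)
            counts = {l: labels.count(l) for l in set(labels)}
            best = max(counts.values())
            winners = {l for l, c in counts.items() if c == best}
            assert got[tr.track_id] in winners


class TestResidenceTime:
    def test_half_life_48h_gives_69h_residence(self):
        lam = LN2 / 48.0
        ps = lt.make_photoconversion_series(lam, [24.0, 48.0, 72.0, 96.0])
        est = lt.estimate_residence_time(ps)
        assert est.half_life == pytest.approx(48.0)
        assert est.residence_time == pytest.approx(48.0 / LN2)
        assert round(est.residence_time) == 69

    def test_noiseless_recovery_exact_with_r2_one(self):
        lam = 0.031
        ps = lt.make_photoconversion_series(lam, [10.0, 20.0, 40.0, 80.0])
        est = lt.estimate_residence_time(ps)
        assert est.lambda_rate == pytest.approx(lam, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0)

    def test_identity_residence_times_ln2_is_half_life(self):
        ps = lt.make_photoconversion_series(0.02, [5.0, 25.0, 60.0])
        est = lt.estimate_residence_time(ps)
        assert est.residence_time * LN2 == pytest.approx(est.half_life)

    def test_no_decay_signalled(self):
        ps = lt.PhotoconversionSeries([0.0, 24.0, 48.0], [100, 150, 220], [100, 100, 100])
        with pytest.raises(MetricError, match="decay"):
            lt.estimate_residence_time(ps)

    def test_poisson_noise_recovery_within_5_percent(self):
        """Median recovered half-life over 1000 noisy replicates within 5%."""
        lam = LN2 / 48.0
        times = [24.0, 48.0, 72.0, 96.0]
        recovered = []
        for rep in range(1000):
            ps = lt.make_photoconversion_series(
                lam, times, n0=2000.0, noise="poisson", seed=rep)
            try:
                recovered.append(lt.estimate_residence_time(ps).half_life)
            except MetricError:
                continue
        assert len(recovered) > 950
        assert abs(np.median(recovered) - 48.0) / 48.0 < 0.05
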