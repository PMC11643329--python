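"""Tracking, condensate membership, and MSD against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from solidhub import simulate, smt
from solidhub.io import Localization, Trajectory, UndefinedValueError

from conftest import truth_class_of_trajectory


def loc(frame, x, y, **kw):
    return Localization(frame=frame, x=float(x), y=float(y), **kw)


# ---------------------------------------------------------------------------
# oracles


def oracle_match(prev_xy, curr_xy, cap):
    """Exhaustive max-cardinality, min-cost matching under the distance cap."""
    cap2 = cap * cap
    feas = [
        [j for j in range(len(curr_xy))
         if (prev_xy[i][0] - curr_xy[j][0]) ** 2
            + (prev_xy[i][1] - curr_xy[j][1]) ** 2 <= cap2]
        for i in range(len(prev_xy))
    ]
    best = {"key": None, "links": {}}

    def rec(i, used, links, cost):
        if i == len(prev_xy):
            key = (-len(links), cost)
            if best["key"] is None or key < best["key"]:
                best["key"], best["links"] = key, dict(links)
            return
        rec(i + 1, used, links, cost)  # leave i unmatched
        for j in feas[i]:
            if j not in used:
                d2 = ((prev_xy[i][0] - curr_xy[j][0]) ** 2
                      + (prev_xy[i][1] - curr_xy[j][1]) ** 2)
                links[i] = j
                rec(i + 1, used | {j}, links, cost + d2)
                del links[i]

    rec(0, frozenset(), {}, 0.0)
    return best["links"]


def links_of(trajs):
    """Set of ((frame,x,y) -> (frame,x,y)) links made by the tracker."""
    out = set()
    for t in trajs:
        for a, b in zip(t.points, t.points[1:]):
            out.add(((a.frame, a.x, a.y), (b.frame, b.x, b.y)))
    return out


# ---------------------------------------------------------------------------
# linking


class TestLinking:
    def test_single_stationary_particle_one_track(self):
        locs = [loc(f, 0, 0) for f in range(3)]
        trajs = smt.link_trajectories(locs)
        assert len(trajs) == 1 and len(trajs[0]) == 3

    def test_cap_splits_distant_points(self):
        locs = [loc(0, 0, 0), loc(1, 500, 0)]
        trajs = smt.link_trajectories(locs, max_link_distance=400)
        assert sorted(len(t) for t in trajs) == [1, 1]
        trajs = smt.link_trajectories(locs, max_link_distance=600)
        assert [len(t) for t in trajs] == [2]

    def test_no_link_spans_more_than_one_frame(self):
        locs = [loc(0, 0, 0), loc(2, 0, 0)]  # frame 1 missing
        trajs = smt.link_trajectories(locs)
        assert sorted(len(t) for t in trajs) == [1, 1]

    def test_channels_and_cells_tracked_separately(self):
        locs = [loc(0, 0, 0, channel=0), loc(1, 0, 0, channel=1)]
        assert len(smt.link_trajectories(locs)) == 2

    def test_partition_property(self, smt_mixture):
        locs, _ = smt_mixture
        trajs = smt.link_trajectories(locs)
        assert sum(len(t) for t in trajs) == len(locs)
        cap = 400.0
        for t in trajs:
            xy = t.xy()
            if len(xy) > 1:
                steps = np.hypot(*(xy[1:] - xy[:-1]).T)
                assert steps.max() <= cap + 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_assignment_oracle(self, seed):
        """Hungarian frame-pair links equal brute-force min-cost matching."""
        rng = np.random.default_rng(seed)
        n, n_frames, cap = 6, 15, 400.0
        frames = [rng.uniform(0, 1500, size=(n, 2)) for _ in range(n_frames)]
        locs = [loc(f, x, y) for f, pts in enumerate(frames) for x, y in pts]
        got = links_of(smt.link_trajectories(locs, max_link_distance=cap))
        want = set()
        for f in range(n_frames - 1):
            m = oracle_match(frames[f], frames[f + 1], cap)
            for i, j in m.items():
                want.add(((f, *frames[f][i]), (f + 1, *frames[f + 1][j])))
        assert got == want


class TestFilter:
    def test_boundary_point_counts(self):
        t5 = Trajectory(0, [loc(f, 0, 0) for f in range(5)])   # 4 steps, 80 ms
        t6 = Trajectory(1, [loc(f, 0, 0) for f in range(6)])
        kept = smt.filter_trajectories([t5, t6], min_points=5, min_duration_ms=80.0)
        assert [t.id for t in kept] == [0, 1]
        kept = smt.filter_trajectories([t5, t6], min_points=6, min_duration_ms=80.0)
        assert [t.id for t in kept] == [1]

    def test_matches_predicate_oracle(self):
        rng = np.random.default_rng(0)
        trajs = []
        for i in range(100):
            n = int(rng.integers(1, 12))
            trajs.append(Trajectory(i, [loc(f, 0, 0) for f in range(n)]))
        kept = smt.filter_trajectories(trajs, min_points=5, min_duration_ms=80.0)
        want = [t for t in trajs if len(t) >= 5 and (len(t) - 1) * 20.0 >= 80.0]
        assert kept == want


# ---------------------------------------------------------------------------
# condensate membership


class TestFlagging:
    def test_six_coincident_points_all_flagged(self):
        locs = [loc(f, 10, 10) for f in range(6)]
        flags = smt.flag_condensate_localizations(locs)
        assert flags.in_condensate.all()
        assert set(flags.cluster_id) == {0}

    def test_five_coincident_points_not_flagged_strict_rule(self):
        # 4 neighbors each does NOT exceed the >4 threshold
        locs = [loc(f, 0, 0) for f in range(5)]
        flags = smt.flag_condensate_localizations(locs)
        assert not flags.in_condensate.any()
        flags = smt.flag_condensate_localizations(locs, strict=False)
        assert flags.in_condensate.all()

    def test_isolated_point_unflagged(self):
        locs = [loc(f, 10, 10) for f in range(6)] + [loc(0, 1000, 1000)]
        flags = smt.flag_condensate_localizations(locs)
        assert not flags.in_condensate[-1]
        assert flags.cluster_id[-1] == -1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 60, size=(500, 2))
        locs = [loc(0, x, y) for x, y in xy]
        flags = smt.flag_condensate_localizations(locs, radius=7.5, min_neighbors=4)
        d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
        counts = (d <= 7.5).sum(axis=1) - 1
        np.testing.assert_array_equal(flags.in_condensate, counts > 4)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_radius_and_threshold(self, seed):
        rng = np.random.default_rng(seed)
        locs = [loc(0, x, y) for x, y in rng.uniform(0, 40, size=(200, 2))]
        base = smt.flag_condensate_localizations(locs, radius=7.5, min_neighbors=4)
        wider = smt.flag_condensate_localizations(locs, radius=10.0, min_neighbors=4)
        looser = smt.flag_condensate_localizations(locs, radius=7.5, min_neighbors=3)
        assert (base.in_condensate <= wider.in_condensate).all()
        assert (base.in_condensate <= looser.in_condensate).all()

    def test_clusters_are_single_linkage_components(self):
        # two tight clumps 100 nm apart -> two clusters
        locs = ([loc(f, 0, 0) for f in range(6)]
                + [loc(f, 100, 0) for f in range(6)])
        flags = smt.flag_condensate_localizations(locs)
        ids = flags.cluster_id
        assert len(set(ids[:6])) == 1 and len(set(ids[6:])) == 1
        assert ids[0] != ids[6]


class TestClassification:
    def test_all_or_none_flagged(self):
        locs = [loc(f, 0, 0) for f in range(6)]
        trajs = smt.link_trajectories(locs)
        flags = smt.flag_condensate_localizations(locs)
        assert smt.classify_trajectories(trajs, flags)[trajs[0].id] == "condensate"
        far = [loc(f, f * 50.0, 0) for f in range(6)]
        trajs = smt.link_trajectories(far)
        flags = smt.flag_condensate_localizations(far)
        assert smt.classify_trajectories(trajs, flags)[trajs[0].id] == "free"

    def test_recovers_planted_labels(self, smt_mixture):
        locs, truth = smt_mixture
        trajs = smt.link_trajectories(locs)
        flags = smt.flag_condensate_localizations(locs)
        classes = smt.classify_trajectories(trajs, flags)
        correct = sum(
            classes[t.id] == truth_class_of_trajectory(t, locs, truth)
            for t in trajs
        )
        assert correct / len(trajs) >= 0.95

    def test_fraction_in_condensates(self, smt_mixture):
        locs, truth = smt_mixture
        flags = smt.flag_condensate_localizations(locs)
        frac = smt.fraction_in_condensates(flags)
        planted = float(np.mean(truth.label == "bound"))
        assert frac == pytest.approx(planted, abs=0.05)
        with pytest.raises(UndefinedValueError):
            smt.fraction_in_condensates(
                smt.flag_condensate_localizations([])
            )


# ---------------------------------------------------------------------------
# displacement statistics


class TestMsd:
    def test_stationary_is_zero(self):
        t = Trajectory(0, [loc(f, 5, 5) for f in range(10)])
        curve = smt.msd_curve([t], 20.0)
        assert np.allclose(curve.msd_mean, 0.0)

    def test_uniform_linear_motion_closed_form(self):
        s = 100.0  # nm per frame
        t = Trajectory(0, [loc(f, f * s, 0) for f in range(12)])
        curve = smt.msd_curve([t], 20.0)
        for k, (lag, m) in enumerate(zip(curve.lags_ms, curve.msd_mean), start=1):
            assert m == pytest.approx((k * s / 1000.0) ** 2, rel=1e-9)

    def test_brownian_tracks_recover_4dt(self):
        d = 0.5
        locs, truth = simulate.gen_smt_localizations(0, 300, d, 0.0, 51, seed=21)
        trajs = simulate.trajectories_from_truth(locs, truth)
        curve = smt.msd_curve(trajs, 20.0, max_lag_ms=100.0)
        for lag, m in zip(curve.lags_ms, curve.msd_mean):
            assert m == pytest.approx(4.0 * d * lag / 1000.0, rel=0.05)
        # free-population slope recovers D within 10%
        slope = np.polyfit(curve.lags_ms / 1000.0, curve.msd_mean, 1)[0]
        assert slope / 4.0 == pytest.approx(d, rel=0.10)

    def test_sd_undefined_with_single_trajectory(self):
        t = Trajectory(0, [loc(f, f * 10.0, 0) for f in range(5)])
        curve = smt.msd_curve([t], 20.0)
        assert np.isnan(curve.msd_sd).all()
        assert (curve.n_trajectories == 1).all()

    def test_rms_displacement_sqrt_scale(self):
        curve = smt.MSDCurve(np.array([80.0]), np.array([0.16]),
                             np.array([np.nan]), np.array([1]))
        assert smt.rms_displacement(curve, 80.0) == pytest.approx(400.0)
        curve.msd_mean[0] = 0.1225
        assert smt.rms_displacement(curve, 80.0) == pytest.approx(350.0)
        curve.msd_mean[0] = 0.0
        assert smt.rms_displacement(curve, 80.0) == 0.0
        with pytest.raises(KeyError):
            smt.rms_displacement(curve, 60.0)

    def test_bound_population_noise_ceiling(self, smt_mixture):
        """Immobile molecules' RMS motion is bounded by localization noise."""
        locs, truth = smt_mixture
        trajs = simulate.trajectories_from_truth(locs, truth)
        bound = [t for t in trajs if truth.track_label[t.id] == "bound"]
        curve = smt.msd_curve(bound, 20.0)
        sigma = truth.sigma_loc_nm
        ceiling = math.sqrt(2.0) * math.sqrt(math.pi / 2.0) * sigma * 2.0
        for lag in curve.lags_ms:
            assert smt.rms_displacement(curve, lag) <= ceiling

    def test_mean_displacement_matches_direct_average(self):
        t = Trajectory(0, [loc(f, f * 30.0, 40.0 * f) for f in range(6)])
        # steps of 50 nm -> at lag 2 frames, displacement 100 nm
        assert smt.mean_displacement([t], 40.0, 20.0) == pytest.approx(100.0)
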