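"""Snapshots, instance selection, membership matrices, assignment, lifecycle."""

from itertools import permutations

import numpy as np
import pytest

from spiketrack.classifiers import DissimilarityVector
from spiketrack.isih import build_isih
from spiketrack.tracker import (
    ACTIVE,
    DROPPED,
    MembershipMatrices,
    Profile,
    ProfileDB,
    TrackerConfig,
    UnitSnapshot,
    assign,
    build_matrices,
    pair_dissimilarity,
    select_instance_fmd,
    select_instance_mmd,
    snapshot,
    track_session,
    update_profiles,
)
from spiketrack.waveform import (
    SpikeUnit,
    Waveform,
    average_waveform,
    peak_height_dissimilarity,
    peak_matching_dissimilarity,
    peak_time_dissimilarity,
    smooth_waveform,
)

from conftest import biphasic, make_unit

CFG = TrackerConfig(feature_set_id=4)


class PHThresholdModel:
    """Stub classifier: match iff the PH component is below a threshold.

    Score is threshold - PH, so closer amplitudes score higher; lets tests
    steer match patterns exactly by choosing waveform amplitudes.
    """

    feature_set_id = 4

    def __init__(self, threshold=0.2):
        self.threshold = threshold
        self.calls = 0

    def score_one(self, x: DissimilarityVector) -> float:
        self.calls += 1
        return self.threshold - float(x.values[list(x.names).index("PH")])


def snap_from_scale(scale, day=0, channel=0, label=0, rng=None):
    """Snapshot with a biphasic waveform scaled to a chosen amplitude."""
    w = Waveform(biphasic().samples * scale)
    t = np.arange(50) * 0.02 + 0.01
    return UnitSnapshot(day=day, channel_id=channel, unit_label=label,
                        waveform=w, isih=build_isih(t), spike_count=50)


class TestSnapshot:
    def test_two_spike_hand_mean(self):
        tpl = biphasic().samples
        unit = SpikeUnit(0, 0, 0, np.stack([tpl - 1.0, tpl + 1.0]),
                         np.array([0.01, 0.03]))
        cfg = TrackerConfig(feature_set_id=4, smoothing_sigma=0.0)
        s = snapshot(unit, cfg)
        np.testing.assert_allclose(s.waveform.samples, tpl)
        assert s.spike_count == 2 and s.isih is not None

    def test_single_spike_has_no_isih(self):
        unit = SpikeUnit(0, 0, 0, biphasic().samples[None, :], np.array([0.5]))
        s = snapshot(unit, CFG)
        assert s.isih is None and s.spike_count == 1

    def test_fields_equal_recomputed_features(self, rng):
        unit = make_unit(rng)
        s = snapshot(unit, CFG)
        expected = smooth_waveform(average_waveform(unit), CFG.smoothing_sigma)
        np.testing.assert_array_equal(s.waveform.samples, expected.samples)
        np.testing.assert_array_equal(
            s.isih.probabilities, build_isih(unit.timestamps, CFG.binning).probabilities
        )


class TestPairDissimilarity:
    def test_self_pair_is_zero(self, rng):
        s = snapshot(make_unit(rng), CFG)
        for fsid in (1, 2, 3, 4):
            v = pair_dissimilarity(s, s, fsid)
            np.testing.assert_allclose(v.values, 0.0, atol=1e-12)

    def test_components_equal_per_measure_calls(self, rng):
        a = snapshot(make_unit(rng), CFG)
        b = snapshot(make_unit(rng, template=biphasic(trough=-550.0, pc=30.0).samples), CFG)
        v = pair_dissimilarity(a, b, 4)
        assert v.values[0] == peak_height_dissimilarity(a.waveform, b.waveform)
        assert v.values[1] == peak_time_dissimilarity(a.waveform, b.waveform)
        assert v.values[2] == peak_matching_dissimilarity(a.waveform, b.waveform)

    def test_isih_feature_set_needs_isih(self):
        a = UnitSnapshot(0, 0, 0, biphasic(), None, 1)
        with pytest.raises(ValueError, match="ISIH"):
            pair_dissimilarity(a, a, 3)

    def test_cross_channel_rejected(self, rng):
        a = snapshot(make_unit(rng, channel=0), CFG)
        b = snapshot(make_unit(rng, channel=1), CFG)
        with pytest.raises(ValueError, match="channel"):
            pair_dissimilarity(a, b, 4)


def profile_with_scales(scales, first_day=0, channel=0, pid=0):
    insts = [snap_from_scale(s, day=first_day + k, channel=channel)
             for k, s in enumerate(scales)]
    return Profile(profile_id=pid, channel_id=channel, instances=insts,
                   status=ACTIVE, last_seen_day=insts[-1].day)


class TestInstanceSelection:
    def test_fmd_stops_at_first_match(self):
        p = profile_with_scales([1.0, 1.0, 1.0])  # newest instance matches
        u = snap_from_scale(1.0, day=3)
        model = PHThresholdModel()
        match, calls = select_instance_fmd(p, u, model, CFG)
        assert match is not None and calls == 1
        assert match.instance_day == 2  # newest first

    def test_fmd_no_match_bounded_calls(self):
        p = profile_with_scales([1.0] * 9)  # 9 instances, only 7 in window
        u = snap_from_scale(3.0, day=9)
        model = PHThresholdModel()
        match, calls = select_instance_fmd(p, u, model, CFG)
        assert match is None and calls <= 7

    def test_fmd_returns_vector_of_matching_instance(self):
        # days 0..4 with only day 2 amplitude-compatible with the unit
        p = profile_with_scales([3.0, 3.0, 1.0, 3.0, 3.0])
        u = snap_from_scale(1.05, day=5)
        match, _ = select_instance_fmd(p, u, PHThresholdModel(), CFG)
        assert match.instance_day == 2
        expected = pair_dissimilarity(u, p.instances[2], 4)
        np.testing.assert_array_equal(match.vector.values, expected.values)

    def test_mmd_picks_maximum_score(self):
        # two matching instances; day-1 amplitude closer to the unit's
        p = profile_with_scales([1.1, 1.0, 3.0])
        u = snap_from_scale(1.0, day=3)
        match, calls = select_instance_mmd(p, u, PHThresholdModel(), CFG)
        assert match.instance_day == 1 and calls == 3

    def test_mmd_equals_bruteforce_argmax_and_costs_at_least_fmd(self, rng):
        for _ in range(20):
            scales = rng.uniform(0.8, 2.5, size=rng.integers(1, 8))
            p = profile_with_scales(list(scales))
            u = snap_from_scale(float(rng.uniform(0.8, 2.5)), day=len(scales))
            m_f = PHThresholdModel()
            m_m = PHThresholdModel()
            fmd, calls_f = select_instance_fmd(p, u, m_f, CFG)
            mmd, calls_m = select_instance_mmd(p, u, m_m, CFG)
            assert calls_m >= calls_f
            # brute-force oracle over all in-window instances
            oracle = PHThresholdModel()
            best = None
            for inst in p.instances:
                s = oracle.score_one(pair_dissimilarity(u, inst, 4))
                if s > 0 and (best is None or s > best[0]):
                    best = (s, inst.day)
            if best is None:
                assert mmd is None
            else:
                assert mmd is not None and (mmd.score, mmd.instance_day) == best

    def test_single_instance_fmd_equals_mmd(self):
        p = profile_with_scales([1.0])
        u = snap_from_scale(1.1, day=1)
        f, _ = select_instance_fmd(p, u, PHThresholdModel(), CFG)
        m, _ = select_instance_mmd(p, u, PHThresholdModel(), CFG)
        assert f.instance_day == m.instance_day and f.score == m.score


def brute_force_assignment(mem, scores, profile_ids, unit_labels):
    """Exhaustive lexicographic optimum over all one-to-one partial matchings."""
    m, n = mem.shape
    best = None
    rows = list(range(m))
    for k in range(min(m, n), -1, -1):
        # all ways to pick k units and k profiles in some order
        from itertools import combinations

        options = []
        for units_sel in combinations(range(n), k):
            for prof_perm in permutations(rows, k):
                if all(mem[i, j] for i, j in zip(prof_perm, units_sel)):
                    pairs = tuple(zip(prof_perm, units_sel))
                    ssum = sum(scores[i, j] for i, j in pairs)
                    key = tuple(sorted((profile_ids[i], unit_labels[j]) for i, j in pairs))
                    options.append((ssum, key, pairs))
        if options:
            best_sum = max(o[0] for o in options)
            near = [o for o in options if o[0] >= best_sum - 1e-12]
            best = min(near, key=lambda o: o[1])
            return k, best
    return 0, (0.0, (), ())


def matrices_from(mem, scores):
    m, n = mem.shape
    return MembershipMatrices(
        profile_ids=list(range(10, 10 + m)),
        unit_labels=list(range(n)),
        dis_mat=[[None] * n for _ in range(m)],
        score_mat=scores,
        mem_mat=mem,
    )


class TestAssignment:
    def test_all_false_gives_empty_matching(self):
        mm = assign(matrices_from(np.zeros((3, 2), bool), np.full((3, 2), np.nan)))
        assert mm.mem_mat_star.sum() == 0

    def test_hand_two_by_two(self):
        mem = np.array([[True, True], [False, True]])
        scores = np.array([[0.9, 0.4], [np.nan, 0.8]])
        mm = assign(matrices_from(mem, scores))
        # cardinality 2 beats the single 0.9 + 0.4 alternative orderings
        assert mm.mem_mat_star[0, 0] and mm.mem_mat_star[1, 1]
        assert mm.mem_mat_star.sum() == 2

    def test_random_matrices_match_bruteforce(self, rng):
        for _ in range(60):
            m, n = rng.integers(1, 6, size=2)
            mem = rng.random((m, n)) < 0.5
            scores = np.where(mem, rng.normal(0.5, 0.5, size=(m, n)), np.nan)
            mm = assign(matrices_from(mem, scores))
            star = mm.mem_mat_star
            assert np.all(star <= mem)
            assert star.sum(axis=0).max(initial=0) <= 1
            assert star.sum(axis=1).max(initial=0) <= 1
            card, (ssum, key, _) = brute_force_assignment(
                mem, scores, mm.profile_ids, mm.unit_labels)
            got_pairs = [(i, j) for i, j in zip(*np.nonzero(star))]
            got_sum = sum(scores[i, j] for i, j in got_pairs)
            got_key = tuple(sorted(
                (mm.profile_ids[i], mm.unit_labels[j]) for i, j in got_pairs))
            assert len(got_pairs) == card
            assert got_sum == pytest.approx(ssum, abs=1e-9)
            assert got_key == key


class TestProfileLifecycle:
    def test_unmatched_units_spawn_profiles(self):
        units = [snap_from_scale(1.0, day=0, label=k) for k in range(3)]
        mm = assign(matrices_from(np.zeros((0, 3), bool), np.empty((0, 3))))
        profiles, next_id, recs = update_profiles([], units, mm, 0, CFG, 0)
        assert len(profiles) == 3 and next_id == 3
        assert all(r["decision"] == "new" for r in recs)

    def test_profile_dropped_beyond_window(self):
        p = profile_with_scales([1.0], first_day=0)
        mm = assign(matrices_from(np.zeros((1, 0), bool), np.empty((1, 0))))
        update_profiles([p], [], mm, 7, CFG, 1)
        assert p.status == ACTIVE  # unseen for exactly the window: still active
        update_profiles([p], [], mm, 8, CFG, 1)
        assert p.status == DROPPED

    def test_duplicate_instance_same_day_rejected(self):
        p = profile_with_scales([1.0], first_day=5)
        u = snap_from_scale(1.0, day=5, label=1)
        mm = matrices_from(np.array([[True]]), np.array([[0.5]]))
        mm = assign(mm)
        mm.profile_ids[0] = p.profile_id
        with pytest.raises(ValueError, match="already has an instance"):
            update_profiles([p], [u], mm, 5, CFG, 1)


class TestTrackSession:
    def session_from_scales(self, rng, scales_by_channel, day):
        session = {}
        for chan, scales in scales_by_channel.items():
            session[chan] = [
                make_unit(rng, channel=chan, day=day, label=k,
                          template=biphasic().samples * s, noise=1.0)
                for k, s in enumerate(scales)
            ]
        return session

    def test_first_session_creates_all_profiles(self, rng):
        db = ProfileDB()
        session = self.session_from_scales(rng, {0: [1.0, 2.0], 1: [1.5]}, day=0)
        report = track_session(db, session, PHThresholdModel(), CFG)
        assert (report.frame["decision"] == "new").all()
        assert len(db.profiles(0)) == 2 and len(db.profiles(1)) == 1

    def test_identical_session_fully_reassigned(self, rng):
        db = ProfileDB()
        scales = {0: [1.0, 2.0], 1: [1.5, 0.6]}
        track_session(db, self.session_from_scales(rng, scales, 0), PHThresholdModel(), CFG)
        report = track_session(db, self.session_from_scales(rng, scales, 1),
                               PHThresholdModel(), CFG)
        assert (report.frame["decision"] == "matched").all()
        assert len(db.profiles(0)) == 2 and len(db.profiles(1)) == 2

    def test_channel_errors_are_isolated(self, rng):
        db = ProfileDB()
        model = PHThresholdModel()
        track_session(db, self.session_from_scales(rng, {0: [1.0], 1: [1.0]}, 0),
                      model, CFG)
        # day 1: a flat (degenerate) unit on channel 1 breaks its features;
        # channel 0 still tracks normally
        session = self.session_from_scales(rng, {0: [1.0]}, day=1)
        session[1] = [SpikeUnit(1, 1, 0, np.full((3, 48), 5.0),
                                np.array([0.1, 0.2, 0.3]))]
        report = track_session(db, session, model, CFG)
        assert 1 in report.errors and 0 not in report.errors
        assert (report.frame["channel"] == 0).all()
        assert (report.frame["decision"] == "matched").all()

    def test_model_config_feature_set_mismatch(self, rng):
        model = PHThresholdModel()
        model.feature_set_id = 2
        with pytest.raises(ValueError, match="feature set"):
            track_session(ProfileDB(), {}, model, CFG, day=0)

    def test_dropped_profiles_never_compared_again(self, rng):
        db = ProfileDB()
        model = PHThresholdModel()
        # day 0: two units; afterwards unit 1 disappears for good
        track_session(db, self.session_from_scales(rng, {0: [1.0, 3.0]}, 0), model, CFG)
        dropped_ids = set()
        for day in range(1, 14):
            report = track_session(
                db, self.session_from_scales(rng, {0: [1.0]}, day), model, CFG)
            for pid in report.compared_profiles.get(0, []):
                assert pid not in dropped_ids
            dropped_ids |= {p.profile_id for p in db.profiles(0) if p.status == DROPPED}
        assert dropped_ids  # the vanished unit's profile was eventually dropped
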