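import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_gps
from homestay import preprocess
from homestay.config import PipelineConfig
from homestay.preprocess import (AWAY, GAP, HomeUndeterminedError, completeness,
                                 detect_stays, haversine, infer_home, locf_impute)

CFG = PipelineConfig()


# ---------------------------------------------------------------------------
# independent brute-force reference for the sequential scan

def brute_force_labels(t, lat, lon, spatial_m, min_dwell_s, split_gap_s):
    """Naive re-derivation of per-fix stay/travel labels.

    Enumerates maximal left-to-right runs whose members all joined while
    within ``spatial_m`` of the run centroid (recomputed from scratch at
    every step with plain Python arithmetic), splitting at time gaps longer
    than ``split_gap_s``; runs spanning >= ``min_dwell_s`` are stays.
    Returns a list of run (start_idx, end_idx, is_stay).
    """
    def dist(la1, lo1, la2, lo2):
        rl1, rl2 = math.radians(la1), math.radians(la2)
        a = (math.sin(math.radians(la2 - la1) / 2) ** 2
             + math.cos(rl1) * math.cos(rl2)
             * math.sin(math.radians(lo2 - lo1) / 2) ** 2)
        return 6_371_000.0 * 2 * math.asin(math.sqrt(min(1.0, a)))

    runs = []
    i = 0
    n = len(t)
    while i < n:
        members = [i]
        j = i + 1
        while j < n:
            if t[j] - t[j - 1] > split_gap_s:
                break
            c_lat = sum(lat[m] for m in members) / len(members)
            c_lon = sum(lon[m] for m in members) / len(members)
            if dist(lat[j], lon[j], c_lat, c_lon) <= spatial_m:
                members.append(j)
                j += 1
            else:
                break
        i0, i1 = members[0], members[-1]
        runs.append((i0, i1, t[i1] - t[i0] >= min_dwell_s))
        i = i1 + 1
    return runs


def random_trajectory(rng, max_fixes=80):
    """Random walk mixing dwell phases and travel, with occasional gaps."""
    n = int(rng.integers(5, max_fixes))
    lat0, lon0 = 38.0, -78.5
    t, lat, lon = [], [], []
    clock = 0.0
    cur_lat, cur_lon = lat0, lon0
    while len(t) < n:
        mode = rng.choice(["dwell", "travel", "gap"], p=[0.5, 0.35, 0.15])
        if mode == "gap":
            # whole seconds so timestamps stay exact through ns quantisation
            clock += float(rng.integers(300, 4000))
            continue
        steps = int(rng.integers(1, 12))
        for _ in range(min(steps, n - len(t))):
            if mode == "travel":
                cur_lat += rng.normal(0, 60) / 111_320
                cur_lon += rng.normal(0, 60) / 111_320
            jitter_lat = cur_lat + rng.normal(0, 5) / 111_320
            jitter_lon = cur_lon + rng.normal(0, 5) / 111_320
            t.append(clock)
            lat.append(jitter_lat)
            lon.append(jitter_lon)
            clock += 150.0
        if mode == "dwell" and rng.uniform() < 0.5:
            cur_lat += rng.uniform(100, 600) / 111_320  # jump to a new place
    return np.array(t), np.array(lat), np.array(lon)


def assert_matches_oracle(t, lat, lon, cfg=CFG):
    runs = brute_force_labels(t, lat, lon, cfg.spatial_threshold_m,
                              cfg.min_dwell_s, cfg.merge_gap_s)
    expected = np.full(len(t), AWAY, dtype=object)
    for i0, i1, is_stay in runs:
        if is_stay:
            expected[i0:i1 + 1] = "stay"
    pre = detect_stays(make_gps(t, lat, lon), cfg)
    got = np.where(np.isin(pre.fix_labels, [AWAY, GAP]), AWAY, "stay")
    np.testing.assert_array_equal(got, expected)


class TestHaversine:
    def test_identity(self):
        assert haversine(38.0, -78.5, 38.0, -78.5) == 0.0

    def test_meridian_arc(self):
        # 0.001 deg of latitude at the equator: R * pi/180 * 0.001
        expected = 6_371_000.0 * math.pi / 180 * 0.001
        assert haversine(0.0, 0.0, 0.001, 0.0) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(111.2, abs=0.1)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.uniform([-80, -170], [80, 170])
            b = rng.uniform([-80, -170], [80, 170])
            assert haversine(*a, *b) == pytest.approx(haversine(*b, *a), rel=1e-12)

    def test_vectorised(self):
        lats = np.array([38.0, 39.0])
        out = haversine(lats, -78.5, 38.0, -78.5)
        assert out.shape == (2,)
        assert out[0] == 0.0


class TestDetectStays:
    def test_single_stationary_visit(self):
        n = 20
        fixes = make_gps(np.arange(n) * 150, [38.0] * n, [-78.5] * n)
        pre = detect_stays(fixes, CFG)
        assert len(pre.clusters) == 1
        assert len(pre.stays) == 1
        dwell = (pre.stays["end"][0] - pre.stays["start"][0]).total_seconds()
        assert dwell == pytest.approx(19 * 150, abs=160)

    def test_constant_travel_yields_no_clusters(self):
        n = 40
        lat = 38.0 + np.arange(n) * 50 / 111_320  # 50 m per 150 s
        fixes = make_gps(np.arange(n) * 150, lat, [-78.5] * n)
        pre = detect_stays(fixes, CFG)
        assert len(pre.clusters) == 0
        assert (pre.fix_labels == AWAY).all()

    def test_empty_and_single_fix(self):
        empty = detect_stays(make_gps([], [], []), CFG)
        assert len(empty.stays) == 0
        one = detect_stays(make_gps([0.0], [38.0], [-78.5]), CFG)
        assert len(one.stays) == 0

    def test_revisit_merged_within_temporal_threshold(self):
        # 40 min home, 20 min excursion 500 m away, 40 min home again
        far = 38.0 + 500 / 111_320
        t = np.concatenate([np.arange(16) * 150,            # 0-37.5 min home
                            2400 + np.arange(8) * 150,       # 40-57.5 min away
                            3600 + np.arange(16) * 150])     # 60-97.5 min home
        lat = np.concatenate([[38.0] * 16, [far] * 8, [38.0] * 16])
        fixes = make_gps(t, lat, [-78.5] * 40)
        pre = detect_stays(fixes, CFG)
        # far point dwelt >= 5 min: kept as its own cluster
        assert len(pre.clusters) == 2
        home_stays = pre.stays[pre.stays["cluster"] == 0]
        assert len(home_stays) == 1  # merged: the revisit gap is ~22 min

    def test_revisit_not_merged_beyond_threshold(self):
        far = 38.0 + 500 / 111_320
        gap = 2400 + 8 * 150 + 2000  # second home visit starts ~33 min later
        t = np.concatenate([np.arange(16) * 150,
                            2400 + np.arange(8) * 150,
                            np.arange(16) * 150 + gap + 3600])
        lat = np.concatenate([[38.0] * 16, [far] * 8, [38.0] * 16])
        fixes = make_gps(t, lat, [-78.5] * 40)
        pre = detect_stays(fixes, CFG)
        home_stays = pre.stays[pre.stays["cluster"] == 0]
        assert len(home_stays) == 2

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t, lat, lon = random_trajectory(rng)
        assert_matches_oracle(t, lat, lon)

    def test_conservation_of_time(self, small_cohort, small_pipe_cfg):
        gps = small_cohort.gps
        pid = gps["participant"].iloc[0]
        fixes = gps[gps["participant"] == pid].reset_index(drop=True)
        pre = detect_stays(fixes, small_pipe_cfg)
        tl = pre.timeline
        span = (tl["end"].iloc[-1] - tl["start"].iloc[0]).total_seconds()
        total = (tl["end"] - tl["start"]).dt.total_seconds().sum()
        assert total == pytest.approx(span, abs=1e-6)
        # segments tile the observation span with no overlap
        assert (tl["start"].iloc[1:].to_numpy() == tl["end"].iloc[:-1].to_numpy()).all()


class TestInferHome:
    def _pre_with_night(self, night_lat):
        # night at `night_lat`, afternoon at another place
        t = np.concatenate([np.arange(48) * 600,               # 00:00-08:00
                            12 * 3600 + np.arange(24) * 600])  # 12:00-16:00
        lat = np.concatenate([[night_lat] * 48, [38.2] * 24])
        return make_gps(t, lat, [-78.5] * 72)

    def test_single_cluster_with_night_presence(self):
        fixes = self._pre_with_night(38.0)
        pre = detect_stays(fixes, CFG)
        home = infer_home(pre, fixes, CFG)
        row = pre.clusters[pre.clusters["cluster"] == home].iloc[0]
        assert row["lat"] == pytest.approx(38.0, abs=1e-3)

    def test_majority_wins(self):
        # cluster A: 5 h of night; cluster B: 1 h of night
        t = np.arange(72) * 300  # 00:00-06:00
        lat = np.concatenate([[38.0] * 60, [38.2] * 12])
        fixes = make_gps(t, lat, [-78.5] * 72)
        pre = detect_stays(fixes, CFG)
        home = infer_home(pre, fixes, CFG)
        row = pre.clusters[pre.clusters["cluster"] == home].iloc[0]
        assert row["lat"] == pytest.approx(38.0, abs=1e-3)

    def test_tie_broken_by_dwell(self):
        # equal night fixes; cluster at 38.2 gets extra daytime dwell
        t = np.concatenate([np.arange(24) * 300,
                            7200 + np.arange(24) * 300,
                            12 * 3600 + np.arange(24) * 300])
        lat = np.concatenate([[38.0] * 24, [38.2] * 24, [38.2] * 24])
        fixes = make_gps(t, lat, [-78.5] * 72)
        pre = detect_stays(fixes, CFG)
        home = infer_home(pre, fixes, CFG)
        row = pre.clusters[pre.clusters["cluster"] == home].iloc[0]
        assert row["lat"] == pytest.approx(38.2, abs=1e-3)

    def test_no_night_fixes_raises(self):
        t = 12 * 3600 + np.arange(24) * 300  # midday only
        fixes = make_gps(t, [38.0] * 24, [-78.5] * 24)
        pre = detect_stays(fixes, CFG)
        with pytest.raises(HomeUndeterminedError, match="p001"):
            infer_home(pre, fixes, CFG)

    def test_recovers_true_home_on_synthetic_cohort(self, small_cohort,
                                                    small_preprocessed):
        truth = small_cohort.truth["participants"]
        home = small_preprocessed["home"]
        assert len(home) == len(truth)
        for _, row in home.iterrows():
            true_lat, true_lon = truth[row["participant"]]["home"]
            d = haversine(row["lat"], row["lon"], true_lat, true_lon)
            assert d < 30.0


class TestLocf:
    def _tl(self, rows):
        return pd.DataFrame({
            "start": pd.to_datetime([r[0] for r in rows], utc=True),
            "end": pd.to_datetime([r[1] for r in rows], utc=True),
            "label": [r[2] for r in rows],
        })

    def test_locf_definition(self):
        tl = self._tl([("2017-02-06T00:00", "2017-02-06T01:00", "0"),
                       ("2017-02-06T01:00", "2017-02-06T02:00", GAP),
                       ("2017-02-06T02:00", "2017-02-06T03:00", AWAY)])
        out = locf_impute(tl)
        assert list(out["label"]) == ["0", AWAY]  # gap merged into home
        assert (out["end"][0] - out["start"][0]).total_seconds() == 7200

    def test_leading_gap_unchanged(self):
        tl = self._tl([("2017-02-06T00:00", "2017-02-06T01:00", GAP),
                       ("2017-02-06T01:00", "2017-02-06T02:00", "0")])
        out = locf_impute(tl)
        assert list(out["label"]) == [GAP, "0"]

    def test_gapless_identity(self):
        tl = self._tl([("2017-02-06T00:00", "2017-02-06T01:00", "0"),
                       ("2017-02-06T01:00", "2017-02-06T02:00", AWAY)])
        pd.testing.assert_frame_equal(locf_impute(tl), tl)

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            labels = rng.choice(["0", "1", AWAY, GAP], size=10)
            times = pd.date_range("2017-02-06", periods=11, freq="1h", tz="UTC")
            tl = pd.DataFrame({"start": times[:-1], "end": times[1:],
                               "label": labels})
            once = locf_impute(tl)
            twice = locf_impute(once)
            pd.testing.assert_frame_equal(twice, once)

    def test_carry_cap(self):
        tl = self._tl([("2017-02-06T00:00", "2017-02-06T01:00", "0"),
                       ("2017-02-06T01:00", "2017-02-06T05:00", GAP)])
        out = locf_impute(tl, locf_max_s=3600)
        assert list(out["label"]) == ["0", GAP]
        assert (out["end"][0] - out["start"][0]).total_seconds() == 7200


class TestCompleteness:
    W0 = pd.Timestamp("2017-02-06T10:00:00-05:00")
    W1 = pd.Timestamp("2017-02-06T18:00:00-05:00")

    def test_full_coverage_denominator_192(self):
        t = 10 * 3600 + np.arange(192) * 150
        fixes = make_gps(t, [38.0] * 192, [-78.5] * 192)
        assert preprocess.possible_fixes(8 * 3600, 150) == 192
        assert completeness(fixes, self.W0, self.W1, 150) == 1.0

    def test_no_fixes(self):
        fixes = make_gps([0.0], [38.0], [-78.5])  # midnight only
        assert completeness(fixes, self.W0, self.W1, 150) == 0.0

    def test_half(self):
        t = 10 * 3600 + np.arange(96) * 150
        fixes = make_gps(t, [38.0] * 96, [-78.5] * 96)
        assert completeness(fixes, self.W0, self.W1, 150) == 0.5

    def test_zero_length_window_rejected(self):
        fixes = make_gps([0.0], [38.0], [-78.5])
        with pytest.raises(ValueError):
            completeness(fixes, self.W0, self.W0, 150)

    def test_cohort_table(self, small_cohort, small_preprocessed):
        comp = small_preprocessed["completeness"]
        assert set(comp.columns) == {"participant", "date", "n_fixes",
                                     "possible", "fraction"}
        assert comp["fraction"].between(0, 1).all()
        assert (comp["possible"] == 48).all()  # 8 h at 600 s sampling
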