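"""Raw GPS fixes -> labeled stays, inferred home, imputed timeline.

Stay detection is a sequential scan: consecutive fixes whose distance to the
running group centroid stays within the spatial threshold (30 m) form a
group; groups spanning at least the minimum dwell (5 min) become visits,
shorter groups are travel.  Successive visits to the same locality separated
by no more than the temporal threshold (30 min) are merged into one episode,
and visits are agglomerated across the study into stay clusters by centroid
proximity.

Timelines are built from per-fix coverage: a fix covers the time until the
next fix, capped at ``fix_cover_max_s``; uncovered time is GAP.  Gaps are
filled by carrying the last observed label forward (:func:`locf_impute`);
a leading gap has nothing to carry and stays GAP.

All intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "EARTH_RADIUS_M", "AWAY", "GAP",
    "haversine", "detect_stays", "infer_home", "locf_impute",
    "completeness", "completeness_table", "preprocess_participant",
    "preprocess_cohort", "HomeUndeterminedError", "ParticipantPreprocess",
]

EARTH_RADIUS_M = 6_371_000.0
AWAY = "AWAY"
GAP = "GAP"


class HomeUndeterminedError(ValueError):
    """No nighttime fix was assigned to any stay cluster."""


def haversine(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres (vectorises over numpy arrays)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_M * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _haversine_scalar(lat1, lon1, lat2, lon2) -> float:
    rl1, rl2 = math.radians(lat1), math.radians(lat2)
    a = (math.sin(math.radians(lat2 - lat1) / 2) ** 2
         + math.cos(rl1) * math.cos(rl2) * math.sin(math.radians(lon2 - lon1) / 2) ** 2)
    return EARTH_RADIUS_M * 2 * math.asin(math.sqrt(min(1.0, a)))


@dataclass
class ParticipantPreprocess:
    participant: str
    stays: pd.DataFrame        # cluster, start, end  (merged visit episodes)
    clusters: pd.DataFrame     # cluster, lat, lon, total_dwell_s, night_fixes
    timeline: pd.DataFrame     # start, end, label
    home_cluster: int | None
    fix_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))


def _scan_groups(t: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                 spatial_m: float, split_gap_s: float) -> list[tuple[int, int]]:
    """Maximal runs of fixes within ``spatial_m`` of the running centroid.

    Runs are also split at time gaps larger than ``split_gap_s`` so a visit
    never silently spans an unobserved excursion.
    """
    groups: list[tuple[int, int]] = []
    n = len(t)
    if n == 0:
        return groups
    start = 0
    s_lat, s_lon, cnt = lat[0], lon[0], 1
    for i in range(1, n):
        if t[i] - t[i - 1] > split_gap_s:
            groups.append((start, i - 1))
            start, s_lat, s_lon, cnt = i, lat[i], lon[i], 1
            continue
        if _haversine_scalar(lat[i], lon[i], s_lat / cnt, s_lon / cnt) <= spatial_m:
            s_lat += lat[i]
            s_lon += lon[i]
            cnt += 1
        else:
            groups.append((start, i - 1))
            start, s_lat, s_lon, cnt = i, lat[i], lon[i], 1
    groups.append((start, n - 1))
    return groups


def detect_stays(fixes: pd.DataFrame, cfg: PipelineConfig) -> ParticipantPreprocess:
    """Cluster one participant's sorted fixes into stays and a labeled timeline."""
    pid = str(fixes["participant"].iloc[0]) if len(fixes) else ""
    t = fixes["time"].astype("int64").to_numpy() / 1e9 if len(fixes) else np.empty(0)
    lat = fixes["lat"].to_numpy(dtype=float) if len(fixes) else np.empty(0)
    lon = fixes["lon"].to_numpy(dtype=float) if len(fixes) else np.empty(0)
    n = len(t)

    empty_cols = {"cluster": pd.Series(dtype=int), "start": pd.Series(dtype="datetime64[ns, UTC]"),
                  "end": pd.Series(dtype="datetime64[ns, UTC]")}
    if n == 0:
        return ParticipantPreprocess(
            participant=pid,
            stays=pd.DataFrame(empty_cols),
            clusters=pd.DataFrame({"cluster": pd.Series(dtype=int), "lat": [], "lon": [],
                                   "total_dwell_s": [], "night_fixes": []}),
            timeline=pd.DataFrame({"start": pd.Series(dtype="datetime64[ns, UTC]"),
                                   "end": pd.Series(dtype="datetime64[ns, UTC]"), "label": []}),
            home_cluster=None)

    # per-fix coverage [t_i, cover_end_i)
    cover_end = np.empty(n)
    cover_end[:-1] = np.minimum(t[1:], t[:-1] + cfg.fix_cover_max_s)
    cover_end[-1] = t[-1] + cfg.gps_interval
    cover = cover_end - t

    groups = _scan_groups(t, lat, lon, cfg.spatial_threshold_m, cfg.merge_gap_s)

    # visits: groups spanning at least the minimum dwell
    visits = []  # (i0, i1, w_lat, w_lon, dwell)
    for i0, i1 in groups:
        if t[i1] - t[i0] >= cfg.min_dwell_s:
            w = cover[i0:i1 + 1]
            dwell = float(w.sum())
            visits.append({
                "i0": i0, "i1": i1, "dwell": dwell,
                "lat": float(np.average(lat[i0:i1 + 1], weights=w)),
                "lon": float(np.average(lon[i0:i1 + 1], weights=w)),
            })

    # agglomerate visits into clusters by dwell-weighted centroid proximity
    clusters: list[dict] = []
    for v in visits:
        best, best_d = None, float("inf")
        for c in clusters:
            d = _haversine_scalar(v["lat"], v["lon"], c["lat"], c["lon"])
            if d <= cfg.spatial_threshold_m and d < best_d:
                best, best_d = c, d
        if best is None:
            best = {"id": len(clusters), "lat": v["lat"], "lon": v["lon"],
                    "dwell": 0.0, "visits": []}
            clusters.append(best)
        w_old, w_new = best["dwell"], v["dwell"]
        tot = w_old + w_new
        best["lat"] = (best["lat"] * w_old + v["lat"] * w_new) / tot
        best["lon"] = (best["lon"] * w_old + v["lon"] * w_new) / tot
        best["dwell"] = tot
        best["visits"].append(v)
        v["cluster"] = best["id"]

    # merge successive visits to the same locality separated by no more than
    # the temporal threshold (an excursion in between does not break the
    # episode; dwell bookkeeping stays per-fix, so nothing double-counts)
    stay_rows: list[dict] = []
    prev_by_cluster: dict[int, dict] = {}
    for v in visits:
        cid = v["cluster"]
        start, end = t[v["i0"]], cover_end[v["i1"]]
        prev = prev_by_cluster.get(cid)
        if prev is not None and start - prev["end"] <= cfg.merge_gap_s:
            prev["end"] = end
        else:
            row = {"cluster": cid, "start": start, "end": end}
            stay_rows.append(row)
            prev_by_cluster[cid] = row

    # fix labels
    labels = np.full(n, AWAY, dtype=object)
    for v in visits:
        labels[v["i0"]:v["i1"] + 1] = str(v["cluster"])

    # timeline segments from fix coverage; uncovered time is GAP
    seg_start, seg_end, seg_label = [], [], []
    for i in range(n):
        if seg_label and seg_label[-1] == labels[i] and seg_end[-1] == t[i]:
            seg_end[-1] = cover_end[i]
        else:
            seg_start.append(t[i])
            seg_end.append(cover_end[i])
            seg_label.append(labels[i])
        if i + 1 < n and cover_end[i] < t[i + 1]:
            seg_start.append(cover_end[i])
            seg_end.append(t[i + 1])
            seg_label.append(GAP)

    def _ts(arr):
        return pd.to_datetime(np.asarray(arr, dtype=float), unit="s", utc=True)

    stays_df = pd.DataFrame({
        "cluster": [r["cluster"] for r in stay_rows],
        "start": _ts([r["start"] for r in stay_rows]),
        "end": _ts([r["end"] for r in stay_rows]),
    }) if stay_rows else pd.DataFrame(empty_cols)

    clusters_df = pd.DataFrame({
        "cluster": [c["id"] for c in clusters],
        "lat": [c["lat"] for c in clusters],
        "lon": [c["lon"] for c in clusters],
        "total_dwell_s": [c["dwell"] for c in clusters],
        "night_fixes": 0,
    })

    timeline_df = pd.DataFrame({"start": _ts(seg_start), "end": _ts(seg_end),
                                "label": seg_label})

    out = ParticipantPreprocess(participant=pid, stays=stays_df,
                                clusters=clusters_df, timeline=timeline_df,
                                home_cluster=None, fix_labels=labels)
    out._fix_times = t          # kept for home inference / audits
    out._fix_cover = cover
    return out


def infer_home(pre: ParticipantPreprocess, fixes: pd.DataFrame,
               cfg: PipelineConfig) -> int:
    """Home = cluster holding the most nighttime (00:00-06:00 local) fixes.

    Ties break deterministically: larger total dwell, then smaller id.
    """
    if len(pre.clusters) == 0:
        raise HomeUndeterminedError(
            f"participant {pre.participant}: no stay clusters at all")
    tz = ZoneInfo(cfg.timezone)
    local_hours = fixes["time"].dt.tz_convert(tz).dt.hour.to_numpy()
    night = (local_hours >= cfg.night_start_hour) & (local_hours < cfg.night_end_hour)
    counts: dict[int, int] = {}
    for lab, is_night in zip(pre.fix_labels, night):
        if is_night and lab not in (AWAY, GAP):
            counts[int(lab)] = counts.get(int(lab), 0) + 1
    if not counts:
        raise HomeUndeterminedError(
            f"participant {pre.participant}: no nighttime fixes assigned to a cluster")
    pre.clusters["night_fixes"] = pre.clusters["cluster"].map(counts).fillna(0).astype(int)
    dwell = dict(zip(pre.clusters["cluster"], pre.clusters["total_dwell_s"]))
    home = min(counts, key=lambda c: (-counts[c], -dwell.get(c, 0.0), c))
    pre.home_cluster = home
    return home


def locf_impute(timeline: pd.DataFrame, locf_max_s: float = 0.0) -> pd.DataFrame:
    """Relabel GAP segments with the preceding segment's label.

    A leading gap stays GAP (nothing to carry).  ``locf_max_s > 0`` caps the
    carry: longer gaps keep only their first ``locf_max_s`` seconds imputed.
    Idempotent.
    """
    if len(timeline) == 0:
        return timeline.copy()
    starts = list(timeline["start"])
    ends = list(timeline["end"])
    labels = list(timeline["label"])
    rows: list[tuple] = []
    prev_label = None
    for s, e, lab in zip(starts, ends, labels):
        if lab == GAP and prev_label is not None:
            length = (e - s).total_seconds()
            if locf_max_s > 0 and length > locf_max_s:
                cut = s + pd.Timedelta(seconds=locf_max_s)
                rows.append((s, cut, prev_label))
                rows.append((cut, e, GAP))
                prev_label = None
                continue
            lab = prev_label
        if lab != GAP:
            prev_label = lab
        rows.append((s, e, lab))
    out_s, out_e, out_l = [], [], []
    for s, e, lab in rows:
        if out_l and out_l[-1] == lab and out_e[-1] == s:
            out_e[-1] = e
        else:
            out_s.append(s); out_e.append(e); out_l.append(lab)
    return pd.DataFrame({"start": out_s, "end": out_e, "label": out_l})


def completeness(fixes: pd.DataFrame, window_start, window_end,
                 gps_interval: float = 150.0) -> float:
    """Observed fixes in the window over the maximum possible, capped at 1."""
    span = (window_end - window_start).total_seconds()
    if span <= 0:
        raise ValueError("window must have positive length")
    possible = span / gps_interval
    t = fixes["time"]
    observed = int(((t >= window_start) & (t < window_end)).sum())
    return min(1.0, observed / possible)


def possible_fixes(window_seconds: float, gps_interval: float = 150.0) -> int:
    """Completeness denominator: sampling slots in a window."""
    return int(window_seconds / gps_interval)


def completeness_table(fixes: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Per participant-day completeness over the daytime audit window."""
    tz = ZoneInfo(cfg.timezone)
    rows = []
    for pid, grp in fixes.groupby("participant", sort=True):
        local = grp["time"].dt.tz_convert(tz)
        dates = local.dt.date
        for day in sorted(set(dates)):
            w0 = pd.Timestamp(day, tz=tz) + pd.Timedelta(hours=cfg.day_start_hour)
            w1 = pd.Timestamp(day, tz=tz) + pd.Timedelta(hours=cfg.day_end_hour)
            span = (w1 - w0).total_seconds()
            possible = possible_fixes(span, cfg.gps_interval)
            n_obs = int(((grp["time"] >= w0) & (grp["time"] < w1)).sum())
            rows.append({"participant": pid, "date": str(day), "n_fixes": n_obs,
                         "possible": possible,
                         "fraction": min(1.0, n_obs / possible)})
    return pd.DataFrame(rows)


def preprocess_participant(fixes: pd.DataFrame, cfg: PipelineConfig) -> ParticipantPreprocess:
    pre = detect_stays(fixes, cfg)
    if len(pre.clusters):
        infer_home(pre, fixes, cfg)
    pre.timeline = locf_impute(pre.timeline, cfg.locf_max_s)
    return pre


def preprocess_cohort(gps: pd.DataFrame, cfg: PipelineConfig,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run preprocessing per participant and stack the outputs.

    Returns ``(stays, home, timeline, completeness)`` frames.
    """
    stays_frames, home_rows, timeline_frames = [], [], []
    for pid, grp in gps.groupby("participant", sort=True):
        grp = grp.reset_index(drop=True)
        pre = preprocess_participant(grp, cfg)
        if pre.home_cluster is None:
            raise HomeUndeterminedError(
                f"participant {pid}: home location could not be determined")
        st = pre.stays.copy()
        st.insert(0, "participant", pid)
        stays_frames.append(st)
        hc = pre.clusters[pre.clusters["cluster"] == pre.home_cluster].iloc[0]
        home_rows.append({"participant": pid, "cluster": int(hc["cluster"]),
                          "lat": float(hc["lat"]), "lon": float(hc["lon"]),
                          "night_fix_count": int(hc["night_fixes"])})
        tl = pre.timeline.copy()
        tl.insert(0, "participant", pid)
        timeline_frames.append(tl)
    stays = pd.concat(stays_frames, ignore_index=True)
    home = pd.DataFrame(home_rows)
    timeline = pd.concat(timeline_frames, ignore_index=True)
    comp = completeness_table(gps, cfg)
    return stays, home, timeline, comp
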