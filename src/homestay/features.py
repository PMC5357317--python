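"""Analysis windows and homestay/affect variables for all temporal framings.

Two window kinds are produced:

``prompt_pair``
    Each same-local-day pair of consecutive answered prompts no more than
    4 hours apart yields one window ``[t1, t2)``; its affect values are the
    change scores (second minus first) and its homestay measures cover that
    span.  Wider pairs are discarded and counted.

``daily``
    Each study day's 10:00-18:00 local window carries that day's homestay;
    its affect values are the calendar day's mean ratings.  Every affect day
    is paired with the same-day, next-day and previous-day homestay window
    (``lag`` 0 / +1 / -1; edge days produce only the feasible lags).

Homestay within a window is home-labeled time divided by observed (non-GAP,
post-imputation) time, normalised by the participant's study-wide average
(the ratio of totals over all daily windows, so the dwell-weighted mean of
daily fractions reproduces it exactly), log-transformed with a configurable
epsilon, plus the any-home binary coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .preprocess import GAP

__all__ = [
    "FeatureDiagnostics", "build_features", "homestay_for_window",
    "personal_average", "window_home_observed",
]

FEATURE_COLUMNS = ["participant", "kind", "lag", "start", "end", "length_s",
                   "frac", "ratio", "log_ratio", "any_home", "na_value", "pa_value"]


@dataclass
class FeatureDiagnostics:
    """Bookkeeping for rows that could not be formed."""

    discarded_pairs: int = 0          # prompt pairs wider than the 4 h cap
    total_pairs: int = 0
    dropped_windows: int = 0          # windows with no observed (non-GAP) time
    excluded_participants: list[str] = field(default_factory=list)

    @property
    def discard_share(self) -> float:
        return self.discarded_pairs / self.total_pairs if self.total_pairs else 0.0


def window_home_observed(seg_start: np.ndarray, seg_end: np.ndarray,
                         is_home: np.ndarray, is_gap: np.ndarray,
                         w0: float, w1: float) -> tuple[float, float]:
    """Seconds at home and seconds observed within ``[w0, w1)``."""
    overlap = np.clip(np.minimum(seg_end, w1) - np.maximum(seg_start, w0), 0.0, None)
    observed = float(overlap[~is_gap].sum())
    home = float(overlap[is_home].sum())
    return home, observed


def homestay_for_window(home_s: float, observed_s: float, personal_avg: float,
                        epsilon: float) -> dict | None:
    """Homestay measures for one window; None if the window is unobserved."""
    if observed_s <= 0:
        return None
    frac = home_s / observed_s
    ratio = frac / personal_avg
    return {
        "frac": frac,
        "ratio": ratio,
        "log_ratio": float(np.log(ratio + epsilon)),
        "any_home": int(frac > 0),
    }


def personal_average(daily_home: np.ndarray, daily_observed: np.ndarray) -> float:
    """Study-wide home fraction: total home time over total observed time."""
    total_obs = float(daily_observed.sum())
    if total_obs <= 0:
        return float("nan")
    return float(daily_home.sum()) / total_obs


def _timeline_arrays(tl: pd.DataFrame, home_label: str):
    seg_start = tl["start"].astype("int64").to_numpy() / 1e9
    seg_end = tl["end"].astype("int64").to_numpy() / 1e9
    labels = tl["label"].astype(str).to_numpy()
    return seg_start, seg_end, labels == home_label, labels == GAP


def build_features(ema: pd.DataFrame, timeline: pd.DataFrame, home: pd.DataFrame,
                   cfg: PipelineConfig) -> tuple[pd.DataFrame, FeatureDiagnostics]:
    """Assemble the per-window analysis rows for a whole cohort."""
    tz = ZoneInfo(cfg.timezone)
    diag = FeatureDiagnostics()
    home_by_pid = {str(r["participant"]): str(int(r["cluster"]))
                   for _, r in home.iterrows()}
    rows: list[dict] = []

    for pid, tl in timeline.groupby("participant", sort=True):
        pid = str(pid)
        if pid not in home_by_pid:
            diag.excluded_participants.append(pid)
            continue
        seg_start, seg_end, is_home, is_gap = _timeline_arrays(tl, home_by_pid[pid])

        # study days = local dates spanned by the timeline
        first_local = tl["start"].iloc[0].tz_convert(tz)
        last_local = tl["end"].iloc[-1].tz_convert(tz)
        days = pd.date_range(first_local.normalize(), last_local.normalize(), freq="D")

        daily = {}  # date -> (w0_epoch, w1_epoch, home_s, observed_s)
        for day in days:
            w0 = (day + pd.Timedelta(hours=cfg.day_start_hour)).timestamp()
            w1 = (day + pd.Timedelta(hours=cfg.day_end_hour)).timestamp()
            h, o = window_home_observed(seg_start, seg_end, is_home, is_gap, w0, w1)
            if o > 0:
                daily[day.date()] = (w0, w1, h, o)
            else:
                diag.dropped_windows += 1
        if not daily:
            diag.excluded_participants.append(pid)
            continue
        p_avg = personal_average(np.array([v[2] for v in daily.values()]),
                                 np.array([v[3] for v in daily.values()]))
        if not p_avg > 0:
            diag.excluded_participants.append(pid)
            continue

        p_ema = ema[ema["participant"] == pid]
        local_times = p_ema["time"].dt.tz_convert(tz)

        # ---- prompt-pair windows -------------------------------------
        dates = local_times.dt.date.to_numpy()
        times = p_ema["time"].to_numpy()
        na = p_ema["na"].to_numpy(dtype=float)
        pa = p_ema["pa"].to_numpy(dtype=float)
        for i in range(len(p_ema) - 1):
            if dates[i + 1] != dates[i]:
                continue
            diag.total_pairs += 1
            span = (times[i + 1] - times[i]) / np.timedelta64(1, "s")
            if span > cfg.max_pair_span_s:
                diag.discarded_pairs += 1
                continue
            w0 = pd.Timestamp(times[i]).timestamp()
            w1 = pd.Timestamp(times[i + 1]).timestamp()
            h, o = window_home_observed(seg_start, seg_end, is_home, is_gap, w0, w1)
            meas = homestay_for_window(h, o, p_avg, cfg.log_epsilon)
            if meas is None:
                diag.dropped_windows += 1
                continue
            rows.append({"participant": pid, "kind": "prompt_pair", "lag": np.nan,
                         "start": pd.Timestamp(times[i]), "end": pd.Timestamp(times[i + 1]),
                         "length_s": float(span),
                         "na_value": na[i + 1] - na[i], "pa_value": pa[i + 1] - pa[i],
                         **meas})

        # ---- daily windows with lags ---------------------------------
        day_means = (pd.DataFrame({"date": dates, "na": na, "pa": pa})
                     .groupby("date")[["na", "pa"]].mean()) if len(p_ema) else None
        if day_means is None or len(day_means) == 0:
            continue
        for affect_date, mrow in day_means.iterrows():
            for lag in (-1, 0, 1):
                target = affect_date + pd.Timedelta(days=lag)
                if target not in daily:
                    continue
                w0, w1, h, o = daily[target]
                meas = homestay_for_window(h, o, p_avg, cfg.log_epsilon)
                rows.append({"participant": pid, "kind": "daily", "lag": lag,
                             "start": pd.Timestamp(w0, unit="s", tz="UTC"),
                             "end": pd.Timestamp(w1, unit="s", tz="UTC"),
                             "length_s": w1 - w0,
                             "na_value": float(mrow["na"]), "pa_value": float(mrow["pa"]),
                             **meas})

    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return features, diag


def write_features(features: pd.DataFrame, path) -> None:
    out = features.copy()
    for col in ("start", "end"):
        out[col] = out[col].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str})
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col], utc=True, format="ISO8601")
    return df
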