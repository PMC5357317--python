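"""Synthetic cohort generator with known ground truth.

Produces GPS fix streams, EMA affect ratings and baseline trait scores whose
statistical structure matches what the downstream pipeline assumes: each
participant has a fixed home, is at home overnight (00:00-06:00 local,
relaxable), and on each day realises a latent *daytime home propensity*
``p_d`` — the exact fraction of the 10:00-18:00 window spent at home.  State
affect is generated from that same latent propensity, so the coupling between
homestay and affect (and its moderation by social anxiety) is configurable
and exactly known for recovery tests.

Mobility is episode-based: each day is tiled by contiguous home/away
episodes, which makes ground-truth homestay exact rather than a property of
a random walk.  GPS fixes are laid on a regular grid anchored at local
midnight, jittered isotropically, with missingness inserted as contiguous
gap runs (exponential lengths) because carry-forward imputation behaves
differently on runs than on isolated drops.

Randomness: one global integer seed; participant ``i`` draws from the
substream ``(seed, i)``, so growing the cohort never reshuffles existing
participants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io as hio
from .config import SimConfig

__all__ = [
    "LatentParticipant", "SimulationResult",
    "generate_traits", "generate_day_propensities", "generate_day_schedule",
    "generate_gps", "generate_ema", "simulate_cohort", "write_cohort",
]

_M_PER_DEG_LAT = 111_320.0
HOME = "home"

SIAS_RANGE = (0.0, 80.0)
DASS_RANGE = (0.0, 21.0)


# ---------------------------------------------------------------------------
# traits

def _calibrated_mu(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter of a [lo, hi]-truncated normal whose mean is exact.

    Truncating a normal at the instrument floor shifts its mean upward; for
    scales whose mean sits within ~1.5 SD of the floor the shift is well
    outside Monte-Carlo error, so the location is solved for numerically
    instead of being set to the target.
    """
    if sd == 0:
        return target_mean

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))

    lo_mu, hi_mu = target_mean - 6 * sd, target_mean + 6 * sd
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo_mu, hi_mu,
                                 xtol=1e-10))


def _draw_truncated(rng: np.random.Generator, n: int, target_mean: float,
                    sd: float, lo: float, hi: float) -> np.ndarray:
    if sd == 0:
        return np.full(n, float(target_mean))
    mu = _calibrated_mu(target_mean, sd, lo, hi)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=n)
    return mu + sd * stats.norm.ppf(u)


def generate_traits(config: SimConfig, rng: np.random.Generator | None = None,
                    n: int | None = None) -> pd.DataFrame:
    """Draw per-participant SIAS and DASS-depression totals.

    Draws come from range-truncated normals whose truncated means equal the
    configured targets exactly (see :func:`_calibrated_mu`).
    """
    config.validate()
    n = config.n_participants if n is None else n
    rng = np.random.default_rng([config.seed, 987]) if rng is None else rng
    sias = _draw_truncated(rng, n, config.sias_mean, config.sias_sd, *SIAS_RANGE)
    dass = _draw_truncated(rng, n, config.dass_mean, config.dass_sd, *DASS_RANGE)
    return pd.DataFrame({
        "participant": [_pid(i) for i in range(n)],
        "sias": sias,
        "dass_dep": dass,
    })


def _pid(i: int) -> str:
    return f"p{i + 1:03d}"


# ---------------------------------------------------------------------------
# latent participants

@dataclass
class LatentParticipant:
    """Ground-truth state for one simulated participant."""

    id: str
    index: int
    home: tuple[float, float]
    away_places: list[tuple[float, float]]
    sias_true: float
    dass_true: float
    baseline_na: float
    baseline_pa: float
    random_intercept_na: float
    random_intercept_pa: float
    propensities: np.ndarray = field(default_factory=lambda: np.empty(0))


def _offset_latlon(lat: float, lon: float, east_m: float, north_m: float) -> tuple[float, float]:
    dlat = north_m / _M_PER_DEG_LAT
    dlon = east_m / (_M_PER_DEG_LAT * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


def _participant_rng(config: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, index])


def make_participant(config: SimConfig, index: int, sias: float,
                     dass: float) -> LatentParticipant:
    rng = _participant_rng(config, index)
    # homes scattered over a ~6 km box around the campus centre
    home = _offset_latlon(config.center_lat, config.center_lon,
                          rng.uniform(-3000, 3000), rng.uniform(-3000, 3000))
    min_sep = 200.0  # well above 2x the 30 m spatial threshold
    places = []
    for _ in range(max(1, config.n_away_places)):
        dist = rng.uniform(min_sep, 2500.0)
        bearing = rng.uniform(0, 2 * math.pi)
        places.append(_offset_latlon(home[0], home[1],
                                     dist * math.sin(bearing), dist * math.cos(bearing)))
    part = LatentParticipant(
        id=_pid(index),
        index=index,
        home=home,
        away_places=places,
        sias_true=sias,
        dass_true=dass,
        baseline_na=float(np.clip(config.baseline_na_mean + config.baseline_sd * rng.standard_normal(), 0, 100)),
        baseline_pa=float(np.clip(config.baseline_pa_mean + config.baseline_sd * rng.standard_normal(), 0, 100)),
        random_intercept_na=float(config.intercept_sd * rng.standard_normal()),
        random_intercept_pa=float(config.intercept_sd * rng.standard_normal()),
    )
    part.propensities = generate_day_propensities(part, config, rng)
    return part


def generate_day_propensities(participant: LatentParticipant, config: SimConfig,
                              rng: np.random.Generator) -> np.ndarray:
    """Latent daytime home fraction for every study day.

    Mixture: with prob ``1 - away_prob`` the participant never leaves
    (``p=1``); otherwise with prob ``zero_home_prob`` the whole 10:00-18:00
    window is spent away (``p=0``); else a clipped normal around the
    participant's propensity mean.  ``trait_propensity_sias`` shifts that
    mean by SDs of SIAS, giving the between-subjects trait models a
    recoverable signal.
    """
    z_sias = 0.0
    if config.sias_sd > 0:
        z_sias = (participant.sias_true - config.sias_mean) / config.sias_sd
    mean_p = config.home_propensity_mean + config.trait_propensity_sias * z_sias
    out = np.empty(config.n_days)
    for d in range(config.n_days):
        if rng.uniform() >= config.away_prob:
            out[d] = 1.0
        elif rng.uniform() < config.zero_home_prob:
            out[d] = 0.0
        else:
            p = mean_p + config.home_propensity_sd * rng.standard_normal()
            out[d] = float(np.clip(p, 0.02, 1.0))
    return out


# ---------------------------------------------------------------------------
# day schedules

def _tz(config: SimConfig) -> ZoneInfo:
    return ZoneInfo(config.timezone)


def _day_start(config: SimConfig, day: int) -> datetime:
    d = date.fromisoformat(config.start_date) + timedelta(days=day)
    return datetime.combine(d, time(0), tzinfo=_tz(config))


def generate_day_schedule(participant: LatentParticipant, day: int,
                          config: SimConfig, rng: np.random.Generator,
                          ) -> list[tuple[object, datetime, datetime]]:
    """Tile one local civil day with alternating home/away episodes.

    The home fraction of the 10:00-18:00 window equals the day's latent
    propensity *exactly*: the away block runs from ``10:00 + m`` to
    ``18:00 - e`` with ``m + e = 8h * p`` and the split ``m`` random.  Nights
    (00:00-06:00) are at home unless ``night_at_home`` is relaxed.
    """
    p = float(participant.propensities[day])
    t0 = _day_start(config, day)
    t24 = t0 + timedelta(days=1)
    place = participant.away_places[int(rng.integers(len(participant.away_places)))]

    episodes: list[tuple[object, datetime, datetime]]
    if p >= 1.0:
        episodes = [(HOME, t0, t24)]
    else:
        if p <= 0.0:
            leave = t0 + timedelta(hours=10) - timedelta(seconds=rng.uniform(0, 7200))
            back = t0 + timedelta(hours=18) + timedelta(seconds=rng.uniform(0, 7200))
        else:
            home_secs = 8 * 3600.0 * p
            morning = rng.uniform(0, home_secs)
            leave = t0 + timedelta(hours=10, seconds=morning)
            back = t0 + timedelta(hours=18, seconds=-(home_secs - morning))
        if (back - leave).total_seconds() < 60:
            episodes = [(HOME, t0, t24)]
        else:
            episodes = [(HOME, t0, leave), (place, leave, back), (HOME, back, t24)]

    if not config.night_at_home and rng.uniform() < 0.3:
        # failure-mode switch: spend the night elsewhere
        night_end = t0 + timedelta(hours=6)
        head = [(place, t0, min(night_end, episodes[0][2]))]
        tail = [(lab, max(s, night_end), e) for lab, s, e in episodes if e > night_end]
        episodes = head + [(lab, s, e) for lab, s, e in tail if e > s]
    return episodes


# ---------------------------------------------------------------------------
# GPS

def _gap_mask(n: int, interval: float, rate: float, mean_gap_s: float,
              rng: np.random.Generator) -> np.ndarray:
    """True where a fix is dropped; alternating exponential observed/gap runs."""
    if rate <= 0:
        return np.zeros(n, dtype=bool)
    if rate >= 1:
        return np.ones(n, dtype=bool)
    mean_obs_s = mean_gap_s * (1 - rate) / rate
    mask = np.zeros(n, dtype=bool)
    pos = 0.0
    total = n * interval
    in_gap = rng.uniform() < rate
    while pos < total:
        run = rng.exponential(mean_gap_s if in_gap else mean_obs_s)
        if in_gap:
            i0 = int(pos // interval)
            i1 = min(n, int(math.ceil((pos + run) / interval)))
            mask[i0:i1] = True
        pos += run
        in_gap = not in_gap
    return mask


def generate_gps(participant: LatentParticipant, config: SimConfig,
                 rng: np.random.Generator) -> tuple[pd.DataFrame, list]:
    """All GPS fixes for one participant; also returns the episode list."""
    interval = config.gps_interval
    rows_t: list[np.ndarray] = []
    rows_lat: list[np.ndarray] = []
    rows_lon: list[np.ndarray] = []
    all_episodes = []
    for day in range(config.n_days):
        episodes = generate_day_schedule(participant, day, config, rng)
        all_episodes.append(episodes)
        t0 = episodes[0][1]
        day_len = (episodes[-1][2] - t0).total_seconds()
        n = int(round(day_len / interval))
        offs = np.arange(n) * interval
        lat = np.empty(n)
        lon = np.empty(n)
        for label, s, e in episodes:
            i0 = int(math.ceil((s - t0).total_seconds() / interval))
            i1 = int(math.ceil((e - t0).total_seconds() / interval))
            plat, plon = participant.home if label == HOME else label
            lat[i0:i1] = plat
            lon[i0:i1] = plon
        if config.gps_noise_sd > 0:
            east = rng.normal(0, config.gps_noise_sd, n)
            north = rng.normal(0, config.gps_noise_sd, n)
            lat = lat + north / _M_PER_DEG_LAT
            lon = lon + east / (_M_PER_DEG_LAT * np.cos(np.radians(lat)))
        keep = ~_gap_mask(n, interval, config.missing_rate,
                          config.missing_gap_mean_s, rng)
        epoch = t0.timestamp() + offs
        rows_t.append(epoch[keep])
        rows_lat.append(lat[keep])
        rows_lon.append(lon[keep])
    epoch = np.concatenate(rows_t)
    df = pd.DataFrame({
        "participant": participant.id,
        "time": pd.to_datetime(epoch, unit="s", utc=True),
        "lat": np.concatenate(rows_lat),
        "lon": np.concatenate(rows_lon),
    })
    return df, all_episodes


# ---------------------------------------------------------------------------
# EMA

def _prompt_windows(config: SimConfig) -> list[tuple[int, int]]:
    # six 2-hour windows, 09:00-21:00 local
    k = min(config.prompts_per_day_max, 6)
    return [(9 + 2 * i, 11 + 2 * i) for i in range(k)]


def generate_ema(participant: LatentParticipant, config: SimConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """EMA ratings for all study days of one participant.

    At most one prompt per 2-hour window, uniform within it, answered with
    probability ``compliance_rate``.  Affect reads the latent propensity of
    day ``d + coupling_lag`` (clamped to the study span), so lagged
    homestay-affect couplings can be planted.
    """
    z_sias = 0.0
    if config.sias_sd > 0:
        z_sias = (participant.sias_true - config.sias_mean) / config.sias_sd
    rows = []
    for day in range(config.n_days):
        aligned = min(max(day + config.coupling_lag, 0), config.n_days - 1)
        p = float(participant.propensities[aligned])
        slope_na = config.coupling_na + config.moderation_na_sias * z_sias
        slope_pa = config.coupling_pa + config.moderation_pa_sias * z_sias
        mu_na = participant.baseline_na + participant.random_intercept_na + slope_na * p
        mu_pa = participant.baseline_pa + participant.random_intercept_pa + slope_pa * p
        t0 = _day_start(config, day)
        for lo, hi in _prompt_windows(config):
            answered = rng.uniform() < config.compliance_rate
            offset = rng.uniform(lo * 3600.0, hi * 3600.0)
            noise_na = rng.normal(0, config.affect_noise_sd)
            noise_pa = rng.normal(0, config.affect_noise_sd)
            if not answered:
                continue  # draws above keep the stream aligned across configs
            rows.append({
                "participant": participant.id,
                "time": t0 + timedelta(seconds=offset),
                "pa": float(np.clip(mu_pa + noise_pa, 0, 100)),
                "na": float(np.clip(mu_na + noise_na, 0, 100)),
            })
    df = pd.DataFrame(rows, columns=["participant", "time", "pa", "na"])
    if len(df):
        df = df.sort_values(["participant", "time"]).reset_index(drop=True)
        df["time"] = pd.to_datetime(df["time"], utc=True)
    return df


# ---------------------------------------------------------------------------
# cohort

@dataclass
class SimulationResult:
    gps: pd.DataFrame
    ema: pd.DataFrame
    traits: pd.DataFrame
    truth: dict


def simulate_cohort(config: SimConfig) -> SimulationResult:
    """Generate a full cohort: GPS, EMA, traits and the ground-truth sidecar."""
    config.validate()
    traits = generate_traits(config)
    gps_frames, ema_frames = [], []
    truth: dict = {"config_seed": config.seed, "participants": {}}
    for i in range(config.n_participants):
        part = make_participant(config, i, float(traits["sias"][i]),
                                float(traits["dass_dep"][i]))
        rng = np.random.default_rng([config.seed, i, 1])  # data stream, post-latents
        gps, _ = generate_gps(part, config, rng)
        ema = generate_ema(part, config, np.random.default_rng([config.seed, i, 2]))
        gps_frames.append(gps)
        ema_frames.append(ema)
        truth["participants"][part.id] = {
            "home": list(part.home),
            "away_places": [list(pl) for pl in part.away_places],
            "sias": part.sias_true,
            "dass_dep": part.dass_true,
            "baseline_na": part.baseline_na,
            "baseline_pa": part.baseline_pa,
            "random_intercept_na": part.random_intercept_na,
            "random_intercept_pa": part.random_intercept_pa,
            "day_propensities": [float(p) for p in part.propensities],
        }
    gps = pd.concat(gps_frames, ignore_index=True)
    ema = pd.concat([f for f in ema_frames if len(f)], ignore_index=True)
    return SimulationResult(gps=gps, ema=ema, traits=traits, truth=truth)


def write_cohort(result: SimulationResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_gps(result.gps, out / "gps.csv")
    hio.write_ema(result.ema, out / "ema.csv")
    hio.write_traits(result.traits, out / "traits.csv")
    (out / "truth.json").write_text(json.dumps(result.truth, indent=1, sort_keys=True))
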