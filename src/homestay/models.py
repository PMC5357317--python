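"""The model grid: homestay outcomes regressed on state affect and trait
moderators under crossed subject/day random intercepts.

Grid structure: 2 outcome codings (continuous log homestay ratio; binary
any-home) x 4 temporal framings (4-hour change windows; daily homestay with
same-day, previous-day and next-day affect) x 2 affect variables (NA, PA).
Each fit carries the affect main effect plus its interactions with the
z-scored SIAS and DASS-depression moderators, giving 3 reported effects per
affect variable and 48 effects over the whole grid.

Continuous fits z-score predictors and outcome (standardized betas); binary
fits keep the affect variable and outcome on their raw scales
(unstandardized betas) but still z-score the moderators before forming
interactions.  The 4-hour framing adds a subject-grouped random slope on
window length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import glmm, lmm
from .config import PipelineConfig

__all__ = [
    "OUTCOMES", "FRAMINGS", "AFFECTS", "ModelSpec", "FitResult",
    "standardize", "fit_lmm", "fit_glmm_binary", "fit_cell", "fit_grid",
    "fit_trait_models", "marginal_r2", "StandardizationError", "ModelFitError",
    "write_fits", "read_fits",
]

OUTCOMES = ("continuous", "binary")
FRAMINGS = ("change_4h", "same_day", "prev_day", "next_day")
AFFECTS = ("na", "pa")

_FRAMING_FILTER = {
    "change_4h": ("prompt_pair", None),
    "same_day": ("daily", 0),
    "prev_day": ("daily", -1),
    "next_day": ("daily", 1),
}


class StandardizationError(ValueError):
    """A variable has zero variance and cannot be z-scored."""


class ModelFitError(RuntimeError):
    """A model in the grid failed to converge."""


@dataclass(frozen=True)
class ModelSpec:
    outcome: str      # continuous | binary
    framing: str      # change_4h | same_day | prev_day | next_day
    affect: str       # na | pa

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.framing not in FRAMINGS:
            raise ValueError(f"unknown framing {self.framing!r}")
        if self.affect not in AFFECTS:
            raise ValueError(f"unknown affect {self.affect!r}")

    @property
    def label(self) -> str:
        return f"{self.outcome}:{self.framing}:{self.affect}"


@dataclass
class FitResult:
    spec: dict
    terms: list[str]
    beta: list[float]
    se: list[float]
    p: list[float]
    f_stat: list[float] | None     # squared Wald z, continuous outcome only
    f_df: tuple[int, int] | None
    vcomp: dict[str, float]
    sigma2: float | None
    r2_fixed: float | None
    n_obs: int
    n_subjects: int
    n_days: int
    singular: bool
    converged: bool

    def effect(self, term: str) -> tuple[float, float]:
        i = self.terms.index(term)
        return self.beta[i], self.p[i]


def _zscore(values: np.ndarray, name: str) -> np.ndarray:
    sd = float(np.std(values))
    if sd == 0 or not np.isfinite(sd):
        raise StandardizationError(f"variable {name!r} has zero variance")
    return (values - float(np.mean(values))) / sd


def standardize(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Z-score the named columns over the analysis rows (grand mean/SD)."""
    out = table.copy()
    for col in columns:
        out[col] = _zscore(out[col].to_numpy(dtype=float), col)
    return out


def _analysis_table(features: pd.DataFrame, traits: pd.DataFrame,
                    framing: str, timezone: str = "UTC") -> pd.DataFrame:
    kind, lag = _FRAMING_FILTER[framing]
    rows = features[features["kind"] == kind]
    if lag is not None:
        rows = rows[rows["lag"] == lag]
    table = rows.merge(traits, on="participant", how="inner").copy()
    # "day" random factor = local calendar date of the window, crossed
    # across participants
    table["day"] = table["start"].dt.tz_convert(timezone).dt.strftime("%Y-%m-%d")
    table = table.dropna(subset=["na_value", "pa_value", "log_ratio", "any_home",
                                 "sias", "dass_dep"])
    return table.reset_index(drop=True)


def _indicator(codes: pd.Series) -> np.ndarray:
    cats, inv = np.unique(codes.to_numpy(), return_inverse=True)
    Z = np.zeros((len(codes), len(cats)))
    Z[np.arange(len(codes)), inv] = 1.0
    return Z


def _random_blocks(table: pd.DataFrame, framing: str) -> list[tuple[str, np.ndarray]]:
    blocks = [("subject", _indicator(table["participant"])),
              ("day", _indicator(table["day"]))]
    if framing == "change_4h":
        length = table["length_s"].to_numpy(dtype=float)
        sd = np.std(length)
        length_z = (length - length.mean()) / sd if sd > 0 else np.zeros_like(length)
        blocks.append(("length_slope", _indicator(table["participant"]) * length_z[:, None]))
    return blocks


def _design(table: pd.DataFrame, affect: str, standardize_affect: bool,
            ) -> tuple[np.ndarray, list[str]]:
    a = table[f"{affect}_value"].to_numpy(dtype=float)
    if standardize_affect:
        a = _zscore(a, f"{affect}_value")
    sias_z = _zscore(table["sias"].to_numpy(dtype=float), "sias")
    dass_z = _zscore(table["dass_dep"].to_numpy(dtype=float), "dass_dep")
    up = affect.upper()
    X = np.column_stack([np.ones(len(table)), a, sias_z, dass_z, a * sias_z, a * dass_z])
    terms = ["(Intercept)", up, "SIAS", "DASS", f"{up}×SIAS", f"{up}×DASS"]
    return X, terms


def marginal_r2(beta: np.ndarray, X: np.ndarray,
                z_blocks: list[tuple[str, np.ndarray]],
                vcomp: dict[str, float], sigma2: float) -> float:
    """Variance explained by the fixed effects (marginal R-squared).

    var(X beta) over var(X beta) + random-effect variance + residual
    variance, where each component contributes its variance times the mean
    squared row norm of its design block (1 for plain indicators).
    """
    var_fixed = float(np.var(X @ beta))
    var_random = sum(vcomp[nm] * float(np.mean((Z ** 2).sum(axis=1)))
                     for nm, Z in z_blocks)
    total = var_fixed + var_random + sigma2
    return var_fixed / total if total > 0 else 0.0


def fit_lmm(table: pd.DataFrame, X: np.ndarray, terms: list[str],
            z_blocks: list[tuple[str, np.ndarray]], y: np.ndarray,
            spec_label: str) -> lmm.LMMResult:
    _check_grouping(table, spec_label)
    try:
        return lmm.fit_reml(y, X, z_blocks, terms=terms)
    except lmm.ConvergenceError as exc:
        raise ModelFitError(f"model {spec_label} did not converge: {exc}") from exc


def fit_glmm_binary(table: pd.DataFrame, X: np.ndarray, terms: list[str],
                    z_blocks: list[tuple[str, np.ndarray]], y: np.ndarray,
                    spec_label: str) -> glmm.GLMMResult:
    _check_grouping(table, spec_label)
    try:
        return glmm.fit_laplace_logit(y, X, z_blocks, terms=terms)
    except glmm.ConvergenceError as exc:
        raise ModelFitError(f"model {spec_label} did not converge: {exc}") from exc


def _check_grouping(table: pd.DataFrame, spec_label: str,
                    min_subjects: int = 10, min_days: int = 2) -> None:
    n_subj = table["participant"].nunique()
    n_days = table["day"].nunique()
    if n_subj < min_subjects or n_days < min_days:
        raise ModelFitError(
            f"model {spec_label}: needs >= {min_subjects} subjects and >= "
            f"{min_days} days, got {n_subj} subjects / {n_days} days")


def fit_cell(features: pd.DataFrame, traits: pd.DataFrame, spec: ModelSpec,
             cfg: PipelineConfig) -> FitResult:
    """Fit one grid cell and package the estimates."""
    table = _analysis_table(features, traits, spec.framing, cfg.timezone)
    if len(table) == 0:
        raise ModelFitError(f"model {spec.label}: no analysis rows")
    z_blocks = _random_blocks(table, spec.framing)

    if spec.outcome == "continuous":
        X, terms = _design(table, spec.affect, standardize_affect=True)
        y = table["log_ratio"].to_numpy(dtype=float)
        if cfg.standardize_outcome:
            y = _zscore(y, "log_ratio")
        res = fit_lmm(table, X, terms, z_blocks, y, spec.label)
        beta = np.asarray(res.beta)
        r2 = marginal_r2(beta, X, z_blocks, res.vcomp, res.sigma2)
        f_stat = list(np.asarray(res.z) ** 2)
        f_df = (1, res.df_resid)
        sigma2 = res.sigma2
    else:
        X, terms = _design(table, spec.affect, standardize_affect=False)
        y = table["any_home"].to_numpy(dtype=float)
        res = fit_glmm_binary(table, X, terms, z_blocks, y, spec.label)
        r2, f_stat, f_df, sigma2 = None, None, None, None

    return FitResult(
        spec=asdict(spec), terms=res.terms,
        beta=[float(b) for b in res.beta], se=[float(s) for s in res.se],
        p=[float(v) for v in res.p], f_stat=f_stat, f_df=f_df,
        vcomp=res.vcomp, sigma2=sigma2, r2_fixed=r2,
        n_obs=res.n_obs,
        n_subjects=int(table["participant"].nunique()),
        n_days=int(table["day"].nunique()),
        singular=res.singular, converged=res.converged)


def fit_grid(features: pd.DataFrame, traits: pd.DataFrame, cfg: PipelineConfig,
             ) -> dict[tuple[str, str, str], FitResult]:
    """Fit all 16 models (2 outcomes x 4 framings x 2 affect variables)."""
    fits = {}
    for outcome in OUTCOMES:
        for framing in FRAMINGS:
            for affect in AFFECTS:
                spec = ModelSpec(outcome, framing, affect)
                fits[(outcome, framing, affect)] = fit_cell(features, traits, spec, cfg)
    return fits


def fit_trait_models(features: pd.DataFrame, traits: pd.DataFrame,
                     cfg: PipelineConfig) -> dict[tuple[str, str], FitResult]:
    """Between-subjects models: SIAS and DASS jointly predicting homestay.

    Four models: {4-hour windows, daily 10-18 windows} x {continuous
    log(frac + eps), binary}, each with subject and day random intercepts.
    The continuous outcome here is the raw home fraction (not the personal
    ratio), log-transformed, z-scored along with the trait predictors.
    """
    out: dict[tuple[str, str], FitResult] = {}
    for window_kind, framing in (("change_4h", "change_4h"), ("daily", "same_day")):
        table = _analysis_table(features, traits, framing, cfg.timezone)
        if len(table) == 0:
            raise ModelFitError(f"trait model {window_kind}: no analysis rows")
        sias_z = _zscore(table["sias"].to_numpy(dtype=float), "sias")
        dass_z = _zscore(table["dass_dep"].to_numpy(dtype=float), "dass_dep")
        X = np.column_stack([np.ones(len(table)), sias_z, dass_z])
        terms = ["(Intercept)", "SIAS", "DASS"]
        z_blocks = _random_blocks(table, framing)
        for outcome in OUTCOMES:
            label = f"traits:{window_kind}:{outcome}"
            if outcome == "continuous":
                y = np.log(table["frac"].to_numpy(dtype=float) + cfg.log_epsilon)
                y = _zscore(y, "log_frac")
                res = fit_lmm(table, X, terms, z_blocks, y, label)
                r2 = marginal_r2(np.asarray(res.beta), X, z_blocks, res.vcomp, res.sigma2)
                sigma2 = res.sigma2
            else:
                y = table["any_home"].to_numpy(dtype=float)
                res = fit_glmm_binary(table, X, terms, z_blocks, y, label)
                r2, sigma2 = None, None
            out[(window_kind, outcome)] = FitResult(
                spec={"outcome": outcome, "framing": window_kind, "affect": "traits"},
                terms=res.terms, beta=[float(b) for b in res.beta],
                se=[float(s) for s in res.se], p=[float(v) for v in res.p],
                f_stat=None, f_df=None, vcomp=res.vcomp, sigma2=sigma2,
                r2_fixed=r2, n_obs=res.n_obs,
                n_subjects=int(table["participant"].nunique()),
                n_days=int(table["day"].nunique()),
                singular=res.singular, converged=res.converged)
    return out


# ---------------------------------------------------------------------------
# serialisation

def write_fits(fits: dict, path: str | Path) -> None:
    payload = {"|".join(key): asdict(fit) for key, fit in fits.items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_fits(path: str | Path) -> dict[tuple[str, ...], FitResult]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for key, item in payload.items():
        item["f_df"] = tuple(item["f_df"]) if item.get("f_df") else None
        out[tuple(key.split("|"))] = FitResult(**item)
    return out
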