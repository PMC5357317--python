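"""Assemble the 48-effect grid, count significances and run the exact
binomial tail test.

The grid is ordered outcome panel (continuous, then binary) x framing
(change_4h, same_day, prev_day, next_day) x term (NA, NAxSIAS, NAxDASS, PA,
PAxSIAS, PAxDASS).  The binomial test asks how surprising ``k`` significant
effects out of ``n`` would be if each had an independent ``alpha`` chance of
a type-I error; the upper tail is summed exactly rather than approximated,
because the interesting ``k`` sits far out in the tail.

A published 48-effect reference table ships with the package
(``data/reference_effects.csv``) for structural checks; its p-values are
stored as printed, including censored entries like ``<.01``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .models import AFFECTS, FRAMINGS, OUTCOMES, FitResult

__all__ = [
    "EFFECT_TERMS", "BinomialSummary", "assemble_effect_table",
    "binomial_tail", "summarize", "count_significant",
    "load_reference_table", "render_report",
    "REFERENCE_SURVEY_COUNTS",
]

EFFECT_TERMS = ("NA", "NA×SIAS", "NA×DASS", "PA", "PA×SIAS", "PA×DASS")

# Published study bookkeeping used by calibration checks: number of
# random-time surveys collected and the number rendered unanalyzable by the
# 4-hour pairing rule.
REFERENCE_SURVEY_COUNTS = {"total_surveys": 2741, "unanalyzable_surveys": 329}


@dataclass
class BinomialSummary:
    n: int
    k: int
    p0: float
    tail_prob: float


class EffectTableError(ValueError):
    """The grid of fits is incomplete or contains duplicates."""


def assemble_effect_table(fits: dict[tuple[str, str, str], FitResult],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Build the 48-row effect table from the 16 grid fits."""
    seen = set()
    for key in fits:
        if key in seen:
            raise EffectTableError(f"duplicate fit for cell {key}")
        seen.add(key)
    missing = [(o, f, a) for o in OUTCOMES for f in FRAMINGS for a in AFFECTS
               if (o, f, a) not in fits]
    if missing:
        raise EffectTableError(f"missing fits for cells: {missing}")

    rows = []
    for outcome in OUTCOMES:
        for framing in FRAMINGS:
            for affect in AFFECTS:
                fit = fits[(outcome, framing, affect)]
                up = affect.upper()
                for term in (up, f"{up}×SIAS", f"{up}×DASS"):
                    beta, p = fit.effect(term)
                    rows.append({"outcome": outcome, "framing": framing,
                                 "term": term, "beta": beta, "p": p,
                                 "significant": int(p < alpha)})
    table = pd.DataFrame(rows)
    if len(table) != 2 * 4 * 6:
        raise EffectTableError(f"expected 48 effects, built {len(table)}")
    return table


def binomial_tail(n: int, k: int, p0: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p0).

    Direct summation: the pmf at ``k`` comes from log-gamma, subsequent
    terms from the stable ratio recurrence
    ``pmf(j+1) = pmf(j) * (n-j)/(j+1) * p0/(1-p0)``.
    """
    if not (isinstance(n, (int, np.integer)) and isinstance(k, (int, np.integer))):
        raise ValueError("n and k must be integers")
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got n={n}, k={k}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if k == 0:
        return 1.0
    log_pmf_k = (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
                 + k * math.log(p0) + (n - k) * math.log1p(-p0))
    term = math.exp(log_pmf_k)
    total = term
    ratio = p0 / (1.0 - p0)
    for j in range(k, n):
        term *= (n - j) / (j + 1) * ratio
        total += term
    return min(1.0, total)


def count_significant(table: pd.DataFrame, alpha: float = 0.05) -> int:
    """Count effects with p below alpha; handles censored '<x' entries."""
    count = 0
    for value in table["p"]:
        if isinstance(value, str) and value.strip().startswith("<"):
            bound = float(value.strip().lstrip("<"))
            if bound <= alpha:
                count += 1
            continue
        if float(value) < alpha:
            count += 1
    return count


def summarize(table: pd.DataFrame, alpha: float = 0.05) -> BinomialSummary:
    n = len(table)
    k = count_significant(table, alpha)
    return BinomialSummary(n=n, k=k, p0=alpha,
                           tail_prob=binomial_tail(n, k, alpha))


def load_reference_table() -> pd.DataFrame:
    """Bundled published 48-effect table (betas and printed p-values)."""
    with resources.files("homestay.data").joinpath("reference_effects.csv").open() as fh:
        # keep_default_na: the affect term "NA" is data, not a missing value
        return pd.read_csv(fh, dtype={"p": str}, keep_default_na=False)


# ---------------------------------------------------------------------------
# rendering

def _interaction_panel(ax, fit: FitResult, affect: str) -> None:
    up = affect.upper()
    terms = fit.terms
    beta = dict(zip(terms, fit.beta))
    x = np.linspace(0, 100, 101)
    for z_sias, color, lab in ((1.0, "tab:red", "high SIAS (+1 SD)"),
                               (-1.0, "tab:blue", "low SIAS (-1 SD)")):
        eta = (beta["(Intercept)"] + beta[up] * x + beta["SIAS"] * z_sias
               + beta[f"{up}×SIAS"] * x * z_sias)
        ax.plot(x, 1.0 / (1.0 + np.exp(-eta)), color=color, label=lab)
    ax.set_xlabel(f"mean daily {up} (0-100)")
    ax.set_ylabel("P(any homestay next day)")
    ax.set_ylim(0, 1)
    ax.set_title(up)
    ax.legend(frameon=False, fontsize=8)


def render_report(table: pd.DataFrame, summary: BinomialSummary,
                  out_dir: str | Path,
                  fits: dict[tuple[str, str, str], FitResult] | None = None) -> dict:
    """Write effects.csv, binomial.txt and (given fits) the interaction plot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    effects_path = out / "effects.csv"
    table.to_csv(effects_path, index=False)
    written["effects"] = effects_path

    binom_path = out / "binomial.txt"
    binom_path.write_text(
        f"n = {summary.n}\nk = {summary.k}\np0 = {summary.p0}\n"
        f"tail_prob = {summary.tail_prob:.17g}\n")
    written["binomial"] = binom_path

    if fits is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), constrained_layout=True)
        for ax, affect in zip(axes, AFFECTS):
            _interaction_panel(ax, fits[("binary", "next_day", affect)], affect)
        plot_path = out / "interaction_next_day.png"
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        written["plot"] = plot_path
    return written
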