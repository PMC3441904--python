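"""Funnel-plot series on the SMR scale and provider classification.

A funnel plot displays each provider's SMR (observed/expected) against its
expected count λ, with the target line at SMR = 1 and nested control-limit
curves (conventionally 95% 'alarm' and 99.8% 'action'). SMR-scale limits
are the count-scale limits divided by λ, so they funnel inwards as λ grows.

Classification happens on the count scale at λ equal to the provider's own
expected count — rescaling by the positive constant 1/λ preserves strict
inequalities, so count-scale and SMR-scale verdicts coincide. An
observation strictly beyond a limit is 'below'/'above'; on the limit is
'inside'. The optional smoothing of the integer prediction limits is
cosmetic and never enters classification.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import _bounds
from .limits import TailRule, as_level, interpolated_prediction_limits, prediction_bounds
from .providers import ProviderRecord, ProviderValidationError

__all__ = ["build_funnel", "classify_one", "classify_providers", "render_funnel"]


def _series_bounds(lam, method, level, tail_rule, smooth_prediction):
    if method == "prediction" and smooth_prediction:
        pairs = [interpolated_prediction_limits(x, level) for x in np.asarray(lam)]
        return (
            np.array([p.lower for p in pairs]),
            np.array([p.upper for p in pairs]),
        )
    return _bounds(lam, method, level, tail_rule)


def build_funnel(
    lam_grid,
    methods=("wald", "exact", "prediction"),
    levels=(0.95, 0.998),
    smooth_prediction: bool = True,
    tail_rule: TailRule = TailRule.CONSERVATIVE,
) -> pd.DataFrame:
    """Control-limit series for plotting, count and SMR scale side by side.

    Returns a tidy frame with columns
    ``lam, method, level, side, count_limit, smr_limit`` (side in
    {lower, upper}). Prediction series use the smoothed real-valued limits
    when ``smooth_prediction`` is on, raw integer steps otherwise; the
    smoothing never changes who is flagged.
    """
    lam = np.asarray(lam_grid, dtype=float)
    if lam.size == 0:
        raise ValueError("lam_grid must be non-empty")
    if len(tuple(methods)) == 0:
        raise ValueError("methods must be non-empty")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("lam_grid must be strictly ascending")
    rows = []
    for level in levels:
        lv = as_level(level)
        for method in methods:
            lo, up = _series_bounds(lam, method, lv, tail_rule, smooth_prediction)
            for side, vals in (("lower", lo), ("upper", up)):
                rows.append(
                    pd.DataFrame(
                        {
                            "lam": lam,
                            "method": method,
                            "level": lv.level,
                            "side": side,
                            "count_limit": vals,
                            "smr_limit": vals / lam,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def classify_one(
    observed: int,
    expected: float,
    method: str = "prediction",
    level=0.95,
    tail_rule: TailRule = TailRule.CONSERVATIVE,
) -> str:
    """'below', 'inside' or 'above' for a single provider (strict-outside)."""
    lower, upper = _bounds(float(expected), method, as_level(level), tail_rule)
    if observed < lower:
        return "below"
    if observed > upper:
        return "above"
    return "inside"


def classify_providers(
    records: Sequence[ProviderRecord],
    method: str = "prediction",
    levels=(0.95, 0.998),
    tail_rule: TailRule = TailRule.CONSERVATIVE,
) -> list:
    """Flag each provider against limits at λ = its own expected count.

    Limits are evaluated at the provider's exact (continuous) expected
    count, not a binned grid value. Returns new records with ``flag_95``
    and ``flag_998`` filled; since 99.8% limits enclose 95% ones, any
    99.8% flag implies the same 95% flag.
    """
    problems = [
        f"row {i}: observed={r.observed} negative"
        if r.observed < 0
        else f"row {i}: expected={r.expected} must be positive"
        for i, r in enumerate(records, start=1)
        if r.observed < 0 or r.expected <= 0
    ]
    if problems:
        raise ProviderValidationError(problems)
    lv95, lv998 = (as_level(l) for l in levels)
    out = []
    for r in records:
        out.append(
            dataclasses.replace(
                r,
                flag_95=classify_one(r.observed, r.expected, method, lv95, tail_rule),
                flag_998=classify_one(r.observed, r.expected, method, lv998, tail_rule),
            )
        )
    return out


def render_funnel(
    series: pd.DataFrame,
    providers: "Sequence[ProviderRecord] | None" = None,
    output_path=None,
    title: str = "Funnel plot of the SMR",
):
    """Render a funnel plot: SMR vs expected events, target line at 1.

    Wald lower limits below zero are clamped to 0 for display only (the
    series data stay unclamped). Flagged providers are highlighted.
    Writes SVG/PNG by extension when ``output_path`` is given; returns the
    matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if series.empty:
        raise ValueError("series must be non-empty")

    fig, ax = plt.subplots(figsize=(8, 5))
    styles = {"wald": "tab:blue", "exact": "tab:green", "prediction": "tab:red"}
    for (method, level, side), grp in series.groupby(["method", "level", "side"]):
        y = grp["smr_limit"].to_numpy()
        if method == "wald" and side == "lower":
            y = np.maximum(y, 0.0)  # display clamp only
        ax.plot(
            grp["lam"],
            y,
            color=styles.get(method, "gray"),
            linestyle="--" if level < 0.998 else ":",
            linewidth=1,
            label=f"{method} {level:g}" if side == "upper" else None,
        )
    ax.axhline(1.0, color="black", linewidth=1, label="target (SMR = 1)")

    if providers:
        exp = np.array([r.expected for r in providers])
        smr = np.array([r.smr for r in providers])
        flagged = np.array(
            [r.flag_95 not in (None, "inside") for r in providers]
        )
        ax.scatter(exp[~flagged], smr[~flagged], s=16, color="0.4", label="providers")
        if flagged.any():
            ax.scatter(
                exp[flagged], smr[flagged], s=28, color="crimson", label="flagged"
            )
    ax.set_xlabel("expected events (λ)")
    ax.set_ylabel("SMR (observed / expected)")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if output_path is not None:
        fig.savefig(output_path)
        plt.close(fig)
    return fig
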