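"""Hypothesis comparison: AIC differences and chi-squared tail P-values.

Each hypothesis model is compared against the base model through
ΔAIC = AIC(base) − AIC(model) (positive when the hypothesis improves on
the base), the extra-parameter count k = T(model) − T(base), and the
tail probability

    P = Pr(χ²_k > ΔAIC + 2k),

which is the likelihood-ratio tail, since ΔAIC + 2k equals the drop in
−2LL for nested models.  The minimum-AIC model is the statistical winner,
but a statistically best model need not be qualitatively correct: the
early (≤ 6 h) collapse of PHO2 mRNA is reported as a separate qualitative
flag so the two judgements can disagree.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .inference import FitResult
from .model import EnvironmentProtocol, ModelVariant
from .simulate import ObservableConfig, simulate, to_fold_change

__all__ = [
    "SelectionRow",
    "selection_pvalue",
    "comparison_table",
    "selection_frame",
    "format_table",
    "best_model",
    "early_drop_flag",
]


def selection_pvalue(delta_aic: float, k: int) -> float:
    """Upper-tail χ²_k probability at ΔAIC + 2k."""
    if k < 1 or int(k) != k:
        raise ValueError(f"k must be a positive integer, got {k}")
    if not np.isfinite(delta_aic):
        raise ValueError("delta_aic must be finite")
    return float(chi2.sf(delta_aic + 2.0 * k, int(k)))


@dataclass
class SelectionRow:
    """One row of the model-comparison table."""

    model: str
    aic: float
    minus2ll: float
    n_params: int
    delta_aic: float | None = None
    k: int | None = None
    pvalue: float | None = None

    def __post_init__(self):
        if abs(self.aic - (self.minus2ll + 2 * self.n_params)) > 1e-6:
            raise ValueError(f"row {self.model}: AIC must equal -2LL + 2T")


def comparison_table(base_fit: FitResult, alt_fits: list[FitResult]) -> list[SelectionRow]:
    """Build the comparison table: base row first, then alternatives by AIC.

    All fits must be on the same data (checked via the data digest).
    """
    for f in alt_fits:
        if f.data_hash != base_fit.data_hash:
            raise ValueError(
                f"fit of {f.variant.name} is on different data than the base fit"
            )
    rows = [SelectionRow(base_fit.variant.name, base_fit.aic,
                         base_fit.minus2ll, base_fit.n_params)]
    for f in sorted(alt_fits, key=lambda f: f.aic):
        delta = base_fit.aic - f.aic
        k = f.n_params - base_fit.n_params
        p = selection_pvalue(delta, k) if k >= 1 else None
        rows.append(SelectionRow(f.variant.name, f.aic, f.minus2ll, f.n_params,
                                 delta_aic=delta, k=k, pvalue=p))
    return rows


def selection_frame(rows: list[SelectionRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(model=r.model, AIC=r.aic, minus2LL=r.minus2ll, T=r.n_params,
                 delta_AIC=r.delta_aic, k=r.k, p_value=r.pvalue)
            for r in rows
        ]
    )


def format_table(rows: list[SelectionRow]) -> str:
    """Plain-text rendering (P-values to three significant figures)."""
    lines = [f"{'Model':<10}{'AIC':>10}{'-2LL':>10}{'T':>5}{'dAIC':>9}{'k':>4}  P-value"]
    for r in rows:
        if r.delta_aic is None:
            lines.append(f"{r.model:<10}{r.aic:>10.2f}{r.minus2ll:>10.2f}{r.n_params:>5d}"
                         f"{'-':>9}{'-':>4}  -")
        else:
            lines.append(
                f"{r.model:<10}{r.aic:>10.2f}{r.minus2ll:>10.2f}{r.n_params:>5d}"
                f"{r.delta_aic:>9.2f}{r.k:>4d}  {r.pvalue:.3g}"
            )
    return "\n".join(lines)


def early_drop_flag(
    fit: FitResult,
    threshold: float = 0.5,
    at_time: float = 6.0,
    config: ObservableConfig | None = None,
    rtol: float = 1e-8,
) -> bool:
    """Whether the fitted model shows the early PHO2 mRNA collapse.

    Simulates the fit under continuous starvation and reports True when
    the PHO2 fold change at ``at_time`` hours falls below ``threshold``.
    """
    protocol = EnvironmentProtocol.starvation(max(at_time * 2, 24.0))
    grid = np.unique(np.concatenate(([0.0, at_time], np.linspace(0, protocol.horizon, 25))))
    traj = simulate(fit.parameters, fit.variant, protocol, grid, rtol=rtol)
    curves = to_fold_change(traj, config=config)
    return bool(curves["PHO2"].at(at_time) < threshold)


@dataclass
class BestModel:
    model: str
    aic: float
    early_drop: dict  # model name -> bool (None when not evaluated)


def best_model(
    rows: list[SelectionRow],
    fits: dict[str, FitResult] | None = None,
    threshold: float = 0.5,
    at_time: float = 6.0,
) -> BestModel:
    """Minimum-AIC model plus per-model early-PHO2-drop qualitative flags."""
    non_base = rows[1:]
    if not non_base:
        raise ValueError("need at least one non-base row")
    winner = min(non_base, key=lambda r: r.aic)
    flags = {}
    for r in rows:
        f = (fits or {}).get(r.model)
        flags[r.model] = early_drop_flag(f, threshold, at_time) if f is not None else None
    return BestModel(model=winner.model, aic=winner.aic, early_drop=flags)
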