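"""Maximum-likelihood estimation of model parameters from fold-change data.

The data likelihood treats each replicate fold change as lognormally
distributed around the model prediction (proportional error — the natural
choice for qPCR fold changes; an additive-Gaussian alternative is
available), with one residual scale per target RNA.  The residual scales
are profiled analytically at every structural parameter vector, which gives
the same maximum as joint optimisation at a fraction of the cost; they are
counted as free statistical parameters in the total parameter count T, so
AIC = −2LL + 2T.

Fitting is bounded multi-start local optimisation in log-parameter space
(Powell search over Latin-hypercube starts plus a warm start), following
the study's convention of initialising a hypothesis variant's shared
parameters from a prior base-model fit.  Standard deviations come from the
inverse observed information at the optimum (central finite differences).
"""
from __future__ import annotations

import copy
import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .model import (
    EnvironmentProtocol,
    ModelVariant,
    default_parameters,
    initial_steady_state,
)
from .parameters import ParameterSet
from .simulate import (
    TARGETS,
    IntegrationError,
    ObservableConfig,
    observe,
    simulate,
    to_fold_change,
)
from .synth import RESUPPLY_AT

__all__ = [
    "ErrorModel",
    "FitResult",
    "neg2_loglik",
    "fit",
    "count_parameters",
    "observation_hash",
]

_LN2PI = np.log(2.0 * np.pi)
_SIGMA2_FLOOR = 1e-12
_FAIL_PENALTY = 1e12


@dataclass(frozen=True)
class ErrorModel:
    """Residual error specification.

    ``sigma`` maps target -> residual scale; ``None`` entries (or a
    ``None`` mapping) are profiled at the MLE and counted as free
    statistical parameters.
    """

    kind: str = "proportional_lognormal"
    sigma: dict | None = None

    def __post_init__(self):
        if self.kind not in ("proportional_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown error model kind {self.kind!r}")
        if self.sigma is not None:
            for t, s in self.sigma.items():
                if s is not None and not s > 0:
                    raise ValueError(f"sigma for {t} must be > 0")

    def n_statistical(self, targets) -> int:
        if self.sigma is None:
            return len(targets)
        return sum(1 for t in targets if self.sigma.get(t) is None)


def observation_hash(data: pd.DataFrame) -> str:
    """Row-order-independent digest of an observation table."""
    canon = (
        data.loc[:, ["time_h", "target", "condition", "replicate", "fold_change"]]
        .sort_values(["target", "condition", "time_h", "replicate", "fold_change"])
        .round(12)
        .to_csv(index=False)
    )
    return hashlib.md5(canon.encode()).hexdigest()


def condition_protocol(condition: str, t_max: float,
                       resupply_at: float = RESUPPLY_AT) -> EnvironmentProtocol:
    """Forcing protocol implied by a condition label."""
    horizon = max(float(t_max), 1.0)
    if condition == "plusPi":
        return EnvironmentProtocol.plus_pi(horizon)
    if condition == "minusPi":
        return EnvironmentProtocol.starvation(horizon)
    if condition == "repletion":
        return EnvironmentProtocol.repletion(resupply_at, max(horizon, resupply_at + 1.0))
    raise ValueError(f"unknown condition {condition!r}")


def _predict_mu(params, data, variant, rtol, atol, config, ss_hint=None):
    """Model fold change for every data row; returns (mu, y0)."""
    y0 = initial_steady_state(params, variant, x0=ss_hint)
    mu = np.empty(len(data))
    for condition, grp in data.groupby("condition", sort=True):
        times = np.unique(grp["time_h"].to_numpy(dtype=float))
        grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
        protocol = condition_protocol(condition, grid[-1])
        traj = simulate(params, variant, protocol, grid, y0=y0, rtol=rtol, atol=atol)
        curves = to_fold_change(traj, reference=y0, config=config)
        pos = {t: i for i, t in enumerate(grid)}
        for target, tgrp in grp.groupby("target", sort=True):
            curve = curves[target]
            mu[tgrp.index.to_numpy()] = curve.fold_change[
                [pos[t] for t in tgrp["time_h"].to_numpy(dtype=float)]
            ]
    return mu, y0


def _validate_data(data: pd.DataFrame) -> pd.DataFrame:
    if data.empty:
        raise ValueError("observation table is empty")
    missing = set(("time_h", "target", "condition", "fold_change")) - set(data.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    if (data["fold_change"] <= 0).any():
        raise ValueError("fold changes must be strictly positive")
    unknown = set(data["target"].unique()) - set(TARGETS)
    if unknown:
        raise ValueError(f"unknown targets {sorted(unknown)}; expected {TARGETS}")
    return data.reset_index(drop=True)


def neg2_loglik(
    params: ParameterSet,
    data: pd.DataFrame,
    variant: ModelVariant,
    error_model: ErrorModel | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    config: ObservableConfig | None = None,
    return_sigma: bool = False,
    ss_hint=None,
):
    """−2 log-likelihood of the data under ``variant`` at ``params``.

    Integration failures return +inf (optimiser-safe) with a warning.
    With the lognormal error model the density is evaluated on the log
    fold change; unspecified residual scales are profiled per target.
    """
    error_model = error_model or ErrorModel()
    data = _validate_data(data)
    try:
        mu, _ = _predict_mu(params, data, variant, rtol, atol, config, ss_hint=ss_hint)
    except (IntegrationError, RuntimeError, ValueError, ZeroDivisionError) as exc:
        warnings.warn(f"likelihood evaluation failed: {exc}", stacklevel=2)
        return (np.inf, {}) if return_sigma else np.inf
    y = data["fold_change"].to_numpy(dtype=float)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        return (np.inf, {}) if return_sigma else np.inf

    if error_model.kind == "proportional_lognormal":
        resid = np.log(y) - np.log(mu)
        extra = 2.0 * np.log(y)
    else:
        resid = y - mu
        extra = np.zeros_like(y)

    total = 0.0
    sigmas = {}
    for target, grp in data.groupby("target", sort=True):
        i = grp.index.to_numpy()
        r2 = resid[i] ** 2
        n_t = r2.size
        s_given = (error_model.sigma or {}).get(target)
        if s_given is None:
            s2 = max(float(r2.mean()), _SIGMA2_FLOOR)
            total += n_t * (_LN2PI + np.log(s2) + 1.0) + extra[i].sum()
        else:
            s2 = float(s_given) ** 2
            total += n_t * (_LN2PI + np.log(s2)) + r2.sum() / s2 + extra[i].sum()
        sigmas[target] = float(np.sqrt(s2))
    return (float(total), sigmas) if return_sigma else float(total)


def count_parameters(
    variant: ModelVariant,
    error_model: ErrorModel | None = None,
    targets=TARGETS,
    n_random_effects: int = 0,
    params: ParameterSet | None = None,
) -> int:
    """Total free parameter count T (structural + statistical).

    Differences between the hypothesis variants and the base model equal
    the k column of the comparison table under the default designation.
    """
    error_model = error_model or ErrorModel()
    params = params if params is not None else default_parameters(variant)
    return params.n_free() + error_model.n_statistical(targets) + n_random_effects


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model variant."""

    variant: ModelVariant
    parameters: ParameterSet
    estimates: dict
    sd: dict
    sd_log: dict
    fixed: dict
    sigma: dict
    minus2ll: float
    n_params: int
    aic: float
    n_obs: int
    seed: int
    n_starts: int
    converged: list
    best_start: int
    data_hash: str
    error_kind: str = "proportional_lognormal"

    def __post_init__(self):
        expected = self.minus2ll + 2.0 * self.n_params
        if np.isfinite(self.minus2ll) and abs(self.aic - expected) > 1e-9:
            raise ValueError("AIC must equal -2LL + 2T exactly")

    def to_dict(self) -> dict:
        return {
            "variant": {"hypothesis": self.variant.hypothesis, "rp": self.variant.rp},
            "estimates": self.estimates,
            "sd": self.sd,
            "sd_log": self.sd_log,
            "fixed": self.fixed,
            "sigma": self.sigma,
            "minus2ll": self.minus2ll,
            "n_params": self.n_params,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "converged": list(self.converged),
            "best_start": self.best_start,
            "data_hash": self.data_hash,
            "error_kind": self.error_kind,
            "parameters": self.parameters.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            variant=ModelVariant(d["variant"]["hypothesis"], rp=d["variant"]["rp"]),
            parameters=ParameterSet.from_dict(d["parameters"]),
            estimates=d["estimates"], sd=d["sd"], sd_log=d["sd_log"],
            fixed=d["fixed"], sigma=d["sigma"], minus2ll=d["minus2ll"],
            n_params=d["n_params"], aic=d["aic"], n_obs=d["n_obs"],
            seed=d["seed"], n_starts=d["n_starts"], converged=d["converged"],
            best_start=d["best_start"], data_hash=d["data_hash"],
            error_kind=d.get("error_kind", "proportional_lognormal"),
        )


def fit(
    data: pd.DataFrame,
    variant: ModelVariant,
    init: ParameterSet | None = None,
    bounds: dict | None = None,
    n_starts: int = 4,
    seed: int = 0,
    error_model: ErrorModel | None = None,
    free: list[str] | None = None,
    warm_from: "FitResult | None" = None,
    rtol: float = 1e-6,
    maxfev: int = 600,
    compute_sd: bool = True,
) -> FitResult:
    """Multi-start bounded MLE of the free parameters of ``variant``.

    Optimisation runs in log-parameter space: the first start is the
    supplied ``init`` (optionally warm-started from a previous base-model
    fit via ``warm_from``), the remainder are seeded Latin-hypercube draws
    within the bounds.  Deterministic given ``(seed, n_starts)``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    error_model = error_model or ErrorModel()
    data = _validate_data(data)
    params = (init if init is not None else default_parameters(variant)).copy()
    if free is not None:
        params = params.set_free(free)
    if warm_from is not None:
        shared = {k: v for k, v in warm_from.estimates.items() if k in params}
        params = params.with_values(**shared)
    if bounds:
        updated = {k: copy.copy(params[k]) for k in params}
        for name, (lo, hi) in bounds.items():
            updated[name].lower, updated[name].upper = lo, hi
        params = ParameterSet(updated)

    names = params.free_names()
    if not names:
        raise ValueError("no free parameters to fit")
    lo = np.log([params[n].lower for n in names])
    hi = np.log([params[n].upper for n in names])
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("bounds must be finite and positive")

    ss_hint = {"y": None}

    def objective(x):
        p = params.with_values(**dict(zip(names, np.exp(x))))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = neg2_loglik(p, data, variant, error_model, rtol=rtol,
                              ss_hint=ss_hint["y"])
        return _FAIL_PENALTY if not np.isfinite(val) else val

    x_init = np.log([params.value(n) for n in names])
    starts = [np.clip(x_init, lo, hi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        draws = sampler.random(n_starts - 1)
        starts.extend(lo + draws * (hi - lo))

    best = None
    converged = []
    best_start = -1
    for i, x0 in enumerate(starts):
        res = minimize(
            objective, x0, method="Powell",
            bounds=list(zip(lo, hi)),
            options={"maxfev": maxfev, "xtol": 1e-4, "ftol": 1e-6},
        )
        converged.append(bool(res.success) and res.fun < _FAIL_PENALTY)
        if best is None or res.fun < best.fun:
            best, best_start = res, i
    if best is None or best.fun >= _FAIL_PENALTY:
        raise RuntimeError(
            f"no start converged for {variant.name} "
            f"(seed={seed}, n_starts={n_starts}, converged={converged})"
        )

    x_hat = np.clip(best.x, lo, hi)
    p_hat = params.with_values(**dict(zip(names, np.exp(x_hat))))
    m2ll, sigmas = neg2_loglik(p_hat, data, variant, error_model, rtol=rtol,
                               return_sigma=True)

    sd_log = {n: np.nan for n in names}
    if compute_sd:
        sd_log = _observed_information_sd(objective, x_hat, names, lo, hi)
    estimates = {n: float(np.exp(x_hat[j])) for j, n in enumerate(names)}
    sd = {n: (estimates[n] * sd_log[n] if np.isfinite(sd_log[n]) else np.nan)
          for n in names}

    T = params.n_free() + error_model.n_statistical(sorted(data["target"].unique()))
    return FitResult(
        variant=variant,
        parameters=p_hat,
        estimates=estimates,
        sd=sd,
        sd_log=sd_log,
        fixed={n: params.value(n) for n in params if params[n].fixed},
        sigma=sigmas,
        minus2ll=float(m2ll),
        n_params=T,
        aic=float(m2ll) + 2.0 * T,
        n_obs=len(data),
        seed=seed,
        n_starts=n_starts,
        converged=converged,
        best_start=best_start,
        data_hash=observation_hash(data),
        error_kind=error_model.kind,
    )


def _observed_information_sd(objective, x_hat, names, lo, hi, step: float = 5e-3):
    """Log-scale SDs from the inverse observed information (central FD)."""
    n = len(x_hat)
    h = np.full(n, step)
    H = np.empty((n, n))
    f0 = objective(x_hat)

    def f(dx):
        return objective(np.clip(x_hat + dx, lo, hi))

    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (f(ei) - 2 * f0 + f(-ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(ei + ej) - f(ei - ej) - f(-ei + ej) + f(-ei - ej)
            ) / (4 * h[i] * h[j])
    info = 0.5 * H  # observed information for -2LL
    out = {}
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        for i, n_ in enumerate(names):
            out[n_] = float(np.sqrt(diag[i])) if diag[i] > 0 else np.nan
    except np.linalg.LinAlgError:
        out = {n_: np.nan for n_ in names}
    return out
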