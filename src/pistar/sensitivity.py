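"""Local sensitivity coefficients and perturbation-based robustness.

Sensitivities are normalised (relative) coefficients

    S[x, p, t] = (p / x) · ∂x/∂p = ∂ln x / ∂ln p,

computed by central finite differences in log-parameter space at a fitted
point.  Robustness of an observable is its inverse coefficient of
variation under random lognormal perturbation of the kinetic parameters:
a low score means small parameter noise already produces large spread in
the observable (the hallmark of IPS1 in these models).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SPECIES, EnvironmentProtocol, ModelVariant
from .parameters import HILL_COEFFICIENTS, ParameterSet
from .simulate import IntegrationError, ObservableConfig, observe, simulate

__all__ = [
    "SensitivityMatrix",
    "RobustnessReport",
    "finite_difference_sensitivity",
    "local_sensitivity",
    "robustness",
]

#: sentinel score returned when the perturbed spread collapses to zero
ROBUSTNESS_CAP = 1e12


def finite_difference_sensitivity(f, params: dict, names=None, rel_step: float = 0.01):
    """Generic engine: normalised sensitivities of ``f`` at ``params``.

    ``f`` maps a parameter dict to an output vector; for each parameter p
    the coefficient is (f(p·e^h) − f(p·e^−h)) / (2h · f0), i.e. ∂ln f/∂ln p
    evaluated without taking logarithms of the outputs (outputs may pass
    through zero).  Where |f0| is below 1e-300 the unnormalised derivative
    is reported instead.  Returns (matrix [n_names, n_out], failed: set).
    """
    if not (0 < rel_step <= 0.1):
        raise ValueError("rel_step must lie in (0, 0.1]")
    names = list(names if names is not None else params)
    f0 = np.atleast_1d(np.asarray(f(dict(params)), dtype=float))
    S = np.full((len(names), f0.size), np.nan)
    failed = set()
    denom = np.where(np.abs(f0) > 1e-300, f0, 1.0)
    for i, name in enumerate(names):
        p_hi, p_lo = dict(params), dict(params)
        p_hi[name] = params[name] * np.exp(rel_step)
        p_lo[name] = params[name] * np.exp(-rel_step)
        try:
            up = np.atleast_1d(np.asarray(f(p_hi), dtype=float))
            dn = np.atleast_1d(np.asarray(f(p_lo), dtype=float))
        except Exception:
            failed.add(name)
            continue
        S[i] = (up - dn) / (2.0 * rel_step) / denom
    return S, failed


@dataclass
class SensitivityMatrix:
    """Normalised coefficients S[observable, parameter, time]."""

    values: np.ndarray
    observables: tuple
    parameters: tuple
    times: tuple
    variant: ModelVariant
    rel_step: float
    failed: set = field(default_factory=set)

    def coefficient(self, observable: str, parameter: str, time: float) -> float:
        return float(
            self.values[
                self.observables.index(observable),
                self.parameters.index(parameter),
                self.times.index(time),
            ]
        )

    def ranking(self, observable: str, time: float) -> pd.Series:
        """Parameters ordered by |S| for one observable/time."""
        col = np.abs(
            self.values[self.observables.index(observable), :, self.times.index(time)]
        )
        return pd.Series(col, index=list(self.parameters)).sort_values(ascending=False)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, obs in enumerate(self.observables):
            for j, par in enumerate(self.parameters):
                for k, t in enumerate(self.times):
                    recs.append(dict(observable=obs, parameter=par, time_h=t,
                                     coefficient=self.values[i, j, k]))
        return pd.DataFrame.from_records(recs)


def _model_observables(states, config):
    """RNA observables plus the cytosolic Pi pool."""
    obs = observe(states, config)
    obs["CytoPi"] = np.atleast_2d(states)[:, SPECIES.index("CytoPi")]
    return obs


def local_sensitivity(
    params: ParameterSet,
    variant: ModelVariant,
    protocol: EnvironmentProtocol,
    observables=("PHO2", "IPS1", "miR399", "CytoPi"),
    times=(264.0,),
    rel_step: float = 0.01,
    parameter_names=None,
    config: ObservableConfig | None = None,
    rtol: float = 1e-8,
) -> SensitivityMatrix:
    """Local sensitivities of model observables at a (fitted) point.

    All structural parameters are perturbed by default.  An integration
    failure at a perturbed point flags the parameter (NaN row) rather than
    silently zeroing it.
    """
    names = list(parameter_names if parameter_names is not None else params)
    times = tuple(float(t) for t in times)
    grid = np.unique(np.concatenate(([protocol.start], times)))

    def run(values: dict):
        p = params.with_values(**values)
        traj = simulate(p, variant, protocol, grid, rtol=rtol)
        obs = _model_observables(traj.states, config)
        idx = [int(np.argmin(np.abs(grid - t))) for t in times]
        return np.concatenate([obs[o][idx] for o in observables])

    base_values = {n: params.value(n) for n in names}
    S_flat, failed = finite_difference_sensitivity(run, base_values, names, rel_step)
    values = np.transpose(
        S_flat.reshape(len(names), len(observables), len(times)), (1, 0, 2)
    )
    return SensitivityMatrix(
        values=values, observables=tuple(observables), parameters=tuple(names),
        times=times, variant=variant, rel_step=rel_step, failed=failed,
    )


@dataclass
class RobustnessReport:
    """Inverse-CV robustness scores per observable."""

    scores: dict
    cv: dict
    perturbation_cv: float
    n_draws: int
    n_failed: int
    seed: int
    variant: ModelVariant

    @property
    def least_robust(self) -> str:
        return min(self.scores, key=self.scores.get)

    def rank_of(self, observable: str) -> int:
        """1-based rank from least to most robust."""
        ordered = sorted(self.scores, key=self.scores.get)
        return ordered.index(observable) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(observable=list(self.scores), score=list(self.scores.values()),
                 cv=[self.cv[o] for o in self.scores])
        )


def robustness(
    params: ParameterSet,
    variant: ModelVariant,
    protocol: EnvironmentProtocol,
    perturbation_cv: float = 0.1,
    n_draws: int = 200,
    seed: int = 0,
    observables=("PHO2", "IPS1", "miR399"),
    config: ObservableConfig | None = None,
    rtol: float = 1e-6,
) -> RobustnessReport:
    """Observable spread under lognormal parameter perturbation.

    Rates and binding/half-saturation constants are multiplied by
    independent lognormal factors (median 1, CV ``perturbation_cv``); Hill
    coefficients are left untouched (integer-like cooperativities).  The
    score per observable is mean/SD of its value at the protocol end; a
    vanishing SD returns the capped sentinel ``ROBUSTNESS_CAP``.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(perturbation_cv**2))
    names = [n for n in params if n not in HILL_COEFFICIENTS]
    grid = np.array([protocol.start, protocol.horizon])

    samples = {o: [] for o in observables}
    n_failed = 0
    for _ in range(n_draws):
        factors = np.exp(rng.normal(0.0, sigma, size=len(names)))
        values = {n: params.value(n) * f for n, f in zip(names, factors)}
        try:
            p = params.with_values(**values)
            traj = simulate(p, variant, protocol, grid, rtol=rtol)
        except (IntegrationError, RuntimeError, ValueError):
            n_failed += 1
            continue
        obs = _model_observables(traj.states[-1:], config)
        for o in observables:
            samples[o].append(float(obs[o][0]))
    if n_failed > n_draws / 2:
        raise RuntimeError(
            f"robustness aborted: {n_failed}/{n_draws} perturbed integrations failed "
            f"for {variant.name} (cv={perturbation_cv})"
        )

    scores, cvs = {}, {}
    for o in observables:
        arr = np.asarray(samples[o])
        mean, sd = arr.mean(), arr.std(ddof=1)
        cvs[o] = float(sd / mean) if mean > 0 else np.inf
        # spread at the level of summation round-off is a degenerate limit
        degenerate = sd <= abs(mean) * 1e-12
        scores[o] = ROBUSTNESS_CAP if degenerate else float(mean / sd)
    return RobustnessReport(
        scores=scores, cv=cvs, perturbation_cv=perturbation_cv,
        n_draws=n_draws, n_failed=n_failed, seed=seed, variant=variant,
    )
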