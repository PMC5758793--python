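"""Synthetic qRT-PCR fold-change observation tables.

The generator emulates the temporal structure, replicate design and noise
of root qRT-PCR time courses under phosphate starvation and re-supply:

* ``long_starvation`` (0, 24, 72, 168, 264 h, −Pi): PHO2 mRNA falls
  monotonically — steepest at the earliest times — to half its initial
  level by 264 h; IPS1 rises exponentially (beyond 1000-fold when
  extrapolated to 21 days); miR399 stays flat for at least 24 h and then
  rises sigmoidally.
* ``early_time`` (0, 3, 6, 12 h): ~80% of PHO2 mRNA is lost by 3 h of Pi
  stress with partial recovery at 6 and 12 h, while the +Pi control is
  flat to slightly increasing.
* ``repletion``: starvation followed by Pi re-supply at 264 h; PHO2 and
  IPS1 collapse toward suppressed/pre-starvation levels within 24 h.

Noise is multiplicative lognormal with median 1 and a configurable
coefficient of variation, matching the proportional-error behaviour of
fold-change measurements; replicate counts default to the study design
(n = 3 for PHO2 throughout; n = 2 for IPS1/miR399 at 0, 24, 72 h and
n = 4 at 168, 264 h; n = 3 elsewhere).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .simulate import TARGETS, FoldChangeCurve

__all__ = [
    "SCENARIOS",
    "GeneratorConfig",
    "reference_curves",
    "generate",
    "replicate_design",
    "OBSERVATION_COLUMNS",
]

SCENARIOS = ("long_starvation", "early_time", "repletion")
OBSERVATION_COLUMNS = ("time_h", "target", "condition", "replicate", "fold_change")

LONG_TIMES = (0.0, 24.0, 72.0, 168.0, 264.0)
EARLY_TIMES = (0.0, 3.0, 6.0, 12.0)
REPLETION_TIMES = (0.0, 24.0, 72.0, 168.0, 264.0, 268.0, 276.0, 288.0)
RESUPPLY_AT = 264.0

# anchor values for the early-time PHO2 profile: 80% lost at 3 h, partial
# recovery (strictly between the trough and baseline) at 6 and 12 h
_EARLY_PHO2_ANCHORS = {0.0: 1.0, 3.0: 0.2, 6.0: 0.3, 12.0: 0.38}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic-data draw."""

    scenario: str = "long_starvation"
    cv: float = 0.2
    seed: int = 0
    design: dict | None = None  # optional {(target, time): n_replicates}

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if not self.cv > 0:
            raise ValueError("noise CV must be > 0")


# ---------------------------------------------------------------------------
# noiseless reference curves
# ---------------------------------------------------------------------------

def _pho2_long(t):
    t = np.asarray(t, dtype=float)
    return 0.5 + 0.5 * np.exp(-t / 40.0)


def _ips1_long(t):
    return np.exp(np.asarray(t, dtype=float) / 70.0)


def _mir399_long(t):
    t = np.asarray(t, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-(t - 120.0) / 18.0))
    sig0 = 1.0 / (1.0 + np.exp(120.0 / 18.0))
    return 1.0 + 24.0 * (sig - sig0) / (1.0 - sig0)

_LONG_FORMS = {"PHO2": _pho2_long, "IPS1": _ips1_long, "miR399": _mir399_long}

_EARLY_INTERP = PchipInterpolator(
    list(_EARLY_PHO2_ANCHORS), list(_EARLY_PHO2_ANCHORS.values())
)

# post-resupply relaxation timescales (h): PHO2 mRNA collapses fast once
# the sequestered miR399 is released; IPS1 relaxes back toward baseline
_REPL_TAU = {"PHO2": 8.0, "IPS1": 5.0, "miR399": 48.0}
_REPL_FLOOR = {"PHO2": 0.05, "IPS1": 1.0, "miR399": 1.0}


def _repletion_curve(target, t):
    t = np.asarray(t, dtype=float)
    base = _LONG_FORMS[target](np.minimum(t, RESUPPLY_AT))
    after = t > RESUPPLY_AT
    if np.any(after):
        v0 = float(_LONG_FORMS[target](RESUPPLY_AT))
        floor, tau = _REPL_FLOOR[target], _REPL_TAU[target]
        decay = floor + (v0 - floor) * np.exp(-(t[after] - RESUPPLY_AT) / tau)
        base = base.copy()
        base[after] = decay
    return base


def reference_curves(scenario: str, times=None) -> dict[str, FoldChangeCurve]:
    """Noiseless mean fold-change curves of a scenario.

    Keys are target names; the ``early_time`` scenario additionally carries
    a ``PHO2+Pi`` control curve (flat to slightly increasing).
    """
    if scenario == "long_starvation":
        t = np.asarray(times if times is not None else LONG_TIMES, dtype=float)
        return {name: FoldChangeCurve(name, t, f(t)) for name, f in _LONG_FORMS.items()}
    if scenario == "early_time":
        t = np.asarray(times if times is not None else EARLY_TIMES, dtype=float)
        return {
            "PHO2": FoldChangeCurve("PHO2", t, _EARLY_INTERP(t)),
            "PHO2+Pi": FoldChangeCurve("PHO2", t, 1.0 + t / 300.0),
        }
    if scenario == "repletion":
        t = np.asarray(times if times is not None else REPLETION_TIMES, dtype=float)
        return {name: FoldChangeCurve(name, t, _repletion_curve(name, t))
                for name in TARGETS}
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


# ---------------------------------------------------------------------------
# replicate design and noisy tables
# ---------------------------------------------------------------------------

def replicate_design(scenario: str) -> dict[tuple[str, float], int]:
    """Biological replicate counts per (target, time) cell."""
    design = {}
    if scenario == "long_starvation":
        for t in LONG_TIMES:
            design[("PHO2", t)] = 3
            n = 4 if t >= 168.0 else 2
            design[("IPS1", t)] = n
            design[("miR399", t)] = n
    elif scenario == "early_time":
        for t in EARLY_TIMES:
            design[("PHO2", t)] = 3
            design[("PHO2+Pi", t)] = 3
    elif scenario == "repletion":
        for t in REPLETION_TIMES:
            for target in TARGETS:
                design[(target, t)] = 3
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return design


_CONDITION = {"long_starvation": "minusPi", "early_time": "minusPi", "repletion": "repletion"}


def generate(config: GeneratorConfig, curves: dict[str, FoldChangeCurve] | None = None) -> pd.DataFrame:
    """Draw a replicate-level observation table.

    Means come from ``curves`` (defaulting to the scenario's built-in
    reference curves — pass model-simulated curves to emulate data
    generated under a fitted variant) and are multiplied by independent
    lognormal noise with median 1 and the configured CV.  Deterministic
    given the seed; the table's ``attrs`` record scenario, seed and CV.
    """
    curves = curves if curves is not None else reference_curves(config.scenario)
    design = config.design or replicate_design(config.scenario)
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log1p(config.cv**2))

    rows = []
    for (curve_key, t), n_rep in sorted(design.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        if curve_key not in curves:
            continue
        curve = curves[curve_key]
        mean = float(curve.at(t))
        is_control = curve_key.endswith("+Pi")
        condition = "plusPi" if is_control else _CONDITION[config.scenario]
        target = curve.target
        for rep in range(1, n_rep + 1):
            noise = float(np.exp(rng.normal(0.0, sigma)))
            rows.append((t, target, condition, rep, mean * noise))
    df = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    df.attrs.update(scenario=config.scenario, seed=config.seed, cv=config.cv)
    return df
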