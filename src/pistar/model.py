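"""Core ODE models of phosphate-starvation signalling in rice roots.

The base model (PiOM) couples ten species: the SUMO ligase SIZ1, the active
(sumoylated) master regulator PHR2, the systemic microRNA miR399, PHO2 mRNA
and protein, the decoy lncRNA IPS1, the IPS1·miR399 target-mimicry complex
(IMC), the high-affinity phosphate transporters (PHT), the xylem loader PHO1
and the cytosolic inorganic-phosphate pool (CytoPi).  External Pi enters
through a piecewise-constant forcing protocol (320 µM under +Pi; 0 under
starvation).

Five hypothesis variants add candidate mechanisms for the early loss of
PHO2 mRNA under Pi stress:

PdTA   Pi-dependent transcriptional activator Z of PHO2;
PdRP   Pi-dependent protector Z of PHO2 mRNA (slows its basal decay);
PsMD   Pi-sensitive binder Z causing mutual degradation with PHO2 mRNA;
PsTR   Pi-sensitive transcriptional repressor Z acting on the PHO2
       activator TA, with TA degraded at a rate proportional to PHO2
       protein (the self-limiting feedback that lets PHO2 mRNA partially
       recover after its initial collapse);
PsRA   Pi-sensitive RNase activity degrading PHO2 mRNA at low CytoPi.

Any variant can additionally carry the RNA-protection (RP) modification, in
which the IPS1 (and IMC) degradation rate becomes d7/CytoPi0 · CytoPi(t):
equal to d7 at the +Pi steady state and vanishing as cytosolic Pi is
depleted, so IPS1 accumulates under starvation and collapses on re-supply.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import fsolve

from .parameters import K7_SECONDS_TO_HOURS, Param, ParameterSet

__all__ = [
    "SPECIES",
    "HYPOTHESES",
    "ModelVariant",
    "EnvironmentProtocol",
    "external_pi",
    "rp_degradation",
    "rhs",
    "make_rhs",
    "variant_terms",
    "species_names",
    "default_parameters",
    "neutral_overrides",
    "initial_steady_state",
    "variant_parameter_count",
    "EXTRA_FREE_PARAMETERS",
    "PLUS_PI_LEVEL",
]

#: the ten core state variables, in state-vector order
SPECIES = ("SIZ1", "PHR2a", "miR399", "PHO2m", "PHO2p", "IPS1", "IMC", "PHT", "PHO1", "CytoPi")
_I = {name: i for i, name in enumerate(SPECIES)}

HYPOTHESES = ("PIOM", "PDTA", "PDRP", "PSMD", "PSTR", "PSRA")

#: extra free structural parameters of each hypothesis relative to PiOM
#: (the k column of the model-comparison table)
EXTRA_FREE_PARAMETERS = {"PIOM": 0, "PDTA": 2, "PDRP": 4, "PSMD": 8, "PSTR": 8, "PSRA": 2}

#: default +Pi external phosphate level, µM (320 µM NaH2PO4 growth medium)
PLUS_PI_LEVEL = 320.0


@dataclass(frozen=True)
class ModelVariant:
    """Identifier of one model structure.

    Parameters
    ----------
    hypothesis:
        One of ``PIOM, PDTA, PDRP, PSMD, PSTR, PSRA`` (case-insensitive).
    rp:
        Whether the RNA-protection modification of IPS1/IMC decay is active.
    mir399_catalytic:
        If True (default), miR399 is recycled when it silences PHO2 mRNA,
        consistent with the non-cleavable target-mimicry framing; if False
        it is co-degraded.
    siz1_dynamic:
        If False, SIZ1 is clamped at its synthesis/degradation balance
        instead of being integrated.
    """

    hypothesis: str = "PIOM"
    rp: bool = False
    mir399_catalytic: bool = True
    siz1_dynamic: bool = True

    def __post_init__(self):
        object.__setattr__(self, "hypothesis", self.hypothesis.upper())
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}; expected one of {HYPOTHESES}")

    @property
    def extra_species(self) -> tuple[str, ...]:
        if self.hypothesis in ("PDTA", "PDRP", "PSMD"):
            return ("Z",)
        if self.hypothesis == "PSTR":
            return ("TA", "Z")
        return ()

    @property
    def n_species(self) -> int:
        return len(SPECIES) + len(self.extra_species)

    @property
    def name(self) -> str:
        pretty = {"PIOM": "PiOM", "PDTA": "PdTA", "PDRP": "PdRP",
                  "PSMD": "PsMD", "PSTR": "PsTR", "PSRA": "PsRA"}[self.hypothesis]
        return pretty + ("-RP" if self.rp else "")


def species_names(variant: ModelVariant) -> tuple[str, ...]:
    return SPECIES + variant.extra_species


@dataclass(frozen=True)
class EnvironmentProtocol:
    """Piecewise-constant external Pi schedule.

    ``segments`` is an ordered tuple of ``(start_h, end_h, level_uM)``;
    segments must be contiguous, non-overlapping and cover the horizon.
    Lookup uses the right-open convention: a boundary time belongs to the
    segment starting there (the final horizon point belongs to the last
    segment).
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        prev_end = None
        for (a, b, level) in self.segments:
            if b <= a:
                raise ValueError(f"segment ({a}, {b}) is empty or reversed")
            if level < 0:
                raise ValueError(f"negative external Pi level {level}")
            if prev_end is not None and not math.isclose(a, prev_end):
                raise ValueError("segments must be contiguous and non-overlapping")
            prev_end = b

    @property
    def start(self) -> float:
        return self.segments[0][0]

    @property
    def horizon(self) -> float:
        return self.segments[-1][1]

    def level_at(self, t: float) -> float:
        if t < self.start or t > self.horizon:
            raise ValueError(f"t={t} outside protocol horizon [{self.start}, {self.horizon}]")
        for (a, b, level) in self.segments:
            if a <= t < b:
                return level
        return self.segments[-1][2]  # t == horizon

    # -- common schedules -------------------------------------------------
    @classmethod
    def constant(cls, level: float, horizon: float, start: float = 0.0) -> "EnvironmentProtocol":
        return cls(((start, horizon, level),))

    @classmethod
    def plus_pi(cls, horizon: float, level: float = PLUS_PI_LEVEL) -> "EnvironmentProtocol":
        return cls.constant(level, horizon)

    @classmethod
    def starvation(cls, horizon: float) -> "EnvironmentProtocol":
        return cls.constant(0.0, horizon)

    @classmethod
    def repletion(
        cls, resupply_at: float, horizon: float, level: float = PLUS_PI_LEVEL
    ) -> "EnvironmentProtocol":
        if not 0 < resupply_at < horizon:
            raise ValueError("resupply time must lie inside the horizon")
        return cls(((0.0, resupply_at, 0.0), (resupply_at, horizon, level)))


def external_pi(protocol: EnvironmentProtocol, t: float) -> float:
    """External Pi level (µM) at time ``t`` under the protocol."""
    return protocol.level_at(t)


def rp_degradation(d7: float, cytopi0: float, cytopi_t: float) -> float:
    """Effective IPS1/IMC degradation rate under RNA protection.

    The rate is d7/CytoPi0 · CytoPi(t): equal to ``d7`` at the reference
    +Pi cytosolic Pi level and falling linearly to zero (full protection)
    as cytosolic Pi is depleted.
    """
    if cytopi0 <= 0:
        raise ValueError(f"reference CytoPi0 must be positive, got {cytopi0}")
    return (d7 / cytopi0) * max(cytopi_t, 0.0)


# ---------------------------------------------------------------------------
# default calibrated parameter values
# ---------------------------------------------------------------------------

# The shipped set reproduces the study conditions: a +Pi steady state with
# order-unity species levels and CytoPi0 = 10 au; PHO2 mRNA halving over
# 264 h of starvation; IPS1 exceeding 1000-fold by 21 days (RP variants);
# a >= 24 h delay before miR399 induction; and the collapse of IPS1/PHO2
# within 24 h of Pi re-supply under RP.  The miR399·IPS1 association
# constant k7 keeps its literature magnitude 1.9e-5 (per-second scale) and
# is converted to per-hour units inside the right-hand side.
_CORE_DEFAULTS: dict[str, tuple[float, str]] = {
    # SIZ1 (constitutive)
    "m1": (0.1, "au/h"), "d1": (0.1, "1/h"),
    # PHR2a: activation = m2·SIZ1·(decreasing Hill in CytoPi)
    "m2": (0.02, "1/h"), "d2": (0.02, "1/h"), "K2": (3.0, "au"), "h2": (2.0, "-"),
    # miR399 transcription: basal + Hill(q) in PHR2a; miRNAs are
    # long-lived, hence the slow turnover d3
    "m3": (0.8, "au/h"), "m3b": (0.004, "au/h"), "d3": (0.02, "1/h"),
    "K3": (1.0, "au"), "q": (6.0, "-"),
    # PHO2 mRNA / protein
    "m4": (0.91, "au/h"), "d5": (0.75, "1/h"), "k_m": (0.8, "1/(au*h)"),
    "m5": (0.3, "1/h"), "d_p": (0.3, "1/h"),
    # IPS1 transcription (m8, r) and decay (d7)
    "m8": (696.0, "au/h"), "d7": (0.5, "1/h"), "K8": (0.5, "au"), "r": (4.0, "-"),
    # IPS1·miR399 binding (k7 stored in literature per-second magnitude)
    "k7": (1.9e-5, "1/(au*s)"), "k7_rev": (0.3, "1/h"),
    # transporters, repressed by PHO2 protein
    "m9": (0.1, "au/h"), "d9": (0.05, "1/h"), "K9": (1.0, "au"), "h9": (2.0, "-"),
    "m10": (0.1, "au/h"), "d10": (0.05, "1/h"), "K10": (1.0, "au"), "h10": (2.0, "-"),
    # cytosolic Pi balance
    "u_max": (0.01, "1/(uM*h)"), "U": (0.3, "1/h"), "e1": (0.02, "1/(au*h)"),
    "CytoPi0": (10.0, "au"),
}

# Hill-coefficient fitting boxes ([1, 12]) differ from the default
# decade box used for rates.
_HILL_BOUNDS = (1.0, 12.0)

_VARIANT_DEFAULTS: dict[str, dict[str, tuple[float, str]]] = {
    "PDTA": {
        "m_a": (1.27, "au/h"), "K_za": (0.5, "au"), "h_za": (2.0, "-"),
        "m_z": (0.2, "au/h"), "d_z": (0.2, "1/h"), "K_zc": (5.0, "au"), "h_zc": (2.0, "-"),
    },
    "PDRP": {
        "m_z": (0.2, "au/h"), "d_z": (0.2, "1/h"), "K_zc": (5.0, "au"), "h_zc": (2.0, "-"),
        "K_zp": (0.4, "au"),
    },
    "PSMD": {
        "m_z0": (0.01, "au/h"), "m_z": (1.0, "au/h"), "d_z": (0.5, "1/h"),
        "K_zc": (6.0, "au"), "h_zc": (6.0, "-"),
        "k_mz": (2.0, "1/(au*h)"), "k_zm": (0.5, "1/(au*h)"), "K_mz": (10.0, "au"),
    },
    "PSTR": {
        "m_a": (16.0, "au/h"),
        "m_ta": (0.5, "au/h"), "d_ta": (0.05, "1/h"), "k_tap": (0.45, "1/(au*h)"),
        "K_ta": (4.0, "au"), "h_ta": (2.0, "-"),
        "m_z": (1.5, "au/h"), "d_z": (1.5, "1/h"), "K_zc": (6.0, "au"), "h_zc": (6.0, "-"),
        "K_zr": (0.4, "au"), "h_zr": (2.0, "-"),
    },
    "PSRA": {
        "d_r": (1.0, "1/h"), "K_r": (2.0, "au"), "h_r": (6.0, "-"),
    },
}

#: free structural parameters of the base model (chosen for identifiability
#: from fold-change data: timescales and interaction strengths; pure scale
#: parameters cancel in fold change and stay fixed)
DEFAULT_FREE_BASE = ("d2", "q", "r", "k_m", "k7")

#: free structural extras per hypothesis (counts match the k column:
#: PdTA 2, PdRP 4, PsMD 8, PsTR 8, PsRA 2)
DEFAULT_FREE_EXTRA = {
    "PIOM": (),
    "PDTA": ("m_a", "K_za"),
    "PDRP": ("m_z", "d_z", "K_zc", "K_zp"),
    "PSMD": ("m_z0", "m_z", "d_z", "K_zc", "h_zc", "k_mz", "k_zm", "K_mz"),
    "PSTR": ("m_a", "m_ta", "d_ta", "k_tap", "K_ta", "m_z", "d_z", "K_zr"),
    "PSRA": ("d_r", "K_r"),
}


def default_parameters(variant: ModelVariant | None = None) -> ParameterSet:
    """Calibrated default :class:`ParameterSet` for a model variant.

    RP variants ship the re-estimated IPS1 synthesis parameters (lower
    maximal synthesis, Hill coefficient r = 2) since protection, not
    super-synthesis, then accounts for the extreme IPS1 accumulation.
    """
    variant = variant or ModelVariant()
    entries: dict[str, Param] = {}
    table = dict(_CORE_DEFAULTS)
    table.update(_VARIANT_DEFAULTS.get(variant.hypothesis, {}))
    if variant.rp:
        table["m8"] = (18.8, "au/h")
        table["r"] = (2.0, "-")
    free = set(DEFAULT_FREE_BASE) | set(DEFAULT_FREE_EXTRA[variant.hypothesis])
    from .parameters import HILL_COEFFICIENTS

    for name, (value, unit) in table.items():
        lower, upper = (None, None)
        if name in HILL_COEFFICIENTS:
            lower, upper = _HILL_BOUNDS
        entries[name] = Param(value=value, unit=unit, lower=lower, upper=upper,
                              fixed=name not in free)
    return ParameterSet(entries)


def variant_parameter_count(variant: ModelVariant, params: ParameterSet | None = None) -> int:
    """Number of free structural parameters of ``variant``.

    With the default designation the difference to PiOM equals the k
    column of the model-comparison table.
    """
    params = params if params is not None else default_parameters(variant)
    return params.n_free()


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def _hill_up(x: float, K: float, h: float) -> float:
    xh = max(x, 0.0) ** h
    denom = K ** h + xh
    if denom == 0.0:  # K^h underflow at x = 0: saturated (K -> 0) limit
        return 1.0
    return xh / denom


def _hill_down(x: float, K: float, h: float) -> float:
    Kh = K ** h
    denom = Kh + max(x, 0.0) ** h
    if denom == 0.0:  # K^h underflow at x = 0: fully de-repressed limit
        return 0.0
    return Kh / denom


def make_rhs(params: ParameterSet, variant: ModelVariant, ext_level=None,
             protocol: EnvironmentProtocol | None = None):
    """Build a fast ``f(t, y) -> dy`` closure for one forcing segment.

    ``ext_level`` fixes the external Pi level (per-segment integration);
    alternatively a protocol may be supplied and is evaluated at each call
    (only used for whole-protocol derivative evaluation, not integration).
    """
    v = params.values_dict()
    hyp = variant.hypothesis
    rp = variant.rp
    catalytic = variant.mir399_catalytic
    siz1_dyn = variant.siz1_dynamic

    m1, d1 = v["m1"], v["d1"]
    m2, d2, K2, h2 = v["m2"], v["d2"], v["K2"], v["h2"]
    m3, m3b, d3, K3, q = v["m3"], v["m3b"], v["d3"], v["K3"], v["q"]
    m4, d5, k_m = v["m4"], v["d5"], v["k_m"]
    m5, d_p = v["m5"], v["d_p"]
    m8, d7, K8, r = v["m8"], v["d7"], v["K8"], v["r"]
    k7h = v["k7"] * K7_SECONDS_TO_HOURS
    k7_rev = v["k7_rev"]
    m9, d9, K9, h9 = v["m9"], v["d9"], v["K9"], v["h9"]
    m10, d10, K10, h10 = v["m10"], v["d10"], v["K10"], v["h10"]
    u_max, U, e1 = v["u_max"], v["U"], v["e1"]
    cytopi0 = v["CytoPi0"]

    n = variant.n_species

    def f(t, y):
        ext = ext_level if ext_level is not None else protocol.level_at(t)
        dy = np.empty(n)
        SIZ1, PHR2a, M, PHO2m, PHO2p = y[0], y[1], y[2], y[3], y[4]
        IPS1, IMC, PHT, PHO1, C = y[5], y[6], y[7], y[8], y[9]

        dy[0] = (m1 - d1 * SIZ1) if siz1_dyn else 0.0
        dy[1] = m2 * SIZ1 * _hill_down(C, K2, h2) - d2 * PHR2a

        bind = k7h * IPS1 * M
        dis = k7_rev * IMC
        d7_eff = rp_degradation(d7, cytopi0, C) if rp else d7

        silencing = k_m * M * PHO2m

        # --- PHO2 mRNA synthesis and extra losses by hypothesis ---------
        extra_loss = 0.0
        if hyp == "PIOM":
            synth4 = m4
        elif hyp == "PDTA":
            Z = y[10]
            synth4 = v["m_a"] * _hill_up(Z, v["K_za"], v["h_za"])
            dy[10] = v["m_z"] * _hill_up(C, v["K_zc"], v["h_zc"]) - v["d_z"] * Z
        elif hyp == "PDRP":
            Z = y[10]
            synth4 = m4
            dy[10] = v["m_z"] * _hill_up(C, v["K_zc"], v["h_zc"]) - v["d_z"] * Z
        elif hyp == "PSMD":
            Z = y[10]
            synth4 = m4
            mutual = v["k_mz"] * Z * PHO2m / (1.0 + max(PHO2m, 0.0) / v["K_mz"])
            extra_loss = mutual
            dy[10] = (
                v["m_z0"]
                + v["m_z"] * _hill_down(C, v["K_zc"], v["h_zc"])
                - v["d_z"] * Z
                - v["k_zm"] * Z * PHO2m / (1.0 + max(PHO2m, 0.0) / v["K_mz"])
            )
        elif hyp == "PSTR":
            TA, Z = y[10], y[11]
            rep = 1.0 / (1.0 + (max(Z, 0.0) / v["K_zr"]) ** v["h_zr"])
            synth4 = v["m_a"] * _hill_up(TA, v["K_ta"], v["h_ta"]) * rep
            dy[10] = v["m_ta"] - v["d_ta"] * TA - v["k_tap"] * PHO2p * TA
            dy[11] = v["m_z"] * _hill_down(C, v["K_zc"], v["h_zc"]) - v["d_z"] * Z
        elif hyp == "PSRA":
            synth4 = m4
            extra_loss = v["d_r"] * PHO2m * _hill_down(C, v["K_r"], v["h_r"])
        else:  # pragma: no cover - guarded by ModelVariant
            raise ValueError(hyp)

        # PdRP: protector Z slows the basal mRNA decay
        d5_eff = d5 / (1.0 + max(y[10], 0.0) / v["K_zp"]) if hyp == "PDRP" else d5

        mir_recycle = d7_eff * IMC  # IMC decay destroys the IPS1 moiety only
        dy[2] = (
            m3b + m3 * _hill_up(PHR2a, K3, q)
            - d3 * M - bind + dis + mir_recycle
            - (0.0 if catalytic else silencing)
        )
        dy[3] = synth4 - d5_eff * PHO2m - silencing - extra_loss
        dy[4] = m5 * PHO2m - d_p * PHO2p
        dy[5] = m8 * _hill_up(PHR2a, K8, r) - d7_eff * IPS1 - bind + dis
        dy[6] = bind - dis - d7_eff * IMC
        dy[7] = m9 * _hill_down(PHO2p, K9, h9) - d9 * PHT
        dy[8] = m10 * _hill_down(PHO2p, K10, h10) - d10 * PHO1
        dy[9] = u_max * PHT * ext - U * C - e1 * PHO1 * C
        return dy

    return f


def rhs(state, t, params: ParameterSet, variant: ModelVariant,
        protocol: EnvironmentProtocol):
    """Time derivative of the state vector (au/h). Contract-checked."""
    state = np.asarray(state, dtype=float)
    if state.shape != (variant.n_species,):
        raise ValueError(
            f"state must have {variant.n_species} components for {variant.name}, "
            f"got shape {state.shape}"
        )
    if np.any(state < -1e-9):
        raise ValueError(f"negative state components: {state[state < -1e-9]}")
    params.validate()
    f = make_rhs(params, variant, ext_level=protocol.level_at(t))
    return f(t, np.maximum(state, 0.0))


def variant_terms(hypothesis: str, state, params: ParameterSet,
                  ext_level: float = 0.0):
    """Additive RHS modification of a hypothesis relative to PiOM.

    Returns a vector over the variant's full state: the difference between
    the variant derivative and the base-model derivative embedded in the
    same state space (extra-species rows carry their full dynamics).
    """
    hypothesis = hypothesis.upper()
    if hypothesis == "PIOM":
        raise ValueError("variant_terms is defined for the non-base hypotheses")
    variant = ModelVariant(hypothesis)
    state = np.asarray(state, dtype=float)
    f_var = make_rhs(params, variant, ext_level=ext_level)
    f_base = make_rhs(params, ModelVariant("PIOM"), ext_level=ext_level)
    d_var = f_var(0.0, state)
    d_base = np.zeros_like(d_var)
    d_base[: len(SPECIES)] = f_base(0.0, state[: len(SPECIES)])
    return d_var - d_base


def neutral_overrides(variant: ModelVariant, params: ParameterSet) -> ParameterSet:
    """Parameter overrides under which a variant reproduces PiOM exactly.

    Each hypothesis admits a neutral limit: its extra interactions are
    switched off (rates to ~0, repression constants to ~infinity) and,
    where the variant replaces the basal PHO2 transcription term, the
    variant maximum is rescaled so the effective synthesis equals m4.
    """
    BIG, TINY = 1e12, 1e-12
    v = params.values_dict()
    hyp = variant.hypothesis
    if hyp == "PIOM":
        return params.copy()
    if hyp == "PDTA":
        # K_za -> 0 saturates the Z-activation Hill (H = 1 for any Z that
        # has not underflowed), so PHO2m synthesis is m_a = m4 throughout
        return params.with_values(K_za=1e-300, m_a=v["m4"])
    if hyp == "PDRP":
        return params.with_values(K_zp=BIG)
    if hyp == "PSMD":
        return params.with_values(k_mz=TINY * v["k_mz"], k_zm=TINY * v["k_zm"])
    if hyp == "PSTR":
        # k_tap -> 0 decouples TA from PHO2p; K_zr -> inf removes repression
        ta0 = v["m_ta"] / v["d_ta"]
        m_a = v["m4"] / _hill_up(ta0, v["K_ta"], v["h_ta"])
        return params.with_values(k_tap=TINY * v["k_tap"], K_zr=BIG, m_a=m_a)
    if hyp == "PSRA":
        return params.with_values(d_r=TINY * v["d_r"])
    raise ValueError(hyp)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def _heuristic_state(params: ParameterSet, variant: ModelVariant,
                     ext_level: float) -> np.ndarray:
    v = params.values_dict()
    C0 = v["CytoPi0"] if ext_level > 0 else 0.01
    y = np.zeros(variant.n_species)
    y[_I["SIZ1"]] = v["m1"] / v["d1"]
    y[_I["PHR2a"]] = v["m2"] * y[0] * _hill_down(C0, v["K2"], v["h2"]) / v["d2"]
    y[_I["miR399"]] = (v["m3b"] + v["m3"] * _hill_up(y[1], v["K3"], v["q"])) / v["d3"]
    y[_I["PHO2m"]] = 1.0
    y[_I["PHO2p"]] = v["m5"] / v["d_p"]
    y[_I["IPS1"]] = v["m8"] * _hill_up(y[1], v["K8"], v["r"]) / v["d7"]
    y[_I["IMC"]] = 0.05
    y[_I["PHT"]] = v["m9"] * _hill_down(y[4], v["K9"], v["h9"]) / v["d9"]
    y[_I["PHO1"]] = v["m10"] * _hill_down(y[4], v["K10"], v["h10"]) / v["d10"]
    y[_I["CytoPi"]] = C0
    if variant.hypothesis in ("PDTA", "PDRP"):
        y[10] = v["m_z"] * _hill_up(C0, v["K_zc"], v["h_zc"]) / v["d_z"]
    elif variant.hypothesis == "PSMD":
        y[10] = (v["m_z0"] + v["m_z"] * _hill_down(C0, v["K_zc"], v["h_zc"])) / v["d_z"]
    elif variant.hypothesis == "PSTR":
        y[10] = v["m_ta"] / (v["d_ta"] + v["k_tap"] * y[4])
        y[11] = v["m_z"] * _hill_down(C0, v["K_zc"], v["h_zc"]) / v["d_z"]
    return y


def initial_steady_state(
    params: ParameterSet,
    variant: ModelVariant | None = None,
    ext_level: float = PLUS_PI_LEVEL,
    tol: float = 1e-10,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Steady state under constant external Pi (default: +Pi, 320 µM).

    Solved with a damped Newton iteration (``scipy.optimize.fsolve``) from
    an analytic heuristic; falls back to a long relaxation integration if
    the root find strays.  Raises ``RuntimeError`` if no non-negative root
    with ``||rhs|| < 1e-6`` is found.
    """
    variant = variant or ModelVariant()
    f = make_rhs(params, variant, ext_level=ext_level)

    def g(y):
        return f(0.0, y)

    y0 = np.asarray(x0, dtype=float) if x0 is not None else _heuristic_state(params, variant, ext_level)
    sol, info, ier, _ = fsolve(g, y0, full_output=True, xtol=tol)
    if ier != 1 or np.any(sol < -1e-9) or np.max(np.abs(g(sol))) > 1e-6:
        # relax toward the attractor, then polish
        from scipy.integrate import solve_ivp

        relax = solve_ivp(f, (0.0, 5000.0), np.maximum(y0, 0.0), method="LSODA",
                          rtol=1e-8, atol=1e-10)
        if not relax.success:
            raise RuntimeError(f"steady-state relaxation failed for {variant.name}")
        sol, info, ier, _ = fsolve(g, relax.y[:, -1], full_output=True, xtol=tol)
        if ier != 1 or np.max(np.abs(g(sol))) > 1e-6:
            raise RuntimeError(
                f"no steady state found for {variant.name}: residual "
                f"{np.max(np.abs(g(sol))):.3g}"
            )
    return np.maximum(sol, 0.0)
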