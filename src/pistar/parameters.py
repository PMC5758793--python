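"""Named kinetic parameters for the phosphate-starvation ODE models.

Every rate and constant is strictly positive; Hill coefficients are >= 1.
Each parameter carries a unit, box bounds for fitting, and a ``fixed`` flag.
The internal utilisation rate ``U`` is always held fixed during fitting.
"""
from __future__ import annotations

import copy as _copy
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

__all__ = ["Param", "ParameterSet", "HILL_COEFFICIENTS"]

#: parameters interpreted as Hill coefficients (dimensionless, >= 1)
HILL_COEFFICIENTS = frozenset(
    {"h2", "q", "r", "h9", "h10", "h_ta", "h_zc", "h_zr", "h_za", "h_r"}
)

#: seconds-per-hour conversion applied to the miR399·IPS1 association
#: constant, which is stored in its literature magnitude (per second).
K7_SECONDS_TO_HOURS = 3600.0


@dataclass
class Param:
    """One named rate or constant with fitting metadata."""

    value: float
    unit: str = "au"
    lower: float | None = None
    upper: float | None = None
    fixed: bool = True

    def __post_init__(self) -> None:
        if self.lower is None:
            self.lower = self.value / 10.0
        if self.upper is None:
            self.upper = self.value * 10.0

    def validate(self, name: str) -> None:
        if not (self.value > 0):
            raise ValueError(f"parameter {name!r} must be strictly positive, got {self.value}")
        if not (0 < self.lower <= self.value <= self.upper):
            raise ValueError(
                f"parameter {name!r}: bounds must satisfy 0 < lower <= value <= upper "
                f"(got lower={self.lower}, value={self.value}, upper={self.upper})"
            )
        if name in HILL_COEFFICIENTS and self.value < 1:
            raise ValueError(f"Hill coefficient {name!r} must be >= 1, got {self.value}")


class ParameterSet(Mapping):
    """Ordered mapping of parameter name -> :class:`Param`.

    Behaves as a read-only mapping of names to :class:`Param` objects;
    use :meth:`value` / :meth:`values_dict` for the bare floats and
    :meth:`with_values` to derive modified copies.
    """

    def __init__(self, params: Mapping[str, Param]):
        self._params: dict[str, Param] = dict(params)
        self.validate()

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> Param:
        return self._params[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    # -- convenience ------------------------------------------------------
    def value(self, name: str) -> float:
        return self._params[name].value

    def values_dict(self) -> dict[str, float]:
        return {k: p.value for k, p in self._params.items()}

    def free_names(self) -> list[str]:
        return [k for k, p in self._params.items() if not p.fixed]

    def n_free(self) -> int:
        return len(self.free_names())

    def bounds(self, names: list[str] | None = None) -> list[tuple[float, float]]:
        names = names if names is not None else self.free_names()
        return [(self._params[n].lower, self._params[n].upper) for n in names]

    def copy(self) -> "ParameterSet":
        return ParameterSet({k: _copy.copy(p) for k, p in self._params.items()})

    def with_values(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given parameter values replaced.

        Bounds are widened when an update falls outside the stored box so
        the copy still validates (used by neutral-limit constructions).
        """
        out = {k: _copy.copy(p) for k, p in self._params.items()}
        for name, value in updates.items():
            if name not in out:
                raise KeyError(f"unknown parameter {name!r}")
            p = out[name]
            p.value = float(value)
            p.lower = min(p.lower, p.value)
            p.upper = max(p.upper, p.value)
        return ParameterSet(out)

    def set_free(self, names: list[str]) -> "ParameterSet":
        """Return a copy in which exactly ``names`` are free (fittable)."""
        unknown = set(names) - set(self._params)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        if "U" in names:
            raise ValueError("the utilisation rate U is held fixed during fitting")
        out = {k: _copy.copy(p) for k, p in self._params.items()}
        for k, p in out.items():
            p.fixed = k not in names
        return ParameterSet(out)

    def validate(self) -> None:
        for name, p in self._params.items():
            p.validate(name)

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            k: {
                "value": p.value,
                "unit": p.unit,
                "lower": p.lower,
                "upper": p.upper,
                "fixed": p.fixed,
            }
            for k, p in self._params.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        params = {}
        for k, spec in d.items():
            if isinstance(spec, Mapping):
                params[k] = Param(
                    value=float(spec["value"]),
                    unit=str(spec.get("unit", "au")),
                    lower=spec.get("lower"),
                    upper=spec.get("upper"),
                    fixed=bool(spec.get("fixed", True)),
                )
            else:  # bare number shorthand
                params[k] = Param(value=float(spec))
        return cls(params)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        free = ", ".join(self.free_names()) or "none"
        return f"<ParameterSet n={len(self)} free=[{free}]>"
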