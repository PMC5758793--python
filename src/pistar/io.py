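"""Readers and writers: observation tables, parameter files, fit results.

Observation tables are plain UTF-8 comma-separated files with the header
``time_h,target,condition,replicate,fold_change`` (time in hours, decimal
point, conditions as the lowercase tokens plusPi/minusPi/repletion).
Parameter/configuration files are JSON or YAML keyed by parameter name,
each entry a ``{value, unit, lower, upper, fixed}`` mapping, with optional
``variant`` and ``protocol`` blocks.  Outputs are never silently
overwritten without ``force``.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .inference import FitResult
from .model import EnvironmentProtocol, ModelVariant
from .parameters import ParameterSet
from .simulate import TARGETS
from .synth import OBSERVATION_COLUMNS

__all__ = [
    "SchemaError",
    "read_observations",
    "write_observations",
    "read_parameter_file",
    "write_parameter_file",
    "read_fit_result",
    "write_fit_result",
]

_CONDITIONS = ("plusPi", "minusPi", "repletion")


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


def _check_overwrite(path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")


def read_observations(path) -> pd.DataFrame:
    """Read and validate a fold-change observation table."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    unknown_targets = sorted(set(df["target"].astype(str)) - set(TARGETS))
    if unknown_targets:
        raise SchemaError(f"{path}: unknown target(s) {unknown_targets}; expected {TARGETS}")
    unknown_cond = sorted(set(df["condition"].astype(str)) - set(_CONDITIONS))
    if unknown_cond:
        raise SchemaError(f"{path}: unknown condition(s) {unknown_cond}; expected {_CONDITIONS}")
    fc = pd.to_numeric(df["fold_change"], errors="coerce")
    bad = df.index[~(fc > 0)].tolist()
    if bad:
        raise SchemaError(f"{path}: non-positive or non-numeric fold_change at row(s) {bad}")
    df["fold_change"] = fc.astype(float)
    df["time_h"] = pd.to_numeric(df["time_h"]).astype(float)

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        df.attrs.update(json.loads(sidecar.read_text()))
    return df[list(OBSERVATION_COLUMNS)]


def write_observations(df: pd.DataFrame, path, metadata: dict | None = None,
                       force: bool = False) -> Path:
    """Write an observation table plus a JSON metadata sidecar."""
    path = Path(path)
    _check_overwrite(path, force)
    df[list(OBSERVATION_COLUMNS)].to_csv(path, index=False)
    meta = dict(df.attrs)
    if metadata:
        meta.update(metadata)
    if meta:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, default=str) + "\n"
        )
    return path


# ---------------------------------------------------------------------------
# parameter / configuration files
# ---------------------------------------------------------------------------

def _protocol_to_obj(protocol: EnvironmentProtocol) -> list:
    return [list(seg) for seg in protocol.segments]


def write_parameter_file(
    params: ParameterSet,
    path,
    variant: ModelVariant | None = None,
    protocol: EnvironmentProtocol | None = None,
    force: bool = False,
) -> Path:
    path = Path(path)
    _check_overwrite(path, force)
    doc: dict = {"parameters": params.to_dict()}
    if variant is not None:
        doc["variant"] = {
            "hypothesis": variant.hypothesis,
            "rp": variant.rp,
            "mir399_catalytic": variant.mir399_catalytic,
        }
    if protocol is not None:
        doc["protocol"] = _protocol_to_obj(protocol)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def read_parameter_file(path):
    """Read a parameter file; returns (ParameterSet, variant|None, protocol|None)."""
    path = Path(path)
    text = path.read_text()
    doc = (yaml.safe_load(text) if path.suffix.lower() in (".yaml", ".yml")
           else json.loads(text))
    if "parameters" not in doc:
        raise SchemaError(f"{path}: missing 'parameters' block")
    params = ParameterSet.from_dict(doc["parameters"])
    variant = None
    if "variant" in doc:
        v = doc["variant"]
        variant = ModelVariant(
            v["hypothesis"], rp=bool(v.get("rp", False)),
            mir399_catalytic=bool(v.get("mir399_catalytic", True)),
        )
    protocol = None
    if "protocol" in doc:
        protocol = EnvironmentProtocol(tuple(tuple(seg) for seg in doc["protocol"]))
    return params, variant, protocol


def write_fit_result(result: FitResult, path, force: bool = False) -> Path:
    path = Path(path)
    _check_overwrite(path, force)
    path.write_text(json.dumps(result.to_dict(), indent=2, default=float) + "\n")
    return path


def read_fit_result(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))
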