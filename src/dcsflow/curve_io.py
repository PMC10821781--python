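"""Curve and configuration I/O.

Curves are columnar CSV (header ``tau_us,value``) with a JSON sidecar
(`<name>.json`) carrying provenance: generator, parameters, seed, kind.
Configs are flat ``key = value`` text documents.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward_models import CorrelationCurve, DelayGrid

__all__ = ["write_curve", "read_curve", "read_config"]


def write_curve(curve: CorrelationCurve, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"tau_us": curve.grid.tau_us, "value": curve.values})
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {"kind": curve.kind, "provenance": curve.provenance}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, default=str))


def read_curve(path: str | Path) -> CorrelationCurve:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["tau_us", "value"]:
        raise ValueError(f"{path}: expected columns tau_us,value")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    kind, prov = "intensity", {}
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        kind = sc.get("kind", "intensity")
        prov = sc.get("provenance", {})
    grid = DelayGrid(df["tau_us"].to_numpy() * 1e-6)
    return CorrelationCurve(grid, df["value"].to_numpy(), kind, prov)


def read_config(path: str | Path) -> dict:
    """Flat key = value document; values parsed as JSON scalars when possible."""
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        try:
            out[key] = json.loads(val)
        except json.JSONDecodeError:
            out[key] = val
    return out
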