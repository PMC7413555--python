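"""Reading and writing force curves, metric tables and run configurations.

Curves travel as plain columnar text (TSV) with a unit-tagged header --
``time_s  indentation_m  force_N  phase`` in SI or
``time_s  indentation_nm  force_nN  phase`` in AFM convention -- plus a
JSON sidecar carrying the simulation metadata.  Values are printed with
``%.12e`` so a write/read round trip preserves them to ~1e-13 relative.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ting import ForceCurve

__all__ = [
    "write_curve",
    "read_curve",
    "write_sweep",
    "load_config",
    "sidecar_path",
]

_SI_COLS = ["time_s", "indentation_m", "force_N", "phase"]
_AFM_COLS = ["time_s", "indentation_nm", "force_nN", "phase"]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".meta.json")


def write_curve(curve: ForceCurve, path, units: str = "si") -> Path:
    """Write a curve as TSV (+ JSON metadata sidecar); returns the sidecar path."""
    path = Path(path)
    if units == "si":
        cols, dscale, fscale = _SI_COLS, 1.0, 1.0
    elif units == "afm":
        cols, dscale, fscale = _AFM_COLS, 1e9, 1e9
    else:
        raise ValueError("units must be 'si' or 'afm'")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t, d, F, ph in zip(curve.t, curve.delta, curve.F, curve.phase):
            fh.write(f"{t:.12e}\t{d * dscale:.12e}\t{F * fscale:.12e}\t{ph}\n")
    meta = dict(curve.metadata)
    meta.update({"t_m": curve.t_m, "t_detach": curve.t_detach, "t_ind": curve.t_detach,
                 "units": units})
    side = sidecar_path(path)
    with open(side, "w") as fh:
        json.dump(meta, fh, indent=1, default=float)
    return side


def read_curve(path) -> ForceCurve:
    """Read a TSV force curve; units are inferred from the header tags.

    A ``phase`` column is honoured when present; otherwise the curve is
    split at the maximum depth.  Detachment is taken at the first zero
    force on the retraction (the end of the record if force stays
    positive).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower(): c for c in df.columns}
    if "indentation_m" in cols:
        dscale, fcol_scale, dcol, fcol = 1.0, 1.0, cols["indentation_m"], cols.get("force_n")
    elif "indentation_nm" in cols:
        dscale, fcol_scale, dcol, fcol = 1e-9, 1e-9, cols["indentation_nm"], cols.get("force_nn")
    else:
        raise ValueError(
            f"{path}: expected a header with indentation_m/force_N or indentation_nm/force_nN"
        )
    if fcol is None or "time_s" not in cols:
        raise ValueError(f"{path}: missing time_s or force column")
    t = df[cols["time_s"]].to_numpy(float)
    delta = df[dcol].to_numpy(float) * dscale
    F = df[fcol].to_numpy(float) * fcol_scale
    if "phase" in cols:
        phase = df[cols["phase"]].astype(str).to_numpy()
        bad = ~np.isin(phase, ["approach", "retract"])
        if np.any(bad):
            raise ValueError(f"{path}: unknown phase labels {set(phase[bad])}")
    else:
        imax = int(np.argmax(delta))
        phase = np.where(np.arange(t.size) <= imax, "approach", "retract")
    app = phase == "approach"
    t_m = float(t[app][-1]) if np.any(app) else float(t[0])
    ret = ~app
    t_detach = float(t[-1])
    if np.any(ret):
        zero = ret & (F <= 0.0)
        if np.any(zero):
            t_detach = float(t[zero][0])
    meta = {"source": str(path)}
    side = sidecar_path(path)
    if side.exists():
        with open(side) as fh:
            meta.update(json.load(fh))
    return ForceCurve(t, delta, F, phase, t_m, t_detach, np.full(t.size, np.nan), meta)


def write_sweep(sweep, path) -> None:
    """Write a metrics-vs-time table as TSV (NaN rendered as NA)."""
    df = sweep.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.12e", na_rep="NA")


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
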