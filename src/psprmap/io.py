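"""Strict readers/writers for the tool's CSV/JSON/YAML interchange formats.

All files are UTF-8 with '.' decimal separators; schema violations raise
:class:`SchemaError` naming the offending column or value.  Write→read round
trips are identity for canonical files.

Formats
-------
calibration CSV   columns: ri, dphase_rad, baseline  (exactly one baseline=true row)
phasogram CSV     columns: time_s, phase_rad, roi_id
sensorgram CSV    columns: time_s, ri, roi_id
trace CSV         columns: iteration, angle_deg, au_nm, probe_nm, probe_ri, ssr, log10_ssr
model JSON        see :mod:`psprmap.metamodel`
stack YAML        wavelength_nm + ordered layers (name, n_re, n_im, thickness_nm|semi_infinite)
bounds YAML       per-parameter [lo, hi]
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationSet, ParameterBounds, TrialRecord
from .fresnel import OpticalLayer, OpticalStack
from .metamodel import SegmentedCubicModel, model_from_json, model_to_json
from .pipeline import Phasogram, Sensorgram

__all__ = [
    "SchemaError",
    "read_calibration",
    "write_calibration",
    "read_phasogram",
    "write_phasogram",
    "read_sensorgram",
    "write_sensorgram",
    "read_model",
    "write_model",
    "read_stack",
    "write_stack",
    "read_bounds",
    "write_bounds",
    "write_trace",
    "read_trace",
]


class SchemaError(ValueError):
    """Malformed input file."""


_FLOAT_FMT = "%.12g"


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def _numeric(df: pd.DataFrame, col: str, fname: str) -> np.ndarray:
    vals = df[col].astype(str)
    if vals.str.contains(",").any():
        row = int(vals.str.contains(",").idxmax())
        raise SchemaError(
            f"{fname}: column {col!r} row {row}: decimal commas are not accepted "
            "(dialect is fixed to '.')"
        )
    try:
        return vals.astype(float).to_numpy()
    except ValueError as exc:
        raise SchemaError(f"{fname}: column {col!r} is not numeric: {exc}") from exc


# -- calibration -------------------------------------------------------------


def read_calibration(path) -> CalibrationSet:
    df = _read_csv(path, ("ri", "dphase_rad", "baseline"))
    name = Path(path).name
    ri = _numeric(df, "ri", name)
    dph = _numeric(df, "dphase_rad", name)
    flags = df["baseline"].str.strip().str.lower().isin(("true", "1", "yes"))
    if flags.sum() != 1:
        raise SchemaError(f"{name}: exactly one row must have baseline=true")
    i = int(np.flatnonzero(flags.to_numpy())[0])
    baseline_ri = float(ri[i])
    mask = ~flags.to_numpy()
    order = np.argsort(ri[mask])
    return CalibrationSet(
        ris=ri[mask][order], dphases=dph[mask][order], baseline_ri=baseline_ri
    )


def write_calibration(cal: CalibrationSet, path) -> None:
    rows = [{"ri": cal.baseline_ri, "dphase_rad": 0.0, "baseline": True}]
    rows += [
        {"ri": r, "dphase_rad": p, "baseline": False}
        for r, p in zip(cal.ris, cal.dphases)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- time series -------------------------------------------------------------


def read_phasogram(path) -> list[Phasogram]:
    """Read one Phasogram per ROI id, in order of first appearance."""
    df = _read_csv(path, ("time_s", "phase_rad", "roi_id"))
    name = Path(path).name
    t = _numeric(df, "time_s", name)
    p = _numeric(df, "phase_rad", name)
    roi = df["roi_id"].astype(str).to_numpy()
    out = []
    for rid in pd.unique(roi):
        m = roi == rid
        out.append(Phasogram(time=t[m], phase=p[m], roi_id=str(rid)))
    return out


def write_phasogram(phasograms: Phasogram | list[Phasogram], path) -> None:
    if isinstance(phasograms, Phasogram):
        phasograms = [phasograms]
    frames = [
        pd.DataFrame({"time_s": p.time, "phase_rad": p.phase, "roi_id": p.roi_id})
        for p in phasograms
    ]
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sensorgram(path) -> list[Sensorgram]:
    df = _read_csv(path, ("time_s", "ri", "roi_id"))
    name = Path(path).name
    t = _numeric(df, "time_s", name)
    r = _numeric(df, "ri", name)
    roi = df["roi_id"].astype(str).to_numpy()
    return [
        Sensorgram(time=t[roi == rid], ri=r[roi == rid], roi_id=str(rid))
        for rid in pd.unique(roi)
    ]


def write_sensorgram(sensorgrams: Sensorgram | list[Sensorgram], path) -> None:
    if isinstance(sensorgrams, Sensorgram):
        sensorgrams = [sensorgrams]
    frames = [
        pd.DataFrame({"time_s": s.time, "ri": s.ri, "roi_id": s.roi_id})
        for s in sensorgrams
    ]
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- model / configs ---------------------------------------------------------


def read_model(path) -> SegmentedCubicModel:
    return model_from_json(Path(path).read_text(encoding="utf-8"))


def write_model(model: SegmentedCubicModel, path) -> None:
    Path(path).write_text(model_to_json(model), encoding="utf-8")


def read_stack(path) -> OpticalStack:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    name = Path(path).name
    if not isinstance(doc, dict) or "layers" not in doc:
        raise SchemaError(f"{name}: stack config must be a mapping with a 'layers' list")
    layers = []
    for i, lay in enumerate(doc["layers"]):
        for key in ("name", "n_re"):
            if key not in lay:
                raise SchemaError(f"{name}: layer {i}: missing key {key!r}")
        thick = lay.get("thickness_nm", "semi_infinite")
        layers.append(
            OpticalLayer(
                label=str(lay["name"]),
                refractive_index=complex(float(lay["n_re"]), float(lay.get("n_im", 0.0))),
                thickness_nm=None if thick == "semi_infinite" else float(thick),
            )
        )
    return OpticalStack(tuple(layers), float(doc.get("wavelength_nm", 850.0)))


def write_stack(stack: OpticalStack, path) -> None:
    doc = {
        "wavelength_nm": stack.wavelength_nm,
        "layers": [
            {
                "name": lay.label,
                "n_re": complex(lay.refractive_index).real,
                "n_im": complex(lay.refractive_index).imag,
                "thickness_nm": "semi_infinite" if lay.semi_infinite else float(lay.thickness_nm),
            }
            for lay in stack.layers
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


_BOUND_KEYS = ("incident_angle", "au_thickness", "probe_thickness", "probe_ri")


def read_bounds(path) -> ParameterBounds:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    name = Path(path).name
    if not isinstance(doc, dict):
        raise SchemaError(f"{name}: bounds config must be a mapping")
    kwargs = {}
    for key in _BOUND_KEYS:
        if key in doc:
            pair = doc[key]
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                raise SchemaError(f"{name}: {key} must be a [lo, hi] pair")
            kwargs[key] = (float(pair[0]), float(pair[1]))
    return ParameterBounds(**kwargs)


def write_bounds(bounds: ParameterBounds, path) -> None:
    doc = {key: list(getattr(bounds, key)) for key in _BOUND_KEYS}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# -- optimizer trace ---------------------------------------------------------


def write_trace(trace, path) -> None:
    pd.DataFrame(
        [
            {
                "iteration": i,
                "angle_deg": t.incident_angle,
                "au_nm": t.au_thickness,
                "probe_nm": t.probe_thickness,
                "probe_ri": t.probe_ri,
                "ssr": t.ssr,
                "log10_ssr": t.log10_ssr,
            }
            for i, t in enumerate(trace)
        ]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace(path) -> list[TrialRecord]:
    df = _read_csv(
        path, ("iteration", "angle_deg", "au_nm", "probe_nm", "probe_ri", "ssr")
    )
    name = Path(path).name
    return [
        TrialRecord(
            incident_angle=float(row["angle_deg"]),
            au_thickness=float(row["au_nm"]),
            probe_thickness=float(row["probe_nm"]),
            probe_ri=float(row["probe_ri"]),
            ssr=float(row["ssr"]),
        )
        for _, row in df.iterrows()
    ]
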