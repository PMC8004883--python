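"""Phasogram → refractive-index sensorgram conversion and consistency reporting.

The converted sensorgram is the paper-trail quantity of a calibrated pSPR
measurement: once each ROI's phasogram is mapped through its own fitted
meta-model, responses from chips with different film thicknesses and angles
become directly comparable in RIU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metamodel import SegmentedCubicModel, PhaseRangeError, invert_phase

__all__ = [
    "Phasogram",
    "Sensorgram",
    "PipelineError",
    "convert",
    "consistency_report",
]


class PipelineError(ValueError):
    """Invalid time series or conversion request."""


@dataclass(frozen=True)
class Phasogram:
    """Phase time series (rad), baseline-referenced, for one region of interest."""

    time: np.ndarray
    phase: np.ndarray
    roi_id: str = "ROI1"
    units: str = "rad"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.phase, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "phase", p)
        if t.ndim != 1 or t.shape != p.shape:
            raise PipelineError("time and phase must be 1-D arrays of equal length")
        if t.size < 1:
            raise PipelineError("empty phasogram")
        if np.any(np.diff(t) <= 0):
            raise PipelineError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise PipelineError("phasogram contains non-finite values")
        if self.units != "rad":
            raise PipelineError(f"phasogram units must be 'rad', got {self.units!r}")


@dataclass(frozen=True)
class Sensorgram:
    """Refractive-index time series; ``kind`` tags Δ-RI from baseline vs absolute."""

    time: np.ndarray
    ri: np.ndarray
    roi_id: str = "ROI1"
    kind: str = "delta"  # "delta" (RI change from baseline) or "absolute"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.ri, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "ri", r)
        if t.ndim != 1 or t.shape != r.shape:
            raise PipelineError("time and ri must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise PipelineError("time must be strictly increasing")
        if self.kind not in ("delta", "absolute"):
            raise PipelineError(f"kind must be 'delta' or 'absolute', got {self.kind!r}")


def convert(
    phasogram: Phasogram,
    model: SegmentedCubicModel,
    baseline_window_s: float = 60.0,
) -> Sensorgram:
    """Convert a phasogram to a Δ-RI sensorgram via the fitted meta-model.

    The mean phase over the leading ``baseline_window_s`` is subtracted first
    (baseline re-referencing), then each sample is inverted with
    temporal-continuity root selection seeded at the model's baseline RI.
    Samples outside the model's valid phase range raise, listing the offending
    indices — never silently clipped.
    """
    if not isinstance(phasogram, Phasogram):
        raise PipelineError(
            f"convert expects a Phasogram in rad, got {type(phasogram).__name__}"
        )
    t0 = phasogram.time[0]
    window = phasogram.time <= t0 + baseline_window_s
    if not np.any(window):
        window = np.zeros_like(phasogram.time, dtype=bool)
        window[0] = True
    phase = phasogram.phase - phasogram.phase[window].mean()

    lo, hi = model.phase_range
    bad = np.flatnonzero((phase < lo) | (phase > hi))
    if bad.size:
        head = ", ".join(str(i) for i in bad[:10])
        raise PhaseRangeError(
            f"{bad.size} phasogram sample(s) outside the model's valid phase range "
            f"[{lo:.4g}, {hi:.4g}] rad (indices: {head}{'...' if bad.size > 10 else ''})"
        )

    # zero re-referenced phase maps to zero delta-RI by construction: the
    # reference point is the model's own inversion of phase 0, which absorbs
    # the meta-model's (sub-noise) fit residual at the baseline
    ri0 = invert_phase(model, 0.0, model.baseline_ri)
    prev = ri0
    ri = np.empty_like(phase)
    for i, ph in enumerate(phase):
        prev = invert_phase(model, float(ph), prev)
        ri[i] = prev
    return Sensorgram(
        time=phasogram.time,
        ri=ri - ri0,
        roi_id=phasogram.roi_id,
        kind="delta",
    )


def consistency_report(sensorgrams: list[Sensorgram]) -> pd.DataFrame:
    """Pairwise RMS differences (RIU) after linear resampling onto the common window."""
    if len(sensorgrams) < 2:
        raise PipelineError("need at least two sensorgrams to compare")
    lo = max(s.time[0] for s in sensorgrams)
    hi = min(s.time[-1] for s in sensorgrams)
    if not (lo < hi):
        raise PipelineError("sensorgrams have non-overlapping time ranges")
    base = sensorgrams[0]
    mask = (base.time >= lo) & (base.time <= hi)
    t = base.time[mask]
    resampled = [np.interp(t, s.time, s.ri) for s in sensorgrams]
    ids = [s.roi_id for s in sensorgrams]
    n = len(sensorgrams)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rms = float(np.sqrt(np.mean((resampled[i] - resampled[j]) ** 2)))
            mat[i, j] = mat[j, i] = rms
    return pd.DataFrame(mat, index=ids, columns=ids)
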