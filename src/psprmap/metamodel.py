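"""Segmented-cubic meta-model of a Fresnel phase-vs-RI mapping curve.

The multilayer reflectivity calculation yields the phase response only
numerically, point by point; to use it as an optimization trial function and as
an invertible phase→RI mapping, the sampled curve is *meta-modeled*: split into
three contiguous chunks of (near-)equal point count, each fitted with an
ordinary least-squares cubic.  Forward evaluation serves the optimizer's
residuals; inversion (cubic root-finding with temporal-continuity root
selection) converts phasograms to refractive-index sensorgrams.

Numerical note: polynomials are fitted and stored in the scaled variable
``w = (ri − origin)/scale`` with the origin at the curve center and the scale
equal to the half-span, so coefficients stay O(1) and root-finding is well
conditioned even though the physical RI span is only a few 1e-3 RIU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MappingCurve",
    "CubicSegment",
    "SegmentedCubicModel",
    "MetaModelError",
    "PhaseRangeError",
    "RIRangeError",
    "build_metamodel",
    "evaluate_phase",
    "invert_phase",
    "model_to_json",
    "model_from_json",
]


class MetaModelError(ValueError):
    """Invalid meta-model input or state."""


class PhaseRangeError(MetaModelError):
    """Requested phase lies outside the model's (extended) valid phase range."""


class RIRangeError(MetaModelError):
    """Requested RI lies outside the model's RI domain."""


@dataclass(frozen=True)
class MappingCurve:
    """Sampled, baseline-referenced, unwrapped phase-vs-RI curve Δφ(n)."""

    ri: np.ndarray
    dphase: np.ndarray
    baseline_ri: float
    extension_fraction: float = 0.0

    def __post_init__(self) -> None:
        ri = np.asarray(self.ri, dtype=float)
        dphase = np.asarray(self.dphase, dtype=float)
        object.__setattr__(self, "ri", ri)
        object.__setattr__(self, "dphase", dphase)
        if ri.ndim != 1 or ri.shape != dphase.shape:
            raise MetaModelError("ri and dphase must be 1-D arrays of equal length")
        if ri.size < 2:
            raise MetaModelError("curve needs at least two samples")
        if np.any(np.diff(ri) <= 0):
            raise MetaModelError("ri must be strictly increasing")
        if not (np.all(np.isfinite(ri)) and np.all(np.isfinite(dphase))):
            raise MetaModelError("curve contains non-finite values")
        if np.any(np.abs(np.diff(dphase)) > np.pi):
            raise MetaModelError("dphase jumps by more than pi between neighbors (unwrap failure)")
        i0 = int(np.argmin(np.abs(ri - self.baseline_ri)))
        if abs(dphase[i0]) > 1e-9:
            raise MetaModelError("dphase is not zero at the baseline RI")

    @property
    def n_points(self) -> int:
        return int(self.ri.size)


@dataclass(frozen=True)
class CubicSegment:
    """One polynomial piece: RI domain [lo, hi] and ascending coefficients in w."""

    lo: float
    hi: float
    coeffs: np.ndarray  # ascending powers of w = (ri - origin)/scale

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))


@dataclass(frozen=True)
class SegmentedCubicModel:
    """Piecewise-cubic Δφ(ri) with invertible evaluation.

    ``phase_range`` is the closed interval of phases the model may be asked to
    invert; it covers the fitted curve's range (the sampled curve itself already
    extends beyond the calibration span so extrapolation stays mild).
    """

    segments: tuple[CubicSegment, ...]
    origin: float
    scale: float
    baseline_ri: float
    phase_range: tuple[float, float]
    max_residual: float
    ssr: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise MetaModelError("model needs at least one segment")
        for a, b in zip(self.segments[:-1], self.segments[1:]):
            if not np.isclose(a.hi, b.lo, rtol=0, atol=1e-12):
                raise MetaModelError("segment domains must partition the RI range without gaps")

    @property
    def ri_range(self) -> tuple[float, float]:
        return (self.segments[0].lo, self.segments[-1].hi)

    # -- forward ----------------------------------------------------------

    def _segment_index(self, ri: np.ndarray) -> np.ndarray:
        """Boundary points are assigned to the lower segment (tie-break)."""
        bounds = np.array([s.hi for s in self.segments[:-1]])
        return np.searchsorted(bounds, ri, side="left")

    def evaluate(self, ri):
        ri_arr = np.atleast_1d(np.asarray(ri, dtype=float))
        lo, hi = self.ri_range
        tol = 1e-12 * max(1.0, abs(hi))
        out_of_domain = (ri_arr < lo - tol) | (ri_arr > hi + tol)
        if np.any(out_of_domain):
            bad = ri_arr[out_of_domain]
            raise RIRangeError(
                f"RI value(s) {bad[:5]} outside model domain [{lo:.6f}, {hi:.6f}]"
            )
        w = (ri_arr - self.origin) / self.scale
        seg = self._segment_index(ri_arr)
        out = np.empty_like(w)
        for k, s in enumerate(self.segments):
            m = seg == k
            if np.any(m):
                out[m] = np.polynomial.polynomial.polyval(w[m], s.coeffs)
        return out if np.ndim(ri) else float(out[0])

    # -- inverse ----------------------------------------------------------

    def _working_branch(self) -> tuple[float, float]:
        """Maximal RI interval around the baseline where the model is monotone."""
        lo, hi = self.ri_range
        grid = np.linspace(lo, hi, 1024)
        vals = self.evaluate(grid)
        d = np.diff(vals)
        i0 = int(np.argmin(np.abs(grid - self.baseline_ri)))
        sgn = np.sign(d[min(i0, d.size - 1)]) or 1.0
        a = i0
        while a > 0 and np.sign(d[a - 1]) == sgn:
            a -= 1
        b = i0
        while b < d.size and np.sign(d[b]) == sgn:
            b += 1
        return float(grid[a]), float(grid[b])

    def invert(self, dphase: float, previous_ri: float | None = None) -> float:
        plo, phi_hi = self.phase_range
        span = max(phi_hi - plo, 1e-12)
        tol = 1e-9 * span
        if not (plo - tol <= dphase <= phi_hi + tol):
            raise PhaseRangeError(
                f"phase {dphase:.6g} rad outside valid range [{plo:.6g}, {phi_hi:.6g}] rad"
            )
        roots: list[float] = []
        lo_all, hi_all = self.ri_range
        dom_tol = 1e-9 * (hi_all - lo_all)
        for k, s in enumerate(self.segments):
            c = s.coeffs.copy()
            c[0] -= dphase
            # ascending -> descending for np.roots
            rts = np.roots(c[::-1]) if np.any(c[1:] != 0) else np.array([])
            for r in rts:
                if abs(r.imag) > 1e-7:
                    continue
                ri = float(r.real) * self.scale + self.origin
                if s.lo - dom_tol <= ri <= s.hi + dom_tol:
                    roots.append(min(max(ri, lo_all), hi_all))
        if not roots:
            # a phase inside the global range can fall into the small jump at a
            # segment joint (no continuity constraint is imposed); land on the
            # nearest attainable value provided the gap is within the fit error
            grid = np.linspace(lo_all, hi_all, 4097)
            vals = self.evaluate(grid)
            i = int(np.argmin(np.abs(vals - dphase)))
            gap = abs(float(vals[i]) - dphase)
            if gap <= max(5 * self.max_residual, 1e-9):
                roots.append(float(grid[i]))
            else:
                raise PhaseRangeError(
                    f"no in-domain root found for phase {dphase:.6g} rad "
                    f"(nearest attainable value is {gap:.3g} rad away)"
                )
        roots_arr = np.array(sorted(set(np.round(roots, 15))))
        if roots_arr.size == 1:
            return float(roots_arr[0])
        if previous_ri is not None:
            return float(roots_arr[np.argmin(np.abs(roots_arr - previous_ri))])
        blo, bhi = self._working_branch()
        inside = roots_arr[(roots_arr >= blo - dom_tol) & (roots_arr <= bhi + dom_tol)]
        if inside.size:
            return float(inside[np.argmin(np.abs(inside - self.baseline_ri))])
        return float(roots_arr[np.argmin(np.abs(roots_arr - self.baseline_ri))])


def build_metamodel(
    curve: MappingCurve, n_segments: int = 3, order: int = 3, provenance: dict | None = None
) -> SegmentedCubicModel:
    """Fit ``n_segments`` least-squares polynomials of ``order`` on equal-count chunks.

    Chunk sizes differ by at most one point.  No continuity constraint is
    imposed at the joints; the joint mismatch is monitored through the stored
    residuals instead.
    """
    if n_segments < 1:
        raise MetaModelError("n_segments must be >= 1")
    n = curve.n_points
    if n < n_segments * (order + 1):
        raise MetaModelError(
            f"{n} samples are too few for {n_segments} segments of order {order}"
        )
    origin = float(0.5 * (curve.ri[0] + curve.ri[-1]))
    scale = float(max(0.5 * (curve.ri[-1] - curve.ri[0]), 1e-12))
    w = (curve.ri - origin) / scale

    chunks = np.array_split(np.arange(n), n_segments)
    # segment k is fitted on chunk k; its domain runs to the first sample of
    # chunk k+1, so the inter-chunk gap belongs to the lower segment
    segments = []
    lo = float(curve.ri[0])
    for k, idx in enumerate(chunks):
        coeffs = np.polynomial.polynomial.polyfit(w[idx], curve.dphase[idx], order)
        hi = float(curve.ri[chunks[k + 1][0]]) if k < n_segments - 1 else float(curve.ri[-1])
        segments.append(CubicSegment(lo, hi, coeffs))
        lo = hi
    model = SegmentedCubicModel(
        segments=tuple(segments),
        origin=origin,
        scale=scale,
        baseline_ri=curve.baseline_ri,
        phase_range=(float(curve.dphase.min()), float(curve.dphase.max())),
        max_residual=0.0,
        ssr=0.0,
        provenance=dict(provenance or {}),
    )
    fitted = model.evaluate(curve.ri)
    res = fitted - curve.dphase
    model = SegmentedCubicModel(
        segments=model.segments,
        origin=origin,
        scale=scale,
        baseline_ri=curve.baseline_ri,
        phase_range=(
            float(min(curve.dphase.min(), fitted.min())),
            float(max(curve.dphase.max(), fitted.max())),
        ),
        max_residual=float(np.max(np.abs(res))),
        ssr=float(np.sum(res**2)),
        provenance=dict(provenance or {}),
    )
    return model


def evaluate_phase(model: SegmentedCubicModel, ri):
    """Forward evaluation Δφ(ri) of the meta-model (rad)."""
    return model.evaluate(ri)


def invert_phase(
    model: SegmentedCubicModel, dphase: float, previous_ri: float | None = None
) -> float:
    """Map a phase shift (rad) back to refractive index (RIU).

    With several in-domain real roots the root nearest ``previous_ri`` wins
    (temporal continuity); without a previous sample, the root on the monotone
    working branch containing the baseline is used.
    """
    return model.invert(float(dphase), previous_ri)


# ---------------------------------------------------------------------------
# serialization


def model_to_json(model: SegmentedCubicModel) -> str:
    doc = {
        "format": "psprmap-segmented-cubic",
        "version": 1,
        "origin": model.origin,
        "scale": model.scale,
        "baseline_ri": model.baseline_ri,
        "phase_range_rad": list(model.phase_range),
        "max_residual_rad": model.max_residual,
        "ssr_rad2": model.ssr,
        "segments": [
            {"ri_lo": s.lo, "ri_hi": s.hi, "coeffs_ascending": s.coeffs.tolist()}
            for s in model.segments
        ],
        "provenance": model.provenance,
    }
    return json.dumps(doc, indent=2)


def model_from_json(text: str) -> SegmentedCubicModel:
    doc = json.loads(text)
    if doc.get("format") != "psprmap-segmented-cubic":
        raise MetaModelError("not a psprmap segmented-cubic model document")
    segments = tuple(
        CubicSegment(s["ri_lo"], s["ri_hi"], np.array(s["coeffs_ascending"]))
        for s in doc["segments"]
    )
    return SegmentedCubicModel(
        segments=segments,
        origin=doc["origin"],
        scale=doc["scale"],
        baseline_ri=doc["baseline_ri"],
        phase_range=tuple(doc["phase_range_rad"]),
        max_residual=doc["max_residual_rad"],
        ssr=doc["ssr_rad2"],
        provenance=doc.get("provenance", {}),
    )
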