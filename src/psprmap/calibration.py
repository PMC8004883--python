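"""Bayesian calibration of the four-parameter chip model against phase-shift data.

A pSPR chip's mapping function depends on quantities that are never known
exactly at fabrication/measurement time: the incidence angle, the gold film
thickness, and the probe monolayer's thickness and effective refractive index.
Given a short calibration table — reference solutions of known RI and their
measured baseline-referenced phase shifts — this module searches that
4-dimensional box with a seeded Gaussian-process expected-improvement optimizer.
Each trial builds the Fresnel mapping curve, meta-models it with the segmented
cubics, and scores the sum of squared phase residuals (rad²) at the calibration
points (baseline included as an ordinary residual term).

The acceptance surface is mapping-function recovery, not parameter recovery:
single-wavelength data cannot uniquely identify the molecular layer, so
different (angle, thickness, RI) combinations yield equivalent mapping
functions.  ``equivalent_model_check`` quantifies that degeneracy in RIU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .fresnel import FresnelError, OpticalStack, default_stack, phase_vs_ri
from .metamodel import (
    MetaModelError,
    SegmentedCubicModel,
    build_metamodel,
    invert_phase,
)

__all__ = [
    "CalibrationSet",
    "ParameterBounds",
    "TrialRecord",
    "OptimizationResult",
    "CalibrationError",
    "objective",
    "optimize",
    "equivalent_model_check",
    "DEFAULT_REFERENCE_RIS",
    "PENALTY_SSR",
]

# NaCl-in-PBS reference solutions used for five-point calibration
DEFAULT_REFERENCE_RIS = (1.3342, 1.3346, 1.3349, 1.3364)
PENALTY_SSR = 1e3  # rad^2, assigned to degenerate trials instead of raising
_LOG10_FLOOR = 1e-300


class CalibrationError(ValueError):
    """Invalid calibration data or optimizer configuration."""


@dataclass(frozen=True)
class CalibrationSet:
    """Known reference RIs with measured baseline-referenced phase shifts (rad)."""

    ris: np.ndarray
    dphases: np.ndarray
    baseline_ri: float

    def __post_init__(self) -> None:
        ris = np.asarray(self.ris, dtype=float)
        dph = np.asarray(self.dphases, dtype=float)
        object.__setattr__(self, "ris", ris)
        object.__setattr__(self, "dphases", dph)
        if ris.shape != dph.shape or ris.ndim != 1:
            raise CalibrationError("ris and dphases must be 1-D arrays of equal length")
        if ris.size < 2:
            raise CalibrationError("need at least two non-baseline calibration points")
        if np.any(np.diff(ris) <= 0):
            raise CalibrationError("reference RIs must be strictly increasing")
        if not np.all(np.isfinite(dph)):
            raise CalibrationError("calibration phases must be finite")

    @property
    def all_ris(self) -> np.ndarray:
        """References plus baseline, sorted."""
        return np.union1d(self.ris, [self.baseline_ri])

    @property
    def all_dphases(self) -> np.ndarray:
        """Phases aligned with :attr:`all_ris` (baseline contributes 0)."""
        ris = self.all_ris
        out = np.zeros_like(ris)
        for r, p in zip(self.ris, self.dphases):
            out[np.argmin(np.abs(ris - r))] = p
        return out

    def ri_span(self, extension: float = 0.1) -> tuple[float, float]:
        """Calibration RI span widened by ``extension`` of the span on each side."""
        ris = self.all_ris
        span = ris[-1] - ris[0]
        return float(ris[0] - extension * span), float(ris[-1] + extension * span)


@dataclass(frozen=True)
class ParameterBounds:
    """Closed search intervals for the four optimized chip parameters."""

    incident_angle: tuple[float, float] = (65.5, 67.5)
    au_thickness: tuple[float, float] = (40.0, 55.0)
    probe_thickness: tuple[float, float] = (5.0, 10.0)
    probe_ri: tuple[float, float] = (1.34, 1.45)

    def __post_init__(self) -> None:
        for name in ("incident_angle", "au_thickness", "probe_thickness", "probe_ri"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise CalibrationError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def lo(self) -> np.ndarray:
        return np.array(
            [
                self.incident_angle[0],
                self.au_thickness[0],
                self.probe_thickness[0],
                self.probe_ri[0],
            ]
        )

    @property
    def hi(self) -> np.ndarray:
        return np.array(
            [
                self.incident_angle[1],
                self.au_thickness[1],
                self.probe_thickness[1],
                self.probe_ri[1],
            ]
        )


@dataclass(frozen=True)
class TrialRecord:
    """One optimizer iteration: the four trial parameters and the SSR they scored."""

    incident_angle: float
    au_thickness: float
    probe_thickness: float
    probe_ri: float
    ssr: float
    penalized: bool = False

    @property
    def log10_ssr(self) -> float:
        return float(np.log10(max(self.ssr, _LOG10_FLOOR)))

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [self.incident_angle, self.au_thickness, self.probe_thickness, self.probe_ri]
        )


@dataclass(frozen=True)
class OptimizationResult:
    best: TrialRecord
    model: SegmentedCubicModel
    trace: tuple[TrialRecord, ...]
    seed: int
    n_iterations: int

    def __post_init__(self) -> None:
        if self.trace and not np.isclose(
            self.best.ssr, min(t.ssr for t in self.trace), rtol=0, atol=0
        ):
            raise CalibrationError("best trial SSR must equal the trace minimum")


def _trial_stack(params: np.ndarray, template: OpticalStack | None) -> OpticalStack:
    _, au, probe_t, probe_ri = (float(v) for v in params)
    if template is None:
        return default_stack(au_thickness_nm=au, probe_thickness_nm=probe_t, probe_ri=probe_ri)
    layers = []
    for lay in template.layers:
        if lay.label == "gold":
            lay = type(lay)(lay.label, lay.refractive_index, au)
        elif lay.label == "probe":
            lay = type(lay)(lay.label, probe_ri, probe_t)
        layers.append(lay)
    return OpticalStack(tuple(layers), template.wavelength_nm)


def _trial_model(
    params: np.ndarray,
    calibration: CalibrationSet,
    stack_template: OpticalStack | None,
    ri_grid_size: int,
    extension: float,
) -> SegmentedCubicModel:
    angle = float(params[0])
    stack = _trial_stack(params, stack_template)
    lo, hi = calibration.ri_span(extension)
    grid = np.union1d(np.linspace(lo, hi, ri_grid_size), calibration.all_ris)
    curve = phase_vs_ri(stack, angle, grid, calibration.baseline_ri)
    return build_metamodel(
        curve,
        provenance={
            "incident_angle_deg": angle,
            "au_thickness_nm": float(params[1]),
            "probe_thickness_nm": float(params[2]),
            "probe_ri": float(params[3]),
            "ri_grid_size": int(ri_grid_size),
            "extension_fraction": float(extension),
        },
    )


def objective(
    params,
    calibration: CalibrationSet,
    stack_template: OpticalStack | None = None,
    ri_grid_size: int = 301,
    extension: float = 0.1,
) -> TrialRecord:
    """Score one trial parameter set: SSR of meta-model phases vs calibration (rad²).

    Degenerate trials (no resonance in range / unwrap failure) are not raised
    but scored with the large finite :data:`PENALTY_SSR` so the surrogate can
    steer away from them.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (4,):
        raise CalibrationError(f"expected 4 parameters, got shape {params.shape}")
    try:
        model = _trial_model(params, calibration, stack_template, ri_grid_size, extension)
        pred = model.evaluate(calibration.all_ris)
        ssr = float(np.sum((pred - calibration.all_dphases) ** 2))
        penalized = False
    except (FresnelError, MetaModelError):
        ssr = PENALTY_SSR
        penalized = True
    return TrialRecord(
        incident_angle=float(params[0]),
        au_thickness=float(params[1]),
        probe_thickness=float(params[2]),
        probe_ri=float(params[3]),
        ssr=ssr,
        penalized=penalized,
    )


def _latin_hypercube(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    """Stratified space-filling design on the unit box."""
    u = (rng.permuted(np.tile(np.arange(n), (dim, 1)), axis=1).T + rng.uniform(size=(n, dim))) / n
    return u


def _expected_improvement(mean: np.ndarray, std: np.ndarray, best: float) -> np.ndarray:
    from scipy.stats import norm

    std = np.maximum(std, 1e-12)
    z = (best - mean) / std
    return (best - mean) * norm.cdf(z) + std * norm.pdf(z)


def _batch_dip_angles(
    au_nm: np.ndarray,
    probe_nm: np.ndarray,
    probe_ri: np.ndarray,
    baseline_ri: float,
    stack_template: OpticalStack | None,
    lo_deg: float = 64.0,
    hi_deg: float = 69.5,
    n_angles: int = 221,
) -> np.ndarray:
    """Resonance-dip angle for a batch of trial stacks (coarse scan + parabolic refine).

    Every optimizer candidate is referenced to its own dip: the useful operating
    angle of a pSPR chip sits a small offset above the dip, and parameterizing
    the search by that offset removes the strong dip-tracking correlation
    between angle and the film parameters.
    """
    from .fresnel import _amplitude_matrix  # noqa: PLC0415

    template = stack_template
    if template is None:
        template = default_stack(buffer_ri=baseline_ri)
    labels = [lay.label for lay in template.layers]
    theta = np.deg2rad(np.linspace(lo_deg, hi_deg, n_angles))[None, :]
    au = np.asarray(au_nm, dtype=float)[:, None]
    pt = np.asarray(probe_nm, dtype=float)[:, None]
    pr = np.asarray(probe_ri, dtype=complex)[:, None]
    indices: list[np.ndarray | complex] = []
    thicknesses: list[np.ndarray | float] = []
    for lay, label in zip(template.layers, labels):
        if label == "gold":
            indices.append(complex(lay.refractive_index))
            thicknesses.append(au)
        elif label == "probe":
            indices.append(pr)
            thicknesses.append(pt)
        else:
            indices.append(complex(lay.refractive_index))
            if not lay.semi_infinite:
                thicknesses.append(float(lay.thickness_nm))
    r_p = _amplitude_matrix(indices, thicknesses, template.wavelength_nm, theta, "p")
    refl = np.abs(r_p) ** 2
    i_min = np.argmin(refl, axis=1)
    i_min = np.clip(i_min, 1, n_angles - 2)
    rows = np.arange(refl.shape[0])
    y0, y1, y2 = refl[rows, i_min - 1], refl[rows, i_min], refl[rows, i_min + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-30, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = (hi_deg - lo_deg) / (n_angles - 1)
    return lo_deg + (i_min + shift) * step


def optimize(
    calibration: CalibrationSet,
    bounds: ParameterBounds | None = None,
    n_iter: int = 120,
    seed: int = 0,
    stack_template: OpticalStack | None = None,
    n_initial: int = 20,
    ri_grid_size: int = 301,
    extension: float = 0.1,
) -> OptimizationResult:
    """Seeded Gaussian-process expected-improvement minimization of :func:`objective`.

    ``n_initial`` Latin-hypercube trials seed the surrogate (a Matérn-5/2 ARD GP
    on log10 SSR); subsequent iterations maximize expected improvement over
    candidates drawn in an adaptive trust region around the incumbent, TuRBO
    style (expand on repeated success, shrink on repeated failure), so the
    optimizer can first locate and then descend the narrow SSR funnel.

    Internally the angle is searched as an *offset from each trial stack's own
    resonance-dip angle*: the SSR landscape is nearly separable in
    (dip offset, Au, probe) coordinates, whereas in absolute angle the optimum
    angle tracks the dip as the film parameters move.  Trial parameters are
    always clipped back into ``bounds``, and the recorded trace carries the
    absolute angle.  Identical seed and inputs reproduce the trace exactly.
    """
    bounds = bounds or ParameterBounds()
    if n_iter < 1:
        raise CalibrationError("n_iter must be >= 1")
    lo, hi = bounds.lo, bounds.hi
    width = hi - lo
    free = width > 0
    rng = np.random.default_rng(seed)

    if not np.any(free):
        rec = objective(lo, calibration, stack_template, ri_grid_size, extension)
        model = _best_model(rec, calibration, stack_template, ri_grid_size, extension)
        return OptimizationResult(rec, model, (rec,), seed, 1)

    # internal unit-box coordinates: [dip-offset, Au, probe thickness, probe RI]
    # (the dip offset replaces the absolute angle; plasmonic phase interrogation
    # operates a fraction of a degree above the dip)
    off_lo, off_hi = -0.2, 0.6
    angle_free = bool(free[0])

    def to_params(u: np.ndarray) -> np.ndarray:
        p = lo.copy()
        p[1:][free[1:]] = lo[1:][free[1:]] + u[1:][free[1:]] * width[1:][free[1:]]
        if angle_free:
            dip = _batch_dip_angles(
                p[1:2], p[2:3], p[3:4], calibration.baseline_ri, stack_template
            )[0]
            p[0] = float(np.clip(dip + off_lo + u[0] * (off_hi - off_lo), lo[0], hi[0]))
        return p

    def run_trial(u: np.ndarray) -> TrialRecord:
        return objective(to_params(u), calibration, stack_template, ri_grid_size, extension)

    trace: list[TrialRecord] = []
    us: list[np.ndarray] = []
    ys: list[float] = []

    n_init = min(n_initial, n_iter)
    for u in _latin_hypercube(rng, n_init, 4):
        rec = run_trial(u)
        trace.append(rec)
        us.append(u)
        ys.append(rec.log10_ssr)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(4, 0.3), length_scale_bounds=(1e-4, 10.0), nu=2.5
    ) + WhiteKernel(1e-8, (1e-12, 1e-1))
    tr_len = 0.4
    n_success = n_fail = 0
    for it in range(n_iter - n_init):
        arr_u = np.array(us)
        arr_y = np.array(ys)
        i_best = int(np.argmin(arr_y))
        u_best, y_best = arr_u[i_best], float(arr_y[i_best])
        dist = np.max(np.abs(arr_u - u_best), axis=1)
        local = dist <= 2 * tr_len
        if local.sum() < 25:
            local = np.argsort(dist)[: min(25, arr_u.shape[0])]
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(seed % (2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            gp.fit(arr_u[local], arr_y[local])
        # candidate pool: trust-region uniform, axis-aligned pattern moves,
        # moves along the principal directions of the current best points (the
        # equivalent-model ridge), and a pinch of global exploration
        pattern = []
        for scale in (0.5, 0.25, 0.1):
            for k in range(4):
                for sign in (1.0, -1.0):
                    step = np.zeros(4)
                    step[k] = sign * scale * tr_len
                    pattern.append(u_best + step)
        order = np.argsort(arr_y)[:15]
        elite = arr_u[order] - arr_u[order].mean(axis=0)
        if elite.shape[0] >= 5:
            _, _, vt = np.linalg.svd(elite, full_matrices=False)
            for v in vt[:2]:
                for t in (-0.4, -0.2, -0.1, -0.05, 0.05, 0.1, 0.2, 0.4):
                    pattern.append(u_best + t * v)
        cand = np.vstack(
            [
                np.clip(u_best + tr_len * (rng.uniform(size=(512, 4)) - 0.5), 0, 1),
                np.clip(np.array(pattern), 0, 1),
                rng.uniform(size=(32, 4)),
            ]
        )
        mean, std = gp.predict(cand, return_std=True)
        if it % 2 == 0:
            acq = _expected_improvement(mean, std, y_best)
        else:
            acq = -mean  # greedy exploitation every other round
        u = cand[int(np.argmax(acq))]
        rec = run_trial(u)
        trace.append(rec)
        us.append(u)
        ys.append(rec.log10_ssr)
        if rec.log10_ssr < y_best - 1e-6:
            n_success += 1
            n_fail = 0
        else:
            n_fail += 1
            n_success = 0
        if n_success >= 2:
            tr_len = min(tr_len * 2.0, 1.0)
            n_success = 0
        if n_fail >= 4:
            tr_len = max(tr_len / 1.7, 1e-3)
            n_fail = 0
        if tr_len <= 1e-3:  # converged trust region: restart wide
            tr_len = 0.4
            n_success = n_fail = 0

    best_idx = int(np.argmin([t.ssr for t in trace]))
    best = trace[best_idx]
    model = _best_model(best, calibration, stack_template, ri_grid_size, extension)
    return OptimizationResult(best, model, tuple(trace), seed, len(trace))


def _best_model(
    rec: TrialRecord,
    calibration: CalibrationSet,
    stack_template,
    ri_grid_size: int,
    extension: float,
) -> SegmentedCubicModel:
    if rec.penalized:
        raise CalibrationError(
            "best trial is degenerate (penalized); widen bounds or check calibration data"
        )
    return _trial_model(rec.params, calibration, stack_template, ri_grid_size, extension)


def equivalent_model_check(
    result_a: OptimizationResult | SegmentedCubicModel,
    result_b: OptimizationResult | SegmentedCubicModel,
    phase_range: tuple[float, float] | None = None,
    n_grid: int = 512,
) -> float:
    """Max |RI_a(φ) − RI_b(φ)| over a dense phase grid (RIU): mapping degeneracy metric."""
    model_a = result_a.model if isinstance(result_a, OptimizationResult) else result_a
    model_b = result_b.model if isinstance(result_b, OptimizationResult) else result_b
    lo = max(model_a.phase_range[0], model_b.phase_range[0])
    hi = min(model_a.phase_range[1], model_b.phase_range[1])
    if phase_range is not None:
        lo, hi = max(lo, phase_range[0]), min(hi, phase_range[1])
    if not (lo < hi):
        raise CalibrationError("models have disjoint valid phase ranges")
    grid = np.linspace(lo, hi, n_grid)
    prev_a = prev_b = None
    worst = 0.0
    for ph in grid:
        ri_a = invert_phase(model_a, ph, prev_a)
        ri_b = invert_phase(model_b, ph, prev_b)
        prev_a, prev_b = ri_a, ri_b
        worst = max(worst, abs(ri_a - ri_b))
    return worst
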