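"""Synthetic ground-truth chips, calibration tables, and binding phasograms.

Everything the pipeline consumes can be generated here from a known chip, so
end-to-end behavior (calibration → meta-model → conversion → kinetics) is
testable against ground truth without instrument data.  Generators are pure
functions of their parameters and seed.

The stated measurement world: five-point calibration (four NaCl reference
solutions at RI 1.3342/1.3346/1.3349/1.3364 plus running-buffer baseline),
i.i.d. Gaussian phase noise of 0.001 rad, and chips within the displayed
regimes (Au 44–48 nm, angles near 66.3–66.5°, an aptamer probe monolayer of
about 22 bp ≈ 7.5 nm at 0.34 nm/bp with effective RI 1.40).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import DEFAULT_REFERENCE_RIS, CalibrationSet
from .fresnel import OpticalStack, default_stack, phase_vs_ri
from .kinetics import KineticParameters
from .pipeline import Phasogram

__all__ = [
    "GroundTruthChip",
    "NoiseModel",
    "DEFAULT_BASELINE_RI",
    "make_calibration",
    "phasogram_from_ri",
    "make_binding_phasogram",
    "make_reference_phasogram",
    "make_roi_pair",
]

DEFAULT_BASELINE_RI = 1.3340  # running PBS buffer, just below the first NaCl reference


@dataclass(frozen=True)
class GroundTruthChip:
    """The four fittable parameters of a chip, with physical plausibility windows."""

    incident_angle: float = 66.4
    au_thickness: float = 46.0
    probe_thickness: float = 7.5
    probe_ri: float = 1.40

    def __post_init__(self) -> None:
        if not (60.0 <= self.incident_angle <= 75.0):
            raise ValueError(f"incident angle {self.incident_angle} outside 60-75 deg")
        if not (35.0 <= self.au_thickness <= 60.0):
            raise ValueError(f"Au thickness {self.au_thickness} outside 35-60 nm")
        if not (0.0 <= self.probe_thickness <= 30.0):
            raise ValueError(f"probe thickness {self.probe_thickness} outside 0-30 nm")
        if not (1.30 <= self.probe_ri <= 1.60):
            raise ValueError(f"probe RI {self.probe_ri} outside 1.30-1.60")

    def to_stack(self, buffer_ri: float = DEFAULT_BASELINE_RI) -> OpticalStack:
        return default_stack(
            au_thickness_nm=self.au_thickness,
            probe_thickness_nm=self.probe_thickness,
            probe_ri=self.probe_ri,
            buffer_ri=buffer_ri,
        )

    def mapping_curve(
        self,
        baseline_ri: float = DEFAULT_BASELINE_RI,
        lo: float | None = None,
        hi: float | None = None,
        n: int = 1001,
    ):
        """Dense ground-truth Fresnel Δφ(n) curve (the chip's true mapping)."""
        refs = np.asarray(DEFAULT_REFERENCE_RIS)
        span = refs[-1] - baseline_ri
        lo = baseline_ri - 0.1 * span if lo is None else lo
        hi = refs[-1] + 0.1 * span if hi is None else hi
        grid = np.linspace(lo, hi, n)
        return phase_vs_ri(self.to_stack(baseline_ri), self.incident_angle, grid, baseline_ri)


@dataclass(frozen=True)
class NoiseModel:
    """i.i.d. Gaussian phase noise; sigma defaults to the instrument's ~0.001 rad."""

    sigma_phase: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_phase < 0:
            raise ValueError("sigma_phase must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_calibration(
    chip: GroundTruthChip,
    reference_ris=DEFAULT_REFERENCE_RIS,
    baseline_ri: float = DEFAULT_BASELINE_RI,
    noise: NoiseModel | None = None,
) -> CalibrationSet:
    """Fresnel-exact reference phase shifts plus seeded Gaussian noise.

    The baseline row is, by construction, the zero of the referencing and
    carries no noise term (the measured quantity is the shift *from* baseline).
    """
    refs = np.sort(np.asarray(reference_ris, dtype=float))
    lo = float(min(refs[0], baseline_ri))
    hi = float(max(refs[-1], baseline_ri))
    grid = np.union1d(np.linspace(lo, hi, 513), refs)
    curve = phase_vs_ri(
        chip.to_stack(baseline_ri), chip.incident_angle, grid, baseline_ri
    )
    exact = {float(r): float(p) for r, p in zip(curve.ri, curve.dphase)}
    dphases = np.array([exact[float(r)] for r in refs])
    if noise is not None and noise.sigma_phase > 0:
        dphases = dphases + noise.rng().normal(0.0, noise.sigma_phase, size=refs.size)
    return CalibrationSet(ris=refs, dphases=dphases, baseline_ri=float(baseline_ri))


def phasogram_from_ri(
    chip: GroundTruthChip,
    time_s: np.ndarray,
    delta_ri: np.ndarray,
    baseline_ri: float = DEFAULT_BASELINE_RI,
    noise: NoiseModel | None = None,
    roi_id: str = "ROI1",
) -> Phasogram:
    """Push an effective-RI time course through the chip's true phase map."""
    time_s = np.asarray(time_s, dtype=float)
    delta_ri = np.asarray(delta_ri, dtype=float)
    ri_values = baseline_ri + delta_ri
    lo = float(min(baseline_ri, ri_values.min())) - 1e-6
    hi = float(max(baseline_ri, ri_values.max())) + 1e-6
    # the sample RIs are folded into the grid so each phase is Fresnel-exact,
    # not interpolated
    grid = np.union1d(np.linspace(lo, hi, 257), np.unique(ri_values))
    curve = phase_vs_ri(chip.to_stack(baseline_ri), chip.incident_angle, grid, baseline_ri)
    idx = np.searchsorted(curve.ri, ri_values)
    phase = curve.dphase[idx]
    if noise is not None and noise.sigma_phase > 0:
        phase = phase + noise.rng().normal(0.0, noise.sigma_phase, size=phase.size)
    return Phasogram(time=time_s, phase=phase, roi_id=roi_id)


def make_binding_phasogram(
    chip: GroundTruthChip,
    kinetics: KineticParameters,
    duration_s: float = 6000.0,
    dt_s: float = 1.0,
    noise: NoiseModel | None = None,
    baseline_s: float = 300.0,
    baseline_ri: float = DEFAULT_BASELINE_RI,
    roi_id: str = "ROI1",
) -> Phasogram:
    """Langmuir association→dissociation RI course through the chip's phase map.

    Timeline: flat baseline until ``baseline_s``; association (rate τ, plateau
    ΔS_max RIU) until the kinetics' dissociation start ``t0``; single-exponential
    dissociation (k_off) afterwards.
    """
    t = np.arange(0.0, duration_s, dt_s)
    delta = np.zeros_like(t)
    t_on = baseline_s
    t_off = kinetics.t0
    if not (t_on < t_off <= duration_s):
        raise ValueError("need baseline_s < kinetics.t0 <= duration_s")
    curve = chip.mapping_curve(baseline_ri)
    if not (curve.ri[0] <= baseline_ri + kinetics.dS_max <= curve.ri[-1]):
        raise ValueError(
            f"binding excursion {kinetics.dS_max:+.3g} RIU leaves the chip's "
            f"mapping range [{curve.ri[0]:.5f}, {curve.ri[-1]:.5f}]"
        )
    assoc = (t >= t_on) & (t < t_off)
    delta[assoc] = kinetics.dS_max * (1 - np.exp(-kinetics.tau * (t[assoc] - t_on)))
    level = kinetics.dS_max * (1 - np.exp(-kinetics.tau * (t_off - t_on)))
    dis = t >= t_off
    delta[dis] = level * np.exp(-kinetics.k_off * (t[dis] - t_off))
    return phasogram_from_ri(chip, t, delta, baseline_ri, noise, roi_id)


def make_reference_phasogram(
    chip: GroundTruthChip,
    reference_ris=DEFAULT_REFERENCE_RIS,
    step_s: float = 300.0,
    dt_s: float = 1.0,
    noise: NoiseModel | None = None,
    baseline_ri: float = DEFAULT_BASELINE_RI,
    roi_id: str = "ROI1",
) -> Phasogram:
    """Staircase reference-solution series: baseline, then each reference, then buffer."""
    refs = list(reference_ris)
    levels = [0.0] + [r - baseline_ri for r in refs] + [0.0]
    t = np.arange(0.0, step_s * len(levels), dt_s)
    delta = np.repeat(levels, int(round(step_s / dt_s)))[: t.size]
    return phasogram_from_ri(chip, t, delta, baseline_ri, noise, roi_id)


def make_roi_pair(
    chip: GroundTruthChip, d_thickness: float = 1.2, d_angle: float = 0.05
) -> tuple[GroundTruthChip, GroundTruthChip]:
    """Two nearby ROIs on one chip: same probe layer, Au thickness and angle offsets."""
    other = replace(
        chip,
        au_thickness=chip.au_thickness + d_thickness,
        incident_angle=chip.incident_angle + d_angle,
    )
    return chip, other
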