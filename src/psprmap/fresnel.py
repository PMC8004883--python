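"""Stratified-medium Fresnel reflectivity for Kretschmann-configuration SPR chips.

The sensor is modeled as a stack of homogeneous, isotropic layers bounded by two
semi-infinite media: the coupling prism (incidence side) and the aqueous buffer
(exit side).  Monochromatic plane-wave reflectivity is computed for both p and s
polarization; the observable used downstream is the baseline-referenced p−s
differential phase, which is what a polarimetric homodyne interferometer reads
out through its analyzer.

Two independent formulations are provided and cross-checked in the test suite:

* the Abelès characteristic-matrix method (``method="matrix"``, the default),
* interface-by-interface recursive Fresnel composition (``method="recursive"``).

Conventions: angles are degrees at the API surface and radians internally; the
normal wavevector branch is chosen with Im(n·cosθ) ≥ 0 so evanescent fields
decay away from each interface; absorbing media carry a non-negative imaginary
refractive-index part.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OpticalLayer",
    "OpticalStack",
    "ComplexReflectivity",
    "FresnelError",
    "GridTooCoarseError",
    "interface_rp",
    "interface_rs",
    "stack_reflectivity",
    "resonance_angle",
    "phase_vs_ri",
    "default_stack",
    "WAVELENGTH_NM",
    "N_PRISM",
    "N_GOLD",
    "N_CHROMIUM",
    "CR_THICKNESS_NM",
]

# Fixed optical constants of the chip family (not optimized).
WAVELENGTH_NM = 850.0
N_PRISM = 1.51 + 0.0j          # BK-7 coupling prism
N_GOLD = 0.16 + 5.34j          # Au plasmonic film at 850 nm
N_CHROMIUM = 3.24 + 3.49j      # Cr adhesion layer at 850 nm
CR_THICKNESS_NM = 2.0


class FresnelError(ValueError):
    """Invalid optical stack or geometry."""


class GridTooCoarseError(FresnelError):
    """Phase changes by more than the unwrap tolerance between adjacent grid points."""


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous layer: complex index and thickness in nm (``None`` = semi-infinite)."""

    label: str
    refractive_index: complex
    thickness_nm: float | None = None

    def __post_init__(self) -> None:
        n = complex(self.refractive_index)
        if not (np.isfinite(n.real) and np.isfinite(n.imag)):
            raise FresnelError(f"layer {self.label!r}: non-finite refractive index {n}")
        if n == 0:
            raise FresnelError(f"layer {self.label!r}: zero refractive index")
        if n.imag < 0:
            raise FresnelError(
                f"layer {self.label!r}: Im(n) = {n.imag} < 0 (absorbing convention requires Im(n) >= 0)"
            )
        if self.thickness_nm is not None:
            t = float(self.thickness_nm)
            if not np.isfinite(t) or t < 0:
                raise FresnelError(f"layer {self.label!r}: invalid thickness {t} nm")

    @property
    def semi_infinite(self) -> bool:
        return self.thickness_nm is None


@dataclass(frozen=True)
class OpticalStack:
    """Ordered layers from incidence medium (prism) to exit medium (buffer)."""

    layers: tuple[OpticalLayer, ...]
    wavelength_nm: float = WAVELENGTH_NM

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if len(layers) < 2:
            raise FresnelError("a stack needs at least incidence and exit media")
        if not (layers[0].semi_infinite and layers[-1].semi_infinite):
            raise FresnelError("first and last layers must be semi-infinite")
        for lay in layers[1:-1]:
            if lay.semi_infinite:
                raise FresnelError(f"internal layer {lay.label!r} marked semi-infinite")
        if not (self.wavelength_nm > 0):
            raise FresnelError("wavelength must be positive")

    def with_buffer_ri(self, ri: complex) -> "OpticalStack":
        exit_layer = OpticalLayer(self.layers[-1].label, ri, None)
        return OpticalStack(self.layers[:-1] + (exit_layer,), self.wavelength_nm)

    @property
    def indices(self) -> np.ndarray:
        return np.array([complex(l.refractive_index) for l in self.layers])

    @property
    def internal_thicknesses(self) -> np.ndarray:
        return np.array([float(l.thickness_nm) for l in self.layers[1:-1]])


@dataclass(frozen=True)
class ComplexReflectivity:
    """Full-stack amplitude reflectivities and derived phases at one geometry."""

    r_p: complex
    r_s: complex

    @property
    def R_p(self) -> float:
        return abs(self.r_p) ** 2

    @property
    def R_s(self) -> float:
        return abs(self.r_s) ** 2

    @property
    def phi_p(self) -> float:
        return float(np.angle(self.r_p))

    @property
    def phi_s(self) -> float:
        return float(np.angle(self.r_s))

    @property
    def phi_diff(self) -> float:
        """p−s differential phase in (−π, π]; the modeled SPR phase contribution."""
        d = self.phi_p - self.phi_s
        return float((d + np.pi) % (2 * np.pi) - np.pi)


def default_stack(
    au_thickness_nm: float = 48.0,
    probe_thickness_nm: float = 0.0,
    probe_ri: complex = 1.40,
    buffer_ri: complex = 1.3344,
    wavelength_nm: float = WAVELENGTH_NM,
) -> OpticalStack:
    """Five-layer chip model: BK7 prism / Cr 2 nm / Au / probe monolayer / buffer."""
    return OpticalStack(
        (
            OpticalLayer("prism", N_PRISM, None),
            OpticalLayer("chromium", N_CHROMIUM, CR_THICKNESS_NM),
            OpticalLayer("gold", N_GOLD, au_thickness_nm),
            OpticalLayer("probe", probe_ri, probe_thickness_nm),
            OpticalLayer("buffer", buffer_ri, None),
        ),
        wavelength_nm,
    )


# ---------------------------------------------------------------------------
# low-level kinematics


def _ncos(n: np.ndarray | complex, kx: np.ndarray | complex) -> np.ndarray:
    """n·cosθ in a layer of index ``n`` given the conserved tangential index ``kx``.

    Branch: Im ≥ 0 (decaying evanescent wave); on the real axis Re ≥ 0.
    """
    val = np.sqrt(np.asarray(n, dtype=complex) ** 2 - np.asarray(kx, dtype=complex) ** 2)
    flip = (val.imag < 0) | ((val.imag == 0) & (val.real < 0))
    return np.where(flip, -val, val)


def _check_angle(theta_deg: float) -> float:
    theta = float(theta_deg)
    if not np.isfinite(theta) or not (0.0 < theta < 90.0):
        raise FresnelError(f"incident angle must be in (0, 90) degrees, got {theta_deg}")
    return np.deg2rad(theta)


def interface_rp(n_in: complex, n_out: complex, theta_in_deg: float) -> complex:
    """Single-interface p-polarization amplitude reflection coefficient.

    The refraction angle follows Snell's law with complex indices; the standard
    form r_p = (n_out·cosθ_in − n_in·cosθ_out) / (n_out·cosθ_in + n_in·cosθ_out)
    is evaluated through the admittances q = cosθ/n.
    """
    return _interface_r(n_in, n_out, theta_in_deg, pol="p")


def interface_rs(n_in: complex, n_out: complex, theta_in_deg: float) -> complex:
    """Single-interface s-polarization amplitude reflection coefficient."""
    return _interface_r(n_in, n_out, theta_in_deg, pol="s")


def _interface_r(n_in: complex, n_out: complex, theta_in_deg: float, pol: str) -> complex:
    for n in (n_in, n_out):
        n = complex(n)
        if not (np.isfinite(n.real) and np.isfinite(n.imag)) or n == 0:
            raise FresnelError(f"non-finite or zero refractive index {n}")
    theta = _check_angle(theta_in_deg)
    kx = complex(n_in) * np.sin(theta)
    q_in = _admittance(np.asarray(complex(n_in)), _ncos(complex(n_in), kx), pol)
    q_out = _admittance(np.asarray(complex(n_out)), _ncos(complex(n_out), kx), pol)
    return complex((q_in - q_out) / (q_in + q_out))


def _admittance(n: np.ndarray, ncos: np.ndarray, pol: str) -> np.ndarray:
    if pol == "p":
        return ncos / n**2
    if pol == "s":
        return ncos
    raise ValueError(f"unknown polarization {pol!r}")


def _amplitude_matrix(
    indices: Sequence[np.ndarray | complex],
    thicknesses_nm: Sequence[float],
    wavelength_nm: float,
    theta0_rad: np.ndarray | float,
    pol: str,
) -> np.ndarray:
    """Characteristic-matrix reflectivity; broadcasts over array-valued indices/angles."""
    kx = np.asarray(indices[0], dtype=complex) * np.sin(np.asarray(theta0_rad))
    ncos = [_ncos(n, kx) for n in indices]
    q = [_admittance(np.asarray(n, dtype=complex), nc, pol) for n, nc in zip(indices, ncos)]
    shape = np.broadcast_shapes(*(np.shape(x) for x in q), np.shape(kx))
    m00 = np.ones(shape, dtype=complex)
    m11 = np.ones(shape, dtype=complex)
    m01 = np.zeros(shape, dtype=complex)
    m10 = np.zeros(shape, dtype=complex)
    k0 = 2.0 * np.pi / wavelength_nm
    for j, d in enumerate(thicknesses_nm, start=1):
        delta = k0 * d * ncos[j]
        c, s = np.cos(delta), np.sin(delta)
        a00, a01 = c, -1j * s / q[j]
        a10, a11 = -1j * q[j] * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    qs = q[-1]
    num = q[0] * (m00 + m01 * qs) - (m10 + m11 * qs)
    den = q[0] * (m00 + m01 * qs) + (m10 + m11 * qs)
    return num / den


def _amplitude_recursive(
    indices: Sequence[np.ndarray | complex],
    thicknesses_nm: Sequence[float],
    wavelength_nm: float,
    theta0_rad: np.ndarray | float,
    pol: str,
) -> np.ndarray:
    """Bottom-up recursive Fresnel composition (independent oracle for the matrix form)."""
    kx = np.asarray(indices[0], dtype=complex) * np.sin(np.asarray(theta0_rad))
    ncos = [_ncos(n, kx) for n in indices]
    q = [_admittance(np.asarray(n, dtype=complex), nc, pol) for n, nc in zip(indices, ncos)]
    k0 = 2.0 * np.pi / wavelength_nm
    nlay = len(indices)
    # r accumulates the reflectivity of the sub-stack seen from layer j downward
    r = (q[nlay - 2] - q[nlay - 1]) / (q[nlay - 2] + q[nlay - 1])
    for j in range(nlay - 3, -1, -1):
        r_if = (q[j] - q[j + 1]) / (q[j] + q[j + 1])
        phase = np.exp(2j * k0 * thicknesses_nm[j] * ncos[j + 1])
        r = (r_if + r * phase) / (1.0 + r_if * r * phase)
    return r


_METHODS = {"matrix": _amplitude_matrix, "recursive": _amplitude_recursive}


def stack_reflectivity(
    stack: OpticalStack,
    incident_angle_deg: float,
    method: str = "matrix",
) -> ComplexReflectivity:
    """Full-stack complex reflectivity at one incidence angle in the prism."""
    theta = _check_angle(incident_angle_deg)
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}, got {method!r}")
    fn = _METHODS[method]
    idx = list(stack.indices)
    th = list(stack.internal_thicknesses)
    r_p = fn(idx, th, stack.wavelength_nm, theta, "p")
    r_s = fn(idx, th, stack.wavelength_nm, theta, "s")
    return ComplexReflectivity(complex(r_p), complex(r_s))


def _phase_diff_on_grid(
    stack: OpticalStack, theta_rad: float, ri_grid: np.ndarray
) -> np.ndarray:
    """Unwrapped p−s phase vs buffer RI at fixed angle (vectorized over the grid)."""
    idx = list(stack.indices)
    idx[-1] = np.asarray(ri_grid, dtype=complex)
    th = list(stack.internal_thicknesses)
    r_p = _amplitude_matrix(idx, th, stack.wavelength_nm, theta_rad, "p")
    r_s = _amplitude_matrix(idx, th, stack.wavelength_nm, theta_rad, "s")
    return np.unwrap(np.angle(r_p)) - np.unwrap(np.angle(r_s))


def resonance_angle(
    stack: OpticalStack, lo_deg: float = 60.0, hi_deg: float = 75.0, n: int = 2001
) -> float:
    """Angle of minimum p-reflectance (the SPR dip) located by a dense scan."""
    theta = np.deg2rad(np.linspace(lo_deg, hi_deg, n))
    idx = list(stack.indices)
    th = list(stack.internal_thicknesses)
    r_p = _amplitude_matrix(idx, th, stack.wavelength_nm, theta, "p")
    return float(np.rad2deg(theta[np.argmin(np.abs(r_p) ** 2)]))


def phase_vs_ri(
    stack: OpticalStack,
    incident_angle_deg: float,
    ri_grid: Sequence[float],
    baseline_ri: float,
    max_refine: int = 8,
    max_step_rad: float = np.pi / 2,
):
    """Baseline-referenced differential-phase mapping curve Δφ(n) over a buffer-RI grid.

    The p−s phase is unwrapped along the grid; wherever the phase still moves by
    more than ``max_step_rad`` between neighbors the grid is refined by midpoint
    insertion (up to ``max_refine`` rounds) so the branch continuation is safe.

    Returns a :class:`psprmap.metamodel.MappingCurve`.
    """
    from .metamodel import MappingCurve  # local import to avoid a cycle

    raw = np.asarray(ri_grid, dtype=float)
    if raw.size < 2:
        raise FresnelError("ri_grid must contain at least two distinct points")
    if not (raw.min() <= baseline_ri <= raw.max()):
        raise FresnelError("baseline_ri must lie within the RI grid")
    grid = np.union1d(raw, [float(baseline_ri)])
    theta = _check_angle(incident_angle_deg)

    for _ in range(max_refine + 1):
        dphi = _phase_diff_on_grid(stack, theta, grid)
        steps = np.abs(np.diff(dphi))
        bad = steps > max_step_rad
        if not np.any(bad):
            break
        mids = 0.5 * (grid[:-1][bad] + grid[1:][bad])
        grid = np.union1d(grid, mids)
    else:
        raise GridTooCoarseError(
            f"phase step exceeds {max_step_rad:.3f} rad after {max_refine} refinement rounds"
        )

    i0 = int(np.searchsorted(grid, baseline_ri))
    dphase = dphi - dphi[i0]
    return MappingCurve(ri=grid, dphase=dphase, baseline_ri=float(baseline_ri))
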