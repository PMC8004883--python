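"""Phase-modulation homodyne interference simulation and GLIA phase extraction.

A VCSEL's drive current is modulated sinusoidally; through the current→wavelength
tuning of the laser (efficiency β) and a YVO4 birefringent crystal, this imposes
a sinusoidal phase modulation Δϕ(t) = Δϕa·sin(ωt) between the p and s
polarizations, while a residual intensity modulation (AC/DC fraction µ) rides
along.  The interference beating is

    I(t) = I0 (1 + µ sin ωt) [1 + m cos(Δϕa sin ωt − ϕSPR)]

and the SPR phase ϕSPR is recovered by a generalized lock-in amplifier (GLIA):
the DC-filtered beating is correlated against the references
RX = cos(Δϕa sin ωt) and RY = sin(Δϕa sin ωt), whose harmonic content (via the
Jacobi–Anger expansion) matches the signal's.

Closed forms used for the inversion (derived from the beating model above;
angle brackets denote the time average over an integer number of periods,
a ≡ Δϕa, Jn the Bessel functions of the first kind):

    X = ⟨Ĩ·RX⟩ = (I0 m / 2) [ cosϕ·(1 + J0(2a) − 2J0²(a))
                               + µ sinϕ·(J1(2a) − 2J0(a)J1(a)) ]
    Y = ⟨Ĩ·RY⟩ = (I0 m / 2) [ sinϕ·(1 − J0(2a)) + µ cosϕ·J1(2a) ] + I0 µ J1(a)

Tuning the depth to the first zero of J1 (≈ 3.8317 rad) kills the J1(a) terms,
removing the residual-amplitude-modulation bias to first order; the remaining
2×2 linear system in (cosϕ, sinϕ) is inverted and ϕ recovered with atan2, which
makes the extraction invariant to any common positive rescaling of (X, Y).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1

__all__ = [
    "ModulatorConfig",
    "BeatingSignal",
    "LockinResult",
    "GliaError",
    "modulation_depth",
    "j1_null_depth",
    "simulate_beating",
    "lockin_xy",
    "extract_phase",
]


class GliaError(ValueError):
    """Invalid modulator configuration or signal."""


@dataclass(frozen=True)
class ModulatorConfig:
    """Physical knobs that set the phase-modulation depth.

    ``ne - no`` is the YVO4 birefringence, ``length_m`` the crystal length,
    ``beta_nm_per_ma`` the VCSEL current-tuning efficiency dλ/di, ``delta_i_ma``
    the current modulation amplitude and ``omega`` the modulation angular
    frequency in rad/s.
    """

    ne: float = 2.1554
    no: float = 1.9573
    length_m: float = 0.01
    beta_nm_per_ma: float = 0.6
    lambda0_nm: float = 852.0
    delta_i_ma: float = 0.0
    omega: float = 2 * np.pi * 1000.0

    def __post_init__(self) -> None:
        for name in ("ne", "no", "length_m", "beta_nm_per_ma", "lambda0_nm", "omega"):
            if not (getattr(self, name) > 0):
                raise GliaError(f"{name} must be positive")
        if self.delta_i_ma < 0:
            raise GliaError("delta_i_ma must be non-negative")

    def with_depth(self, depth_rad: float) -> "ModulatorConfig":
        """Return a config whose drive-current amplitude realizes ``depth_rad``."""
        per_ma = modulation_depth(replace(self, delta_i_ma=1.0))
        return replace(self, delta_i_ma=float(depth_rad) / per_ma)


def modulation_depth(config: ModulatorConfig) -> float:
    """Phase-modulation depth Δϕa = 2π(ne−no)·β·L·Δi / λ0² in rad (magnitude)."""
    length_nm = config.length_m * 1e9
    return abs(
        2.0
        * np.pi
        * (config.ne - config.no)
        * config.beta_nm_per_ma
        * length_nm
        * config.delta_i_ma
        / config.lambda0_nm**2
    )


def j1_null_depth() -> float:
    """Smallest positive depth at which J1 vanishes (the RAM-immune operating point).

    Found by root-bracketing J1 on (3, 4.5); ≈ 3.8317 rad.
    """
    return float(brentq(j1, 3.0, 4.5, xtol=1e-14, rtol=8.9e-16))


@dataclass(frozen=True)
class BeatingSignal:
    """Sampled interference beating plus the generator parameters that made it."""

    t: np.ndarray
    intensity: np.ndarray
    depth_rad: float
    omega: float
    i0: float
    mu: float
    m: float
    phi_spr: float
    n_periods: int
    samples_per_period: int


def simulate_beating(
    phi_spr: float,
    i0: float = 1.0,
    mu: float = 0.0,
    m: float = 1.0,
    config: ModulatorConfig | None = None,
    depth_rad: float | None = None,
    n_periods: int = 4,
    samples_per_period: int = 256,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> BeatingSignal:
    """Generate the interference beating for one SPR phase value.

    The modulation depth comes from ``config`` (via :func:`modulation_depth`)
    unless ``depth_rad`` overrides it.  Sampling covers exactly ``n_periods``
    modulation periods with a uniform grid (endpoint excluded), so period
    averages downstream are alias-free.  Optional additive Gaussian intensity
    noise is drawn from a seeded generator.
    """
    if not (0.0 <= mu <= 1.0) or not (0.0 <= m <= 1.0):
        raise GliaError(f"mu and m must lie in [0, 1], got mu={mu}, m={m}")
    if i0 <= 0:
        raise GliaError("i0 must be positive")
    if int(n_periods) < 1 or n_periods != int(n_periods):
        raise GliaError("n_periods must be a positive integer")
    if samples_per_period < 64:
        raise GliaError("samples_per_period must be >= 64 for alias-free averaging")
    config = config or ModulatorConfig()
    depth = float(depth_rad) if depth_rad is not None else modulation_depth(config)
    omega = config.omega
    period = 2 * np.pi / omega
    n = int(n_periods) * int(samples_per_period)
    t = np.arange(n) * (int(n_periods) * period / n)
    intensity = i0 * (1 + mu * np.sin(omega * t)) * (
        1 + m * np.cos(depth * np.sin(omega * t) - phi_spr)
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, size=n)
    return BeatingSignal(
        t=t,
        intensity=intensity,
        depth_rad=depth,
        omega=omega,
        i0=i0,
        mu=mu,
        m=m,
        phi_spr=float(phi_spr),
        n_periods=int(n_periods),
        samples_per_period=int(samples_per_period),
    )


@dataclass(frozen=True)
class LockinResult:
    """GLIA quadrature outputs (time averages, intensity units)."""

    X: float
    Y: float


def lockin_xy(signal: BeatingSignal, depth_rad: float | None = None) -> LockinResult:
    """Correlate the DC-filtered beating against the Bessel-matched references.

    The high-pass filter is exact mean removal over the (integer-period)
    record; X and Y are sample means of the filtered signal times RX and RY.
    """
    depth = float(depth_rad) if depth_rad is not None else signal.depth_rad
    n = signal.t.size
    if n % signal.samples_per_period != 0:
        raise GliaError("signal does not cover an integer number of periods")
    arg = depth * np.sin(signal.omega * signal.t)
    filtered = signal.intensity - signal.intensity.mean()
    x = float(np.mean(filtered * np.cos(arg)))
    y = float(np.mean(filtered * np.sin(arg)))
    return LockinResult(X=x, Y=y)


def closed_form_xy(
    phi_spr: float, depth: float, i0: float = 1.0, mu: float = 0.0, m: float = 1.0
) -> tuple[float, float]:
    """Analytic X, Y for the noiseless beating (quadrature oracle for tests)."""
    a = depth
    A = 1 + j0(2 * a) - 2 * j0(a) ** 2
    B = 1 - j0(2 * a)
    cx = j1(2 * a) - 2 * j0(a) * j1(a)
    cy = j1(2 * a)
    x = 0.5 * i0 * m * (np.cos(phi_spr) * A + mu * np.sin(phi_spr) * cx)
    y = 0.5 * i0 * m * (np.sin(phi_spr) * B + mu * np.cos(phi_spr) * cy) + i0 * mu * j1(a)
    return float(x), float(y)


def extract_phase(result: LockinResult, depth_rad: float, mu: float = 0.0) -> float:
    """Invert the GLIA quadratures to the SPR phase in (−π, π].

    Valid to first order when the depth is near the J1 null (the
    residual-amplitude-modulation offset in Y then vanishes); the µ cross-terms
    are corrected exactly for the given depth.
    """
    a = float(depth_rad)
    A = 1 + j0(2 * a) - 2 * j0(a) ** 2
    B = 1 - j0(2 * a)
    cx = j1(2 * a) - 2 * j0(a) * j1(a)
    cy = j1(2 * a)
    x, y = result.X, result.Y
    c_est = B * x - mu * cx * y
    s_est = A * y - mu * cy * x
    if c_est == 0.0 and s_est == 0.0:
        raise GliaError("degenerate quadratures X = Y = 0; phase undefined")
    det = A * B - mu**2 * cx * cy
    if det <= 0:
        raise GliaError(f"non-invertible quadrature system (det={det:.3g})")
    return float(np.arctan2(s_est, c_est))
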