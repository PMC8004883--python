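"""Langmuir 1:1 binding kinetics on converted sensorgrams.

Association follows ΔS(t)/ΔS_max = 1 − exp(−τ·(t − t_start)) with observed rate
τ = k_on·C + k_off (C the analyte molar concentration); dissociation follows
ΔS(t) = ΔS0·exp(−k_off·(t − t0)).  Fitting both segments and knowing C gives
k_on = (τ − k_off)/C and the equilibrium constant K_D = k_off/k_on.

Fits are deterministic nonlinear least squares with documented initial guesses:
ΔS_max ← last sample, τ ← inverse of the time to reach 63% of ΔS_max; for
dissociation ΔS0 ← first sample and k_off ← log-ratio of the endpoint levels
over the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .pipeline import Sensorgram

__all__ = [
    "KineticParameters",
    "KineticsError",
    "AssociationFit",
    "DissociationFit",
    "fit_association",
    "fit_dissociation",
    "derive_constants",
]

NO_DECAY_TOL = 1e-10  # s^-1; below this the dissociation segment is flagged flat


class KineticsError(ValueError):
    """Invalid kinetics input or failed fit."""


@dataclass(frozen=True)
class KineticParameters:
    """Ground-truth or fitted 1:1 Langmuir parameters.

    ``tau`` is the observed association rate in s⁻¹ (τ = k_on·C + k_off; the
    equation form governs, the units are a rate, not a half-life), ``dS_max``
    the association plateau and ``dS0`` the dissociation start level in signal
    units (RIU on converted sensorgrams), ``t0`` the dissociation start time.
    """

    tau: float
    k_off: float
    concentration: float
    dS_max: float = 1.0
    dS0: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.k_off < 0 or self.concentration <= 0:
            raise KineticsError("tau must be > 0, k_off >= 0, concentration > 0")

    @property
    def k_on(self) -> float:
        return derive_constants(self.tau, self.k_off, self.concentration)[0]

    @property
    def K_D(self) -> float:
        return derive_constants(self.tau, self.k_off, self.concentration)[1]


@dataclass(frozen=True)
class AssociationFit:
    tau: float
    dS_max: float
    rmse: float


@dataclass(frozen=True)
class DissociationFit:
    k_off: float
    dS0: float
    rmse: float
    no_decay: bool


def _segment(sensorgram_or_arrays, t_start: float, t_end: float | None):
    if isinstance(sensorgram_or_arrays, Sensorgram):
        t, s = sensorgram_or_arrays.time, sensorgram_or_arrays.ri
    else:
        t, s = (np.asarray(a, dtype=float) for a in sensorgram_or_arrays)
    mask = t >= t_start
    if t_end is not None:
        mask &= t <= t_end
    t, s = t[mask], s[mask]
    if t.size < 10:
        raise KineticsError(f"segment has {t.size} points; need at least 10")
    return t, s


def fit_association(
    sensorgram: Sensorgram | tuple,
    t_start: float,
    t_end: float | None = None,
) -> AssociationFit:
    """Least-squares fit of ΔS(t) = ΔS_max·(1 − e^{−τ(t−t_start)}) on a rising segment."""
    t, s = _segment(sensorgram, t_start, t_end)
    s = s - s[0]
    tt = t - t[0]
    ds_guess = float(s[-1])
    if ds_guess == 0:
        raise KineticsError("flat association segment; nothing to fit")
    i63 = int(np.argmax(s >= 0.632 * ds_guess)) if ds_guess > 0 else int(
        np.argmax(s <= 0.632 * ds_guess)
    )
    t63 = tt[i63] if tt[i63] > 0 else tt[-1] / 2
    p0 = (1.0 / t63, ds_guess)

    def model(x, tau, ds_max):
        return ds_max * (1 - np.exp(-tau * x))

    try:
        popt, _ = curve_fit(model, tt, s, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise KineticsError(f"association fit did not converge: {exc}") from exc
    resid = model(tt, *popt) - s
    return AssociationFit(
        tau=float(popt[0]), dS_max=float(popt[1]), rmse=float(np.sqrt(np.mean(resid**2)))
    )


def fit_dissociation(
    sensorgram: Sensorgram | tuple,
    t0: float,
    t_end: float | None = None,
) -> DissociationFit:
    """Least-squares fit of ΔS(t) = ΔS0·e^{−k_off(t−t0)} on a decaying segment."""
    t, s = _segment(sensorgram, t0, t_end)
    tt = t - t[0]
    ds0_guess = float(s[0])
    if ds0_guess == 0:
        raise KineticsError("dissociation segment starts at zero signal")
    ratio = s[-1] / ds0_guess
    k_guess = -np.log(ratio) / tt[-1] if 0 < ratio < 1 else 1e-6

    def model(x, k_off, ds0):
        return ds0 * np.exp(-k_off * x)

    try:
        popt, _ = curve_fit(model, tt, s, p0=(max(k_guess, 1e-12), ds0_guess), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise KineticsError(f"dissociation fit did not converge: {exc}") from exc
    resid = model(tt, *popt) - s
    k_off = float(popt[0])
    return DissociationFit(
        k_off=k_off,
        dS0=float(popt[1]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        no_decay=abs(k_off) < NO_DECAY_TOL,
    )


def derive_constants(tau: float, k_off: float, concentration: float) -> tuple[float, float]:
    """k_on = (τ − k_off)/C and K_D = k_off/k_on from the fitted rates.

    τ ≤ k_off signals an inconsistent concentration or fit (the observed
    association rate can never fall below the reverse rate).
    """
    if concentration <= 0:
        raise KineticsError("concentration must be positive")
    if tau <= k_off:
        raise KineticsError(
            f"tau ({tau:.4g}) must exceed k_off ({k_off:.4g}); "
            "check the concentration or the fits"
        )
    k_on = (tau - k_off) / concentration
    return float(k_on), float(k_off / k_on)
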