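"""Fractional-motion (FM) forward signal model.

The FM framework describes water diffusion in tissue as an H-self-similar
process with α-stable, stationary increments.  Its signal equation for a
PGSE experiment is

    S / S0 = exp( −η · D_{α,H} · γ^α · G0^α · Δ^(α + αH) ),

where α is the Noah exponent (α = 2: Gaussian increments; 0 < α < 2:
heavy-tailed Lévy increments), H is the Hurst exponent (self-similarity of
the trajectory), D_{α,H} is the anomalous diffusion coefficient, and η is a
dimensionless factor determined by (α, H, δ, Δ).  The memory parameter

    μ = H − 1/α

summarises increment correlation: μ < 0 anti-persistent, μ = 0 memoryless
(α = 2, H = 1/2 is ordinary Brownian motion), μ > 0 persistent.

η strategy
----------
η's exact finite-pulse form depends on which FM theory variant one adopts;
this package makes it pluggable (``eta_model``).  The default is the
narrow-pulse factorisation η = (δ/Δ)^α, under which the decay exponent
becomes D·γ^α·G0^α·δ^α·Δ^(αH) and the model reduces *exactly* to the
mono-exponential model with b = γ²G0²δ²Δ at α = 2, H = 1/2.  Fitted D
values are only comparable within one η convention; α, H and μ enter
through the G0 and Δ exponents and are convention-independent within this
family.

Units
-----
The decay exponent is evaluated with G0 expressed in T/mm, so that D_{α,H}
carries units mm^α·s^(−αH) and coincides numerically with the ADC in mm²/s
at the Gaussian limit (with b in s/mm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .acquisition import AcquisitionScheme

__all__ = [
    "FMParams",
    "SignalSeries",
    "ETA_MODELS",
    "compute_eta",
    "fm_attenuation",
    "fm_signal",
    "memory_parameter",
    "mono_exp_signal",
]

ALPHA_MAX = 2.0
_G0_TO_PER_MM = 1e-3  # T/m → T/mm


@dataclass(frozen=True)
class FMParams:
    """One voxel's (or region's) FM model state.

    D: anomalous diffusion coefficient D_{α,H}, mm^α·s^(−αH);
    alpha: Noah exponent in (0, 2]; hurst: Hurst exponent in (0, 1).
    """

    D: float
    alpha: float
    hurst: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= ALPHA_MAX):
            raise ValueError(f"alpha must be in (0, 2], got {self.alpha}")
        if not (0.0 < self.hurst < 1.0):
            raise ValueError(f"hurst must be in (0, 1), got {self.hurst}")
        if not (self.D >= 0.0 and math.isfinite(self.D)):
            raise ValueError(f"D must be finite and >= 0, got {self.D}")

    @property
    def mu(self) -> float:
        """Memory parameter μ = H − 1/α (derived, never independently set)."""
        return memory_parameter(self.alpha, self.hurst)


@dataclass(frozen=True)
class SignalSeries:
    """Signals aligned with an acquisition scheme's weighted measurements."""

    S0: float
    signals: np.ndarray

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValueError(f"S0 must be > 0, got {self.S0}")
        if np.any(np.asarray(self.signals) < 0):
            raise ValueError("signals must be >= 0")


def _eta_narrow_pulse(alpha: float, hurst: float, delta: float, Delta: float) -> float:
    return (delta / Delta) ** alpha


#: Registry of η strategies; keys are valid ``eta_model`` config values.
ETA_MODELS: dict[str, Callable[[float, float, float, float], float]] = {
    "narrow_pulse": _eta_narrow_pulse,
}


def compute_eta(
    alpha: float,
    hurst: float,
    delta: float,
    Delta: float,
    model: str = "narrow_pulse",
) -> float:
    """The dimensionless η factor of the FM signal equation.

    Dispatches on ``model`` (see :data:`ETA_MODELS`); the default
    narrow-pulse form is (δ/Δ)^α.  Alternative finite-pulse expressions can
    be registered without touching any caller.
    """
    if not (0.0 < alpha <= ALPHA_MAX):
        raise ValueError(f"alpha must be in (0, 2], got {alpha}")
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if not (0.0 < delta <= Delta):
        raise ValueError(f"need 0 < delta <= Delta, got delta={delta}, Delta={Delta}")
    try:
        fn = ETA_MODELS[model]
    except KeyError:
        raise ValueError(f"unknown eta model {model!r}; available: {sorted(ETA_MODELS)}") from None
    return fn(alpha, hurst, delta, Delta)


def fm_attenuation(
    D: float,
    alpha: float,
    hurst: float,
    G0,
    Delta,
    delta,
    gamma: float,
    eta_model: str = "narrow_pulse",
) -> np.ndarray:
    """Normalised FM signal S/S0 for arrays of (G0, Δ, δ) measurements.

    The exponent is assembled in log space to stay stable for extreme
    (α, H); G0 = 0 or D = 0 gives exactly no attenuation.
    """
    G0 = np.asarray(G0, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    G0, Delta, delta = np.broadcast_arrays(G0, Delta, delta)
    E = np.zeros(G0.shape)
    active = (G0 > 0) & (D > 0)
    if np.any(active):
        eta = np.array(
            [
                compute_eta(alpha, hurst, d, Dl, model=eta_model)
                for d, Dl in zip(delta[active], Delta[active])
            ]
        )
        log_E = (
            np.log(eta)
            + math.log(D)
            + alpha * np.log(gamma * G0[active] * _G0_TO_PER_MM)
            + alpha * (1.0 + hurst) * np.log(Delta[active])
        )
        E[active] = np.exp(log_E)
    return np.exp(-E)


def fm_signal(
    params: FMParams,
    scheme: AcquisitionScheme,
    S0: float = 1.0,
    eta_model: str = "narrow_pulse",
) -> SignalSeries:
    """Forward FM signals for every weighted measurement of ``scheme``.

    The model is isotropic: the three orthogonal directions of a (Δ, G0)
    cell receive identical signals.  All outputs lie in (0, S0].
    """
    if not S0 > 0:
        raise ValueError(f"S0 must be > 0, got {S0}")
    G0 = np.array([m.G0 for m in scheme.measurements])
    Delta = np.array([m.Delta for m in scheme.measurements])
    delta = np.array([m.delta for m in scheme.measurements])
    atten = fm_attenuation(
        params.D, params.alpha, params.hurst, G0, Delta, delta, scheme.gamma, eta_model
    )
    return SignalSeries(S0=S0, signals=S0 * atten)


def memory_parameter(alpha, hurst):
    """Memory parameter μ = H − 1/α.  Accepts scalars or arrays."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be > 0")
    out = np.asarray(hurst, dtype=float) - 1.0 / alpha
    return float(out) if out.ndim == 0 else out


def mono_exp_signal(adc: float, b, S0: float = 1.0):
    """Mono-exponential (ADC) comparison model: S = S0·exp(−b·ADC)."""
    b = np.asarray(b, dtype=float)
    if adc < 0:
        raise ValueError(f"adc must be >= 0, got {adc}")
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if not S0 > 0:
        raise ValueError(f"S0 must be > 0, got {S0}")
    out = S0 * np.exp(-b * adc)
    return float(out) if out.ndim == 0 else out
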