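"""Multi-(Δ, G0) pulsed-gradient spin-echo (PGSE) acquisition schemes.

A fractional-motion protocol varies both the gradient separation time Δ and
the gradient amplitude G0 (the quantities the anomalous-diffusion exponents
act on), rather than only the composite b-value.  This module builds such
schemes, derives the Stejskal–Tanner b-value for every weighted measurement,

    b = γ² G0² δ² (Δ − δ/3),

and fixes the volume ordering used throughout the package: all b=0 volumes
first, then weighted volumes grouped by Δ ascending, G0 ascending, and
gradient direction in x, y, z order.

Internally everything is SI (seconds, tesla/metre, rad·s⁻¹·T⁻¹); b-values
are reported in the conventional s/mm².  Clinical-unit constructors
(milliseconds, mT/m) are provided because protocols are usually quoted that
way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "DIRECTIONS",
    "DiffusionMeasurement",
    "AcquisitionScheme",
    "Cell",
    "compute_bvalue",
    "make_gradient_amplitudes",
    "build_scheme",
    "build_scheme_clinical",
    "default_scheme",
]

#: Proton gyromagnetic ratio, rad·s⁻¹·T⁻¹.
GAMMA_PROTON = 2.6752218744e8

#: Canonical gradient-direction labels (orthogonal scanner axes).
DIRECTIONS = ("x", "y", "z")

_SI_TO_S_PER_MM2 = 1e-6  # s/m² → s/mm²


def _check_finite_positive(name: str, value: float, allow_zero: bool = False) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if allow_zero:
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value!r}")
    elif value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


def compute_bvalue(gamma: float, G0: float, delta: float, Delta: float) -> float:
    """Stejskal–Tanner b-value of one PGSE measurement, in s/mm².

    Parameters are SI: ``gamma`` in rad·s⁻¹·T⁻¹, ``G0`` in T/m, pulse
    duration ``delta`` and separation ``Delta`` in seconds.  Full precision
    is retained; round only for display.
    """
    _check_finite_positive("gamma", gamma)
    _check_finite_positive("G0", G0, allow_zero=True)
    _check_finite_positive("delta", delta)
    _check_finite_positive("Delta", Delta)
    if delta > Delta:
        raise ValueError(f"delta ({delta}) must not exceed Delta ({Delta})")
    return gamma**2 * G0**2 * delta**2 * (Delta - delta / 3.0) * _SI_TO_S_PER_MM2


def make_gradient_amplitudes(gmin: float, gmax: float, n: int) -> np.ndarray:
    """``n`` gradient amplitudes geometrically spaced from ``gmin`` to ``gmax``.

    Geometric spacing places the amplitudes evenly on a log axis, which
    spreads the resulting b-values evenly on a log axis as well (b ∝ G0²).
    Endpoints are included; the ratio between consecutive values is constant.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not (0 < gmin < gmax):
        raise ValueError(f"need 0 < gmin < gmax, got gmin={gmin}, gmax={gmax}")
    return np.geomspace(gmin, gmax, n)


@dataclass(frozen=True)
class DiffusionMeasurement:
    """One diffusion-weighted volume's gradient timing and amplitude (SI).

    ``bvalue`` (s/mm²) is derived from the other fields and verified against
    the Stejskal–Tanner formula on construction.
    """

    Delta: float  # gradient separation time, s
    G0: float  # gradient amplitude, T/m
    delta: float  # gradient pulse duration, s
    direction: str  # one of "x", "y", "z"
    bvalue: float  # s/mm², derived

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        _check_finite_positive("Delta", self.Delta)
        _check_finite_positive("G0", self.G0, allow_zero=True)
        _check_finite_positive("delta", self.delta)
        if self.delta > self.Delta:
            raise ValueError(f"delta ({self.delta}) must not exceed Delta ({self.Delta})")
        if self.bvalue < 0:
            raise ValueError(f"bvalue must be >= 0, got {self.bvalue}")


def _measurement(gamma: float, Delta: float, G0: float, delta: float, direction: str) -> DiffusionMeasurement:
    return DiffusionMeasurement(
        Delta=Delta,
        G0=G0,
        delta=delta,
        direction=direction,
        bvalue=compute_bvalue(gamma, G0, delta, Delta),
    )


@dataclass(frozen=True)
class Cell:
    """One (Δ, G0) combination with the weighted-volume indices of its directions."""

    Delta: float
    G0: float
    delta: float
    bvalue: float
    indices: tuple[int, ...]  # positions within the weighted measurements


@dataclass(frozen=True)
class AcquisitionScheme:
    """An ordered PGSE acquisition: ``n_b0`` unweighted volumes followed by
    the weighted ``measurements``, in one-to-one correspondence with the 4th
    axis of the acquired 4D volume."""

    gamma: float
    n_b0: int
    measurements: tuple[DiffusionMeasurement, ...]

    def __post_init__(self) -> None:
        _check_finite_positive("gamma", self.gamma)
        if self.n_b0 < 1:
            raise ValueError("n_b0 must be >= 1 (normalization needs at least one b=0 volume)")
        if not self.measurements:
            raise ValueError("scheme must contain at least one weighted measurement")

    @property
    def n_weighted(self) -> int:
        return len(self.measurements)

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + self.n_weighted

    @property
    def bvalues(self) -> np.ndarray:
        """b-values of the weighted measurements, s/mm²."""
        return np.array([m.bvalue for m in self.measurements])

    @property
    def delta(self) -> float:
        """Common gradient pulse duration; raises if δ varies across measurements."""
        deltas = {m.delta for m in self.measurements}
        if len(deltas) != 1:
            raise ValueError("scheme has heterogeneous delta; query per measurement")
        return deltas.pop()

    def cells(self) -> list[Cell]:
        """Unique (Δ, G0) combinations in first-appearance order.

        Each cell carries the indices (within the weighted measurements) of
        its direction repeats; direction-averaging operates cell by cell.
        """
        order: dict[tuple[float, float, float], list[int]] = {}
        for i, m in enumerate(self.measurements):
            order.setdefault((m.Delta, m.G0, m.delta), []).append(i)
        out = []
        for (Delta, G0, delta), idx in order.items():
            out.append(
                Cell(
                    Delta=Delta,
                    G0=G0,
                    delta=delta,
                    bvalue=compute_bvalue(self.gamma, G0, delta, Delta),
                    indices=tuple(idx),
                )
            )
        return out


def build_scheme(
    Deltas: Sequence[float],
    G0s: Sequence[float],
    delta: float,
    n_b0: int = 12,
    directions: Sequence[str] = DIRECTIONS,
    gamma: float = GAMMA_PROTON,
) -> AcquisitionScheme:
    """Build a full multi-(Δ, G0) scheme from SI inputs.

    One weighted measurement is produced per (Δ, G0, direction) triple,
    ordered by Δ ascending, then G0 ascending, then direction in the given
    order.  ``delta`` must not exceed any Δ.
    """
    Deltas = sorted(float(D) for D in Deltas)
    G0s = sorted(float(g) for g in G0s)
    directions = tuple(directions)
    if not Deltas or not G0s or not directions:
        raise ValueError("Deltas, G0s and directions must all be non-empty")
    bad = set(directions) - set(DIRECTIONS)
    if bad:
        raise ValueError(f"unknown directions {sorted(bad)}; allowed: {DIRECTIONS}")
    _check_finite_positive("delta", delta)
    if delta > min(Deltas):
        raise ValueError(f"delta ({delta}) exceeds the smallest Delta ({min(Deltas)})")
    measurements = tuple(
        _measurement(gamma, Delta, G0, delta, d)
        for Delta in Deltas
        for G0 in G0s
        for d in directions
    )
    return AcquisitionScheme(gamma=gamma, n_b0=n_b0, measurements=measurements)


def build_scheme_clinical(
    Deltas_ms: Sequence[float],
    G0s_mT_per_m: Sequence[float],
    delta_ms: float,
    n_b0: int = 12,
    directions: Sequence[str] = DIRECTIONS,
    gamma: float = GAMMA_PROTON,
) -> AcquisitionScheme:
    """As :func:`build_scheme` but with times in ms and amplitudes in mT/m."""
    return build_scheme(
        Deltas=[D * 1e-3 for D in Deltas_ms],
        G0s=[g * 1e-3 for g in G0s_mT_per_m],
        delta=delta_ms * 1e-3,
        n_b0=n_b0,
        directions=directions,
        gamma=gamma,
    )


#: Default protocol parameters: Δ ∈ {27.060, 39.560, 52.060} ms, six gradient
#: amplitudes geometrically spaced over 15.67–49.00 mT/m, δ = 20.676 ms fixed,
#: three orthogonal directions, and 12 b=0 volumes, for 66 volumes total and
#: 18 distinct non-zero b-values spanning ≈150–3300 s/mm².
DEFAULT_DELTAS_MS = (27.060, 39.560, 52.060)
DEFAULT_G0_RANGE_MT_PER_M = (15.67, 49.00)
DEFAULT_N_G0 = 6
DEFAULT_SMALL_DELTA_MS = 20.676
DEFAULT_N_B0 = 12


def default_scheme(gamma: float = GAMMA_PROTON) -> AcquisitionScheme:
    """The package's default hippocampal FM imaging protocol (see above)."""
    G0s = make_gradient_amplitudes(*DEFAULT_G0_RANGE_MT_PER_M, DEFAULT_N_G0)
    return build_scheme_clinical(
        Deltas_ms=DEFAULT_DELTAS_MS,
        G0s_mT_per_m=list(G0s),
        delta_ms=DEFAULT_SMALL_DELTA_MS,
        n_b0=DEFAULT_N_B0,
        gamma=gamma,
    )
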