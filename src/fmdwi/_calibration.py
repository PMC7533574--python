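"""Mapping between ADC and the FM diffusion coefficient D_{α,H}.

D's numerical scale depends strongly on (α, H), so synthetic subjects (and
fit initialisation) anchor it to the mono-exponential model: D is chosen so
that the FM decay exponent at the scheme's median-b (Δ, G0) cell equals
b·ADC at that cell.  At α = 2, H = 1/2 with the narrow-pulse η this mapping
is exact at every cell, not just the anchor.
"""

from __future__ import annotations

import numpy as np

from .acquisition import AcquisitionScheme, Cell
from .fm_model import compute_eta

_G0_TO_PER_MM = 1e-3

__all__ = ["median_b_cell", "decay_constant", "calibrate_D"]


def median_b_cell(scheme: AcquisitionScheme) -> Cell:
    """The (Δ, G0) cell with the median b-value (upper median for even counts)."""
    cells = scheme.cells()
    b = np.array([c.bvalue for c in cells])
    return cells[int(np.argsort(b)[len(b) // 2])]


def decay_constant(
    alpha: float, hurst: float, cell: Cell, gamma: float, eta_model: str = "narrow_pulse"
) -> float:
    """K(α, H; cell) such that the cell's FM decay exponent is D·K."""
    eta = compute_eta(alpha, hurst, cell.delta, cell.Delta, model=eta_model)
    return float(
        eta
        * (gamma * cell.G0 * _G0_TO_PER_MM) ** alpha
        * cell.Delta ** (alpha * (1.0 + hurst))
    )


def calibrate_D(
    alpha: float,
    hurst: float,
    adc: float,
    scheme: AcquisitionScheme,
    eta_model: str = "narrow_pulse",
) -> float:
    """D_{α,H} whose FM signal at the median-b cell matches exp(−b·ADC)."""
    cell = median_b_cell(scheme)
    return cell.bvalue * adc / decay_constant(alpha, hurst, cell, scheme.gamma, eta_model)
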