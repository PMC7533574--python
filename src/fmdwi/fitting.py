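"""Voxelwise estimation of FM parameters and ADC.

Pipeline per voxel: estimate S0 from the b=0 volumes, collapse the three
orthogonal gradient directions of each (Δ, G0) cell into one attenuation
(geometric mean by default, minimising the influence of residual
anisotropy), then fit (D, α, H) by bounded trust-region-reflective
nonlinear least squares in the signal domain, multi-started from a coarse
(α, H) grid.  μ = H − 1/α is derived from the fit, never estimated
separately.  ADC is computed from the b=0 signal and the single weighted
cell whose b-value is nearest a configurable target (default 954 s/mm²).

D is fitted on a log scale for conditioning; reported values are linear.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .acquisition import AcquisitionScheme, Cell
from .fm_model import compute_eta, memory_parameter, FMParams
from ._calibration import decay_constant

__all__ = [
    "FitConfig",
    "FMFit",
    "NormalizedSignals",
    "ParameterMaps",
    "normalize_and_average",
    "fit_fm_voxel",
    "fit_fm_volume",
    "compute_adc",
    "select_adc_cell",
]

logger = logging.getLogger(__name__)

_G0_TO_PER_MM = 1e-3


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the voxelwise fit.

    Bounds are deliberately broader than any plausible hippocampal value so
    healthy fits land in the interior; the α lower bound of 0.5 and the H
    band [0.05, 0.95] keep the exponents numerically tame.
    """

    bounds_D: tuple[float, float] = (1e-8, 10.0)
    bounds_alpha: tuple[float, float] = (0.5, 2.0)
    bounds_hurst: tuple[float, float] = (0.05, 0.95)
    alpha_init: tuple[float, ...] = (1.0, 1.5, 2.0)
    hurst_init: tuple[float, ...] = (0.3, 0.5, 0.7)
    ftol: float = 1e-10
    xtol: float = 1e-12
    gtol: float = 1e-10
    max_nfev: int = 1000
    eta_model: str = "narrow_pulse"
    direction_average: str = "geometric"  # or "arithmetic"
    adc_b_target: float = 954.0
    eps: float = 1e-6


@dataclass(frozen=True)
class FMFit:
    """Result of one voxel's FM fit; ``ok`` is False for unfittable voxels."""

    params: FMParams | None
    mu: float
    sse: float
    converged: bool
    n_starts_used: int
    ok: bool = True


_UNFITTABLE = FMFit(
    params=None, mu=math.nan, sse=math.nan, converged=False, n_starts_used=0, ok=False
)


@dataclass(frozen=True)
class NormalizedSignals:
    """Per-voxel S0 and direction-averaged attenuations, one per (Δ, G0) cell."""

    s0: np.ndarray  # spatial shape
    atten: np.ndarray  # spatial shape + (n_cells,)
    fittable: np.ndarray  # spatial shape, bool: S0 > 0
    cells: list[Cell]


@dataclass
class ParameterMaps:
    """Voxel-aligned parameter maps over one mask; NaN outside / unfittable."""

    alpha_map: np.ndarray
    hurst_map: np.ndarray
    mu_map: np.ndarray
    D_map: np.ndarray
    adc_map: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.875, 1.875, 5.0)
    qc: dict = field(default_factory=dict)


def normalize_and_average(
    dwi4d: np.ndarray, scheme: AcquisitionScheme, config: FitConfig | None = None
) -> NormalizedSignals:
    """Normalise a 4D DWI by its b=0 mean and average over directions.

    S0 is the arithmetic mean of the ``n_b0`` leading volumes.  Each
    (Δ, G0) cell's directional repeats are combined by the geometric mean
    of S/S0 (equivalently the arithmetic mean of log-attenuations), with
    attenuations clipped to ≥ ``eps`` before the log.  Voxels with S0 ≤ 0
    are flagged unfittable rather than raising.
    """
    config = config or FitConfig()
    dwi4d = np.asarray(dwi4d, dtype=float)
    if dwi4d.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {dwi4d.shape}")
    if dwi4d.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"volume count {dwi4d.shape[3]} does not match scheme "
            f"({scheme.n_b0} b0 + {scheme.n_weighted} weighted)"
        )
    s0 = dwi4d[..., : scheme.n_b0].mean(axis=-1)
    fittable = s0 > 0
    safe_s0 = np.where(fittable, s0, 1.0)
    weighted = dwi4d[..., scheme.n_b0 :]
    atten_all = np.clip(weighted / safe_s0[..., None], config.eps, None)
    cells = scheme.cells()
    atten = np.empty(dwi4d.shape[:3] + (len(cells),))
    for j, cell in enumerate(cells):
        block = atten_all[..., list(cell.indices)]
        if config.direction_average == "geometric":
            atten[..., j] = np.exp(np.log(block).mean(axis=-1))
        elif config.direction_average == "arithmetic":
            atten[..., j] = block.mean(axis=-1)
        else:
            raise ValueError(f"unknown direction_average {config.direction_average!r}")
    return NormalizedSignals(s0=s0, atten=atten, fittable=fittable, cells=cells)


def _cell_arrays(cells: list[Cell], gamma: float):
    G0 = np.array([c.G0 for c in cells])
    Delta = np.array([c.Delta for c in cells])
    delta = np.array([c.delta for c in cells])
    b = np.array([c.bvalue for c in cells])
    lnG = np.log(gamma * G0 * _G0_TO_PER_MM)
    return G0, Delta, delta, b, lnG


def _init_adc(atten: np.ndarray, b: np.ndarray, eps: float) -> float:
    """Gaussian-limit log-linear ADC estimate used to seed D."""
    y = np.log(np.clip(atten, eps, None))
    slope = np.polyfit(b, y, 1)[0]
    adc = -slope
    if not np.isfinite(adc) or adc <= 0:
        adc = 1e-3  # fall back to a typical parenchymal value
    return adc


def fit_fm_voxel(
    atten: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
    cells: list[Cell] | None = None,
) -> FMFit:
    """Fit (D, α, H) to one voxel's direction-averaged attenuations.

    Minimises Σ (model − observed)² in the signal domain with scipy's
    trust-region-reflective solver under the configured bounds, restarting
    from every point of the (α, H) init grid; D is seeded per start by
    matching the decay exponent at the median-b cell to a Gaussian-limit
    log-linear ADC estimate.  The lowest-SSE start wins (ties: first in
    grid order).  Returns an unfittable result when fewer than 3 cells are
    available or the signals are all at the clipping floor.
    """
    config = config or FitConfig()
    cells = cells if cells is not None else scheme.cells()
    atten = np.asarray(atten, dtype=float)
    if atten.shape != (len(cells),):
        raise ValueError(f"expected {len(cells)} attenuations, got shape {atten.shape}")
    if len(cells) < 3 or not np.all(np.isfinite(atten)) or np.all(atten <= config.eps):
        return _UNFITTABLE

    gamma = scheme.gamma
    _, Delta, delta, b, lnG = _cell_arrays(cells, gamma)
    lnDelta = np.log(Delta)
    narrow = config.eta_model == "narrow_pulse"
    ln_dD = np.log(delta / Delta)  # used by the narrow-pulse fast path

    lo = np.array([math.log(config.bounds_D[0]), config.bounds_alpha[0], config.bounds_hurst[0]])
    hi = np.array([math.log(config.bounds_D[1]), config.bounds_alpha[1], config.bounds_hurst[1]])

    def exponent(u, a, h):
        if narrow:
            return np.exp(u + a * (ln_dD + lnG) + a * (1.0 + h) * lnDelta)
        eta = np.array(
            [compute_eta(a, h, c.delta, c.Delta, model=config.eta_model) for c in cells]
        )
        return eta * np.exp(u + a * lnG + a * (1.0 + h) * lnDelta)

    def residuals(x):
        return np.exp(-exponent(*x)) - atten

    def jacobian(x):
        u, a, h = x
        E = exponent(u, a, h)
        m = np.exp(-E)
        J = np.empty((len(cells), 3))
        J[:, 0] = -m * E
        J[:, 1] = -m * E * (ln_dD + lnG + (1.0 + h) * lnDelta)
        J[:, 2] = -m * E * a * lnDelta
        return J

    adc0 = _init_adc(atten, b, config.eps)
    ref = cells[int(np.argsort(b)[len(b) // 2])]  # median-b cell

    best = None
    n_starts = 0
    for a0 in config.alpha_init:
        for h0 in config.hurst_init:
            a0c = float(np.clip(a0, lo[1], hi[1]))
            h0c = float(np.clip(h0, lo[2], hi[2]))
            K = decay_constant(a0c, h0c, ref, gamma, config.eta_model)
            D0 = ref.bvalue * adc0 / K
            u0 = float(np.clip(math.log(max(D0, 1e-300)), lo[0], hi[0]))
            x0 = np.array([u0, a0c, h0c])
            res = least_squares(
                residuals,
                x0,
                jac=jacobian if narrow else "2-point",
                bounds=(lo, hi),
                method="trf",
                ftol=config.ftol,
                xtol=config.xtol,
                gtol=config.gtol,
                max_nfev=config.max_nfev,
            )
            n_starts += 1
            sse = float(2.0 * res.cost)
            if best is None or sse < best[0]:
                best = (sse, res)
    sse, res = best
    u, a, h = res.x
    params = FMParams(D=math.exp(u), alpha=float(a), hurst=float(h))
    return FMFit(
        params=params,
        mu=memory_parameter(a, h),
        sse=sse,
        converged=bool(res.status > 0),
        n_starts_used=n_starts,
    )


def select_adc_cell(cells: list[Cell], target: float) -> int:
    """Index of the cell whose b is nearest ``target`` (ties → lower b)."""
    b = np.array([c.bvalue for c in cells])
    dist = np.abs(b - target)
    candidates = np.flatnonzero(dist == dist.min())
    return int(candidates[np.argmin(b[candidates])])


def compute_adc(S_b0: float, S_b1: float, b1: float) -> float:
    """Two-point ADC in mm²/s: ln(S_b0/S_b1)/b1, b1 in s/mm².

    Negative values (possible under noise) are returned as-is; callers
    count them in QC.  Non-positive signals raise.
    """
    if not (S_b0 > 0 and S_b1 > 0):
        raise ValueError("signals must be > 0 to compute ADC")
    if not b1 > 0:
        raise ValueError(f"b1 must be > 0, got {b1}")
    return math.log(S_b0 / S_b1) / b1


def fit_fm_volume(
    dwi4d: np.ndarray,
    mask: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
    spacing: tuple[float, float, float] = (1.875, 1.875, 5.0),
) -> ParameterMaps:
    """Fit every masked voxel of a 4D DWI, producing α/H/μ/D/ADC maps.

    Deterministic given inputs and config.  Unfittable voxels stay NaN and
    are counted in the QC summary along with convergence statistics and
    negative-ADC occurrences.
    """
    config = config or FitConfig()
    dwi4d = np.asarray(dwi4d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != dwi4d.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match spatial shape {dwi4d.shape[:3]}"
        )
    norm = normalize_and_average(dwi4d, scheme, config)
    cells = norm.cells
    adc_idx = select_adc_cell(cells, config.adc_b_target)
    adc_b = cells[adc_idx].bvalue

    shape = mask.shape
    maps = {name: np.full(shape, np.nan) for name in ("alpha", "hurst", "mu", "D", "adc")}
    n_fitted = n_unfittable = n_nonconverged = n_neg_adc = 0
    for idx in np.argwhere(mask):
        i, j, k = idx
        if not norm.fittable[i, j, k]:
            n_unfittable += 1
            continue
        fit = fit_fm_voxel(norm.atten[i, j, k], scheme, config, cells=cells)
        if not fit.ok:
            n_unfittable += 1
            continue
        maps["alpha"][i, j, k] = fit.params.alpha
        maps["hurst"][i, j, k] = fit.params.hurst
        maps["mu"][i, j, k] = fit.mu
        maps["D"][i, j, k] = fit.params.D
        a = norm.atten[i, j, k, adc_idx]
        adc = -math.log(a) / adc_b  # attenuation is already S/S0
        maps["adc"][i, j, k] = adc
        if adc < 0:
            n_neg_adc += 1
        n_fitted += 1
        if not fit.converged:
            n_nonconverged += 1
    qc = {
        "n_mask": int(mask.sum()),
        "n_fitted": n_fitted,
        "n_unfittable": n_unfittable,
        "n_nonconverged": n_nonconverged,
        "n_negative_adc": n_neg_adc,
        "adc_bvalue_used": adc_b,
    }
    logger.info("fit_fm_volume: %s", qc)
    return ParameterMaps(
        alpha_map=maps["alpha"],
        hurst_map=maps["hurst"],
        mu_map=maps["mu"],
        D_map=maps["D"],
        adc_map=maps["adc"],
        mask=mask,
        spacing=spacing,
        qc=qc,
    )
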