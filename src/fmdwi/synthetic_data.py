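"""Digital cohorts for end-to-end testing of the FM pipeline.

Generates desk-scale synthetic studies: per-subject "true" hippocampal FM
parameters and ADC drawn from group-level means/SDs, demographic covariates
and cognitive scores, and block-geometry 4D phantoms imaged under a given
acquisition scheme with Rician magnitude noise.  The default group
specifications emulate a three-group hippocampal study (healthy controls,
mild and moderate Alzheimer's disease; 11/12/12 subjects) with α ≈ 1.52–1.60,
H ≈ 0.46–0.49 and ADC ≈ 1.0–1.4 × 10⁻³ mm²/s, where α decreases and ADC
increases with disease severity.

Modelling choices:

* Each parameter is drawn from a normal distribution truncated to its legal
  range; between-parameter correlations are zero except a configurable
  positive coupling between cognitive scores and α (default target r = 0.45
  per hippocampus, implemented through the bilateral α latent).
* μ is always derived as H − 1/α, never sampled — a sampled μ could
  contradict the (α, H) pair it accompanies.
* D_{α,H} is chosen so the FM signal at the scheme's median-b cell equals
  the mono-exponential signal with the subject's ADC at that cell, keeping
  phantom contrast realistic across (α, H) combinations.
* Phantom geometry is abstract: two disjoint rectangular ROIs ("left" and
  "right") in a low-intensity background; the nominal 1.875×1.875×5 mm
  voxel size is recorded but plays no computational role.
* Reproducibility: one master seed; each subject's random stream is derived
  from (seed, global subject index) via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .acquisition import AcquisitionScheme, default_scheme
from .fm_model import FMParams, fm_signal, memory_parameter
from ._calibration import calibrate_D

__all__ = [
    "ROIStats",
    "GroupSpec",
    "SyntheticSubject",
    "default_group_specs",
    "sample_group_params",
    "add_rician_noise",
    "generate_phantom",
    "generate_cohort",
]

ALPHA_RANGE = (0.5, 2.0)
HURST_RANGE = (0.05, 0.95)
ADC_RANGE = (1e-5, 1e-1)
SCORE_RANGE = (0.0, 30.0)
AGE_RANGE = (18.0, 100.0)
ROI_NAMES = ("left", "right")


@dataclass(frozen=True)
class ROIStats:
    """Group-level mean ± SD of α, H and ADC (mm²/s) in one ROI."""

    alpha_mean: float
    alpha_sd: float
    hurst_mean: float
    hurst_sd: float
    adc_mean: float
    adc_sd: float

    def __post_init__(self) -> None:
        for name in ("alpha_sd", "hurst_sd", "adc_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (ALPHA_RANGE[0] < self.alpha_mean <= ALPHA_RANGE[1]):
            raise ValueError(f"alpha_mean {self.alpha_mean} outside {ALPHA_RANGE}")
        if not (HURST_RANGE[0] < self.hurst_mean < HURST_RANGE[1]):
            raise ValueError(f"hurst_mean {self.hurst_mean} outside {HURST_RANGE}")
        if not (ADC_RANGE[0] < self.adc_mean < ADC_RANGE[1]):
            raise ValueError(f"adc_mean {self.adc_mean} outside {ADC_RANGE}")


@dataclass(frozen=True)
class GroupSpec:
    """Generative description of one study group.

    ``score_alpha_r`` is the target Pearson correlation between each
    cognitive score and the per-hemisphere α (must be ≤ 0.7, since the
    coupling runs through the bilateral latent).  A NaN ``moca_mean`` marks
    a group without MoCA assessment.
    """

    name: str
    n: int
    roi: dict[str, ROIStats]
    age_mean: float
    age_sd: float
    mmse_mean: float
    mmse_sd: float
    moca_mean: float
    moca_sd: float
    female_fraction: float = 0.5
    score_alpha_r: float = 0.45

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if set(self.roi) != set(ROI_NAMES):
            raise ValueError(f"roi must have keys {ROI_NAMES}, got {sorted(self.roi)}")
        for name in ("age_sd", "mmse_sd", "moca_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if not abs(self.score_alpha_r) <= 0.7:
            raise ValueError("|score_alpha_r| must be <= 0.7")


@dataclass
class SyntheticSubject:
    """One synthetic subject: covariates, per-ROI ground truth, optional phantom."""

    id: str
    group: str
    age: float
    sex: str
    mmse: float
    moca: float
    roi_params: dict[str, FMParams]
    roi_adc: dict[str, float]
    dwi: np.ndarray | None = None
    masks: dict[str, np.ndarray] | None = None
    seed_key: tuple[int, int] | None = None


def default_group_specs() -> tuple[GroupSpec, GroupSpec, GroupSpec]:
    """Default three-group cohort specification (controls, mild AD, moderate AD).

    Group sizes 11/12/12; hippocampal α/H/ADC means and SDs, ages and
    MMSE/MoCA scores follow the group-level summaries the generator is
    designed to emulate.  Controls carry no MoCA assessment (NaN).
    """
    controls = GroupSpec(
        name="controls",
        n=11,
        roi={
            "left": ROIStats(1.588, 0.047, 0.464, 0.033, 0.00108, 0.00013),
            "right": ROIStats(1.604, 0.049, 0.479, 0.028, 0.00104, 0.00012),
        },
        age_mean=65.27,
        age_sd=6.60,
        mmse_mean=28.82,
        mmse_sd=1.08,
        moca_mean=math.nan,
        moca_sd=0.0,
        female_fraction=9 / 11,
    )
    mild = GroupSpec(
        name="mild_AD",
        n=12,
        roi={
            "left": ROIStats(1.563, 0.030, 0.470, 0.027, 0.00119, 0.00013),
            "right": ROIStats(1.562, 0.040, 0.485, 0.040, 0.00115, 0.00017),
        },
        age_mean=65.83,
        age_sd=10.06,
        mmse_mean=23.17,
        mmse_sd=11.27,
        moca_mean=19.50,
        moca_sd=2.39,
        female_fraction=6 / 12,
    )
    moderate = GroupSpec(
        name="moderate_AD",
        n=12,
        roi={
            "left": ROIStats(1.531, 0.045, 0.468, 0.030, 0.00139, 0.00021),
            "right": ROIStats(1.519, 0.041, 0.481, 0.049, 0.00137, 0.00025),
        },
        age_mean=72.08,
        age_sd=3.75,
        mmse_mean=19.08,
        mmse_sd=1.44,
        moca_mean=16.50,
        moca_sd=2.15,
        female_fraction=9 / 12,
    )
    return controls, mild, moderate


def _truncnorm_draw(mean: float, sd: float, lo: float, hi: float, rng) -> float:
    if sd == 0:
        return mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _sample_subject(
    spec: GroupSpec, rng: np.random.Generator, scheme: AcquisitionScheme
) -> SyntheticSubject:
    roi_params: dict[str, FMParams] = {}
    roi_adc: dict[str, float] = {}
    z: dict[str, float] = {}
    for roi in ROI_NAMES:
        st = spec.roi[roi]
        alpha = _truncnorm_draw(st.alpha_mean, st.alpha_sd, ALPHA_RANGE[0] + 1e-9, ALPHA_RANGE[1], rng)
        hurst = _truncnorm_draw(st.hurst_mean, st.hurst_sd, *HURST_RANGE, rng)
        adc = _truncnorm_draw(st.adc_mean, st.adc_sd, *ADC_RANGE, rng)
        z[roi] = (alpha - st.alpha_mean) / st.alpha_sd if st.alpha_sd > 0 else 0.0
        D = calibrate_D(alpha, hurst, adc, scheme)
        roi_params[roi] = FMParams(D=D, alpha=alpha, hurst=hurst)
        roi_adc[roi] = adc

    age = _truncnorm_draw(spec.age_mean, spec.age_sd, *AGE_RANGE, rng)
    sex = "F" if rng.random() < spec.female_fraction else "M"

    # Couple each score to the bilateral α latent: with independent unit
    # latents z_left, z_right, weight c = r·√2 on (z_l+z_r)/√2 yields
    # corr(score, α_roi) ≈ r per hemisphere.
    z_bar = (z["left"] + z["right"]) / math.sqrt(2.0)
    c = spec.score_alpha_r * math.sqrt(2.0)
    s = math.sqrt(max(0.0, 1.0 - c * c))

    def score(mean: float, sd: float) -> float:
        if math.isnan(mean):
            return math.nan
        if sd == 0:
            return mean
        raw = mean + sd * (c * z_bar + s * rng.standard_normal())
        return float(np.clip(raw, *SCORE_RANGE))

    return SyntheticSubject(
        id="",
        group=spec.name,
        age=age,
        sex=sex,
        mmse=score(spec.mmse_mean, spec.mmse_sd),
        moca=score(spec.moca_mean, spec.moca_sd),
        roi_params=roi_params,
        roi_adc=roi_adc,
    )


def sample_group_params(
    spec: GroupSpec,
    rng: np.random.Generator,
    scheme: AcquisitionScheme | None = None,
) -> list[SyntheticSubject]:
    """Draw ``spec.n`` subjects' true parameters and covariates (no phantoms)."""
    scheme = scheme or default_scheme()
    subjects = []
    for i in range(spec.n):
        subj = _sample_subject(spec, rng, scheme)
        subj.id = f"{spec.name}-{i + 1:03d}"
        subjects.append(subj)
    return subjects


def add_rician_noise(signal, sigma: float, rng: np.random.Generator):
    """Rician magnitude noise: |signal + n1 + i·n2| with n1, n2 ~ N(0, σ).

    σ = 0 returns the input unchanged.  For signal 0 the output follows a
    Rayleigh distribution (mean σ·√(π/2)); in general the second moment is
    ν² + 2σ².
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + n1, n2)


DEFAULT_SHAPE = (16, 16, 4)
DEFAULT_ROI_SIZE = (3, 3, 2)


def _default_roi_slices(shape, roi_size):
    sx, sy, sz = roi_size
    left = (slice(3, 3 + sx), slice(3, 3 + sy), slice(1, 1 + sz))
    right = (slice(shape[0] - 3 - sx, shape[0] - 3), slice(3, 3 + sy), slice(1, 1 + sz))
    return {"left": left, "right": right}


def generate_phantom(
    subject: SyntheticSubject,
    scheme: AcquisitionScheme,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    snr: float | None = 50.0,
    rng: np.random.Generator | None = None,
    s0: float = 1000.0,
    background_frac: float = 0.1,
    roi_size: tuple[int, int, int] = DEFAULT_ROI_SIZE,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render one subject's 4D phantom plus left/right ROI masks.

    ROI voxels follow the FM forward model with the subject's per-ROI
    parameters (b=0 volumes at ``s0``); background voxels sit at a constant
    low amplitude.  ``snr`` sets the per-channel Rician σ = s0/SNR applied
    to every volume; ``None`` (or ``inf``) gives a noiseless phantom.
    """
    slices = _default_roi_slices(shape, roi_size)
    masks = {}
    for roi, sl in slices.items():
        m = np.zeros(shape, dtype=bool)
        m[sl] = True
        if m.sum() != np.prod(roi_size):
            raise ValueError(f"shape {shape} too small for two {roi_size} ROIs")
        masks[roi] = m
    if np.any(masks["left"] & masks["right"]):
        raise ValueError("ROIs overlap; enlarge the phantom shape")

    n_vol = scheme.n_volumes
    dwi = np.full(shape + (n_vol,), background_frac * s0)
    for roi in ROI_NAMES:
        series = fm_signal(subject.roi_params[roi], scheme, S0=s0)
        voxel_ts = np.concatenate([np.full(scheme.n_b0, s0), series.signals])
        dwi[masks[roi]] = voxel_ts

    if snr is not None and math.isfinite(snr):
        if rng is None:
            raise ValueError("rng is required when adding noise")
        dwi = add_rician_noise(dwi, s0 / snr, rng)
    return dwi, masks


def _subjects_dataframe(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "mmse": s.mmse,
            "moca": s.moca,
        }
        for roi in ROI_NAMES:
            p = s.roi_params[roi]
            row[f"alpha_{roi}"] = p.alpha
            row[f"hurst_{roi}"] = p.hurst
            row[f"mu_{roi}"] = memory_parameter(p.alpha, p.hurst)
            row[f"adc_{roi}"] = s.roi_adc[roi]
            row[f"D_{roi}"] = p.D
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    specs: Sequence[GroupSpec] | None = None,
    scheme: AcquisitionScheme | None = None,
    snr: float | None = 50.0,
    seed: int = 0,
    outdir: str | Path | None = None,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    roi_size: tuple[int, int, int] = DEFAULT_ROI_SIZE,
    with_phantoms: bool = True,
) -> list[SyntheticSubject]:
    """Generate a full multi-group cohort, optionally writing it to disk.

    Fully reproducible from ``seed``: subject j (in global enumeration
    order) draws from ``SeedSequence([seed, j])``.  With ``outdir`` set,
    writes ``scheme.json``, ``subjects.csv`` (covariates + ground truth)
    and per-subject NIfTI phantoms and masks under ``sub-XXX/``.
    """
    specs = list(specs) if specs is not None else list(default_group_specs())
    names = [g.name for g in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names in specs: {names}")
    scheme = scheme or default_scheme()

    subjects: list[SyntheticSubject] = []
    j = 0
    for spec in specs:
        for _ in range(spec.n):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), j]))
            subj = _sample_subject(spec, rng, scheme)
            subj.id = f"sub-{j + 1:03d}"
            subj.seed_key = (int(seed), j)
            if with_phantoms:
                subj.dwi, subj.masks = generate_phantom(
                    subj, scheme, shape=shape, snr=snr, rng=rng, roi_size=roi_size
                )
            subjects.append(subj)
            j += 1

    if outdir is not None:
        from . import io as fio  # local import: keeps nibabel out of array-only use

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_scheme(scheme, outdir / "scheme.json")
        _subjects_dataframe(subjects).to_csv(outdir / "subjects.csv", index=False)
        for s in subjects:
            sdir = outdir / s.id
            sdir.mkdir(exist_ok=True)
            if s.dwi is not None:
                fio.save_volume(s.dwi, np.eye(4), sdir / "dwi.nii.gz")
                for roi, m in s.masks.items():
                    fio.save_volume(m.astype(np.uint8), np.eye(4), sdir / f"mask_{roi}.nii.gz")
    return subjects
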