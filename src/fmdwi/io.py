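"""File formats: acquisition schemes (JSON/CSV), NIfTI volumes, FSL tables,
parameter-map bundles and run manifests.

Scheme files carry clinical units (ms, mT/m) because protocols are quoted
that way; conversion to SI happens on read.  All floats are written at full
precision so write→read round-trips are lossless; invariants (δ ≤ Δ,
b-value consistency with the Stejskal–Tanner formula) are validated on
read with errors naming the offending row.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import AcquisitionScheme, DiffusionMeasurement, compute_bvalue
from .fitting import ParameterMaps

__all__ = [
    "write_scheme",
    "read_scheme",
    "export_fsl",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_parameter_maps",
    "write_manifest",
]

_B_RTOL = 1e-6  # tolerance when validating stored b against the formula


def _scheme_rows(scheme: AcquisitionScheme) -> list[dict]:
    # clinical units for human readers; exact SI duplicates for lossless
    # round-trips (ms → s conversion is not always ulp-exact)
    return [
        {
            "Delta_ms": m.Delta * 1e3,
            "G0_mT_per_m": m.G0 * 1e3,
            "direction": m.direction,
            "b_s_per_mm2": m.bvalue,
            "Delta_s": m.Delta,
            "G0_T_per_m": m.G0,
            "delta_s": m.delta,
        }
        for m in scheme.measurements
    ]


def write_scheme(scheme: AcquisitionScheme, path: str | Path) -> None:
    """Write a scheme as JSON (``.json``) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "gamma": scheme.gamma,
            "delta_ms": scheme.delta * 1e3,
            "n_b0": scheme.n_b0,
            "measurements": _scheme_rows(scheme),
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    else:
        with open(path, "w", newline="") as fh:
            fh.write(f"# gamma={scheme.gamma!r}\n")
            fh.write(f"# delta_ms={scheme.delta * 1e3!r}\n")
            fh.write(f"# n_b0={scheme.n_b0}\n")
            writer = csv.DictWriter(
                fh,
                fieldnames=[
                    "Delta_ms", "G0_mT_per_m", "direction", "b_s_per_mm2",
                    "Delta_s", "G0_T_per_m", "delta_s",
                ],
            )
            writer.writeheader()
            for row in _scheme_rows(scheme):
                writer.writerow({k: repr(v) if isinstance(v, float) else v for k, v in row.items()})


def _build_measurement(row: dict, delta_ms: float, gamma: float, idx: int) -> DiffusionMeasurement:
    try:
        if row.get("Delta_s") not in (None, ""):  # exact SI fields, if present
            Delta = float(row["Delta_s"])
            G0 = float(row["G0_T_per_m"])
            delta = float(row["delta_s"])
        else:
            Delta = float(row["Delta_ms"]) * 1e-3
            G0 = float(row["G0_mT_per_m"]) * 1e-3
            delta = delta_ms * 1e-3
        direction = str(row["direction"])
        b_stored = float(row["b_s_per_mm2"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"scheme row {idx}: malformed field ({exc})") from exc
    if delta > Delta:
        raise ValueError(f"scheme row {idx}: delta ({delta_ms} ms) exceeds Delta ({row['Delta_ms']} ms)")
    b_check = compute_bvalue(gamma, G0, delta, Delta)
    if abs(b_stored - b_check) > _B_RTOL * max(1.0, b_check):
        raise ValueError(
            f"scheme row {idx}: stored b={b_stored} disagrees with "
            f"Stejskal-Tanner value {b_check:.6f}"
        )
    return DiffusionMeasurement(Delta=Delta, G0=G0, delta=delta, direction=direction, bvalue=b_stored)


def read_scheme(path: str | Path) -> AcquisitionScheme:
    """Read and validate a scheme file written by :func:`write_scheme`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            doc = json.loads(path.read_text())
            gamma = float(doc["gamma"])
            delta_ms = float(doc["delta_ms"])
            n_b0 = int(doc["n_b0"])
            rows = doc["measurements"]
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise ValueError(f"malformed scheme file {path}: {exc}") from exc
    else:
        header: dict[str, str] = {}
        body: list[str] = []
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                header[key.strip()] = val.strip()
            elif line.strip():
                body.append(line)
        try:
            gamma = float(header["gamma"])
            delta_ms = float(header["delta_ms"])
            n_b0 = int(header["n_b0"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed scheme header in {path}: {exc}") from exc
        rows = list(csv.DictReader(body))
    measurements = tuple(
        _build_measurement(row, delta_ms, gamma, idx) for idx, row in enumerate(rows)
    )
    return AcquisitionScheme(gamma=gamma, n_b0=n_b0, measurements=measurements)


def export_fsl(scheme: AcquisitionScheme, prefix: str | Path) -> tuple[Path, Path]:
    """Write FSL-style ``.bval``/``.bvec`` files (b0 volumes included)."""
    prefix = Path(prefix)
    bvals = [0.0] * scheme.n_b0 + [m.bvalue for m in scheme.measurements]
    unit = {"x": (1, 0, 0), "y": (0, 1, 0), "z": (0, 0, 1)}
    vecs = [(0, 0, 0)] * scheme.n_b0 + [unit[m.direction] for m in scheme.measurements]
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    bval_path.write_text(" ".join(f"{b:.6f}" for b in bvals) + "\n")
    bvec_path.write_text(
        "\n".join(" ".join(str(v[i]) for v in vecs) for i in range(3)) + "\n"
    )
    return bval_path, bvec_path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data as float array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI mask as boolean (any non-zero voxel is True)."""
    data, affine = load_volume(path)
    return data != 0, affine


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def save_parameter_maps(maps: ParameterMaps, affine: np.ndarray, outdir: str | Path) -> None:
    """Write one NIfTI per parameter map plus a JSON QC report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in (
        ("alpha", maps.alpha_map),
        ("hurst", maps.hurst_map),
        ("mu", maps.mu_map),
        ("D", maps.D_map),
        ("adc", maps.adc_map),
    ):
        save_volume(arr, affine, outdir / f"{name}.nii.gz")
    save_volume(maps.mask.astype(np.uint8), affine, outdir / "fit_mask.nii.gz")
    (outdir / "qc.json").write_text(json.dumps(maps.qc, indent=1) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    config: dict,
    inputs: list[str | Path] = (),
    seed: int | None = None,
) -> Path:
    """Record everything needed to reproduce a run: command, config echo,
    seed, package version and input-file checksums."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str) + "\n")
    return path
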