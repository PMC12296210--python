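"""Readers and writers: NIfTI-1 volumes, spectrum CSVs, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import SusceptibilityMap, VoxelGrid
from .lineshape import Spectrum
from .magnetostatics import FieldMap

__all__ = [
    "write_nifti",
    "read_susceptibility_nifti",
    "read_field_nifti",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_json_report",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag([*grid.spacing, 1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_nifti(img) -> VoxelGrid:
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelGrid(counts=tuple(img.shape[:3]), spacing=spacing, origin=origin)


def write_nifti(volume: SusceptibilityMap | FieldMap, path: str | Path) -> Path:
    """Write a χ map or field map as a NIfTI-1 volume (mm spacing, ppm
    values, float32)."""
    data = volume.chi if isinstance(volume, SusceptibilityMap) else volume.offset_ppm
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(volume.grid))
    img.header.set_xyzt_units(xyz="mm")
    img.header["descrip"] = (b"nmrcell susceptibility ppm"
                             if isinstance(volume, SusceptibilityMap)
                             else b"nmrcell nuclear offset ppm")
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_susceptibility_nifti(path: str | Path, background_chi: float = 0.0) -> SusceptibilityMap:
    img = nib.load(str(path))
    return SusceptibilityMap(grid=_grid_from_nifti(img),
                             chi=np.asarray(img.dataobj, dtype=np.float64),
                             background_chi=background_chi)


def read_field_nifti(path: str | Path) -> FieldMap:
    img = nib.load(str(path))
    return FieldMap(grid=_grid_from_nifti(img),
                    offset_ppm=np.asarray(img.dataobj, dtype=np.float64))


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> Path:
    """Two-column CSV (ppm, intensity) plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("ppm,intensity\n")
        for p, i in zip(spec.ppm, spec.intensity):
            fh.write(f"{p:.10g},{i:.10g}\n")
    meta = {"spectrometer_mhz": spec.spectrometer_mhz,
            "n_points": int(spec.ppm.size),
            "total_intensity": spec.total_intensity()}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_spectrum_csv(path: str | Path, spectrometer_mhz: float | None = None) -> Spectrum:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if spectrometer_mhz is None:
        meta_path = path.with_suffix(path.suffix + ".json")
        if meta_path.exists():
            spectrometer_mhz = json.loads(meta_path.read_text())["spectrometer_mhz"]
        else:
            from .constants import DEFAULT_SPECTROMETER_MHZ
            spectrometer_mhz = DEFAULT_SPECTROMETER_MHZ
    return Spectrum(ppm=data[:, 0], intensity=data[:, 1],
                    spectrometer_mhz=spectrometer_mhz)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n")
    return path
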