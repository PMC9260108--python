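"""NIfTI + YAML-sidecar readers/writers and the study configuration.

Images travel as NIfTI-1 with the acquisition metadata that NIfTI cannot carry
(orientation label, frame timing, b-values, flip angles, TR) in a YAML sidecar
next to the image (``image.nii.gz`` + ``image.yaml``). The sidecar is the
source of truth for acquisition metadata; geometric fields it shares with the
NIfTI header (voxel sizes) must agree — a mismatch is a hard error naming both
sources, never a silent preference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dce import DynamicSeries
from .diffusion import DiffusionSeries
from .geometry import AcquisitionGeometry
from .relaxometry import VFASeries

__all__ = [
    "StudyConfig",
    "write_image",
    "read_image",
    "write_series",
    "read_dwi",
    "read_vfa",
    "read_dce",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".yaml")
    return path.with_suffix(".yaml")


def _geometry_meta(geometry: AcquisitionGeometry) -> dict:
    return {
        "fov_mm": [float(f) for f in geometry.fov_mm],
        "matrix": [int(m) for m in geometry.matrix],
        "slice_thickness_mm": float(geometry.slice_thickness_mm),
        "n_slices": int(geometry.n_slices),
        "orientation": geometry.orientation,
    }


def write_image(path, data: np.ndarray, geometry: AcquisitionGeometry,
                meta: dict | None = None) -> Path:
    """Write a 3D/4D volume as NIfTI-1 with a YAML sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), geometry.affine())
    zooms = geometry.voxel_size_mm + ((1.0,) if data.ndim == 4 else ())
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    sidecar = {"geometry": _geometry_meta(geometry)}
    if meta:
        sidecar.update(meta)
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return path


def read_image(path) -> tuple[np.ndarray, AcquisitionGeometry, dict]:
    """Read a NIfTI volume + sidecar; reconstruct and cross-check geometry."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file} for {path}")
    meta = yaml.safe_load(sidecar_file.read_text())
    g = meta["geometry"]
    geometry = AcquisitionGeometry(
        fov_mm=tuple(g["fov_mm"]),
        matrix=tuple(g["matrix"]),
        slice_thickness_mm=float(g["slice_thickness_mm"]),
        n_slices=int(g["n_slices"]),
        orientation=g["orientation"],
    )
    zooms = img.header.get_zooms()[:3]
    expect = geometry.voxel_size_mm
    if not np.allclose(zooms, expect, rtol=1e-4):
        raise ValueError(
            f"geometry conflict for {path}: NIfTI header voxel size {tuple(zooms)} "
            f"vs sidecar {sidecar_file} voxel size {expect}"
        )
    if data.shape[:3] != geometry.shape:
        raise ValueError(
            f"geometry conflict for {path}: image shape {data.shape[:3]} vs "
            f"sidecar {sidecar_file} shape {geometry.shape}"
        )
    return data, geometry, meta


def write_series(path, series) -> Path:
    """Write a DWI/VFA/DCE series with its acquisition metadata sidecar."""
    if isinstance(series, DiffusionSeries):
        meta = {"series": "dwi", "b_values": [float(b) for b in series.b_values]}
    elif isinstance(series, VFASeries):
        meta = {
            "series": "vfa",
            "flip_angles_deg": [float(a) for a in series.flip_angles_deg],
            "tr_s": float(series.tr_s),
        }
    elif isinstance(series, DynamicSeries):
        meta = {
            "series": "dce",
            "dt_s": float(series.dt_s),
            "n_frames": int(series.n_frames),
            "n_dummy": int(series.n_dummy),
            "baseline_window": [int(i) for i in series.baseline_window],
            "tr_s": float(series.tr_s),
            "flip_deg": float(series.flip_deg),
            "r1_relaxivity": float(series.r1_relaxivity),
        }
    else:
        raise TypeError(f"unsupported series type {type(series).__name__}")
    return write_image(path, series.data, series.geometry, meta)


def read_dwi(path, b_values=None) -> DiffusionSeries:
    """Read a 4D DWI series; b-values from the sidecar or an FSL-style file.

    ``b_values`` may be a path to a single-line space-separated bval file or an
    explicit sequence, overriding the sidecar.
    """
    data, geometry, meta = read_image(path)
    if b_values is None:
        b = meta.get("b_values")
        if b is None:
            raise ValueError(f"no b-values in sidecar of {path} and none given")
    elif isinstance(b_values, (str, Path)):
        b = [float(x) for x in Path(b_values).read_text().split()]
    else:
        b = [float(x) for x in b_values]
    if data.shape[-1] != len(b):
        raise ValueError(
            f"{path}: {data.shape[-1]} volumes but {len(b)} b-values"
        )
    return DiffusionSeries(data=data, b_values=tuple(b), geometry=geometry)


def read_vfa(path) -> VFASeries:
    data, geometry, meta = read_image(path)
    return VFASeries(
        data=data,
        flip_angles_deg=tuple(meta["flip_angles_deg"]),
        tr_s=float(meta["tr_s"]),
        geometry=geometry,
    )


def read_dce(path) -> DynamicSeries:
    data, geometry, meta = read_image(path)
    if data.shape[-1] != int(meta["n_frames"]):
        raise ValueError(
            f"{path}: {data.shape[-1]} frames but sidecar says {meta['n_frames']}"
        )
    return DynamicSeries(
        data=data,
        dt_s=float(meta["dt_s"]),
        geometry=geometry,
        baseline_window=tuple(meta["baseline_window"]),
        n_dummy=int(meta.get("n_dummy", 0)),
        tr_s=float(meta.get("tr_s", 0.039)),
        flip_deg=float(meta.get("flip_deg", 40.0)),
        r1_relaxivity=float(meta.get("r1_relaxivity", 3.4)),
    )


# ---------------------------------------------------------------------- config
def _default_geometry() -> dict:
    return {
        "fov_mm": [30.0, 30.0],
        "matrix": [128, 128],
        "slice_thickness_mm": 1.0,
        "n_slices": 16,
        "orientation": "axial",
    }


def _default_dce() -> dict:
    return {
        "dt_s": 5.0,
        "n_frames": 50,
        "n_dummy": 40,
        "arrival_s": 25.0,
        "r1_relaxivity": 3.4,
        "tr_s": 0.039,
        "flip_deg": 40.0,
        "aif": {
            "dose_mmol_per_kg": 0.27,
            "a1_kg_per_l": 3.99,
            "a2_kg_per_l": 4.78,
            "m1_per_min": 0.144,
            "m2_per_min": 0.0111,
        },
    }


@dataclass
class StudyConfig:
    """Full pipeline configuration; round-trips losslessly through YAML.

    All units are explicit in the field names. The defaults are the study's
    acquisition settings (30 × 30 mm FOV; DWI b = 25/180/323/508 s/mm²; VFA
    flip angles 2–40° at TR 39 ms; DCE 5 s × 50 frames after 40 dummy scans).
    """

    seed: int = 0
    geometry: dict = field(default_factory=_default_geometry)
    phantom: dict = field(default_factory=lambda: {
        "n_lesions_mean": 36.0, "n_lesions_sd": 5.7,
        "volume_range_mm3": [0.016, 5.12],
    })
    t2w: dict = field(default_factory=lambda: {
        "te_ms": 10.0, "tr_s": 3.0, "snr": 40.0,
    })
    dwi: dict = field(default_factory=lambda: {
        "b_values": [25.0, 180.0, 323.0, 508.0], "snr": 0.0,
    })
    vfa: dict = field(default_factory=lambda: {
        "flip_angles_deg": [2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0],
        "tr_s": 0.039, "snr": 0.0,
    })
    dce: dict | None = field(default_factory=_default_dce)
    analysis: dict = field(default_factory=lambda: {
        "fraction_threshold": 0.5,
        "cystic_adc_threshold": 0.0022,
        "papillary_adc_threshold": 0.0012,
        "adc_method": "loglinear",
    })

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def build_geometry(self) -> AcquisitionGeometry:
        g = self.geometry
        return AcquisitionGeometry(
            fov_mm=tuple(g["fov_mm"]),
            matrix=tuple(g["matrix"]),
            slice_thickness_mm=float(g["slice_thickness_mm"]),
            n_slices=int(g["n_slices"]),
            orientation=g.get("orientation", "axial"),
        )
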