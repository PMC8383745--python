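"""HDF5/NIfTI/raw I-O, YAML configuration and run manifests.

HDF5 is the native container: sinograms and images are dense arrays with
geometry attributes, validated against the run's geometry on read.  A raw
binary + JSON header export is provided for interoperability, and 3D
images can be exported as NIfTI for viewing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom_sim import Insert, PhantomSpec
from .scaling import VOISpec
from .scanner_model import (
    ActivityImage,
    AttenuationImage,
    ImageGrid,
    ScanGeometry,
    Sinogram,
    TOFModel,
    TOFSinogram,
)

__version__ = "0.1.0"


class GeometryMismatchError(ValueError):
    pass


def geometry_hash(geometry: ScanGeometry, tof: Optional[TOFModel] = None) -> str:
    parts = [repr(geometry)]
    if tof is not None:
        parts.append(repr(tof))
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def array_checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _write_geometry_attrs(obj, geometry: ScanGeometry, tof: Optional[TOFModel]) -> None:
    obj.attrs["geometry_hash"] = geometry_hash(geometry, tof)
    for k, v in asdict(geometry).items():
        obj.attrs[f"geom_{k}"] = v
    if tof is not None:
        for k, v in asdict(tof).items():
            obj.attrs[f"tof_{k}"] = v


def _check_geometry(attrs, geometry: Optional[ScanGeometry], tof: Optional[TOFModel]) -> None:
    if geometry is None:
        return
    expected = geometry_hash(geometry, tof)
    stored = attrs.get("geometry_hash")
    if stored is not None and stored != expected:
        raise GeometryMismatchError(
            f"stored geometry hash {stored} does not match expected {expected}")


def write_sinogram(path, sino: Union[Sinogram, TOFSinogram],
                   geometry: ScanGeometry, tof: Optional[TOFModel] = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=sino.values)
        d.attrs["kind"] = sino.kind
        d.attrs["is_tof"] = isinstance(sino, TOFSinogram)
        _write_geometry_attrs(f, geometry, tof)


def read_sinogram(path, geometry: Optional[ScanGeometry] = None,
                  tof: Optional[TOFModel] = None) -> Union[Sinogram, TOFSinogram]:
    with h5py.File(path, "r") as f:
        _check_geometry(f.attrs, geometry, tof)
        d = f["values"]
        values = d[()]
        kind = d.attrs.get("kind", "counts")
        is_tof = bool(d.attrs.get("is_tof", False))
    cls = TOFSinogram if is_tof else Sinogram
    return cls(values, kind=kind)


def write_image(path, image: Union[ActivityImage, AttenuationImage],
                geometry: Optional[ScanGeometry] = None) -> None:
    grid = image.grid
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=image.values)
        d.attrs["image_class"] = type(image).__name__
        d.attrs["voxel_size"] = grid.voxel_size
        d.attrs["origin"] = list(grid.origin)
        d.attrs["n_x"], d.attrs["n_y"] = grid.n_x, grid.n_y
        if grid.n_z is not None:
            d.attrs["n_z"] = grid.n_z
        if geometry is not None:
            _write_geometry_attrs(f, geometry, None)


def read_image(path, geometry: Optional[ScanGeometry] = None):
    with h5py.File(path, "r") as f:
        _check_geometry(f.attrs, geometry, None)
        d = f["values"]
        values = d[()]
        grid = ImageGrid(int(d.attrs["n_x"]), int(d.attrs["n_y"]),
                         float(d.attrs["voxel_size"]),
                         origin=tuple(d.attrs["origin"]),
                         n_z=int(d.attrs["n_z"]) if "n_z" in d.attrs else None)
        cls = ActivityImage if d.attrs.get("image_class") == "ActivityImage" else AttenuationImage
    return cls(values, grid)


def export_raw(path_prefix, values: np.ndarray, meta: Optional[dict] = None) -> None:
    """Raw little-endian float64 binary plus a JSON header."""
    arr = np.ascontiguousarray(values, dtype="<f8")
    prefix = Path(path_prefix)
    arr.tofile(prefix.with_suffix(".bin"))
    header = {"dtype": "<f8", "shape": list(arr.shape), "order": "C"}
    header.update(meta or {})
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))


def import_raw(path_prefix) -> np.ndarray:
    prefix = Path(path_prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    arr = np.fromfile(prefix.with_suffix(".bin"), dtype=header["dtype"])
    return arr.reshape(header["shape"])


def export_nifti(path, image: Union[ActivityImage, AttenuationImage]) -> None:
    """Export a (preferably 3D) image as NIfTI with the voxel size in the affine."""
    grid = image.grid
    vals = image.values
    if vals.ndim == 2:
        vals = vals[None, :, :]
    data = np.transpose(vals, (2, 1, 0))  # (x, y, z) order
    affine = np.diag([grid.voxel_size * 10, grid.voxel_size * 10,
                      grid.voxel_size * 10, 1.0])  # cm -> mm
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# YAML configuration

def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    inserts = tuple(
        Insert(center=tuple(i["center"]), diameter=float(i["diameter"]),
               activity_contrast=i.get("activity_contrast"),
               attenuation=i.get("attenuation"),
               spherical=bool(i.get("spherical", False)))
        for i in d.get("inserts", ()))
    return PhantomSpec(
        background_center=tuple(d.get("background_center", (0.0, 0.0))),
        background_diameter=float(d.get("background_diameter", 35.0)),
        background_activity=float(d.get("background_activity", 1.0)),
        background_attenuation=float(d.get("background_attenuation", 0.096)),
        inserts=inserts,
        total_trues=float(d.get("total_trues", 5e6)),
    )


def load_phantom_spec(path) -> PhantomSpec:
    with open(path) as f:
        return phantom_spec_from_dict(yaml.safe_load(f) or {})


def voi_from_dict(d: dict, grid: ImageGrid) -> VOISpec:
    """A VOI given either as a geometric disk or as a mask image file."""
    if "mask_file" in d:
        img = read_image(d["mask_file"])
        return VOISpec(weights=np.asarray(img.values, dtype=np.float64),
                       mu_true=float(d["mu_true"]))
    return VOISpec.disk(grid, tuple(d["center"]), float(d["diameter"]),
                        float(d["mu_true"]))


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run bit-exactly."""

    command: str
    config: dict
    geometry_hash: str
    seed: int
    version: str = __version__
    checksums: Dict[str, str] = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))
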