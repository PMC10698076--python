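"""NIfTI volume I/O and run configuration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .lesion import DynamicVolume, ParameterMaps
from .phantom import PhantomConfig

__all__ = [
    "FormatError",
    "RunConfig",
    "default_brain_mask",
    "read_nifti_4d",
    "write_volume_4d",
    "write_mask",
    "read_mask",
    "write_maps",
    "read_maps",
]


class FormatError(ValueError):
    """Input file has the wrong layout for the requested reader."""


@dataclass
class RunConfig:
    """Whole-toolkit configuration; defaults are the published settings.

    Round-trips losslessly through YAML.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    reg_frac: float = 0.2
    jwl_k_values: tuple = (0.1, 0.2, 0.4, 0.8, 1.6)
    rcbf_reference: float = 0.30
    tmax_reference_s: float = 6.0
    hypo_thresh_s: float = 4.0
    normal_cbf_gt: float = 50.0
    max_core_ml: float = 70.0
    min_penumbra_ml: float = 15.0
    min_ratio: float = 1.8
    smoothing_sigma_mm: float = 2.4
    morph_radius_mm: float = 2.5
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, val in list(data["phantom"].items()):
            if isinstance(val, tuple):
                data["phantom"][key] = list(val)
        data["jwl_k_values"] = list(self.jwl_k_values)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        ph = data.pop("phantom", {})
        for key in ("t0_grid", "mtt_grid", "cbv_grid"):
            if key in ph:
                ph[key] = tuple(ph[key])
        if "jwl_k_values" in data:
            data["jwl_k_values"] = tuple(data["jwl_k_values"])
        return cls(phantom=PhantomConfig(**ph), **data)


def default_brain_mask(data: np.ndarray, lo: float = 0.0, hi: float = 100.0) -> np.ndarray:
    """Parenchyma by HU range of the temporal-average image (crude)."""
    avg = data.mean(axis=-1)
    return (avg > lo) & (avg < hi)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_nifti_4d(
    path,
    times: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    aif_voxel: tuple | None = None,
    vof_voxel: tuple | None = None,
) -> DynamicVolume:
    """Load a 4D dynamic study; spacing and frame interval from the header."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D volume, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    if times is None:
        dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        times = np.arange(data.shape[3]) * dt
    if brain_mask is None:
        brain_mask = default_brain_mask(data)
    return DynamicVolume(data, spacing, times, brain_mask, aif_voxel, vof_voxel)


def write_volume_4d(data: np.ndarray, spacing, path, dt_s: float | None = None) -> None:
    data = np.asarray(data)
    if data.ndim != 4:
        raise FormatError("expected a 4D array")
    img = nib.Nifti1Image(data, _affine(spacing))
    zooms = list(spacing) + [dt_s if dt_s else 1.0]
    img.header.set_zooms(zooms)
    if dt_s:
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, spacing, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing)), str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D mask, got {data.ndim}D: {path}")
    return data.astype(bool)


MAP_NAMES = ("cbf", "cbv", "mtt", "tmax")


def write_maps(maps: ParameterMaps, out_dir) -> dict:
    """Write cbf/cbv/mtt/tmax as NIfTI files; returns {name: path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in MAP_NAMES:
        path = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(getattr(maps, name), _affine(maps.spacing)), str(path))
        written[name] = path
    return written


def read_maps(map_dir) -> ParameterMaps:
    map_dir = Path(map_dir)
    arrays = {}
    spacing = None
    for name in MAP_NAMES:
        path = map_dir / f"{name}.nii"
        if not path.exists():
            raise FormatError(f"missing parameter map: {path}")
        img = nib.load(str(path))
        arrays[name] = np.asanyarray(img.dataobj).astype(float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ParameterMaps(spacing=spacing, **arrays)
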