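"""Scalar image volumes and NIfTI-1 I/O.

The package-wide coordinate convention: volumes are 3-D arrays indexed
``(x, y, z)`` with 0-based voxel indices; world coordinates are millimetres
from the grid corner (voxel centre ``i`` sits at ``i * spacing``); axial
slices are indexed along ``z``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import nibabel as nib
import numpy as np

Modality = Literal["CT", "MR"]


@dataclass
class ImageVolume:
    """A scalar image: CT in Hounsfield units or MR in arbitrary signal units.

    Parameters
    ----------
    data:
        3-D float array, axes ``(x, y, z)``.
    spacing:
        Voxel size in mm per axis (isotropic or anisotropic).
    modality:
        ``"CT"`` or ``"MR"``.
    units:
        ``"HU"`` for CT, ``"a.u."`` for MR signal.
    acquisition:
        The protocol/sequence object the volume was simulated with (or None
        for loaded data).
    meta:
        Free-form provenance (seed, diagnostics, frequency-encode axis ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = "MR"
    units: str = "a.u."
    acquisition: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        self.spacing = spacing
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def copy(self) -> "ImageVolume":
        return ImageVolume(
            self.data.copy(), self.spacing, self.modality, self.units,
            self.acquisition, dict(self.meta),
        )


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(vol: ImageVolume | np.ndarray, path, spacing=None) -> None:
    """Write a volume (or bare array) to NIfTI-1, with a JSON sidecar for
    acquisition metadata when present."""
    if isinstance(vol, ImageVolume):
        data, spacing = vol.data, vol.spacing
        sidecar = {"modality": vol.modality, "units": vol.units, **_jsonable(vol.meta)}
        if vol.acquisition is not None:
            sidecar["acquisition"] = _jsonable(vol.acquisition)
    else:
        data = np.asarray(vol)
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
        sidecar = None
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(spacing))
    path = Path(path)
    nib.save(img, str(path))
    if sidecar:
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, default=str)
        )


def load_nifti(path, modality: Modality = "MR", units: str | None = None) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if units is None:
        units = "HU" if modality == "CT" else "a.u."
    return ImageVolume(data, spacing, modality, units)


def _jsonable(obj):
    """Best-effort conversion of dataclasses / arrays to JSON-clean values."""
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
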