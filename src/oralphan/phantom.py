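"""Digital twin of the CT/MR oral phantom.

The physical object being emulated is a 200 mm acrylic sphere (10 mm wall)
filled with CuSO4/NaCl-doped water, carrying an 11-tooth dental arch on a
thermoplastic retainer in the axial mid-plane, Teflon rods mimicking spine
and mandible, and 0-2 metallic dental restorations that can replace normal
teeth.  Everything downstream (CT/MR simulation, segmentation, registration,
fusion, metrics) is scored against the label map built here, so ground truth
is always available by label equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "MaterialSpec",
    "PhantomGeometry",
    "PhantomLabelMap",
    "default_materials",
    "build_phantom",
    "ground_truth_mask",
    "LABELS",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent phantom / pipeline configuration."""


@dataclass(frozen=True)
class MaterialSpec:
    """Physical and imaging properties of one phantom material.

    ``density`` in g/cm^3, ``hu`` in Hounsfield units, ``t1``/``t2`` in ms,
    ``susceptibility`` in ppm relative to vacuum (water is about -9 ppm),
    ``spin_density`` as relative MR-visible proton density in [0, 1].
    """

    name: str
    density: float
    hu: float
    t1: float
    t2: float
    susceptibility: float
    spin_density: float = 0.0

    def __post_init__(self):
        if self.density <= 0:
            raise ConfigurationError(f"{self.name}: density must be > 0")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ConfigurationError(f"{self.name}: relaxation times must be > 0")
        if self.t2 > self.t1:
            raise ConfigurationError(f"{self.name}: T2 must not exceed T1")
        if not 0 <= self.spin_density:
            raise ConfigurationError(f"{self.name}: spin density must be >= 0")


def default_materials() -> dict[str, MaterialSpec]:
    """The default material table.

    HU anchors: the metallic restoration measures 3095 HU and the Teflon
    cervical-vertebra mimic 1013 HU on the phantom scans; columnar Teflon is
    890 HU at 2.16 g/cm^3; acrylic is 1.20 g/cm^3.  Acrylic (120 HU) and
    solution (0 HU) sit well outside the oral segmentation window
    (1200-3500 HU); tooth is 2350 HU — an enamel/dentin composite value
    centred in the window, so the window cut falls at the true tooth
    boundary rather than eroding partial-volume edges.  The CuSO4 doping shortens solution T1 (300 ms here).
    Non-metal susceptibilities are set water-like so the restoration is the
    sole source of off-resonance, matching the role of the implant-free
    scans as artifact-free references; only the metal/water contrast (a
    titanium-like +180 ppm) drives the simulated artifacts.
    """
    return {
        "air": MaterialSpec("air", 1.2e-3, -1000.0, 1.0, 1.0, -9.0, 0.0),
        "acrylic": MaterialSpec("acrylic", 1.20, 120.0, 400.0, 30.0, -9.0, 0.02),
        "solution": MaterialSpec("solution", 1.00, 0.0, 300.0, 250.0, -9.05, 1.0),
        "teflon_bone": MaterialSpec("teflon_bone", 2.16, 1013.0, 100.0, 1.0, -9.0, 0.0),
        "teflon_rod": MaterialSpec("teflon_rod", 2.16, 890.0, 100.0, 1.0, -9.0, 0.0),
        "tooth": MaterialSpec("tooth", 2.00, 2350.0, 150.0, 1.0, -9.0, 0.10),
        "restoration_metal": MaterialSpec(
            "restoration_metal", 4.50, 3095.0, 1.0, 1.0, 180.0, 0.0
        ),
    }


# Fixed label assignment; label 0 is background air everywhere.
LABELS: dict[str, int] = {
    "air": 0,
    "acrylic": 1,
    "solution": 2,
    "teflon_bone": 3,
    "teflon_rod": 4,
    "tooth": 5,
    "restoration_metal": 6,
}

IMPLANT_CONFIGS = ("none", "left_single", "top_middle_double")


@dataclass(frozen=True)
class PhantomGeometry:
    """Geometry of the spherical oral phantom (all lengths in mm).

    The dental arch is a semi-ellipse in the axial mid-plane, anterior along
    +y; tooth angles are measured from the anterior direction so the arch is
    mirror-symmetric about the mid-sagittal (x = 0) plane.  ``left_index``
    and ``top_middle_indices`` choose which of the 11 retainer positions
    hold restorations (positions are not dictated by the physical design,
    hence configurable).
    """

    outer_diameter: float = 200.0
    inner_diameter: float = 180.0
    wall_thickness: float = 10.0
    rod_diameters: tuple[float, ...] = (40.0, 10.0, 10.0, 10.0)
    n_teeth: int = 11
    tooth_positions: tuple[float, ...] | None = None  # degrees from anterior
    implant_config: str = "none"
    # arch layout
    arch_semi_axis_x: float = 32.0
    arch_semi_axis_y: float = 26.0
    arch_center_y: float = 28.0
    tooth_radius: float = 3.0
    tooth_half_height: float = 4.0
    # which retainer slots hold metal
    left_index: int = 8
    top_middle_indices: tuple[int, int] = (5, 6)

    def __post_init__(self):
        if abs((self.outer_diameter - self.inner_diameter) - 2 * self.wall_thickness) > 1e-9:
            raise ConfigurationError(
                "outer_diameter - inner_diameter must equal 2 * wall_thickness"
            )
        if self.implant_config not in IMPLANT_CONFIGS:
            raise ConfigurationError(
                f"implant_config must be one of {IMPLANT_CONFIGS}, "
                f"got {self.implant_config!r}"
            )
        if self.n_teeth < 1:
            raise ConfigurationError("n_teeth must be >= 1")
        if self.tooth_positions is not None and len(self.tooth_positions) != self.n_teeth:
            raise ConfigurationError("tooth_positions length must equal n_teeth")

    @property
    def angles_deg(self) -> np.ndarray:
        if self.tooth_positions is not None:
            return np.asarray(self.tooth_positions, dtype=float)
        return np.linspace(-80.0, 80.0, self.n_teeth)

    @property
    def implant_indices(self) -> tuple[int, ...]:
        if self.implant_config == "none":
            return ()
        if self.implant_config == "left_single":
            return (self.left_index,)
        return tuple(self.top_middle_indices)

    @property
    def n_implants(self) -> int:
        return len(self.implant_indices)

    @property
    def n_teeth_normal(self) -> int:
        # normal teeth + restorations always total n_teeth (11 by default)
        return self.n_teeth - self.n_implants


@dataclass
class PhantomLabelMap:
    """Voxelized phantom: integer label grid plus material table and geometry."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_table: dict[int, MaterialSpec]
    geometry: PhantomGeometry

    def __post_init__(self):
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ConfigurationError(f"labels without material entry: {missing}")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def roles(self) -> set[str]:
        return {m.name for m in self.label_table.values()}

    def material_map(self, attribute: str) -> np.ndarray:
        """Per-voxel map of one MaterialSpec attribute (e.g. ``"hu"``)."""
        out = np.empty(self.labels.shape, dtype=np.float64)
        background = getattr(default_materials()["air"], attribute)
        out.fill(background)
        for lbl, mat in self.label_table.items():
            out[self.labels == lbl] = getattr(mat, attribute)
        return out

    def hu_map(self) -> np.ndarray:
        return self.material_map("hu")

    def save(self, path, extra_meta: dict | None = None) -> None:
        """Write labels to integer NIfTI-1 plus a JSON metadata sidecar."""
        import nibabel as nib

        from .volume import _affine, _jsonable

        path = Path(path)
        img = nib.Nifti1Image(self.labels.astype(np.int16), _affine(self.spacing))
        nib.save(img, str(path))
        meta = {
            "geometry": _jsonable(self.geometry),
            "materials": {str(k): _jsonable(v) for k, v in self.label_table.items()},
        }
        if extra_meta:
            meta.update(_jsonable(extra_meta))
        path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _tooth_mask(xx, yy, zz, cx, cy, radius, half_height) -> np.ndarray:
    """Cylinder with a hemispherical occlusal cap, axis along z."""
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    body = (r2 <= radius**2) & (np.abs(zz) <= half_height)
    cap = r2 + (zz - half_height) ** 2 <= radius**2
    return body | cap


def build_phantom(
    geometry: PhantomGeometry | None = None,
    spacing: float | tuple[float, float, float] = 1.875,
    materials: dict[str, MaterialSpec] | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    fov: float = 240.0,
) -> PhantomLabelMap:
    """Voxelize the oral phantom onto a regular grid.

    The grid is centred on the sphere; the default field of view (240 mm,
    matching the acquisition protocols) determines the grid shape when none
    is given.  The construction is fully deterministic.
    """
    geometry = geometry or PhantomGeometry()
    materials = materials or default_materials()
    for role in LABELS:
        if role not in materials:
            raise ConfigurationError(f"material table is missing role {role!r}")

    spacing = tuple(float(s) for s in np.broadcast_to(spacing, (3,)))
    if any(s <= 0 for s in spacing):
        raise ConfigurationError("spacing must be positive")
    if grid_shape is None:
        grid_shape = tuple(int(round(fov / s)) for s in spacing)
    extents = [n * s for n, s in zip(grid_shape, spacing)]
    if min(extents) < geometry.outer_diameter:
        raise ConfigurationError(
            f"grid extent {extents} mm cannot contain the "
            f"{geometry.outer_diameter} mm phantom"
        )

    # voxel-centre coordinates, origin at the grid centre so that flipping
    # an axis is an exact mirror (keeps the mid-sagittal symmetry testable)
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(grid_shape, spacing)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=False)

    labels = np.zeros(grid_shape, dtype=np.int16)
    r_out = geometry.outer_diameter / 2.0
    r_in = geometry.inner_diameter / 2.0
    rr2 = xx**2 + yy**2 + zz**2
    labels[rr2 <= r_out**2] = LABELS["acrylic"]
    solution = rr2 <= r_in**2
    labels[solution] = LABELS["solution"]

    # Teflon rods: vertical columns; the large one mimics the mandible /
    # cervical vertebrae (the 1013 HU material), the small ones the spine.
    big = max(geometry.rod_diameters)
    small = [d for d in geometry.rod_diameters if d != big] or []
    rod_specs = [(big, (0.0, -40.0), "teflon_bone")]
    small_centers = [(0.0, -65.0), (-20.0, -58.0), (20.0, -58.0)]
    for d, c in zip(small, small_centers):
        rod_specs.append((d, c, "teflon_rod"))
    for d, (cx, cy), role in rod_specs:
        rod = ((xx - cx) ** 2 + (yy - cy) ** 2 <= (d / 2.0) ** 2) & solution
        labels[rod] = LABELS[role]

    # dental arch in the axial mid-plane
    ang = np.deg2rad(geometry.angles_deg)
    cxs = geometry.arch_semi_axis_x * np.sin(ang)
    cys = geometry.arch_center_y + geometry.arch_semi_axis_y * np.cos(ang)
    implant_idx = set(geometry.implant_indices)
    for i, (cx, cy) in enumerate(zip(cxs, cys)):
        tooth = _tooth_mask(
            xx, yy, zz, cx, cy, geometry.tooth_radius, geometry.tooth_half_height
        )
        tooth &= solution  # teeth sit inside the filled container
        role = "restoration_metal" if i in implant_idx else "tooth"
        labels[tooth] = LABELS[role]

    label_table = {lbl: materials[role] for role, lbl in LABELS.items() if lbl != 0}
    return PhantomLabelMap(labels, spacing, label_table, geometry)


def ground_truth_mask(phantom: PhantomLabelMap, roles) -> np.ndarray:
    """Voxelwise OR of the labels for the requested material roles.

    Idempotent and union-compatible: ``mask(A | B) == mask(A) | mask(B)``.
    """
    roles = set(roles)
    known = set(LABELS)
    unknown = roles - known
    if unknown:
        raise ConfigurationError(f"unknown material roles: {sorted(unknown)}")
    mask = np.zeros(phantom.labels.shape, dtype=bool)
    for role in roles:
        mask |= phantom.labels == LABELS[role]
    return mask


def count_components(mask: np.ndarray) -> int:
    """Number of face-connected components in a binary mask."""
    _, n = ndimage.label(mask)
    return int(n)


def tooth_voxel_counts(phantom: PhantomLabelMap) -> list[int]:
    """Voxel count of each tooth-or-restoration component."""
    mask = ground_truth_mask(phantom, {"tooth", "restoration_metal"})
    lab, n = ndimage.label(mask)
    return sorted(int((lab == i).sum()) for i in range(1, n + 1))
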