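"""CT simulation with metal streak artifacts.

Each axial slice is forward-projected to a parallel-beam sinogram, corrupted
by a concave beam-hardening transform of the line integrals and by Poisson
photon noise (photon starvation through metal), then reconstructed by
filtered back-projection and converted back to Hounsfield units.  This
reproduces the streak / dark-band morphology that dental restorations cause
on clinical scanners without energy-resolved physics: kVp and mA are carried
as metadata and only rescale the photon fluence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

from .phantom import PhantomLabelMap
from .volume import ImageVolume

__all__ = ["CtProtocol", "hu_to_mu", "mu_to_hu", "simulate_ct", "write_dicom_series"]

#: linear attenuation of water at ~70 keV effective energy, 1/mm
MU_WATER = 0.02

#: fluence at the reference 120 kVp / 190 mA protocol, photons per detector bin
REFERENCE_FLUENCE = 2.0e4
REFERENCE_KVP = 120.0
REFERENCE_MA = 190.0


@dataclass(frozen=True)
class CtProtocol:
    """Acquisition protocol; defaults follow the study scanner settings
    (120 kVp, 190 mA, 1 mm slices, 240 mm FOV, 16-slice CT)."""

    kvp: float = 120.0
    tube_current: float = 190.0
    slice_thickness: float = 1.0
    fov: float = 240.0
    matrix: int | None = None  # None -> phantom grid
    n_projections: int | None = None  # None -> ~pi/2 * matrix
    photon_fluence: float = REFERENCE_FLUENCE

    def __post_init__(self):
        if self.fov <= 0:
            raise ValueError("fov must be positive")
        if self.matrix is not None and self.matrix < 64:
            raise ValueError("matrix must be >= 64")

    def effective_fluence(self) -> float:
        """mA and kVp scale fluence linearly about the reference protocol."""
        return self.photon_fluence * (self.tube_current / REFERENCE_MA) * (
            self.kvp / REFERENCE_KVP
        )


def hu_to_mu(hu, mu_water: float = MU_WATER):
    """Hounsfield units -> linear attenuation (1/mm); water maps to
    ``mu_water`` and air (-1000 HU) to zero."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return mu_water * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0)


def mu_to_hu(mu, mu_water: float = MU_WATER):
    """Inverse of :func:`hu_to_mu`; round-trips exactly."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return 1000.0 * (np.asarray(mu, dtype=np.float64) / mu_water - 1.0)


def simulate_ct(
    phantom: PhantomLabelMap,
    protocol: CtProtocol | None = None,
    beam_hardening: float = 0.0,
    photon_fluence: float | None = None,
    seed: int = 0,
    slices: slice | None = None,
) -> ImageVolume:
    """Simulate a CT volume of the phantom, slice by slice.

    Parameters
    ----------
    beam_hardening:
        Strength ``beta`` of the water-correction-residual transform
        ``p' = p - beta * p**2`` applied to the line integrals ``p``; 0
        disables it.  Streak magnitude is a free calibration knob — the
        study never quantifies it.
    photon_fluence:
        Photons per detector bin for Poisson noise; ``None`` uses the
        protocol's (mA/kVp-scaled) fluence, ``numpy.inf`` disables noise.
        Zero detector readings are clipped to 0.25 counts before the log,
        so starved rays produce streaks rather than infinities.
    slices:
        Optional ``slice`` restricting simulation to a z-range (other
        slices are filled with the noiseless ground-truth HU); useful for
        quick experiments.

    With ``beam_hardening=0`` and ``photon_fluence=numpy.inf`` the output is
    the plain filtered-back-projection round trip of the label map's HU.
    """
    protocol = protocol or CtProtocol()
    if photon_fluence is None:
        photon_fluence = protocol.effective_fluence()
    rng = np.random.default_rng(seed)

    hu_true = phantom.hu_map()
    nx, ny, nz = hu_true.shape
    sx, sy, sz = phantom.spacing
    if abs(sx - sy) > 1e-9:
        raise ValueError("in-plane spacing must be isotropic for the Radon step")
    n_proj = protocol.n_projections or max(int(np.ceil(np.pi / 2 * nx)), nx)
    if n_proj < nx:
        raise ValueError("n_projections must be at least the matrix size")
    theta = np.linspace(0.0, 180.0, n_proj, endpoint=False)

    out = hu_true.astype(np.float64).copy()
    z_range = range(nz)[slices] if slices is not None else range(nz)
    for iz in z_range:
        mu = hu_to_mu(hu_true[:, :, iz]) * sx  # per-pixel attenuation
        sino = radon(mu, theta=theta, circle=True)
        if beam_hardening:
            sino = sino - beam_hardening * sino**2
        if np.isfinite(photon_fluence):
            counts = rng.poisson(photon_fluence * np.exp(-sino)).astype(np.float64)
            counts = np.maximum(counts, 0.25)
            sino = np.log(photon_fluence / counts)
        recon = iradon(sino, theta=theta, filter_name="ramp", circle=True)
        out[:, :, iz] = mu_to_hu(recon / sx)

    return ImageVolume(
        out,
        phantom.spacing,
        modality="CT",
        units="HU",
        acquisition=protocol,
        meta={
            "seed": seed,
            "beam_hardening": beam_hardening,
            "photon_fluence": photon_fluence,
        },
    )


def write_dicom_series(vol: ImageVolume, out_dir) -> list:
    """Export a CT volume as an axial DICOM series.

    Stored values are int16 with Rescale Slope 1 / Intercept 0, so the
    stored integers reproduce the (rounded) HU bit-exactly.
    """
    from pathlib import Path

    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    data = np.round(vol.data).astype(np.int16)
    nx, ny, nz = data.shape
    for iz in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = iz + 1
        ds.ImagePositionPatient = [0.0, 0.0, iz * vol.spacing[2]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [vol.spacing[1], vol.spacing[0]]
        ds.SliceThickness = vol.spacing[2]
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.RescaleType = "HU"
        if vol.acquisition is not None:
            ds.KVP = getattr(vol.acquisition, "kvp", None)
            ds.XRayTubeCurrent = int(getattr(vol.acquisition, "tube_current", 0))
        ds.PixelData = np.ascontiguousarray(data[:, :, iz].T).tobytes()
        path = out_dir / f"ct_{iz:04d}.dcm"
        pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
        paths.append(path)
    return paths
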