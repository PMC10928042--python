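"""4-D DWI volumes, per-voxel decays and 3-D parameter maps.

A :class:`DwiVolume` stacks one magnitude image per b-value on a shared
voxel grid (x, y, z, b).  Pre-smoothing uses an isotropic in-plane Gaussian
specified by its full width at half maximum (σ = FWHM/√(8 ln 2)); smoothing
is 2-D only because the slice thickness (2 mm) is much larger than the
in-plane voxel size (0.6 mm).  NIfTI read/write goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .protocol import AcquisitionProtocol

#: Relative floor applied to signals after smoothing, as a fraction of S(0).
SIGNAL_EPS_REL = 1e-6

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class DwiVolume:
    """4-D multi-b-value DWI stack.

    ``data`` has shape (nx, ny, nz, nb) with nb == len(protocol.b_values);
    ``voxel_size`` is (dx, dy, dz) in mm.
    """

    data: np.ndarray
    protocol: AcquisitionProtocol
    voxel_size: tuple[float, float, float] = (0.6, 0.6, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, b)")
        if self.data.shape[3] != len(self.protocol.b_values):
            raise ValueError("4th dimension must match the protocol's b table")
        if np.any(self.data < 0):
            raise ValueError("signal magnitudes must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class SignalDecay:
    """Relative decay S(b)/S(0) of one voxel over a b subset (b=0 included)."""

    b_values: np.ndarray
    s_rel: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "b_values", np.asarray(self.b_values, dtype=float))
        object.__setattr__(self, "s_rel", np.asarray(self.s_rel, dtype=float))
        if self.b_values.shape != self.s_rel.shape:
            raise ValueError("b_values and s_rel must have the same length")
        if self.b_values[0] != 0 or self.s_rel[0] != 1.0:
            raise ValueError("decay must start at b=0 with s_rel=1")
        if np.any(self.s_rel <= 0):
            raise ValueError("relative signals must be positive")


@dataclass
class ParameterMap:
    """3-D raster of one fitted parameter with a fit-success mask.

    Values outside ``fit_mask`` are NaN.  ``units`` carries the reporting
    unit (e.g. ``10^-3 mm^2/s`` for diffusivities, ``um`` for μ).
    """

    name: str
    values: np.ndarray
    fit_mask: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.fit_mask = np.asarray(self.fit_mask, dtype=bool)
        if self.values.shape != self.fit_mask.shape:
            raise ValueError("values and fit_mask shapes differ")
        self.values = np.where(self.fit_mask, self.values, np.nan)


def smooth_volume(vol: DwiVolume, fwhm: float) -> DwiVolume:
    """Gaussian pre-smoothing of every b-image, in-plane only.

    ``fwhm`` is in mm; σ in voxels is fwhm/√(8 ln 2) divided by the in-plane
    voxel size.  ``fwhm=0`` returns the input unchanged.  Boundary handling
    is 'reflect'.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return vol
    sigma_mm = fwhm * FWHM_TO_SIGMA
    sigma_vox = (sigma_mm / vol.voxel_size[0], sigma_mm / vol.voxel_size[1], 0.0, 0.0)
    smoothed = gaussian_filter(vol.data, sigma=sigma_vox, mode="reflect")
    return DwiVolume(smoothed, vol.protocol, vol.voxel_size)


def extract_decay(
    vol: DwiVolume,
    voxel_index: tuple[int, int, int],
    b_subset=None,
) -> SignalDecay | None:
    """Relative decay of one voxel over ``b_subset`` (default: all b's).

    Signals are divided by the voxel's measured S(0).  Returns None when the
    voxel is unfittable (S(0) at or below the noise floor).  Signals that
    fall at or below ``SIGNAL_EPS_REL``·S(0) are clipped up to that floor.
    """
    x, y, z = voxel_index
    if b_subset is None:
        b_subset = vol.protocol.b_values
    idx = vol.protocol.subset_indices(b_subset)
    if idx[0] != 0:
        raise ValueError("b_subset must contain b=0")
    signals = vol.data[x, y, z, idx]
    s0 = signals[0]
    if s0 <= 0:
        return None
    s_rel = np.clip(signals / s0, SIGNAL_EPS_REL, None)
    s_rel[0] = 1.0
    return SignalDecay(np.asarray(b_subset, dtype=float), s_rel)


# --- NIfTI I/O -------------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    aff = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    return aff


def save_volume(vol: DwiVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data, _affine(vol.voxel_size)), str(path))


def load_volume(path: str | Path, protocol: AcquisitionProtocol) -> DwiVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return DwiVolume(np.asarray(img.dataobj, dtype=float), protocol,
                     tuple(float(z) for z in zooms))


def save_map(pmap: ParameterMap, path: str | Path, voxel_size=(0.6, 0.6, 2.0)) -> None:
    img = nib.Nifti1Image(pmap.values, _affine(voxel_size))
    img.header["descrip"] = f"{pmap.name} [{pmap.units}]".encode()[:79]
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0
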