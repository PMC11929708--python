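"""Volume handling: NIfTI I/O, intensity windowing, coordinate transforms
and per-point intensity-patch features.

Conventions
-----------
* Voxel arrays are indexed ``(x, y, z)`` with 0-based integer indices.
* Normalized coordinates map the index lattice of each axis to ``[-1, 1]``:
  ``c = 2 i / (n - 1) - 1``.  Physical spacing (mm) is carried alongside and
  only used when distances are reported in millimetres.
* Patch features are ``5**3 = 125``-dimensional flattened neighborhoods of
  windowed intensity, x-fastest flattening order (frozen for model
  reproducibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

PATCH_SIZE = 5
PATCH_FEATURE_DIM = PATCH_SIZE ** 3

#: Default CT lung window in Hounsfield units.
DEFAULT_WINDOW = (-1000.0, 600.0)


class FormatError(ValueError):
    """Raised for malformed or unsupported image input."""


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm) and origin (mm)."""

    voxels: np.ndarray
    spacing: np.ndarray = field(
        default_factory=lambda: np.ones(3, dtype=np.float64))
    origin: np.ndarray = field(
        default_factory=lambda: np.zeros(3, dtype=np.float64))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"expected a 3D volume, got {self.voxels.ndim}D")
        if any(s < 2 for s in self.voxels.shape):
            raise FormatError("volume must have at least 2 voxels per axis")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if not np.all(self.spacing > 0):
            raise FormatError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


def load_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI image, got {data.ndim}D")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    origin = np.asarray(img.affine[:3, 3], dtype=np.float64)
    return Volume(np.asarray(data), spacing, origin)


def save_volume(vol: Volume, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.voxels), affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def normalize_intensity(vol: Volume,
                        window: tuple = DEFAULT_WINDOW) -> Volume:
    """Clip to the HU window and map it affinely onto [0, 1]."""
    low, high = float(window[0]), float(window[1])
    if not low < high:
        raise ValueError(f"degenerate intensity window {window}")
    v = np.clip(vol.voxels.astype(np.float32), low, high)
    v = (v - low) / (high - low)
    return Volume(v, vol.spacing.copy(), vol.origin.copy())


def voxel_to_norm(indices: np.ndarray, shape: tuple) -> np.ndarray:
    """Map 0-based voxel indices onto the normalized cube [-1, 1]^3."""
    idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
    shape = np.asarray(shape, dtype=np.float64)
    if np.any(idx < 0) or np.any(idx > shape - 1):
        raise ValueError("voxel index outside the volume")
    return 2.0 * idx / (shape - 1.0) - 1.0


def norm_to_voxel(coords: np.ndarray, shape: tuple) -> np.ndarray:
    """Inverse of :func:`voxel_to_norm`; rounds to the nearest lattice index."""
    c = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    shape = np.asarray(shape, dtype=np.float64)
    idx = np.rint((c + 1.0) * (shape - 1.0) / 2.0).astype(np.int64)
    return np.clip(idx, 0, (shape - 1).astype(np.int64))


def norm_to_world(coords: np.ndarray, vol: Volume) -> np.ndarray:
    """Continuous normalized coordinates -> physical mm (origin included)."""
    c = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    shape = np.asarray(vol.shape, dtype=np.float64)
    vox = (c + 1.0) * (shape - 1.0) / 2.0
    return vox * vol.spacing + vol.origin


# Patch offsets, x-fastest: flat index m = ix + 5*iy + 25*iz, i* = d* + 2.
_r = np.arange(PATCH_SIZE) - PATCH_SIZE // 2
_dz, _dy, _dx = np.meshgrid(_r, _r, _r, indexing="ij")
_OFFSETS = np.stack([_dx.ravel(), _dy.ravel(), _dz.ravel()], axis=1)


def extract_patch_features(vol: Volume, indices: np.ndarray) -> np.ndarray:
    """125-dim flattened 5x5x5 intensity patches around each voxel index.

    Out-of-bounds neighbors are filled by edge replication.  Expects a
    volume already normalized to [0, 1].
    """
    idx = np.atleast_2d(np.asarray(indices, dtype=np.int64))
    shape = np.asarray(vol.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError("voxel index outside the volume")
    pad = PATCH_SIZE // 2
    padded = np.pad(vol.voxels, pad, mode="edge")
    pos = idx[:, None, :] + pad + _OFFSETS[None, :, :]  # (n, 125, 3)
    feats = padded[pos[..., 0], pos[..., 1], pos[..., 2]]
    return feats.astype(np.float32)
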