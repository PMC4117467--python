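"""Lifting diffusion-tensor fields to orientation fields on positions x orientations.

A DTI tensor ``D(y)`` (mm^2/s, symmetric positive-definite) is converted to a
vertex-sampled spherical profile per voxel: the solid-angle Gaussian ODF

    psi_y(n) = (4 pi sqrt(det D))^-1 (n^T D^-1 n)^(-3/2),

which integrates to 1 over the sphere, multiplied by a spatial density
``mu(y)`` proportional to ``sqrt(det D(y))`` (the tensor-ellipsoid volume).
The determinants cancel, so the lifted field is simply

    U(y, n) = (4 pi)^-1 (n^T D(y)^-1 n)^(-3/2),

with any global constant irrelevant downstream (the pathway score uses U
relative to its global maximum).

Also here: the white-matter mask rule (FA/MD thresholds + dilation), the
per-voxel / global normalization schemes, squaring as a grey-value sharpening
transform, and NIfTI I/O for tensor and orientation fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .sphere import SphereTessellation, tessellate_icosphere

__all__ = [
    "TensorField",
    "OrientationField",
    "NormalizationMode",
    "tensor_to_orientation_field",
    "white_matter_mask",
    "normalize",
    "square_sharpen",
    "fractional_anisotropy",
    "mean_diffusivity",
]

# lower-triangular NIfTI tensor volume order (FSL/camino convention)
_LT_ORDER = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


@dataclass
class TensorField:
    """Voxel grid of symmetric positive-definite diffusion tensors.

    ``tensors`` has shape (X, Y, Z, 3, 3) in mm^2/s; ``affine`` maps 0-based
    voxel indices (voxel centers) to world mm; ``mask`` flags voxels where the
    tensor is valid.
    """

    tensors: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (X, Y, Z, 3, 3)")
        if self.mask.shape != self.tensors.shape[:3]:
            raise ValueError("mask shape must match the voxel grid")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        m = self.tensors[self.mask]
        if m.size:
            if not np.allclose(m, np.swapaxes(m, -1, -2), atol=1e-9):
                raise ValueError("in-mask tensors must be symmetric within 1e-9")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def eigenvalues(self) -> np.ndarray:
        """Per-voxel eigenvalues, ascending, shape (X, Y, Z, 3)."""
        return np.linalg.eigvalsh(self.tensors)

    def to_nifti(self) -> nib.Nifti1Image:
        """Lower-triangular 6-volume layout (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)."""
        data = np.stack([self.tensors[..., i, j] for i, j in _LT_ORDER], axis=-1)
        return nib.Nifti1Image(data.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, mask: np.ndarray | None = None,
                   layout: str = "lower_triangular") -> "TensorField":
        """Load tensors from NIfTI: 6-volume lower-triangular or (..., 3, 3)."""
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) else nib.load(str(img_or_path))
        data = np.asarray(img.dataobj, dtype=float)
        if layout == "lower_triangular":
            if data.ndim == 5 and data.shape[3] == 1:
                data = data[:, :, :, 0, :]
            if data.ndim != 4 or data.shape[-1] != 6:
                raise ValueError("lower-triangular layout needs a 4-D volume with 6 components")
            t = np.empty(data.shape[:3] + (3, 3))
            for k, (i, j) in enumerate(_LT_ORDER):
                t[..., i, j] = data[..., k]
                t[..., j, i] = data[..., k]
        elif layout == "matrix":
            if data.shape[-2:] != (3, 3):
                raise ValueError("matrix layout needs trailing (3, 3) axes")
            t = data
        else:
            raise ValueError(f"unknown tensor layout {layout!r}")
        if mask is None:
            mask = np.linalg.eigvalsh(t)[..., 0] > 0
        return cls(tensors=t, affine=img.affine, mask=mask)


def mean_diffusivity(T: TensorField) -> np.ndarray:
    return np.trace(T.tensors, axis1=-2, axis2=-1) / 3.0


def fractional_anisotropy(T: TensorField) -> np.ndarray:
    """Standard FA from tensor eigenvalues (0 for zero tensors)."""
    ev = T.eigenvalues()
    m = ev.mean(axis=-1, keepdims=True)
    num = np.sum((ev - m) ** 2, axis=-1)
    den = np.sum(ev**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


class NormalizationMode(str, Enum):
    """Profile normalization schemes applied before/after processing."""

    MINMAX_PER_VOXEL = "minmax_per_voxel"
    MIN_PER_VOXEL_THEN_GLOBAL_MAX = "min_per_voxel_then_global_max"
    GLOBAL_MAX_ONLY = "global_max_only"
    NONE = "none"


@dataclass
class OrientationField:
    """Function U(y, n) on the voxel grid x tessellation vertices.

    ``values`` has shape (X, Y, Z, N) with N the vertex count; non-negative.
    ``global_max`` caches the maximum entry (the score normalizer).
    """

    values: np.ndarray
    affine: np.ndarray
    tess: SphereTessellation
    global_max: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 4 or self.values.shape[3] != self.tess.n_vertices:
            raise ValueError("values must have shape (X, Y, Z, n_vertices)")
        if np.any(self.values < 0):
            raise ValueError("orientation-field values must be non-negative")
        if self.global_max is None:
            self.global_max = float(self.values.max()) if self.values.size else 0.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def copy_with(self, values: np.ndarray) -> "OrientationField":
        return OrientationField(values=values, affine=self.affine, tess=self.tess)

    def total_mass(self) -> float:
        """Voxel sum weighted by the angular quadrature."""
        return float((self.values.reshape(-1, self.tess.n_vertices) @ self.tess.weights).sum())

    def save(self, path) -> None:
        """5-D NIfTI (X, Y, Z, 1, N) plus a '<stem>.dirs.txt' vertex sidecar."""
        path = Path(path)
        img = nib.Nifti1Image(self.values[:, :, :, None, :].astype(np.float64), self.affine)
        nib.save(img, str(path))
        stem = path.name
        for suf in (".nii.gz", ".nii"):
            if stem.endswith(suf):
                stem = stem[: -len(suf)]
                break
        self.tess.save_directions(path.parent / f"{stem}.dirs.txt")

    @classmethod
    def load(cls, path, tess: SphereTessellation | None = None) -> "OrientationField":
        path = Path(path)
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 5:
            data = data[:, :, :, 0, :]
        if tess is None:
            stem = path.name
            for suf in (".nii.gz", ".nii"):
                if stem.endswith(suf):
                    stem = stem[: -len(suf)]
                    break
            dirs = np.loadtxt(path.parent / f"{stem}.dirs.txt")
            n = data.shape[-1]
            # reconstruct the tessellation from the vertex count
            order = int(round(np.sqrt((n - 2) / 10.0))) - 1
            tess = tessellate_icosphere(order)
            if not np.allclose(tess.vertices, dirs, atol=1e-8):
                raise ValueError("direction sidecar does not match an icosphere tessellation")
        return cls(values=data, affine=img.affine, tess=tess)


def tensor_to_orientation_field(T: TensorField, tess: SphereTessellation) -> OrientationField:
    """Lift a tensor field to U(y, n) = (4 pi)^-1 (n^T D(y)^-1 n)^(-3/2).

    Out-of-mask voxels are zero.  Raises if an in-mask tensor is singular or
    not positive-definite, naming the voxel.
    """
    idx = np.argwhere(T.mask)
    values = np.zeros(T.shape + (tess.n_vertices,))
    if idx.size:
        tens = T.tensors[T.mask]
        ev = np.linalg.eigvalsh(tens)
        bad = np.nonzero(ev[:, 0] <= 0)[0]
        if bad.size:
            vox = tuple(int(c) for c in idx[bad[0]])
            raise ValueError(f"tensor at voxel {vox} is not positive-definite")
        Dinv = np.linalg.inv(tens)
        # quadratic form n^T D^-1 n for all vertices at once
        q = np.einsum("vi,mij,vj->mv", tess.vertices, Dinv, tess.vertices)
        values[T.mask] = q ** (-1.5) / (4.0 * np.pi)
    return OrientationField(values=values, affine=T.affine, tess=tess)


def white_matter_mask(T: TensorField, fa_min: float = 0.25, fa_alt: float = 0.15,
                      md_max: float = 1.5e-3, dilate_voxels: int = 1) -> np.ndarray:
    """White-matter voxel mask: FA >= fa_min, or FA >= fa_alt with MD <= md_max,
    then dilated ``dilate_voxels`` times with 26-connectivity."""
    if not (0 < fa_alt < 1 and 0 < fa_min < 1):
        raise ValueError("FA thresholds must lie in (0, 1)")
    if md_max <= 0:
        raise ValueError("md_max must be positive")
    fa = fractional_anisotropy(T)
    md = mean_diffusivity(T)
    mask = (fa >= fa_min) | ((fa >= fa_alt) & (md <= md_max))
    mask &= T.mask
    if dilate_voxels > 0:
        struct = np.ones((3, 3, 3), dtype=bool)
        mask = ndimage.binary_dilation(mask, structure=struct, iterations=dilate_voxels)
    if not mask.any():
        warnings.warn("white-matter mask is empty", stacklevel=2)
    return mask


def normalize(U: OrientationField, mode: NormalizationMode | str) -> OrientationField:
    """Apply one of the profile normalization schemes (see NormalizationMode).

    ``minmax_per_voxel`` maps each voxel profile to [0, 1] (constant profiles
    become all-zero); ``min_per_voxel_then_global_max`` subtracts the per-voxel
    minimum then divides by the global maximum of the min-subtracted data;
    ``global_max_only`` divides by the global maximum; ``none`` is the identity.
    """
    mode = NormalizationMode(mode)
    v = U.values
    if mode is NormalizationMode.NONE:
        return U.copy_with(v.copy())
    if mode is NormalizationMode.GLOBAL_MAX_ONLY:
        g = v.max()
        return U.copy_with(v / g if g > 0 else v.copy())
    vmin = v.min(axis=-1, keepdims=True)
    shifted = v - vmin
    if mode is NormalizationMode.MINMAX_PER_VOXEL:
        rng = shifted.max(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(rng > 0, shifted / np.where(rng > 0, rng, 1.0), 0.0)
        return U.copy_with(out)
    # MIN_PER_VOXEL_THEN_GLOBAL_MAX
    g = shifted.max()
    return U.copy_with(shifted / g if g > 0 else shifted)


def square_sharpen(U: OrientationField) -> OrientationField:
    """Grey-value sharpening by squaring every value (peaks grow relative to
    the bulk; dominant global maxima are amplified, which is why erosion is
    the more controlled alternative)."""
    return U.copy_with(U.values**2)
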