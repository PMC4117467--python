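"""Streamline I/O and lifting of pathways to position-orientation space.

Candidate pathways (polylines in world mm, e.g. probabilistic-tractography
output) are fit with a cubic spline, resampled at equal arclength, and lifted:
each sample carries the unit tangent (the orientation of the curve at that
point) and the Frenet–Serret curvature kappa = |x' x x''| / |x'|^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline

__all__ = [
    "Pathway",
    "LiftedPathway",
    "read_streamlines",
    "write_streamlines",
    "lift_pathway",
]

_MIN_SEG = 1e-9  # mm; consecutive duplicate points below this are merged


@dataclass
class Pathway:
    """Ordered 3-D world coordinates (mm) of one candidate pathway."""

    points: np.ndarray
    id: int = 0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("a pathway needs at least two 3-D points")
        # drop consecutive duplicates
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        keep = np.concatenate([[True], seg > _MIN_SEG])
        pts = pts[keep]
        if pts.shape[0] < 2:
            raise ValueError("pathway degenerates to a single point after cleaning")
        self.points = pts


@dataclass
class LiftedPathway:
    """Arclength-resampled pathway with tangents and curvature.

    points (M, 3) mm; tangents (M, 3) unit vectors; curvature (M,) 1/mm;
    arclength (M,) cumulative s in mm; length = arclength[-1].
    """

    points: np.ndarray
    tangents: np.ndarray
    curvature: np.ndarray
    arclength: np.ndarray
    id: int = 0

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]


def read_streamlines(path) -> list[Pathway]:
    """Read a TRK or TCK file; coordinates returned in world mm (RAS).

    Streamlines with fewer than two distinct points are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as e:  # malformed header/body
        raise ValueError(f"could not parse streamline file {path}: {e}") from e
    out: list[Pathway] = []
    dropped = 0
    for i, s in enumerate(tfile.tractogram.streamlines):
        try:
            out.append(Pathway(points=np.asarray(s, dtype=float), id=i))
        except ValueError:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} degenerate streamline(s) from {path.name}",
                      stacklevel=2)
    if not out:
        warnings.warn(f"{path.name} contains no usable streamlines", stacklevel=2)
    return out


def write_streamlines(paths: list[Pathway], out_path, affine: np.ndarray | None = None,
                      shape: tuple[int, int, int] | None = None) -> None:
    """Write pathways (world mm) as TRK or TCK, chosen by the file extension.

    TRK needs a voxel grid reference; pass the field's ``affine`` and ``shape``
    (identity / unit grid is used otherwise).
    """
    out_path = Path(out_path)
    streams = [p.points.astype(np.float32) for p in paths]
    tractogram = nib.streamlines.Tractogram(streams, affine_to_rasmm=np.eye(4))
    suffix = out_path.suffix.lower()
    if suffix == ".trk":
        header = {}
        if affine is not None:
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = np.asarray(affine, dtype=np.float32)
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = tuple(
                np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
            )
        if shape is not None:
            header[nib.streamlines.trk.Field.DIMENSIONS] = tuple(int(s) for s in shape)
        nib.streamlines.save(tractogram, str(out_path), header=header)
    elif suffix == ".tck":
        nib.streamlines.save(tractogram, str(out_path))
    else:
        raise ValueError(f"unsupported streamline format {suffix!r} (use .trk or .tck)")


def _spline(points: np.ndarray):
    """Cubic spline through the points on a chord-length parameter; curves
    with fewer than four points fall back to a lower spline order."""
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    if points.shape[0] >= 4:
        return CubicSpline(chord, points, bc_type="natural"), chord[-1]
    k = points.shape[0] - 1  # 1 or 2
    return make_interp_spline(chord, points, k=k), chord[-1]


def lift_pathway(p: Pathway, step: float = 1.0) -> LiftedPathway:
    """Lift a pathway: spline fit, equal-arclength resampling, unit tangents,
    Frenet–Serret curvature.

    ``step`` is the target arclength spacing in mm (the actual spacing is
    L / (M - 1) with M chosen so it is ~step).  Endpoint curvatures are copied
    from the nearest interior sample.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    spl, t_max = _spline(p.points)
    if t_max <= _MIN_SEG:
        raise ValueError(f"pathway {p.id} is degenerate")

    # arclength along the spline on a fine grid, then invert
    n_fine = max(4 * p.points.shape[0], int(np.ceil(t_max / (0.1 * step))) + 1, 32)
    t_fine = np.linspace(0.0, t_max, n_fine)
    d_fine = spl(t_fine, 1)
    speed = np.linalg.norm(d_fine, axis=1)
    s_fine = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2.0 * np.diff(t_fine))])
    L = s_fine[-1]
    m = max(2, int(round(L / step)) + 1)
    s_target = np.linspace(0.0, L, m)
    t_target = np.interp(s_target, s_fine, t_fine)

    pts = spl(t_target)
    d1 = spl(t_target, 1)
    d2 = spl(t_target, 2)
    speed_t = np.linalg.norm(d1, axis=1)
    tangents = d1 / speed_t[:, None]
    cross = np.cross(d1, d2)
    curvature = np.linalg.norm(cross, axis=1) / speed_t**3
    if m > 2:
        curvature[0] = curvature[1]
        curvature[-1] = curvature[-2]
    arclength = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    return LiftedPathway(points=pts, tangents=tangents, curvature=curvature,
                         arclength=arclength, id=p.id)
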