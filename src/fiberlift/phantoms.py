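"""Synthetic DTI phantoms and labeled candidate pathways.

The phantom emulates the geometry that makes optic-radiation tractography
hard: a high-anisotropy bundle following a C-shaped centerline with a sharp
(Meyer's-loop-like) turn, an optional second straight bundle crossing the
first (tensor averaging in the overlap produces planar, reduced-FA tensors),
isotropic background, and multiplicative log-normal noise on the tensor
eigenvalues.

Candidate pathways stand in for probabilistic-tracking output: plausible ones
stay inside the bundle tube; implausible ones come in three seeded families —
chords short-cutting the bend, wanderers drifting into background, and tracts
switching onto the crossing bundle — each verified to leave the tube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .odf import TensorField
from .tracts import Pathway

__all__ = ["PhantomSpec", "make_phantom", "simulate_candidate_tracts"]


@dataclass
class PhantomSpec:
    """Geometry and noise of the synthetic phantom.

    Defaults: 24 x 24 x 12 grid of 2 mm isotropic voxels (clinical DTI
    resolution), 4 mm bundle radius, 6 mm turn radius, bundle FA 0.8 at a
    physiological trace of 2.1e-3 mm^2/s, crossing bundle on, eigenvalue noise
    sigma 0.15.
    """

    shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size: float = 2.0
    bundle_radius: float = 4.0
    turn_radius: float = 6.0
    fa_bundle: float = 0.8
    trace: float = 2.1e-3
    background_md: float = 0.7e-3
    crossing: bool = True
    noise_sigma: float = 0.15
    seed: int = 42

    def __post_init__(self):
        if min(self.shape) < 4:
            raise ValueError("grid too small")
        if not (0.0 < self.fa_bundle < 1.0):
            raise ValueError("fa_bundle must lie in (0, 1)")
        for name in ("voxel_size", "bundle_radius", "turn_radius", "trace"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size] * 3 + [1.0])
        return a


def prolate_eigenvalues(fa: float, trace: float) -> tuple[float, float]:
    """(lambda1, lambda23) of an axially symmetric tensor with the given FA
    and trace; FA = (x - 1)/sqrt(x^2 + 2) for the ratio x = l1/l23."""
    x = (1.0 + fa * np.sqrt(3.0 - 2.0 * fa**2)) / (1.0 - fa**2)
    lam23 = trace / (x + 2.0)
    return x * lam23, lam23


def _centerline_points(spec: PhantomSpec, step: float = 0.25) -> tuple[np.ndarray, dict]:
    """C-shaped centerline in world mm: straight leg, half-turn arc of
    ``turn_radius``, straight return leg.  Returns points and geometry info."""
    ext = np.array(spec.shape) * spec.voxel_size
    z = ext[2] / 2.0
    R = spec.turn_radius
    margin = spec.bundle_radius + 2.0
    x_in = ext[0] / 2.0 - R
    x_out = ext[0] / 2.0 + R
    y0 = margin
    y1 = ext[1] - margin - R
    pts = []
    for y in np.arange(y0, y1, step):
        pts.append([x_in, y, z])
    center = np.array([ext[0] / 2.0, y1, z])
    for th in np.arange(np.pi, 0.0, -step / R):
        pts.append([center[0] + R * np.cos(th), center[1] + R * np.sin(th), z])
    for y in np.arange(y1, y0, -step):
        pts.append([x_out, y, z])
    pts = np.asarray(pts)
    info = {
        "x_in": x_in, "x_out": x_out, "y0": y0, "y1": y1, "z": z,
        "arc_center": center, "extent": ext,
        # the crossing bundle runs along x halfway up the legs
        "cross_y": (y0 + y1) / 2.0,
    }
    return pts, info


def _min_dist_to_polyline(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to a polyline (segment-wise, vectorized)."""
    a = poly[:-1]
    ab = poly[1:] - a  # (S, 3)
    ab2 = np.einsum("sj,sj->s", ab, ab)
    # (P, S, 3) differences
    ap = pts[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("psj,sj->ps", ap, ab) / ab2[None, :], 0.0, 1.0)
    closest = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(pts[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def make_phantom(spec: PhantomSpec) -> tuple[TensorField, Pathway, np.ndarray]:
    """Build the phantom tensor field.

    Returns (tensor field, centerline pathway, bundle-voxel mask).  Bundle
    voxels get a prolate tensor whose principal axis follows the local
    centerline tangent; crossing-region voxels get the average of the two
    bundle tensors (planar shape); background is isotropic; seeded log-normal
    noise multiplies the eigenvalues.
    """
    cline, info = _centerline_points(spec)
    ext = info["extent"]
    if (cline.min() < 0).any() or np.any(cline.max(axis=0) > ext):
        raise ValueError("bundle leaves the grid; enlarge the phantom shape")

    shape = spec.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spec.voxel_size
    lam1, lam23 = prolate_eigenvalues(spec.fa_bundle, spec.trace)

    def prolate(axis: np.ndarray) -> np.ndarray:
        axis = axis / np.linalg.norm(axis)
        return lam23 * np.eye(3) + (lam1 - lam23) * np.outer(axis, axis)

    # distance to centerline and local tangent for every voxel center
    d = _min_dist_to_polyline(centers, cline)
    in_main = d <= spec.bundle_radius
    seg_dir = np.diff(cline, axis=0)
    # tangent of the closest segment
    a = cline[:-1]
    ab = seg_dir
    ab2 = np.einsum("sj,sj->s", ab, ab)
    ap = centers[:, None, :] - a[None]
    t = np.clip(np.einsum("psj,sj->ps", ap, ab) / ab2[None], 0.0, 1.0)
    closest = a[None] + t[..., None] * ab[None]
    seg_idx = np.argmin(np.linalg.norm(centers[:, None, :] - closest, axis=2), axis=1)

    tensors = np.empty(shape + (3, 3))
    iso = (spec.background_md) * np.eye(3)
    tensors[...] = iso
    mask_main = in_main.reshape(shape)

    flat = tensors.reshape(-1, 3, 3)
    for v in np.nonzero(in_main)[0]:
        flat[v] = prolate(seg_dir[seg_idx[v]])

    bundle_mask = mask_main.copy()
    if spec.crossing:
        cross_axis = np.array([1.0, 0.0, 0.0])
        line = np.array([[0.0, info["cross_y"], info["z"]], [ext[0], info["cross_y"], info["z"]]])
        d_cross = _min_dist_to_polyline(centers, line)
        in_cross = d_cross <= spec.bundle_radius
        cross_tensor = prolate(cross_axis)
        both = in_cross & in_main
        only = in_cross & ~in_main
        flat[only] = cross_tensor
        # interdigitated overlap: eigenvalue-average of the two bundles
        for v in np.nonzero(both)[0]:
            flat[v] = 0.5 * (flat[v] + cross_tensor)
        bundle_mask |= in_cross.reshape(shape)

    if spec.noise_sigma > 0:
        # noise on the tensor eigen-parameters: multiplicative log-normal on the
        # eigenvalues, plus a random small rotation of the eigenvectors (angle
        # ~ noise_sigma rad), emulating the per-voxel principal-direction
        # uncertainty of clinical DTI
        rng = np.random.default_rng(spec.seed)
        evals, evecs = np.linalg.eigh(tensors.reshape(-1, 3, 3))
        noise = np.exp(spec.noise_sigma * rng.standard_normal(evals.shape))
        evals = evals * noise
        axes = rng.standard_normal((evals.shape[0], 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = spec.noise_sigma * rng.standard_normal(evals.shape[0])
        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec(axes * angles[:, None]).as_matrix()
        evecs = np.einsum("vij,vjk->vik", R, evecs)
        tensors = np.einsum("vij,vj,vkj->vik", evecs, evals, evecs).reshape(shape + (3, 3))

    T = TensorField(tensors=tensors, affine=spec.affine, mask=np.ones(shape, dtype=bool))
    centerline = Pathway(points=cline[:: max(1, len(cline) // 200)], id=-1)
    return T, centerline, bundle_mask


def _smooth_bump(n: int, rng: np.random.Generator, n_modes: int = 3) -> np.ndarray:
    """Random smooth profile on [0, 1] vanishing at both ends."""
    s = np.linspace(0.0, 1.0, n)
    out = np.zeros(n)
    for k in range(1, n_modes + 1):
        out += rng.normal() / k * np.sin(np.pi * k * s)
    return out


def simulate_candidate_tracts(
    spec: PhantomSpec, centerline: Pathway, n_plausible: int, n_implausible: int,
    jitter_mm: float = 1.5, seed: int = 0,
) -> tuple[list[Pathway], np.ndarray]:
    """Labeled candidate pathways emulating probabilistic-tracking output.

    Plausible: centerline plus smooth seeded perturbations verified to stay
    inside the bundle tube.  Implausible (40% / 30% / 30%): chords cutting the
    bend, wanderers into background, and switches onto the crossing bundle —
    each verified to leave the tube at >= 1 sample.  Fully reproducible for a
    fixed seed.
    """
    if n_plausible < 1 or n_implausible < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    cline = centerline.points
    _, info = _centerline_points(spec)
    n_pts = 60
    s_idx = np.linspace(0, len(cline) - 1, n_pts)
    base = np.stack([np.interp(s_idx, np.arange(len(cline)), cline[:, c]) for c in range(3)], axis=1)
    tube_tol = 0.25  # mm slack on tube membership checks

    def perturbed_inside() -> np.ndarray:
        for _ in range(100):
            p = base.copy()
            for c in range(3):
                p[:, c] += jitter_mm * _smooth_bump(n_pts, rng)
            if _min_dist_to_polyline(p, cline).max() <= spec.bundle_radius - tube_tol:
                return p
        raise RuntimeError("could not generate an in-tube pathway in 100 attempts")

    def verified_outside(p: np.ndarray) -> np.ndarray:
        if _min_dist_to_polyline(p, cline).max() > spec.bundle_radius + tube_tol:
            return p
        raise RuntimeError("implausible pathway failed to leave the tube")

    def shortcut() -> np.ndarray:
        # cut the chord across the bend between the two legs
        y_cut = info["y1"] - rng.uniform(0.0, 4.0)
        k_in = np.searchsorted(base[:, 1], y_cut) if base[0, 0] == info["x_in"] else None
        going_up = base[:, 0] < info["extent"][0] / 2.0
        i_last_in = np.nonzero(going_up & (base[:, 1] <= y_cut))[0].max()
        i_first_out = np.nonzero(~going_up & (base[:, 1] <= y_cut))[0].min()
        a, b = base[i_last_in], base[i_first_out]
        n_chord = max(4, int(np.linalg.norm(b - a) / 1.0))
        chord = np.linspace(a, b, n_chord)[1:-1]
        p = np.vstack([base[: i_last_in + 1], chord, base[i_first_out:]])
        p = p + rng.normal(0, 0.2, p.shape)
        return verified_outside(p)

    def wanderer() -> np.ndarray:
        # drifts clearly out of the tube into isotropic background
        p = base.copy()
        amp = spec.bundle_radius + rng.uniform(2.5, 6.0)
        direction = rng.normal(size=3)
        direction[2] *= 0.3  # keep roughly in-slab
        direction /= np.linalg.norm(direction)
        bump = np.abs(_smooth_bump(n_pts, rng, n_modes=2))
        bump /= max(bump.max(), 1e-9)
        p += amp * bump[:, None] * direction[None, :]
        return verified_outside(p)

    def cross_switch() -> np.ndarray:
        # follow the entry leg, then turn onto the crossing bundle line
        y_sw = info["cross_y"]
        going_up = base[:, 0] < info["extent"][0] / 2.0
        i_sw = np.nonzero(going_up & (base[:, 1] >= y_sw))[0].min()
        start = base[: i_sw + 1]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        x_end = info["extent"][0] - 4.0 if sign > 0 else 4.0
        n_tail = max(6, int(abs(x_end - start[-1, 0]) / 2.0))
        tail = np.linspace(
            start[-1] + np.array([sign * 2.0, 1.0, 0.0]),
            [x_end, y_sw, info["z"]],
            n_tail,
        )
        p = np.vstack([start, tail]) + rng.normal(0, 0.2, (len(start) + n_tail, 3))
        return verified_outside(p)

    paths: list[Pathway] = []
    labels = []
    for i in range(n_plausible):
        paths.append(Pathway(points=perturbed_inside(), id=i))
        labels.append(True)
    n_short = int(round(0.4 * n_implausible))
    n_wander = int(round(0.3 * n_implausible))
    n_switch = n_implausible - n_short - n_wander
    gens = [shortcut] * n_short + [wanderer] * n_wander + [cross_switch] * n_switch
    for j, gen in enumerate(gens):
        for attempt in range(100):
            try:
                p = gen()
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError("could not generate a valid implausible pathway in 100 attempts")
        paths.append(Pathway(points=p, id=n_plausible + j))
        labels.append(False)
    return paths, np.asarray(labels, dtype=bool)
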