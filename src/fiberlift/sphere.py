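"""Discrete orientation sphere: geodesic icosphere tessellation and angular operators.

Orientation profiles are vertex-sampled spherical functions.  The tessellation
at order ``k`` is the geodesic subdivision of the regular icosahedron at edge
frequency ``k + 1``, giving ``10*(k+1)**2 + 2`` unit vectors; order 2 yields the
92-direction set conventionally used for discretizing diffusion ODFs.

Angular differentiation is mesh-based: a cotangent-weighted Laplacian (lumped
with the per-vertex solid-angle quadrature) approximates the Laplace–Beltrami
operator, and per-vertex tangent-plane least-squares fits give the tangential
gradient used by the erosion evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SphereTessellation",
    "AngularOperators",
    "tessellate_icosphere",
    "quadrature_weights",
    "nearest_direction",
    "build_angular_operators",
]

_DEDUP_TOL = 1e-10


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Vertices (12,3) and triangles (20,3) of the unit regular icosahedron."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    tris = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, tris


@dataclass
class SphereTessellation:
    """Geodesic icosphere: unit-vector vertices, triangles, quadrature, adjacency.

    Attributes
    ----------
    order : int
        Subdivision order; vertex count is ``10*(order+1)**2 + 2``.
    vertices : (N, 3) float array of unit vectors.
    triangles : (M, 3) int array of vertex index triples.
    weights : (N,) float array
        Per-vertex solid angle (steradians); sums to 4*pi.
    adjacency : list of int arrays, one-ring neighbor indices per vertex.
    antipode : (N,) int array, index of the antipodal vertex.
    """

    order: int
    vertices: np.ndarray
    triangles: np.ndarray
    weights: np.ndarray = field(repr=False)
    adjacency: list = field(repr=False)
    antipode: np.ndarray = field(repr=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def mean_edge_angle(self) -> float:
        """Mean geodesic angle (rad) between adjacent vertices."""
        i = self.triangles[:, [0, 1, 2]].ravel()
        j = self.triangles[:, [1, 2, 0]].ravel()
        d = np.einsum("ij,ij->i", self.vertices[i], self.vertices[j])
        return float(np.mean(np.arccos(np.clip(d, -1.0, 1.0))))

    def save_directions(self, path) -> None:
        """Write one 'x y z' unit vector per line (plain-text sidecar)."""
        np.savetxt(path, self.vertices, fmt="%.17g")


def _subdivide(verts: np.ndarray, tris: np.ndarray, freq: int) -> tuple[np.ndarray, np.ndarray]:
    """Subdivide each triangle at edge frequency ``freq`` on the barycentric
    lattice, project to the sphere, and deduplicate shared vertices."""
    new_verts: list[np.ndarray] = []
    new_tris: list[list[int]] = []
    lookup: dict[tuple, int] = {}

    def vid(p: np.ndarray) -> int:
        p = p / np.linalg.norm(p)
        key = tuple(np.round(p / _DEDUP_TOL).astype(np.int64))
        idx = lookup.get(key)
        if idx is None:
            idx = len(new_verts)
            lookup[key] = idx
            new_verts.append(p)
        return idx

    for a, b, c in tris:
        va, vb, vc = verts[a], verts[b], verts[c]
        # lattice[i][j] indexes point (i rows down from apex, j along the row)
        lattice = [
            [vid(((freq - i) * va + (i - j) * vb + j * vc) / freq) for j in range(i + 1)]
            for i in range(freq + 1)
        ]
        for i in range(freq):
            for j in range(i + 1):
                new_tris.append([lattice[i][j], lattice[i + 1][j], lattice[i + 1][j + 1]])
                if j < i:
                    new_tris.append([lattice[i][j], lattice[i + 1][j + 1], lattice[i][j + 1]])
    return np.asarray(new_verts), np.asarray(new_tris, dtype=np.int64)


def _spherical_triangle_area(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized spherical excess via l'Huilier's theorem. Inputs (M, 3)."""

    def ang(u, v):
        return np.arccos(np.clip(np.einsum("ij,ij->i", u, v), -1.0, 1.0))

    al, bl, cl = ang(b, c), ang(a, c), ang(a, b)
    s = 0.5 * (al + bl + cl)
    t = (
        np.tan(s / 2) * np.tan((s - al) / 2) * np.tan((s - bl) / 2) * np.tan((s - cl) / 2)
    )
    return 4.0 * np.arctan(np.sqrt(np.maximum(t, 0.0)))


def quadrature_weights(tess: SphereTessellation) -> np.ndarray:
    """Per-vertex solid-angle weights: one third of incident triangle areas.

    The triangle areas partition the sphere, so the weights sum to ``4*pi``.
    """
    v, t = tess.vertices, tess.triangles
    areas = _spherical_triangle_area(v[t[:, 0]], v[t[:, 1]], v[t[:, 2]])
    if np.any(areas <= 0):
        raise RuntimeError("degenerate (zero-area) triangle in tessellation")
    w = np.zeros(len(v))
    np.add.at(w, t.ravel(), np.repeat(areas / 3.0, 3))
    return w


def tessellate_icosphere(order: int) -> SphereTessellation:
    """Build the geodesic icosphere of the given order.

    Order ``k`` subdivides each icosahedral edge into ``k + 1`` segments
    (edge frequency ``k + 1``), yielding ``10*(k+1)**2 + 2`` vertices:
    12 at order 0, 42 at order 1, 92 at order 2.
    """
    if not isinstance(order, (int, np.integer)) or order < 0:
        raise ValueError(f"order must be a non-negative integer, got {order!r}")
    verts, tris = _icosahedron()
    if order > 0:
        verts, tris = _subdivide(verts, tris, order + 1)

    n = len(verts)
    expected = 10 * (order + 1) ** 2 + 2
    if n != expected:  # pragma: no cover - construction sanity
        raise RuntimeError(f"tessellation produced {n} vertices, expected {expected}")

    adjacency: list[set] = [set() for _ in range(n)]
    for a, b, c in tris:
        adjacency[a].update((b, c))
        adjacency[b].update((a, c))
        adjacency[c].update((a, b))
    adj = [np.array(sorted(s), dtype=np.int64) for s in adjacency]

    # The icosahedron and its geodesic subdivisions are centrally symmetric,
    # so the nearest vertex to -v is the exact antipode.
    dots = verts @ verts.T
    antipode = np.argmin(dots, axis=1).astype(np.int64)

    tess = SphereTessellation(
        order=int(order), vertices=verts, triangles=tris,
        weights=np.empty(n), adjacency=adj, antipode=antipode,
    )
    tess.weights = quadrature_weights(tess)
    return tess


def nearest_direction(tess: SphereTessellation, v: np.ndarray, antipodal: bool = False) -> int:
    """Index of the tessellation vertex nearest to direction ``v``.

    With ``antipodal=True`` the sign of ``v`` is ignored (argmax of ``|v.n|``),
    appropriate for symmetric (tensor-derived) profiles.  Ties break toward
    the lowest index (``argmax`` convention).
    """
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        raise ValueError("cannot look up the nearest direction of a zero vector")
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError(f"direction must be unit-norm (got norm {nrm:.3g})")
    d = tess.vertices @ v
    if antipodal:
        d = np.abs(d)
    return int(np.argmax(d))


def nearest_directions(tess: SphereTessellation, vs: np.ndarray, antipodal: bool = False) -> np.ndarray:
    """Vectorized :func:`nearest_direction` for an (M, 3) array of unit vectors."""
    d = np.asarray(vs, dtype=float) @ tess.vertices.T
    if antipodal:
        d = np.abs(d)
    return np.argmax(d, axis=1)


def barycentric_weights(tess: SphereTessellation, vs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-mesh interpolation weights for directions ``vs`` (M, 3).

    Returns ``(indices, weights)`` of shape (M, 3): for each direction the
    vertices of the containing spherical triangle and convex weights summing
    to 1 (gnomonic/central-projection barycentric coordinates).
    """
    vs = np.asarray(vs, dtype=float)
    tri = tess.triangles
    # coefficients c solving  M_t c = v  for every triangle (central projection)
    M = tess.vertices[tri]  # (T, 3 verts, 3 xyz)
    Minv = np.linalg.inv(np.swapaxes(M, 1, 2))  # (T, 3, 3) mapping xyz -> coeffs
    c = np.einsum("tij,mj->mti", Minv, vs)  # (M, T, 3)
    # containing triangle: all coefficients non-negative (choose max of min-coeff)
    t_best = np.argmax(c.min(axis=2), axis=1)
    cm = c[np.arange(len(vs)), t_best]
    cm = np.maximum(cm, 0.0)
    cm /= cm.sum(axis=1, keepdims=True)
    return tri[t_best], cm


@dataclass
class AngularOperators:
    """Discrete angular differential operators on a tessellation.

    ``laplacian`` is the lumped cotangent Laplace–Beltrami matrix (N x N,
    sparse, rows sum to zero, symmetric under the quadrature inner product).
    ``grad_e1``/``grad_e2`` give the two tangent-frame components of the
    tangential gradient (least-squares one-ring fit); ``gradient_sq`` applied
    to per-vertex values returns the squared tangential gradient magnitude.
    """

    tess: SphereTessellation
    laplacian: sp.csr_matrix
    grad_e1: sp.csr_matrix
    grad_e2: sp.csr_matrix

    def gradient_sq(self, values: np.ndarray) -> np.ndarray:
        """Squared tangential gradient of per-vertex values (last axis = vertex)."""
        g1 = values @ self.grad_e1.T
        g2 = values @ self.grad_e2.T
        return g1 * g1 + g2 * g2

    def apply_laplacian(self, values: np.ndarray) -> np.ndarray:
        return values @ self.laplacian.T


def _tangent_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Any orthonormal pair spanning the plane perpendicular to unit vector n."""
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def build_angular_operators(tess: SphereTessellation) -> AngularOperators:
    """Construct the mesh Laplacian and tangential-gradient operators.

    The Laplacian uses cotangent edge weights divided by the per-vertex
    solid-angle (lumped mass), approximating the Laplace–Beltrami operator;
    applied to a degree-l spherical harmonic it returns ~ -l(l+1) times it.
    """
    v, t = tess.vertices, tess.triangles
    n = len(v)

    # cotangent weights: for each triangle corner, the opposite edge gets cot(angle)/2
    rows, cols, vals = [], [], []
    for k in range(3):
        a = t[:, k]
        b = t[:, (k + 1) % 3]
        c = t[:, (k + 2) % 3]
        u = v[b] - v[a]
        w = v[c] - v[a]
        cos = np.einsum("ij,ij->i", u, w)
        sin = np.linalg.norm(np.cross(u, w), axis=1)
        cot = cos / np.maximum(sin, 1e-300)
        rows.extend([b, c])
        cols.extend([c, b])
        vals.extend([cot / 2.0, cot / 2.0])
    W = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    L = W - sp.diags(np.asarray(W.sum(axis=1)).ravel())
    lap = sp.diags(1.0 / tess.weights) @ L

    # tangential gradient: least-squares linear fit over each one-ring,
    # displacements projected into the local tangent plane
    g1_rows, g1_cols, g1_vals = [], [], []
    g2_rows, g2_cols, g2_vals = [], [], []
    for i in range(n):
        nbrs = tess.adjacency[i]
        e1, e2 = _tangent_basis(v[i])
        d = v[nbrs] - v[i]
        X = np.column_stack([d @ e1, d @ e2])  # (k, 2)
        # gradient g solves min ||X g - (f_nbr - f_i)||; g = pinv(X) (f_nbr - f_i)
        P = np.linalg.pinv(X)  # (2, k)
        for comp, (r_, c_, v_) in zip(
            (0, 1), ((g1_rows, g1_cols, g1_vals), (g2_rows, g2_cols, g2_vals))
        ):
            coeff = P[comp]
            r_.extend([i] * (len(nbrs) + 1))
            c_.extend(list(nbrs) + [i])
            v_.extend(list(coeff) + [-float(coeff.sum())])
    G1 = sp.coo_matrix((g1_vals, (g1_rows, g1_cols)), shape=(n, n)).tocsr()
    G2 = sp.coo_matrix((g2_vals, (g2_rows, g2_cols)), shape=(n, n)).tocsr()
    return AngularOperators(tess=tess, laplacian=lap.tocsr(), grad_e1=G1, grad_e2=G2)
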