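"""Pathway plausibility scoring against a processed orientation field.

Each lifted pathway gets

    total = external - lam * internal,

    external = (1/L) * sum_i log( max(u_i / U_max, floor) ) * ds,
    internal = sum_i (kappa_i^2 + eps) * ds,           ds = L / N,

where ``u_i`` is the field sampled at interior point i (trilinear in space,
nearest tessellation vertex to the tangent, sign-insensitive), ``U_max`` the
global maximum of the field, ``kappa_i`` the Frenet–Serret curvature and L the
pathway length.  The 1/L on the data term averages the log-support so long
pathways are not preferred per se; the internal term penalizes curvature and
(through eps > 0) length.  The first and last samples are excluded (pathway
endpoints typically sit in grey matter).

Evaluation: the *critical threshold* is the lowest score cut at which no
implausible pathway survives (specificity 1); the retained fraction of
plausible pathways is the sensitivity.  A method whose top-scoring pathway is
implausible has sensitivity 0 and is flagged inadequate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .odf import OrientationField
from .sphere import nearest_directions
from .tracts import LiftedPathway

__all__ = [
    "ScoringParams",
    "ScoreResult",
    "EvaluationReport",
    "sample_field_along",
    "score_pathway",
    "score_pathways",
    "critical_threshold",
    "anterior_extent_metrics",
]


@dataclass
class ScoringParams:
    """lam: internal-energy weight (0 = data term only); eps: length
    penalty in the internal term (typical 0.01-0.1); floor: lower clip on
    u/U_max before the log (keeps scores finite off the data)."""

    lam: float = 0.0
    eps: float = 0.05
    floor: float = 1e-6

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if not (0.0 < self.floor < 1.0):
            raise ValueError("floor must lie in (0, 1)")


@dataclass
class ScoreResult:
    pathway_id: int
    external: float
    internal: float
    lam: float
    n_samples: int

    @property
    def total(self) -> float:
        return self.external - self.lam * self.internal


@dataclass
class EvaluationReport:
    threshold: float
    sensitivity: float
    specificity: float
    n_true_positive: int
    n_false_positive: int
    n_false_negative: int
    inadequate: bool = False

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_true_positive": self.n_true_positive,
            "n_false_positive": self.n_false_positive,
            "n_false_negative": self.n_false_negative,
            "inadequate": self.inadequate,
        }


def _world_to_voxel(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def _trilinear(values: np.ndarray, vox: np.ndarray, vert_idx: np.ndarray) -> np.ndarray:
    """Trilinear sample of values[..., vert_idx[i]] at voxel coords vox[i];
    out-of-grid corners contribute zero."""
    shape = np.array(values.shape[:3])
    lo = np.floor(vox).astype(int)
    frac = vox - lo
    out = np.zeros(len(vox))
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                corner = lo + np.array([cx, cy, cz])
                w = (
                    (frac[:, 0] if cx else 1 - frac[:, 0])
                    * (frac[:, 1] if cy else 1 - frac[:, 1])
                    * (frac[:, 2] if cz else 1 - frac[:, 2])
                )
                inside = np.all((corner >= 0) & (corner < shape), axis=1)
                if inside.any():
                    c = corner[inside]
                    out[inside] += w[inside] * values[c[:, 0], c[:, 1], c[:, 2], vert_idx[inside]]
    return out


def sample_field_along(U: OrientationField, lp: LiftedPathway) -> np.ndarray:
    """Field values at the interior samples of a lifted pathway.

    Spatial lookup is trilinear over the 8 surrounding voxels; angular lookup
    picks the tessellation vertex nearest the tangent (antipodally symmetric).
    Samples outside the grid contribute 0 (with a warning); a pathway entirely
    outside the field is an error.
    """
    if lp.n_samples < 3:
        raise ValueError("lifted pathway has no interior samples")
    pts = lp.points[1:-1]
    tans = lp.tangents[1:-1]
    vox = _world_to_voxel(U.affine, pts)
    shape = np.array(U.shape)
    inside = np.all((vox >= -0.5) & (vox <= shape - 0.5), axis=1)
    if not inside.any():
        raise ValueError(f"pathway {lp.id} lies entirely outside the field")
    if not inside.all():
        warnings.warn(
            f"pathway {lp.id}: {np.count_nonzero(~inside)} sample(s) outside the field "
            "contribute zero", stacklevel=2,
        )
    vert_idx = nearest_directions(U.tess, tans, antipodal=True)
    return _trilinear(U.values, vox, vert_idx)


def score_pathway(U: OrientationField, lp: LiftedPathway, sp: ScoringParams) -> ScoreResult:
    """Score one lifted pathway against the field (see module docstring)."""
    if U.global_max <= 0:
        raise ValueError("field global maximum must be positive")
    u = sample_field_along(U, lp)
    L = lp.length
    # step size L/N over the N interior samples, so the length-normalized
    # data term is exactly the mean log-support (a constant-support pathway
    # scores log c regardless of its length)
    ds = L / len(u)
    ratio = np.maximum(u / U.global_max, sp.floor)
    if np.all(ratio <= sp.floor):
        warnings.warn(f"pathway {lp.id}: all samples at the floor", stacklevel=2)
    external = float(np.sum(np.log(ratio)) * ds / L)
    kappa = lp.curvature[1:-1]
    internal = float(np.sum(kappa**2 + sp.eps) * ds)
    return ScoreResult(pathway_id=lp.id, external=external, internal=internal,
                       lam=sp.lam, n_samples=len(u))


def score_pathways(U: OrientationField, lps: list[LiftedPathway],
                   sp: ScoringParams | None = None) -> list[ScoreResult]:
    sp = sp or ScoringParams()
    return [score_pathway(U, lp, sp) for lp in lps]


def critical_threshold(scores: np.ndarray, labels: np.ndarray) -> EvaluationReport:
    """Critical-threshold evaluation at specificity 1.

    ``scores``: per-pathway totals; ``labels``: True for anatomically
    plausible.  The threshold is the smallest cut with no implausible pathway
    scoring >= cut; sensitivity is the plausible fraction retained.  If the
    top-scoring pathway is implausible, sensitivity is 0 and the method is
    flagged inadequate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if labels.all() or not labels.any():
        raise ValueError("need at least one plausible and one implausible pathway")
    plaus = scores[labels]
    implaus = scores[~labels]
    m = implaus.max()
    surviving = plaus[plaus > m]
    if surviving.size:
        threshold = float(surviving.min())
    else:
        threshold = float(np.nextafter(m, np.inf))
    tp = int(np.count_nonzero(plaus >= threshold))
    fn = plaus.size - tp
    sensitivity = tp / plaus.size
    inadequate = bool(scores.max() <= m) or sensitivity == 0.0
    return EvaluationReport(
        threshold=threshold,
        sensitivity=float(sensitivity),
        specificity=1.0,
        n_true_positive=tp,
        n_false_positive=0,
        n_false_negative=fn,
        inadequate=inadequate,
    )


def anterior_extent_metrics(bundle: list[LiftedPathway], tp_landmark: np.ndarray,
                            ih_landmark: np.ndarray, ap_axis: np.ndarray) -> tuple[float, float]:
    """Anterior-extent distances of a bundle relative to two landmarks.

    ``ap_axis`` is a unit vector pointing anteriorly.  Returns
    ``(ml_tp, ml_ih)`` in mm: ``ml_tp`` is the gap from the bundle's most
    anterior point forward to the temporal-pole landmark (positive when the
    bundle edge lies posterior to the pole); ``ml_ih`` is the signed offset of
    the bundle edge relative to the inferior-horn landmark, negative when the
    edge lies posterior to it.
    """
    if not bundle:
        raise ValueError("bundle is empty")
    ap = np.asarray(ap_axis, dtype=float)
    ap = ap / np.linalg.norm(ap)
    anterior = max(float(np.max(lp.points @ ap)) for lp in bundle)
    ml_tp = float(np.asarray(tp_landmark, dtype=float) @ ap - anterior)
    ml_ih = float(anterior - np.asarray(ih_landmark, dtype=float) @ ap)
    return ml_tp, ml_ih
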