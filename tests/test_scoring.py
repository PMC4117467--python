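"""Pathway scoring, critical-threshold evaluation, anterior-extent metrics."""

import numpy as np
import pytest

from fiberlift.odf import OrientationField
from fiberlift.scoring import (
    ScoringParams,
    anterior_extent_metrics,
    critical_threshold,
    sample_field_along,
    score_pathway,
)
from fiberlift.sphere import nearest_directions
from fiberlift.tracts import Pathway, lift_pathway


def _const_field(tess, value=1.0, shape=(20, 20, 20), vox=1.0):
    return OrientationField(
        values=np.full(shape + (tess.n_vertices,), value),
        affine=np.diag([vox, vox, vox, 1.0]),
        tess=tess,
    )


def _line(a, b, n=21):
    return Pathway(points=np.linspace(a, b, n))


def test_constant_field_sampling(tess1):
    U = _const_field(tess1, 0.7)
    lp = lift_pathway(_line([2.0, 10, 10], [17.0, 10, 10]), 1.0)
    u = sample_field_along(U, lp)
    assert len(u) == lp.n_samples - 2  # endpoints excluded
    assert np.allclose(u, 0.7, atol=1e-12)


def test_sampling_at_voxel_center_vertex(tess1, rng):
    vals = rng.random((9, 9, 9, tess1.n_vertices))
    U = OrientationField(values=vals, affine=np.eye(4), tess=tess1)
    k = 7
    n = tess1.vertices[k]
    # straight pathway through voxel (4,4,4) along vertex k's direction
    pts = np.array([[4.0, 4, 4]]) + np.outer(np.linspace(-3, 3, 7), n)
    lp = lift_pathway(Pathway(points=pts), 1.0)
    u = sample_field_along(U, lp)
    mid = len(u) // 2
    expect = vals[4, 4, 4, k] if k == nearest_directions(tess1, n[None], True)[0] else None
    assert u[mid] == pytest.approx(expect, abs=1e-9)


def test_trilinear_matches_bruteforce_oracle(tess1, rng):
    vals = rng.random((8, 8, 8, tess1.n_vertices))
    U = OrientationField(values=vals, affine=np.eye(4), tess=tess1)
    pts = rng.uniform(1.5, 5.5, size=(102, 3))
    lp = lift_pathway(Pathway(points=pts), step=0.1)
    # independent brute-force trilinear interpolation at the lifted samples
    vert_idx = nearest_directions(tess1, lp.tangents[1:-1], antipodal=True)
    u = sample_field_along(U, lp)
    for s, (p, k) in enumerate(zip(lp.points[1:-1], vert_idx)):
        i0 = np.floor(p).astype(int)
        f = p - i0
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((f[0] if dx else 1 - f[0]) * (f[1] if dy else 1 - f[1])
                         * (f[2] if dz else 1 - f[2]))
                    acc += w * vals[i0[0] + dx, i0[1] + dy, i0[2] + dz, k]
        assert abs(u[s] - acc) < 1e-12


def test_score_perfect_support_is_zero(tess1):
    U = _const_field(tess1, 2.5)  # global max equals the sampled value
    lp = lift_pathway(_line([3.0, 10, 10], [16.0, 10, 10]), 1.0)
    r = score_pathway(U, lp, ScoringParams(lam=0.0))
    assert r.external == pytest.approx(0.0, abs=1e-12)
    assert r.total == pytest.approx(0.0, abs=1e-12)


def test_score_constant_ratio_is_log_c_any_length(tess1):
    vals = np.full((20, 20, 20, tess1.n_vertices), 0.3)
    vals[0, 0, 0, 0] = 1.0  # global max elsewhere
    U = OrientationField(values=vals, affine=np.eye(4), tess=tess1)
    for end in (10.0, 17.0):
        lp = lift_pathway(_line([3.0, 10, 10], [end, 10, 10]), 1.0)
        r = score_pathway(U, lp, ScoringParams(lam=0.0))
        assert r.total == pytest.approx(np.log(0.3), rel=1e-9)


def test_curvature_penalty_prefers_straight(tess2):
    U = _const_field(tess2, 1.0, shape=(40, 40, 10), vox=1.0)
    sp = ScoringParams(lam=1.0, eps=0.01)
    straight = lift_pathway(_line([5.0, 20, 5], [5.0 + 10 * np.pi, 20, 5], n=40), 1.0)
    th = np.linspace(0, np.pi, 40)
    arc = lift_pathway(
        Pathway(points=np.column_stack([20 + 10 * np.cos(th), 20 + 10 * np.sin(th), np.full(40, 5.0)])),
        1.0,
    )
    assert abs(straight.length - arc.length) / arc.length < 0.01  # equal length
    s1 = score_pathway(U, straight, sp)
    s2 = score_pathway(U, arc, sp)
    assert s1.total > s2.total
    assert s1.external == pytest.approx(s2.external, abs=1e-9)


def test_score_invariant_under_global_scaling(tess1, rng):
    vals = rng.random((12, 12, 12, tess1.n_vertices))
    U1 = OrientationField(values=vals, affine=np.eye(4), tess=tess1)
    U2 = OrientationField(values=7.3 * vals, affine=np.eye(4), tess=tess1)
    lp = lift_pathway(_line([2.0, 6, 6], [9.0, 6, 6]), 1.0)
    sp = ScoringParams()
    assert score_pathway(U1, lp, sp).total == pytest.approx(
        score_pathway(U2, lp, sp).total, rel=1e-12
    )


def test_score_resampling_density_stability(tess2, rng):
    from scipy.ndimage import gaussian_filter

    gen = np.random.default_rng(8)
    vals = 0.2 + gen.random((20, 20, 20, tess2.n_vertices))
    vals = gaussian_filter(vals, sigma=(2.0, 2.0, 2.0, 0.0))  # smooth data
    U = OrientationField(values=vals, affine=np.eye(4), tess=tess2)
    th = np.linspace(0, 1.2, 30)
    pts = np.column_stack([4 + 10 * th, 10 + 3 * np.sin(th * 2), np.full(30, 10.0)])
    sp = ScoringParams(lam=0.0)
    s1 = score_pathway(U, lift_pathway(Pathway(points=pts), 1.0), sp).total
    s05 = score_pathway(U, lift_pathway(Pathway(points=pts), 0.5), sp).total
    assert abs(s1 - s05) / abs(s1) < 0.02


def test_external_term_nonpositive(tess1, rng):
    vals = rng.random((10, 10, 10, tess1.n_vertices))
    U = OrientationField(values=vals, affine=np.eye(4), tess=tess1)
    lp = lift_pathway(_line([2.0, 5, 5], [8.0, 5, 5]), 1.0)
    assert score_pathway(U, lp, ScoringParams()).external <= 0.0


def test_pathway_outside_field_errors(tess1):
    U = _const_field(tess1, 1.0, shape=(5, 5, 5))
    lp = lift_pathway(_line([50.0, 50, 50], [60.0, 50, 50]), 1.0)
    with pytest.raises(ValueError, match="outside"):
        sample_field_along(U, lp)


def test_critical_threshold_perfect_separation():
    r = critical_threshold(np.array([-1.0, -2.0, -5.0, -6.0]),
                           np.array([True, True, False, False]))
    assert r.sensitivity == 1.0
    assert r.specificity == 1.0
    assert r.n_false_positive == 0
    assert not r.inadequate


def test_critical_threshold_inadequate_when_top_is_implausible():
    r = critical_threshold(np.array([-1.0, -3.0, -0.5, -6.0]),
                           np.array([True, True, False, False]))
    assert r.sensitivity == 0.0
    assert r.inadequate


def test_critical_threshold_single_class_rejected():
    with pytest.raises(ValueError):
        critical_threshold(np.array([1.0, 2.0]), np.array([True, True]))


def _sweep_oracle(scores, labels):
    """Exhaustive sweep over all distinct cuts: best sensitivity with zero
    false positives, retention rule score >= cut."""
    best = (0.0, np.inf)
    cuts = np.unique(scores)
    cuts = np.concatenate([cuts, [np.nextafter(cuts.max(), np.inf)]])
    plaus, implaus = scores[labels], scores[~labels]
    for c in cuts:
        if (implaus >= c).any():
            continue
        sens = np.mean(plaus >= c)
        if sens > best[0] or (sens == best[0] and c < best[1]):
            best = (sens, c)
    return best


def test_critical_threshold_matches_sweep_oracle(rng):
    for trial in range(1000):
        gen = np.random.default_rng(trial)
        n = 20
        scores = np.round(gen.normal(size=n), 2)  # ties likely
        labels = gen.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        r = critical_threshold(scores, labels)
        sens_o, cut_o = _sweep_oracle(scores, labels)
        assert r.sensitivity == pytest.approx(sens_o, abs=1e-12)
        assert np.all(scores[~labels] < r.threshold)


def _lp(points):
    return lift_pathway(Pathway(points=np.asarray(points, dtype=float)), 1.0)


def test_anterior_extent_metrics():
    ap = np.array([0.0, 1.0, 0.0])  # anterior = +y
    bundle = [_lp([[0, 0, 0], [0, 5, 0], [0, 10, 0]])]  # collinear: no overshoot
    anterior_y = 10.0
    # landmark at the bundle edge: zero distance
    ml_tp, ml_ih = anterior_extent_metrics(bundle, [0, anterior_y, 0], [0, anterior_y, 0], ap)
    assert ml_tp == pytest.approx(0.0, abs=1e-9)
    assert ml_ih == pytest.approx(0.0, abs=1e-9)
    # temporal pole 27 mm anterior of the bundle edge: ml_tp = +27
    ml_tp, _ = anterior_extent_metrics(bundle, [0, anterior_y + 27.0, 0], [0, 0, 0], ap)
    assert ml_tp == pytest.approx(27.0, abs=1e-9)
    # bundle edge 3 mm posterior to the inferior-horn landmark: ml_ih = -3
    _, ml_ih = anterior_extent_metrics(bundle, [0, 0, 0], [0, anterior_y + 3.0, 0], ap)
    assert ml_ih == pytest.approx(-3.0, abs=1e-9)
    # translating the landmark by +5 mm along the axis shifts ml_tp by 5 mm
    a, _ = anterior_extent_metrics(bundle, [0, 40.0, 0], [0, 0, 0], ap)
    b, _ = anterior_extent_metrics(bundle, [0, 45.0, 0], [0, 0, 0], ap)
    assert b - a == pytest.approx(5.0, abs=1e-9)


# -- property tests ----------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=30),
       st.integers(1, 2**31 - 1))
def test_critical_threshold_property(score_list, seed):
    """For any score set: specificity is exactly 1 (no implausible pathway at
    or above the threshold) and sensitivity matches the exhaustive sweep."""
    scores = np.asarray(score_list)
    labels = np.random.default_rng(seed).random(len(scores)) < 0.5
    if labels.all() or not labels.any():
        return
    r = critical_threshold(scores, labels)
    assert np.all(scores[~labels] < r.threshold)
    sens_o, _ = _sweep_oracle(scores, labels)
    assert r.sensitivity == pytest.approx(sens_o, abs=1e-12)
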