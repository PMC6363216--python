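"""Superimposition, thin-plate-spline and sliding machinery, each checked
against an independent oracle (closed forms, grid searches, a hand-built
TPS system)."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from equiposture.gm_core import (
    DegenerateShapeError,
    articulation_angle,
    bending_energy,
    bending_energy_model,
    centroid_size,
    gpa,
    optimal_rotation,
    slide_semilandmarks,
    stabilize_articulation_angle,
    tps_warp,
    _slide_one,
    _tangents,
)
from equiposture.landmark_io import LandmarkConfiguration, MethodScheme, ShapeSample
from equiposture.synthetic import ProfileParams, generate_profile


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


# ---------------------------------------------------------------------- size


def test_centroid_size_unit_square():
    square = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], float)
    assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)


def test_centroid_size_homogeneity_and_bruteforce(profile):
    cs = centroid_size(profile)
    for c in (-2.5, 0.3, 7.0):
        assert centroid_size(profile * c) == pytest.approx(abs(c) * cs, rel=1e-12)
    # independent direct-summation oracle
    centroid = profile.sum(axis=0) / len(profile)
    brute = 0.0
    for p in profile:
        brute += (p[0] - centroid[0]) ** 2 + (p[1] - centroid[1]) ** 2
    assert cs == pytest.approx(np.sqrt(brute), rel=1e-12)


def test_centroid_size_degenerate():
    with pytest.raises(DegenerateShapeError):
        centroid_size(np.ones((5, 2)))


# ------------------------------------------------------------------ rotation


def test_optimal_rotation_recovers_known_angle(profile):
    src = profile - profile.mean(axis=0)
    theta = np.deg2rad(30.0)
    assert optimal_rotation(src, src @ _rot(theta).T) == pytest.approx(
        theta, abs=1e-9
    )
    assert optimal_rotation(src, src) == pytest.approx(0.0, abs=1e-12)


def test_optimal_rotation_matches_grid_search(rng):
    src = rng.normal(size=(10, 2))
    src -= src.mean(axis=0)
    tgt = rng.normal(size=(10, 2))
    tgt -= tgt.mean(axis=0)
    theta = optimal_rotation(src, tgt)
    grid = np.arange(-np.pi, np.pi, 1e-4)
    # SS(theta) = const - 2*(den*cos + num*sin): evaluate directly
    ss = np.array(
        [np.sum((src @ _rot(t).T - tgt) ** 2) for t in grid[:: len(grid) // 4000]]
    )
    coarse = grid[:: len(grid) // 4000][np.argmin(ss)]
    fine = coarse + np.arange(-2e-3, 2e-3, 1e-5)
    ss_fine = np.array([np.sum((src @ _rot(t).T - tgt) ** 2) for t in fine])
    best = fine[np.argmin(ss_fine)]
    assert theta == pytest.approx(best, abs=1e-4)
    assert np.sum((src @ _rot(theta).T - tgt) ** 2) <= ss_fine.min() + 1e-10


def test_optimal_rotation_degenerate():
    with pytest.raises(DegenerateShapeError):
        optimal_rotation(np.zeros((4, 2)), np.eye(2).repeat(2, 0))


# ----------------------------------------------------------------------- GPA


def test_gpa_collapses_similarity_copies(profile, rng):
    copies = []
    for _ in range(6):
        theta = rng.uniform(-np.pi, np.pi)
        scale = rng.uniform(0.2, 5.0)
        shift = rng.uniform(-100, 100, 2)
        copies.append(scale * profile @ _rot(theta).T + shift)
    res = gpa(np.stack(copies))
    assert res.converged
    for a in res.aligned:
        np.testing.assert_allclose(a, res.aligned[0], atol=1e-8)
    np.testing.assert_allclose(res.consensus, res.aligned[0], atol=1e-8)


def test_gpa_postconditions(profile_sample):
    res = gpa(profile_sample(n=10, noise=2.0))
    # unit centroid size, centered, consensus is the mean of aligned shapes
    for a in res.aligned:
        assert centroid_size(a) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(a.mean(axis=0), 0.0, atol=1e-8)
    np.testing.assert_allclose(res.consensus, res.aligned.mean(axis=0), atol=1e-12)
    # full Procrustes sum of squares never increases across iterations
    assert all(
        b <= a + 1e-10 for a, b in zip(res.sum_of_squares, res.sum_of_squares[1:])
    )


def test_gpa_invariant_under_input_similarity_transforms(profile_sample, rng):
    sample = profile_sample(n=6, noise=1.0)
    coords = sample.coords()
    res1 = gpa(coords)
    transformed = np.stack(
        [
            rng.uniform(0.5, 2.0) * c @ _rot(rng.uniform(-np.pi, np.pi)).T
            + rng.uniform(-50, 50, 2)
            for c in coords
        ]
    )
    res2 = gpa(transformed)
    np.testing.assert_allclose(res2.aligned, res1.aligned, atol=1e-6)


def test_gpa_two_shapes_matches_pairwise_procrustes(profile, rng):
    """With two configurations GPA must reduce to ordinary (pairwise)
    Procrustes superimposition; scipy's orthogonal_procrustes is the
    independent oracle for the optimal rotation."""
    a = profile + rng.normal(0, 1.5, profile.shape)
    b = profile + rng.normal(0, 1.5, profile.shape)
    res = gpa(np.stack([a, b]))

    def unit(x):
        x = x - x.mean(axis=0)
        return x / np.linalg.norm(x)

    ua, ub = unit(a), unit(b)
    R, _ = orthogonal_procrustes(ub, ua)
    assert np.linalg.det(R) > 0
    oracle_dist = np.linalg.norm(ub @ R - ua)
    gpa_dist = np.linalg.norm(res.aligned[0] - res.aligned[1])
    assert gpa_dist == pytest.approx(oracle_dist, abs=1e-8)


# ----------------------------------------------------------------------- TPS


def test_tps_identity_and_interpolation(profile, rng):
    q = rng.uniform(0, 100, (40, 2))
    np.testing.assert_allclose(tps_warp(profile, profile, q), q, atol=1e-8)
    target = profile + rng.normal(0, 3, profile.shape)
    np.testing.assert_allclose(
        tps_warp(profile, target, profile), target, atol=1e-8
    )


def test_tps_affine_target_is_affine_everywhere(profile, rng):
    A = np.array([[1.2, 0.4], [0.0, 0.9]])  # shear + scale
    b = np.array([5.0, -3.0])
    target = profile @ A.T + b
    q = rng.uniform(-20, 120, (60, 2))
    np.testing.assert_allclose(tps_warp(profile, target, q), q @ A.T + b, atol=1e-7)
    model = bending_energy_model(profile)
    assert bending_energy(model, target) == pytest.approx(0.0, abs=1e-8)


def test_tps_collinear_source_raises():
    line = np.column_stack([np.arange(6.0), np.zeros(6)])
    with pytest.raises(DegenerateShapeError):
        tps_warp(line, line + 1.0, np.array([[0.5, 0.5]]))


# ------------------------------------------------------------ bending energy


def test_bending_matrix_properties(profile):
    model = bending_energy_model(profile)
    B = model.bending_matrix
    np.testing.assert_allclose(B, B.T, atol=1e-10)
    eig = np.linalg.eigvalsh(B)
    assert eig.min() > -1e-8
    # affine null space: constants and both coordinate vectors annihilated
    k = len(profile)
    np.testing.assert_allclose(B @ np.ones(k), 0.0, atol=1e-8)
    np.testing.assert_allclose(B @ profile[:, 0], 0.0, atol=1e-6)
    np.testing.assert_allclose(B @ profile[:, 1], 0.0, atol=1e-6)
    assert np.sum(eig < eig.max() * 1e-9) == 3


def test_bending_energy_zero_on_affine_images(profile, rng):
    model = bending_energy_model(profile)
    assert bending_energy(model, profile) == pytest.approx(0.0, abs=1e-10)
    for _ in range(3):
        A = rng.normal(0, 1, (2, 2)) + np.eye(2)
        b = rng.normal(0, 10, 2)
        assert bending_energy(model, profile @ A.T + b) == pytest.approx(
            0.0, abs=1e-8
        )
    bumped = profile.copy()
    bumped[10] += [0.0, 5.0]
    assert bending_energy(model, bumped) > 1e-6


def test_bending_energy_matches_hand_built_system():
    """5-point reference with one displaced point, against an L-matrix
    assembled and inverted independently, element by element."""
    ref = np.array([[0.0, 0.0], [1.0, 0.2], [2.0, -0.1], [3.0, 0.3], [4.0, 0.0]])
    cfg = ref.copy()
    cfg[2] += [0.15, 0.4]

    k = 5
    K = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            r = np.hypot(*(ref[i] - ref[j]))
            K[i, j] = r**2 * np.log(r) if r > 0 else 0.0
    P = np.hstack([np.ones((k, 1)), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    B_oracle = np.linalg.inv(L)[:k, :k]
    expected = cfg[:, 0] @ B_oracle @ cfg[:, 0] + cfg[:, 1] @ B_oracle @ cfg[:, 1]

    model = bending_energy_model(ref)
    assert bending_energy(model, cfg) == pytest.approx(expected, rel=1e-10)


def test_bending_energy_size_mismatch():
    model = bending_energy_model(np.array([[0, 0], [1, 0], [0, 1.0]]))
    with pytest.raises(ValueError):
        bending_energy(model, np.zeros((4, 2)))


# ------------------------------------------------------------------- sliding


def test_slide_zero_at_reference(profile):
    model = bending_energy_model(profile)
    out = _slide_one(profile.copy(), model.bending_matrix, np.array([9]))
    np.testing.assert_allclose(out, profile, atol=1e-8)


def test_slide_fixed_landmarks_bitwise_unchanged(profile, rng):
    cfg = profile + rng.normal(0, 1.0, profile.shape)
    model = bending_energy_model(profile)
    slide_pos = np.array([4, 9, 17])
    out = _slide_one(cfg.copy(), model.bending_matrix, slide_pos)
    fixed = np.setdiff1d(np.arange(30), slide_pos)
    assert np.array_equal(out[fixed], cfg[fixed])


def test_slide_single_point_matches_grid_search(profile, rng):
    """Closed-form 1D minimizer for one sliding point equals a brute-force
    grid search over the tangent parameter."""
    cfg = profile + rng.normal(0, 1.0, profile.shape)
    model = bending_energy_model(profile)
    B = model.bending_matrix
    pos = 9
    out = _slide_one(cfg.copy(), B, np.array([pos]))
    lam_impl = float(
        (out[pos] - cfg[pos]) @ _tangents(cfg)[pos]
    )
    tang = _tangents(cfg)[pos]
    grid = np.arange(-5.0, 5.0, 1e-5)
    trial = np.repeat(cfg[None], 1, axis=0)

    def energy(lam):
        c = cfg.copy()
        c[pos] = cfg[pos] + lam * tang
        return c[:, 0] @ B @ c[:, 0] + c[:, 1] @ B @ c[:, 1]

    # quadratic in lam: coarse-to-fine grid search oracle
    coarse = grid[::100]
    e = np.array([energy(l) for l in coarse])
    c0 = coarse[np.argmin(e)]
    fine = c0 + np.arange(-1e-3, 1e-3, 1e-5)
    e_fine = np.array([energy(l) for l in fine])
    lam_oracle = fine[np.argmin(e_fine)]
    assert lam_impl == pytest.approx(lam_oracle, abs=1e-5)
    assert energy(lam_impl) <= e_fine.min() + 1e-12


def test_sliding_monotone_energy_and_convergence(profile_sample):
    sample = profile_sample(n=6, noise=1.5)
    res0 = gpa(sample)
    model = bending_energy_model(res0.consensus)
    scheme = sample.scheme
    slide_pos = scheme.positions_of(sorted(scheme.sliding_indices))
    before = sum(bending_energy(model, c) for c in res0.aligned)
    after = sum(
        bending_energy(
            model, _slide_one(c.copy(), model.bending_matrix, slide_pos)
        )
        for c in res0.aligned
    )
    assert after <= before + 1e-10

    slid, proc = slide_semilandmarks(sample)
    model2 = bending_energy_model(proc.consensus)
    final = sum(bending_energy(model2, c) for c in proc.aligned)
    assert final <= before + 1e-10


def test_sliding_no_semilandmarks_is_plain_gpa(profile_sample):
    sample = profile_sample(n=4, noise=1.0, seed=7)
    all_fixed = ShapeSample(
        sample.configurations, MethodScheme("fixed", frozenset(range(1, 31)))
    )
    slid, proc = slide_semilandmarks(all_fixed)
    np.testing.assert_allclose(proc.aligned, gpa(sample).aligned, atol=1e-12)


# ------------------------------------------------------- angle stabilization


def test_stabilize_angle_variance_zero(profile_sample):
    sample = profile_sample(n=8, noise=1.5)
    out = stabilize_articulation_angle(sample)
    angles = [articulation_angle(c) for c in out.coords()]
    assert np.var(angles) < 1e-12


def test_stabilize_noop_at_reference_angle(profile):
    cfg = LandmarkConfiguration(profile)
    sample = ShapeSample([cfg, LandmarkConfiguration(profile.copy())])
    out = stabilize_articulation_angle(sample)
    np.testing.assert_allclose(out.coords()[0], profile, atol=1e-9)


def test_stabilize_collapses_constructed_rotation_pair(profile):
    """A configuration and its copy with the neck chain rigidly rotated
    +10 degrees about the withers stabilize to identical outputs."""
    rotated = profile.copy()
    pivot = profile[14]
    rotated[15:] = (profile[15:] - pivot) @ _rot(np.deg2rad(10)).T + pivot
    sample = ShapeSample(
        [LandmarkConfiguration(profile), LandmarkConfiguration(rotated)]
    )
    out = stabilize_articulation_angle(sample)
    np.testing.assert_allclose(out.coords()[0], out.coords()[1], atol=1e-9)


def test_stabilize_is_rigid_within_subsets(profile_sample):
    sample = profile_sample(n=5, noise=1.0)
    out = stabilize_articulation_angle(sample)
    for before, after in zip(sample.coords(), out.coords()):
        for sl in (slice(0, 15), slice(15, 30)):
            d0 = np.linalg.norm(before[sl][:, None] - before[sl][None], axis=-1)
            d1 = np.linalg.norm(after[sl][:, None] - after[sl][None], axis=-1)
            np.testing.assert_allclose(d1, d0, atol=1e-9)


def test_stabilize_degenerate_pivot():
    pts = np.zeros((30, 2))
    pts[:, 0] = np.arange(30)
    pts[0] = pts[14]  # arm coincides with pivot
    sample = ShapeSample([LandmarkConfiguration(pts), LandmarkConfiguration(pts)])
    with pytest.raises(DegenerateShapeError):
        stabilize_articulation_angle(sample)
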