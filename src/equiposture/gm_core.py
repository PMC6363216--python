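"""Superimposition and semilandmark machinery.

Implements the geometric core of the posture analysis: centroid-size
scaling, optimal 2D rotation, Generalized Procrustes Analysis (GPA),
thin-plate-spline (TPS) interpolation and bending energy, bending-energy
semilandmark sliding, and rigid stabilization of the head/neck
articulation angle about the withers.

Conventions
-----------
Shapes are ``(k, 2)`` float arrays; samples are ``(n, k, 2)`` stacks.
Rotations are proper (det +1); reflections are never produced because
profile orientation is normalized upstream (``landmark_io.flip_horizontal``).
The TPS kernel is ``U(r) = r^2 log r`` with ``U(0) = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_io import MethodScheme, ShapeSample

__all__ = [
    "DegenerateShapeError",
    "ProcrustesResult",
    "BendingEnergyModel",
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "tps_warp",
    "bending_energy_model",
    "bending_energy",
    "slide_semilandmarks",
    "stabilize_articulation_angle",
]


class DegenerateShapeError(ValueError):
    """Raised for configurations without enough geometric information
    (coincident points, rank-0 shapes, singular TPS systems)."""


def centroid_size(points: np.ndarray) -> float:
    """Square root of the summed squared deviations from the centroid."""
    pts = np.asarray(points, dtype=float)
    dev = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(dev**2)))
    if cs == 0.0:
        raise DegenerateShapeError("all points coincident: centroid size is zero")
    return cs


def _center(points: np.ndarray) -> np.ndarray:
    return points - points.mean(axis=0)


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> float:
    """Angle (radians, counter-clockwise) of the proper rotation of
    ``source`` minimizing the summed squared distance to ``target``.

    Both shapes must already be centered. In 2D the least-squares
    orthogonal solution has the closed form
    ``theta = atan2(sum(x_s y_t - y_s x_t), sum(x_s x_t + y_s y_t))``,
    which is automatically a proper rotation (no reflection).
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.shape != t.shape:
        raise ValueError("source and target must have the same shape")
    if not np.any(np.abs(s - s.mean(axis=0)) > 0):
        raise DegenerateShapeError("rank-0 source shape: rotation undefined")
    num = float(np.sum(s[:, 0] * t[:, 1] - s[:, 1] * t[:, 0]))
    den = float(np.sum(s[:, 0] * t[:, 0] + s[:, 1] * t[:, 1]))
    return float(np.arctan2(num, den))


def _rotate(points: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return points @ rot.T


def _rotate_all_to(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate every centered shape in an (n, k, 2) stack onto ``target``."""
    num = np.einsum("nk,nk->n", coords[:, :, 0], target[None, :, 1]) - np.einsum(
        "nk,nk->n", coords[:, :, 1], target[None, :, 0]
    )
    den = np.einsum("nk,nk->n", coords[:, :, 0], target[None, :, 0]) + np.einsum(
        "nk,nk->n", coords[:, :, 1], target[None, :, 1]
    )
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    x, y = coords[:, :, 0], coords[:, :, 1]
    return np.stack([c[:, None] * x - s[:, None] * y, s[:, None] * x + c[:, None] * y], axis=-1)


@dataclass
class ProcrustesResult:
    """Outcome of a Generalized Procrustes superimposition."""

    aligned: np.ndarray          # (n, k, 2), unit centroid size, common orientation
    consensus: np.ndarray        # (k, 2) coordinate-wise mean of aligned shapes
    centroid_sizes: np.ndarray   # (n,) original sizes
    iterations: int
    converged: bool
    sum_of_squares: list[float]  # full Procrustes SS trace across iterations

    @property
    def n_configurations(self) -> int:
        return self.aligned.shape[0]


def gpa(
    sample: ShapeSample | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes Analysis (partial Procrustes variant).

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated onto the running consensus; the consensus is the
    renormalized coordinate-wise mean. Iteration stops when the relative
    consensus change drops below ``tol``. The result is invariant (to
    numerical tolerance) under arbitrary pre-applied translation,
    rotation and positive scaling of any input.

    Non-convergence within ``max_iter`` is flagged in the result rather
    than raised: the aligned coordinates are still usable.
    """
    coords = sample.coords() if isinstance(sample, ShapeSample) else np.asarray(sample, float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("GPA needs at least 2 configurations of equal point count")
    n = coords.shape[0]
    sizes = np.empty(n)
    centered = np.empty_like(coords)
    for i in range(n):
        centered[i] = _center(coords[i])
        sizes[i] = centroid_size(coords[i])
        centered[i] /= sizes[i]

    consensus = centered[0].copy()
    ss_trace: list[float] = []
    converged = False
    it = 0
    aligned = centered
    for it in range(1, max_iter + 1):
        aligned = _rotate_all_to(aligned, consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus = _center(new_consensus)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        ss_trace.append(float(np.sum((aligned - new_consensus) ** 2)))
        delta = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    # Canonical orientation: rotate the whole solution so the consensus
    # chord from the first to the last landmark points along +x (for a
    # dorsal outline: croup left, head right, dorsum up). This makes the
    # result invariant to similarity transforms of the inputs, not just
    # invariant up to rotation.
    mean_shape = aligned.mean(axis=0)
    chord = mean_shape[-1] - mean_shape[0]
    if np.hypot(*chord) > 1e-12 * np.abs(mean_shape).max():
        phi = -np.arctan2(chord[1], chord[0])
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        aligned = aligned @ rot.T
    # The reported consensus is the plain coordinate-wise mean of the
    # aligned shapes; the renormalized mean is only the internal rotation
    # target during iteration.
    return ProcrustesResult(aligned, aligned.mean(axis=0), sizes, it, converged, ss_trace)


# ---------------------------------------------------------------------------
# Thin-plate spline


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, expressed in r^2 for stability; U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)
    return np.where(r2 > 0.0, out, 0.0)


def _tps_system(source: np.ndarray) -> np.ndarray:
    k = source.shape[0]
    d2 = np.sum((source[:, None, :] - source[None, :, :]) ** 2, axis=-1)
    K = _tps_kernel(d2)
    P = np.column_stack([np.ones(k), source])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L


@dataclass
class BendingEnergyModel:
    """Bending-energy quadratic form of the TPS anchored at a reference shape.

    ``bending_matrix`` is the upper-left ``k x k`` block of the inverted
    TPS system; it is symmetric positive semi-definite and annihilates
    every affine image of the reference.
    """

    reference: np.ndarray
    bending_matrix: np.ndarray


def bending_energy_model(reference: np.ndarray) -> BendingEnergyModel:
    ref = np.asarray(reference, dtype=float)
    L = _tps_system(ref)
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError(
            "singular TPS system: reference points are collinear or coincident"
        ) from exc
    k = ref.shape[0]
    B = Linv[:k, :k]
    B = 0.5 * (B + B.T)  # enforce exact symmetry
    return BendingEnergyModel(ref, B)


def bending_energy(model: BendingEnergyModel, config: np.ndarray) -> float:
    """``x' B x + y' B y`` of a configuration against the model reference.

    Zero exactly when the configuration is an affine image of the
    reference; tiny negative round-off is clamped to zero.
    """
    cfg = np.asarray(config, dtype=float)
    if cfg.shape != model.reference.shape:
        raise ValueError(
            f"configuration shape {cfg.shape} != reference {model.reference.shape}"
        )
    B = model.bending_matrix
    e = float(cfg[:, 0] @ B @ cfg[:, 0] + cfg[:, 1] @ B @ cfg[:, 1])
    return max(e, 0.0)


def tps_warp(
    source: np.ndarray, target: np.ndarray, query_points: np.ndarray
) -> np.ndarray:
    """Evaluate the TPS interpolant carrying ``source`` landmarks exactly
    onto ``target`` landmarks at arbitrary query points."""
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    q = np.asarray(query_points, dtype=float)
    if src.shape != tgt.shape:
        raise ValueError("source and target must have the same shape")
    k = src.shape[0]
    L = _tps_system(src)
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    try:
        params = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError(
            "singular TPS system: source points are collinear or coincident"
        ) from exc
    W, A = params[:k], params[k:]
    d2 = np.sum((q[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    U = _tps_kernel(d2)
    return A[0] + q @ A[1:] + U @ W


# ---------------------------------------------------------------------------
# Semilandmark sliding


def _tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangent at every point of an ordered open curve: central
    difference of the neighbours, one-sided at the two endpoints."""
    t = np.empty_like(points)
    t[1:-1] = points[2:] - points[:-2]
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DegenerateShapeError("coincident neighbouring points: tangent undefined")
    return t / norms


def _slide_one(
    config: np.ndarray, B: np.ndarray, slide_pos: np.ndarray
) -> np.ndarray:
    """Minimize bending energy of one configuration against the model by
    displacing sliding points along their local tangents (closed-form
    quadratic minimizer)."""
    tang = _tangents(config)[slide_pos]
    tx, ty = tang[:, 0], tang[:, 1]
    Bss = B[np.ix_(slide_pos, slide_pos)]
    M = Bss * (np.outer(tx, tx) + np.outer(ty, ty))
    rhs = -(tx * (B @ config[:, 0])[slide_pos] + ty * (B @ config[:, 1])[slide_pos])
    lam = np.linalg.lstsq(M, rhs, rcond=None)[0]
    out = config.copy()
    out[slide_pos, 0] += tx * lam
    out[slide_pos, 1] += ty * lam
    return out


def slide_semilandmarks(
    sample: ShapeSample,
    reference: np.ndarray | None = None,
    max_outer: int = 5,
    tol: float = 1e-6,
    gpa_tol: float = 1e-8,
) -> tuple[ShapeSample, ProcrustesResult]:
    """Slide the scheme's semilandmarks to minimize bending energy.

    Each sliding point moves only along its local tangent direction; the
    displacement magnitudes solve the linear system minimizing the TPS
    bending energy toward the reference (the current GPA consensus unless
    an explicit reference is given). Fixed landmarks never move. The
    slide/re-superimpose cycle repeats until the total bending energy
    drops by less than ``tol`` or ``max_outer`` iterations.

    Returns the slid sample (Procrustes-aligned coordinates) together
    with the final superimposition.
    """
    scheme = sample.scheme
    sliding = sorted(scheme.sliding_indices)
    if not sliding:
        res = gpa(sample, tol=gpa_tol)
        return sample.with_coords(res.aligned), res
    slide_pos = scheme.positions_of(sliding)
    k = len(scheme.window)
    if k < 3:
        raise ValueError("sliding needs at least 3 points")

    res = gpa(sample, tol=gpa_tol)
    coords = res.aligned.copy()
    prev_total = np.inf
    for _ in range(max_outer):
        ref = res.consensus if reference is None else np.asarray(reference, float)
        model = bending_energy_model(ref)
        B = model.bending_matrix
        total = 0.0
        for i in range(coords.shape[0]):
            coords[i] = _slide_one(coords[i], B, slide_pos)
            total += bending_energy(model, coords[i])
        res = gpa(coords, tol=gpa_tol)
        coords = res.aligned.copy()
        if prev_total - total < tol:
            break
        prev_total = total
    return sample.with_coords(coords), res


# ---------------------------------------------------------------------------
# Articulation-angle stabilization


def articulation_angle(
    points: np.ndarray, pivot: int = 15, arm_a: int = 1, arm_b: int = 30
) -> float:
    """Signed angle (radians) at the pivot landmark from the vector toward
    ``arm_a`` to the vector toward ``arm_b`` (1-based indices)."""
    p = points[pivot - 1]
    va = points[arm_a - 1] - p
    vb = points[arm_b - 1] - p
    if np.allclose(va, 0) or np.allclose(vb, 0):
        raise DegenerateShapeError("pivot coincides with an arm point: angle undefined")
    return float(
        np.arctan2(va[0] * vb[1] - va[1] * vb[0], va[0] * vb[0] + va[1] * vb[1])
    )


def stabilize_articulation_angle(
    sample: ShapeSample,
    pivot: int = 15,
    arm_a: int = 1,
    arm_b: int = 30,
    moved: tuple[int, int] = (16, 30),
    reference_angle: float | None = None,
) -> ShapeSample:
    """Cancel neck balance movements by fixing the croup-withers-eye angle.

    For each configuration the neck-and-head chain (1-based indices
    ``moved[0]..moved[1]``) is rigidly rotated about the withers pivot so
    that the angle formed by landmarks ``arm_a``, ``pivot`` and ``arm_b``
    equals a common reference (default: circular mean over the sample).
    All other points are untouched, so the operation is rigid within both
    the moved and unmoved subsets.
    """
    if sample.scheme.region != "full":
        raise ValueError("angle stabilization operates on full configurations only")
    coords = sample.coords()
    angles = np.array(
        [articulation_angle(c, pivot, arm_a, arm_b) for c in coords]
    )
    if reference_angle is None:
        reference_angle = float(
            np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
        )
    lo, hi = moved[0] - 1, moved[1]
    out = coords.copy()
    for i, cfg in enumerate(coords):
        phi = reference_angle - angles[i]
        p = cfg[pivot - 1]
        out[i, lo:hi] = _rotate(cfg[lo:hi] - p, phi) + p
    return sample.with_coords(out)
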