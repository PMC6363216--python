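"""Shape PCA and thin-plate-spline deformation grids.

PCA is computed on the covariance of the flattened Procrustes-aligned
coordinates (the standard choice for shape data, where all variables
share units). Deformation grids visualize shape change along one
component by warping a regular lattice from the consensus to the shape
at the component's observed extreme score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gm_core import ProcrustesResult, tps_warp


@dataclass
class PCAResult:
    """Principal components of aligned shape coordinates.

    ``loadings`` rows are orthonormal directions in flattened shape space
    (length ``2k``); ``scores[:, j]`` are zero-mean projections onto
    component ``j``; ``variance_fraction`` sums to 1 over the retained
    (non-null) components.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    consensus: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def shape_pca(aligned: ProcrustesResult | np.ndarray, allow_degenerate: bool = False) -> PCAResult:
    """PCA of flattened aligned coordinates with a deterministic sign
    convention (the largest-magnitude loading entry is positive).

    A sample whose total shape variance is numerically zero raises,
    unless ``allow_degenerate`` requests all-zero scores instead.
    """
    if isinstance(aligned, ProcrustesResult):
        coords = aligned.aligned
        consensus = aligned.consensus
    else:
        coords = np.asarray(aligned, dtype=float)
        consensus = coords.mean(axis=0)
    n, k, _ = coords.shape
    if n < 3:
        raise ValueError("shape PCA needs at least 3 configurations")
    flat = coords.reshape(n, 2 * k)
    centered = flat - flat.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 1e-24:
        if allow_degenerate:
            return PCAResult(
                np.zeros((n, 1)), vt[:1] * 0.0, np.ones(1), consensus
            )
        raise ValueError("zero total shape variance: PCA undefined")
    rank = int(np.sum(s > s[0] * 1e-10))
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    # sign convention: largest-|entry| loading coefficient positive
    flip = np.sign(vt[np.arange(rank), np.argmax(np.abs(vt), axis=1)])
    vt = vt * flip[:, None]
    scores = u * s * flip[None, :]
    var_frac = s**2 / np.sum(s**2)
    return PCAResult(scores, vt, var_frac, consensus)


def shape_at_score(pca: PCAResult, component: int, score: float) -> np.ndarray:
    """Model shape at a given score along one component (0-based):
    consensus + score * loading, reshaped to ``(k, 2)``."""
    if not 0 <= component < pca.n_components:
        raise IndexError(
            f"component {component} out of range 0..{pca.n_components - 1}"
        )
    flat = pca.consensus.reshape(-1) + score * pca.loadings[component]
    return flat.reshape(-1, 2)


@dataclass
class DeformationGrid:
    """A regular lattice over the consensus warped to a component extreme."""

    source_grid: np.ndarray   # (ny, nx, 2)
    warped_grid: np.ndarray   # (ny, nx, 2)
    consensus: np.ndarray     # (k, 2)
    shape_min: np.ndarray     # shape at the observed minimum score
    shape_max: np.ndarray     # shape at the observed maximum score
    component: int
    extreme: str              # "min" | "max"


def deformation_grid(
    pca: PCAResult,
    component: int,
    extreme: str = "max",
    grid_density: tuple[int, int] = (24, 12),
    margin: float = 0.10,
) -> DeformationGrid:
    """TPS-warp a regular lattice from the consensus to the shape at the
    component's observed extreme score.

    The lattice covers the consensus bounding box plus a fractional
    margin; density and margin are presentational knobs only.
    """
    if extreme not in ("min", "max"):
        raise ValueError("extreme must be 'min' or 'max'")
    scores = pca.scores[:, component]
    s_min, s_max = float(scores.min()), float(scores.max())
    shape_min = shape_at_score(pca, component, s_min)
    shape_max = shape_at_score(pca, component, s_max)
    target = shape_max if extreme == "max" else shape_min

    lo = pca.consensus.min(axis=0)
    hi = pca.consensus.max(axis=0)
    span = hi - lo
    lo = lo - margin * span
    hi = hi + margin * span
    nx, ny = grid_density
    gx = np.linspace(lo[0], hi[0], nx)
    gy = np.linspace(lo[1], hi[1], ny)
    xx, yy = np.meshgrid(gx, gy)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    if np.allclose(target, pca.consensus):
        warped = nodes.copy()
    else:
        warped = tps_warp(pca.consensus, target, nodes)
    return DeformationGrid(
        nodes.reshape(ny, nx, 2),
        warped.reshape(ny, nx, 2),
        pca.consensus,
        shape_min,
        shape_max,
        component,
        extreme,
    )


def plot_deformation_grid(grid: DeformationGrid, path: str) -> None:
    """Render a deformation grid to a vector-graphics (SVG) file:
    grey consensus outline, red minimum-score shape, blue maximum-score
    shape, thin lattice lines showing where the deformation concentrates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    w = grid.warped_grid
    for row in w:
        ax.plot(row[:, 0], row[:, 1], color="0.75", lw=0.5)
    for col in np.transpose(w, (1, 0, 2)):
        ax.plot(col[:, 0], col[:, 1], color="0.75", lw=0.5)
    ax.plot(grid.consensus[:, 0], grid.consensus[:, 1], "-o", color="0.4",
            ms=2.5, lw=1.2, label="consensus")
    ax.plot(grid.shape_min[:, 0], grid.shape_min[:, 1], "-", color="crimson",
            lw=1.2, label="axis minimum")
    ax.plot(grid.shape_max[:, 0], grid.shape_max[:, 1], "-", color="royalblue",
            lw=1.2, label="axis maximum")
    ax.set_aspect("equal")
    ax.set_title(f"PC{grid.component + 1} deformation ({grid.extreme})")
    ax.legend(loc="best", fontsize=7)
    ax.axis("off")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
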