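"""Shape-space ordination and thin-plate-spline visualization.

PCA of the flattened Procrustes coordinates summarises shape variation;
for 2-D data with k landmarks at most min(n - 1, 2k - 4) axes carry
variance (four dimensions are removed by the superimposition: two of
translation, one of rotation, one of scale).  Thin-plate-spline (TPS)
deformation grids visualise the difference between two configurations
as the minimal-bending-energy interpolating warp of the plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LandmarkConfiguration, ShapeDataset

__all__ = [
    "ShapePCA",
    "shape_pca",
    "GridSpec",
    "TPSGrid",
    "tps_warp",
    "axis_extreme_shapes",
    "plot_tps_grid",
]


# ---------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------

@dataclass
class ShapePCA:
    """Principal components of aligned shape coordinates.

    ``loadings`` columns are orthonormal axis vectors in the 2k space
    (sign fixed: largest-magnitude loading positive); ``scores`` are the
    centred data projected on all retained axes; ``variance_fractions``
    cover the non-null axes and sum to 1.
    """

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    landmark_labels: tuple[str, ...]

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def variance_percents(self, ndigits: int = 0) -> np.ndarray:
        """Variance shares as (rounded) percentages."""
        return np.round(100.0 * self.variance_fractions, ndigits)


def shape_pca(data: ShapeDataset) -> ShapePCA:
    """PCA (covariance eigen-decomposition) of aligned shapes.

    Null axes (eigenvalue below 1e-10 of the leading one) are dropped;
    for 2-D GPA coordinates that leaves at most min(n - 1, 2k - 4) axes.
    """
    if not data.aligned:
        raise ValueError("shape PCA requires Procrustes-aligned data")
    if data.n < 3:
        raise ValueError("PCA needs at least three specimens")
    y = data.flatten()
    mean = y.mean(axis=0)
    centered = y - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (data.n - 1)
    keep = eig > (eig[0] * 1e-10 if eig[0] > 0 else 0)
    eig = eig[keep]
    loadings = vt[keep].T
    # sign convention: largest-|loading| entry positive per axis
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1.0
    scores = centered @ loadings
    fractions = eig / eig.sum()
    return ShapePCA(
        eigenvalues=eig,
        variance_fractions=fractions,
        loadings=loadings,
        scores=scores,
        mean=mean,
        landmark_labels=data.landmark_labels,
    )


def axis_extreme_shapes(
    pca: ShapePCA, axis: int, magnitude: float | str
) -> LandmarkConfiguration:
    """Model shape at a position along a principal axis.

    ``magnitude`` may be ``'min'``/``'max'`` (the extreme observed score
    on the axis) or a real number interpreted as a multiple of the
    axis's score standard deviation.  ``magnitude=0`` returns the
    consensus exactly.
    """
    if not 0 <= axis < pca.n_axes:
        raise ValueError(f"axis {axis} outside the non-null range 0..{pca.n_axes - 1}")
    if isinstance(magnitude, str):
        if magnitude == "min":
            score = float(pca.scores[:, axis].min())
        elif magnitude == "max":
            score = float(pca.scores[:, axis].max())
        else:
            raise ValueError("magnitude must be 'min', 'max' or a number")
    else:
        score = float(magnitude) * float(np.sqrt(pca.eigenvalues[axis]))
    vec = pca.mean + score * pca.loadings[:, axis]
    return LandmarkConfiguration(
        specimen_id=f"PC{axis + 1}@{magnitude}",
        coords=vec.reshape(-1, 2),
        landmark_labels=pca.landmark_labels,
    )


# ---------------------------------------------------------------------
# thin-plate spline
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular lattice over the reference bounding box, padded by a fraction."""

    nx: int = 24
    ny: int = 24
    padding: float = 0.10


@dataclass
class TPSGrid:
    """A fitted 2-D thin-plate-spline warp with its deformed lattice.

    The warp maps the reference configuration exactly onto the target;
    ``bending_energy`` is the quadratic form of the non-affine weights
    with the kernel matrix (zero iff the map is affine).
    """

    reference: LandmarkConfiguration
    target: LandmarkConfiguration
    affine: np.ndarray  # (3, 2): row 0 offset, rows 1-2 linear part
    weights: np.ndarray  # (k, 2)
    grid_shape: tuple[int, int]
    grid_points: np.ndarray = field(repr=False)  # (nx*ny, 2) source lattice
    warped_grid: np.ndarray = field(repr=False)  # (nx*ny, 2)
    bending_energy: float = 0.0

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Apply the fitted warp to arbitrary (m, 2) points."""
        return _tps_apply(
            np.asarray(points, dtype=float),
            self.reference.coords,
            self.affine,
            self.weights,
        )


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2 with the removable singularity U(0) = 0."""
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = r2[pos] * np.log(r2[pos])
    return out


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
    return _tps_kernel(d2)


def _tps_apply(points, ref, affine, weights):
    k = _kernel_matrix(points, ref)
    return affine[0] + points @ affine[1:] + k @ weights


def tps_warp(
    reference: LandmarkConfiguration,
    target: LandmarkConfiguration,
    lattice: GridSpec = GridSpec(),
) -> TPSGrid:
    """Fit the TPS interpolant reference -> target and warp a lattice.

    Solves the standard (k + 3) linear system per output coordinate for
    the kernel weights and affine part; raises on collinear reference
    landmarks (singular system).
    """
    ref = reference.coords
    tgt = target.coords
    if ref.shape != tgt.shape:
        raise ValueError("reference and target must share the landmark count")
    k = ref.shape[0]
    km = _kernel_matrix(ref, ref)
    p = np.column_stack([np.ones(k), ref])
    lhs = np.zeros((k + 3, k + 3))
    lhs[:k, :k] = km
    lhs[:k, k:] = p
    lhs[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=2)
    if np.min(d2[~np.eye(k, dtype=bool)]) == 0.0:
        raise ValueError("singular TPS system: coincident reference landmarks")
    if np.linalg.matrix_rank(p) < 3:
        raise ValueError("singular TPS system: reference landmarks are collinear")
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system: reference landmarks are collinear"
        ) from exc
    weights = sol[:k]
    affine = sol[k:]  # rows: 1, x, y

    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    pad = lattice.padding * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], lattice.nx)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], lattice.ny)
    gx, gy = np.meshgrid(xs, ys)
    grid_points = np.column_stack([gx.ravel(), gy.ravel()])
    warped = _tps_apply(grid_points, ref, affine, weights)

    be = float(np.einsum("ki,kl,li->", weights, km, weights))
    return TPSGrid(
        reference=reference,
        target=target,
        affine=affine,
        weights=weights,
        grid_shape=(lattice.ny, lattice.nx),
        grid_points=grid_points,
        warped_grid=warped,
        bending_energy=max(0.0, be),
    )


def plot_tps_grid(grid: TPSGrid, ax=None, **landmark_kwargs):
    """Draw the deformed lattice with the target landmarks (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ny, nx = grid.grid_shape
    w = grid.warped_grid.reshape(ny, nx, 2)
    for row in range(ny):
        ax.plot(w[row, :, 0], w[row, :, 1], color="0.6", lw=0.6)
    for col in range(nx):
        ax.plot(w[:, col, 0], w[:, col, 1], color="0.6", lw=0.6)
    landmark_kwargs.setdefault("color", "k")
    landmark_kwargs.setdefault("zorder", 3)
    ax.scatter(grid.target.coords[:, 0], grid.target.coords[:, 1], **landmark_kwargs)
    ax.set_aspect("equal")
    return ax
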