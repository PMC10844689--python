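"""Phenotypic trajectory analysis.

A phenotypic trajectory is the ordered path of a group's mean shapes
across an ordered environmental gradient (here: per-clone mean shapes
over increasing predation-risk level).  Two trajectories are compared by
three attributes:

* **magnitude** — the path distance, the summed Euclidean segment
  lengths in the flattened shape space;
* **direction** — the angle between the trajectories' principal axes,
  each sign-oriented along increasing risk;
* **shape** — the Procrustes distance between the trajectories after
  treating their L mean shapes as L "landmarks" in shape space and
  superimposing (centre, unit-scale, optimal rotation).

Significance of pairwise attribute differences uses RRPP: residuals of
the group + gradient main-effects model are randomly re-assigned to
specimens, cell means and attributes recomputed each iteration, and
p = (b + 1)/(B + 1) for each attribute with b the count of permuted
values at or above the observed one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import LSMeans, nested_bases, term_columns
from .core import MorphokitError, ShapeDataset

__all__ = [
    "Trajectory",
    "build_trajectories",
    "path_distance",
    "trajectory_angle",
    "trajectory_shape_distance",
    "trajectory_test",
    "TrajectoryComparison",
]


class UndefinedDirectionError(MorphokitError):
    """All trajectory points coincide; the direction is undefined."""


@dataclass
class Trajectory:
    """Ordered sequence of L mean shapes for one group.

    ``points`` is (L, d) with d the flattened shape-space dimension,
    rows ordered by the declared gradient ordering (increasing risk).
    """

    group: str
    points: np.ndarray
    levels: tuple

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be (L, d)")
        if self.points.shape[0] < 2:
            raise ValueError("a trajectory needs at least two gradient levels")

    @property
    def L(self) -> int:
        return self.points.shape[0]


def build_trajectories(
    means: LSMeans, group_factor: str = "clone", order_factor: str = "risk"
) -> list[Trajectory]:
    """One trajectory per group from per-cell mean shapes.

    ``means`` must cover the full (group x level) cross; levels are
    connected in the declared gradient order.
    """
    if group_factor not in means.cells.columns or order_factor not in means.cells.columns:
        raise ValueError(
            f"means must be grouped by {group_factor!r} and {order_factor!r}"
        )
    out = []
    for group, sub in means.cells.groupby(group_factor, sort=True):
        idx = sub.index.to_numpy()
        levels = means.cells.loc[idx, order_factor].tolist()
        out.append(Trajectory(group=str(group), points=means.means[idx], levels=tuple(levels)))
    return out


def path_distance(t: Trajectory) -> float:
    """Summed Euclidean segment lengths along the trajectory."""
    return float(np.sum(np.linalg.norm(np.diff(t.points, axis=0), axis=1)))


def _direction(points: np.ndarray) -> np.ndarray:
    """Unit first principal axis, sign-oriented along the gradient."""
    centered = points - points.mean(axis=0)
    if not np.any(np.abs(centered) > 0):
        raise UndefinedDirectionError("all trajectory points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    chord = points[-1] - points[0]
    proj = float(d @ chord)
    if proj < 0 or (proj == 0 and d[np.argmax(np.abs(d))] < 0):
        d = -d
    return d


def _chord_direction(points: np.ndarray) -> np.ndarray:
    chord = points[-1] - points[0]
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise UndefinedDirectionError("first and last trajectory points coincide")
    return chord / norm


def trajectory_angle(t1: Trajectory, t2: Trajectory, method: str = "principal-axis") -> float:
    """Angle in degrees [0, 180] between two trajectories' directions.

    ``method='principal-axis'`` (default) uses the first principal axis
    of each trajectory's points, oriented along increasing gradient;
    ``method='chord'`` uses the last-minus-first chord.
    """
    if t1.points.shape != t2.points.shape:
        raise ValueError("trajectories must share L and shape-space dimension")
    fn = {"principal-axis": _direction, "chord": _chord_direction}[method]
    d1, d2 = fn(t1.points), fn(t2.points)
    return float(np.degrees(np.arccos(np.clip(d1 @ d2, -1.0, 1.0))))


def _unit_centered(points: np.ndarray) -> np.ndarray:
    z = points - points.mean(axis=0)
    size = np.linalg.norm(z)
    if size == 0:
        raise MorphokitError("degenerate (zero-size) trajectory")
    return z / size


def trajectory_shape_distance(t1: Trajectory, t2: Trajectory) -> float:
    """Procrustes distance between trajectories as L-point configurations.

    Both point sets are centred and scaled to unit size in the shape
    space, then optimally rotated onto each other (orthogonal
    superimposition); the residual root-sum-of-squares is returned.
    """
    if t1.points.shape != t2.points.shape:
        raise ValueError("trajectories must share L and shape-space dimension")
    z1 = _unit_centered(t1.points)
    z2 = _unit_centered(t2.points)
    u, _, vt = np.linalg.svd(z1.T @ z2)
    return float(np.linalg.norm(z1 @ (u @ vt) - z2))


# ---------------------------------------------------------------------
# RRPP test
# ---------------------------------------------------------------------

@dataclass
class TrajectoryComparison:
    """Pairwise trajectory attribute differences with RRPP p-values.

    ``attributes`` has one row per unordered group pair with the
    observed |delta path distance|, angle (degrees) and trajectory shape
    distance, plus their permutation p-values.  ``trajectories`` are the
    observed per-group trajectories.
    """

    attributes: pd.DataFrame
    trajectories: list[Trajectory]
    n_permutations: int
    seed: int | None

    def __str__(self) -> str:
        return self.attributes.to_string(float_format=lambda v: f"{v:.6g}")


def _cell_mean_operator(groups: np.ndarray, levels: np.ndarray, group_order, level_order):
    """(G*L, n) matrix averaging specimens into (group, level) cells."""
    n = len(groups)
    rows = []
    for g in group_order:
        for lev in level_order:
            mask = (groups == g) & (levels == lev)
            cnt = int(mask.sum())
            if cnt == 0:
                raise ValueError(f"empty design cell (group={g!r}, level={lev!r})")
            rows.append(mask / cnt)
    return np.array(rows)


def _batched_attributes(means: np.ndarray, n_groups: int, n_levels: int):
    """Per-permutation trajectory attributes from stacked cell means.

    ``means`` is (B, G*L, d).  Returns (pd, dirs, shapes): path distances
    (B, G), unit directions (B, G, d) and unit-centred point sets
    (B, G, L, d).
    """
    b, _, d = means.shape
    pts = means.reshape(b, n_groups, n_levels, d)
    seg = np.diff(pts, axis=2)
    pd_ = np.sum(np.linalg.norm(seg, axis=3), axis=2)

    centered = pts - pts.mean(axis=2, keepdims=True)
    # directions via batched SVD of (B, G, L, d)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    dirs = vt[..., 0, :]
    chord = pts[:, :, -1, :] - pts[:, :, 0, :]
    sign = np.sign(np.einsum("bgd,bgd->bg", dirs, chord))
    sign[sign == 0] = 1.0
    dirs = dirs * sign[..., None]

    size = np.linalg.norm(centered, axis=(2, 3), keepdims=True)
    shapes = centered / np.where(size == 0, 1.0, size)
    return pd_, dirs, shapes


def trajectory_test(
    data: ShapeDataset,
    group_factor: str = "clone",
    order_factor: str = "risk",
    n_permutations: int = 1000,
    seed: int | None = None,
    angle_method: str = "principal-axis",
    extra_terms: tuple[str, ...] = (),
) -> TrajectoryComparison:
    """Pairwise RRPP tests of trajectory magnitude, direction and shape.

    Cell means over (group, gradient level) form the observed
    trajectories.  The null randomizes residuals of the group + level
    main-effects model (the reduced model for their interaction) across
    specimens and recomputes every attribute.  ``extra_terms`` adds
    further known design factors (e.g. instar) to the reduced model so
    their systematic variation is not mistaken for exchangeable noise.
    """
    if not data.aligned:
        raise ValueError("trajectory analysis requires Procrustes-aligned data")
    if angle_method not in ("principal-axis", "chord"):
        raise ValueError(f"unknown angle method {angle_method!r}")
    y = data.flatten()
    groups = data.factor_values(group_factor)
    levels = data.factor_values(order_factor)
    group_order = sorted(pd.unique(groups).tolist())
    level_order = (
        data.factors.level_order(order_factor)
        if order_factor == "risk"
        else sorted(pd.unique(levels).tolist())
    )
    n_groups, n_levels = len(group_order), len(level_order)
    if n_levels < 2:
        raise ValueError("the gradient needs at least two levels")

    cmat = _cell_mean_operator(groups, levels, group_order, level_order)

    # reduced model: group + level main effects (+ declared nuisance terms)
    blocks = term_columns(data, (group_factor, order_factor) + tuple(extra_terms))
    q_list, _ = nested_bases(data.n, blocks)
    q_red = q_list[-1]
    fitted = q_red @ (q_red.T @ y)
    resid = y - fitted

    rng = np.random.default_rng(seed)
    perms = np.vstack(
        [np.arange(data.n)[None, :]]
        + [rng.permutation(data.n)[None, :] for _ in range(n_permutations)]
    )

    b_tot = perms.shape[0]
    d = y.shape[1]
    means = np.empty((b_tot, cmat.shape[0], d))
    chunk = max(1, int(4e7 // (data.n * d)))
    for start in range(0, b_tot, chunk):
        sel = perms[start : start + chunk]
        ystar = fitted[None, :, :] + resid[sel]
        means[start : start + chunk] = np.einsum("cn,bnp->bcp", cmat, ystar)

    pd_, dirs, shapes = _batched_attributes(means, n_groups, n_levels)

    pairs = list(itertools.combinations(range(n_groups), 2))
    rows = []
    for i, j in pairs:
        dmag = np.abs(pd_[:, i] - pd_[:, j])
        cosang = np.clip(np.einsum("bd,bd->b", dirs[:, i], dirs[:, j]), -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        s = np.linalg.svd(
            np.einsum("bld,ble->bde", shapes[:, i], shapes[:, j]), compute_uv=False
        )
        dshape = np.sqrt(np.clip(2.0 - 2.0 * s.sum(axis=1), 0.0, None))
        if angle_method == "chord":
            chord_i = means[:, i * n_levels + (n_levels - 1)] - means[:, i * n_levels]
            chord_j = means[:, j * n_levels + (n_levels - 1)] - means[:, j * n_levels]
            ci = chord_i / np.linalg.norm(chord_i, axis=1, keepdims=True)
            cj = chord_j / np.linalg.norm(chord_j, axis=1, keepdims=True)
            ang = np.degrees(
                np.arccos(np.clip(np.einsum("bd,bd->b", ci, cj), -1.0, 1.0))
            )

        def pval(stat: np.ndarray) -> float:
            obs = stat[0]
            b = int(np.sum(stat[1:] >= obs))
            return (b + 1) / (len(stat[1:]) + 1)

        rows.append(
            {
                "group_1": group_order[i],
                "group_2": group_order[j],
                "d_magnitude": float(dmag[0]),
                "p_magnitude": pval(dmag),
                "angle_deg": float(ang[0]),
                "p_angle": pval(ang),
                "d_shape": float(dshape[0]),
                "p_shape": pval(dshape),
            }
        )

    trajectories = [
        Trajectory(
            group=str(g),
            points=means[0, gi * n_levels : (gi + 1) * n_levels],
            levels=tuple(level_order),
        )
        for gi, g in enumerate(group_order)
    ]
    return TrajectoryComparison(
        attributes=pd.DataFrame(rows),
        trajectories=trajectories,
        n_permutations=n_permutations,
        seed=seed,
    )
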