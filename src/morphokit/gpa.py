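"""Procrustes superimposition and digitising repeatability.

Ordinary Procrustes analysis (OPA) removes translation, scale and
rotation between two configurations; Generalized Procrustes Analysis
(GPA) iteratively superimposes a whole sample onto its consensus,
leaving pure shape variation plus a recorded centroid size per
specimen.  Reflections are never introduced by the alignment itself
(rotation determinant forced to +1) unless explicitly requested —
left/right mirroring is an ingest decision, not an alignment one.

Repeatability of digitisation is estimated from repeated digitising
sessions of the same photographs via a one-way Procrustes ANOVA on the
jointly aligned coordinates and the usual variance-component ratio
(intraclass correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .core import (
    DegenerateConfigurationError,
    LandmarkConfiguration,
    ShapeDataset,
)

__all__ = [
    "centroid_size",
    "squared_centroid_size",
    "size_measure",
    "opa_align",
    "procrustes_distance",
    "gpa",
    "ProcrustesResult",
    "repeatability",
    "RepeatabilityResult",
]


# ---------------------------------------------------------------------
# size
# ---------------------------------------------------------------------

def _coords_of(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def squared_centroid_size(config) -> float:
    """Sum of squared distances of each landmark to the landmark centroid."""
    x = _coords_of(config)
    c = x - x.mean(axis=0)
    return float(np.sum(c * c))


def centroid_size(config) -> float:
    """Standard centroid size: sqrt of :func:`squared_centroid_size`.

    Raises :class:`DegenerateConfigurationError` when all landmarks
    coincide (zero size).
    """
    cs2 = squared_centroid_size(config)
    if cs2 <= 0.0:
        raise DegenerateConfigurationError("all landmarks coincident (zero centroid size)")
    return float(np.sqrt(cs2))


def size_measure(config, variant: str = "cs") -> float:
    """Centroid size under a named variant: ``cs``, ``cs-squared`` or ``log-cs``."""
    cs = centroid_size(config)
    if variant == "cs":
        return cs
    if variant == "cs-squared":
        return cs * cs
    if variant == "log-cs":
        return float(np.log(cs))
    raise ValueError(f"unknown size variant {variant!r}")


# ---------------------------------------------------------------------
# ordinary Procrustes
# ---------------------------------------------------------------------

def _center_scale(x: np.ndarray) -> np.ndarray:
    """Center at the origin and scale to unit centroid size."""
    c = x - x.mean(axis=0)
    cs = np.sqrt(np.sum(c * c))
    if cs <= 0.0:
        raise DegenerateConfigurationError("all landmarks coincident (zero centroid size)")
    return c / cs


def _optimal_rotation(x: np.ndarray, y: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Orthogonal R minimising ||x @ R - y||_F; det forced to +1 unless allowed."""
    u, _, vt = np.linalg.svd(x.T @ y)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        d = np.ones(x.shape[1])
        d[-1] = -1.0
        r = (u * d) @ vt
    return r


def opa_align(
    target,
    reference,
    allow_reflection: bool = False,
):
    """Superimpose *target* onto *reference* by translation, scale, rotation.

    Both configurations are centred and scaled to unit centroid size;
    the rotation minimising the residual sum of squares is found by SVD
    of the cross-product matrix.  Returns the aligned target and the
    (partial) Procrustes distance — the root-sum-of-squares deviation
    between the unit-size superimposed configurations.
    """
    tx = _coords_of(target)
    rx = _coords_of(reference)
    if tx.shape != rx.shape:
        raise ValueError(f"landmark count mismatch: {tx.shape[0]} vs {rx.shape[0]}")
    xs = _center_scale(tx)
    ys = _center_scale(rx)
    rot = _optimal_rotation(xs, ys, allow_reflection)
    aligned = xs @ rot
    dist = float(np.linalg.norm(aligned - ys))
    if isinstance(target, LandmarkConfiguration):
        aligned_config = LandmarkConfiguration(
            specimen_id=target.specimen_id,
            coords=aligned,
            landmark_labels=target.landmark_labels,
        )
        return aligned_config, dist
    return aligned, dist


def procrustes_distance(a, b, allow_reflection: bool = False) -> float:
    """Partial Procrustes distance between two configurations."""
    return opa_align(a, b, allow_reflection=allow_reflection)[1]


# ---------------------------------------------------------------------
# generalized Procrustes
# ---------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    """Outcome of a GPA run.

    ``aligned`` holds unit-centroid-size Procrustes shape coordinates;
    ``consensus`` the mean shape (unit size, centred, orientation fixed
    by the principal-axis convention); ``centroid_sizes`` the raw sizes
    removed from each specimen.
    """

    aligned: ShapeDataset
    consensus: LandmarkConfiguration
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    tolerance: float


def _orient_by_principal_axes(consensus: np.ndarray, stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate so the consensus's principal axes align with x/y.

    GPA fixes shape only up to a global rotation; this convention makes
    repeated runs (and permuted-input runs) bit-comparable.  A proper
    rotation is used (no reflection): the first principal axis of the
    consensus goes to the x-axis, and the orientation is flipped by
    180 degrees if needed so the largest-magnitude x-coordinate of the
    consensus is positive.
    """
    cov = np.cov(consensus, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    axes = eigvec[:, order]
    if np.linalg.det(axes) < 0:  # keep it a rotation
        axes[:, 1] *= -1.0
    consensus = consensus @ axes
    stack = stack @ axes
    j = int(np.argmax(np.abs(consensus[:, 0])))
    if consensus[j, 0] < 0:  # 180-degree turn, still a rotation
        consensus = -consensus
        stack = -stack
    return consensus, stack


def _project_to_tangent(stack: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent space.

    At the (unit-size, centred) consensus c the directions of pure
    scaling (c itself) and pure rotation (c turned 90 degrees landmark-
    wise) carry no shape information; removing the residual components
    of each specimen along them puts the sample exactly into the
    2k - 4 dimensional linear tangent space, as the superimposition's
    nonlinear constraints only guarantee to first order.
    """
    c = consensus.reshape(-1)
    c_rot = np.column_stack([-consensus[:, 1], consensus[:, 0]]).reshape(-1)
    basis = np.column_stack([c, c_rot])
    q, _ = np.linalg.qr(basis)
    flat = stack.reshape(stack.shape[0], -1) - c
    flat = flat - (flat @ q) @ q.T
    return (flat + c).reshape(stack.shape)


def gpa(
    data: ShapeDataset,
    tolerance: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = False,
    project: bool = True,
) -> ProcrustesResult:
    """Generalized Procrustes superimposition of a dataset.

    Iterates: align every configuration to the current consensus by
    OPA, replace the consensus with the mean of the aligned
    configurations rescaled to unit centroid size, until the change in
    summed squared Procrustes deviation falls below ``tolerance`` or
    ``max_iter`` is reached (then the result is flagged unconverged,
    with a warning, rather than raising).  With ``project=True`` the
    aligned shapes are finally projected into the linear tangent space
    at the consensus.
    """
    if data.n < 2:
        raise ValueError("GPA needs at least two configurations")
    sizes = np.array([centroid_size(data.coords[i]) for i in range(data.n)])
    stack = np.stack([_center_scale(data.coords[i]) for i in range(data.n)])

    consensus = stack[0].copy()
    last_q = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(stack.shape[0]):
            rot = _optimal_rotation(stack[i], consensus, allow_reflection)
            stack[i] = stack[i] @ rot
        consensus = stack.mean(axis=0)
        consensus = _center_scale(consensus)
        q = float(np.sum((stack - consensus) ** 2))
        if abs(last_q - q) < tolerance:
            converged = True
            break
        last_q = q
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last change {abs(last_q - q):.3g})",
            RuntimeWarning,
        )
    # final pass so every specimen is aligned to the final consensus
    for i in range(stack.shape[0]):
        rot = _optimal_rotation(stack[i], consensus, allow_reflection)
        stack[i] = stack[i] @ rot
    consensus, stack = _orient_by_principal_axes(consensus, stack)
    if project:
        stack = _project_to_tangent(stack, consensus)

    aligned = ShapeDataset(
        coords=stack,
        specimen_ids=data.specimen_ids,
        landmark_labels=data.landmark_labels,
        factors=data.factors,
        centroid_sizes=sizes,
        aligned=True,
        provenance=list(data.provenance) + [f"GPA ({iterations} iterations)"],
    )
    return ProcrustesResult(
        aligned=aligned,
        consensus=LandmarkConfiguration("consensus", consensus, data.landmark_labels),
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    """Variance-component repeatability of digitisation.

    ``repeatability`` is the intraclass correlation
    s2_among / (s2_among + s2_within) with
    s2_among = (MS_among − MS_within) / m over m sessions, clamped to
    [0, 1] (a negative component estimate means no detectable
    among-specimen variance).
    """

    ms_individual: float
    ms_session_error: float
    repeatability: float
    n_specimens: int
    m_sessions: int


def repeatability(data: ShapeDataset, session_factor: str = "session") -> RepeatabilityResult:
    """Digitising repeatability from jointly aligned repeated measurements.

    Specimens must each appear in the same number m >= 2 of digitising
    sessions and the dataset must already be jointly superimposed.  A
    one-way Procrustes ANOVA on specimen identity, summed over all 2k
    coordinates, gives MS_among and MS_within, from which the
    variance-component ratio is formed.
    """
    if not data.aligned:
        raise ValueError("repeatability requires jointly Procrustes-aligned data")
    sessions = data.factor_values(session_factor)
    if "individual" not in data.factors.table.columns:
        raise ValueError("factor table needs an 'individual' column mapping replicates")
    individuals = data.factor_values("individual")

    uniq, inverse = np.unique(individuals, return_inverse=True)
    counts = np.bincount(inverse)
    if counts.min() < 2:
        bad = uniq[counts < 2].tolist()
        raise ValueError(f"individuals with a single session: {bad}")
    if counts.min() != counts.max():
        raise ValueError("all individuals must appear in the same number of sessions")
    m = int(counts[0])
    n_spec = len(uniq)

    y = data.flatten()
    grand = y.mean(axis=0)
    means = np.zeros((n_spec, y.shape[1]))
    np.add.at(means, inverse, y)
    means /= counts[:, None]

    ss_among = float(np.sum(counts[:, None] * (means - grand) ** 2))
    ss_within = float(np.sum((y - means[inverse]) ** 2))
    ms_among = ss_among / (n_spec - 1)
    ms_within = ss_within / (n_spec * (m - 1)) if m > 1 else 0.0

    s2_among = (ms_among - ms_within) / m
    s2_within = ms_within
    total = s2_among + s2_within
    r = 0.0 if total <= 0 else s2_among / total
    r = float(min(1.0, max(0.0, r)))
    # sessions array is unused beyond validation that the factor exists;
    # balance is enforced through the per-individual counts above
    del sessions
    return RepeatabilityResult(
        ms_individual=ms_among,
        ms_session_error=ms_within,
        repeatability=r,
        n_specimens=n_spec,
        m_sessions=m,
    )
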