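"""Covariance-ratio modularity and two-block PLS (singular warps) integration.

Both tests operate on two declared landmark partitions (blocks); each
landmark contributes its x and y coordinate columns.  The covariance
ratio (CR) compares the magnitude of between-block covariances to the
within-block covariances,

    CR = sqrt( sum S12_ij^2 / sqrt( sum* S11_ij^2 * sum* S22_ij^2 ) ),

where sum* excludes diagonal entries.  Modularity (a small CR) is
tested against a null built by re-assigning whole landmarks at random
into blocks of the observed sizes.  Two-block partial least squares —
singular warps for landmark data — takes the SVD of the between-block
covariance; the correlation of the first pair of composite scores
(r-PLS) measures integration, tested by permuting specimens of one
block relative to the other.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MorphokitError, ShapeDataset, STUDY_LANDMARKS

__all__ = [
    "ModulePartition",
    "HEAD_BODY",
    "DORSAL_VENTRAL",
    "covariance_ratio",
    "cr_from_covariance",
    "modularity_test",
    "CRResult",
    "pls_two_block",
    "integration_test",
    "PLSResult",
    "population_r_pls",
]


@dataclass(frozen=True)
class ModulePartition:
    """Two disjoint landmark-label blocks (each of size >= 2)."""

    blocks: tuple[tuple[str, ...], tuple[str, ...]]
    names: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        a, b = (tuple(x) for x in self.blocks)
        object.__setattr__(self, "blocks", (a, b))
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each block needs at least two landmarks")
        if set(a) & set(b):
            raise ValueError(f"blocks overlap: {sorted(set(a) & set(b))}")

    def coordinate_columns(self, landmark_labels: tuple[str, ...]):
        """(block-A columns, block-B columns) into the flattened 2k matrix."""
        cols = []
        for block in self.blocks:
            idx = []
            for label in block:
                if label not in landmark_labels:
                    raise KeyError(
                        f"landmark {label!r} not in scheme {landmark_labels}"
                    )
                j = landmark_labels.index(label)
                idx.extend((2 * j, 2 * j + 1))
            cols.append(np.asarray(idx, dtype=np.intp))
        return cols[0], cols[1]


#: The study's first partition: head vs lower body.
HEAD_BODY = ModulePartition(
    blocks=(("rostrum", "eye", "neck"), ("mid-ventral", "spine-base", "mid-dorsal")),
    names=("head", "body"),
)

#: The study's second partition: dorsal vs ventral landmarks.
DORSAL_VENTRAL = ModulePartition(
    blocks=(("eye", "neck", "mid-dorsal"), ("rostrum", "mid-ventral", "spine-base")),
    names=("dorsal", "ventral"),
)


# ---------------------------------------------------------------------
# covariance ratio
# ---------------------------------------------------------------------

def cr_from_covariance(s: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    """CR evaluated on an explicit covariance matrix and column index sets."""
    s = np.asarray(s, dtype=float)
    s12 = s[np.ix_(idx1, idx2)]
    s11 = s[np.ix_(idx1, idx1)].copy()
    s22 = s[np.ix_(idx2, idx2)].copy()
    np.fill_diagonal(s11, 0.0)
    np.fill_diagonal(s22, 0.0)
    within = math.sqrt(float(np.sum(s11**2)) * float(np.sum(s22**2)))
    # guard against exactly-zero within-block covariation up to round-off
    scale = float(np.abs(np.diag(s)).max(initial=0.0)) * s.shape[0]
    if within <= (np.finfo(float).eps * scale) ** 2:
        raise MorphokitError(
            "zero within-block covariation: the covariance ratio is undefined"
        )
    return float(np.sqrt(np.sum(s12**2) / within))


def _data_matrix(data: ShapeDataset) -> np.ndarray:
    if not data.aligned:
        raise ValueError("modularity/integration tests require Procrustes-aligned data")
    if data.n <= 2:
        raise ValueError("need more than two specimens")
    return data.flatten()


def covariance_ratio(data: ShapeDataset, partition: ModulePartition) -> float:
    """Observed CR of the dataset under the given landmark partition."""
    y = _data_matrix(data)
    idx1, idx2 = partition.coordinate_columns(data.landmark_labels)
    s = np.cov(y, rowvar=False)
    return cr_from_covariance(s, idx1, idx2)


@dataclass
class CRResult:
    """Observed CR with its landmark-reassignment null distribution.

    p is one-tailed low (with the +1 exact-validity correction for
    sampled nulls): small CR relative to the null indicates modularity.
    effect_size is (observed - mean null) / sd null.
    """

    cr_observed: float
    null_distribution: np.ndarray = field(repr=False)
    p: float
    effect_size: float
    partition: ModulePartition
    exhaustive: bool = False


def modularity_test(
    data: ShapeDataset,
    partition: ModulePartition,
    n_permutations: int = 999,
    seed: int | None = None,
) -> CRResult:
    """CR modularity test with a landmark-reassignment null.

    Whole landmarks (x and y kept together) are re-assigned at random to
    two blocks of the observed sizes.  When the number of distinct
    assignments does not exceed the requested permutations the null is
    enumerated exhaustively (with a warning) and p is the exact
    proportion of assignments with CR at or below the observed value.
    """
    y = _data_matrix(data)
    s = np.cov(y, rowvar=False)
    labels = tuple(partition.blocks[0]) + tuple(partition.blocks[1])
    m1 = len(partition.blocks[0])
    idx1, idx2 = partition.coordinate_columns(data.landmark_labels)
    cr_obs = cr_from_covariance(s, idx1, idx2)

    def cr_of(assignment: tuple[str, ...]) -> float:
        pa = ModulePartition(
            (tuple(assignment), tuple(l for l in labels if l not in assignment))
        )
        i1, i2 = pa.coordinate_columns(data.landmark_labels)
        return cr_from_covariance(s, i1, i2)

    n_distinct = math.comb(len(labels), m1)
    if n_distinct <= n_permutations:
        warnings.warn(
            f"only {n_distinct} distinct landmark assignments exist; "
            "using exhaustive enumeration instead of sampling",
            RuntimeWarning,
        )
        null = np.array([cr_of(c) for c in itertools.combinations(labels, m1)])
        tol = 1e-12 * max(1.0, cr_obs)
        p = float(np.mean(null <= cr_obs + tol))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        labels_arr = np.array(labels)
        for b in range(n_permutations):
            pick = rng.choice(len(labels), size=m1, replace=False)
            null[b] = cr_of(tuple(labels_arr[pick]))
        p = (int(np.sum(null <= cr_obs)) + 1) / (n_permutations + 1)
        exhaustive = False
    sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    z = (cr_obs - float(null.mean())) / sd if sd > 0 else float("nan")
    return CRResult(
        cr_observed=cr_obs,
        null_distribution=null,
        p=p,
        effect_size=z,
        partition=partition,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------
# two-block PLS
# ---------------------------------------------------------------------

@dataclass
class PLSResult:
    """First singular-warp pair of a two-block PLS.

    ``r_pls`` is the absolute Pearson correlation of the first pair of
    composite scores; ``singular_vectors`` the unit-length loading
    vectors over each block's coordinates (sign fixed: the
    largest-magnitude component of the block-A vector is positive).
    ``null_distribution`` and ``p`` are populated by
    :func:`integration_test` (p one-tailed high).
    """

    r_pls: float
    singular_vectors: tuple[np.ndarray, np.ndarray]
    singular_value: float
    scores: np.ndarray = field(repr=False)
    partition: ModulePartition | None = None
    null_distribution: np.ndarray | None = field(default=None, repr=False)
    p: float | None = None
    exhaustive: bool = False


def _first_singular_pair(s12: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    u, sv, vt = np.linalg.svd(s12, full_matrices=False)
    u1, v1, s1 = u[:, 0], vt[0], float(sv[0])
    j = int(np.argmax(np.abs(u1)))
    if u1[j] < 0:
        u1, v1 = -u1, -v1
    return u1, v1, s1


def pls_two_block(data: ShapeDataset, partition: ModulePartition) -> PLSResult:
    """Observed two-block PLS (singular warps) of a landmark partition."""
    y = _data_matrix(data)
    idx1, idx2 = partition.coordinate_columns(data.landmark_labels)
    x1 = y[:, idx1] - y[:, idx1].mean(axis=0)
    x2 = y[:, idx2] - y[:, idx2].mean(axis=0)
    s12 = x1.T @ x2 / (data.n - 1)
    if not np.any(np.abs(s12) > 0):
        warnings.warn("zero cross-block covariance; r-PLS set to 0", RuntimeWarning)
        p1, p2 = x1.shape[1], x2.shape[1]
        return PLSResult(
            r_pls=0.0,
            singular_vectors=(np.zeros(p1), np.zeros(p2)),
            singular_value=0.0,
            scores=np.zeros((data.n, 2)),
            partition=partition,
        )
    u1, v1, s1 = _first_singular_pair(s12)
    xs = x1 @ u1
    ys = x2 @ v1
    r = float(np.abs(np.corrcoef(xs, ys)[0, 1]))
    return PLSResult(
        r_pls=r,
        singular_vectors=(u1, v1),
        singular_value=s1,
        scores=np.column_stack([xs, ys]),
        partition=partition,
    )


def integration_test(
    data: ShapeDataset,
    partition: ModulePartition,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PLSResult:
    """PLS integration test: permute specimens of block B against block A.

    For very small samples (n! <= requested permutations) all row
    permutations are enumerated and p is exact; otherwise p uses the
    (b + 1)/(B + 1) correction, one-tailed high (large r-PLS relative to
    the null indicates integration).
    """
    observed = pls_two_block(data, partition)
    y = _data_matrix(data)
    idx1, idx2 = partition.coordinate_columns(data.landmark_labels)
    x1 = y[:, idx1] - y[:, idx1].mean(axis=0)
    x2 = y[:, idx2] - y[:, idx2].mean(axis=0)
    n = data.n

    def r_of(perm: np.ndarray) -> float:
        x2p = x2[perm]
        s12 = x1.T @ x2p / (n - 1)
        if not np.any(np.abs(s12) > 0):
            return 0.0
        u1, v1, _ = _first_singular_pair(s12)
        c = np.corrcoef(x1 @ u1, x2p @ v1)[0, 1]
        return float(abs(c))

    exhaustive = math.factorial(n) <= n_permutations
    if exhaustive:
        null = np.array([r_of(np.array(p)) for p in itertools.permutations(range(n))])
        tol = 1e-12
        p = float(np.mean(null >= observed.r_pls - tol))
    else:
        rng = np.random.default_rng(seed)
        null = np.array([r_of(rng.permutation(n)) for _ in range(n_permutations)])
        p = (int(np.sum(null >= observed.r_pls)) + 1) / (n_permutations + 1)
    observed.null_distribution = null
    observed.p = p
    observed.exhaustive = exhaustive
    return observed


def population_r_pls(sigma: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    """Population r-PLS implied by a coordinate covariance matrix.

    The first singular pair (u1, v1) of the between-block covariance
    gives composite variables with correlation
    u1' S12 v1 / sqrt(u1' S11 u1 * v1' S22 v1).
    """
    sigma = np.asarray(sigma, dtype=float)
    s12 = sigma[np.ix_(idx1, idx2)]
    if not np.any(np.abs(s12) > 0):
        return 0.0
    u1, v1, _ = _first_singular_pair(s12)
    s11 = sigma[np.ix_(idx1, idx1)]
    s22 = sigma[np.ix_(idx2, idx2)]
    num = float(u1 @ s12 @ v1)
    den = math.sqrt(float(u1 @ s11 @ u1) * float(v1 @ s22 @ v1))
    return float(abs(num) / den)
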