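"""Synthetic landmark data with the study's factorial structure.

The generator emulates the statistical structure the analyses assume: a
stylized six-landmark *Daphnia* outline; a 3 clones x 2 instars x 6
predation-risk-levels factorial design with 4-20 replicates per cell;
risk-dependent displacement of the neck landmark (the inducible
defence); clone-specific response directions and gains in shape space;
correlated within-cell landmark noise with a controllable modular block
structure; independent digitisation noise; and per-specimen nuisance
rotation / translation / scale so the raw output exercises Procrustes
superimposition.  Every dataset ships with its :class:`GroundTruth`
(true cell means, trajectory path distances and angles, and closed-form
population values of the covariance ratio and r-PLS) so parameter
recovery is directly testable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FactorTable,
    LandmarkConfiguration,
    MorphokitError,
    RISK_LEVELS,
    STUDY_LANDMARKS,
    ShapeDataset,
)
from .modularity import HEAD_BODY, ModulePartition, cr_from_covariance, population_r_pls
from .trajectory import Trajectory, path_distance, trajectory_angle

__all__ = [
    "BASE_SHAPE",
    "CloneSpec",
    "BlockCovariance",
    "NuisanceSpec",
    "SimulationSpec",
    "GroundTruth",
    "default_spec",
    "simulate",
    "simulate_digitising_sessions",
    "closed_form_cr",
    "closed_form_r_pls",
    "displacement_pattern",
    "angled_clone_pair",
    "unbalanced_replicates",
]


#: Stylized lateral Daphnia outline (head at the top, facing left), in
#: arbitrary image-like units.  Carries no claim of matching real
#: specimens; it only fixes a non-degenerate, non-collinear geometry.
BASE_SHAPE = LandmarkConfiguration(
    specimen_id="base",
    coords=np.array(
        [
            [-0.10, 0.95],  # eye
            [0.16, 0.88],  # neck (inducible-defence region)
            [0.42, 0.10],  # mid-dorsal
            [0.05, -0.95],  # spine-base
            [-0.40, 0.05],  # mid-ventral
            [-0.28, 0.72],  # rostrum
        ]
    ),
    landmark_labels=STUDY_LANDMARKS,
)


def displacement_pattern(kind: str, base: LandmarkConfiguration = BASE_SHAPE) -> np.ndarray:
    """Unit displacement field (2k,) for a named shape change.

    ``neck``: the neck landmark moves radially outward from the centroid
    (neck pedestal growth).  ``head-height``: eye and rostrum move up.
    ``bulge``: the mid-ventral landmark moves outward (carapace bulge).
    ``elongation``: all landmarks stretch along y relative to the centroid.

    The raw field is projected into the tangent space of the base shape
    (components along pure translation, scaling and rotation removed)
    before normalisation, so the pattern is a pure *shape* direction:
    angles and distances built from these fields survive Procrustes
    superimposition.  The nominal landmark still dominates the field;
    the other landmarks pick up the small compensating shifts that any
    pure shape change entails.
    """
    coords = base.coords
    centroid = coords.mean(axis=0)
    field_ = np.zeros_like(coords)
    if kind == "neck":
        j = base.landmark_labels.index("neck")
        v = coords[j] - centroid
        field_[j] = v / np.linalg.norm(v)
    elif kind == "head-height":
        for label in ("eye", "rostrum"):
            field_[base.landmark_labels.index(label)] = (0.0, 1.0)
    elif kind == "bulge":
        j = base.landmark_labels.index("mid-ventral")
        v = coords[j] - centroid
        field_[j] = v / np.linalg.norm(v)
    elif kind == "elongation":
        field_[:, 1] = coords[:, 1] - centroid[1]
    else:
        raise ValueError(f"unknown displacement pattern {kind!r}")
    flat = field_.reshape(-1)
    k = coords.shape[0]
    centered = coords - centroid
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    scale_dir = centered.reshape(-1)
    rot_dir = np.column_stack([-centered[:, 1], centered[:, 0]]).reshape(-1)
    q, _ = np.linalg.qr(np.column_stack([tx, ty, scale_dir, rot_dir]))
    flat = flat - q @ (q.T @ flat)
    norm = np.linalg.norm(flat)
    if norm == 0:
        raise ValueError(f"pattern {kind!r} vanishes after tangent projection")
    return flat / norm


@dataclass(frozen=True)
class CloneSpec:
    """One clone's response: a unit direction in shape space and a gain."""

    name: str
    gain: float
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("clone direction must be non-zero")
        object.__setattr__(self, "direction", d / norm)


@dataclass(frozen=True)
class BlockCovariance:
    """Modular coordinate covariance: equal variance, block correlations.

    Correlation is ``rho_within`` between coordinates whose landmarks
    share a module and ``rho_between`` across modules; the implied
    matrix must be positive semi-definite (checked at construction
    time via :meth:`matrix`).
    """

    partition: ModulePartition
    sigma: float = 0.02
    rho_within: float = 0.6
    rho_between: float = 0.3

    def matrix(self, landmark_labels: Sequence[str] = STUDY_LANDMARKS) -> np.ndarray:
        labels = tuple(landmark_labels)
        idx1, idx2 = self.partition.coordinate_columns(labels)
        p = 2 * len(labels)
        member = np.full(p, -1)
        member[idx1] = 0
        member[idx2] = 1
        if np.any(member < 0):
            raise ValueError("covariance partition must cover every landmark")
        same = member[:, None] == member[None, :]
        corr = np.where(same, self.rho_within, self.rho_between)
        np.fill_diagonal(corr, 1.0)
        sigma2 = self.sigma**2 * corr
        eigmin = float(np.linalg.eigvalsh(sigma2).min())
        if eigmin < -1e-10 * self.sigma**2:
            raise ValueError(
                f"implied covariance is not positive semi-definite (min eig {eigmin:.3g})"
            )
        return sigma2


@dataclass(frozen=True)
class NuisanceSpec:
    """Per-specimen rigid + scale nuisance applied to the raw output."""

    rotation: tuple[float, float] = (-math.pi, math.pi)
    translation: tuple[float, float] = (-2.0, 2.0)
    scale: tuple[float, float] = (0.75, 1.35)


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic study.

    Defaults reproduce the study's design: 3 clones x 2 instars x 6 risk
    levels with 12 replicates per cell (the midpoint of the study's
    4-20 range), a linear response in risk, modular head/body noise and
    photo-like nuisance transforms.  ``response`` may be ``linear`` or
    ``saturating`` (risk / (risk + 0.25), normalised to 1 at full risk).
    """

    base_shape: LandmarkConfiguration = field(default_factory=lambda: BASE_SHAPE)
    risk_levels: tuple[float, ...] = RISK_LEVELS
    instars: tuple[int, ...] = (2, 3)
    clones: tuple[CloneSpec, ...] = ()
    instar_offset: np.ndarray | None = None
    neck_gain: float = 0.08
    covariance: BlockCovariance | None = None
    replicates: int | Mapping[tuple, int] = 12
    digitisation_noise_sd: float = 0.0055
    nuisance: NuisanceSpec | None = NuisanceSpec()
    response: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.clones:
            object.__setattr__(self, "clones", _default_clones())
        if self.covariance is None:
            object.__setattr__(self, "covariance", BlockCovariance(HEAD_BODY))
        if self.instar_offset is None:
            object.__setattr__(
                self, "instar_offset", 0.04 * displacement_pattern("elongation", self.base_shape)
            )
        if self.response not in ("linear", "saturating"):
            raise ValueError(f"response must be 'linear' or 'saturating', got {self.response!r}")
        # validate PSD and replicate counts up front, not at sampling time
        self.covariance.matrix(self.base_shape.landmark_labels)
        for cell in self._cells():
            if self._reps(cell) < 1:
                raise ValueError(f"cell {cell} has fewer than one replicate")

    def _cells(self):
        return list(
            itertools.product(
                [c.name for c in self.clones], self.instars, self.risk_levels
            )
        )

    def _reps(self, cell: tuple) -> int:
        if isinstance(self.replicates, Mapping):
            return int(self.replicates[cell])
        return int(self.replicates)

    def response_value(self, risk: float) -> float:
        top_risk = float(max(self.risk_levels))
        if top_risk == 0.0:
            return 0.0
        if self.response == "linear":
            return float(risk) / top_risk
        h = 0.25
        top = max(self.risk_levels) / (max(self.risk_levels) + h)
        return (risk / (risk + h)) / top

    def cell_mean(self, clone: CloneSpec, instar: int, risk: float) -> np.ndarray:
        """True (noise-free) flattened mean shape of one design cell."""
        mean = self.base_shape.coords.reshape(-1).copy()
        if instar == self.instars[-1]:
            mean = mean + self.instar_offset
        f = self.response_value(risk)
        mean = mean + clone.gain * f * clone.direction
        mean = mean + self.neck_gain * risk * displacement_pattern("neck", self.base_shape)
        return mean


def _default_clones() -> tuple[CloneSpec, ...]:
    neck = displacement_pattern("neck")
    head = displacement_pattern("head-height")
    bulge = displacement_pattern("bulge")
    # One strongly inducible clone and two weak ones, the weak pair
    # differing in direction (one recruits the carapace bulge), mirroring
    # the study's high/low-induction clone contrast.
    return (
        CloneSpec("Carlos", gain=0.06, direction=0.9 * neck + 0.44 * head),
        CloneSpec("Chardonnay", gain=0.03, direction=0.8 * neck + 0.6 * head),
        CloneSpec("Cletus", gain=0.03, direction=0.6 * neck + 0.8 * bulge),
    )


def default_spec(**overrides) -> SimulationSpec:
    """The study-design simulation spec, with keyword overrides."""
    return replace(SimulationSpec(), **overrides) if overrides else SimulationSpec()


def unbalanced_replicates(spec: SimulationSpec, seed: int = 0) -> dict[tuple, int]:
    """Per-cell replicate counts drawn uniformly from the study's 4-20 range."""
    rng = np.random.default_rng(seed)
    return {cell: int(rng.integers(4, 21)) for cell in spec._cells()}


@dataclass
class GroundTruth:
    """Deterministic truth derived from a :class:`SimulationSpec`.

    Trajectory quantities are computed on instar-averaged true cell
    means.  ``cr`` and ``r_pls`` are population values of the covariance
    ratio and PLS correlation implied by the noise covariance (under the
    spec's own partition).
    """

    cell_means: dict[tuple, np.ndarray] = field(repr=False)
    trajectories: dict[str, Trajectory] = field(repr=False)
    path_distances: dict[str, float]
    pairwise_angles: dict[tuple[str, str], float]
    cr: float
    r_pls: float
    covariance: np.ndarray = field(repr=False)
    base_centroid_size: float = float("nan")

    def path_distances_procrustes(self) -> dict[str, float]:
        """True path distances on the unit-centroid-size Procrustes scale.

        Raw-unit path distances divide by the base shape's centroid
        size, matching (to first order in the small shape changes) the
        scale of trajectories estimated from superimposed data.
        """
        return {k: v / self.base_centroid_size for k, v in self.path_distances.items()}


def _ground_truth(spec: SimulationSpec) -> GroundTruth:
    cell_means = {
        (c.name, instar, risk): spec.cell_mean(c, instar, risk)
        for c in spec.clones
        for instar in spec.instars
        for risk in spec.risk_levels
    }
    trajectories: dict[str, Trajectory] = {}
    pds: dict[str, float] = {}
    angles: dict[tuple[str, str], float] = {}
    if len(spec.risk_levels) >= 2:
        for c in spec.clones:
            pts = np.array(
                [
                    np.mean([cell_means[(c.name, i, r)] for i in spec.instars], axis=0)
                    for r in spec.risk_levels
                ]
            )
            trajectories[c.name] = Trajectory(
                group=c.name, points=pts, levels=spec.risk_levels
            )
        pds = {name: path_distance(t) for name, t in trajectories.items()}
        for a, b in itertools.combinations(sorted(trajectories), 2):
            angles[(a, b)] = trajectory_angle(trajectories[a], trajectories[b])
    sigma = spec.covariance.matrix(spec.base_shape.landmark_labels)
    idx1, idx2 = spec.covariance.partition.coordinate_columns(spec.base_shape.landmark_labels)
    try:
        cr = cr_from_covariance(sigma, idx1, idx2)
    except MorphokitError:
        cr = float("nan")  # diagonal noise: no within-block covariation
    return GroundTruth(
        cell_means=cell_means,
        trajectories=trajectories,
        path_distances=pds,
        pairwise_angles=angles,
        cr=cr,
        r_pls=population_r_pls(sigma, idx1, idx2),
        covariance=sigma,
        base_centroid_size=float(
            np.linalg.norm(
                spec.base_shape.coords - spec.base_shape.coords.mean(axis=0)
            )
        ),
    )


def closed_form_cr(spec: SimulationSpec, partition: ModulePartition) -> float:
    """Population CR of the spec's noise covariance under *partition*."""
    sigma = spec.covariance.matrix(spec.base_shape.landmark_labels)
    idx1, idx2 = partition.coordinate_columns(spec.base_shape.landmark_labels)
    return cr_from_covariance(sigma, idx1, idx2)


def closed_form_r_pls(spec: SimulationSpec, partition: ModulePartition) -> float:
    """Population r-PLS of the spec's noise covariance under *partition*."""
    sigma = spec.covariance.matrix(spec.base_shape.landmark_labels)
    idx1, idx2 = partition.coordinate_columns(spec.base_shape.landmark_labels)
    return population_r_pls(sigma, idx1, idx2)


def _psd_factor(sigma: np.ndarray) -> np.ndarray:
    """Exact factor L with L L' = sigma for any PSD matrix (zero included)."""
    if not np.any(sigma):
        return np.zeros_like(sigma)
    w, v = np.linalg.eigh(sigma)
    return v * np.sqrt(np.clip(w, 0.0, None))


def _apply_nuisance(coords: np.ndarray, nuisance: NuisanceSpec, rng: np.random.Generator):
    theta = rng.uniform(*nuisance.rotation)
    scale = rng.uniform(*nuisance.scale)
    shift = rng.uniform(*nuisance.translation, size=2)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    return scale * coords @ rot + shift


def simulate(
    spec: SimulationSpec, seed: int | None = None
) -> tuple[ShapeDataset, GroundTruth]:
    """Draw one synthetic study dataset (raw, un-superimposed).

    Specimens are their cell mean plus correlated modular noise plus
    independent digitisation noise, then rotated/translated/scaled per
    specimen when nuisance is enabled.  Deterministic for a given seed
    (``seed`` overrides ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truth = _ground_truth(spec)
    chol = _psd_factor(truth.covariance)
    k = spec.base_shape.k

    coords, ids, rows = [], [], []
    for cell in spec._cells():
        clone, instar, risk = cell
        mean = truth.cell_means[cell]
        for rep in range(spec._reps(cell)):
            vec = mean + chol @ rng.standard_normal(2 * k)
            if spec.digitisation_noise_sd > 0:
                vec = vec + rng.normal(0.0, spec.digitisation_noise_sd, size=2 * k)
            xy = vec.reshape(k, 2)
            if spec.nuisance is not None:
                xy = _apply_nuisance(xy, spec.nuisance, rng)
            sid = f"{clone}-i{instar}-r{risk:g}-{rep + 1}"
            coords.append(xy)
            ids.append(sid)
            rows.append({"specimen": sid, "clone": clone, "instar": instar, "risk": risk})

    factors = FactorTable(pd.DataFrame(rows), risk_levels=spec.risk_levels)
    data = ShapeDataset(
        coords=np.stack(coords),
        specimen_ids=tuple(ids),
        landmark_labels=spec.base_shape.landmark_labels,
        factors=factors,
        provenance=[f"simulated ({len(ids)} specimens, seed={spec.seed if seed is None else seed})"],
    )
    return data, truth


def simulate_digitising_sessions(
    spec: SimulationSpec, m_sessions: int = 2, seed: int | None = None
) -> tuple[ShapeDataset, GroundTruth]:
    """Each simulated photo digitised in m independent sessions.

    The specimen (photo) — biological shape plus nuisance — is fixed;
    each session re-adds independent digitisation noise, emulating
    repeated manual landmark placement on the same image.  The factor
    table carries ``individual`` and ``session`` columns for
    :func:`morphokit.gpa.repeatability`.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    base = replace(spec, digitisation_noise_sd=0.0)
    truth = _ground_truth(base)
    chol = _psd_factor(truth.covariance)
    k = spec.base_shape.k

    coords, ids, rows = [], [], []
    for cell in spec._cells():
        clone, instar, risk = cell
        mean = truth.cell_means[cell]
        for rep in range(spec._reps(cell)):
            vec = mean + chol @ rng.standard_normal(2 * k)
            xy = vec.reshape(k, 2)
            if spec.nuisance is not None:
                xy = _apply_nuisance(xy, spec.nuisance, rng)
            indiv = f"{clone}-i{instar}-r{risk:g}-{rep + 1}"
            for session in range(1, m_sessions + 1):
                noisy = xy + rng.normal(0.0, spec.digitisation_noise_sd, size=(k, 2))
                sid = f"{indiv}-s{session}"
                coords.append(noisy)
                ids.append(sid)
                rows.append(
                    {
                        "specimen": sid,
                        "clone": clone,
                        "instar": instar,
                        "risk": risk,
                        "session": session,
                        "individual": indiv,
                    }
                )
    factors = FactorTable(pd.DataFrame(rows), risk_levels=spec.risk_levels)
    data = ShapeDataset(
        coords=np.stack(coords),
        specimen_ids=tuple(ids),
        landmark_labels=spec.base_shape.landmark_labels,
        factors=factors,
        provenance=[f"simulated, {m_sessions} digitising sessions"],
    )
    return data, truth


def angled_clone_pair(theta_deg: float, gain: float = 0.05) -> tuple[CloneSpec, CloneSpec]:
    """Two clones whose true trajectory directions differ by exactly theta.

    Built in the plane spanned by orthonormalised neck and head-height
    displacement fields; combine with ``neck_gain=0`` so the shared risk
    term does not tilt the directions.
    """
    e1 = displacement_pattern("neck")
    h = displacement_pattern("head-height")
    e2 = h - (h @ e1) * e1
    e2 /= np.linalg.norm(e2)
    t = math.radians(theta_deg)
    return (
        CloneSpec("A", gain=gain, direction=e1),
        CloneSpec("B", gain=gain, direction=math.cos(t) * e1 + math.sin(t) * e2),
    )
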