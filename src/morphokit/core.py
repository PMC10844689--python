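"""Core containers for 2-D landmark data.

A *landmark configuration* is an ordered set of k anatomical (x, y)
coordinates digitised on one specimen.  A :class:`ShapeDataset` stacks n
configurations that share a landmark scheme, together with per-specimen
factors (clone, instar, predation-risk level, digitising session) and,
after superimposition, centroid sizes.

The default landmark scheme is the six-point lateral *Daphnia pulex*
outline: eye centre, neck (inducible-defence region), dorsal midpoint of
the carapace, base of the apical spine, ventral midpoint, and rostrum.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Study landmark labels in digitising order (1-6).
STUDY_LANDMARKS: tuple[str, ...] = (
    "eye",
    "neck",
    "mid-dorsal",
    "spine-base",
    "mid-ventral",
    "rostrum",
)

#: Ordered predation-risk levels (volume of Chaoborus kairomone extract,
#: microlitre per millilitre) used in the factorial design.
RISK_LEVELS: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0)

#: Factor columns recognised as categorical design factors.
CATEGORICAL_FACTORS = ("clone", "instar", "risk", "session")


class MorphokitError(Exception):
    """Base class for all package errors."""


class ParseError(MorphokitError):
    """Malformed landmark or factor file."""


class DegenerateConfigurationError(MorphokitError):
    """All landmarks coincident (size zero) or otherwise unusable."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmarks.

    Parameters
    ----------
    specimen_id:
        Unique identifier of the specimen (photo).
    coords:
        ``(k, 2)`` array of (x, y) pairs, image units (pixels) for raw
        data or dimensionless Procrustes units after superimposition.
    landmark_labels:
        Ordered semantic labels, length k.  Defaults to the study scheme
        when k == 6, otherwise ``lm1..lmk``.
    """

    specimen_id: str
    coords: np.ndarray
    landmark_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coords must be (k, 2); got shape {self.coords.shape}"
            )
        k = self.coords.shape[0]
        if k < 3:
            raise ValueError(f"need at least 3 landmarks, got {k}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinate in specimen {self.specimen_id!r}")
        if not self.landmark_labels:
            self.landmark_labels = (
                STUDY_LANDMARKS if k == len(STUDY_LANDMARKS) else tuple(f"lm{i + 1}" for i in range(k))
            )
        self.landmark_labels = tuple(self.landmark_labels)
        if len(self.landmark_labels) != k:
            raise ValueError(
                f"{len(self.landmark_labels)} labels for {k} landmarks "
                f"(specimen {self.specimen_id!r})"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def flatten(self) -> np.ndarray:
        """Row-major (x1, y1, x2, y2, ...) vector of length 2k."""
        return self.coords.reshape(-1)


class FactorTable:
    """Per-specimen design factors.

    Wraps a :class:`pandas.DataFrame` indexed by specimen id with any of
    the columns ``clone`` (categorical), ``instar`` (categorical, {2, 3}
    in the study), ``risk`` (ordered numeric level) and ``session``
    (digitising session, for repeatability designs).  Exactly one row
    per specimen; risk values must come from the declared ordered set.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        risk_levels: Sequence[float] = RISK_LEVELS,
    ) -> None:
        table = table.copy()
        if "specimen" in table.columns:
            table = table.set_index("specimen")
        table.index = table.index.astype(str)
        if table.index.has_duplicates:
            dupes = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate factor rows for specimens {dupes}")
        if "risk" in table.columns:
            risk = pd.to_numeric(table["risk"])
            declared = np.asarray(sorted(risk_levels), dtype=float)
            bad = sorted(set(np.round(risk, 12)) - set(np.round(declared, 12)))
            if bad:
                raise ValueError(
                    f"risk levels {bad} not in declared set {list(declared)}"
                )
            table["risk"] = risk.astype(float)
        self.table = table
        self.risk_levels = tuple(sorted(float(r) for r in risk_levels))

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, specimen_id: str) -> bool:
        return str(specimen_id) in self.table.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FactorTable):
            return NotImplemented
        mine = self.table.sort_index().sort_index(axis=1)
        theirs = other.table.sort_index().sort_index(axis=1)
        return mine.equals(theirs) and self.risk_levels == other.risk_levels

    def level_order(self, factor: str) -> list:
        """Declared ordering of a factor's levels (risk: numeric ascending)."""
        if factor == "risk":
            present = set(self.table["risk"])
            return [r for r in self.risk_levels if r in present]
        return sorted(self.table[factor].unique().tolist())


@dataclass
class ShapeDataset:
    """n stacked landmark configurations sharing one landmark scheme.

    ``coords`` is ``(n, k, 2)``.  ``centroid_sizes`` is populated by
    superimposition (the sizes removed from each raw configuration);
    ``aligned`` marks Procrustes shape coordinates.
    """

    coords: np.ndarray
    specimen_ids: tuple[str, ...]
    landmark_labels: tuple[str, ...] = ()
    factors: FactorTable | None = None
    centroid_sizes: np.ndarray | None = None
    aligned: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError(f"coords must be (n, k, 2); got {self.coords.shape}")
        n, k, _ = self.coords.shape
        if n < 1:
            raise ValueError("dataset needs at least one configuration")
        self.specimen_ids = tuple(str(s) for s in self.specimen_ids)
        if len(self.specimen_ids) != n:
            raise ValueError("one specimen id per configuration required")
        if len(set(self.specimen_ids)) != n:
            seen: set[str] = set()
            dupes = [s for s in self.specimen_ids if s in seen or seen.add(s)]
            raise ValueError(f"duplicate specimen ids: {sorted(set(dupes))}")
        if not self.landmark_labels:
            self.landmark_labels = (
                STUDY_LANDMARKS if k == len(STUDY_LANDMARKS) else tuple(f"lm{i + 1}" for i in range(k))
            )
        self.landmark_labels = tuple(self.landmark_labels)
        if len(self.landmark_labels) != k:
            raise ValueError("landmark_labels length must equal k")
        if self.centroid_sizes is not None:
            self.centroid_sizes = np.asarray(self.centroid_sizes, dtype=float)
            if self.centroid_sizes.shape != (n,):
                raise ValueError("centroid_sizes must have one entry per specimen")

    # -- construction -------------------------------------------------
    @classmethod
    def from_configurations(
        cls, configurations: Iterable[LandmarkConfiguration], **kwargs
    ) -> "ShapeDataset":
        configs = list(configurations)
        if not configs:
            raise ValueError("empty configuration list")
        k = configs[0].k
        labels = configs[0].landmark_labels
        for c in configs[1:]:
            if c.k != k or c.landmark_labels != labels:
                raise ValueError(
                    f"specimen {c.specimen_id!r} does not share the landmark scheme"
                )
        return cls(
            coords=np.stack([c.coords for c in configs]),
            specimen_ids=tuple(c.specimen_id for c in configs),
            landmark_labels=labels,
            **kwargs,
        )

    # -- basic views ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def configuration(self, specimen_id: str) -> LandmarkConfiguration:
        i = self.index_of(specimen_id)
        return LandmarkConfiguration(
            specimen_id=self.specimen_ids[i],
            coords=self.coords[i].copy(),
            landmark_labels=self.landmark_labels,
        )

    def configurations(self) -> list[LandmarkConfiguration]:
        return [self.configuration(s) for s in self.specimen_ids]

    def index_of(self, specimen_id: str) -> int:
        try:
            return self.specimen_ids.index(str(specimen_id))
        except ValueError:
            raise KeyError(f"unknown specimen id {specimen_id!r}") from None

    def landmark_index(self, label: str) -> int:
        try:
            return self.landmark_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown landmark label {label!r}; scheme is {self.landmark_labels}"
            ) from None

    def flatten(self) -> np.ndarray:
        """(n, 2k) row-major coordinate matrix (x1, y1, ..., xk, yk)."""
        return self.coords.reshape(self.n, -1)

    def copy(self) -> "ShapeDataset":
        return ShapeDataset(
            coords=self.coords.copy(),
            specimen_ids=self.specimen_ids,
            landmark_labels=self.landmark_labels,
            factors=_copy.deepcopy(self.factors),
            centroid_sizes=None if self.centroid_sizes is None else self.centroid_sizes.copy(),
            aligned=self.aligned,
            provenance=list(self.provenance),
        )

    # -- factors -------------------------------------------------------
    def factor_values(self, factor: str) -> np.ndarray:
        """Factor levels aligned with specimen order."""
        if self.factors is None:
            raise ValueError("dataset has no attached factor table")
        if factor not in self.factors.table.columns:
            raise KeyError(f"no factor {factor!r} in the factor table")
        return self.factors.table.loc[list(self.specimen_ids), factor].to_numpy()

    def cell_counts(self, factors: Sequence[str] = ("clone", "instar", "risk")) -> pd.Series:
        """Replicate count per design cell over the given factors."""
        if self.factors is None:
            raise ValueError("dataset has no attached factor table")
        cols = {f: self.factor_values(f) for f in factors}
        frame = pd.DataFrame(cols, index=list(self.specimen_ids))
        return frame.groupby(list(factors), observed=True).size()


def attach_factors(data: ShapeDataset, factors: FactorTable | pd.DataFrame) -> ShapeDataset:
    """Return a copy of *data* carrying the factor table.

    Every specimen must have exactly one factor row; extra factor rows
    for specimens absent from the dataset are dropped.  Attachment is
    insensitive to factor-row ordering.
    """
    if isinstance(factors, pd.DataFrame):
        factors = FactorTable(factors)
    missing = [s for s in data.specimen_ids if s not in factors]
    if missing:
        raise ValueError(f"factor table is missing specimens {missing}")
    out = data.copy()
    out.factors = FactorTable(
        factors.table.loc[list(data.specimen_ids)], risk_levels=factors.risk_levels
    )
    out.provenance.append(f"attached factors ({len(out.factors)} rows)")
    return out


def mirror_configurations(
    data: ShapeDataset, axis: str, which: Iterable[str]
) -> ShapeDataset:
    """Reflect selected specimens about a coordinate axis.

    ``axis='horizontal'`` negates x (mirror about the vertical line
    x = 0, i.e. a left/right flip); ``axis='vertical'`` negates y.  Used
    at ingest so all animals face the same direction — downstream
    superimposition deliberately excludes reflections.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    which = [str(s) for s in which]
    out = data.copy()
    col = 0 if axis == "horizontal" else 1
    for s in which:
        i = out.index_of(s)  # raises KeyError on unknown id
        out.coords[i, :, col] *= -1.0
    out.provenance.append(f"mirrored {len(which)} specimens ({axis})")
    return out
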