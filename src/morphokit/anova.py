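"""Procrustes ANOVA by residual randomization (RRPP).

The response is the n x 2k matrix of Procrustes-aligned coordinates.
Sums of squares are sequential (type I): each term's SS is the drop in
residual sum of squares (trace of the residual cross-product) when the
term is added to the model built from all preceding terms.  Significance
uses residual randomization in a permutation procedure: for each term,
the residuals of its reduced model are randomly re-assigned to
specimens, the term SS recomputed, and

    p = (b + 1) / (B + 1),   b = #{permuted SS >= observed SS},

with the effect size Z reported as the standard-normal deviate of the
observed SS within the permuted distribution.

Predation risk enters as a categorical factor with its declared level
ordering; centroid size enters as a numeric covariate under a selectable
variant (cs, cs-squared, log-cs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CATEGORICAL_FACTORS, ShapeDataset

__all__ = ["ModelSpec", "AnovaTable", "procrustes_anova", "fit_lsmeans", "LSMeans"]

DEFAULT_TERMS = ("size", "instar", "clone", "risk", "risk:instar", "risk:clone")


@dataclass
class ModelSpec:
    """Sequential (type I) model specification for Procrustes ANOVA.

    ``terms`` are factor/covariate names and ``a:b`` interactions, fitted
    in order.  ``size_variant`` selects how centroid size enters the
    model.  ``exhaustive=True`` replaces the ``n_permutations`` random
    residual assignments by full enumeration of all n! assignments
    (small n only).
    """

    terms: tuple[str, ...] = DEFAULT_TERMS
    n_permutations: int = 10_000
    seed: int | None = None
    size_variant: str = "cs"
    exhaustive: bool = False

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        declared = set()
        for t in self.terms:
            if ":" in t:
                for part in t.split(":"):
                    if part not in declared:
                        raise ValueError(
                            f"interaction {t!r} references undeclared main effect {part!r}"
                        )
            declared.add(t)


@dataclass
class AnovaTable:
    """Per-term df / SS / MS / R-squared / F / Z / p plus residual and total rows."""

    table: pd.DataFrame
    n_permutations: int
    seed: int | None = None
    null_ss: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.6g}")


# ---------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------

def _is_categorical(name: str, values: np.ndarray) -> bool:
    if name in CATEGORICAL_FACTORS:
        return True
    return not np.issubdtype(np.asarray(values).dtype, np.number)


def _contrast_columns(data: ShapeDataset, name: str, size_values: np.ndarray | None):
    """Expand one main effect into its design columns (treatment coding)."""
    if name == "size":
        if size_values is None:
            raise ValueError("model includes 'size' but no centroid sizes are available")
        return size_values[:, None].astype(float)
    values = data.factor_values(name)
    if _is_categorical(name, values):
        levels = (
            data.factors.level_order(name)
            if name == "risk"
            else sorted(pd.unique(values).tolist())
        )
        cols = [(values == lev).astype(float) for lev in levels[1:]]
        return np.column_stack(cols) if cols else np.empty((data.n, 0))
    return np.asarray(values, dtype=float)[:, None]


def term_columns(
    data: ShapeDataset, terms: Sequence[str], size_values: np.ndarray | None = None
) -> list[tuple[str, np.ndarray]]:
    """Design-column blocks per term; interactions are products of contrasts."""
    mains: dict[str, np.ndarray] = {}
    blocks: list[tuple[str, np.ndarray]] = []
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            cols = mains[parts[0]]
            for part in parts[1:]:
                cols = np.einsum("ni,nj->nij", cols, mains[part]).reshape(len(cols), -1)
        else:
            cols = _contrast_columns(data, term, size_values)
            mains[term] = cols
        blocks.append((term, cols))
    return blocks


def _orth_increment(q_prev: np.ndarray | None, block: np.ndarray, tol: float = 1e-9):
    """Orthonormal basis of the span added by *block* beyond q_prev."""
    b = block.astype(float)
    if q_prev is not None and q_prev.shape[1]:
        b = b - q_prev @ (q_prev.T @ b)
    if b.size == 0:
        return np.empty((block.shape[0], 0))
    q, r = np.linalg.qr(b)
    keep = np.abs(np.diag(r)) > tol * max(1.0, np.abs(r).max())
    return q[:, keep]


def nested_bases(n: int, blocks: list[tuple[str, np.ndarray]]):
    """Cumulative orthonormal bases for intercept + each term in sequence.

    Returns ``(q_list, deltas)`` where ``q_list[i]`` spans the model
    through term i-1 (``q_list[0]`` is the intercept) and ``deltas[i]``
    is the orthonormal increment contributed by term i.
    """
    q = np.full((n, 1), 1.0 / math.sqrt(n))
    q_list = [q]
    deltas = []
    for name, block in blocks:
        d = _orth_increment(q, block)
        if d.shape[1] == 0:
            raise ValueError(
                f"term {name!r} is aliased with preceding terms (rank-deficient design)"
            )
        q = np.column_stack([q, d])
        deltas.append(d)
        q_list.append(q)
    return q_list, deltas


def _permutation_indices(
    n: int, n_permutations: int, seed: int | None, exhaustive: bool
) -> np.ndarray:
    if exhaustive:
        return np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_permutations)], dtype=np.intp)


# ---------------------------------------------------------------------
# the ANOVA itself
# ---------------------------------------------------------------------

def procrustes_anova(data: ShapeDataset, model: ModelSpec | None = None) -> AnovaTable:
    """Sequential Procrustes ANOVA with RRPP significance.

    See the module docstring for the decomposition and the permutation
    scheme.  With ``model.exhaustive`` the permutation p-values are exact
    over all n! residual assignments (the identity assignment included),
    matching a brute-force enumeration oracle.
    """
    if not data.aligned:
        raise ValueError("Procrustes ANOVA requires Procrustes-aligned data")
    model = model or ModelSpec()
    y = data.flatten()
    n = data.n

    size_values = None
    if "size" in model.terms:
        if data.centroid_sizes is None:
            raise ValueError("dataset has no centroid sizes; run GPA first")
        cs = data.centroid_sizes
        size_values = {
            "cs": cs,
            "cs-squared": cs**2,
            "log-cs": np.log(cs),
        }[model.size_variant]

    blocks = term_columns(data, model.terms, size_values)
    q_list, deltas = nested_bases(n, blocks)
    q_full = q_list[-1]
    df_model = q_full.shape[1]
    if n <= df_model:
        raise ValueError(f"n = {n} does not exceed model df = {df_model}")

    grand = y.mean(axis=0)
    ss_total = float(np.sum((y - grand) ** 2))
    resid_full = y - q_full @ (q_full.T @ y)
    ss_res = float(np.sum(resid_full**2))
    df_res = n - df_model

    perms = _permutation_indices(n, model.n_permutations, model.seed, model.exhaustive)
    n_perm = perms.shape[0]

    rows = []
    null_ss: dict[str, np.ndarray] = {}
    for i, (name, _) in enumerate(blocks):
        q_red = q_list[i]
        delta = deltas[i]
        df_i = delta.shape[1]
        ss_obs = float(np.sum((delta.T @ y) ** 2))
        # reduced-model residuals for this term's RRPP null
        resid_red = y - q_red @ (q_red.T @ y)
        # SS under a permuted residual assignment: the reduced-model fitted
        # values are invariant under the added subspace, so only the
        # permuted residuals contribute.
        ss_null = np.empty(n_perm)
        chunk = max(1, int(2e7 // (n * y.shape[1])))
        for start in range(0, n_perm, chunk):
            sel = perms[start : start + chunk]
            rp = resid_red[sel]  # (c, n, p)
            proj = np.einsum("nd,cnp->cdp", delta, rp)
            ss_null[start : start + chunk] = np.sum(proj**2, axis=(1, 2))
        if model.exhaustive:
            p = float(np.mean(ss_null >= ss_obs - 1e-12 * max(1.0, ss_obs)))
        else:
            b = int(np.sum(ss_null >= ss_obs))
            p = (b + 1) / (n_perm + 1)
        sd = float(ss_null.std(ddof=1)) if n_perm > 1 else 0.0
        z = (ss_obs - float(ss_null.mean())) / sd if sd > 0 else np.nan
        ms = ss_obs / df_i
        f = (ss_obs / df_i) / (ss_res / df_res) if df_res > 0 else np.inf
        rows.append(
            {
                "term": name,
                "df": df_i,
                "SS": ss_obs,
                "MS": ms,
                "Rsq": ss_obs / ss_total if ss_total > 0 else np.nan,
                "F": f,
                "Z": z,
                "p": p,
            }
        )
        null_ss[name] = ss_null

    rows.append(
        {
            "term": "Residuals",
            "df": df_res,
            "SS": ss_res,
            "MS": ss_res / df_res if df_res else np.nan,
            "Rsq": ss_res / ss_total if ss_total > 0 else np.nan,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "MS": np.nan,
            "Rsq": 1.0,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return AnovaTable(table=table, n_permutations=n_perm, seed=model.seed, null_ss=null_ss)


# ---------------------------------------------------------------------
# least-squares means
# ---------------------------------------------------------------------

@dataclass
class LSMeans:
    """Per-cell least-squares mean shapes.

    ``cells`` holds one row of factor levels per mean; ``means`` the
    matching (C, 2k) flattened mean shapes, ordered by the declared
    level ordering of each grouping factor (risk: ascending).
    """

    cells: pd.DataFrame
    means: np.ndarray
    landmark_labels: tuple[str, ...]

    def mean_for(self, **levels) -> np.ndarray:
        mask = np.ones(len(self.cells), dtype=bool)
        for name, value in levels.items():
            mask &= self.cells[name].to_numpy() == value
        idx = np.flatnonzero(mask)
        if len(idx) != 1:
            raise KeyError(f"levels {levels} select {len(idx)} cells, expected 1")
        return self.means[idx[0]]


def fit_lsmeans(data: ShapeDataset, grouping: Sequence[str]) -> LSMeans:
    """Least-squares mean shape for every cell of the grouping factors.

    Cell means are computed on the finest cross of the grouping factors
    with any remaining categorical design factors, then averaged with
    equal weight across the levels of the non-grouping factors.  On a
    balanced design this reduces to per-cell arithmetic means; on an
    unbalanced design it gives means of cell means rather than pooled
    specimen means.  An empty grouping cell raises an error naming it.
    """
    if data.factors is None:
        raise ValueError("dataset has no attached factor table")
    grouping = list(grouping)
    available = [c for c in data.factors.table.columns if c in CATEGORICAL_FACTORS]
    others = [c for c in available if c not in grouping]
    y = data.flatten()

    frame = pd.DataFrame({g: data.factor_values(g) for g in grouping + others})
    fine = frame.groupby(grouping + others, observed=True, sort=False).indices

    # declared level order per grouping factor
    orders = []
    for g in grouping:
        if g == "risk":
            orders.append(data.factors.level_order("risk"))
        else:
            orders.append(sorted(pd.unique(frame[g]).tolist()))

    cells = list(itertools.product(*orders))
    means = np.empty((len(cells), y.shape[1]))
    for ci, cell in enumerate(cells):
        sub_means = []
        for key, idx in fine.items():
            key = key if isinstance(key, tuple) else (key,)
            if tuple(key[: len(grouping)]) == cell:
                sub_means.append(y[idx].mean(axis=0))
        if not sub_means:
            raise ValueError(f"empty design cell {dict(zip(grouping, cell))}")
        means[ci] = np.mean(sub_means, axis=0)
    cells_frame = pd.DataFrame(cells, columns=grouping)
    return LSMeans(cells=cells_frame, means=means, landmark_labels=data.landmark_labels)
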