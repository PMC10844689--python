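"""Readers and writers for landmark and factor files.

Supports the community-standard TPS landmark format (``LM=`` count line,
coordinate lines, ``ID=`` line per record) and two CSV dialects:

* ``long`` — columns ``specimen, landmark, x, y``, one row per landmark;
* ``wide`` — one row per specimen with columns ``x1..xk, y1..yk``.

Digitised images use the graphics convention (origin top-left, y
increasing downwards); pass ``image_convention=True`` to flip y into the
mathematical convention on ingest.  All writers/readers round-trip
coordinates losslessly (to double precision).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    FactorTable,
    LandmarkConfiguration,
    ParseError,
    RISK_LEVELS,
    ShapeDataset,
)

__all__ = [
    "read_tps",
    "write_tps",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_factors_csv",
    "write_factors_csv",
]


def _flip_y(data: ShapeDataset) -> ShapeDataset:
    data.coords[:, :, 1] *= -1.0
    data.provenance.append("converted from image convention (y flipped)")
    return data


def read_tps(
    path: str | Path,
    landmark_labels: Sequence[str] = (),
    image_convention: bool = False,
) -> ShapeDataset:
    """Parse a TPS landmark file into a :class:`ShapeDataset`.

    Each record must contain an ``LM=k`` line, k coordinate lines and an
    ``ID=`` line; ``IMAGE=`` and ``SCALE=`` lines are accepted and
    ignored.  Record order is preserved.  Raises :class:`ParseError`
    naming the offending record on a landmark-count mismatch, and
    ``ValueError`` on duplicate specimen ids.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ParseError(f"{path.name}: expected 'LM=' at line {i + 1}, got {line!r}")
        record += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise ParseError(f"{path.name}: bad landmark count in record {record}") from None
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row:
                break  # next keyword reached before k coordinate lines
            parts = row.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path.name}: record {record}: expected 'x y' at line {i + 1}"
                )
            coords.append((float(parts[0]), float(parts[1])))
            i += 1
        if len(coords) != k:
            raise ParseError(
                f"{path.name}: record {record}: LM={k} but only "
                f"{len(coords)} coordinate lines found"
            )
        specimen_id = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            key, _, value = row.partition("=")
            if key.strip().upper() == "ID":
                specimen_id = value.strip()
            i += 1
        if specimen_id is None:
            raise ParseError(f"{path.name}: record {record}: missing ID= line")
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                coords=np.asarray(coords),
                landmark_labels=tuple(landmark_labels),
            )
        )
    if not configs:
        raise ParseError(f"{path.name}: no TPS records found")
    data = ShapeDataset.from_configurations(configs)
    data.provenance.append(f"read {len(configs)} records from {path.name} (tps)")
    return _flip_y(data) if image_convention else data


def write_tps(data: ShapeDataset, path: str | Path) -> None:
    """Write a dataset as TPS records, one per specimen, in order."""
    path = Path(path)
    out = []
    for i, sid in enumerate(data.specimen_ids):
        out.append(f"LM={data.k}")
        for x, y in data.coords[i]:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={sid}")
    path.write_text("\n".join(out) + "\n")


def read_landmarks_csv(
    path: str | Path,
    dialect: str = "long",
    landmark_labels: Sequence[str] = (),
    image_convention: bool = False,
) -> ShapeDataset:
    """Read landmarks from CSV in the ``long`` or ``wide`` dialect.

    Both dialects yield identical datasets for the same data.  A
    specimen missing a landmark (long) or with a missing cell (wide)
    raises :class:`ParseError` naming specimen and landmark.
    """
    path = Path(path)
    if dialect not in ("long", "wide"):
        raise ValueError(f"dialect must be 'long' or 'wide', got {dialect!r}")
    frame = pd.read_csv(path)
    if dialect == "long":
        required = {"specimen", "landmark", "x", "y"}
        if not required.issubset(frame.columns):
            raise ParseError(
                f"{path.name}: long dialect needs columns {sorted(required)}"
            )
        frame["specimen"] = frame["specimen"].astype(str)
        # landmark column may be 1-based index or label
        counts = frame.groupby("specimen", sort=False).size()
        k = int(counts.iloc[0])
        short = counts[counts != k]
        if len(short):
            sid = short.index[0]
            have = set(frame.loc[frame["specimen"] == sid, "landmark"])
            want = set(frame.loc[frame["specimen"] == counts.index[0], "landmark"])
            missing = sorted(str(m) for m in (want - have)) or ["?"]
            raise ParseError(
                f"{path.name}: specimen {sid!r} is missing landmark(s) {missing}"
            )
        configs = []
        first_order = frame.loc[frame["specimen"] == counts.index[0], "landmark"].tolist()
        for sid, sub in frame.groupby("specimen", sort=False):
            sub = sub.set_index("landmark").loc[first_order]
            configs.append(
                LandmarkConfiguration(
                    specimen_id=str(sid),
                    coords=sub[["x", "y"]].to_numpy(dtype=float),
                    landmark_labels=tuple(landmark_labels),
                )
            )
        data = ShapeDataset.from_configurations(configs)
    else:
        if "specimen" not in frame.columns:
            raise ParseError(f"{path.name}: wide dialect needs a 'specimen' column")
        xcols = sorted(
            (c for c in frame.columns if c.startswith("x") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        ycols = sorted(
            (c for c in frame.columns if c.startswith("y") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if not xcols or [c[1:] for c in xcols] != [c[1:] for c in ycols]:
            raise ParseError(f"{path.name}: wide dialect needs matching x1..xk, y1..yk")
        sub = frame[xcols + ycols]
        if sub.isna().any().any():
            row = int(sub.isna().any(axis=1).idxmax())
            sid = frame.loc[row, "specimen"]
            lm = sub.columns[sub.loc[row].isna()].tolist()
            raise ParseError(f"{path.name}: specimen {sid!r} is missing {lm}")
        coords = np.stack(
            [frame[xcols].to_numpy(dtype=float), frame[ycols].to_numpy(dtype=float)],
            axis=2,
        )
        data = ShapeDataset(
            coords=coords,
            specimen_ids=tuple(frame["specimen"].astype(str)),
            landmark_labels=tuple(landmark_labels),
        )
    data.provenance.append(f"read {data.n} specimens from {path.name} (csv-{dialect})")
    return _flip_y(data) if image_convention else data


def write_landmarks_csv(data: ShapeDataset, path: str | Path, dialect: str = "long") -> None:
    """Write a dataset as CSV in the requested dialect."""
    path = Path(path)
    if dialect == "long":
        rows = [
            {
                "specimen": sid,
                "landmark": data.landmark_labels[j],
                "x": data.coords[i, j, 0],
                "y": data.coords[i, j, 1],
            }
            for i, sid in enumerate(data.specimen_ids)
            for j in range(data.k)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "wide":
        cols: dict[str, object] = {"specimen": list(data.specimen_ids)}
        for j in range(data.k):
            cols[f"x{j + 1}"] = data.coords[:, j, 0]
        for j in range(data.k):
            cols[f"y{j + 1}"] = data.coords[:, j, 1]
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        raise ValueError(f"dialect must be 'long' or 'wide', got {dialect!r}")


def read_factors_csv(
    path: str | Path, risk_levels: Sequence[float] = RISK_LEVELS
) -> FactorTable:
    """Read a factor table CSV (columns: specimen, clone, instar, risk[, session])."""
    frame = pd.read_csv(path)
    if "specimen" not in frame.columns:
        raise ParseError(f"{Path(path).name}: factor table needs a 'specimen' column")
    return FactorTable(frame, risk_levels=risk_levels)


def write_factors_csv(factors: FactorTable, path: str | Path) -> None:
    factors.table.rename_axis("specimen").reset_index().to_csv(path, index=False)
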