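"""Optional adapter for a locally downloaded Dryad deposit.

The core readers never depend on any deposit layout; this module maps a
directory containing the archived study data (a TPS or CSV landmark
file plus a factor table CSV) onto the package's containers.  Nothing
here downloads anything: point it at an already-unpacked directory.
"""

from __future__ import annotations

from pathlib import Path

from .core import ShapeDataset, attach_factors
from .io import read_factors_csv, read_landmarks_csv, read_tps

__all__ = ["load_deposit"]

_LANDMARK_CANDIDATES = ("landmarks.tps", "landmarks.csv", "coords.tps", "coords.csv")
_FACTOR_CANDIDATES = ("factors.csv", "classifiers.csv", "metadata.csv")


def load_deposit(
    directory: str | Path,
    landmark_file: str | None = None,
    factor_file: str | None = None,
    image_convention: bool = True,
) -> ShapeDataset:
    """Assemble a dataset from an unpacked deposit directory.

    Looks for a landmark file (TPS preferred, else long-dialect CSV) and
    a factor table CSV under conventional names unless explicit
    filenames are given.  Digitised photo coordinates use the image
    convention (y down) by default.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")

    def _find(explicit: str | None, candidates: tuple[str, ...], kind: str) -> Path:
        if explicit is not None:
            path = directory / explicit
            if not path.exists():
                raise FileNotFoundError(f"{kind} file {path} not found")
            return path
        for name in candidates:
            if (directory / name).exists():
                return directory / name
        raise FileNotFoundError(
            f"no {kind} file found in {directory}; tried {list(candidates)} — "
            "pass the filename explicitly"
        )

    lm_path = _find(landmark_file, _LANDMARK_CANDIDATES, "landmark")
    fct_path = _find(factor_file, _FACTOR_CANDIDATES, "factor")

    if lm_path.suffix.lower() == ".tps":
        data = read_tps(lm_path, image_convention=image_convention)
    else:
        data = read_landmarks_csv(lm_path, dialect="long", image_convention=image_convention)
    return attach_factors(data, read_factors_csv(fct_path))
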