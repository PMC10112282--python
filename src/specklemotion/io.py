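"""Standard-format I/O: curve CSVs with '#' metadata, TIFF stacks, configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .exceptions import ParameterError
from .speckle_sim import SpeckleStack

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "load_config",
    "write_json",
]

_FLOAT_FMT = "%.10g"


def write_curve_csv(path, columns: dict[str, np.ndarray], metadata: dict | None = None) -> None:
    """Write named columns as CSV with '#'-prefixed metadata header lines.

    Float formatting is fixed so that identical inputs give byte-identical
    files.
    """
    cols = {name: np.asarray(vals) for name, vals in columns.items()}
    lengths = {len(v) for v in cols.values()}
    if len(lengths) != 1:
        raise ParameterError("all columns must have the same length")
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"# {key} = {value}")
    lines.append(",".join(cols))
    for row in zip(*cols.values()):
        lines.append(",".join(_FLOAT_FMT % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve_csv(path) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Read a curve CSV written by :func:`write_curve_csv`."""
    metadata: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            metadata[key.strip()] = value.strip()
        elif header is None:
            header = [c.strip() for c in line.split(",")]
        else:
            rows.append([float(v) for v in line.split(",")])
    if header is None:
        raise ParameterError(f"{path} contains no column header")
    data = np.array(rows, dtype=float).reshape(len(rows), len(header))
    return metadata, {name: data[:, i] for i, name in enumerate(header)}


def write_stack_tiff(path, stack: SpeckleStack) -> None:
    """Write an intensity stack as a multi-page float32 grayscale TIFF."""
    if stack.kind != "intensity":
        raise ParameterError("TIFF export stores intensity stacks only")
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")


def read_stack_tiff(path, frame_interval: float) -> SpeckleStack:
    """Read a multi-page TIFF as an intensity stack with the given frame interval."""
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    return SpeckleStack(frames, frame_interval, "intensity")


def load_config(path) -> dict:
    """Load a YAML or JSON config file (YAML is a superset of JSON)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"{path} must contain a mapping at the top level")
    return data


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
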