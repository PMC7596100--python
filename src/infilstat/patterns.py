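"""Point patterns of cell centroids in a rectangular observation window.

Coordinates are stored in millimetres.  The default window is the
1.5 mm x 1.5 mm region-of-interest tile used throughout the package; the
window origin is fixed at (0, 0) and points exactly on the boundary are
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Window",
    "PointPattern",
    "read_pattern",
    "write_pattern",
    "read_manifest",
    "write_manifest",
    "PatternError",
]

MANIFEST_COLUMNS = ["pattern_id", "file", "rho", "l", "d", "seed"]


class PatternError(ValueError):
    """Raised for invalid point-pattern inputs."""


@dataclass(frozen=True)
class Window:
    """Rectangular observation window [0, width] x [0, height] in mm."""

    width: float = 1.5
    height: float = 1.5

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise PatternError(
                f"window dimensions must be positive, got {self.width} x {self.height}"
            )

    @property
    def area(self) -> float:
        """Window area in mm^2."""
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of rows of ``xy`` inside the closed window."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= 0.0)
            & (xy[:, 0] <= self.width)
            & (xy[:, 1] >= 0.0)
            & (xy[:, 1] <= self.height)
        )


@dataclass
class PointPattern:
    """An ordered set of (x, y) centroids inside a :class:`Window`.

    Parameters
    ----------
    xy:
        Array of shape (n, 2) with coordinates in mm.
    window:
        Observation window; defaults to the 1.5 mm square ROI.
    label:
        Optional free-text identifier.
    """

    xy: np.ndarray
    window: Window = field(default_factory=Window)
    label: str | None = None

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if xy.size and not np.all(np.isfinite(xy)):
            raise PatternError("non-finite coordinates in point pattern")
        inside = self.window.contains(xy)
        if xy.size and not inside.all():
            bad = int(np.flatnonzero(~inside)[0])
            raise PatternError(
                f"point {tuple(xy[bad])} at row {bad} lies outside the "
                f"{self.window.width} x {self.window.height} mm window"
            )
        self.xy = xy

    def __len__(self) -> int:
        return int(self.xy.shape[0])

    @property
    def n(self) -> int:
        return len(self)

    @property
    def density(self) -> float:
        """Intensity n / area in cells per mm^2."""
        return self.n / self.window.area

    def translated(self, dx: float, dy: float) -> "PointPattern":
        return PointPattern(self.xy + np.array([dx, dy]), self.window, self.label)

    def rotated90(self) -> "PointPattern":
        """Rotate the pattern by 90 degrees within a square window."""
        if self.window.width != self.window.height:
            raise PatternError("90-degree rotation requires a square window")
        xy = np.column_stack([self.xy[:, 1], self.window.width - self.xy[:, 0]])
        return PointPattern(xy, self.window, self.label)


def read_pattern(path: str | Path, window: Window | None = None) -> PointPattern:
    """Read a two-column (x, y) delimited text file into a PointPattern.

    A single header line is auto-detected (non-numeric first row).  Every
    point is validated against the window; an out-of-window point raises
    :class:`PatternError` naming its row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    window = window or Window()
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    start = 0
    if lines:
        first = lines[0].replace("\t", ",").split(",")
        try:
            [float(v) for v in first[:2]]
        except ValueError:
            start = 1  # header line
    for i, ln in enumerate(lines[start:]):
        parts = ln.replace("\t", ",").split(",")
        if len(parts) < 2:
            raise PatternError(f"{path}: row {i} has fewer than two columns")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise PatternError(f"{path}: non-numeric value at row {i}: {ln!r}") from exc
        rows.append((x, y))
    xy = np.array(rows, dtype=float).reshape(-1, 2)
    inside = window.contains(xy)
    if xy.size and not inside.all():
        bad = int(np.flatnonzero(~inside)[0])
        raise PatternError(
            f"{path}: point {rows[bad]} at row {bad} lies outside the window"
        )
    return PointPattern(xy, window, label=path.stem)


def write_pattern(pattern: PointPattern, path: str | Path) -> None:
    """Write a pattern as CSV with header ``x,y``; 12 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in pattern.xy:
            fh.write(f"{x:.12g},{y:.12g}\n")


def write_manifest(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write a dataset manifest CSV (columns pattern_id,file,rho,l,d,seed)."""
    df = pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS)
    if df["pattern_id"].duplicated().any():
        raise PatternError("duplicate pattern_id in manifest")
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path, validate_files: bool = False,
                  window: Window | None = None) -> pd.DataFrame:
    """Read a manifest CSV; optionally check every pattern file parses."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise PatternError(f"manifest {path} missing columns {missing}")
    if df["pattern_id"].duplicated().any():
        raise PatternError(f"manifest {path} has duplicate pattern_id values")
    if validate_files:
        base = path.parent
        for f in df["file"]:
            fp = Path(f)
            if not fp.is_absolute():
                fp = base / fp
            read_pattern(fp, window)
    return df
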