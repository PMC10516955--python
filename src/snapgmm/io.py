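"""Snapshot CSV input/output and the nonnegativity filter.

Snapshot data live in two directories: ``X`` holds one CSV of initial
per-cell abundances and ``Y`` one CSV per observed time point.  Rows are
cells, columns are species (in the model's species order unless
overridden).  A separate single-column CSV lists the observation times.
Because mass-cytometry preprocessing can push zero readings negative,
any row containing a negative entry is dropped at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnapshotDataset",
    "DatasetError",
    "read_snapshot_csv",
    "filter_nonnegative",
    "load_dataset",
    "write_matrix_csv",
    "write_moments_csv",
    "write_estimates_csv",
]

_FLOAT_FMT = "%.17g"


class DatasetError(ValueError):
    """Malformed or inconsistent snapshot data."""


@dataclass
class SnapshotDataset:
    """Initial-condition matrix plus time-stamped observation matrices.

    ``x0`` is n0 x p; ``observations`` is a list of ``(time, Y_t)`` pairs
    with strictly increasing positive times, each Y_t of shape n_t x p.
    Cells at different times are disjoint sets (snapshot data are
    destructive), which is why no row correspondence across matrices is
    assumed anywhere.
    """

    x0: np.ndarray
    observations: list[tuple[float, np.ndarray]]
    species_order: list[str] | None = None

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.ndim != 2:
            raise DatasetError("x0 must be a 2-D matrix")
        p = self.x0.shape[1]
        obs = []
        last_t = 0.0
        for t, y in self.observations:
            y = np.asarray(y, dtype=float)
            if y.ndim != 2 or y.shape[1] != p:
                raise DatasetError(
                    f"observation at t={t} has {y.shape} columns, expected {p}"
                )
            if t <= 0:
                raise DatasetError(f"observation time {t} must be positive")
            if obs and t <= last_t:
                raise DatasetError("observation times must be strictly increasing")
            last_t = t
            obs.append((float(t), y))
        self.observations = obs
        if self.x0.shape[0] < 2 or any(y.shape[0] < 2 for _, y in obs):
            raise DatasetError("every snapshot needs at least 2 cells")
        if (self.x0 < 0).any() or any((y < 0).any() for _, y in obs):
            raise DatasetError("negative entries present; apply filter_nonnegative first")
        if self.species_order is not None and len(self.species_order) != p:
            raise DatasetError("species_order length does not match column count")

    @property
    def n_species(self) -> int:
        return self.x0.shape[1]

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.observations]


def read_snapshot_csv(path, expect_cols: int | None = None) -> np.ndarray:
    """Read one snapshot CSV into an n x p float matrix, preserving row order.

    A single header line is auto-detected: if the first line contains any
    cell that does not parse as a number it is treated as a header.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines:
        raise DatasetError(f"{path}: empty file")
    first = lines[0].split(",")
    header = False
    for cell in first:
        try:
            float(cell)
        except ValueError:
            header = True
            break
    body = lines[1:] if header else lines
    if not body:
        raise DatasetError(f"{path}: no data rows")
    ncol = len(body[0].split(","))
    rows = []
    for i, ln in enumerate(body, start=2 if header else 1):
        cells = ln.split(",")
        if len(cells) != ncol:
            raise DatasetError(
                f"{path}: ragged row at line {i} ({len(cells)} cells, expected {ncol})"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            bad = next(c for c in cells if not _is_number(c))
            raise DatasetError(f"{path}: non-numeric cell {bad!r} at line {i}")
    m = np.array(rows, dtype=float)
    if expect_cols is not None and m.shape[1] != expect_cols:
        raise DatasetError(
            f"{path}: {m.shape[1]} columns, expected {expect_cols}"
        )
    return m


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def filter_nonnegative(m: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop every row containing a negative entry; keep original order.

    Returns the filtered matrix and the number of dropped rows; logs a
    warning when anything was dropped.  Idempotent by construction.
    """
    m = np.asarray(m, dtype=float)
    keep = (m >= 0).all(axis=1)
    n_dropped = int((~keep).sum())
    out = m[keep]
    if n_dropped:
        logger.warning(
            "dropped %d of %d rows containing negative values", n_dropped, m.shape[0]
        )
    if out.shape[0] < 2:
        raise DatasetError(
            f"only {out.shape[0]} rows remain after removing negative-valued "
            "cells; at least 2 are required to form moments"
        )
    return out, n_dropped


def _csv_files(directory: Path) -> list[Path]:
    return sorted(p for p in directory.iterdir() if p.suffix.lower() == ".csv")


def read_times_csv(path) -> list[float]:
    """Read the single-column time-steps CSV."""
    raw = read_snapshot_csv(path)
    if raw.shape[1] != 1:
        raise DatasetError(f"{path}: time-steps file must have one column")
    return [float(t) for t in raw[:, 0]]


def load_dataset(
    x_dir,
    y_dir,
    times_path,
    species_order: list[str] | None = None,
    manifest: dict[str, float] | None = None,
) -> SnapshotDataset:
    """Assemble a :class:`SnapshotDataset` from the X/Y directory layout.

    Only the lexicographically first CSV in ``x_dir`` is read for X.  Y
    files are paired with times in lexicographic filename order, unless
    ``manifest`` maps filenames to times explicitly.  The nonnegativity
    filter is applied to every matrix independently.
    """
    x_dir, y_dir = Path(x_dir), Path(y_dir)
    x_files = _csv_files(x_dir)
    if not x_files:
        raise DatasetError(f"no CSV file found in X directory {x_dir}")
    if len(x_files) > 1:
        logger.info("X directory holds %d CSVs; reading only %s",
                    len(x_files), x_files[0].name)
    x0 = read_snapshot_csv(x_files[0])
    p = x0.shape[1]
    x0, _ = filter_nonnegative(x0)

    times = read_times_csv(times_path)
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise DatasetError(f"times in {times_path} are not strictly increasing")

    y_files = _csv_files(y_dir)
    if manifest is not None:
        pairs = []
        for fname, t in manifest.items():
            fpath = y_dir / fname
            if not fpath.exists():
                raise DatasetError(f"manifest entry {fname!r} not found in {y_dir}")
            pairs.append((float(t), fpath))
        pairs.sort()
    else:
        if len(y_files) != len(times):
            raise DatasetError(
                f"{len(y_files)} Y files but {len(times)} entries in the "
                "time-steps file"
            )
        pairs = list(zip(times, y_files))

    observations = []
    for t, fpath in pairs:
        y = read_snapshot_csv(fpath, expect_cols=p)
        y, _ = filter_nonnegative(y)
        observations.append((t, y))
    return SnapshotDataset(x0=x0, observations=observations,
                           species_order=species_order)


# ---------------------------------------------------------------------------
# writers (deterministic column order, 17 significant digits)

def write_matrix_csv(path, m: np.ndarray) -> None:
    m = np.asarray(m, dtype=float)
    with open(path, "w", encoding="utf-8") as fh:
        for row in m:
            fh.write(",".join(_FLOAT_FMT % v for v in row) + "\n")


def write_moments_csv(path, labels, observed, predicted) -> None:
    """Write per-moment observed/predicted values: label,observed,predicted."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if not (len(labels) == observed.size == predicted.size):
        raise ValueError("labels, observed and predicted lengths differ")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label,observed,predicted\n")
        for lab, o, pr in zip(labels, observed, predicted):
            fh.write(f"{lab},{_FLOAT_FMT % o},{_FLOAT_FMT % pr}\n")


def read_moments_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_estimates_csv(path, names, replicate_estimates, point_estimate,
                        ci_low=None, ci_high=None) -> None:
    """Write parameter estimates: name,estimate,ci_low,ci_high,rep_1..rep_R.

    With no replicates the file carries only the estimate column; CI
    columns are left empty when intervals are unavailable.
    """
    point_estimate = np.asarray(point_estimate, float)
    reps = (np.asarray(replicate_estimates, float)
            if replicate_estimates is not None and len(replicate_estimates)
            else np.empty((0, point_estimate.size)))
    if reps.size and reps.shape[1] != point_estimate.size:
        raise ValueError("replicate matrix width does not match estimate length")
    n_rep = reps.shape[0]
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["name", "estimate"]
        if ci_low is not None:
            cols += ["ci_low", "ci_high"]
        cols += [f"rep_{r + 1}" for r in range(n_rep)]
        fh.write(",".join(cols) + "\n")
        for j, name in enumerate(names):
            row = [name, _FLOAT_FMT % point_estimate[j]]
            if ci_low is not None:
                row += [_FLOAT_FMT % ci_low[j], _FLOAT_FMT % ci_high[j]]
            row += [_FLOAT_FMT % reps[r, j] for r in range(n_rep)]
            fh.write(",".join(row) + "\n")
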