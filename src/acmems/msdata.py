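"""Observation container, axis conventions, slicing, and file I/O.

A CE-MS observation is a dense 2D grid of ion counts with rows indexed
by mass-to-charge ratio (m/z, ascending, amu) and columns by migration
time (ascending, seconds).  Summing rows over an m/z band yields an
electropherogram; summing columns over a time window yields a mass
spectrum.  All index windows in the package are half-open ``[lo, hi)``.

Persistence uses an HDF5 container with datasets ``counts``, ``mz_axis``
and ``time_axis`` plus a ``meta`` attribute group, or a small CSV
fixture dialect (first row = time axis, first column = m/z axis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import h5py

from acmems.errors import EmptyBandError, FormatError, ValidationError

__all__ = [
    "Observation",
    "Electropherogram",
    "load_observation",
    "save_observation",
    "slice_electropherogram",
    "slice_mass_spectrum",
]


@dataclass
class Observation:
    """Dense 2D ion-count grid with its axis vectors.

    Parameters
    ----------
    counts
        Non-negative matrix of shape ``(n_mz, n_time)``.
    mz_axis
        Strictly ascending m/z bin centers, amu.
    time_axis
        Strictly ascending migration-time bin centers, seconds.
    meta
        Free-form key/value metadata (sample id, injection settings).
    """

    counts: np.ndarray
    mz_axis: np.ndarray
    time_axis: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2D matrix")
        n_mz, n_time = self.counts.shape
        if self.mz_axis.shape != (n_mz,) or self.time_axis.shape != (n_time,):
            raise ValidationError(
                f"axis lengths ({self.mz_axis.size}, {self.time_axis.size}) "
                f"do not match counts shape {self.counts.shape}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        for name, ax in (("mz_axis", self.mz_axis), ("time_axis", self.time_axis)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValidationError(f"{name} must be strictly ascending")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def mz_step(self) -> float:
        """Median m/z bin width, amu (0.08 for flight-like data)."""
        return float(np.median(np.diff(self.mz_axis))) if self.mz_axis.size > 1 else 0.08

    @property
    def time_step(self) -> float:
        """Median time bin width, seconds."""
        return float(np.median(np.diff(self.time_axis))) if self.time_axis.size > 1 else 0.5


@dataclass
class Electropherogram:
    """Summed ion counts versus migration time for an m/z band."""

    time_axis: np.ndarray
    values: np.ndarray
    mz_lo: float
    mz_hi: float

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.time_axis.shape:
            raise ValidationError("values length must equal time_axis length")
        if np.any(self.values < 0):
            raise ValidationError("electropherogram values must be non-negative")


def slice_electropherogram(obs: Observation, mz_lo: float, mz_hi: float) -> Electropherogram:
    """Sum counts over the half-open m/z band ``[mz_lo, mz_hi)``.

    A band covering the full m/z range reproduces the total-ion-count
    trace.  Raises :class:`EmptyBandError` if no row falls in the band.
    """
    if mz_lo > mz_hi:
        raise ValidationError("mz_lo must not exceed mz_hi")
    mask = (obs.mz_axis >= mz_lo) & (obs.mz_axis < mz_hi)
    if not mask.any():
        raise EmptyBandError(f"band [{mz_lo}, {mz_hi}) contains no m/z bins")
    return Electropherogram(
        time_axis=obs.time_axis.copy(),
        values=obs.counts[mask].sum(axis=0),
        mz_lo=mz_lo,
        mz_hi=mz_hi,
    )


def slice_mass_spectrum(
    obs: Observation, t_center: float, half_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sum counts over the time window ``[t_center - hw, t_center + hw]``.

    Returns ``(mz_axis, values)``.  Raises :class:`EmptyBandError` if the
    window misses every time bin.
    """
    mask = (obs.time_axis >= t_center - half_width) & (obs.time_axis <= t_center + half_width)
    if not mask.any():
        raise EmptyBandError(
            f"window {t_center}+-{half_width} s contains no time bins"
        )
    return obs.mz_axis.copy(), obs.counts[:, mask].sum(axis=1)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        return "container"
    if path.suffix.lower() == ".csv":
        return "csv"
    raise FormatError(f"cannot infer format from suffix {path.suffix!r}")


def save_observation(obs: Observation, path: str | Path, format: str | None = None) -> None:
    """Write an observation to an HDF5 container or a CSV fixture."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "container":
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=obs.counts)
            f.create_dataset("mz_axis", data=obs.mz_axis)
            f.create_dataset("time_axis", data=obs.time_axis)
            grp = f.create_group("meta")
            grp.attrs["json"] = json.dumps(obs.meta, default=str)
    elif fmt == "csv":
        header = "mz\\time," + ",".join(repr(float(t)) for t in obs.time_axis)
        rows = [header]
        for mz, row in zip(obs.mz_axis, obs.counts):
            rows.append(",".join([repr(float(mz))] + [repr(float(v)) for v in row]))
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    else:
        raise FormatError(f"unknown format {fmt!r}")


def load_observation(path: str | Path, format: str | None = None) -> Observation:
    """Read an observation written by :func:`save_observation`.

    Raises :class:`FormatError` when an axis or the counts matrix is
    missing, :class:`ValidationError` when the contents violate the
    container invariants (negative counts, descending axes, shape
    mismatch).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "container":
        with h5py.File(path, "r") as f:
            for ds in ("counts", "mz_axis", "time_axis"):
                if ds not in f:
                    raise FormatError(f"container missing dataset {ds!r}")
            counts = f["counts"][()]
            mz_axis = f["mz_axis"][()]
            time_axis = f["time_axis"][()]
            meta: dict[str, Any] = {}
            if "meta" in f and "json" in f["meta"].attrs:
                meta = json.loads(f["meta"].attrs["json"])
        return Observation(counts, mz_axis, time_axis, meta)
    if fmt == "csv":
        lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
        if len(lines) < 2:
            raise FormatError("CSV fixture must have a time-axis row and data rows")
        try:
            time_axis = np.array([float(v) for v in lines[0].split(",")[1:]])
            mz_axis, rows = [], []
            for ln in lines[1:]:
                cells = ln.split(",")
                mz_axis.append(float(cells[0]))
                rows.append([float(v) for v in cells[1:]])
        except ValueError as exc:
            raise FormatError(f"unparseable CSV fixture: {exc}") from exc
        return Observation(np.array(rows), np.array(mz_axis), time_axis)
    raise FormatError(f"unknown format {fmt!r}")
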