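"""Background summarization as a tiling of rectangular noise regions.

The ion-count background of a CE-MS observation is well described by
axis-aligned rectangles of fairly uniform noise.  The summarizer
segments the background estimate in two passes — horizontal edges from
the per-row mean profile, then vertical edges within each row band
from per-column mean profiles — and stores each rectangle's mean and
SD.  A percentile threshold on adjacent-profile differences controls
the resolution; a byte budget selects among several resolutions.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from acmems.errors import ConfigError, ValidationError
from acmems.simulate import NoiseRegion

__all__ = [
    "BackgroundSummary",
    "segment_background",
    "select_resolution",
    "reconstruct_background",
]

# fixed-width binary record per region: 4 bin-index bounds (uint16)
# + mean and sd (float32) = 16 bytes
_RECORD = struct.Struct("<4H2f")


@dataclass
class BackgroundSummary:
    """A tiling of the grid into uniform-noise rectangles."""

    regions: list[NoiseRegion]
    threshold_percentile: float
    mz_axis: np.ndarray = field(repr=False)
    time_axis: np.ndarray = field(repr=False)
    over_budget: bool = False

    @property
    def byte_size(self) -> int:
        return _RECORD.size * len(self.regions)

    # -- serialization ------------------------------------------------------

    def _bounds_to_bins(self, reg: NoiseRegion) -> tuple[int, int, int, int]:
        r0 = int(np.searchsorted(self.mz_axis, reg.mz_lo))
        r1 = int(np.searchsorted(self.mz_axis, reg.mz_hi))
        c0 = int(np.searchsorted(self.time_axis, reg.t_lo))
        c1 = int(np.searchsorted(self.time_axis, reg.t_hi))
        return r0, r1, c0, c1

    def to_bytes(self) -> bytes:
        out = bytearray()
        for reg in self.regions:
            r0, r1, c0, c1 = self._bounds_to_bins(reg)
            out += _RECORD.pack(r0, r1, c0, c1, reg.mean, reg.sd)
        return bytes(out)

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold_percentile": self.threshold_percentile,
                "over_budget": self.over_budget,
                "regions": [
                    {"mz_lo": r.mz_lo, "mz_hi": r.mz_hi, "t_lo": r.t_lo,
                     "t_hi": r.t_hi, "mean": r.mean, "sd": r.sd}
                    for r in self.regions
                ],
            },
            indent=1,
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_bytes(self.to_bytes())
        path.with_suffix(".json").write_text(self.to_json(), encoding="utf-8")


def _edges(profile: np.ndarray, threshold: float) -> list[int]:
    """Indices where the adjacent-difference profile exceeds threshold."""
    diffs = np.abs(np.diff(profile))
    return [int(i) + 1 for i in np.nonzero(diffs > threshold)[0]]


def segment_background(
    background: np.ndarray,
    mz_axis: np.ndarray,
    time_axis: np.ndarray,
    percentile: float = 97.0,
    row_stat: str = "mean",
) -> BackgroundSummary:
    """Two-pass edge segmentation of the background estimate.

    Pass 1 splits rows where the absolute difference of adjacent
    row-mean profile values exceeds the given percentile of all
    adjacent-row differences; pass 2 splits columns within each row
    band analogously.  Each resulting rectangle stores the mean and SD
    of the background cells it covers.  A flat input yields one region.
    """
    background = np.asarray(background, dtype=float)
    if np.any(background < 0):
        raise ValidationError("background must be non-negative")
    if not (50.0 < percentile < 100.0):
        raise ConfigError("segmentation percentile must lie in (50, 100)")
    n_mz, n_time = background.shape
    stat = np.mean if row_stat == "mean" else np.median

    row_profile = stat(background, axis=1)
    row_diffs = np.abs(np.diff(row_profile))
    regions: list[NoiseRegion] = []
    if row_diffs.size and row_diffs.max() > 0:
        row_thr = float(np.percentile(row_diffs, percentile))
        row_cuts = _edges(row_profile, row_thr)
    else:
        row_cuts = []
    row_bounds = [0] + row_cuts + [n_mz]

    mz_hi_edge = float(mz_axis[-1]) + (float(np.median(np.diff(mz_axis))) if n_mz > 1 else 0.08)
    t_hi_edge = float(time_axis[-1]) + (float(np.median(np.diff(time_axis))) if n_time > 1 else 0.5)

    def mz_at(i: int) -> float:
        return float(mz_axis[i]) if i < n_mz else mz_hi_edge

    def t_at(j: int) -> float:
        return float(time_axis[j]) if j < n_time else t_hi_edge

    for r0, r1 in zip(row_bounds[:-1], row_bounds[1:]):
        band = background[r0:r1]
        col_profile = stat(band, axis=0)
        col_diffs = np.abs(np.diff(col_profile))
        if col_diffs.size and col_diffs.max() > 0:
            col_thr = float(np.percentile(col_diffs, percentile))
            col_cuts = _edges(col_profile, col_thr)
        else:
            col_cuts = []
        col_bounds = [0] + col_cuts + [n_time]
        for c0, c1 in zip(col_bounds[:-1], col_bounds[1:]):
            block = band[:, c0:c1]
            regions.append(NoiseRegion(
                mz_lo=mz_at(r0), mz_hi=mz_at(r1),
                t_lo=t_at(c0), t_hi=t_at(c1),
                mean=float(block.mean()), sd=float(block.std()),
            ))
    return BackgroundSummary(
        regions=regions, threshold_percentile=percentile,
        mz_axis=np.asarray(mz_axis, dtype=float),
        time_axis=np.asarray(time_axis, dtype=float),
    )


def select_resolution(
    background: np.ndarray,
    mz_axis: np.ndarray,
    time_axis: np.ndarray,
    max_bytes: int,
    percentiles: Sequence[float] = (90.0, 95.0, 97.0, 99.0),
) -> BackgroundSummary:
    """Pick the finest summary that fits a byte budget.

    Produces one summary per percentile and returns the one with the
    most regions whose serialized size is within ``max_bytes``.  If
    none fits, the coarsest is returned with ``over_budget`` set.
    """
    if not percentiles:
        raise ConfigError("at least one percentile required")
    summaries = [
        segment_background(background, mz_axis, time_axis, p) for p in percentiles
    ]
    fitting = [s for s in summaries if s.byte_size <= max_bytes]
    if fitting:
        return max(fitting, key=lambda s: len(s.regions))
    coarsest = min(summaries, key=lambda s: len(s.regions))
    coarsest.over_budget = True
    return coarsest


def reconstruct_background(
    summary: BackgroundSummary,
    mz_axis: np.ndarray | None = None,
    time_axis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill a (mean, sd) matrix pair from a region tiling.

    Raises :class:`ValidationError` when the regions do not tile the
    grid exactly (overlap or gap).
    """
    mz_axis = summary.mz_axis if mz_axis is None else np.asarray(mz_axis, dtype=float)
    time_axis = summary.time_axis if time_axis is None else np.asarray(time_axis, dtype=float)
    shape = (mz_axis.size, time_axis.size)
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    cover = np.zeros(shape, dtype=int)
    for reg in summary.regions:
        r0 = int(np.searchsorted(mz_axis, reg.mz_lo))
        r1 = int(np.searchsorted(mz_axis, reg.mz_hi))
        c0 = int(np.searchsorted(time_axis, reg.t_lo))
        c1 = int(np.searchsorted(time_axis, reg.t_hi))
        mean[r0:r1, c0:c1] = reg.mean
        sd[r0:r1, c0:c1] = reg.sd
        cover[r0:r1, c0:c1] += 1
    if not np.all(cover == 1):
        raise ValidationError("regions do not tile the grid exactly")
    return mean, sd
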