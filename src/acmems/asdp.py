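"""Assembly of the downlinkable autonomous science data products.

Per observation the bundle holds: the valid-peak property table, raw
crops around valid peaks (high priority only), the background summary
(high priority only), downsampled/quantized total-ion-count traces,
and the science-utility / diversity scalars, with byte accounting for
every product.  The complete candidate table is written to local
storage only — it is transmitted solely on operator request.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from acmems.bgsummary import BackgroundSummary
from acmems.config import AcmeConfig
from acmems.detect import DetectionResult, PeakProperties
from acmems.msdata import Observation

__all__ = ["PeakCrop", "AsdpBundle", "crop_peak", "make_tic", "assemble_bundle"]

log = logging.getLogger(__name__)

_PEAK_COLUMNS = [
    "center_mz", "center_time", "height", "volume", "width", "z_score",
    "gauss_loss", "bg_level", "bg_sd", "bg_diff", "bg_ratio", "valid",
]


def _quantize(values: np.ndarray, bit_depth: int) -> tuple[np.ndarray, float, float]:
    """Linear min-max encoding; returns (codes, scale, offset).

    ``decode = codes * scale + offset``; a degenerate window (flat)
    encodes as all-zero codes with scale 0 and offset = the value.
    """
    values = np.asarray(values, dtype=float)
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    levels = (1 << bit_depth) - 1
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        return np.zeros(values.shape, dtype=dtype), 0.0, lo
    scale = (hi - lo) / levels
    codes = np.round((values - lo) / scale)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return codes.astype(dtype), scale, lo


@dataclass
class PeakCrop:
    """Quantized raw-data window around one valid peak."""

    peak_id: int
    codes: np.ndarray                  # quantized window, or float window
    scale: float
    offset: float
    bit_depth: int                     # 8, 16, or 0 for float passthrough
    row_bounds: tuple[int, int]        # actual grid bounds after clipping
    col_bounds: tuple[int, int]
    trace: np.ndarray | None = None    # optional m/z-integrated trace

    def decode(self) -> np.ndarray:
        if self.bit_depth == 0:
            return np.asarray(self.codes, dtype=float)
        return self.codes.astype(float) * self.scale + self.offset

    @property
    def byte_size(self) -> int:
        n = self.codes.size * (1 if self.bit_depth == 8 else 2 if self.bit_depth == 16 else 8)
        if self.trace is not None:
            n += self.trace.size * 4
        return n + 16   # scale/offset/bounds header


def crop_peak(
    obs: Observation,
    peak: PeakProperties,
    window: tuple[int, int] = (13, 121),
    bit_depth: int = 8,
    integrate: bool = False,
    peak_id: int = 0,
) -> PeakCrop:
    """Capture the raw ion-count window around a peak.

    The window is centered on the peak's grid cell and clipped at grid
    edges (actual bounds are recorded).  8/16-bit encodings are linear
    min-max with stored scale/offset; ``integrate=True`` additionally
    stores the +-0.5 m/z row-summed electropherogram trace.
    """
    hm, ht = (window[0] - 1) // 2, (window[1] - 1) // 2
    n_mz, n_time = obs.shape
    r0, r1 = max(0, peak.row - hm), min(n_mz, peak.row + hm + 1)
    c0, c1 = max(0, peak.col - ht), min(n_time, peak.col + ht + 1)
    raw = obs.counts[r0:r1, c0:c1]
    if bit_depth in (8, 16):
        codes, scale, offset = _quantize(raw, bit_depth)
    else:
        codes, scale, offset, bit_depth = raw.copy(), 1.0, 0.0, 0
    trace = None
    if integrate:
        half_rows = int(round(0.5 / obs.mz_step))
        tr0 = max(0, peak.row - half_rows)
        tr1 = min(n_mz, peak.row + half_rows + 1)
        trace = obs.counts[tr0:tr1, c0:c1].sum(axis=0)
    return PeakCrop(
        peak_id=peak_id, codes=codes, scale=scale, offset=offset,
        bit_depth=bit_depth, row_bounds=(r0, r1), col_bounds=(c0, c1),
        trace=trace,
    )


def make_tic(
    obs: Observation, downsample: int = 4, bit_depth: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Total-ion-count traces along both axes, downsampled and encoded.

    ``tic_time`` sums the grid over m/z (per time bin), ``tic_mz`` over
    time (per m/z bin); each is block-mean downsampled by the given
    factor (trailing partial blocks are averaged over their actual
    length) and quantized unless ``bit_depth`` is 0/float.
    """
    if downsample < 1:
        raise ValueError("downsample factor must be >= 1")

    def process(series: np.ndarray) -> np.ndarray:
        if downsample > 1:
            n_full = series.size // downsample
            blocks = [series[: n_full * downsample].reshape(n_full, downsample).mean(axis=1)]
            if series.size % downsample:
                blocks.append([series[n_full * downsample:].mean()])
            series = np.concatenate(blocks)
        if bit_depth in (8, 16):
            codes, scale, offset = _quantize(series, bit_depth)
            return codes.astype(float) * scale + offset
        return series

    tic_time = process(obs.counts.sum(axis=0))
    tic_mz = process(obs.counts.sum(axis=1))
    return tic_time, tic_mz


@dataclass
class AsdpBundle:
    """The per-observation downlink products with byte accounting."""

    peaks: pd.DataFrame
    tic_time: np.ndarray
    tic_mz: np.ndarray
    sue: float
    dd: np.ndarray
    priority: str                              # "low" or "high"
    crops: list[PeakCrop] = field(default_factory=list)
    background: BackgroundSummary | None = None
    alerts: list[str] = field(default_factory=list)
    byte_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def total_bytes(self) -> int:
        return sum(self.byte_sizes.values())

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.peaks.to_csv(out / "peaks.csv", index=False)
        np.concatenate([self.tic_time, self.tic_mz]).astype(np.float32).tofile(
            out / "tic.bin"
        )
        if self.crops:
            with open(out / "crops.bin", "wb") as f:
                index = []
                for crop in self.crops:
                    data = crop.codes.tobytes()
                    index.append({
                        "peak_id": crop.peak_id, "bit_depth": crop.bit_depth,
                        "scale": crop.scale, "offset": crop.offset,
                        "row_bounds": list(crop.row_bounds),
                        "col_bounds": list(crop.col_bounds),
                        "shape": list(crop.codes.shape), "nbytes": len(data),
                    })
                    f.write(data)
            (out / "crops_index.json").write_text(json.dumps(index), encoding="utf-8")
        if self.background is not None:
            self.background.write(out / "background.bin")
        meta = {
            "sue": self.sue,
            "dd": [float(v) for v in self.dd],
            "priority": self.priority,
            "alerts": self.alerts,
            "byte_sizes": self.byte_sizes,
            "total_bytes": self.total_bytes,
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def _peaks_frame(peaks: list[PeakProperties]) -> pd.DataFrame:
    return pd.DataFrame(
        [{col: getattr(p, col) for col in _PEAK_COLUMNS} for p in peaks],
        columns=_PEAK_COLUMNS,
    )


def assemble_bundle(
    obs: Observation,
    detection: DetectionResult,
    bg_summary: BackgroundSummary | None,
    priority: str,
    cfg: AcmeConfig | None = None,
    sue: float = 0.0,
    dd: np.ndarray | None = None,
    candidates_path: str | Path | None = None,
) -> AsdpBundle:
    """Assemble the downlink bundle for one observation.

    ``priority`` may be "low", "high" or "auto".  The bundle is forced
    to low priority when the valid-peak count exceeds the configured
    cap (over-sensitivity failure mode); an alert is logged when the
    TIC shows a strong excursion despite zero valid peaks (possible
    under-sensitivity).  Low-priority bundles exclude crops and the
    background summary.
    """
    cfg = cfg or AcmeConfig()
    dd = np.zeros(2 + cfg.n_presence_bins) if dd is None else np.asarray(dd, float)
    alerts: list[str] = []

    valid = detection.valid
    if detection.over_sensitive or len(valid) > cfg.detect.max_peaks:
        alerts.append("over_sensitive: valid peak count exceeds configured cap")
        priority = "low"
    if priority == "auto":
        priority = "high" if valid else "low"

    tic_time, tic_mz = make_tic(obs, cfg.tic_downsample, cfg.tic_bit_depth)
    if not valid:
        excursion = tic_time - np.median(tic_time)
        sd = max(float(np.std(tic_time)), 1e-9)
        if float(excursion.max()) > cfg.tic_alert_sd * sd:
            alerts.append("tic_excursion: structure in TIC with zero valid peaks")
            log.warning("TIC excursion with zero valid peaks; possible under-sensitivity")

    peaks_df = _peaks_frame(valid)
    byte_sizes = {
        "peaks": int(peaks_df.to_csv(index=False).encode().__len__()),
        "tic": int((tic_time.size + tic_mz.size) * 4),
        "sue_dd": int(4 + 4 * dd.size),
    }

    crops: list[PeakCrop] = []
    background = None
    if priority == "high":
        chosen = sorted(valid, key=lambda p: -p.z_score)[: cfg.max_crops]
        crops = [
            crop_peak(obs, p, (cfg.detect.crop_mz_bins, cfg.detect.crop_time_bins),
                      cfg.crop_bit_depth, peak_id=i)
            for i, p in enumerate(chosen)
        ]
        byte_sizes["crops"] = int(sum(c.byte_size for c in crops))
        if bg_summary is not None:
            background = bg_summary
            byte_sizes["background"] = int(bg_summary.byte_size)

    if candidates_path is not None:
        # kept onboard; transmitted only upon operator request
        _peaks_frame(detection.candidates).to_csv(candidates_path, index=False)

    return AsdpBundle(
        peaks=peaks_df, tic_time=tic_time, tic_mz=tic_mz, sue=sue, dd=dd,
        priority=priority, crops=crops, background=background,
        alerts=alerts, byte_sizes=byte_sizes,
    )
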