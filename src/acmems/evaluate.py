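"""Scoring of detections against simulator ground truth.

Detections and truth peaks are matched one-to-one greedily in
ascending (tolerance-scaled) distance; precision and recall follow
from the matched counts.  A z-score threshold sweep re-applies only
the filtering stage, and the two-peak overlap study measures how
recall changes as peak pairs converge, counting a truth peak as
detected when a raw-data crop of any detection would capture it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from acmems.config import DetectConfig
from acmems.detect import PeakProperties, apply_filter, detect_peaks
from acmems.errors import ConfigError
from acmems.simulate import GroundTruthPeak, SimSample

__all__ = [
    "MatchResult",
    "match_detections",
    "precision_recall",
    "zscore_sweep",
    "overlap_study",
    "DEFAULT_TOL_MZ",
    "DEFAULT_TOL_T",
]

# development annotations were binned at 0.7 m/z; the time tolerance
# reflects the seconds-scale localization of the fitted centers
DEFAULT_TOL_MZ = 0.7   # amu
DEFAULT_TOL_T = 5.0    # s


@dataclass
class MatchResult:
    """Outcome of one-to-one matching between detections and truth."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]       # (detection index, truth index)
    tol_mz: float
    tol_t: float


def match_detections(
    detections: list[PeakProperties],
    truth: list[GroundTruthPeak],
    tol_mz: float = DEFAULT_TOL_MZ,
    tol_t: float = DEFAULT_TOL_T,
) -> MatchResult:
    """Greedy one-to-one matching in ascending scaled distance.

    A detection within (tol_mz, tol_t) of an unmatched truth peak is a
    true positive; remaining detections are false positives, remaining
    truth peaks false negatives.  Equidistant pairs are broken by lower
    truth m/z, then earlier truth time.
    """
    if tol_mz <= 0 or tol_t <= 0:
        raise ConfigError("matching tolerances must be positive")
    edges = []
    for i, d in enumerate(detections):
        for j, t in enumerate(truth):
            dmz = abs(d.center_mz - t.mz)
            dt = abs(d.center_time - t.time)
            if dmz <= tol_mz and dt <= tol_t:
                dist = math.hypot(dmz / tol_mz, dt / tol_t)
                edges.append((dist, t.mz, t.time, i, j))
    edges.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in edges:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(detections) - tp, fn=len(truth) - tp,
        pairs=pairs, tol_mz=tol_mz, tol_t=tol_t,
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """(precision, recall); an undefined ratio is reported as NaN."""
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else float("nan")
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else float("nan")
    return precision, recall


def zscore_sweep(
    samples: list[SimSample],
    thresholds: list[float],
    cfg: DetectConfig | None = None,
    tol_mz: float = DEFAULT_TOL_MZ,
    tol_t: float = DEFAULT_TOL_T,
) -> pd.DataFrame:
    """Re-apply the filtering stage at each z threshold and score.

    Detection (background, DoG, candidate characterization) runs once
    per sample; only the expert-system filter is re-evaluated.  Returns
    a tidy table of (threshold, precision, recall, mean_fp).
    """
    cfg = cfg or DetectConfig()
    if list(thresholds) != sorted(thresholds):
        raise ConfigError("thresholds must be ascending")
    detections = [detect_peaks(s.obs, cfg) for s in samples]
    rows = []
    for thr in thresholds:
        thr_cfg = replace(cfg, z_threshold=thr)
        tp = fp = fn = 0
        for sample, result in zip(samples, detections):
            valid = [p for p in result.candidates if apply_filter(p, thr_cfg)]
            m = match_detections(valid, sample.truth, tol_mz, tol_t)
            tp += m.tp
            fp += m.fp
            fn += m.fn
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn) if tp + fn else 0.0
        rows.append({
            "threshold": thr, "precision": precision, "recall": recall,
            "mean_fp": fp / len(samples),
        })
    return pd.DataFrame(rows)


def _crop_covered(
    truth: GroundTruthPeak, detections: list[PeakProperties], cfg: DetectConfig,
    mz_step: float, time_step: float,
) -> bool:
    half_mz = (cfg.crop_mz_bins - 1) // 2 * mz_step
    half_t = (cfg.crop_time_bins - 1) // 2 * time_step
    return any(
        abs(d.center_mz - truth.mz) <= half_mz
        and abs(d.center_time - truth.time) <= half_t
        for d in detections
    )


def overlap_study(
    series: list[SimSample],
    cfg: DetectConfig | None = None,
    tol_mz: float = DEFAULT_TOL_MZ,
    tol_t: float = DEFAULT_TOL_T,
) -> pd.DataFrame:
    """Recall versus pair separation, with crop-coverage counting.

    A truth peak counts as detected when it is matched one-to-one or
    when it falls inside the raw-crop window of any valid detection —
    the raw data product would capture it even if the filter removed
    its own detection.  ``delta_recall`` is relative to the recall at
    the largest separation in the series (the isolated-peak baseline).
    """
    cfg = cfg or DetectConfig()
    rows = []
    for sample in series:
        sep = float(sample.obs.meta.get("separation_s", float("nan")))
        result = detect_peaks(sample.obs, cfg)
        m = match_detections(result.valid, sample.truth, tol_mz, tol_t)
        matched_truth = {j for _, j in m.pairs}
        covered = 0
        for j, t in enumerate(sample.truth):
            if j in matched_truth or _crop_covered(
                t, result.valid, cfg, sample.obs.mz_step, sample.obs.time_step
            ):
                covered += 1
        rows.append({
            "separation_s": sep,
            "n_truth": len(sample.truth),
            "n_covered": covered,
        })
    df = (
        pd.DataFrame(rows)
        .groupby("separation_s", as_index=False)[["n_truth", "n_covered"]]
        .sum()
        .sort_values("separation_s")
        .reset_index(drop=True)
    )
    df["recall"] = df["n_covered"] / df["n_truth"]
    baseline = df.loc[df["separation_s"].idxmax(), "recall"]
    df["delta_recall"] = df["recall"] - baseline
    return df
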