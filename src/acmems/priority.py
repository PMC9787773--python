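"""Science utility, diversity descriptors, and downlink ordering.

The science utility estimate (SUE) is a weighted average of saturating
normalized features:

    y_i = sqrt(x_i / x_i,max)  for x_i < x_i,max, else 1
    SUE = sum(w_i * y_i) / sum(w_i)                    in [0, 1]

The square-root rise rewards the first occurrences of a feature and
tapers toward saturation.  The diversity descriptor (DD) is a vector
of linearly clamped features (background level/noise plus a binary
m/z-presence sub-vector); observations are compared by the weighted,
normalized Euclidean distance

    D(a, b) = sqrt(sum(((a_i - b_i) * w_i)^2)) / sqrt(sum(w_i^2))

which is 0 for identical observations and 1 for maximally different
ones.  Downlink ordering greedily maximizes SUE-per-byte with a
penalty on similarity to already-selected observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from acmems.config import AcmeConfig
from acmems.detect import DetectionResult
from acmems.errors import ConfigError, ValidationError

__all__ = [
    "DdVector",
    "normalize_feature",
    "compute_sue",
    "extract_sue_features",
    "compute_dd",
    "dd_distance",
    "rank_downlink",
]


def normalize_feature(x: float, x_max: float) -> float:
    """Saturating square-root normalization onto [0, 1]."""
    if x_max <= 0:
        raise ConfigError("x_max must be positive")
    if x < 0:
        raise ValidationError("feature values must be non-negative")
    if x >= x_max:
        return 1.0
    return float(np.sqrt(x / x_max))


def compute_sue(features: list[tuple[float, float]]) -> float:
    """Weighted average of normalized features; ``features`` is (y, w)."""
    weights = [w for _, w in features]
    if not weights or sum(weights) <= 0:
        raise ConfigError("SUE undefined: all feature weights are zero")
    return float(sum(y * w for y, w in features) / sum(weights))


def extract_sue_features(
    detection: DetectionResult, cfg: AcmeConfig | None = None
) -> dict[str, float]:
    """Raw (unnormalized) SUE feature values for one observation.

    Features: (a) valid peaks whose m/z matches the onboard priority-
    compound list within tolerance, (b) total valid peaks, (c) mean
    z-score of valid peaks, (d) unique migration times at 36 s
    granularity, (e) unique m/z at 1 amu granularity.
    """
    cfg = cfg or AcmeConfig()
    peaks = detection.valid
    if not peaks:
        return {spec.name: 0.0 for spec in cfg.sue_features}
    compound_mz = np.asarray(cfg.compound_mz, dtype=float)
    n_compound = sum(
        1 for p in peaks
        if compound_mz.size and np.min(np.abs(compound_mz - p.center_mz)) <= cfg.compound_tolerance
    )
    unique_times = len({int(p.center_time // cfg.time_granularity) for p in peaks})
    unique_mz = len({int(p.center_mz // cfg.mz_granularity) for p in peaks})
    return {
        "priority_compound_peaks": float(n_compound),
        "total_valid_peaks": float(len(peaks)),
        "mean_z_score": float(np.mean([p.z_score for p in peaks])),
        "unique_migration_times": float(unique_times),
        "unique_mz": float(unique_mz),
    }


def observation_sue(detection: DetectionResult, cfg: AcmeConfig | None = None) -> float:
    """SUE of one observation from its detection result."""
    cfg = cfg or AcmeConfig()
    raw = extract_sue_features(detection, cfg)
    pairs = [
        (normalize_feature(raw[spec.name], spec.x_max), spec.weight)
        for spec in cfg.sue_features
    ]
    return compute_sue(pairs)


@dataclass
class DdVector:
    """Diversity descriptor: normalized values with per-element weights."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape:
            raise ValidationError("DD values and weights must have equal length")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValidationError("DD elements must lie in [0, 1]")


def _dd_normalize(x: float, x_max: float, use_sqrt: bool) -> float:
    if use_sqrt:
        return normalize_feature(x, x_max)
    return float(min(max(x, 0.0) / x_max, 1.0))


def compute_dd(
    detection: DetectionResult,
    bg_mean: float,
    cfg: AcmeConfig | None = None,
) -> DdVector:
    """Diversity descriptor for one observation.

    Elements: normalized average background level, normalized SD of the
    background near detected peaks (the mean of per-peak local noise
    SDs), then one binary presence flag per coarse m/z bin (10 amu over
    the instrument range), whose cumulative weight of 1.0 is split
    evenly across the bins.
    """
    cfg = cfg or AcmeConfig()
    mean_spec, sd_spec, presence_spec = cfg.dd_features
    peaks = detection.valid
    bg_sd_near_peaks = float(np.mean([p.bg_sd for p in peaks])) if peaks else 0.0
    n_bins = cfg.n_presence_bins
    presence = np.zeros(n_bins)
    for p in peaks:
        idx = int((p.center_mz - cfg.mz_bin_lo) // cfg.mz_bin_width)
        if 0 <= idx < n_bins:
            presence[idx] = 1.0
    values = np.concatenate([
        [_dd_normalize(bg_mean, mean_spec.x_max, cfg.dd_sqrt_normalization)],
        [_dd_normalize(bg_sd_near_peaks, sd_spec.x_max, cfg.dd_sqrt_normalization)],
        presence,
    ])
    weights = np.concatenate([
        [mean_spec.weight], [sd_spec.weight],
        np.full(n_bins, presence_spec.weight / n_bins),
    ])
    return DdVector(values=values, weights=weights)


def dd_distance(a: DdVector, b: DdVector) -> float:
    """Weighted, normalized Euclidean distance in [0, 1]."""
    if a.values.shape != b.values.shape:
        raise ValidationError("DD vectors must have equal length")
    if not np.allclose(a.weights, b.weights):
        raise ValidationError("DD vectors must share weights")
    w = a.weights
    num = np.sqrt(np.sum(((a.values - b.values) * w) ** 2))
    den = np.sqrt(np.sum(w ** 2))
    return float(num / den) if den > 0 else 0.0


def rank_downlink(
    bundles: list,
    dd_penalty: float | None = None,
    bins: list[int] | None = None,
) -> list[int]:
    """Greedy downlink ordering; returns indices into ``bundles``.

    Each bundle must expose ``sue`` (float), ``dd`` (DdVector or array
    with shared weights) and ``total_bytes``.  Within each priority bin
    (higher bin labels strictly first) the next pick maximizes

        SUE/bytes - lambda * (1 - min distance to already-selected)

    With ``dd_penalty=0`` this reduces to a pure SUE-per-byte sort.
    When ``dd_penalty`` is None it defaults to 0.1 of the largest
    SUE-per-byte value, so the penalty acts on the utility scale.
    """
    n = len(bundles)
    if n == 0:
        return []
    if bins is None:
        bins = [0] * n
    if len(bins) != n:
        raise ValidationError("bins must match bundles in length")

    def spb(b) -> float:
        size = max(getattr(b, "total_bytes"), 1)
        return b.sue / size

    if dd_penalty is None:
        dd_penalty = 0.1 * max(spb(b) for b in bundles)

    def dist(i: int, j: int) -> float:
        di, dj = bundles[i].dd, bundles[j].dd
        if isinstance(di, DdVector):
            return dd_distance(di, dj)
        di, dj = np.asarray(di, float), np.asarray(dj, float)
        den = np.sqrt(di.size) if di.size else 1.0
        return float(np.sqrt(np.sum((di - dj) ** 2)) / den)

    order: list[int] = []
    selected: list[int] = []
    for level in sorted(set(bins), reverse=True):
        remaining = [i for i in range(n) if bins[i] == level]
        while remaining:
            def score(i: int) -> float:
                if not selected:
                    return spb(bundles[i])
                d_min = min(dist(i, j) for j in selected)
                return spb(bundles[i]) - dd_penalty * (1.0 - d_min)
            best = max(remaining, key=lambda i: (score(i), -i))
            remaining.remove(best)
            selected.append(best)
            order.append(best)
    return order
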