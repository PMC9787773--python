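"""Synthetic CE-MS observation generator with ground truth.

Two reference data-set styles are produced:

* **golden** — a single uniform noise field with non-overlapping 2D
  Gaussian peaks whose z-scores all exceed 10: ideal conditions.
* **silver** — several horizontal bands of differing noise mean/SD,
  cliff-like "salt front" features (narrow in m/z, persisting in
  time), and peaks with z-scores exceeding 5: lab-like conditions.

plus a two-peak **overlap series** that places pairs of equal-m/z
peaks at controlled time separations to probe how detection degrades
as peaks merge.

Noise model: ion counts are drawn as rounded Gaussians (per-region
mean and SD) truncated at zero — a positive, discrete surrogate for
detector counting noise that matches the mean/SD parameterization used
by the background summarizer.  Peak amplitudes are expressed through
their z-score (height over the local noise SD); z-scores are drawn
log-uniformly over two decades above the floor, mimicking the orders-
of-magnitude concentration spread of real samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from acmems.errors import PlacementError
from acmems.msdata import Observation, save_observation

__all__ = [
    "GroundTruthPeak",
    "NoiseRegion",
    "SaltFront",
    "SimSample",
    "generate_golden",
    "generate_silver",
    "generate_overlap_series",
    "write_sample",
    "DEFAULT_GRID_SHAPE",
]

# Desk-scale default grid: m/z 70-117.92 at 0.08 amu (600 rows),
# 1000 s at 0.5 s (2000 cols).  Full-size 5000 x 4000 grids are
# supported by passing grid_shape explicitly.
DEFAULT_GRID_SHAPE: tuple[int, int] = (600, 2000)
MZ_START, MZ_STEP = 70.0, 0.08
TIME_STEP = 0.5

# peak shape defaults: time SDs span the filterable width range,
# m/z SDs a fraction of the narrow DoG kernel
SIGMA_T_RANGE = (1.0, 4.5)      # s
SIGMA_MZ_RANGE = (0.1, 0.3)     # amu
Z_DECADES = 1.0                 # z drawn log-uniformly over this many decades
Z_MARGIN = 0.02                 # decades above min_z (keeps z strictly > min_z)

GOLDEN_NOISE_MEAN = 50.0
GOLDEN_NOISE_SD = 10.0
SILVER_MEAN_RANGE = (30.0, 150.0)
SILVER_SD_RANGE = (8.0, 20.0)
FRONT_AMPLITUDE_RANGE = (50.0, 300.0)
FRONT_WIDTH_RANGE = (0.5, 2.0)  # amu

_MAX_TRIES = 1000


@dataclass
class GroundTruthPeak:
    """One injected 2D Gaussian peak."""

    mz: float          # amu
    time: float        # s
    height: float      # counts above local background
    sigma_mz: float    # amu
    sigma_t: float     # s
    z_score: float     # height / local noise SD


@dataclass
class NoiseRegion:
    """Axis-aligned rectangle of (approximately) uniform noise."""

    mz_lo: float
    mz_hi: float
    t_lo: float
    t_hi: float
    mean: float
    sd: float


@dataclass
class SaltFront:
    """Cliff-like background elevation: narrow in m/z, persistent in time."""

    mz_lo: float
    mz_hi: float
    t_onset: float
    amplitude: float


@dataclass
class SimSample:
    """A simulated observation with its unambiguous truth source."""

    obs: Observation
    truth: list[GroundTruthPeak]
    regions: list[NoiseRegion]
    seed: int
    fronts: list[SaltFront] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _axes(grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    n_mz, n_time = grid_shape
    return (
        MZ_START + MZ_STEP * np.arange(n_mz),
        TIME_STEP * np.arange(n_time),
    )


def _draw_z(rng: np.random.Generator, min_z: float, n: int) -> np.ndarray:
    return min_z * 10.0 ** rng.uniform(Z_MARGIN, Z_DECADES, size=n)


def _place_peaks(
    rng: np.random.Generator,
    n_peaks: int,
    grid_shape: tuple[int, int],
    sigma_t_range: tuple[float, float] = SIGMA_T_RANGE,
) -> list[tuple[int, int, float, float]]:
    """Rejection-sample peak centers so no two peaks collide.

    Two peaks collide when they are simultaneously close on both axes:
    within the larger of 3*(sigma1+sigma2) and the non-maximum-
    suppression footprint (19 m/z bins, 6 time bins for the default
    detection kernels).  Returns (row, col, sigma_mz, sigma_t) tuples.
    """
    n_mz, n_time = grid_shape
    row_margin = 8
    col_margin = 66
    placed: list[tuple[int, int, float, float]] = []
    for _ in range(n_peaks):
        for attempt in range(_MAX_TRIES):
            s_mz = rng.uniform(*SIGMA_MZ_RANGE)
            s_t = rng.uniform(*sigma_t_range)
            r = int(rng.integers(row_margin, n_mz - row_margin))
            c = int(rng.integers(col_margin, n_time - col_margin))
            ok = True
            for (pr, pc, pmz, pt) in placed:
                dr_lim = max(int(np.ceil(3 * (s_mz + pmz) / MZ_STEP)), 19)
                dc_lim = max(int(np.ceil(3 * (s_t + pt) / TIME_STEP)), 6)
                if abs(r - pr) <= dr_lim and abs(c - pc) <= dc_lim:
                    ok = False
                    break
            if ok:
                placed.append((r, c, s_mz, s_t))
                break
        else:
            raise PlacementError(
                f"could not place peak {len(placed) + 1}/{n_peaks} "
                f"after {_MAX_TRIES} tries"
            )
    return placed


def _add_gaussian(counts: np.ndarray, r: int, c: int, h: float,
                  s_mz_bins: float, s_t_bins: float) -> None:
    """Add a 2D separable Gaussian onto a local patch (in place)."""
    n_mz, n_time = counts.shape
    er = int(np.ceil(4 * s_mz_bins))
    ec = int(np.ceil(4 * s_t_bins))
    r0, r1 = max(0, r - er), min(n_mz, r + er + 1)
    c0, c1 = max(0, c - ec), min(n_time, c + ec + 1)
    gy = np.exp(-0.5 * ((np.arange(r0, r1) - r) / s_mz_bins) ** 2)
    gx = np.exp(-0.5 * ((np.arange(c0, c1) - c) / s_t_bins) ** 2)
    counts[r0:r1, c0:c1] += h * np.outer(gy, gx)


def _render(
    rng: np.random.Generator,
    grid_shape: tuple[int, int],
    regions: list[NoiseRegion],
    fronts: list[SaltFront],
    peaks: list[GroundTruthPeak],
    seed: int,
    meta: dict | None = None,
) -> SimSample:
    """Noise field + fronts + analytic peaks, rounded and clipped at 0."""
    n_mz, n_time = grid_shape
    mz_axis, time_axis = _axes(grid_shape)
    counts = np.empty(grid_shape, dtype=float)
    for reg in regions:
        rows = slice(*np.searchsorted(mz_axis, [reg.mz_lo, reg.mz_hi]))
        cols = slice(*np.searchsorted(time_axis, [reg.t_lo, reg.t_hi]))
        block_shape = (rows.stop - rows.start, cols.stop - cols.start)
        counts[rows, cols] = rng.normal(reg.mean, reg.sd, size=block_shape)
    for fr in fronts:
        rows = slice(*np.searchsorted(mz_axis, [fr.mz_lo, fr.mz_hi]))
        cols = slice(np.searchsorted(time_axis, fr.t_onset), n_time)
        counts[rows, cols] += fr.amplitude
    for pk in peaks:
        r = int(round((pk.mz - MZ_START) / MZ_STEP))
        c = int(round(pk.time / TIME_STEP))
        _add_gaussian(counts, r, c, pk.height, pk.sigma_mz / MZ_STEP, pk.sigma_t / TIME_STEP)
    counts = np.clip(np.round(counts), 0.0, None)
    obs = Observation(counts, mz_axis, time_axis, meta=dict(meta or {}))
    return SimSample(obs=obs, truth=peaks, regions=regions, seed=seed, fronts=fronts)


def _region_at(regions: list[NoiseRegion], mz: float, t: float) -> NoiseRegion:
    for reg in regions:
        if reg.mz_lo <= mz < reg.mz_hi and reg.t_lo <= t < reg.t_hi:
            return reg
    return regions[0]


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_golden(
    seed: int,
    n_peaks: int = 100,
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
    min_z: float = 10.0,
    noise_mean: float = GOLDEN_NOISE_MEAN,
    noise_sd: float = GOLDEN_NOISE_SD,
) -> SimSample:
    """Ideal-conditions sample: uniform noise, all peak z-scores > min_z."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x601d]))
    mz_axis, time_axis = _axes(grid_shape)
    region = NoiseRegion(
        mz_lo=float(mz_axis[0]), mz_hi=float(mz_axis[-1]) + MZ_STEP,
        t_lo=float(time_axis[0]), t_hi=float(time_axis[-1]) + TIME_STEP,
        mean=noise_mean, sd=noise_sd,
    )
    placed = _place_peaks(rng, n_peaks, grid_shape)
    zs = _draw_z(rng, min_z, len(placed))
    peaks = [
        GroundTruthPeak(
            mz=float(mz_axis[r]), time=float(time_axis[c]),
            height=float(z * noise_sd), sigma_mz=s_mz, sigma_t=s_t,
            z_score=float(z),
        )
        for (r, c, s_mz, s_t), z in zip(placed, zs)
    ]
    return _render(rng, grid_shape, [region], [], peaks, seed,
                   meta={"kind": "golden", "seed": seed})


def generate_silver(
    seed: int,
    n_peaks: int = 100,
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
    min_z: float = 5.0,
    n_salt_fronts: int = 3,
    n_noise_regions: int = 4,
) -> SimSample:
    """Lab-like sample: banded noise, salt fronts, peak z-scores > min_z.

    The background is split into ``n_noise_regions`` horizontal bands of
    differing mean and SD (adjacent means forced apart by >= 15 counts);
    ``n_salt_fronts`` cliff-like elevations (0.5-2 amu wide, onset at a
    random time, persisting to the end) are added on top.  Each truth
    peak's z-score is defined against its own band's noise SD.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5117e5]))
    n_mz, n_time = grid_shape
    mz_axis, time_axis = _axes(grid_shape)

    # horizontal noise bands
    n_bands = max(1, n_noise_regions)
    min_rows = max(20, n_mz // (4 * n_bands))
    while True:
        cuts = np.sort(rng.integers(min_rows, n_mz - min_rows, size=n_bands - 1)) \
            if n_bands > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [n_mz]])
        if np.all(np.diff(bounds) >= min_rows):
            break
    regions: list[NoiseRegion] = []
    prev_mean = None
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        for _ in range(_MAX_TRIES):
            mean = rng.uniform(*SILVER_MEAN_RANGE)
            if prev_mean is None or abs(mean - prev_mean) >= 15.0:
                break
        sd = rng.uniform(*SILVER_SD_RANGE)
        regions.append(NoiseRegion(
            mz_lo=float(mz_axis[lo]),
            mz_hi=float(mz_axis[hi - 1]) + MZ_STEP,
            t_lo=float(time_axis[0]),
            t_hi=float(time_axis[-1]) + TIME_STEP,
            mean=mean, sd=sd,
        ))
        prev_mean = mean

    fronts: list[SaltFront] = []
    for _ in range(n_salt_fronts):
        width = rng.uniform(*FRONT_WIDTH_RANGE)
        lo = rng.uniform(mz_axis[0], mz_axis[-1] - width)
        fronts.append(SaltFront(
            mz_lo=float(lo), mz_hi=float(lo + width),
            t_onset=float(rng.uniform(0.15, 0.6) * time_axis[-1]),
            amplitude=float(rng.uniform(*FRONT_AMPLITUDE_RANGE)),
        ))

    placed = _place_peaks(rng, n_peaks, grid_shape)
    zs = _draw_z(rng, min_z, len(placed))
    peaks = []
    for (r, c, s_mz, s_t), z in zip(placed, zs):
        mz, t = float(mz_axis[r]), float(time_axis[c])
        sd = _region_at(regions, mz, t).sd
        peaks.append(GroundTruthPeak(
            mz=mz, time=t, height=float(z * sd),
            sigma_mz=s_mz, sigma_t=s_t, z_score=float(z),
        ))
    return _render(rng, grid_shape, regions, fronts, peaks, seed,
                   meta={"kind": "silver", "seed": seed})


def generate_overlap_series(
    seed: int,
    separations: Sequence[float],
    peak_width_range: tuple[float, float] = (1.0, 27.0),
    n_pairs_per_sample: int = 140,
    min_z: float = 5.0,
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
    noise_mean: float = GOLDEN_NOISE_MEAN,
    noise_sd: float = GOLDEN_NOISE_SD,
) -> list[SimSample]:
    """Pairs of equal-m/z peaks at controlled time separations.

    One sample per separation; pairs are laid out on a slot grid (rows
    45 bins apart, time slots 150 bins apart) so different pairs never
    interact.  One full peak width (6 sigma) is drawn uniformly from
    ``peak_width_range`` per pair and shared by both members, so the
    separation sweep compares like with like; amplitudes are drawn
    independently.  Pair parameters, positions and the noise field are
    shared across all separations (common random draws), so recall
    differences between separations are a paired comparison, not
    sampling noise.  The truth lists both members even when the pair
    coincides.
    """
    n_mz, n_time = grid_shape
    mz_axis, time_axis = _axes(grid_shape)
    max_sep_bins = int(round(max(separations) / TIME_STEP)) if len(separations) else 0

    # one draw of pair geometry and shapes, reused for every separation
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0e1a]))
    row_slots = list(range(30, n_mz - 30, 45))
    col_slots = list(range(60, n_time - 60 - max_sep_bins - 30, 150))
    slots = [(r, c) for r in row_slots for c in col_slots]
    if n_pairs_per_sample > len(slots):
        raise PlacementError(
            f"{n_pairs_per_sample} pairs exceed {len(slots)} available slots"
        )
    pick = rng.permutation(len(slots))[:n_pairs_per_sample]
    pair_params = []
    for idx in pick:
        r, c = slots[idx]
        r += int(rng.integers(-5, 6))
        c += int(rng.integers(-10, 11))
        pair_params.append({
            "row": r, "col": c,
            "sigma_mz": rng.uniform(*SIGMA_MZ_RANGE),
            "width": rng.uniform(*peak_width_range),
            "z": [float(z) for z in _draw_z(rng, min_z, 2)],
        })
    noise_seed = int(rng.integers(0, 2**31))

    region = NoiseRegion(
        mz_lo=float(mz_axis[0]), mz_hi=float(mz_axis[-1]) + MZ_STEP,
        t_lo=float(time_axis[0]), t_hi=float(time_axis[-1]) + TIME_STEP,
        mean=noise_mean, sd=noise_sd,
    )
    samples: list[SimSample] = []
    for sep in separations:
        sep_bins = int(round(sep / TIME_STEP))
        peaks: list[GroundTruthPeak] = []
        for pp in pair_params:
            for member in range(2):
                peaks.append(GroundTruthPeak(
                    mz=float(mz_axis[pp["row"]]),
                    time=float(time_axis[pp["col"] + member * sep_bins]),
                    height=float(pp["z"][member] * noise_sd),
                    sigma_mz=pp["sigma_mz"],
                    sigma_t=pp["width"] / 6.0,
                    z_score=pp["z"][member],
                ))
        noise_rng = np.random.default_rng(noise_seed)
        samples.append(_render(noise_rng, grid_shape, [region], [], peaks, seed,
                               meta={"kind": "overlap", "separation_s": float(sep),
                                     "seed": seed}))
    return samples


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_sample(sample: SimSample, out_dir: str | Path, stem: str = "sample") -> None:
    """Write observation container plus truth and regions CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_observation(sample.obs, out / f"{stem}.h5")
    pd.DataFrame(
        [
            {"mz": p.mz, "time_s": p.time, "height": p.height,
             "sigma_mz": p.sigma_mz, "sigma_t": p.sigma_t, "z_score": p.z_score}
            for p in sample.truth
        ]
    ).to_csv(out / f"{stem}_truth.csv", index=False)
    pd.DataFrame(
        [
            {"mz_lo": r.mz_lo, "mz_hi": r.mz_hi, "t_lo": r.t_lo, "t_hi": r.t_hi,
             "mean": r.mean, "sd": r.sd}
            for r in sample.regions
        ]
    ).to_csv(out / f"{stem}_regions.csv", index=False)
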