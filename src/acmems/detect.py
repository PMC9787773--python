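"""Peak detection pipeline for CE-MS ion-count grids.

Five stages, applied in order:

1. **Background isolation** — a running median along the migration-time
   axis (per m/z row) estimates the slowly varying background, which is
   subtracted with negatives clamped to zero.
2. **Difference-of-Gaussians (DoG) filtering** — the residual is
   convolved with a zero-sum bandpass kernel (narrow Gaussian minus
   wide Gaussian) that enhances peak-like blobs.
3. **Non-maximum suppression** — strict local maxima of the DoG
   response with positive value become peak candidates.
4. **Characterization** — each candidate is cropped from the *raw*
   grid, a local background (per-row median over the flanking regions
   B1 and B2) is removed, and height, volume, width, z-score, Gaussian
   loss and background statistics are extracted.
5. **Filtering** — an interpretable expert system thresholds z-score,
   volume, Gaussian loss and width to separate valid target peaks from
   spurious candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from acmems.config import DetectConfig
from acmems.errors import ConfigError, ValidationError
from acmems.msdata import Observation

__all__ = [
    "PeakProperties",
    "DetectionResult",
    "estimate_background",
    "subtract_background",
    "dog_filter",
    "find_candidates",
    "characterize_peak",
    "apply_filter",
    "detect_peaks",
]

log = logging.getLogger(__name__)


@dataclass
class PeakProperties:
    """Extracted properties of one peak candidate.

    ``width`` is the fitted full peak duration, defined as six fitted
    standard deviations (+-3 sigma) of the Gaussian fit to the central
    m/z slice of the locally background-subtracted crop.  ``z_score``
    is the peak height divided by the larger of the two flanking-region
    noise SDs (with a one-count noise floor).  ``gauss_loss`` is the
    mean squared error between the central slice and its Gaussian fit,
    normalized by the squared peak height so it reads as a fraction.
    """

    center_mz: float
    center_time: float          # s
    height: float               # counts, above local background
    volume: float               # counts, integrated over the central region
    width: float                # s, 6 sigma of the Gaussian fit
    z_score: float
    gauss_loss: float
    bg_level: float             # counts, max of the two flank medians
    bg_sd: float                # counts, max of the two flank SDs
    bg_diff: float              # counts, |B1 median - B2 median|
    bg_ratio: float             # min(B1/B2, B2/B1), in [0, 1]
    valid: bool = False
    row: int = -1               # grid indices of the candidate maximum
    col: int = -1
    unfit: bool = False         # crop clipped too severely at a grid edge


@dataclass
class DetectionResult:
    """Valid peaks, the complete candidate list, and pipeline flags.

    The complete candidate list is retained (it stays available onboard
    for operator request); ``over_sensitive`` is set when the number of
    valid peaks exceeds the configured cap.
    """

    valid: list[PeakProperties]
    candidates: list[PeakProperties]
    over_sensitive: bool = False
    background: np.ndarray | None = None

    def __iter__(self):
        return iter((self.valid, self.candidates))


# ---------------------------------------------------------------------------
# Stage 1: background isolation
# ---------------------------------------------------------------------------

def estimate_background(obs: Observation, median_window: float | None = None) -> np.ndarray:
    """Per-row running median along the time axis (reflective edges).

    ``median_window`` is in seconds; the window in bins is rounded and
    forced odd.  Raises :class:`ConfigError` if the window spans fewer
    than 3 bins or exceeds the time axis.
    """
    if median_window is None:
        median_window = DetectConfig().median_window
    dt = obs.time_step
    w = int(round(median_window / dt))
    if w % 2 == 0:
        w += 1
    if w < 3:
        raise ConfigError(f"median window of {median_window} s spans fewer than 3 time bins")
    if w > obs.shape[1]:
        raise ConfigError("median window longer than the time axis")
    return ndimage.median_filter(obs.counts, size=(1, w), mode="reflect")


def subtract_background(obs: Observation | np.ndarray, background: np.ndarray) -> np.ndarray:
    """Elementwise ``max(counts - background, 0)``."""
    counts = obs.counts if isinstance(obs, Observation) else np.asarray(obs, dtype=float)
    if counts.shape != background.shape:
        raise ValidationError("counts and background shapes differ")
    return np.maximum(counts - background, 0.0)


# ---------------------------------------------------------------------------
# Stage 2: DoG filtering
# ---------------------------------------------------------------------------

def _sigma_bins(sigma: tuple[float, float], mz_step: float, time_step: float) -> tuple[float, float]:
    return sigma[0] / mz_step, sigma[1] / time_step


def dog_filter(
    residual: np.ndarray,
    cfg: DetectConfig,
    mz_step: float = 0.08,
    time_step: float = 0.5,
) -> np.ndarray:
    """Convolve with a zero-sum difference-of-Gaussians bandpass kernel.

    Each Gaussian is unit-sum normalized, so a constant field maps to
    (numerically) zero.  Kernel SDs are configured in physical units
    and converted to bins via the axis resolutions.
    """
    residual = np.asarray(residual, dtype=float)
    s_small = _sigma_bins(cfg.dog_sigma_small, mz_step, time_step)
    s_large = _sigma_bins(cfg.dog_sigma_large, mz_step, time_step)
    # default truncation of 4 SDs; reject kernels that exceed the grid
    if any(2 * int(4 * s + 0.5) + 1 > dim for s, dim in zip(s_large, residual.shape)):
        raise ConfigError("DoG kernel larger than the grid")
    small = ndimage.gaussian_filter(residual, sigma=s_small, mode="reflect")
    large = ndimage.gaussian_filter(residual, sigma=s_large, mode="reflect")
    return small - large


# ---------------------------------------------------------------------------
# Stage 3: non-maximum suppression
# ---------------------------------------------------------------------------

def _nms_halfwidths(cfg: DetectConfig, mz_step: float, time_step: float) -> tuple[int, int]:
    # suppression neighborhood at the scale of the narrow (blob-matched)
    # kernel: a wide neighborhood lets the negative skirt of a strong
    # peak's DoG response suppress genuine neighbors
    s_mz, s_t = _sigma_bins(cfg.dog_sigma_small, mz_step, time_step)
    return max(1, int(round(s_mz))), max(1, int(round(s_t)))


def find_candidates(
    dog: np.ndarray,
    cfg: DetectConfig,
    mz_step: float = 0.08,
    time_step: float = 0.5,
) -> list[tuple[int, int]]:
    """Strict local maxima of the DoG response with positive value.

    The neighborhood is one narrow-kernel SD footprint per axis.  The
    result is sorted by descending response, ties broken by ascending
    (row, col).  Candidates within 2 bins (both axes) of a stronger
    candidate are suppressed.
    """
    dog = np.asarray(dog, dtype=float)
    hr, hc = _nms_halfwidths(cfg, mz_step, time_step)
    footprint = np.ones((2 * hr + 1, 2 * hc + 1), dtype=bool)
    footprint[hr, hc] = False
    neigh = ndimage.maximum_filter(dog, footprint=footprint, mode="constant", cval=-np.inf)
    rows, cols = np.nonzero((dog > neigh) & (dog > 0))
    if rows.size == 0:
        return []
    order = np.lexsort((cols, rows, -dog[rows, cols]))
    rows, cols = rows[order], cols[order]
    kept: list[tuple[int, int]] = []
    taken = np.zeros(dog.shape, dtype=bool)
    for r, c in zip(rows.tolist(), cols.tolist()):
        if taken[r, c]:
            continue
        kept.append((r, c))
        taken[max(0, r - 2):r + 3, max(0, c - 2):c + 3] = True
    return kept


# ---------------------------------------------------------------------------
# Stage 4: characterization
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _moment_sigma(x: np.ndarray, y: np.ndarray) -> float:
    yy = np.clip(y, 0.0, None)
    tot = yy.sum()
    if tot <= 0:
        return 1.0
    m = float((x * yy).sum() / tot)
    var = float((((x - m) ** 2) * yy).sum() / tot)
    return max(np.sqrt(var), 0.3)


def _fit_gaussian(
    x: np.ndarray, y: np.ndarray, mu0: float, mu_tol: float = 6.0
) -> tuple[float, float, float, bool]:
    """Bounded least-squares Gaussian fit; returns (a, mu, sigma, converged).

    The center is confined to ``mu_tol`` bins around the candidate (the
    blob detector localizes maxima to a bin or two) and sigma to a third
    of the window, so a neighboring peak or the baseline cannot hijack
    the fit.
    """
    a0 = max(float(y.max()), 1e-9)
    sig_hi = max(len(x) / 3.0, 1.0)
    s0 = float(np.clip(_moment_sigma(x, y), 0.35, sig_hi - 1e-6))
    mu0 = float(np.clip(mu0, x[0], x[-1]))

    def admissible(a: float, mu: float, sigma: float) -> bool:
        return (
            np.isfinite([a, mu, sigma]).all()
            and a > 0
            and 0 < sigma <= sig_hi
            and abs(mu - mu0) <= mu_tol
        )

    # fast unconstrained fit first; fall back to a bounded fit when the
    # unconstrained solution wanders off the candidate or degenerates
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=(a0, mu0, s0), maxfev=200)
        a, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        if admissible(a, mu, sigma):
            return a, mu, sigma, True
    except RuntimeError:
        pass
    try:
        popt, _ = curve_fit(
            _gauss, x, y, p0=(a0, mu0, s0),
            bounds=([0.0, mu0 - mu_tol, 0.3], [10.0 * a0 + 10.0, mu0 + mu_tol, sig_hi]),
            maxfev=300,
        )
        a, mu, sigma = (float(v) for v in popt)
        if not np.isfinite([a, mu, sigma]).all() or a <= 0 or sigma <= 0:
            raise RuntimeError("degenerate fit")
        return a, mu, sigma, True
    except RuntimeError:
        return a0, mu0, s0, False


_ATTENUATION_CACHE: dict[float, float] = {}


def _smooth_attenuation(s_k: float) -> float:
    """White-noise variance attenuation of the Gaussian smoothing kernel.

    Equals the sum of squared kernel taps (1 for no smoothing); computed
    from the discrete kernel actually applied, not the continuous limit.
    """
    f = _ATTENUATION_CACHE.get(s_k)
    if f is None:
        impulse = np.zeros(2 * int(np.ceil(4 * s_k)) + 9)
        impulse[impulse.size // 2] = 1.0
        kernel = ndimage.gaussian_filter1d(impulse, sigma=s_k)
        f = float(np.sum(kernel ** 2))
        _ATTENUATION_CACHE[s_k] = f
    return f


def _flank_sd(flank: np.ndarray) -> float:
    """Robust noise SD of a flank block via the scaled MAD.

    After local background subtraction the flank residuals are roughly
    symmetric noise; the median absolute deviation ignores the minority
    of cells covered by the tails of a neighboring peak.
    """
    if flank.size == 0 or flank.shape[1] < 3:
        return 0.0
    med = np.median(flank)
    return float(1.4826 * np.median(np.abs(flank - med)))


def characterize_peak(
    obs: Observation,
    candidate: tuple[int, int],
    cfg: DetectConfig,
    quick_reject_z: float | None = None,
) -> PeakProperties:
    """Crop, locally background-subtract, fit, and measure one candidate.

    The crop spans ``cfg.crop_mz_bins x cfg.crop_time_bins`` (clipped at
    grid edges).  The time extent is partitioned into a pre-peak flank
    B1, a central region C (6 fitted sigmas, at least ``min_c_bins``),
    and a post-peak flank B2.  The local background is the per-row
    median over B1 and B2.  The Gaussian is fitted to the central m/z
    slice of the subtracted crop after mild smoothing at the narrow
    DoG time scale, so the Gaussian loss measures shape divergence
    above the single-bin noise level; the fitted SD is deconvolved for
    the smoothing kernel before the width is reported.  The loss is
    evaluated on a window around the peak rather than the whole slice
    so that a resolved neighbor elsewhere in the crop does not
    penalize this peak's shape.
    """
    row, col = candidate
    n_mz, n_time = obs.shape
    if not (0 <= row < n_mz and 0 <= col < n_time):
        raise ValidationError(f"candidate {candidate} outside grid {obs.shape}")

    hm = (cfg.crop_mz_bins - 1) // 2
    ht = (cfg.crop_time_bins - 1) // 2
    r0, r1 = max(0, row - hm), min(n_mz, row + hm + 1)
    c0, c1 = max(0, col - ht), min(n_time, col + ht + 1)
    crop = obs.counts[r0:r1, c0:c1]
    cc = col - c0              # candidate column within the crop
    cr = row - r0              # candidate row within the crop
    ncols = crop.shape[1]
    x = np.arange(ncols, dtype=float)
    dt = obs.time_step
    s_k = max(cfg.slice_smooth_s / dt, 0.5)   # smoothing scale, bins

    # the central region may never swallow the flanks: without flank
    # columns there is no local background or noise estimate, and the
    # fit degenerates onto the raw baseline
    min_flank = 12
    c_half_cap = max((ncols - 2 * min_flank - 1) // 2, (cfg.min_c_bins - 1) // 2)

    def split(c_half: int) -> tuple[slice, slice, slice]:
        c_half = min(c_half, c_half_cap)
        lo = max(0, cc - c_half)
        hi = min(ncols, cc + c_half + 1)
        return slice(0, lo), slice(lo, hi), slice(hi, ncols)

    def local_subtract(b1: slice, b2: slice) -> np.ndarray:
        flank = np.concatenate([crop[:, b1], crop[:, b2]], axis=1)
        if flank.shape[1] >= 4:
            bg_row = np.median(flank, axis=1)
        else:
            bg_row = np.zeros(crop.shape[0])
        return crop - bg_row[:, None]

    def fit_slice(
        sub: np.ndarray, fit_half: int
    ) -> tuple[np.ndarray, tuple[int, int], tuple[float, float, float, bool]]:
        # fit only a window around the candidate so a resolved neighbor
        # elsewhere in the slice cannot hijack center and width
        smoothed = ndimage.gaussian_filter1d(sub[cr, :], sigma=s_k, mode="reflect")
        w0 = max(0, cc - fit_half)
        w1 = min(ncols, cc + fit_half + 1)
        fit = _fit_gaussian(x[w0:w1], smoothed[w0:w1], float(cc))
        return smoothed, (w0, w1), fit

    def true_sigma(sigma_fit: float) -> float:
        # deconvolve the smoothing kernel from the fitted width
        return float(np.sqrt(max(sigma_fit**2 - s_k**2, 0.09)))

    # pass 1: provisional central region and fit window
    c_half0 = (cfg.min_c_bins - 1) // 2
    b1, c_sl, b2 = split(c_half0)
    sub = local_subtract(b1, b2)

    if quick_reject_z is not None:
        # cheap screen: candidates whose raw peak-to-noise ratio is far
        # below the filter threshold never reach the fitting stage
        central0 = sub[:, c_sl]
        p0 = float(central0.max()) if central0.size else 0.0
        sd0 = max(_flank_sd(sub[:, b1]), _flank_sd(sub[:, b2]))
        if p0 / max(sd0, cfg.noise_floor) < quick_reject_z:
            s_mom = _moment_sigma(x, sub[cr, :])
            return PeakProperties(
                center_mz=float(obs.mz_axis[row]),
                center_time=float(obs.time_axis[col]),
                height=p0,
                volume=float(np.clip(central0, 0.0, None).sum()),
                width=6.0 * s_mom * dt,
                z_score=p0 / max(sd0, cfg.noise_floor),
                gauss_loss=1.0,
                bg_level=float(np.median(crop)),
                bg_sd=sd0,
                bg_diff=0.0,
                bg_ratio=1.0,
                row=row,
                col=col,
            )

    r_smooth, (w0, w1), (a, mu, sigma_fit, converged) = fit_slice(sub, 10)

    # pass 2: widen the central region and fit window to 3 fitted sigmas
    sigma_bins = true_sigma(sigma_fit)
    c_half = max(int(round(3 * sigma_bins)), c_half0)
    if c_half > c_half0 + 1:
        b1, c_sl, b2 = split(c_half)
        sub = local_subtract(b1, b2)
        r_smooth, (w0, w1), (a, mu, sigma_fit, converged) = fit_slice(
            sub, max(int(round(3 * sigma_fit)), 8)
        )
        sigma_bins = true_sigma(sigma_fit)
        c_half = max(int(round(3 * sigma_bins)), c_half0)
        b1, c_sl, b2 = split(c_half)

    nominal_c = 2 * c_half + 1
    actual_c = c_sl.stop - c_sl.start
    unfit = actual_c < 0.5 * nominal_c or crop.shape[0] < 0.5 * cfg.crop_mz_bins

    central = sub[:, c_sl]
    p = float(central.max()) if central.size else 0.0
    volume = float(np.clip(central, 0.0, None).sum()) if central.size else 0.0

    bg_sd = max(_flank_sd(sub[:, b1]), _flank_sd(sub[:, b2]))
    z = p / max(bg_sd, cfg.noise_floor)

    # background level/asymmetry on the raw crop flanks (pre-subtraction),
    # so the level and ratio keep their physical meaning
    raw1, raw2 = crop[:, b1], crop[:, b2]
    b1_hat = float(np.median(raw1)) if raw1.size else 0.0
    b2_hat = float(np.median(raw2)) if raw2.size else 0.0
    bg_level = max(b1_hat, b2_hat)
    bg_diff = abs(b1_hat - b2_hat)
    if max(b1_hat, b2_hat) > 0:
        bg_ratio = min(b1_hat, b2_hat) / max(b1_hat, b2_hat)
    else:
        bg_ratio = 1.0

    width = 6.0 * sigma_bins * dt
    # structures wider than the background median window are background
    # by the pipeline's own definition, not fittable peaks
    if width > cfg.median_window:
        converged = False

    if converged and p > 0:
        g = _gauss(x[w0:w1], a, mu, sigma_fit)
        mse = float(np.mean((r_smooth[w0:w1] - g) ** 2))
        # the slice MSE of a perfect Gaussian peak is the smoothed noise
        # variance; subtract that known floor so the loss measures shape
        # structure above the noise, not the noise itself
        noise_floor_mse = _smooth_attenuation(s_k) * bg_sd ** 2
        gauss_loss = max(mse - noise_floor_mse, 0.0) / p ** cfg.gauss_loss_exponent
    else:
        gauss_loss = 1.0
    center_time = float(np.interp(mu, x, obs.time_axis[c0:c1])) if converged else float(
        obs.time_axis[col]
    )

    return PeakProperties(
        center_mz=float(obs.mz_axis[row]),
        center_time=center_time,
        height=p,
        volume=volume,
        width=width,
        z_score=z,
        gauss_loss=gauss_loss,
        bg_level=bg_level,
        bg_sd=bg_sd,
        bg_diff=bg_diff,
        bg_ratio=bg_ratio,
        row=row,
        col=col,
        unfit=unfit,
    )


# ---------------------------------------------------------------------------
# Stage 5: expert-system filter
# ---------------------------------------------------------------------------

def apply_filter(props: PeakProperties, cfg: DetectConfig) -> bool:
    """Threshold checks separating valid target peaks from spurious ones.

    A candidate is valid iff its z-score, volume and Gaussian loss pass
    their thresholds and its width exceeds the z-dependent minimum
    (peaks at exactly the high-z boundary use the low-z width rule).
    """
    if props.z_score <= cfg.z_threshold:
        return False
    if props.volume <= cfg.volume_threshold:
        return False
    if props.gauss_loss >= cfg.gauss_loss_threshold:
        return False
    width_min = (
        cfg.width_threshold_highz
        if props.z_score > cfg.highz_boundary
        else cfg.width_threshold_lowz
    )
    return props.width > width_min


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def detect_peaks(obs: Observation, cfg: DetectConfig | None = None) -> DetectionResult:
    """Run the five-stage pipeline on one observation.

    Returns the filtered valid peaks and the complete candidate list
    (valid is a subset of candidates).  Candidates whose central region
    is clipped by more than half at a grid edge are dropped with a
    logged reason.  The observation is flagged over-sensitive when the
    valid count exceeds ``cfg.max_peaks``.
    """
    cfg = cfg or DetectConfig()
    background = estimate_background(obs, cfg.median_window)
    residual = subtract_background(obs, background)
    dog = dog_filter(residual, cfg, obs.mz_step, obs.time_step)
    locations = find_candidates(dog, cfg, obs.mz_step, obs.time_step)

    candidates: list[PeakProperties] = []
    quick_z = 0.7 * cfg.z_threshold
    for rc in locations:
        props = characterize_peak(obs, rc, cfg, quick_reject_z=quick_z)
        if props.unfit:
            log.debug("dropping edge-clipped candidate at (%d, %d)", *rc)
            continue
        props.valid = apply_filter(props, cfg)
        candidates.append(props)

    # twin NMS maxima of one blob converge to the same fitted center;
    # keep only the tallest detection per (0.25 amu, 1.5 s) locus
    by_height = sorted(
        (p for p in candidates if p.valid), key=lambda p: -p.height
    )
    deduped: list[PeakProperties] = []
    for p in by_height:
        dup = any(
            abs(p.center_mz - q.center_mz) <= 0.25
            and abs(p.center_time - q.center_time) <= 1.5
            for q in deduped
        )
        if dup:
            p.valid = False
        else:
            deduped.append(p)

    valid = [p for p in candidates if p.valid]
    over = len(valid) > cfg.max_peaks
    if over:
        log.warning("over-sensitive: %d valid peaks exceed cap %d", len(valid), cfg.max_peaks)
    return DetectionResult(valid=valid, candidates=candidates, over_sensitive=over,
                           background=background)
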