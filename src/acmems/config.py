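"""Configuration objects for the full pipeline.

All tunables live in two dataclasses: :class:`DetectConfig` for the
detection stage and :class:`AcmeConfig` for the end-to-end pipeline
(detection, background summarization, product assembly, and the science
utility / diversity feature definitions).  Defaults are the flight-like
reference configuration; everything can be overridden from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from acmems.errors import ConfigError

__all__ = ["DetectConfig", "FeatureSpec", "AcmeConfig", "DEFAULT_COMPOUND_MZ"]


@dataclass
class DetectConfig:
    """Detection-stage parameters.

    The defaults are the reference configuration: a 36 s median-filter
    window for background estimation; a difference-of-Gaussians bandpass
    with a small kernel of SD (0.54 amu, 1.0 s) and a large kernel of
    SD (1.5 amu, 2.9 s); and an expert-system filter requiring z-score
    > 5, volume > 500 ion counts, Gaussian loss < 2%, and a minimum
    width of 1.5 s for z > 10 (2.4 s for 5 < z <= 10).
    """

    median_window: float = 36.0          # s, background median filter
    dog_sigma_large: tuple[float, float] = (1.5, 2.9)   # (amu, s)
    dog_sigma_small: tuple[float, float] = (0.54, 1.0)  # (amu, s)
    z_threshold: float = 5.0
    volume_threshold: float = 500.0      # ion counts
    width_threshold_highz: float = 1.5   # s, applies when z > 10
    width_threshold_lowz: float = 2.4    # s, applies when 5 < z <= 10
    highz_boundary: float = 10.0         # z above which the high-z width rule applies
    gauss_loss_threshold: float = 0.02
    gauss_loss_exponent: int = 2         # loss = MSE(r, g) / p**exponent
    crop_mz_bins: int = 13               # crop extent, rows (~1 amu)
    crop_time_bins: int = 121            # crop extent, cols (~36-60 s)
    max_peaks: int = 500                 # over-sensitivity cap per observation
    noise_floor: float = 1.0             # minimum background SD used in z
    min_c_bins: int = 9                  # minimum central-region width, bins
    slice_smooth_s: float = 0.25         # s, pre-fit smoothing of the central slice

    def __post_init__(self) -> None:
        self.dog_sigma_large = tuple(self.dog_sigma_large)
        self.dog_sigma_small = tuple(self.dog_sigma_small)
        for name in (
            "median_window", "z_threshold", "volume_threshold",
            "width_threshold_highz", "width_threshold_lowz",
            "gauss_loss_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not all(s < l for s, l in zip(self.dog_sigma_small, self.dog_sigma_large)):
            raise ConfigError("dog_sigma_small must be componentwise below dog_sigma_large")


@dataclass
class FeatureSpec:
    """A saturating, weighted feature entering the SUE or DD."""

    name: str
    x_max: float
    weight: float

    def __post_init__(self) -> None:
        if self.x_max <= 0:
            raise ConfigError(f"feature {self.name}: x_max must be positive")
        if self.weight < 0:
            raise ConfigError(f"feature {self.name}: weight must be non-negative")


# Protonated masses ([M+H]+, amu) for a reference list of astrobiology-
# relevant organics (amino acids and nucleobases) within the 70-400 m/z
# range of the instrument; used by the priority-compound SUE feature.
DEFAULT_COMPOUND_MZ: tuple[float, ...] = (
    76.04,   # glycine
    90.05,   # alanine / beta-alanine
    104.07,  # GABA / AIB
    106.05,  # serine
    112.05,  # cytosine
    113.03,  # uracil
    118.09,  # valine
    132.10,  # leucine / isoleucine
    133.06,  # glutamine-like fragment
    134.04,  # aspartic acid
    136.06,  # adenine
    148.06,  # glutamic acid
    152.06,  # guanine
    156.08,  # histidine
    133.06,  # gly-gly
    190.08,  # gly-gly-gly
    244.09,  # cytidine
    268.10,  # adenosine
    284.10,  # guanosine
    243.10,  # thymidine
    245.08,  # uridine
)


def _default_sue_features() -> list[FeatureSpec]:
    return [
        FeatureSpec("priority_compound_peaks", 100, 1.0),
        FeatureSpec("total_valid_peaks", 200, 0.5),
        FeatureSpec("mean_z_score", 100, 0.2),
        FeatureSpec("unique_migration_times", 50, 1.0),
        FeatureSpec("unique_mz", 100, 1.0),
    ]


def _default_dd_features() -> list[FeatureSpec]:
    # the binary m/z-presence sub-vector carries a cumulative weight of 1.0
    return [
        FeatureSpec("mean_background", 50, 0.2),
        FeatureSpec("background_sd_near_peaks", 50, 0.2),
        FeatureSpec("mz_presence", 1.0, 1.0),
    ]


@dataclass
class AcmeConfig:
    """End-to-end pipeline configuration."""

    detect: DetectConfig = field(default_factory=DetectConfig)
    # background summarization
    bg_percentiles: tuple[float, ...] = (90.0, 95.0, 97.0, 99.0)
    bg_max_bytes: int = 100 * 1024
    # product assembly
    max_crops: int = 200
    crop_bit_depth: int = 8
    tic_downsample: int = 4
    tic_bit_depth: int = 8
    tic_alert_sd: float = 5.0
    # prioritization
    sue_features: list[FeatureSpec] = field(default_factory=_default_sue_features)
    dd_features: list[FeatureSpec] = field(default_factory=_default_dd_features)
    dd_sqrt_normalization: bool = False
    dd_penalty: float = 0.1
    compound_mz: tuple[float, ...] = DEFAULT_COMPOUND_MZ
    compound_tolerance: float = 0.5      # amu
    time_granularity: float = 36.0       # s, unique-migration-time bucketing
    mz_granularity: float = 1.0          # amu, unique-m/z bucketing
    mz_bin_lo: float = 70.0              # presence-vector range, amu
    mz_bin_hi: float = 400.0
    mz_bin_width: float = 10.0

    @property
    def n_presence_bins(self) -> int:
        import math
        return math.ceil((self.mz_bin_hi - self.mz_bin_lo) / self.mz_bin_width)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcmeConfig":
        d = dict(d)
        if "detect" in d and isinstance(d["detect"], dict):
            d["detect"] = DetectConfig(**d["detect"])
        for key in ("sue_features", "dd_features"):
            if key in d:
                d[key] = [
                    FeatureSpec(**f) if isinstance(f, dict) else f for f in d[key]
                ]
        for key in ("bg_percentiles", "compound_mz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "AcmeConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
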