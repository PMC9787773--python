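"""End-to-end per-observation processing.

detect -> background summary -> utility/diversity features -> bundle.
Deterministic for a fixed observation and configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from acmems.asdp import AsdpBundle, assemble_bundle
from acmems.bgsummary import select_resolution
from acmems.config import AcmeConfig
from acmems.detect import detect_peaks
from acmems.errors import AcmeError
from acmems.msdata import Observation, load_observation
from acmems.priority import compute_dd, observation_sue

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def run_pipeline(
    obs: Observation | str | Path,
    cfg: AcmeConfig | None = None,
    priority: str = "auto",
    candidates_path: str | Path | None = None,
) -> AsdpBundle:
    """Process one observation into its downlink bundle.

    ``obs`` may be an :class:`Observation` or a path to one.  Stage
    failures abort with a stage-tagged message.
    """
    cfg = cfg or AcmeConfig()
    if not isinstance(obs, Observation):
        obs = load_observation(obs)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except AcmeError as exc:
            raise AcmeError(f"[{name}] {exc}") from exc

    detection = stage("detect", detect_peaks, obs, cfg.detect)
    log.info("detect: %d candidates, %d valid", len(detection.candidates),
             len(detection.valid))
    bg_summary = stage(
        "background", select_resolution,
        detection.background, obs.mz_axis, obs.time_axis,
        cfg.bg_max_bytes, cfg.bg_percentiles,
    )
    if bg_summary.over_budget:
        log.warning("background summary exceeds %d bytes at all resolutions",
                    cfg.bg_max_bytes)
    sue = stage("priority", observation_sue, detection, cfg)
    dd = stage("priority", compute_dd, detection,
               float(np.mean(detection.background)), cfg)
    bundle = stage(
        "asdp", assemble_bundle, obs, detection, bg_summary, priority, cfg,
        sue=sue, dd=dd.values, candidates_path=candidates_path,
    )
    for alert in bundle.alerts:
        log.warning("alert: %s", alert)
    return bundle
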