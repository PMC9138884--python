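"""Reproducible end-to-end runs: synthesize → calibrate → detect → profiles.

A :class:`RunConfig` (typically loaded from YAML) fixes the seed, the
detector, the particle events and the detection parameters; ``run_pipeline``
executes the chain deterministically and writes one profile file per
detected pulse plus a pulse table and a manifest sufficient to re-run it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import fit_calibration
from .classify import BENCHMARK_CLASSES
from .instrument import (DetectorConfig, TransitEvent, generate_calibration_sweep,
                         generate_stream, rows_to_stokes)
from .mie import OpticalContext, SphereParticle, simulate_pclar
from .profiles import write_profile
from .pulses import (PulseDetectionConfig, compute_stokes_stream, extract_pulses,
                     to_pclar, write_pulse_table)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("pclar.pipeline")

_KNOWN_KEYS = {"seed", "duration_s", "out_dir", "events", "detector",
               "detection", "calibrate", "wavelength_nm", "n_medium"}
_EVENT_KEYS = {"label", "diameter_um", "n_real", "n_imag", "arrival_time",
               "duration", "peak_amplitude"}
_DETECTOR_KEYS = {"frame_rate", "background_level", "read_noise_sd",
                  "extinction_ratio", "perturb_seed", "gain_spread",
                  "angle_error_deg"}
_DETECTION_KEYS = {"threshold_factor", "min_separation"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run (unknown keys rejected)."""

    seed: int = 0
    duration_s: float = 1.0
    out_dir: str = "pclar_run"
    events: list[dict] = field(default_factory=list)
    detector: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    calibrate: bool = True
    wavelength_nm: float = 532.0
    n_medium: float = 1.330

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for ev in raw.get("events", []):
            bad = set(ev) - _EVENT_KEYS
            if bad:
                raise ValueError(f"unknown event keys: {sorted(bad)}")
        for block, keys in (("detector", _DETECTOR_KEYS),
                            ("detection", _DETECTION_KEYS)):
            bad = set(raw.get(block, {})) - keys
            if bad:
                raise ValueError(f"unknown {block} keys: {sorted(bad)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _build_detector(cfg: RunConfig) -> DetectorConfig:
    d = dict(cfg.detector)
    perturb_seed = d.pop("perturb_seed", None)
    if perturb_seed is not None:
        spread = d.pop("gain_spread", 0.10)
        angle_err = d.pop("angle_error_deg", 3.0)
        return DetectorConfig.perturbed(perturb_seed, gain_spread=spread,
                                        angle_error_deg=angle_err, **d)
    d.pop("gain_spread", None)
    d.pop("angle_error_deg", None)
    return DetectorConfig(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain; returns a summary dict (also written as the
    run manifest)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    context = OpticalContext(config.wavelength_nm, config.n_medium)
    rng_seed = int(config.seed)

    stage = "simulate-events"
    try:
        events = []
        for ev in config.events:
            particle = SphereParticle(ev["diameter_um"],
                                      complex(ev.get("n_real", 1.45),
                                              ev.get("n_imag", 0.0)))
            prof = simulate_pclar(particle, context)
            events.append(TransitEvent(
                pclar=prof, arrival_time=ev["arrival_time"],
                duration=ev.get("duration", 4e-3),
                peak_amplitude=ev.get("peak_amplitude", 10.0),
                label=ev.get("label")))
        log.info("%s: %d events prepared", stage, len(events))

        stage = "synth-stream"
        detector = _build_detector(config)
        stream = generate_stream(events, config.duration_s, detector,
                                 seed=rng_seed)

        stage = "calibrate"
        cal = None
        if config.calibrate:
            measured, reference = generate_calibration_sweep(
                detector, seed=rng_seed + 1)
            sweep = rows_to_stokes(measured)  # (18, 3, n_pixels)
            act = detector.active_slice
            per_pixel = sweep[:, :, act].transpose(2, 1, 0)  # (1458, 3, 18)
            cal = fit_calibration(per_pixel, reference)

        stage = "detect"
        ts = compute_stokes_stream(stream, cal)
        det_cfg = PulseDetectionConfig(**config.detection)
        pulses = extract_pulses(ts, det_cfg)
        log.info("%s: %d pulses found", stage, len(pulses))

        stage = "write-artifacts"
        write_pulse_table(pulses, out / "pulses.csv")
        for p in pulses:
            write_profile(to_pclar(p), out / f"profile_{p.index:04d}.csv")
        manifest = {
            "version": __version__,
            "seed": rng_seed,
            "duration_s": config.duration_s,
            "n_events": len(events),
            "n_pulses": len(pulses),
            "calibrated": config.calibrate,
            "detection": {"threshold_factor": det_cfg.threshold_factor,
                          "min_separation": det_cfg.min_separation},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
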