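"""Virtual polarization line-scan camera and particle-transit generator.

Emulates the acquisition chain of the real instrument so the downstream
pipeline (calibration → pulse extraction → classification/inversion) is fully
testable without hardware: a 4×2048-pixel line sensor whose upper three rows
carry polarizers at 0°, 135° and 90° (the fourth row is unfiltered), sampling
at up to 70 kHz with 12-bit depth.  The middle 1458 pixels map linearly onto
scattering angles 60°–120°.

Particle transits appear as temporal pulses: each event contributes a Gaussian
intensity envelope (FWHM ≈ 4 ms, the typical transit time) multiplied by the
particle's angular profile I(θ)·[1, q(θ), u(θ)], on top of an unpolarized
background.  Imperfections modelled per pixel: multiplicative gain, polarizer
angle error, finite extinction ratio, Poisson shot noise, Gaussian read noise
and uniform 12-bit quantization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import StokesLinear, StokesSweep, stokes_linear
from .profiles import N_ANGLES, THETA_MAX_DEG, THETA_MIN_DEG, PCLARProfile

__all__ = [
    "DetectorConfig",
    "TransitEvent",
    "RawStream",
    "CoincidenceError",
    "pixel_to_angle",
    "render_rows",
    "generate_stream",
    "generate_mean_trace",
    "generate_calibration_sweep",
    "rows_to_stokes",
    "save_stream",
    "load_stream",
]

MAX_FRAME_RATE = 70_000.0
N_PIXELS = 2048
BIT_DEPTH = 12
ROW_ANGLES_DEG = (0.0, 135.0, 90.0)  # row 3 is unfiltered


class CoincidenceError(ValueError):
    """Two transits overlap in time (single-particle regime violated)."""


def pixel_to_angle(pixel_index, n_pixels: int = N_ANGLES,
                   theta_min: float = THETA_MIN_DEG,
                   theta_max: float = THETA_MAX_DEG):
    """Linear map of active-window pixel index (1-based) to scattering angle.

    Pixel 1 → 60°, pixel 1458 → 120°; fractional indices interpolate
    (midpoint 729.5 → 90°).
    """
    p = np.asarray(pixel_index, dtype=float)
    if np.any(p < 1) or np.any(p > n_pixels):
        raise ValueError(f"pixel index outside 1..{n_pixels}")
    out = theta_min + (p - 1.0) * (theta_max - theta_min) / (n_pixels - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DetectorConfig:
    """Geometry, rates and per-pixel imperfections of the virtual sensor.

    ``gain`` is a (4, 2048) multiplicative response, ``angle_error_deg`` a
    (3, 2048) polarizer orientation error, ``extinction_ratio`` the analyzer
    contrast (np.inf = ideal).  ``active_window`` is the half-open pixel index
    range mapped onto [60°, 120°]; it must contain exactly 1458 pixels.
    """

    n_pixels: int = N_PIXELS
    frame_rate: float = 20_000.0
    bit_depth: int = BIT_DEPTH
    gain: np.ndarray | None = None
    angle_error_deg: np.ndarray | None = None
    extinction_ratio: float = np.inf
    read_noise_sd: float = 2.0
    background_level: float = 50.0
    active_window: tuple[int, int] = (296, 1754)
    angle_ascending: bool = True

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.frame_rate > MAX_FRAME_RATE:
            raise ValueError(f"frame_rate must be in (0, {MAX_FRAME_RATE:g}] Hz")
        if self.bit_depth != BIT_DEPTH:
            raise ValueError("the sensor has 12-bit depth")
        lo, hi = self.active_window
        if hi - lo != N_ANGLES or lo < 0 or hi > self.n_pixels:
            raise ValueError(f"active window must contain exactly {N_ANGLES} pixels")
        if self.gain is not None:
            g = np.asarray(self.gain, dtype=float)
            if g.shape != (4, self.n_pixels):
                raise ValueError("gain must have shape (4, n_pixels)")
            object.__setattr__(self, "gain", g)
        if self.angle_error_deg is not None:
            e = np.asarray(self.angle_error_deg, dtype=float)
            if e.shape != (3, self.n_pixels):
                raise ValueError("angle_error_deg must have shape (3, n_pixels)")
            object.__setattr__(self, "angle_error_deg", e)

    @property
    def max_count(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def active_slice(self) -> slice:
        return slice(*self.active_window)

    def effective_gain(self) -> np.ndarray:
        return self.gain if self.gain is not None else np.ones((4, self.n_pixels))

    def effective_angle_error(self) -> np.ndarray:
        return (self.angle_error_deg if self.angle_error_deg is not None
                else np.zeros((3, self.n_pixels)))

    def active_angles(self) -> np.ndarray:
        """Scattering angle of each active-window pixel, in readout order."""
        theta = pixel_to_angle(np.arange(1, N_ANGLES + 1))
        return theta if self.angle_ascending else theta[::-1]

    @classmethod
    def perturbed(cls, seed: int, gain_spread: float = 0.10,
                  angle_error_deg: float = 3.0,
                  extinction_ratio: float = 200.0, **kwargs) -> "DetectorConfig":
        """Random imperfect detector: gains in 1±spread (uniform), polarizer
        angle errors in ±angle_error_deg (uniform), finite extinction."""
        rng = np.random.default_rng(seed)
        n = kwargs.get("n_pixels", N_PIXELS)
        gain = 1.0 + gain_spread * rng.uniform(-1.0, 1.0, size=(4, n))
        err = angle_error_deg * rng.uniform(-1.0, 1.0, size=(3, n))
        return cls(gain=gain, angle_error_deg=err,
                   extinction_ratio=extinction_ratio, **kwargs)


@dataclass
class TransitEvent:
    """One particle crossing the scattering volume.

    ``arrival_time`` is the pulse center; ``duration`` the Gaussian FWHM
    (≈4 ms typical); ``peak_amplitude`` the pulse height of the pixel-averaged
    intensity trace in multiples of the background level.
    """

    pclar: PCLARProfile
    arrival_time: float
    duration: float = 4e-3
    peak_amplitude: float = 10.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.peak_amplitude <= 0:
            raise ValueError("duration and peak_amplitude must be positive")

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Gaussian temporal envelope with FWHM = duration, peak 1."""
        return np.exp(-4.0 * np.log(2.0) * ((t - self.arrival_time) / self.duration) ** 2)


@dataclass
class RawStream:
    """Time-indexed 4×2048 detector frames with optional ground truth."""

    timestamps: np.ndarray
    frames: np.ndarray  # (n_frames, 4, n_pixels), integer counts
    detector: DetectorConfig
    ground_truth: list[TransitEvent] | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[1] != 4:
            raise ValueError("frames must have shape (n_frames, 4, n_pixels)")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("timestamps/frames length mismatch")


def _expected_rows(I: np.ndarray, Q: np.ndarray, U: np.ndarray,
                   detector: DetectorConfig) -> np.ndarray:
    """Noise-free expected counts of all four rows; shapes broadcast over (..., n_pixels)."""
    gain = detector.effective_gain()
    err = detector.effective_angle_error()
    k2 = 0.0 if np.isinf(detector.extinction_ratio) else 1.0 / detector.extinction_ratio
    rows = []
    for r, phi in enumerate(ROW_ANGLES_DEG):
        a = np.deg2rad(2.0 * (phi + err[r]))
        rows.append(gain[r] * 0.5 * ((1.0 + k2) * I
                                     + (1.0 - k2) * (Q * np.cos(a) + U * np.sin(a))))
    rows.append(gain[3] * I)  # unfiltered row
    return np.stack(rows, axis=-2)  # (..., 4, n_pixels)


def render_rows(stokes: StokesLinear, detector: DetectorConfig,
                rng: np.random.Generator | None = None,
                add_noise: bool = False, quantize: bool = False) -> np.ndarray:
    """Render a per-pixel Stokes field through the four sensor rows.

    With an ideal detector and no noise, applying the three-row Stokes
    reconstruction to the output recovers (I, Q, U) exactly.
    """
    I = np.broadcast_to(np.asarray(stokes.I, float), (detector.n_pixels,))
    Q = np.broadcast_to(np.asarray(stokes.Q, float), (detector.n_pixels,))
    U = np.broadcast_to(np.asarray(stokes.U, float), (detector.n_pixels,))
    counts = _expected_rows(I, Q, U, detector)
    if add_noise:
        if rng is None:
            rng = np.random.default_rng()
        counts = (rng.poisson(np.clip(counts, 0.0, None)).astype(float)
                  + rng.normal(0.0, detector.read_noise_sd, size=counts.shape))
    if quantize:
        counts = _quantize(counts, detector)
    return counts


def _quantize(counts: np.ndarray, detector: DetectorConfig) -> np.ndarray:
    clipped = np.clip(np.rint(counts), 0, detector.max_count)
    n_sat = int(np.count_nonzero(np.rint(counts) > detector.max_count))
    if n_sat:
        warnings.warn(f"{n_sat} samples saturated at {detector.max_count} counts",
                      RuntimeWarning, stacklevel=3)
    return clipped.astype(np.uint16)


def _check_overlap(events: list[TransitEvent], allow_overlap: bool) -> None:
    ev = sorted(events, key=lambda e: e.arrival_time)
    for a, b in zip(ev, ev[1:]):
        if b.arrival_time - a.arrival_time < (a.duration + b.duration):
            if not allow_overlap:
                raise CoincidenceError(
                    f"transits at {a.arrival_time:.4f}s and {b.arrival_time:.4f}s overlap")


def _event_stokes_fields(events: list[TransitEvent], detector: DetectorConfig):
    """Per-event active-window fields (I_shape, q, u) with mean(I_shape) = 1."""
    fields = []
    for ev in events:
        if len(ev.pclar) != N_ANGLES:
            raise ValueError("event profile must have 1458 angles")
        shape = (np.ones(N_ANGLES) if ev.pclar.intensity is None
                 else ev.pclar.intensity / ev.pclar.intensity.mean())
        q, u = ev.pclar.q, ev.pclar.u
        if not detector.angle_ascending:
            shape, q, u = shape[::-1], q[::-1], u[::-1]
        fields.append((shape, q, u))
    return fields


def generate_stream(events: list[TransitEvent], duration: float,
                    detector: DetectorConfig | None = None,
                    seed: int | None = None,
                    allow_overlap: bool = False,
                    add_noise: bool = True, quantize: bool = True,
                    chunk_frames: int = 1024) -> RawStream:
    """Synthesize a raw detector stream containing the given transits.

    Each event adds ``peak_amplitude × background`` of pixel-averaged signal
    intensity at its peak, distributed over the active window as the event's
    angular intensity profile and polarized as its (q, u); pixels outside the
    active window see only background.  Deterministic for a fixed seed.
    """
    detector = detector or DetectorConfig()
    for ev in events:
        if not (0.0 <= ev.arrival_time <= duration):
            raise ValueError("event arrival_time outside stream duration")
    _check_overlap(events, allow_overlap)
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * detector.frame_rate))
    t = np.arange(n_frames) / detector.frame_rate
    B = detector.background_level
    fields = _event_stokes_fields(events, detector)
    act = detector.active_slice

    frames = np.empty((n_frames, 4, detector.n_pixels),
                      dtype=np.uint16 if quantize else np.float64)
    for start in range(0, n_frames, chunk_frames):
        stop = min(start + chunk_frames, n_frames)
        tc = t[start:stop]
        I = np.full((stop - start, detector.n_pixels), B)
        Q = np.zeros_like(I)
        U = np.zeros_like(I)
        for ev, (shape, q, u) in zip(events, fields):
            env = ev.peak_amplitude * B * ev.envelope(tc)  # (T,)
            if not np.any(env > 1e-12 * B):
                continue
            sig = env[:, None] * shape[None, :]  # (T, 1458)
            I[:, act] += sig
            Q[:, act] += sig * q[None, :]
            U[:, act] += sig * u[None, :]
        counts = _expected_rows(I, Q, U, detector)
        if add_noise:
            counts = (rng.poisson(np.clip(counts, 0.0, None)).astype(float)
                      + rng.normal(0.0, detector.read_noise_sd, size=counts.shape))
        if quantize:
            frames[start:stop] = _quantize(counts, detector)
        else:
            frames[start:stop] = counts
    return RawStream(timestamps=t, frames=frames, detector=detector,
                     ground_truth=list(events))


def generate_mean_trace(events: list[TransitEvent], duration: float,
                        detector: DetectorConfig | None = None,
                        seed: int | None = None,
                        allow_overlap: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-averaged intensity trace Ī(t) of a stream, generated directly.

    Statistically equivalent to averaging the reconstructed per-pixel
    intensity of a full frame stream over the 1458 active pixels (background
    + Gaussian pulse envelopes + pixel-averaged shot and read noise), at a
    fraction of the cost; used for long-duration pulse-detection studies.
    """
    detector = detector or DetectorConfig()
    _check_overlap(events, allow_overlap)
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * detector.frame_rate))
    t = np.arange(n_frames) / detector.frame_rate
    B = detector.background_level
    trace = np.full(n_frames, B)
    for ev in events:
        trace = trace + ev.peak_amplitude * B * ev.envelope(t)
    # I = I0 + I90: shot variance ≈ trace counts, read variance 2·σ_r², both
    # averaged over the active pixels
    noise_sd = np.sqrt((trace + 2.0 * detector.read_noise_sd ** 2) / N_ANGLES)
    trace = trace + rng.normal(0.0, 1.0, size=n_frames) * noise_sd
    return t, trace


def measure_beam(beam: StokesLinear, detector: DetectorConfig,
                 n_frames: int = 64,
                 rng: np.random.Generator | None = None,
                 add_noise: bool = True) -> np.ndarray:
    """Average ``n_frames`` exposures of a uniform beam: (4, n_pixels) counts.

    Each frame carries shot noise, read noise and 12-bit quantization; the
    average is what a calibration or validation measurement would use.
    """
    expected = render_rows(beam, detector)
    if not add_noise:
        return expected
    if rng is None:
        rng = np.random.default_rng()
    counts = (rng.poisson(np.clip(expected, 0.0, None),
                          size=(n_frames,) + expected.shape).astype(float)
              + rng.normal(0.0, detector.read_noise_sd,
                           size=(n_frames,) + expected.shape))
    counts = np.clip(np.rint(counts), 0, detector.max_count)
    return counts.mean(axis=0)


def generate_calibration_sweep(detector: DetectorConfig | None = None,
                               intensity: float = 2000.0,
                               n_frames: int = 64,
                               seed: int | None = None,
                               add_noise: bool = True
                               ) -> tuple[np.ndarray, StokesSweep]:
    """Measured frames and reference states for the 18-step polarizer sweep.

    A uniform beam is modulated by a rotating polarizer stepped 0°..170° in
    10° increments, giving 18 fully linearly polarized states; the reference
    sweep is the ideal rotating-polarizer model (the stand-in for a
    commercial polarimeter).  Returns (measured_rows, reference) where
    ``measured_rows`` has shape (18, 4, n_pixels) — counts averaged over
    ``n_frames`` exposures.
    """
    detector = detector or DetectorConfig()
    rng = np.random.default_rng(seed)
    reference = StokesSweep.ideal_rotating_polarizer(intensity)
    measured = np.empty((18, 4, detector.n_pixels))
    for k in range(18):
        I, Q, U = reference.matrix[:, k]
        beam = StokesLinear(I=I, Q=Q, U=U)
        measured[k] = measure_beam(beam, detector, n_frames=n_frames, rng=rng,
                                   add_noise=add_noise)
    return measured, reference


def rows_to_stokes(rows: np.ndarray) -> np.ndarray:
    """Apply the three-row Stokes reconstruction pixel-wise.

    ``rows``: (..., 4, n_pixels) or (..., 3, n_pixels) counts with row order
    (0°, 135°, 90°[, unfiltered]).  Returns (..., 3, n_pixels) = (I, Q, U).
    """
    I0 = rows[..., 0, :]
    I135 = rows[..., 1, :]
    I90 = rows[..., 2, :]
    I = I0 + I90
    return np.stack([I, I0 - I90, I - 2.0 * I135], axis=-2)


def save_stream(stream: RawStream, path) -> None:
    """Persist a raw stream to a chunked HDF5 container (runtime artifact)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stream.frames,
                         chunks=(min(256, len(stream.timestamps)), 4,
                                 stream.detector.n_pixels),
                         compression="gzip", compression_opts=4)
        f.create_dataset("timestamps", data=stream.timestamps)
        d = stream.detector
        f.attrs["config"] = json.dumps({
            "n_pixels": d.n_pixels, "frame_rate": d.frame_rate,
            "extinction_ratio": (None if np.isinf(d.extinction_ratio)
                                 else d.extinction_ratio),
            "read_noise_sd": d.read_noise_sd,
            "background_level": d.background_level,
            "active_window": list(d.active_window),
            "angle_ascending": d.angle_ascending,
        })
        if d.gain is not None:
            f.create_dataset("gain", data=d.gain)
        if d.angle_error_deg is not None:
            f.create_dataset("angle_error_deg", data=d.angle_error_deg)
        if stream.ground_truth:
            g = f.create_group("ground_truth")
            for i, ev in enumerate(stream.ground_truth):
                gi = g.create_group(f"event_{i:05d}")
                gi.attrs["arrival_time"] = ev.arrival_time
                gi.attrs["duration"] = ev.duration
                gi.attrs["peak_amplitude"] = ev.peak_amplitude
                gi.attrs["label"] = ev.label or ""
                gi.create_dataset("theta_deg", data=ev.pclar.theta_deg)
                gi.create_dataset("q", data=ev.pclar.q)
                gi.create_dataset("u", data=ev.pclar.u)
                if ev.pclar.intensity is not None:
                    gi.create_dataset("intensity", data=ev.pclar.intensity)


def load_stream(path) -> RawStream:
    import h5py

    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config"])
        cfg["extinction_ratio"] = (np.inf if cfg["extinction_ratio"] is None
                                   else cfg["extinction_ratio"])
        cfg["active_window"] = tuple(cfg["active_window"])
        detector = DetectorConfig(
            gain=f["gain"][...] if "gain" in f else None,
            angle_error_deg=f["angle_error_deg"][...] if "angle_error_deg" in f else None,
            **cfg)
        events = None
        if "ground_truth" in f:
            events = []
            for name in sorted(f["ground_truth"]):
                gi = f["ground_truth"][name]
                prof = PCLARProfile(
                    theta_deg=gi["theta_deg"][...], q=gi["q"][...], u=gi["u"][...],
                    intensity=gi["intensity"][...] if "intensity" in gi else None,
                    label=gi.attrs["label"] or None)
                events.append(TransitEvent(
                    pclar=prof, arrival_time=float(gi.attrs["arrival_time"]),
                    duration=float(gi.attrs["duration"]),
                    peak_amplitude=float(gi.attrs["peak_amplitude"]),
                    label=gi.attrs["label"] or None))
        return RawStream(timestamps=f["timestamps"][...], frames=f["frames"][...],
                         detector=detector, ground_truth=events)
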