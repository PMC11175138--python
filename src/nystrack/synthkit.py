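"""Synthetic video-oculography data: gaze traces, blink gaps, rendered frames.

Emulates the data regime of an infrared two-eye VOG recorder: 320x120
grayscale frames at 30 fps, dark elliptical pupils on a brighter iris and
sclera, conjugate horizontal motion, blinks that knock out pupil detection,
and jerk-nystagmus epochs whose position trace is a sawtooth — a linear
slow-phase drift followed by a fast saccadic reset — that typically begins
some way into the recording.

Positions throughout are horizontal pupil-centre offsets in pixels,
relative to each eye's rest centre; positive is rightward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk

__all__ = [
    "NystagmusParams", "SceneParams",
    "simulate_trace", "inject_missing", "render_frames",
    "write_trace_csv", "read_trace_csv", "write_manifest",
]


@dataclass
class NystagmusParams:
    """Jerk-nystagmus waveform parameters.

    beat_frequency : Hz, typical pathological range 2-5.
    slow_phase_amplitude : px, peak-to-trough excursion of one beat.
    quick_phase_duration : frames taken by the saccadic reset (1-3).
    onset_fraction : fraction of the trace before nystagmus begins.
    noise_sd : px, white measurement noise added to every frame.
    drift_sd : px, slow baseline wander (smoothed noise, sd in px).
    fps : sampling rate, Hz.
    """

    beat_frequency: float = 3.0
    slow_phase_amplitude: float = 8.0
    quick_phase_duration: int = 1
    onset_fraction: float = 0.0
    noise_sd: float = 0.5
    drift_sd: float = 0.0
    fps: float = 30.0

    @property
    def beat_period(self) -> int:
        """Beat period in frames."""
        return int(round(self.fps / self.beat_frequency))

    def validate(self) -> None:
        if not 0.0 <= self.onset_fraction < 1.0:
            raise ValueError("onset_fraction must be in [0, 1)")
        if self.quick_phase_duration < 1:
            raise ValueError("quick_phase_duration must be >= 1 frame")
        if self.beat_period < self.quick_phase_duration + 1:
            raise ValueError(
                f"beat period {self.beat_period} frames is shorter than "
                f"quick_phase_duration+1 = {self.quick_phase_duration + 1}")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise_sd and drift_sd must be >= 0")


@dataclass
class SceneParams:
    """Rendering parameters for the two-eye infrared canvas.

    Intensities are 8-bit gray levels and must be ordered
    pupil < iris < background (the pupil is the darkest structure under
    infrared illumination).
    """

    frame_size: tuple[int, int] = (320, 120)  # (width, height)
    pupil_radius: float = 18.0
    pupil_intensity: int = 30
    iris_intensity: int = 110
    background_intensity: int = 200
    glint: bool = False
    pixel_noise_sd: float = 2.0
    blink_rate: float = 6.0       # events / minute
    blink_duration: int = 5       # frames
    iris_radius: float = field(default=40.0)

    def validate(self) -> None:
        if not (self.pupil_intensity < self.iris_intensity
                < self.background_intensity):
            raise ValueError("need pupil < iris < background intensity")
        w, h = self.frame_size
        if w % 2:
            raise ValueError("canvas width must be even (two eye halves)")
        if self.pupil_radius * 2 >= min(w // 2, h):
            raise ValueError("pupil does not fit inside an eye half")


# ---------------------------------------------------------------------------
# 1D trace simulation
# ---------------------------------------------------------------------------

def _sawtooth(n: int, onset: int, params: NystagmusParams) -> np.ndarray:
    """Noise-free jerk waveform: zero before onset, repeating beats after.

    Within a beat of period P frames, the slow phase climbs linearly from 0
    to the full amplitude over P - q frame intervals (slope A / (P - q)),
    then the quick phase returns to baseline over the remaining q intervals.
    """
    period = params.beat_period
    q = params.quick_phase_duration
    amp = params.slow_phase_amplitude
    t = np.arange(n)
    tb = (t - onset) % period
    slow = amp * tb / (period - q)
    quick = amp * (period - tb) / q
    w = np.where(tb <= period - q, slow, quick)
    w[t < onset] = 0.0
    return w


def simulate_trace(params: NystagmusParams, n_frames: int, kind: str,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a horizontal gaze trace and its per-frame nystagmus labels.

    Parameters
    ----------
    params : NystagmusParams
    n_frames : trace length in frames.
    kind : ``"nystagmus"`` (sawtooth beats after onset) or ``"normal"``
        (low-pass-filtered noise plus a slow sinusoidal pursuit component).
    seed : RNG seed; identical seeds give bit-identical output.

    Returns
    -------
    positions : float array (px offsets), length ``n_frames``.
    frame_labels : int array in {0, 1}; 1 exactly on nystagmus frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if kind not in ("nystagmus", "normal"):
        raise ValueError(f"unknown trace kind {kind!r}")
    params.validate()
    rng = np.random.default_rng(seed)

    labels = np.zeros(n_frames, dtype=np.int8)
    if kind == "nystagmus":
        onset = int(np.ceil(params.onset_fraction * n_frames))
        x = _sawtooth(n_frames, onset, params)
        labels[onset:] = 1
    else:
        # fixation noise, low-passed so it has no saccade-like steps,
        # plus a slow smooth-pursuit sinusoid of comparable amplitude
        # (keeps the classes inseparable by variance alone)
        raw = rng.normal(0.0, 1.0, n_frames)
        x = gaussian_filter1d(raw, sigma=5.0, mode="nearest")
        sd = x.std()
        if sd > 0:
            x *= params.noise_sd * 2.0 / sd
        amp = params.slow_phase_amplitude * rng.uniform(0.5, 1.0)
        freq = rng.uniform(0.1, 0.5)  # Hz, smooth pursuit
        phase = rng.uniform(0, 2 * np.pi)
        x = x + amp * np.sin(
            2 * np.pi * freq * np.arange(n_frames) / params.fps + phase)

    if params.drift_sd > 0:
        drift = gaussian_filter1d(rng.normal(0.0, 1.0, n_frames),
                                  sigma=params.fps, mode="nearest")
        sd = drift.std()
        if sd > 0:
            x = x + drift * (params.drift_sd / sd)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n_frames)
    return x.astype(np.float64), labels


def inject_missing(positions: np.ndarray, blink_rate: float,
                   blink_duration: int, fps: float, seed: int,
                   starts: list[int] | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Knock out blink-length runs of a trace, Poisson-placed in time.

    Missingness is returned as an explicit validity flag (never a sentinel
    value): the positions array is returned unchanged alongside a boolean
    ``valid`` array that is False on exactly the blinked frames.

    Parameters
    ----------
    positions : trace to mask.
    blink_rate : expected blink events per minute (homogeneous Poisson).
    blink_duration : frames per blink; every run is exactly this long.
    fps : frame rate, used to convert the rate to per-trace counts.
    seed : RNG seed.
    starts : optional explicit blink start frames, overriding the Poisson
        draw (useful for reproducing a specific gap pattern).
    """
    n = len(positions)
    if blink_duration < 1:
        raise ValueError("blink_duration must be >= 1")
    if blink_duration > n:
        raise ValueError("blink_duration exceeds series length")
    valid = np.ones(n, dtype=bool)
    if starts is None:
        rng = np.random.default_rng(seed)
        minutes = n / fps / 60.0
        n_events = rng.poisson(blink_rate * minutes)
        starts = rng.integers(0, n - blink_duration + 1, size=n_events)
    for s in starts:
        if not 0 <= s <= n - blink_duration:
            raise ValueError(f"blink at frame {s} does not fit in the trace")
        valid[s:s + blink_duration] = False
    return positions.copy(), valid


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

def _render_eye(img: np.ndarray, mask: np.ndarray, cx: float, cy: float,
                scene: SceneParams, blink: bool) -> None:
    """Draw one eye (iris disc + pupil disc, or a closed lid) in place."""
    h, w = img.shape
    if blink:
        # closed lid: skin-toned band across the eye, no pupil visible
        lid = int(scene.iris_intensity + scene.background_intensity) // 2
        img[:, :] = lid
        return
    rr, cc = disk((cy, cx), scene.iris_radius, shape=(h, w))
    img[rr, cc] = scene.iris_intensity
    rr, cc = disk((cy, cx), scene.pupil_radius, shape=(h, w))
    img[rr, cc] = scene.pupil_intensity
    mask[rr, cc] = True
    if scene.glint:
        gr = max(2.0, scene.pupil_radius / 6.0)
        rr, cc = disk((cy - scene.pupil_radius / 3,
                       cx + scene.pupil_radius / 3), gr, shape=(h, w))
        img[rr, cc] = 255
        mask[rr, cc] = False


def render_frames(left_trace: np.ndarray, right_trace: np.ndarray,
                  scene: SceneParams, seed: int,
                  left_valid: np.ndarray | None = None,
                  right_valid: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Render a two-eye infrared frame stack from commanded gaze offsets.

    Each 320x120 frame holds the left eye in columns [0, 160) and the right
    eye in [160, 320); the pupil centre of each eye sits at the eye-half
    centre plus the commanded horizontal offset. Frames whose validity flag
    is False are rendered as blinks (closed lid, empty pupil mask).

    Returns
    -------
    frames : uint8 stack ``(T, H, W)``.
    masks : bool stack ``(T, H, W)``, the exact rendered pupil support.
    """
    scene.validate()
    left_trace = np.asarray(left_trace, dtype=float)
    right_trace = np.asarray(right_trace, dtype=float)
    if left_trace.shape != right_trace.shape:
        raise ValueError("left and right traces must have equal length")
    n = len(left_trace)
    w, h = scene.frame_size
    half = w // 2
    cy = h / 2.0
    rest = half / 2.0
    margin = scene.pupil_radius
    for name, tr in (("left", left_trace), ("right", right_trace)):
        lo, hi = np.nanmin(tr), np.nanmax(tr)
        if rest + lo - margin < 0 or rest + hi + margin > half:
            raise ValueError(f"{name} trace drives the pupil out of bounds")
    if left_valid is None:
        left_valid = np.ones(n, dtype=bool)
    if right_valid is None:
        right_valid = np.ones(n, dtype=bool)

    rng = np.random.default_rng(seed)
    frames = np.empty((n, h, w), dtype=np.uint8)
    masks = np.zeros((n, h, w), dtype=bool)
    for t in range(n):
        img = np.full((h, w), scene.background_intensity, dtype=float)
        for side, (tr, ok) in enumerate(
                ((left_trace, left_valid), (right_trace, right_valid))):
            sl = slice(side * half, (side + 1) * half)
            _render_eye(img[:, sl], masks[t][:, sl],
                        rest + tr[t], cy, scene, blink=not ok[t])
        if scene.pixel_noise_sd > 0:
            img += rng.normal(0.0, scene.pixel_noise_sd, img.shape)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)
    return frames, masks


# ---------------------------------------------------------------------------
# on-disk interchange
# ---------------------------------------------------------------------------

def write_trace_csv(path: str | Path, x: np.ndarray, valid: np.ndarray,
                    labels: np.ndarray | None = None) -> None:
    """Write a trace as CSV with columns frame, x, valid[, label]."""
    n = len(x)
    cols = {"frame": np.arange(n), "x": x, "valid": valid.astype(int)}
    if labels is not None:
        cols["label"] = np.asarray(labels, dtype=int)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trace_csv(path: str | Path):
    """Read a trace CSV; returns (x, valid, labels-or-None)."""
    df = pd.read_csv(path)
    labels = df["label"].to_numpy(int) if "label" in df.columns else None
    return (df["x"].to_numpy(float), df["valid"].to_numpy(bool), labels)


def write_manifest(path: str | Path, entries: list[dict]) -> None:
    """Write a JSON manifest of simulated videos (id, kind, seed, files)."""
    Path(path).write_text(json.dumps(entries, indent=2))
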