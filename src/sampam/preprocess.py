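"""Raw A-scan volumes to windowed envelope volumes on a common depth grid.

Processing order mirrors the acquisition chain: per-A-line bias subtraction
(mean of the pre-trigger samples), Hilbert-envelope detection (magnitude of
the analytic signal), time-to-depth mapping that halves the round-trip SAM
times relative to the one-way PAM times, resampling of both modalities onto
one shared depth grid, and explicit depth/time windowing that keeps the
tissue signal and drops the noisy remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from sampam.io_hdf5 import AScanVolume

__all__ = [
    "TimeWindow",
    "EnvelopeVolume",
    "subtract_bias",
    "hilbert_envelope",
    "align_and_coregister",
    "apply_window",
    "auto_window",
]


@dataclass(frozen=True)
class TimeWindow:
    """A half-open axis interval [start, end] in seconds or metres."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end}]")


@dataclass
class EnvelopeVolume:
    """Envelope-detected volume on an explicit (strictly increasing) axis.

    Before depth mapping the axis is the acquisition time axis; after
    :func:`align_and_coregister` it is depth in metres (or a relabelled
    time axis, depending on the alignment reference).
    """

    data: np.ndarray
    depth_axis: np.ndarray
    pixel_pitch: float
    modality: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D [x, y, z]")
        if self.depth_axis.ndim != 1 or len(self.depth_axis) != self.data.shape[2]:
            raise ValueError("depth_axis must match the third data dimension")
        if len(self.depth_axis) > 1 and not np.all(np.diff(self.depth_axis) > 0):
            raise ValueError("depth_axis must be strictly increasing")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("envelope data must be nonnegative")


def subtract_bias(volume: AScanVolume, pre_trigger_samples: int = 64) -> AScanVolume:
    """Remove the per-A-line DC bias estimated from the pre-trigger region.

    The mean of the first ``pre_trigger_samples`` samples of each trace is
    subtracted from the whole trace; using only the signal-free head keeps a
    genuine unipolar signal from biasing the baseline.
    """
    nt = volume.n_samples
    if not (1 <= pre_trigger_samples < nt):
        raise ValueError(
            f"pre_trigger_samples must be in [1, {nt - 1}], got {pre_trigger_samples}")
    bias = volume.data[:, :, :pre_trigger_samples].mean(axis=2, keepdims=True)
    return AScanVolume(
        data=volume.data - bias,
        sampling_rate=volume.sampling_rate,
        trigger_delay=volume.trigger_delay,
        pixel_pitch=volume.pixel_pitch,
        modality=volume.modality,
        repeats=volume.repeats,
        report=dict(volume.report),
    )


def hilbert_envelope(volume: AScanVolume) -> EnvelopeVolume:
    """Envelope detection: magnitude of the analytic signal per A-line.

    The output axis is still the acquisition time axis; depth mapping is
    a separate, modality-aware step.
    """
    if volume.n_samples < 4:
        raise ValueError("traces must have at least 4 samples")
    finite = np.isfinite(volume.data)
    if not finite.all():
        bad = np.argwhere(~finite.all(axis=2))[0]
        raise ValueError(f"non-finite samples in A-line (x={bad[0]}, y={bad[1]})")
    env = np.abs(hilbert(volume.data.astype(np.float64), axis=2))
    return EnvelopeVolume(
        data=env,
        depth_axis=volume.time_axis(),
        pixel_pitch=volume.pixel_pitch,
        modality=volume.modality,
    )


def _resample_axis(data: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Linear resampling along the last axis from grid ``src`` to ``dst``."""
    idx = np.clip(np.searchsorted(src, dst) - 1, 0, len(src) - 2)
    denom = src[idx + 1] - src[idx]
    w = np.clip((dst - src[idx]) / denom, 0.0, 1.0)
    return data[..., idx] * (1.0 - w) + data[..., idx + 1] * w


def align_and_coregister(
    sam: AScanVolume,
    pam: AScanVolume,
    sound_speed: float = 1500.0,
    reference: str = "depth",
) -> tuple[EnvelopeVolume, EnvelopeVolume]:
    """Map both modalities to depth and resample onto one common grid.

    SAM times are round-trip, PAM times one-way, so on the absolute time
    axis (recording start offset by the trigger delay) z = v·t/2 for SAM
    and z = v·t for PAM.  Both
    envelope volumes are linearly resampled onto the overlap of their depth
    ranges at the finer of the two native depth spacings (normally the SAM
    grid), so a point structure lands at the same depth index in both.

    ``reference`` selects the output axis labelling: ``"depth"`` (metres,
    default), ``"sam_time"`` (round-trip seconds) or ``"pam_time"``
    (one-way seconds); the three are equivalent up to axis scaling.
    """
    if sam.data.shape[:2] != pam.data.shape[:2]:
        raise ValueError("SAM and PAM volumes must share the lateral grid")
    if sam.pixel_pitch != pam.pixel_pitch:
        raise ValueError("SAM and PAM volumes must share pixel_pitch")
    if not sound_speed > 0:
        raise ValueError("sound_speed must be positive")
    if reference not in ("depth", "sam_time", "pam_time"):
        raise ValueError(f"unknown alignment reference {reference!r}")

    env_sam = hilbert_envelope(sam)
    env_pam = hilbert_envelope(pam)
    z_sam = sound_speed * sam.time_axis() / 2.0
    z_pam = sound_speed * pam.time_axis()

    lo = max(z_sam[0], z_pam[0])
    hi = min(z_sam[-1], z_pam[-1])
    if hi <= lo:
        raise ValueError(
            "non-overlapping depth ranges: "
            f"SAM [{z_sam[0]:.3e}, {z_sam[-1]:.3e}] m vs "
            f"PAM [{z_pam[0]:.3e}, {z_pam[-1]:.3e}] m")
    dz = min(sound_speed / (2.0 * sam.sampling_rate),
             sound_speed / pam.sampling_rate)
    n = int(np.floor((hi - lo) / dz)) + 1
    grid = lo + dz * np.arange(n)

    out_sam = _resample_axis(env_sam.data, z_sam, grid)
    out_pam = _resample_axis(env_pam.data, z_pam, grid)

    if reference == "depth":
        axis = grid
    elif reference == "sam_time":
        axis = 2.0 * grid / sound_speed
    else:
        axis = grid / sound_speed

    return (
        EnvelopeVolume(data=out_sam, depth_axis=axis,
                       pixel_pitch=sam.pixel_pitch, modality="SAM"),
        EnvelopeVolume(data=out_pam, depth_axis=axis,
                       pixel_pitch=pam.pixel_pitch, modality="PAM"),
    )


def apply_window(volume: EnvelopeVolume, window: TimeWindow) -> EnvelopeVolume:
    """Crop the volume to the samples whose axis value lies in the window."""
    keep = (volume.depth_axis >= window.start) & (volume.depth_axis <= window.end)
    if not keep.any():
        raise ValueError(
            f"window [{window.start}, {window.end}] does not intersect the axis "
            f"range [{volume.depth_axis[0]}, {volume.depth_axis[-1]}]")
    return EnvelopeVolume(
        data=volume.data[:, :, keep],
        depth_axis=volume.depth_axis[keep],
        pixel_pitch=volume.pixel_pitch,
        modality=volume.modality,
    )


def auto_window(volume: EnvelopeVolume, guard_before: float,
                guard_after: float) -> TimeWindow:
    """Window around the strongest envelope peak, with guard margins.

    A convenience for the manual window choice the study made by eye: the
    window is centred on the global envelope maximum and extends
    ``guard_before``/``guard_after`` axis units either side (clipped to the
    axis range).
    """
    flat = np.unravel_index(int(np.argmax(volume.data)), volume.data.shape)
    z0 = volume.depth_axis[flat[2]]
    start = max(float(volume.depth_axis[0]), z0 - guard_before)
    end = min(float(volume.depth_axis[-1]), z0 + guard_after)
    return TimeWindow(start=max(start, 0.0), end=end)
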