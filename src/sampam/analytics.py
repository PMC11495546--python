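"""Projections and voxel statistics of envelope volumes.

C-scans are maximum-amplitude projections over a depth window (each pixel
is the largest envelope value along its A-line), B-scans are exact lateral
slices, and the voxel statistics follow the study's conventions: an 8-bit
volume histogram (256 unit bins after rescaling to [0, 255] by the global
maximum), the percentage of voxels above a minimum threshold, and the mean
foreground/background contrast ratio of a C-scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from sampam.preprocess import EnvelopeVolume, TimeWindow

__all__ = [
    "CScan",
    "BScan",
    "VolumeHistogram",
    "cscan_map",
    "extract_bscan",
    "volume_histogram",
    "occupancy_fraction",
    "contrast_ratio",
    "count_local_maxima",
    "noise_threshold",
]


@dataclass
class CScan:
    """En-face maximum-amplitude projection over a depth window."""

    data: np.ndarray  # [x, y], nonnegative
    pixel_pitch: float
    source_window: TimeWindow


@dataclass
class BScan:
    """One exact cross-sectional slice (lateral x depth) of a volume."""

    data: np.ndarray  # [x, z]
    depth_axis: np.ndarray
    lateral_axis: np.ndarray
    line_index: int


@dataclass
class VolumeHistogram:
    """8-bit-style histogram: 256 unit bins spanning the scaled range."""

    bin_edges: np.ndarray  # 257 edges, 0..256
    counts: np.ndarray     # 256 nonnegative integers

    def to_rows(self) -> list[tuple[float, float, int]]:
        """(bin_start, bin_end, count) rows for CSV export."""
        return [(float(self.bin_edges[i]), float(self.bin_edges[i + 1]),
                 int(self.counts[i])) for i in range(len(self.counts))]


def cscan_map(volume: EnvelopeVolume, window: TimeWindow) -> CScan:
    """Maximum amplitude projection: out[x, y] = max over z in window."""
    keep = (volume.depth_axis >= window.start) & (volume.depth_axis <= window.end)
    if not keep.any():
        raise ValueError("projection window does not intersect the depth axis")
    return CScan(
        data=volume.data[:, :, keep].max(axis=2),
        pixel_pitch=volume.pixel_pitch,
        source_window=window,
    )


def extract_bscan(volume: EnvelopeVolume, line_index: int) -> BScan:
    """Exact [x, z] slice of the volume at lateral line ``line_index`` (y)."""
    ny = volume.data.shape[1]
    if not (0 <= line_index < ny):
        raise IndexError(f"line_index must be in [0, {ny - 1}], got {line_index}")
    nx = volume.data.shape[0]
    return BScan(
        data=volume.data[:, line_index, :].copy(),
        depth_axis=volume.depth_axis.copy(),
        lateral_axis=np.arange(nx) * volume.pixel_pitch,
        line_index=line_index,
    )


def volume_histogram(volume: EnvelopeVolume, fixed_max: float | None = None
                     ) -> VolumeHistogram:
    """Frequency distribution of voxel values in 256 bins from 0 to 256.

    Values are linearly rescaled to [0, 255] by the global maximum (or by
    ``fixed_max`` when a fixed-range histogram is wanted) and binned into
    unit-width bins.  Counts always sum to the voxel total; an all-zero
    volume puts all mass in bin 0.
    """
    data = np.asarray(volume.data, dtype=float)
    if data.size == 0 or not np.isfinite(data).all():
        raise ValueError("volume must be nonempty and finite")
    scale_max = float(data.max()) if fixed_max is None else float(fixed_max)
    scaled = data * (255.0 / scale_max) if scale_max > 0 else np.zeros_like(data)
    edges = np.arange(257, dtype=float)
    counts, _ = np.histogram(np.clip(scaled, 0.0, 255.999), bins=edges)
    return VolumeHistogram(bin_edges=edges, counts=counts.astype(np.int64))


def occupancy_fraction(volume: EnvelopeVolume, threshold: float) -> float:
    """Percentage of voxels strictly above the threshold.

    Quantifies how sparse the signal-bearing part of the volume is: the
    count of supra-threshold voxels over the voxel total, times 100.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    data = volume.data
    return 100.0 * float(np.count_nonzero(data > threshold)) / data.size


def noise_threshold(volume: EnvelopeVolume, noise_window: TimeWindow,
                    k: float = 3.0) -> float:
    """Default occupancy threshold: mean + k*std of a noise-only window."""
    keep = (volume.depth_axis >= noise_window.start) & \
           (volume.depth_axis <= noise_window.end)
    if not keep.any():
        raise ValueError("noise window does not intersect the depth axis")
    region = volume.data[:, :, keep]
    return float(region.mean() + k * region.std())


def contrast_ratio(cscan: CScan, foreground_mask: np.ndarray,
                   background_mask: np.ndarray) -> float:
    """Mean foreground amplitude over mean background amplitude.

    Returns ``inf`` (flagged distinctly, not raised) when the background
    mean is exactly zero.  Masks must be disjoint, nonempty booleans of the
    C-scan's shape.
    """
    fg = np.asarray(foreground_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if fg.shape != cscan.data.shape or bg.shape != cscan.data.shape:
        raise ValueError("masks must match the C-scan shape")
    if not fg.any() or not bg.any():
        raise ValueError("both masks must be nonempty")
    if (fg & bg).any():
        raise ValueError("foreground and background masks must be disjoint")
    fg_mean = float(cscan.data[fg].mean())
    bg_mean = float(cscan.data[bg].mean())
    if bg_mean == 0.0:
        return float("inf")
    return fg_mean / bg_mean


def count_local_maxima(cscan: CScan, rel_threshold: float = 0.5) -> int:
    """Count 8-connected local maxima above ``rel_threshold``x global max.

    Used for phantom recovery checks (counting resolved pigment-cell blobs
    in a PAM C-scan); plateaus of equal value count once.
    """
    data = cscan.data
    if data.size == 0 or data.max() <= 0:
        return 0
    above = data > rel_threshold * data.max()
    peak = data == ndimage.maximum_filter(data, size=3, mode="constant")
    labels, n = ndimage.label(above & peak,
                              structure=np.ones((3, 3), dtype=int))
    return int(n)
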