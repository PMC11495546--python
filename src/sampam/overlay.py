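"""Split colormap / alpha map construction and dual-modality overlay rendering.

The overlay convention follows the study's visualisation: SAM intensity is
shown on a grayscale ramp, PAM on an inverted hot-style ramp, and the two
lookup tables are stacked into one combined 2N-row matrix (first half gray,
second half inverted hot).  All ramps and the transparency (alpha) maps are
built by monotone piecewise-cubic Hermite interpolation (PCHIP) through a
small set of reference stops, so every curve passes exactly through its
stops, stays C1, and never overshoots monotone data.

Two compositing modes are provided: physically sensible source-over alpha
blending of the two colored volumes (default), and a literal
``index_product`` mode where the per-voxel normalized intensities are
multiplied and the product indexes the combined lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

from sampam.preprocess import EnvelopeVolume

__all__ = [
    "ColorStop",
    "SplitColormapSet",
    "OverlayVolume",
    "pchip_interpolate",
    "build_colormaps",
    "build_alphamap",
    "compose_overlay",
    "render_views",
    "GRAY_STOPS",
    "INVERTED_HOT_STOPS",
]


@dataclass(frozen=True)
class ColorStop:
    """One colormap reference point: (position in [0,1], rgb in [0,1]^3)."""

    position: float
    rgb: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.position <= 1.0):
            raise ValueError("stop position must lie in [0, 1]")
        if len(self.rgb) != 3 or not all(0.0 <= c <= 1.0 for c in self.rgb):
            raise ValueError("rgb must be three channel values in [0, 1]")


#: Default SAM ramp: plain grayscale, black to white.
GRAY_STOPS = (
    ColorStop(0.0, (0.0, 0.0, 0.0)),
    ColorStop(1.0, (1.0, 1.0, 1.0)),
)

#: Default PAM ramp: the hot ramp (black-red-yellow-white) reversed.
INVERTED_HOT_STOPS = (
    ColorStop(0.0, (1.0, 1.0, 1.0)),
    ColorStop(0.25, (1.0, 1.0, 0.0)),
    ColorStop(0.625, (1.0, 0.0, 0.0)),
    ColorStop(1.0, (0.0, 0.0, 0.0)),
)

#: Default transparency: fully transparent at zero signal, opaque at full.
DEFAULT_ALPHA_STOPS = ((0.0, 0.0), (1.0, 1.0))


@dataclass
class SplitColormapSet:
    """Paired lookup tables: gray SAM half, inverted-hot PAM half."""

    sam_lut: np.ndarray      # [n, 3]
    pam_lut: np.ndarray      # [n, 3]
    combined_lut: np.ndarray  # [2n, 3]: sam_lut stacked over pam_lut
    sam_alpha: np.ndarray    # [n]
    pam_alpha: np.ndarray    # [n]

    @property
    def n(self) -> int:
        return self.sam_lut.shape[0]


@dataclass
class OverlayVolume:
    """RGBA voxel volume composed from co-registered SAM and PAM envelopes."""

    rgba: np.ndarray  # [x, y, z, 4] in [0, 1]
    provenance: dict = field(default_factory=dict)


def pchip_interpolate(xs: np.ndarray, ys: np.ndarray,
                      query: np.ndarray) -> np.ndarray:
    """Shape-preserving cubic Hermite interpolation through (xs, ys).

    The interpolant passes exactly through the breakpoints, has a
    continuous first derivative, never overshoots beyond adjacent data
    values, and is monotone wherever the data are monotone.  Extrapolation
    is refused: all query points must lie in [xs[0], xs[-1]].
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    q = np.asarray(query, dtype=float)
    if xs.ndim != 1 or len(xs) < 2:
        raise ValueError("need at least 2 breakpoints")
    if np.any(np.diff(xs) == 0):
        raise ValueError("duplicate breakpoints in xs")
    if np.any(np.diff(xs) < 0):
        raise ValueError("xs must be strictly increasing")
    if q.size and (q.min() < xs[0] or q.max() > xs[-1]):
        raise ValueError(
            f"query outside [{xs[0]}, {xs[-1]}]: extrapolation is not supported")
    return PchipInterpolator(xs, ys)(q)


def _validate_stops(stops) -> tuple[np.ndarray, np.ndarray]:
    stops = [s if isinstance(s, ColorStop) else ColorStop(s[0], tuple(s[1]))
             for s in stops]
    pos = np.array([s.position for s in stops])
    if len(pos) < 2 or np.any(np.diff(pos) <= 0):
        raise ValueError("stop positions must be strictly increasing")
    if pos[0] != 0.0 or pos[-1] != 1.0:
        raise ValueError("stop positions must start at 0 and end at 1")
    rgb = np.array([s.rgb for s in stops])
    return pos, rgb


def build_colormaps(sam_stops=GRAY_STOPS, pam_stops=INVERTED_HOT_STOPS,
                    n: int = 256,
                    sam_alpha_stops=DEFAULT_ALPHA_STOPS,
                    pam_alpha_stops=DEFAULT_ALPHA_STOPS) -> SplitColormapSet:
    """Build the split colormap matrix and both alpha maps.

    Each lookup table is interpolated channel-wise with PCHIP over ``n``
    equally spaced positions; the combined matrix stacks the SAM half above
    the PAM half (2n rows).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    grid = np.linspace(0.0, 1.0, n)

    def lut_from(stops) -> np.ndarray:
        pos, rgb = _validate_stops(stops)
        lut = np.column_stack([pchip_interpolate(pos, rgb[:, c], grid)
                               for c in range(3)])
        return np.clip(lut, 0.0, 1.0)

    sam_lut = lut_from(sam_stops)
    pam_lut = lut_from(pam_stops)
    return SplitColormapSet(
        sam_lut=sam_lut,
        pam_lut=pam_lut,
        combined_lut=np.vstack([sam_lut, pam_lut]),
        sam_alpha=build_alphamap(sam_alpha_stops, n),
        pam_alpha=build_alphamap(pam_alpha_stops, n),
    )


def build_alphamap(stops, n: int) -> np.ndarray:
    """PCHIP-interpolated transparency table of ``n`` alphas in [0, 1]."""
    if n < 2:
        raise ValueError("n must be at least 2")
    pos = np.array([float(p) for p, _ in stops])
    alpha = np.array([float(a) for _, a in stops])
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha values must lie in [0, 1]")
    if len(pos) < 2 or np.any(np.diff(pos) <= 0) or pos[0] != 0.0 or pos[-1] != 1.0:
        raise ValueError("alpha stop positions must increase from 0 to 1")
    grid = np.linspace(0.0, 1.0, n)
    return np.clip(pchip_interpolate(pos, alpha, grid), 0.0, 1.0)


def _normalize(data: np.ndarray) -> np.ndarray:
    m = float(data.max()) if data.size else 0.0
    return data / m if m > 0 else np.zeros_like(data, dtype=float)


def compose_overlay(sam: EnvelopeVolume, pam: EnvelopeVolume,
                    maps: SplitColormapSet, mode: str = "blend"
                    ) -> OverlayVolume:
    """Fuse two co-registered envelope volumes into one RGBA volume.

    Each modality is first normalized to [0, 1] by its own global maximum.
    ``blend`` colors each modality through its LUT and alpha map and
    composites PAM over SAM with source-over alpha blending.
    ``index_product`` is the literal matrix combination: the two normalized
    intensities are multiplied and the product indexes the combined
    (gray + inverted-hot) lookup table and the concatenated alpha tables.
    """
    if sam.data.shape != pam.data.shape:
        raise ValueError(
            "SAM and PAM volumes differ in shape; run align_and_coregister first")
    if not np.allclose(sam.depth_axis, pam.depth_axis):
        raise ValueError(
            "SAM and PAM depth axes differ; run align_and_coregister first")
    s = _normalize(np.asarray(sam.data, dtype=float))
    p = _normalize(np.asarray(pam.data, dtype=float))
    n = maps.n

    if mode == "blend":
        si = np.rint(s * (n - 1)).astype(np.intp)
        pi = np.rint(p * (n - 1)).astype(np.intp)
        s_rgb = maps.sam_lut[si]
        p_rgb = maps.pam_lut[pi]
        a_s = maps.sam_alpha[si][..., None]
        a_p = maps.pam_alpha[pi][..., None]
        a_out = a_p + a_s * (1.0 - a_p)
        rgb = p_rgb * a_p + s_rgb * a_s * (1.0 - a_p)
        with np.errstate(invalid="ignore", divide="ignore"):
            rgb = np.where(a_out > 0, rgb / np.where(a_out > 0, a_out, 1.0), 0.0)
        rgba = np.concatenate([rgb, a_out], axis=-1)
    elif mode == "index_product":
        ci = np.rint(s * p * (2 * n - 1)).astype(np.intp)
        rgb = maps.combined_lut[ci]
        alpha_table = np.concatenate([maps.sam_alpha, maps.pam_alpha])
        rgba = np.concatenate([rgb, alpha_table[ci][..., None]], axis=-1)
    else:
        raise ValueError(f"unknown compositing mode {mode!r}")

    return OverlayVolume(
        rgba=np.clip(rgba, 0.0, 1.0),
        provenance={"mode": mode, "lut_rows": 2 * n,
                    "sam_shape": sam.data.shape, "pam_shape": pam.data.shape},
    )


def render_views(overlay: OverlayVolume, view: str = "side",
                 azimuth: float = 30.0, elevation: float = 30.0) -> np.ndarray:
    """Project the RGBA volume to a 2-D image.

    ``side``: orthographic projection along the y axis keeping, for each
    (x, z), the voxel of maximum opacity; the image has shape [nz, nx, 4]
    (depth down the rows).  ``angular``: the same projection after rotating
    the voxel grid by ``azimuth`` about the depth axis and ``elevation``
    about the x axis (nearest-neighbour resampling, grid expanded to fit);
    a 0/0 rotation reproduces the side view exactly.
    """
    rgba = overlay.rgba
    if rgba.size == 0:
        raise ValueError("cannot render an empty overlay volume")
    if view == "angular":
        if azimuth != 0.0:
            rgba = ndimage.rotate(rgba, azimuth, axes=(0, 1), order=0,
                                  reshape=True, mode="constant", cval=0.0)
        if elevation != 0.0:
            rgba = ndimage.rotate(rgba, elevation, axes=(1, 2), order=0,
                                  reshape=True, mode="constant", cval=0.0)
    elif view != "side":
        raise ValueError(f"unknown view {view!r}")
    alpha = rgba[..., 3]
    sel = np.argmax(alpha, axis=1)                      # [x, z]
    img = np.take_along_axis(rgba, sel[:, None, :, None], axis=1)[:, 0]
    return np.transpose(img, (1, 0, 2))                 # [z, x, 4]
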