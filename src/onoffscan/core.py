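"""Multi-scale center-surround analysis of ON/OFF stimulus strength.

The analyzer scans a grayscale frame with a dense grid of simplified
"receptive fields": at every interior pixel, the mean gray level of 8
peripheral pixels at distance ``k`` is subtracted from the gray level of
the center pixel.  A positive response marks the position as
ON-stimulating (bright center on darker surround), a negative response as
OFF-stimulating.  Running the same grid at several scales ``k`` probes a
range of spatial frequencies; per scale, the signed responses are
aggregated into ON and OFF strengths whose ratio summarizes the contrast
polarity of the scene.

The receptive field is deliberately minimal — a raw center-minus-surround
difference, not a difference of Gaussians and not contrast-normalized —
so the output tracks stimulus structure, not any particular retinal model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SURROUND_OFFSETS",
    "GrayFrame",
    "ScaleSet",
    "Calibration",
    "AggregatorSpec",
    "OnOffProfile",
    "to_grayscale",
    "sampling_grid",
    "rf_response",
    "aggregate",
    "analyze_frame",
    "spatial_frequency",
    "polarity_index",
]

#: Unit offsets (dx, dy) of the 8 peripheral samples; scaled by k at scale k.
SURROUND_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (0, -1), (1, -1),
    (-1, 0), (1, 0),
    (-1, 1), (0, 1), (1, 1),
)

#: ITU-R BT.601 luma weights for R, G, B.
_LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class GrayFrame:
    """A 2-D grid of luminance values, nominal range 0–255.

    Pixels are stored as float64 in row-major order with the origin at the
    top-left; ``pixels[y, x]`` addresses column ``x`` of row ``y`` (both
    0-based).  ``meta`` carries optional provenance (e.g. the achieved ink
    fraction of a rendered text stimulus).
    """

    __slots__ = ("pixels", "meta")

    def __init__(self, pixels: np.ndarray, meta: dict | None = None):
        arr = np.asarray(pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D pixel array, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"frame must be at least 1x1, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("frame contains non-finite luminance values")
        self.pixels = arr
        self.meta = dict(meta) if meta else {}

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def mean_luminance(self) -> float:
        return float(self.pixels.mean())

    def inverted(self) -> "GrayFrame":
        """Photometric inverse: every pixel v becomes 255 - v."""
        return GrayFrame(255.0 - self.pixels)

    def __eq__(self, other) -> bool:
        return isinstance(other, GrayFrame) and np.array_equal(self.pixels, other.pixels)

    def __repr__(self) -> str:
        return f"GrayFrame({self.width}x{self.height}, mean={self.mean_luminance():.1f})"


@dataclass(frozen=True)
class ScaleSet:
    """Ordered set of receptive-field scales (peripheral pixel distances)."""

    scales: tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self):
        if len(self.scales) == 0:
            raise ValueError("ScaleSet needs at least one scale")
        scales = tuple(int(k) for k in self.scales)
        if any(k < 1 for k in scales):
            raise ValueError(f"scales must be positive integers, got {scales}")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError(f"scales must be strictly increasing, got {scales}")
        object.__setattr__(self, "scales", scales)

    @property
    def margin(self) -> int:
        """Sampling margin: the largest scale sets how far the grid must
        stay from the frame edge for every surround sample to be in-frame."""
        return self.scales[-1]

    def __iter__(self):
        return iter(self.scales)

    def __len__(self):
        return len(self.scales)


@dataclass(frozen=True)
class Calibration:
    """Mapping from receptive-field scale to retinal spatial frequency.

    A field at scale ``k`` samples a spatial period of 2k pixels, so the
    frequency falls off as 1/k from the scale-1 value.  The default 22.4
    cyc/deg reproduces the frequency axis of the original video setup
    (monochrome camera with a 16 mm lens); use :meth:`from_optics` to
    derive the constant for other sensor geometries.
    """

    sf_at_scale_1: float = 22.4

    def __post_init__(self):
        if not (self.sf_at_scale_1 > 0):
            raise ValueError(f"sf_at_scale_1 must be > 0, got {self.sf_at_scale_1}")

    @classmethod
    def from_optics(cls, focal_length_mm: float, pixel_pitch_um: float) -> "Calibration":
        """Calibration from lens focal length and sensor pixel pitch.

        One pixel subtends ``atan(pitch / f)`` of visual angle; the highest
        sampled frequency (scale 1, period 2 px) is the Nyquist frequency
        1 / (2 * degrees-per-pixel).
        """
        if focal_length_mm <= 0 or pixel_pitch_um <= 0:
            raise ValueError("focal length and pixel pitch must be positive")
        deg_per_px = math.degrees(math.atan(pixel_pitch_um * 1e-3 / focal_length_mm))
        return cls(sf_at_scale_1=1.0 / (2.0 * deg_per_px))

    def spatial_frequency(self, k: int) -> float:
        return spatial_frequency(k, self)


@dataclass(frozen=True)
class AggregatorSpec:
    """How signed receptive-field responses are combined per scale.

    mode
        ``power``     – strengths are sums of |response|**gamma (default
                        gamma=2, i.e. response energy); the default, because
                        it weights the few large stroke responses over the
                        many weak halo responses.
        ``sum``       – plain magnitude sums (gamma=1).
        ``count``     – strengths equal the position counts.
        ``threshold`` – like ``sum`` but only responses with |r| > threshold
                        contribute to counts and strengths.
    """

    mode: str = "power"
    gamma: float = 2.0
    threshold: float = 0.0

    _MODES = ("power", "sum", "count", "threshold")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        if self.gamma < 1:
            raise ValueError(f"gamma must be >= 1, got {self.gamma}")
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")


@dataclass
class OnOffProfile:
    """Per-scale ON/OFF strengths and counts for one analyzed frame."""

    scales: tuple[int, ...]
    spatial_frequency_cpd: tuple[float, ...]
    on_strength: np.ndarray
    off_strength: np.ndarray
    on_count: np.ndarray
    off_count: np.ndarray
    frame_width: int
    frame_height: int
    frame_mean_luminance: float
    aggregator: AggregatorSpec = field(default_factory=AggregatorSpec)

    def polarity_index(self, k: int) -> float:
        """Normalized polarity (on - off) / (on + off) at scale ``k``.

        +1 means purely ON-stimulating, -1 purely OFF-stimulating,
        0 balanced.  Undefined (NaN) when both strengths are zero.
        """
        i = self.scales.index(k)
        return polarity_index(float(self.on_strength[i]), float(self.off_strength[i]))

    def polarity_indices(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            tot = self.on_strength + self.off_strength
            return np.where(tot > 0, (self.on_strength - self.off_strength) / np.where(tot > 0, tot, 1.0), np.nan)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "scale_k": list(self.scales),
                "spatial_frequency_cpd": list(self.spatial_frequency_cpd),
                "on_strength": self.on_strength,
                "off_strength": self.off_strength,
                "on_count": self.on_count,
                "off_count": self.off_count,
                "polarity_index": self.polarity_indices(),
            }
        )


def to_grayscale(frame: np.ndarray | GrayFrame) -> GrayFrame:
    """Convert a raster to a GrayFrame.

    2-D input passes through unchanged; 3-channel input is converted with
    BT.601 luma weights (0.299 R + 0.587 G + 0.114 B).
    """
    if isinstance(frame, GrayFrame):
        return frame
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 2:
        return GrayFrame(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        luma = (
            _LUMA_WEIGHTS[0] * arr[:, :, 0]
            + _LUMA_WEIGHTS[1] * arr[:, :, 1]
            + _LUMA_WEIGHTS[2] * arr[:, :, 2]
        )
        return GrayFrame(luma)
    raise ValueError(
        f"expected a 2-D grayscale or HxWx3 color array, got shape {arr.shape}"
    )


def sampling_grid(width: int, height: int, margin: int) -> np.ndarray:
    """All center positions (x, y) with a full surround inside the frame.

    Returns an (N, 2) integer array of [x, y] pairs covering every pixel
    with margin <= x < width - margin and margin <= y < height - margin.
    For a 640x480 frame and margin 10 this is (640-20)*(480-20) = 285,200
    positions.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    if width <= 2 * margin:
        raise ValueError(
            f"frame width {width} leaves an empty sampling grid at margin {margin}"
        )
    if height <= 2 * margin:
        raise ValueError(
            f"frame height {height} leaves an empty sampling grid at margin {margin}"
        )
    xs = np.arange(margin, width - margin)
    ys = np.arange(margin, height - margin)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def rf_response(frame: GrayFrame, x: int, y: int, k: int) -> float:
    """Signed center-surround response at one position and scale.

    response = center - mean of the 8 peripheral pixels at offsets
    {(+-k, 0), (0, +-k), (+-k, +-k)}.  Positive = ON-stimulating,
    negative = OFF-stimulating, zero = neither.
    """
    if k < 1:
        raise ValueError(f"scale k must be >= 1, got {k}")
    px = frame.pixels
    h, w = px.shape
    if not (k <= x < w - k and k <= y < h - k):
        raise ValueError(
            f"surround of scale {k} at ({x}, {y}) falls outside the {w}x{h} frame"
        )
    s = 0.0
    for dx, dy in SURROUND_OFFSETS:
        s += px[y + dy * k, x + dx * k]
    return float(px[y, x] - s / 8.0)


def aggregate(
    responses: Sequence[float] | np.ndarray, spec: AggregatorSpec | None = None
) -> tuple[float, float, int, int]:
    """Combine signed responses into (on_strength, off_strength, on_count, off_count).

    Zero responses count as neither ON nor OFF and never contribute.
    """
    spec = spec or AggregatorSpec()
    r = np.asarray(responses, dtype=np.float64)
    if r.size and not np.isfinite(r).all():
        raise ValueError("responses must be finite")
    if spec.mode == "threshold":
        pos = r[r > spec.threshold]
        neg = -r[r < -spec.threshold]
        return float(pos.sum()), float(neg.sum()), int(pos.size), int(neg.size)
    pos = r[r > 0]
    neg = -r[r < 0]
    on_count, off_count = int(pos.size), int(neg.size)
    if spec.mode == "count":
        return float(on_count), float(off_count), on_count, off_count
    if spec.mode == "sum":
        return float(pos.sum()), float(neg.sum()), on_count, off_count
    # power
    return (
        float(np.sum(pos ** spec.gamma)),
        float(np.sum(neg ** spec.gamma)),
        on_count,
        off_count,
    )


def _response_field(px: np.ndarray, margin: int, k: int) -> np.ndarray:
    """Vectorized signed responses at scale k over the shared interior grid."""
    h, w = px.shape
    center = px[margin : h - margin, margin : w - margin]
    s = np.zeros_like(center)
    for dx, dy in SURROUND_OFFSETS:
        s = s + px[margin + dy * k : h - margin + dy * k, margin + dx * k : w - margin + dx * k]
    return center - s / 8.0


def analyze_frame(
    frame: GrayFrame | np.ndarray,
    scales: ScaleSet | Sequence[int] | None = None,
    cal: Calibration | None = None,
    spec: AggregatorSpec | None = None,
) -> OnOffProfile:
    """Scan a frame at every scale and aggregate per-scale ON/OFF strengths.

    One shared sampling grid (margin = the largest scale) is used for all
    scales, so counts are comparable across scales.  The analysis is fully
    deterministic: identical frames give identical profiles.
    """
    frame = to_grayscale(frame)
    if scales is None:
        scales = ScaleSet()
    elif not isinstance(scales, ScaleSet):
        scales = ScaleSet(tuple(scales))
    cal = cal or Calibration()
    spec = spec or AggregatorSpec()

    margin = scales.margin
    # raises with the offending dimension if the grid would be empty
    sampling_grid(frame.width, frame.height, margin)

    on_s, off_s, on_c, off_c = [], [], [], []
    for k in scales:
        resp = _response_field(frame.pixels, margin, k)
        a, b, ca, cb = aggregate(resp.ravel(), spec)
        on_s.append(a)
        off_s.append(b)
        on_c.append(ca)
        off_c.append(cb)

    return OnOffProfile(
        scales=scales.scales,
        spatial_frequency_cpd=tuple(spatial_frequency(k, cal) for k in scales),
        on_strength=np.array(on_s),
        off_strength=np.array(off_s),
        on_count=np.array(on_c, dtype=np.int64),
        off_count=np.array(off_c, dtype=np.int64),
        frame_width=frame.width,
        frame_height=frame.height,
        frame_mean_luminance=frame.mean_luminance(),
        aggregator=spec,
    )


def spatial_frequency(k: int, cal: Calibration | None = None) -> float:
    """Spatial frequency (cyc/deg) probed at scale ``k``: sf(1) / k."""
    if k < 1:
        raise ValueError(f"scale k must be >= 1, got {k}")
    cal = cal or Calibration()
    return cal.sf_at_scale_1 / k


def polarity_index(on_strength: float, off_strength: float) -> float:
    """(on - off) / (on + off); NaN when both strengths are zero."""
    if on_strength < 0 or off_strength < 0:
        raise ValueError("strengths must be non-negative")
    total = on_strength + off_strength
    if total == 0:
        return math.nan
    return (on_strength - off_strength) / total
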