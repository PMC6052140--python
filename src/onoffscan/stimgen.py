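"""Synthetic visual stimuli: polarity-controlled text, matched-luminance
pairs, checkerboards, constant fields and 1/f-noise scene surrogates.

Text is rendered with an embedded axis-aligned segment font rather than a
system font, so stimuli are bit-reproducible across platforms and the
stroke width — the variable that controls how OFF-dominated dark text is —
can be set exactly, independent of glyph height.  Only the contrast
structure of printed text (thin uniform strokes on a uniform field) is
emulated, not any particular typeface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import GrayFrame

__all__ = [
    "TextStimulusSpec",
    "render_text",
    "match_mean_luminance",
    "checkerboard",
    "constant_field",
    "pink_noise",
]

# ---------------------------------------------------------------------------
# Embedded segment font.
#
# Each glyph is a list of axis-aligned strokes ((x0, y0), (x1, y1)) on a
# 3x3 anchor grid: x in {0, 1, 2} spans the glyph width, y in {0, 1, 2}
# spans its height (top/middle/bottom).  Letters are blocky approximations
# (no diagonals); legibility is secondary to having controlled thin strokes
# of a single polarity on a uniform background.
# ---------------------------------------------------------------------------

_H_TOP = ((0, 0), (2, 0))
_H_MID = ((0, 1), (2, 1))
_H_BOT = ((0, 2), (2, 2))
_V_L = ((0, 0), (0, 2))
_V_R = ((2, 0), (2, 2))
_V_LU = ((0, 0), (0, 1))
_V_LD = ((0, 1), (0, 2))
_V_RU = ((2, 0), (2, 1))
_V_RD = ((2, 1), (2, 2))
_V_C = ((1, 0), (1, 2))

_FONT: dict[str, tuple] = {
    " ": (),
    "A": (_V_L, _V_R, _H_TOP, _H_MID),
    "B": (_V_L, _V_R, _H_TOP, _H_MID, _H_BOT),
    "C": (_V_L, _H_TOP, _H_BOT),
    "D": (_V_L, _V_R, _H_TOP, _H_BOT),
    "E": (_V_L, _H_TOP, _H_MID, _H_BOT),
    "F": (_V_L, _H_TOP, _H_MID),
    "G": (_V_L, _H_TOP, _H_BOT, _V_RD, ((1, 1), (2, 1))),
    "H": (_V_L, _V_R, _H_MID),
    "I": (_V_C, _H_TOP, _H_BOT),
    "J": (_V_R, _H_BOT, _V_LD),
    "K": (_V_L, _H_MID, _V_RU, _V_RD),
    "L": (_V_L, _H_BOT),
    "M": (_V_L, _V_R, _H_TOP, ((1, 0), (1, 1))),
    "N": (_V_L, _V_R, _H_TOP),
    "O": (_V_L, _V_R, _H_TOP, _H_BOT),
    "P": (_V_L, _V_RU, _H_TOP, _H_MID),
    "Q": (_V_L, _V_R, _H_TOP, _H_BOT, ((1, 1), (1, 2))),
    "R": (_V_L, _V_RU, _H_TOP, _H_MID, _V_RD),
    "S": (_H_TOP, _V_LU, _H_MID, _V_RD, _H_BOT),
    "T": (_V_C, _H_TOP),
    "U": (_V_L, _V_R, _H_BOT),
    "V": (_V_L, _V_R, _H_BOT),
    "W": (_V_L, _V_R, _H_BOT, ((1, 1), (1, 2))),
    "X": (_V_LU, _V_RU, _H_MID, _V_LD, _V_RD),
    "Y": (_V_LU, _V_RU, _H_MID, ((1, 1), (1, 2))),
    "Z": (_H_TOP, ((1, 0), (1, 2)), _H_BOT),
    "0": (_V_L, _V_R, _H_TOP, _H_BOT),
    "1": (_V_C,),
    "2": (_H_TOP, _V_RU, _H_MID, _V_LD, _H_BOT),
    "3": (_H_TOP, _H_MID, _H_BOT, _V_R),
    "4": (_V_LU, _H_MID, _V_R),
    "5": (_H_TOP, _V_LU, _H_MID, _V_RD, _H_BOT),
    "6": (_V_L, _H_TOP, _H_MID, _V_RD, _H_BOT),
    "7": (_H_TOP, _V_R),
    "8": (_V_L, _V_R, _H_TOP, _H_MID, _H_BOT),
    "9": (_V_LU, _H_TOP, _H_MID, _V_R, _H_BOT),
    ".": (((1, 2), (1, 2)),),
    ",": (((1, 2), (1, 2)),),
    "-": (_H_MID,),
    ":": (((1, 1), (1, 1)), ((1, 2), (1, 2))),
}


@dataclass(frozen=True)
class TextStimulusSpec:
    """Parameters of a polarity-controlled text stimulus.

    ``foreground_level`` is the ink gray value, ``background_level`` the
    page; ``polarity`` must be consistent with the two levels.  Defaults
    give black text on a white page.
    """

    text: str = "READING"
    polarity: str = "dark_on_light"
    glyph_height: int = 14
    stroke_width: int = 1
    foreground_level: float = 0.0
    background_level: float = 255.0
    margin: int = 20
    frame_width: int = 256
    frame_height: int = 128

    def __post_init__(self):
        if not self.text:
            raise ValueError("text must be non-empty")
        if self.polarity not in ("dark_on_light", "light_on_dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.foreground_level == self.background_level:
            raise ValueError("foreground and background levels must differ")
        dark_fg = self.foreground_level < self.background_level
        if dark_fg != (self.polarity == "dark_on_light"):
            raise ValueError(
                "polarity is inconsistent with foreground/background levels"
            )
        if self.stroke_width < 1:
            raise ValueError("stroke_width must be >= 1")
        if self.glyph_height < 2 * self.stroke_width + 1:
            raise ValueError("glyph_height too small for the requested stroke width")
        unknown = {c for c in self.text.upper() if c not in _FONT and c != "\n"}
        if unknown:
            raise ValueError(f"characters not in the embedded font: {sorted(unknown)}")

    def flipped(self) -> "TextStimulusSpec":
        """The photometric inverse spec (levels inverted, polarity swapped)."""
        return replace(
            self,
            polarity=(
                "light_on_dark" if self.polarity == "dark_on_light" else "dark_on_light"
            ),
            foreground_level=255.0 - self.foreground_level,
            background_level=255.0 - self.background_level,
        )


def _glyph_geometry(spec: TextStimulusSpec) -> tuple[int, int, int]:
    gh = spec.glyph_height
    gw = max(2 * spec.stroke_width + 1, round(0.6 * gh))
    advance = gw + max(2, spec.stroke_width)
    return gw, gh, advance


def _draw_glyph(canvas: np.ndarray, ch: str, x0: int, y0: int, spec: TextStimulusSpec) -> None:
    gw, gh, _ = _glyph_geometry(spec)
    sw = spec.stroke_width
    # anchor coordinate -> top-left pixel of a stroke of width sw inside the box
    ax = [0, (gw - sw) // 2, gw - sw]
    ay = [0, (gh - sw) // 2, gh - sw]
    for (sx0, sy0), (sx1, sy1) in _FONT[ch]:
        px0, px1 = sorted((ax[sx0], ax[sx1]))
        py0, py1 = sorted((ay[sy0], ay[sy1]))
        canvas[y0 + py0 : y0 + py1 + sw, x0 + px0 : x0 + px1 + sw] = spec.foreground_level


def render_text(spec: TextStimulusSpec, seed: int = 0) -> GrayFrame:
    """Render a text stimulus; deterministic for a fixed spec (the seed is
    accepted for interface symmetry with the noise generators).

    The returned frame's ``meta`` records the spec fields and the achieved
    ink fraction (fraction of pixels at the foreground level).
    """
    del seed  # rendering has no random component
    gw, gh, advance = _glyph_geometry(spec)
    line_height = gh + max(3, gh // 3)

    canvas = np.full(
        (spec.frame_height, spec.frame_width), spec.background_level, dtype=np.float64
    )
    x, y = spec.margin, spec.margin
    x_max = spec.frame_width - spec.margin
    y_max = spec.frame_height - spec.margin
    for ch in spec.text.upper():
        if ch == "\n":
            x, y = spec.margin, y + line_height
            continue
        if x + gw > x_max:  # soft wrap
            x, y = spec.margin, y + line_height
        if x + gw > x_max or y + gh > y_max:
            raise ValueError(
                f"text does not fit a {spec.frame_width}x{spec.frame_height} frame "
                f"with margin {spec.margin} at glyph height {spec.glyph_height}"
            )
        _draw_glyph(canvas, ch, x, y, spec)
        x += advance

    ink = float(np.mean(canvas == spec.foreground_level))
    if not (0.0 < ink < 1.0):
        raise ValueError("rendered ink fraction must lie strictly between 0 and 1")
    meta = {
        "kind": "text",
        "text": spec.text,
        "polarity": spec.polarity,
        "glyph_height": spec.glyph_height,
        "stroke_width": spec.stroke_width,
        "foreground_level": spec.foreground_level,
        "background_level": spec.background_level,
        "ink_fraction": ink,
    }
    return GrayFrame(canvas, meta=meta)


def match_mean_luminance(
    a: GrayFrame, b: GrayFrame, target_mean: float = 128.0
) -> tuple[GrayFrame, GrayFrame]:
    """Shift both frames so their mean pixel values equal ``target_mean``.

    Each frame is offset by (target - mean), which preserves every
    center-surround response exactly.  If the offset would push any pixel
    outside [0, 255] the frame is *not* silently clipped: a ValueError
    reports the feasible target range instead.
    """
    out = []
    for name, f in (("first", a), ("second", b)):
        m = f.mean_luminance()
        shift = target_mean - m
        if abs(shift) < 1e-12:
            out.append(f)
            continue
        lo = m - float(f.pixels.min())  # lowest reachable target mean
        hi = m + 255.0 - float(f.pixels.max())  # highest reachable target mean
        if not (lo - 1e-9 <= target_mean <= hi + 1e-9):
            raise ValueError(
                f"target mean {target_mean} infeasible for the {name} frame without "
                f"clipping; feasible range is [{lo:.3f}, {hi:.3f}]"
            )
        out.append(GrayFrame(f.pixels + shift, meta=dict(f.meta)))
    return out[0], out[1]


def checkerboard(
    width: int,
    height: int,
    square: int = 8,
    levels: tuple[float, float] = (0.0, 255.0),
) -> GrayFrame:
    """Two-level checkerboard, phase fixed at the origin.

    A square size of at least the frame size degenerates to a constant
    field at ``levels[0]``.
    """
    if square < 1:
        raise ValueError(f"square size must be >= 1, got {square}")
    ys, xs = np.indices((height, width))
    parity = (xs // square + ys // square) % 2
    lo, hi = levels
    return GrayFrame(np.where(parity == 0, lo, hi), meta={"kind": "checkerboard"})


def constant_field(width: int, height: int, level: float = 128.0) -> GrayFrame:
    """Uniform frame; analyzes to a zero profile at every scale."""
    return GrayFrame(np.full((height, width), float(level)), meta={"kind": "constant"})


def pink_noise(width: int, height: int, seed: int = 0) -> GrayFrame:
    """1/f-amplitude-spectrum noise as a natural-scene surrogate.

    Natural scenes have approximately 1/f amplitude spectra; this generator
    produces a luminance field with that second-order structure and a
    symmetric value distribution, so ON and OFF strengths come out nearly
    balanced.  Output is affinely rescaled to mean 128 with all values in
    [20, 235]; deterministic per seed.
    """
    if width < 64 or height < 64:
        raise ValueError(f"frame must be at least 64x64, got {width}x{height}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((height, width))
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill DC; mean is set explicitly below
    field = np.real(np.fft.ifft2(np.fft.fft2(white) / f))
    field -= field.mean()
    # gain that maps the extremes inside [20, 235] around a mean of 128
    span = max(field.max() / 107.0, -field.min() / 108.0)
    if span > 0:
        pixels = 128.0 + field / span
    else:
        pixels = np.full_like(field, 128.0)
    return GrayFrame(pixels, meta={"kind": "pink_noise", "seed": seed})
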