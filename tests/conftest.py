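"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized code paths:
they walk the sampling grid with plain Python loops so that agreement with
the library is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from onoffscan import GrayFrame


def naive_onoff_profile(pixels, scales, mode="power", gamma=2.0, threshold=0.0):
    """Double-loop reference analyzer.

    Returns per scale: (on_strength, off_strength, on_count, off_count),
    computed position by position with scalar arithmetic.
    """
    px = np.asarray(pixels, dtype=np.float64)
    h, w = px.shape
    margin = max(scales)
    offsets = [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)]
    out = {}
    for k in scales:
        on_s = off_s = 0.0
        on_c = off_c = 0
        for y in range(margin, h - margin):
            for x in range(margin, w - margin):
                s = 0.0
                for dx, dy in offsets:
                    s += px[y + dy * k, x + dx * k]
                r = px[y, x] - s / 8.0
                if mode == "threshold":
                    if r > threshold:
                        on_s += r
                        on_c += 1
                    elif r < -threshold:
                        off_s += -r
                        off_c += 1
                    continue
                if r > 0:
                    on_c += 1
                    on_s += r if mode == "sum" else (1.0 if mode == "count" else r**gamma)
                elif r < 0:
                    off_c += 1
                    off_s += -r if mode == "sum" else (1.0 if mode == "count" else (-r) ** gamma)
        if mode == "count":
            out[k] = (float(on_c), float(off_c), on_c, off_c)
        else:
            out[k] = (on_s, off_s, on_c, off_c)
    return out


def anova_f_oracle(wide):
    """Brute-force one-way repeated-measures F from the sums of squares.

    ``wide``: units x timepoints array.  F = MS_time / MS_error with the
    error term the unit-by-time interaction.
    """
    y = np.asarray(wide, dtype=np.float64)
    n, t = y.shape
    grand = y.mean()
    ss_time = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_units = t * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_time - ss_units
    df_time, df_err = t - 1, (n - 1) * (t - 1)
    return (ss_time / df_time) / (ss_err / df_err), df_time, df_err


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_int_frame(rng):
    """Factory for integer-valued random frames (exact float arithmetic)."""

    def make(width=32, height=32, lo=0, hi=256):
        return GrayFrame(rng.integers(lo, hi, size=(height, width)).astype(np.float64))

    return make
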