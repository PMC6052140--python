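"""Frame loading, profile serialization and run configuration."""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

from .core import (
    AggregatorSpec,
    Calibration,
    GrayFrame,
    OnOffProfile,
    ScaleSet,
    to_grayscale,
)

__all__ = [
    "IMAGE_EXTENSIONS",
    "RunConfig",
    "read_frames",
    "write_frame_png",
    "write_profile_csv",
    "write_profile_json",
    "plot_profile",
]

IMAGE_EXTENSIONS = (".png", ".pgm", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")

_PROFILE_COLUMNS = (
    "scale_k",
    "spatial_frequency_cpd",
    "on_strength",
    "off_strength",
    "on_count",
    "off_count",
    "polarity_index",
)


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; round-trips losslessly through a flat
    key=value file and is embedded in every JSON output."""

    scales: tuple[int, ...] = tuple(range(1, 11))
    sf_at_scale_1: float = 22.4
    mode: str = "power"
    gamma: float = 2.0
    threshold: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def scale_set(self) -> ScaleSet:
        return ScaleSet(self.scales)

    def calibration(self) -> Calibration:
        return Calibration(self.sf_at_scale_1)

    def aggregator(self) -> AggregatorSpec:
        return AggregatorSpec(self.mode, self.gamma, self.threshold)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if key == "scales":
                value = ",".join(str(k) for k in value)
            lines.append(f"{key}={value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key == "scales":
                kwargs[key] = tuple(int(v) for v in raw.split(","))
            elif key in ("sf_at_scale_1", "gamma", "threshold"):
                kwargs[key] = float(raw)
            elif key == "seed":
                kwargs[key] = int(raw)
            elif key in ("mode", "log_level"):
                kwargs[key] = raw
            else:
                raise ValueError(f"unknown config key {key!r} in {path}")
        return cls(**kwargs)


def _natural_key(path: Path):
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in re.split(r"(\d+)", path.name)]


def _load_image(path: Path) -> GrayFrame:
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    frame = to_grayscale(arr.astype(np.float64))
    frame.meta["source"] = str(path)
    return frame


def read_frames(path: str | Path) -> Iterator[GrayFrame]:
    """Yield GrayFrames from an image file or a directory of frame files.

    Directory entries are ordered by natural numeric filename sort
    (f1, f2, ..., f10) and must share one frame size; color inputs are
    converted to luma.
    """
    path = Path(path)
    if path.is_file():
        yield _load_image(path)
        return
    if not path.is_dir():
        raise FileNotFoundError(f"no such file or directory: {path}")
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS),
        key=_natural_key,
    )
    if not files:
        raise ValueError(f"directory {path} contains no image frames")
    shape = None
    for f in files:
        frame = _load_image(f)
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise ValueError(
                f"frame {f} has size {frame.shape[1]}x{frame.shape[0]}, "
                f"expected {shape[1]}x{shape[0]}"
            )
        yield frame


def write_frame_png(frame: GrayFrame, path: str | Path) -> None:
    iio.imwrite(Path(path), np.clip(np.rint(frame.pixels), 0, 255).astype(np.uint8))


def _fmt(value: float) -> str:
    """Fixed 6-significant-digit float formatting for diffable CSV."""
    return format(float(value), ".6g")


def write_profile_csv(profile: OnOffProfile, path: str | Path) -> None:
    lines = [",".join(_PROFILE_COLUMNS)]
    pol = profile.polarity_indices()
    for i, k in enumerate(profile.scales):
        lines.append(
            ",".join(
                [
                    str(k),
                    _fmt(profile.spatial_frequency_cpd[i]),
                    _fmt(profile.on_strength[i]),
                    _fmt(profile.off_strength[i]),
                    str(int(profile.on_count[i])),
                    str(int(profile.off_count[i])),
                    _fmt(pol[i]) if np.isfinite(pol[i]) else "nan",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile_json(
    profile: OnOffProfile, path: str | Path, config: RunConfig | None = None,
    extra: dict | None = None,
) -> None:
    pol = profile.polarity_indices()
    payload = {
        "frame": {
            "width": profile.frame_width,
            "height": profile.frame_height,
            "mean_luminance": round(profile.frame_mean_luminance, 6),
        },
        "aggregator": asdict(profile.aggregator),
        "profile": [
            {
                "scale_k": int(k),
                "spatial_frequency_cpd": float(_fmt(profile.spatial_frequency_cpd[i])),
                "on_strength": float(_fmt(profile.on_strength[i])),
                "off_strength": float(_fmt(profile.off_strength[i])),
                "on_count": int(profile.on_count[i]),
                "off_count": int(profile.off_count[i]),
                "polarity_index": float(_fmt(pol[i])) if np.isfinite(pol[i]) else None,
            }
            for i, k in enumerate(profile.scales)
        ],
    }
    if config is not None:
        payload["config"] = asdict(config)
    if extra:
        payload["meta"] = extra
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def plot_profile(profile: OnOffProfile, path: str | Path, title: str = "") -> None:
    """ON (green) and OFF (red) strength curves over spatial frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sf = np.asarray(profile.spatial_frequency_cpd)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sf, profile.on_strength, color="green", marker="o", label="ON")
    ax.plot(sf, profile.off_strength, color="red", marker="o", label="OFF")
    ax.set_xlabel("spatial frequency (cyc/deg)")
    ax.set_ylabel("aggregated strength")
    ax.set_xscale("log")
    ax.invert_xaxis()
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
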