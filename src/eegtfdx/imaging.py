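"""Render time-frequency matrices into square RGB rasters.

The image is the bare matrix — no axes, ticks or margins, so no
label-independent decoration reaches the classifier.  Each matrix is
min-max normalised per image (optionally after a log10 compression),
mapped through a fixed 256-entry rainbow lookup table with control points
blue -> cyan -> yellow -> red, flipped so frequency increases upward, and
resampled to ``side x side`` by bilinear interpolation.  Per-image
normalisation removes inter-subject amplitude scale (and with it any
absolute-power class cue); pass ``global_range`` to normalise a whole
dataset against one common range instead.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .io_signals import DatasetManifest
from .preprocess import Segment
from .tfr import TFRMatrix, cwt_bump, stft_spectrogram

__all__ = ["RenderedImage", "rainbow_lut", "render", "build_image_dataset",
           "segments_to_arrays"]

_LOG_EPS = 1e-12

_RAINBOW_STOPS = (
    (0.0, (0, 0, 255)),     # blue
    (1 / 3, (0, 255, 255)),  # cyan
    (2 / 3, (255, 255, 0)),  # yellow
    (1.0, (255, 0, 0)),     # red
)


def rainbow_lut() -> np.ndarray:
    """The fixed 256 x 3 uint8 colour table used for all renderings."""
    pos = np.array([p for p, _ in _RAINBOW_STOPS])
    cols = np.array([c for _, c in _RAINBOW_STOPS], dtype=float)
    x = np.linspace(0.0, 1.0, 256)
    lut = np.stack(
        [np.interp(x, pos, cols[:, k]) for k in range(3)], axis=1
    )
    return np.round(lut).astype(np.uint8)


_LUT = rainbow_lut()


@dataclass
class RenderedImage:
    """A square 8-bit RGB raster plus the provenance of its pixels."""

    pixels: np.ndarray  # (side, side, 3) uint8
    side: int
    source: dict

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (self.side, self.side, 3):
            raise ValueError(
                f"pixels shape {self.pixels.shape} does not match side {self.side}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit per channel")


def render(
    tfr: TFRMatrix,
    side: int,
    colormap: str = "rainbow",
    scaling: str | None = None,
    global_range: tuple[float, float] | None = None,
) -> RenderedImage:
    """Deterministically rasterise one TFR matrix.

    ``scaling`` defaults to ``log`` for scalograms and ``linear`` for
    spectrograms.  An all-constant matrix maps to the colormap's zero
    colour rather than dividing by zero.
    """
    if side < 1:
        raise ValueError("side must be a positive pixel count")
    if colormap != "rainbow":
        raise ValueError("only the documented 'rainbow' table is available")
    if scaling is None:
        scaling = "log" if tfr.kind == "scalogram" else "linear"
    if scaling not in ("linear", "log"):
        raise ValueError(f"unknown scaling {scaling!r}")

    v = tfr.values
    if scaling == "log":
        v = np.log10(v + _LOG_EPS)
    if global_range is not None:
        lo, hi = global_range
    else:
        lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        norm = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    else:
        norm = np.zeros_like(v)
    idx = np.round(norm * 255.0).astype(np.uint8)
    rgb = _LUT[idx][::-1]  # freq_axis ascending -> flip so high freq is on top
    img = Image.fromarray(rgb, mode="RGB").resize((side, side), Image.BILINEAR)
    return RenderedImage(
        pixels=np.asarray(img, dtype=np.uint8), side=side, source={"kind": tfr.kind}
    )


def _transform(segment: Segment, method: str, tfr_config: dict | None) -> TFRMatrix:
    cfg = dict(tfr_config or {})
    if method == "cwt":
        return cwt_bump(
            segment.samples,
            segment.fs,
            wavelet=cfg.get("wavelet"),
            grid=cfg.get("grid"),
        )
    if method == "stft":
        return stft_spectrogram(
            segment.samples,
            segment.fs,
            window=cfg.get("window", "hann"),
            window_len=cfg.get("window_len"),
            overlap=cfg.get("overlap", 0.5),
        )
    raise ValueError(f"unknown method {method!r}; expected 'cwt' or 'stft'")


def render_segment(
    segment: Segment, method: str, side: int, tfr_config: dict | None = None
) -> RenderedImage:
    """Transform one segment and rasterise it, tagging full provenance."""
    image = render(_transform(segment, method, tfr_config), side=side)
    image.source = {
        "subject_id": segment.subject_id,
        "channel": segment.channel_name,
        "method": method,
        "condition": segment.condition,
        "label": segment.label,
    }
    return image


def segments_to_arrays(
    segments: list[Segment], method: str, side: int, tfr_config: dict | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-memory dataset: (images (n, side, side, 3) uint8, labels, subjects)."""
    if not segments:
        raise ValueError("no segments given")
    images = np.empty((len(segments), side, side, 3), dtype=np.uint8)
    labels, subjects = [], []
    for i, seg in enumerate(segments):
        images[i] = render_segment(seg, method, side, tfr_config).pixels
        labels.append(seg.label)
        subjects.append(seg.subject_id)
    return images, np.array(labels), np.array(subjects)


def build_image_dataset(
    segments: list[Segment],
    method: str,
    side: int,
    tfr_config: dict | None,
    out_dir: str,
) -> DatasetManifest:
    """Write one PNG per segment plus a manifest indexing them."""
    if not segments:
        raise ValueError("no segments given")
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for seg in segments:
        try:
            image = render_segment(seg, method, side, tfr_config)
        except Exception as exc:
            raise RuntimeError(
                f"rendering failed for subject={seg.subject_id} "
                f"channel={seg.channel_name} method={method}: {exc}"
            ) from exc
        fname = f"{seg.subject_id}_{seg.channel_name}_{method}_{seg.condition}.png"
        Image.fromarray(image.pixels, mode="RGB").save(os.path.join(out_dir, fname))
        rows.append(
            {
                "path": fname,
                "subject_id": seg.subject_id,
                "label": seg.label,
                "condition": seg.condition,
                "channel": seg.channel_name,
                "method": method,
            }
        )
    manifest = DatasetManifest(entries=pd.DataFrame(rows), root=out_dir)
    return manifest
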