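"""Frame ingestion, CIELAB conversion, and the quantized 24-bin Lab colour descriptor.

A capsule-endoscopy recording arrives as an ordered sequence of RGB frames
(~2 frames/s).  Each frame is described by a compact colour histogram in the
CIELAB space, where Euclidean differences track perceived colour differences
far better than in RGB: 16 uniform bins over L in [0, 100] and 4 bins over
each of a and b in [-128, 127], each channel max-normalized and concatenated
into a 24-element descriptor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as _skcolor

__all__ = [
    "FrameSequence",
    "LabFrame",
    "ColorHistogram",
    "load_frames",
    "rgb_to_lab",
    "lab_histogram",
    "histograms_to_frame",
    "L_RANGE",
    "AB_RANGE",
    "L_BINS",
    "AB_BINS",
]

# Canonical channel ranges and quantization (full-gamut, uniform edges).
L_RANGE = (0.0, 100.0)
AB_RANGE = (-128.0, 127.0)
L_BINS = 16
AB_BINS = 4


@dataclass
class FrameSequence:
    """Ordered RGB frames with indices and a frame rate.

    Invariants: all frames share one (H, W, 3) uint8 shape, indices are
    strictly increasing, fps > 0.
    """

    frames: list[np.ndarray]
    indices: list[int] = field(default=None)  # type: ignore[assignment]
    fps: float = 2.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("no frames")
        if self.indices is None:
            self.indices = list(range(len(self.frames)))
        if len(self.indices) != len(self.frames):
            raise ValueError("indices and frames length mismatch")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("indices must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        shape0 = self.frames[0].shape
        if len(shape0) != 3 or shape0[2] != 3:
            raise ValueError("not RGB")
        if any(f.shape != shape0 for f in self.frames):
            raise ValueError("inconsistent frame size")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of every frame."""
        return self.frames[0].shape[:2]


@dataclass
class LabFrame:
    """One frame in CIELAB; L in [0, 100], a and b in [-128, 127] after clipping."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def channel(self, c: int) -> np.ndarray:
        """Channel by 1-based index (1 = L, 2 = a, 3 = b)."""
        return (self.L, self.a, self.b)[c - 1]


@dataclass
class ColorHistogram:
    """24-element fused Lab descriptor: 16 L-bins then 4 a-bins then 4 b-bins.

    Each channel block is max-normalized (its maximum equals 1 unless the
    channel histogram is all-zero), so the descriptor is *not* a probability
    vector; the divergence in :mod:`wcesum.redundancy` is applied to it as is.
    """

    values: np.ndarray
    bin_edges: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (L_BINS + 2 * AB_BINS,):
            raise ValueError("descriptor must have exactly 24 entries")


def _natural_key(name: str) -> list:
    """Sort key treating digit runs as integers, so f2 < f10."""
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def load_frames(path: str | Path, pattern: str = "*.png", fps: float = 2.0) -> FrameSequence:
    """Load an image sequence from a directory, ordered by natural filename sort.

    Parameters
    ----------
    path : directory containing the frames.
    pattern : glob pattern selecting the image files (PNG/JPEG).
    fps : frame rate to attach to the sequence (capsule default 2.0).
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such directory: {path}")
    files = sorted(path.glob(pattern), key=lambda p: _natural_key(p.name))
    if not files:
        raise ValueError("no frames")
    frames = []
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[-1] == 4:  # drop alpha
            img = img[..., :3]
        frames.append(img.astype(np.uint8))
    shape0 = frames[0].shape
    if any(f.shape != shape0 for f in frames):
        raise ValueError("inconsistent frame size")
    return FrameSequence(frames=frames, indices=list(range(len(frames))), fps=fps)


def rgb_to_lab(frame: np.ndarray) -> LabFrame:
    """Convert an 8-bit sRGB frame (D65 white point) to CIELAB.

    L is clipped to [0, 100] and a, b to [-128, 127].
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("not RGB")
    lab = _skcolor.rgb2lab(frame.astype(np.float64) / 255.0)
    L = np.clip(lab[..., 0], *L_RANGE)
    a = np.clip(lab[..., 1], *AB_RANGE)
    b = np.clip(lab[..., 2], *AB_RANGE)
    return LabFrame(L=L, a=a, b=b)


def _channel_hist(values: np.ndarray, n_bins: int, vrange: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    counts, edges = np.histogram(values.ravel(), bins=n_bins, range=vrange)
    counts = counts.astype(float)
    m = counts.max()
    if m > 0:
        counts /= m
    return counts, edges


def lab_histogram(lab: LabFrame) -> ColorHistogram:
    """Quantized Lab histogram descriptor: 16 + 4 + 4 = 24 entries.

    Per-channel counts are divided by that channel's maximum count before the
    three blocks are concatenated; an all-zero channel (possible only for
    masked inputs) is left as zeros.
    """
    hl, el = _channel_hist(lab.L, L_BINS, L_RANGE)
    ha, ea = _channel_hist(lab.a, AB_BINS, AB_RANGE)
    hb, eb = _channel_hist(lab.b, AB_BINS, AB_RANGE)
    return ColorHistogram(
        values=np.concatenate([hl, ha, hb]),
        bin_edges={"L": el, "a": ea, "b": eb},
    )


def histograms_to_frame(seq: FrameSequence) -> pd.DataFrame:
    """Descriptors for every frame as a DataFrame (index column + 24 bins)."""
    rows = [lab_histogram(rgb_to_lab(f)).values for f in seq.frames]
    cols = [f"L{i}" for i in range(L_BINS)] + [f"a{i}" for i in range(AB_BINS)] + [f"b{i}" for i in range(AB_BINS)]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "index", seq.indices)
    return df
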