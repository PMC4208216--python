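"""Seeded generator of synthetic capsule-like frame sequences with ground truth.

The generator emulates the statistical contrasts a capsule summarizer
exploits, not photo-realism:

* informative scenes: high-gradient mucosa-like texture (band-limited noise
  plus darker vessel-like curves) in a warm red/pink palette, each scene on a
  distinct lightness rung so neighbouring scenes are moderately, and
  comparably, separated in colour-histogram terms;
* redundant runs: each scene (and each non-informative episode) is repeated
  as near-duplicate copies under a smooth directional translation walk and a
  monotone brightness drift plus pixel noise — the slow sliding of a capsule
  resting against the mucosa;
* non-informative episodes: bubble fields (overlapping discs with bright
  rims and flat interiors), turbid low-contrast washes (yellow-green, heavily
  blurred) and defocused frames (strong Gaussian blur of a mucosa texture).

All randomness flows from one seeded generator; a fixed seed reproduces the
output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ensemble import LabeledDataset
from .frames import FrameSequence

__all__ = ["SyntheticSpec", "FrameTruth", "generate_sequence", "generate_feature_dataset"]

# Successive scene/episode appearances alternate between two lightness rungs
# (8-bit), so every pair of neighbouring appearances — scene to scene, scene
# to episode, episode to scene — is separated by one rung: a moderate,
# consistent colour-histogram divergence (chosen once for the default
# palette).  Per-kind offsets compensate for each construct's own effective
# lightness and hue so all adjacent divergences land in a comparable band.
_L_LOW = 112.0
_L_HIGH = 152.0

_NONINF_KINDS = ("bubbles", "turbid", "defocus")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic capsule sequence."""

    n_scenes: int = 5
    copies_per_scene: int = 10
    jitter_px: int = 2
    brightness_drift: float = 0.12
    noninformative_fraction: float = 0.3
    noninformative_kinds: tuple[str, ...] = _NONINF_KINDS
    frame_size: tuple[int, int] = (256, 256)
    fps: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noninformative_fraction < 1.0):
            raise ValueError("noninformative_fraction must lie in [0, 1)")
        if min(self.frame_size) < 32:
            raise ValueError("frame size must be at least 32")
        if self.n_scenes < 1 or self.copies_per_scene < 1:
            raise ValueError("need at least one scene and one copy")
        if any(k not in _NONINF_KINDS for k in self.noninformative_kinds):
            raise ValueError("unknown non-informative kind")


@dataclass
class FrameTruth:
    """Ground-truth labels for one generated frame."""

    index: int
    scene_id: int  # >= 0 for informative scenes, negative for episodes
    is_informative: bool
    is_redundant_copy: bool


def _band_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Band-limited noise field in [-1, 1] (smoothed white noise, max-normalized)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    m = np.abs(f).max()
    return f / m if m > 0 else f


def _vessel_mask(rng: np.random.Generator, shape, n_vessels: int = 6) -> np.ndarray:
    """Soft mask of vessel-like random-walk curves."""
    h, w = shape
    mask = np.zeros(shape)
    for _ in range(n_vessels):
        y, x = rng.uniform(0, h), rng.uniform(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(int(1.5 * max(h, w))):
            ang += rng.normal(0, 0.3)
            y = (y + np.sin(ang)) % h
            x = (x + np.cos(ang)) % w
            mask[int(y), int(x)] = 1.0
    return np.clip(ndimage.gaussian_filter(mask, 1.0) * 3.0, 0.0, 1.0)


def _mucosa_scene(rng: np.random.Generator, shape, level: float) -> np.ndarray:
    """Informative base frame: textured warm mucosa at the given lightness level."""
    tex = _band_noise(rng, shape, sigma=1.5) * 0.5 + _band_noise(rng, shape, sigma=6.0) * 0.5
    vessels = _vessel_mask(rng, shape)
    lum = level * (1.0 + 0.35 * tex) * (1.0 - 0.35 * vessels)
    # warm palette: strong red, weaker green/blue modulated by the texture
    r = lum * 1.15
    g = lum * (0.55 + 0.10 * tex)
    b = lum * (0.50 + 0.05 * tex)
    return np.clip(np.stack([r, g, b], axis=-1), 0, 255).astype(np.uint8)


def _bubble_frame(rng: np.random.Generator, shape, level: float) -> np.ndarray:
    """Bubble field: flat wash with overlapping discs, bright rims, flat interiors."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # gentle large-scale variation keeps the wash from being perfectly flat
    lum = level * (0.9 + 0.08 * _band_noise(rng, shape, sigma=24.0))
    for _ in range(rng.integers(12, 20)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rad = rng.uniform(8, 32)
        dist = np.hypot(yy - cy, xx - cx)
        interior = dist < rad - 2
        rim = (dist >= rad - 2) & (dist < rad + 1)
        lum[interior] = level * rng.uniform(0.75, 0.95)
        lum[rim] = np.minimum(level * 1.45, 250)
    lum = ndimage.gaussian_filter(lum, 1.0)
    r, g, b = lum * 1.05, lum * 0.72, lum * 0.62
    return np.clip(np.stack([r, g, b], axis=-1), 0, 255).astype(np.uint8)


def _turbid_frame(rng: np.random.Generator, shape, level: float) -> np.ndarray:
    """Turbid wash: low-frequency yellow-green field under strong blur."""
    field_ = _band_noise(rng, shape, sigma=18.0)
    lum = level * (1.0 + 0.18 * field_)
    r = lum * 1.05
    g = lum * 0.65
    b = lum * 0.50
    rgb = np.stack([r, g, b], axis=-1)
    rgb = ndimage.gaussian_filter(rgb, (4.0, 4.0, 0))
    return np.clip(rgb, 0, 255).astype(np.uint8)


def _defocus_frame(rng: np.random.Generator, shape, level: float) -> np.ndarray:
    """Heavy defocus: Gaussian blur (sigma >= 6) of a fresh mucosa texture."""
    sharp = _mucosa_scene(rng, shape, level).astype(float)
    blurred = ndimage.gaussian_filter(sharp, (6.5, 6.5, 0))
    return np.clip(blurred, 0, 255).astype(np.uint8)


def _jittered_copies(
    rng: np.random.Generator,
    base: np.ndarray,
    n: int,
    jitter_px: int,
    drift: float,
    direction: float | None = None,
) -> list[np.ndarray]:
    """Near-duplicate copies of one base frame.

    The capsule slides slowly and steadily while resting against the mucosa,
    so the copies follow a constant-velocity sub-pixel translation (bilinear,
    wrap-around — the colour statistics of the base stay intact) and a slow
    illumination swing that rises for the first half of the dwell and falls
    back over the second (peak amplitude ``drift``), plus mild sensor noise.
    Drift and translation dominate the noise, so consecutive inter-frame
    change maps share their sign structure, as near-duplicate capsule frames
    do.  ``direction`` sets the initial swing direction (the camera's gain
    keeps adapting in the direction of the preceding scene change before
    correcting back); when None it is drawn at random."""
    ang = rng.uniform(0, 2 * np.pi)
    step = rng.uniform(0.4, 1.0) * jitter_px / max(1, n - 1) if n > 1 else 0.0
    if direction is None:
        direction = float(rng.choice([-1.0, 1.0]))
    half = max(1, n // 2)
    per_step = drift / half
    frames = []
    gain = 1.0
    for k in range(n):
        if k > 0:
            gain += direction * per_step * (1.0 if k <= half else -1.0)
        if k == 0:
            shifted = base.astype(float)
        else:
            shifted = ndimage.shift(
                base.astype(float),
                (k * step * np.sin(ang), k * step * np.cos(ang), 0.0),
                order=1,
                mode="grid-wrap",
            )
        noisy = shifted * gain + rng.normal(0.0, 0.4, base.shape)
        frames.append(np.clip(noisy, 0, 255).astype(np.uint8))
    return frames


def generate_sequence(spec: SyntheticSpec) -> tuple[FrameSequence, list[FrameTruth]]:
    """Generate a capsule-like sequence and its per-frame ground truth.

    Scene blocks of ``copies_per_scene`` near-duplicates are interleaved with
    non-informative episodes (short near-duplicate runs of bubble, turbid or
    defocus frames) sized so that roughly ``noninformative_fraction`` of all
    frames are non-informative.  Episode frames carry negative scene ids; the
    first frame of every block/episode is the non-redundant representative.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.frame_size

    n_inf = spec.n_scenes * spec.copies_per_scene
    f = spec.noninformative_fraction
    n_noninf = int(round(f / (1.0 - f) * n_inf)) if f > 0 else 0

    # Episodes sit in the gaps after each scene block; spread the frames into
    # near-equal runs over the first gaps.
    n_gaps = spec.n_scenes if n_noninf else 0
    run_lengths = [len(c) for c in np.array_split(np.arange(n_noninf), n_gaps)] if n_gaps else []

    frames: list[np.ndarray] = []
    truth: list[FrameTruth] = []
    appearance = 0
    episode_id = 0

    def next_level() -> float:
        nonlocal appearance
        level = _L_LOW if appearance % 2 == 0 else _L_HIGH
        appearance += 1
        return float(level)

    def emit(block: list[np.ndarray], scene_id: int, informative: bool) -> None:
        for k, fr in enumerate(block):
            truth.append(
                FrameTruth(
                    index=len(frames),
                    scene_id=scene_id,
                    is_informative=informative,
                    is_redundant_copy=k > 0,
                )
            )
            frames.append(fr)

    prev_level: float | None = None

    def swing_direction(level: float) -> float | None:
        # camera gain keeps adapting in the direction of the scene change
        return None if prev_level is None else (1.0 if level > prev_level else -1.0)

    for s in range(spec.n_scenes):
        level = next_level()
        base = _mucosa_scene(rng, shape, level)
        emit(
            _jittered_copies(
                rng, base, spec.copies_per_scene, spec.jitter_px, spec.brightness_drift,
                direction=swing_direction(level),
            ),
            scene_id=s,
            informative=True,
        )
        prev_level = level
        if s < len(run_lengths) and run_lengths[s] > 0:
            kind = spec.noninformative_kinds[episode_id % len(spec.noninformative_kinds)]
            level = next_level()
            if kind == "bubbles":
                base_n = _bubble_frame(rng, shape, level)
            elif kind == "turbid":
                base_n = _turbid_frame(rng, shape, level)
            else:
                base_n = _defocus_frame(rng, shape, level)
            episode_id += 1
            emit(
                _jittered_copies(
                    rng, base_n, run_lengths[s], spec.jitter_px, spec.brightness_drift,
                    direction=swing_direction(level),
                ),
                scene_id=-episode_id,
                informative=False,
            )
            prev_level = level

    seq = FrameSequence(frames=frames, indices=list(range(len(frames))), fps=spec.fps)
    return seq, truth


def generate_feature_dataset(
    n_per_class: int, separation: float = 6.0, dim: int = 8, seed: int = 0
) -> LabeledDataset:
    """Two balanced multivariate Gaussian blobs at the given mean separation.

    Class means are ``separation`` common standard deviations apart along the
    first axis; labels are 1/0 and the draw is deterministic per seed.
    """
    if n_per_class < 2 or dim < 1:
        raise ValueError("need n_per_class >= 2 and dim >= 1")
    rng = np.random.default_rng(seed)
    offset = np.zeros(dim)
    offset[0] = separation
    x0 = rng.standard_normal((n_per_class, dim))
    x1 = rng.standard_normal((n_per_class, dim)) + offset
    X = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)])
    return LabeledDataset(features=X, labels=y)
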