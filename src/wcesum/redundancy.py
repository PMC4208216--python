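"""Inter-frame dissimilarity and resource-adaptive redundant-frame elimination.

Two complementary dissimilarity cues are fused per frame transition:

* the Jeffrey divergence D_J between the 24-bin Lab descriptors of the two
  frames — an entropy-based, symmetric histogram distance that is stable
  under noise and bin-size choices; and
* the Boolean-series correlation BC of per-channel intensity-change sign
  maps of consecutive transitions — a cheap structural change detector.
  BC is a similarity in [0, 3] (3 = identical change maps).

Each cue is smoothed over the previous ``q`` transitions by a 1/(lag+1)
weighted sum, and the fused distance d is compared against a resource-adaptive
threshold tau = exp(-(BW^2 + B^2)) * U: a transition with d <= tau marks the
incoming frame as redundant.  High bandwidth/battery lower tau so only nearly
identical frames are discarded; scarce resources raise it toward U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import ColorHistogram, FrameSequence, LabFrame, lab_histogram, rgb_to_lab

__all__ = [
    "BooleanSeries",
    "DissimilarityTrace",
    "ResourceContext",
    "SummarySelection",
    "jeffrey_divergence",
    "boolean_series",
    "boolean_correlation",
    "accumulate",
    "fuse",
    "adaptive_threshold",
    "remove_redundant",
]

BC_MAX = 3.0  # three Lab channels, each contributing at most 1


@dataclass
class BooleanSeries:
    """Per-channel binary change maps of one frame transition.

    ``bits[c]`` is 1 where the incoming frame is >= the reference frame in
    channel c (ties count as "no decrease"), 0 elsewhere.
    """

    bits: np.ndarray  # shape (3, H, W), dtype bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape[1:]


@dataclass
class ResourceContext:
    """Normalized smartphone resources: bandwidth BW, battery B, user preference U.

    All three lie in (0, 1]; 1 means the resource is at its maximum (e.g. a
    full battery) and U scales the threshold directly.
    """

    bw: float
    battery: float
    preference: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("bw", self.bw), ("battery", self.battery), ("preference", self.preference)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"resource out of range: {name}={v!r} not in (0, 1]")


@dataclass
class DissimilarityTrace:
    """Per-transition audit record of the redundancy stage.

    One row per transition t -> t+1: raw D_J and BC, accumulated delta and
    rho, and the fused distance d.  In coherent fusion mode ``rho`` is the
    accumulated Boolean *dissimilarity* stream (1 - BC/3); in literal mode it
    is the accumulated BC itself.
    """

    transitions: list[int] = field(default_factory=list)
    dj: list[float] = field(default_factory=list)
    bc: list[float] = field(default_factory=list)
    delta: list[float] = field(default_factory=list)
    rho: list[float] = field(default_factory=list)
    d: list[float] = field(default_factory=list)
    q: int = 4
    tau: float = 0.5
    mode: str = "coherent"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.transitions,
                "dj": self.dj,
                "bc": self.bc,
                "delta": self.delta,
                "rho": self.rho,
                "d": self.d,
            }
        )


@dataclass
class SummarySelection:
    """Outcome of redundancy elimination: kept/dropped indices and kept segments."""

    kept_indices: list[int]
    dropped_indices: list[int]
    segments: list[tuple[int, int]]  # inclusive (start, end) runs of kept frames

    def __post_init__(self) -> None:
        if set(self.kept_indices) & set(self.dropped_indices):
            raise ValueError("kept and dropped overlap")


def jeffrey_divergence(h1, h2) -> float:
    """Jeffrey divergence between two non-negative histograms (natural log).

    D_J = sum_i h1_i log[2 h1_i / (h1_i + h2_i)] + h2_i log[2 h2_i / (h1_i + h2_i)],
    with the 0 * log 0 = 0 convention.  Symmetric, non-negative, and zero iff
    the histograms are equal.
    """
    v1 = h1.values if isinstance(h1, ColorHistogram) else np.asarray(h1, dtype=float)
    v2 = h2.values if isinstance(h2, ColorHistogram) else np.asarray(h2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("incompatible histograms")
    if (v1 < 0).any() or (v2 < 0).any():
        raise ValueError("invalid histogram")
    s = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(v1 > 0, v1 * np.log(np.where(v1 > 0, 2 * v1 / np.where(s > 0, s, 1.0), 1.0)), 0.0)
        t2 = np.where(v2 > 0, v2 * np.log(np.where(v2 > 0, 2 * v2 / np.where(s > 0, s, 1.0), 1.0)), 0.0)
    return float(np.sum(t1 + t2))


def boolean_series(curr: LabFrame, prev: LabFrame) -> BooleanSeries:
    """Binary change maps of a transition: 1 where curr >= prev, per Lab channel."""
    if curr.shape != prev.shape:
        raise ValueError("shape mismatch")
    bits = np.stack([curr.channel(c) >= prev.channel(c) for c in (1, 2, 3)])
    return BooleanSeries(bits=bits)


def boolean_correlation(bs1: BooleanSeries, bs2: BooleanSeries) -> float:
    """Boolean correlation BC in [0, 3]: 3 - summed XOR fraction per channel."""
    if bs1.bits.shape != bs2.bits.shape:
        raise ValueError("shape mismatch")
    mn = bs1.bits.shape[1] * bs1.bits.shape[2]
    xor_frac = np.logical_xor(bs1.bits, bs2.bits).reshape(3, -1).sum(axis=1) / mn
    return float(np.sum(1.0 - xor_frac))


def accumulate(values, q: int) -> float:
    """Weighted history sum of a dissimilarity stream, evaluated at its last entry.

    With full history (at least q lagged values available) this is
    (1/q) * sum_{i=0..q} values[-1-i] / (i+1).  During warm-up at the start of
    a stream, the sum runs over the available lags and is divided by
    max(1, number of available lagged terms), so a lone first value passes
    through unchanged.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    vals = list(values)
    if not vals:
        raise ValueError("empty stream")
    p = len(vals) - 1
    n_lags = min(p, q)
    total = sum(vals[p - i] / (i + 1) for i in range(n_lags + 1))
    return total / max(1, n_lags)


def fuse(delta: float, rho: float, mode: str = "coherent") -> float:
    """Fuse the accumulated divergence delta with the accumulated BC rho.

    coherent (default): d = delta + (1 - rho/3) — the similarity-valued BC is
    converted into a dissimilarity so identical frames fuse to zero distance.
    literal: d = delta + rho, the linear combination exactly as printed.
    """
    if mode == "coherent":
        return float(delta + (1.0 - rho / BC_MAX))
    if mode == "literal":
        return float(delta + rho)
    raise ValueError(f"unknown fusion mode: {mode!r}")


def adaptive_threshold(ctx: ResourceContext) -> float:
    """Resource-adaptive redundancy threshold tau = exp(-(BW^2 + B^2)) * U.

    Monotonically decreasing in bandwidth and battery, linear in the user
    preference; tends to 1 as resources vanish with U = 1.
    """
    return math.exp(-(ctx.bw**2 + ctx.battery**2)) * ctx.preference


def remove_redundant(
    seq: FrameSequence,
    ctx: ResourceContext | None = None,
    q: int = 4,
    anchor: str = "consecutive",
    mode: str = "coherent",
    tau: float | None = None,
) -> tuple[SummarySelection, DissimilarityTrace]:
    """Drop redundant frames: frame t+1 is kept iff the fused distance d > tau.

    Parameters
    ----------
    seq : the frame sequence.
    ctx : resource context from which tau is derived (ignored if ``tau`` given).
    q : history length of the weighted accumulation (default 4, ~2 s at 2 fps).
    anchor : ``"consecutive"`` compares each frame with its predecessor;
        ``"last_kept"`` compares with the most recently kept frame, catching
        slow drift.
    mode : fusion polarity, ``"coherent"`` or ``"literal"``.
    tau : explicit threshold override in (0, 1].

    Notes
    -----
    In coherent mode the Boolean correlation of each transition is converted
    to a dissimilarity (1 - BC/3) *before* accumulation so that a run of
    identical frames has d = 0 at every history depth; ties d == tau count as
    redundant.  The first frame is always kept.  The first transition has no
    preceding change map, so its BC is defined as 3 (the structural term is
    uninformative there and the divergence term decides alone).
    """
    if anchor not in ("consecutive", "last_kept"):
        raise ValueError(f"unknown anchor: {anchor!r}")
    if tau is None:
        if ctx is None:
            raise ValueError("either ctx or tau is required")
        tau = adaptive_threshold(ctx)
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")

    labs = [rgb_to_lab(f) for f in seq.frames]
    hists = [lab_histogram(lab) for lab in labs]

    trace = DissimilarityTrace(q=q, tau=tau, mode=mode)
    kept = [seq.indices[0]]
    dropped: list[int] = []
    dj_stream: list[float] = []
    bc_stream: list[float] = []  # converted stream in coherent mode
    prev_series: BooleanSeries | None = None
    anchor_pos = 0  # position of the comparison reference

    for pos in range(1, len(seq)):
        ref = anchor_pos if anchor == "last_kept" else pos - 1
        dj = jeffrey_divergence(hists[ref], hists[pos])
        series = boolean_series(labs[pos], labs[ref])
        bc = BC_MAX if prev_series is None else boolean_correlation(series, prev_series)
        prev_series = series

        dj_stream.append(dj)
        bc_stream.append(1.0 - bc / BC_MAX if mode == "coherent" else bc)
        delta = accumulate(dj_stream, q)
        rho = accumulate(bc_stream, q)
        d = delta + rho  # bc_stream already carries the mode's polarity

        idx = seq.indices[pos]
        trace.transitions.append(idx)
        trace.dj.append(dj)
        trace.bc.append(bc)
        trace.delta.append(delta)
        trace.rho.append(rho)
        trace.d.append(d)

        if d > tau:
            kept.append(idx)
            anchor_pos = pos
        else:
            dropped.append(idx)

    segments = _runs(kept, set(seq.indices))
    return SummarySelection(kept_indices=kept, dropped_indices=dropped, segments=segments), trace


def _runs(kept: list[int], all_indices: set[int]) -> list[tuple[int, int]]:
    """Maximal contiguous runs of kept frames (with respect to sequence indices)."""
    kept_set = set(kept)
    ordered = sorted(all_indices)
    segments = []
    start = None
    for i, idx in enumerate(ordered):
        in_run = idx in kept_set
        if in_run and start is None:
            start = idx
        if start is not None and (not in_run):
            segments.append((start, ordered[i - 1]))
            start = None
    if start is not None:
        segments.append((start, ordered[-1]))
    return segments
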