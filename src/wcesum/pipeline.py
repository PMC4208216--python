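"""End-to-end orchestration: redundancy removal, then informative-frame classification.

Stage 1 drops redundant frames with the fused-dissimilarity threshold rule;
stage 2 extracts multi-fractal features from the survivors and drops the
frames the ensemble labels non-informative.  The final keyframe set is
therefore a subset of the stage-1 survivors, which is a subset of the input.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .ensemble import TrainedEnsemble, classify_batch
from .frames import FrameSequence
from .multifractal import MultifractalParams, extract_features
from .redundancy import DissimilarityTrace, ResourceContext, remove_redundant

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline defaults in one serializable record (embedded in every report)."""

    q: int = 4
    fusion_mode: str = "coherent"
    anchor: str = "consecutive"
    bw: float = 0.3
    battery: float = 0.45
    preference: float = 0.9
    tau_override: float | None = None
    sigma_gauss: float = 1.0
    radii: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_bins: int = 8
    box_sizes: tuple[int, ...] = (2, 4, 8, 16, 32)
    alpha_range: tuple[float, float] = (0.5, 3.5)
    kfold: int = 5
    kernel: str = "rbf"
    agg_rule: str = "median"
    seed: int = 0
    match_window: int = 0
    version: str = __version__

    def resource_context(self) -> ResourceContext:
        return ResourceContext(bw=self.bw, battery=self.battery, preference=self.preference)

    def multifractal_params(self) -> MultifractalParams:
        return MultifractalParams(
            sigma_gauss=self.sigma_gauss,
            radii=tuple(self.radii),
            n_bins=self.n_bins,
            box_sizes=tuple(self.box_sizes),
            alpha_range=tuple(self.alpha_range),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        for key in ("radii", "box_sizes", "alpha_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineReport:
    """Per-frame fates and traces for one run."""

    kept_indices: list[int]
    redundant_indices: list[int]
    noninformative_indices: list[int]
    tau: float
    trace: DissimilarityTrace
    probabilities: dict = field(default_factory=dict)
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def frame_fates(self) -> dict[int, str]:
        fates = {i: "kept" for i in self.kept_indices}
        fates.update({i: "redundant" for i in self.redundant_indices})
        fates.update({i: "non-informative" for i in self.noninformative_indices})
        return fates

    def to_dict(self) -> dict:
        return {
            "kept_indices": list(map(int, self.kept_indices)),
            "redundant_indices": list(map(int, self.redundant_indices)),
            "noninformative_indices": list(map(int, self.noninformative_indices)),
            "tau": self.tau,
            "trace": self.trace.to_frame().to_dict(orient="records"),
            "probabilities": {int(k): float(v) for k, v in self.probabilities.items()},
            "config": dataclasses.asdict(self.config),
        }


def run_pipeline(
    seq: FrameSequence,
    config: PipelineConfig | None = None,
    model: TrainedEnsemble | None = None,
    skip_classify: bool = False,
) -> PipelineReport:
    """Run both summarization stages and report every frame's fate.

    ``model`` is required unless ``skip_classify``; with ``skip_classify`` the
    result equals the redundancy-stage output.
    """
    config = config or PipelineConfig()
    if model is None and not skip_classify:
        raise ValueError("a trained ensemble is required unless skip_classify=True")

    selection, trace = remove_redundant(
        seq,
        ctx=None if config.tau_override is not None else config.resource_context(),
        q=config.q,
        anchor=config.anchor,
        mode=config.fusion_mode,
        tau=config.tau_override,
    )

    if skip_classify:
        return PipelineReport(
            kept_indices=selection.kept_indices,
            redundant_indices=selection.dropped_indices,
            noninformative_indices=[],
            tau=trace.tau,
            trace=trace,
            config=config,
        )

    pos_by_index = {idx: i for i, idx in enumerate(seq.indices)}
    params = config.multifractal_params()
    feats = np.stack(
        [extract_features(seq.frames[pos_by_index[idx]], params).e_alpha for idx in selection.kept_indices]
    )
    labels, probs = classify_batch(model, feats)

    kept, noninf = [], []
    for idx, lab in zip(selection.kept_indices, labels):
        (kept if lab == 1 else noninf).append(idx)
    return PipelineReport(
        kept_indices=kept,
        redundant_indices=selection.dropped_indices,
        noninformative_indices=noninf,
        tau=trace.tau,
        trace=trace,
        probabilities=dict(zip(selection.kept_indices, probs)),
        config=config,
    )
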