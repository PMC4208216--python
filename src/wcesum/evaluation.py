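"""Summary-quality metrics against ground-truth keyframes.

A generated summary is compared with human-selected keyframes by greedy
nearest matching within a frame window: matched pairs are true positives,
unmatched selections false positives, unmatched truth frames false negatives.
Recall, precision and their harmonic mean (F-measure) follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["EvalReport", "match_keyframes", "prf", "f_measure_from_rp", "evaluate", "evaluate_table"]


def f_measure_from_rp(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both vanish."""
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


@dataclass
class EvalReport:
    """Counts and derived metrics for one video."""

    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f_measure: float
    match_window: int = 0

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "recall": self.recall,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "match_window": self.match_window,
        }


def match_keyframes(selected, truth, window: int = 0) -> tuple[int, int, int]:
    """Greedy nearest matching of selected frames to truth frames.

    Each truth index is matched at most once and a match requires
    |selected - truth| <= window.  Returns (TP, FP, FN).  With window 0 this
    reduces to exact set-intersection counting.
    """
    if window < 0:
        raise ValueError("negative window")
    sel = sorted(set(selected))
    available = sorted(set(truth))
    tp = 0
    for s in sel:
        best, best_dist = None, None
        for t in available:
            dist = abs(s - t)
            if dist <= window and (best_dist is None or dist < best_dist):
                best, best_dist = t, dist
        if best is not None:
            available.remove(best)
            tp += 1
    fp = len(sel) - tp
    fn = len(available)
    return tp, fp, fn


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Recall, precision and F-measure from the match counts.

    R = TP/(TP+FN), P = TP/(TP+FP), F = 2RP/(R+P); a metric with an empty
    denominator is defined as 0 (with a warning) so empty summaries do not
    crash evaluation.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        warnings.warn("no truth keyframes: recall defined as 0", stacklevel=2)
        recall = 0.0
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn("empty summary: precision defined as 0", stacklevel=2)
        precision = 0.0
    if recall + precision > 0:
        f = 2 * recall * precision / (recall + precision)
    else:
        f = 0.0
    return recall, precision, f


def evaluate(selected, truth, window: int = 0) -> EvalReport:
    """Full report for one summary against one ground-truth keyframe list."""
    tp, fp, fn = match_keyframes(selected, truth, window)
    r, p, f = prf(tp, fp, fn)
    return EvalReport(tp=tp, fp=fp, fn=fn, recall=r, precision=p, f_measure=f, match_window=window)


def evaluate_table(per_video_reports) -> dict:
    """Arithmetic mean of recall/precision/F across a list of per-video reports.

    Accepts :class:`EvalReport` objects or (R, P, F) triples.
    """
    reports = list(per_video_reports)
    if not reports:
        raise ValueError("empty report list")
    triples = [
        (r.recall, r.precision, r.f_measure) if isinstance(r, EvalReport) else tuple(r)
        for r in reports
    ]
    n = len(triples)
    return {
        "recall": sum(t[0] for t in triples) / n,
        "precision": sum(t[1] for t in triples) / n,
        "f_measure": sum(t[2] for t in triples) / n,
        "n_videos": n,
    }
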