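"""Scan-level reactivation/suppression scores and template pattern similarity.

Two read-outs are computed from the resting scans:

* the decoder's *probability of classification* — the trained decoder is
  applied to every 6-volume window and the window probabilities for the
  orientation of interest are averaged within the scan (above 0.5 toward
  a recently seen orientation = reactivation; below 0.5 = suppression);
* *pattern similarity* — each window's multivoxel pattern is correlated
  (Pearson) with the per-orientation template built from the decoder-scan
  samples, and the correlations are averaged within the scan.

The two pre-exposure scans are combined into a single "pre" score by
averaging their scan scores with equal weight; the two post-exposure
scans (post1, post2) are analyzed separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decoder import ARDLogisticModel, predict_proba, prob_of
from .preprocess import SampleMatrix

__all__ = [
    "ScanDecodingResult",
    "TemplatePattern",
    "SimilarityResult",
    "scan_probability",
    "combine_scan_scores",
    "build_templates",
    "similarity_timecourse",
    "percent_change",
    "suppression_index",
    "reactivation_index",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanDecodingResult:
    """Decoder output for one resting scan and one target orientation."""

    scan_role: str
    roi: str
    target_label: str
    window_probabilities: np.ndarray
    n_windows: int

    @property
    def scan_probability(self) -> float:
        """Mean window probability of the target orientation."""
        return float(np.mean(self.window_probabilities))


@dataclass(frozen=True)
class TemplatePattern:
    """Per-orientation mean multivoxel patterns from the decoder scan."""

    patterns: dict
    voxel_ids: np.ndarray
    n_samples: dict


@dataclass(frozen=True)
class SimilarityResult:
    """Pearson correlations of rest windows to the orientation templates."""

    scan_role: str
    roi: str
    window_correlations: dict  # label -> (n_windows,) array, NaN = undefined
    n_windows: int

    def mean_correlation(self, label) -> float:
        """Scan-mean correlation to one template; undefined windows excluded."""
        r = self.window_correlations[label]
        valid = ~np.isnan(r)
        if not valid.any():
            return float("nan")
        return float(np.mean(r[valid]))

    def n_excluded(self, label) -> int:
        return int(np.isnan(self.window_correlations[label]).sum())


def scan_probability(
    model: ARDLogisticModel,
    rest_windows: SampleMatrix,
    target_label,
    scan_role: str = "rest",
    roi: str = "",
) -> ScanDecodingResult:
    """Decode every rest window and average toward the target orientation."""
    if rest_windows.n_samples == 0:
        raise ValueError("rest scan contains zero windows")
    probs = prob_of(model, rest_windows, target_label)
    return ScanDecodingResult(
        scan_role=scan_role,
        roi=roi,
        target_label=str(target_label),
        window_probabilities=probs,
        n_windows=rest_windows.n_samples,
    )


def combine_scan_scores(results: list[ScanDecodingResult]) -> float:
    """Equal-weight mean of scan scores (the combined "pre" score)."""
    if not results:
        raise ValueError("no scans to combine")
    return float(np.mean([r.scan_probability for r in results]))


def build_templates(samples: SampleMatrix) -> TemplatePattern:
    """Per-orientation voxel-wise mean over the decoder-scan samples."""
    if samples.labels is None:
        raise ValueError("decoder samples must be labeled")
    labels = np.unique(samples.labels)
    if labels.size < 2:
        raise ValueError("need samples from both orientations")
    patterns, counts = {}, {}
    for lab in labels:
        sel = samples.labels == lab
        patterns[lab] = samples.data[sel].mean(axis=0)
        counts[lab] = int(sel.sum())
    return TemplatePattern(
        patterns=patterns, voxel_ids=np.asarray(samples.voxel_ids), n_samples=counts
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def similarity_timecourse(
    templates: TemplatePattern,
    rest_windows: SampleMatrix,
    scan_role: str = "rest",
    roi: str = "",
) -> SimilarityResult:
    """Correlate each rest window with each orientation template.

    Zero-variance windows or templates make the correlation undefined;
    such windows are recorded as NaN, logged, and excluded from the scan
    means (never imputed).
    """
    if not np.array_equal(templates.voxel_ids, rest_windows.voxel_ids):
        raise ValueError("template and window voxel sets are not aligned")
    out = {}
    for lab, tpl in templates.patterns.items():
        r = np.array([_pearson(win, tpl) for win in rest_windows.data])
        n_bad = int(np.isnan(r).sum())
        if n_bad:
            logger.warning(
                "similarity: %d undefined window correlation(s) for %r excluded",
                n_bad,
                lab,
            )
        out[lab] = r
    return SimilarityResult(
        scan_role=scan_role,
        roi=roi,
        window_correlations=out,
        n_windows=rest_windows.n_samples,
    )


def percent_change(pre_score: float, post_score: float) -> float:
    """Signed percentage change of the classification probability, 100*(post-pre)/pre."""
    if pre_score == 0:
        raise ValueError("pre score must be nonzero")
    if pre_score < 0:
        raise ValueError("pre score must be positive")
    return 100.0 * (post_score - pre_score) / pre_score


def suppression_index(post1_result: ScanDecodingResult) -> float:
    """Awake suppression score: the post1 probability of classifying the
    resting activity as the familiar orientation (combined early visual
    cortex).  Lower values = stronger suppression; 0.5 is chance."""
    return post1_result.scan_probability


def reactivation_index(post1_result: ScanDecodingResult) -> float:
    """Awake reactivation score: the post1 probability of the novel
    orientation in V1.  Higher values = stronger reactivation."""
    return post1_result.scan_probability
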