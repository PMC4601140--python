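r"""Image-quality metrics and subjective-score statistics.

Quantitative metrics follow clinical ROI practice:

* ``SNR = 20 log10(mean / std)`` over one region,
* ``CNR = 20 log10(|mean_A - mean_B| / std_A)`` with the noise standard
  deviation taken from the background region A,
* edge preservation ``Upsilon`` — the correlation of the mean-centred
  3x3 Laplacians of the input and the reconstruction over an evaluation
  mask; 1 means perfect structural retention.

Standard deviations use the ``n - 1`` sample convention.

Subjective 1-5 ordinal scores are summarised by rank sums, medians and
the F-pseudosigma ``IQR / 1.349`` (a robust spread comparable to a
standard deviation for normal data); quartiles use the
linear-interpolation convention.  Paired comparisons between methods
use a two-tailed z-test on per-case differences.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DegenerateDataError, DomainError, UndefinedMetricError
from .image import ImageRecord, as_image

__all__ = [
    "RegionSpec",
    "ScoreTable",
    "SCORE_CRITERIA",
    "snr_db",
    "cnr_db",
    "edge_preservation",
    "rank_sum",
    "f_pseudosigma",
    "median_score",
    "paired_two_tailed_pvalue",
]

#: Criteria used in the blinded subjective reading study.
SCORE_CRITERIA = ("contrast", "sharpness", "lack of noise", "fitness for purpose")

_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class RegionSpec:
    """A labelled pixel set (boolean mask) used for ROI metrics."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DomainError(f"region {self.label!r} is empty")

    @classmethod
    def from_rect(cls, label: str, shape: tuple[int, int], row: int, col: int,
                  height: int, width: int) -> "RegionSpec":
        """Build a rectangular region from 0-based (row, col, height, width)."""
        h, w = shape
        if row < 0 or col < 0 or height < 1 or width < 1 or row + height > h or col + width > w:
            raise DomainError(f"rectangle for {label!r} exceeds image bounds {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[row:row + height, col:col + width] = True
        return cls(label, mask)

    def values(self, image: ImageRecord | np.ndarray) -> np.ndarray:
        data = as_image(image).data
        if data.shape != self.mask.shape:
            raise DomainError("region mask shape must match the image")
        return data[self.mask]


def snr_db(image, region: RegionSpec) -> float:
    """Region SNR in decibels, ``20 log10(mean / std)``."""
    vals = region.values(image)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    if sd == 0.0:
        raise UndefinedMetricError(f"region {region.label!r} has zero spread; SNR undefined")
    return float(20.0 * np.log10(np.mean(vals) / sd))


def cnr_db(image, region_a: RegionSpec, region_b: RegionSpec) -> float:
    """Contrast-to-noise ratio in dB; ``region_a`` is the background whose
    standard deviation represents the noise process."""
    va, vb = region_a.values(image), region_b.values(image)
    sd = float(np.std(va, ddof=1)) if va.size > 1 else 0.0
    if sd == 0.0:
        raise UndefinedMetricError(f"background region {region_a.label!r} has zero spread")
    diff = abs(float(np.mean(va)) - float(np.mean(vb)))
    if diff == 0.0:
        raise UndefinedMetricError("regions have equal means; CNR undefined")
    return float(20.0 * np.log10(diff / sd))


def edge_preservation(V, G_hat, mask: np.ndarray | RegionSpec | None = None) -> float:
    """Edge-preservation statistic ``Upsilon`` in ``[-1, 1]``.

    Correlation of the mean-centred discrete Laplacians of the input
    and the reconstruction, evaluated over ``mask`` (default: whole
    image).  Image borders use mirror padding.
    """
    v = as_image(V).data
    g = as_image(G_hat).data
    if v.shape != g.shape:
        raise DomainError("images must share a shape")
    if isinstance(mask, RegionSpec):
        m = mask.mask
    elif mask is None:
        m = np.ones_like(v, dtype=bool)
    else:
        m = np.asarray(mask, dtype=bool)
    if m.shape != v.shape or not m.any():
        raise DomainError("mask must be a non-empty boolean array matching the image")
    lv = ndimage.convolve(v, _LAPLACIAN, mode="mirror")[m]
    lg = ndimage.convolve(g, _LAPLACIAN, mode="mirror")[m]
    lv = lv - lv.mean()
    lg = lg - lg.mean()
    denom = np.sqrt(np.sum(lv * lv) * np.sum(lg * lg))
    if denom == 0.0:
        raise UndefinedMetricError("Laplacian is constant within the mask; EP undefined")
    return float(np.clip(np.sum(lv * lg) / denom, -1.0, 1.0))


class ScoreTable:
    """Evaluator x slice x criterion table of 1-5 ordinal scores.

    Backed by a long-format DataFrame with columns
    ``evaluator, slice, criterion, score``.
    """

    COLUMNS = ("evaluator", "slice", "criterion", "score")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise DomainError(f"score table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        scores = frame["score"]
        if not np.all(scores == scores.astype(int)) or scores.min() < 1 or scores.max() > 5:
            raise DomainError("scores must be integers on the 1-5 ordinal scale")
        frame["score"] = scores.astype(int)
        if frame.duplicated(subset=["evaluator", "slice", "criterion"]).any():
            raise DomainError("duplicate (evaluator, slice, criterion) entries")
        self.frame = frame

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls(pd.read_csv(path))

    def criterion_scores(self, criterion: str) -> np.ndarray:
        """All scores for one criterion; errors on an incomplete table."""
        sub = self.frame[self.frame["criterion"] == criterion]
        if sub.empty:
            raise DomainError(f"no scores recorded for criterion {criterion!r}")
        pivot = sub.pivot(index="evaluator", columns="slice", values="score")
        if pivot.isna().any().any():
            raise DomainError(f"incomplete score table for criterion {criterion!r}")
        return pivot.to_numpy().ravel()


def rank_sum(table: ScoreTable, criterion: str) -> int:
    """Total of all subjective scores over evaluators and slices."""
    return int(table.criterion_scores(criterion).sum())


def f_pseudosigma(scores: Iterable[float]) -> float:
    """Robust spread ``IQR / 1.349``; zero for unanimous scores."""
    s = np.asarray(list(scores), dtype=float)
    if s.size == 0:
        raise DomainError("f_pseudosigma needs at least one score")
    q1, q3 = np.percentile(s, [25.0, 75.0], method="linear")
    return float((q3 - q1) / 1.349)


def median_score(scores: Iterable[float]) -> float:
    """Median score (mean of the middle pair for even counts)."""
    s = np.asarray(list(scores), dtype=float)
    if s.size == 0:
        raise DomainError("median_score needs at least one score")
    return float(np.median(s))


def paired_two_tailed_pvalue(metric_a, metric_b) -> float:
    """Two-tailed normal p-value for paired per-case metric differences.

    Uses the z-statistic ``mean(d) / (sd(d) / sqrt(n))`` on the paired
    differences.  The 0.05 significance threshold is the caller's
    concern.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("paired metrics must be equal-length 1-D sequences")
    if a.size < 2:
        raise DomainError("need at least two paired cases")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("paired differences have zero variance; z undefined")
    z = float(np.mean(d)) / (sd / np.sqrt(d.size))
    return float(2.0 * stats.norm.sf(abs(z)))
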