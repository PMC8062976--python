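"""Evaluation metrics for predicted stool compositions.

* ``maes`` — per family, the mean absolute error between predicted and real
  abundances scaled to one (sample) standard deviation of the real data;
  values below 1 indicate the prediction beats the spread of the truth.
* per-sample Spearman rank correlation between the predicted and real
  13-feature profiles, binned into quality classes
  (excellent / good / discrete / incorrect).
* family-wise two-sided rank-sum (unpaired Wilcoxon / Mann-Whitney) tests
  between two groups of compositions, e.g. predicted ancient vs modern
  stool profiles. No multiple-testing correction is applied; reports state
  this.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import FamilyTable

logger = logging.getLogger(__name__)

QUALITY_BINS = ("excellent", "good", "discrete", "incorrect")


@dataclass
class MaesReport:
    """Per-family scaled mean absolute errors and their mean.

    Families whose real-data sd is 0 have an undefined (NaN) entry; they are
    listed in ``undefined_families`` and excluded from ``mean_maes``.
    """

    families: list[str]
    per_family_maes: np.ndarray
    reference_sds: np.ndarray
    mean_maes: float
    undefined_families: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"maes": self.per_family_maes, "reference_sd": self.reference_sds},
            index=self.families,
        )


@dataclass
class SampleQuality:
    """Spearman r between a sample's predicted and real profile, with bin."""

    sample_id: str
    r: float
    bin: str


def _check_aligned(pred: FamilyTable, truth: FamilyTable) -> None:
    if pred.sample_ids != truth.sample_ids:
        raise ValueError("prediction and truth are not aligned on sample ids")
    if pred.families != truth.families:
        raise ValueError("prediction and truth are not aligned on families")


def compute_maes(pred: FamilyTable, truth: FamilyTable) -> MaesReport:
    """Mean absolute error per family, scaled to the truth's sample sd."""
    _check_aligned(pred, truth)
    if truth.n_samples < 2:
        raise ValueError("need at least 2 samples to compute maes")
    abs_err = np.abs(pred.values - truth.values).mean(axis=0)
    sds = truth.values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        maes = np.where(sds > 0, abs_err / sds, np.nan)
    undefined = [f for f, s in zip(truth.families, sds) if s == 0]
    defined = maes[~np.isnan(maes)]
    mean_maes = float(defined.mean()) if defined.size else math.nan
    return MaesReport(list(truth.families), maes, sds, mean_maes, undefined)


def assign_quality_bin(r: float) -> str:
    """Right-closed quality bins on the unrounded correlation."""
    if math.isnan(r):
        return "incorrect"
    if r > 0.8:
        return "excellent"
    if r > 0.7:
        return "good"
    if r > 0.4:
        return "discrete"
    return "incorrect"


def spearman_per_sample(
    pred: FamilyTable, truth: FamilyTable
) -> list[SampleQuality]:
    """Spearman r (average-rank ties) per sample across the 13 features."""
    _check_aligned(pred, truth)
    out: list[SampleQuality] = []
    for i, sid in enumerate(pred.sample_ids):
        p, t = pred.values[i], truth.values[i]
        if np.ptp(p) == 0 or np.ptp(t) == 0:
            logger.warning(
                "sample %s has a constant profile; Spearman r undefined, "
                "binned as incorrect",
                sid,
            )
            out.append(SampleQuality(sid, float("nan"), "incorrect"))
            continue
        r = float(stats.spearmanr(p, t).statistic)
        out.append(SampleQuality(sid, r, assign_quality_bin(r)))
    return out


def summarize_bins(qualities: list[SampleQuality]) -> dict[str, float]:
    """Fraction of samples per quality bin; fractions sum to 1."""
    if not qualities:
        raise ValueError("no samples to summarize")
    n = len(qualities)
    return {b: sum(q.bin == b for q in qualities) / n for b in QUALITY_BINS}


def wilcoxon_family_compare(
    group_a: FamilyTable, group_b: FamilyTable
) -> pd.Series:
    """Two-sided rank-sum p-value per family between two sample groups.

    Exact for small tie-free groups, normal approximation with tie
    correction otherwise. A family constant and identical across both
    groups has p = 1. No multiple-testing correction is applied.
    """
    if group_a.families != group_b.families:
        raise ValueError("groups are not aligned on families")
    if group_a.n_samples < 2 or group_b.n_samples < 2:
        raise ValueError("each group needs at least 2 samples")
    pvals = {}
    for j, fam in enumerate(group_a.families):
        a = group_a.values[:, j]
        b = group_b.values[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[fam] = 1.0
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        pvals[fam] = float(res.pvalue)
    return pd.Series(pvals, name="p_value")
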