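"""Turn raw network outputs into valid compositions; correct recurring bias.

Two steps: (i) negative predictions are set to 0 and each sample is rescaled
to sum to 100%; (ii) families with a recurring over- or underestimation on
the training set — detected by comparing the mean signed error to a fraction
of the family's training standard deviation — receive a multiplicative
mean-matching correction, after which the composition is re-closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_tables import FamilyTable

logger = logging.getLogger(__name__)


@dataclass
class BiasCorrection:
    """Per-family multiplicative correction for systematic prediction bias.

    A family is flagged when |mean(pred - true)| on the training set exceeds
    ``flag_threshold`` times the family's training sd; flagged families get
    factor = mean(true)/mean(pred), everything else keeps factor 1.
    """

    families: list[str]
    factors: np.ndarray
    flagged: list[str]
    flag_threshold: float = 0.25

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if len(self.factors) != len(self.families):
            raise ValueError("one factor per family required")
        if np.any(self.factors <= 0):
            raise ValueError("correction factors must be positive")
        flagged_set = set(self.flagged)
        for fam, fac in zip(self.families, self.factors):
            if fam not in flagged_set and fac != 1.0:
                raise ValueError(f"non-flagged family {fam!r} has factor != 1")


def clip_and_rescale(
    raw: np.ndarray,
    families: Sequence[str],
    sample_ids: Sequence[str],
) -> FamilyTable:
    """Clip negatives to 0, rescale each row to sum to 100.

    A row with no positive entry cannot be rescaled; it falls back to the
    uniform composition with a warning rather than failing the batch.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != len(families):
        raise ValueError(
            f"raw matrix shape {raw.shape} does not match {len(families)} families"
        )
    clipped = np.clip(raw, 0.0, None)
    sums = clipped.sum(axis=1)
    degenerate = np.flatnonzero(sums <= 0)
    if degenerate.size:
        logger.warning(
            "samples with no positive prediction set to the uniform "
            "composition: %s",
            ", ".join(str(sample_ids[i]) for i in degenerate),
        )
        clipped[degenerate] = 1.0
        sums[degenerate] = clipped.shape[1]
    out = clipped * (100.0 / sums)[:, None]
    # snap float residue so rows sum to 100 exactly enough for the invariant
    out[:, -1] += 100.0 - out.sum(axis=1)
    np.clip(out, 0.0, 100.0, out=out)
    return FamilyTable(list(sample_ids), list(families), out)


def _check_aligned(a: FamilyTable, b: FamilyTable) -> None:
    if a.sample_ids != b.sample_ids:
        raise ValueError("tables are not aligned on sample ids")
    if a.families != b.families:
        raise ValueError("tables are not aligned on families")


def estimate_bias_correction(
    pred_train: FamilyTable,
    true_train: FamilyTable,
    flag_threshold: float = 0.25,
) -> BiasCorrection:
    """Detect families with recurring over/underestimation on training data."""
    _check_aligned(pred_train, true_train)
    if pred_train.n_samples < 2:
        raise ValueError("need at least 2 training samples")
    pred = pred_train.values
    true = true_train.values
    signed_err = (pred - true).mean(axis=0)
    true_sd = true.std(axis=0, ddof=1)
    factors = np.ones(len(pred_train.families))
    flagged: list[str] = []
    for j, fam in enumerate(pred_train.families):
        if np.abs(signed_err[j]) > flag_threshold * true_sd[j]:
            flagged.append(fam)
            mean_pred = pred[:, j].mean()
            if mean_pred > 0:
                factors[j] = true[:, j].mean() / mean_pred
    return BiasCorrection(
        list(pred_train.families), factors, flagged, flag_threshold
    )


def apply_bias_correction(
    table: FamilyTable, corr: BiasCorrection
) -> FamilyTable:
    """Multiply each family by its factor, then re-close the composition."""
    if table.families != corr.families:
        raise ValueError("correction families do not match the table")
    adjusted = table.values * corr.factors[None, :]
    return clip_and_rescale(adjusted, table.families, table.sample_ids)
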