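"""Feature engineering: genus filtering, z-scoring, target construction.

The oral genus table is reduced to the genera that are both prevalent and
non-trace (present above a relative-abundance floor in more than a minimum
number of samples), then standardized genus-wise to zero mean / unit sample
standard deviation. The stool side is reduced to a fixed 12-family schema
plus a residual "Other" feature that closes each composition to 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io_tables import FamilyTable, GenusTable

logger = logging.getLogger(__name__)

#: The 12 stool families with the highest median relative abundance in the
#: cohorts the default model targets, in fixed order; "Other" (the residual
#: percentage) is always appended as the 13th predicted feature.
DEFAULT_FAMILIES: tuple[str, ...] = (
    "Bacteroidaceae",
    "Porphyromonadaceae",
    "Lachnospiraceae",
    "Ruminococcaceae",
    "Veillonellaceae",
    "Rikenellaceae",
    "Alcaligenaceae",
    "Streptococcaceae",
    "Bifidobacteriaceae",
    "Clostridiaceae",
    "Prevotellaceae",
    "Erysipelotrichaceae",
)

OTHER = "Other"


@dataclass
class FeatureSet:
    """Genera retained by the prevalence/abundance filter, in input order."""

    retained_genera: list[str]
    min_samples: int = 4
    min_abundance: float = 0.001

    def __len__(self) -> int:
        return len(self.retained_genera)


@dataclass
class FeatureScaler:
    """Per-genus mean and sample (n-1) standard deviation on the fit table."""

    genus_means: np.ndarray
    genus_sds: np.ndarray

    def __post_init__(self) -> None:
        self.genus_means = np.asarray(self.genus_means, dtype=float)
        self.genus_sds = np.asarray(self.genus_sds, dtype=float)
        if self.genus_means.shape != self.genus_sds.shape:
            raise ValueError("means and sds must have equal length")
        if np.any(self.genus_sds < 0):
            raise ValueError("standard deviations must be nonnegative")


@dataclass
class TargetSchema:
    """Ordered names of the stool families predicted explicitly.

    ``Other`` is implicit: it is always the last output feature and never a
    schema member.
    """

    family_names: list[str] = field(
        default_factory=lambda: list(DEFAULT_FAMILIES)
    )

    def __post_init__(self) -> None:
        if OTHER in self.family_names:
            raise ValueError('"Other" is implicit and cannot be a schema family')
        if len(set(self.family_names)) != len(self.family_names):
            raise ValueError("duplicate family in schema")

    @property
    def output_names(self) -> list[str]:
        return [*self.family_names, OTHER]

    @property
    def n_outputs(self) -> int:
        return len(self.family_names) + 1


def filter_genera(
    table: GenusTable, min_samples: int = 4, min_abundance: float = 0.001
) -> FeatureSet:
    """Retain genera exceeding the prevalence/abundance filter.

    A genus is retained iff the number of samples where its relative
    abundance is strictly greater than ``min_abundance`` is strictly greater
    than ``min_samples``. Both inequalities are strict.
    """
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    if not 0 <= min_abundance < 1:
        raise ValueError("min_abundance must be in [0, 1)")
    counts = (table.values > min_abundance).sum(axis=0)
    labels = table.genus_labels
    retained = [lab for lab, c in zip(labels, counts) if c > min_samples]
    return FeatureSet(retained, min_samples=min_samples, min_abundance=min_abundance)


def fit_scaler(table: GenusTable, features: FeatureSet) -> FeatureScaler:
    """Per-genus mean and sample sd over the table's samples."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to fit the scaler")
    frame = table.to_frame()
    missing = [g for g in features.retained_genera if g not in frame.columns]
    if missing:
        raise KeyError(f"retained genera absent from table: {missing}")
    sub = frame[features.retained_genera].to_numpy()
    sds = sub.std(axis=0, ddof=1)
    sds[sds <= 1e-12] = 0.0  # constant columns: exact zero, not float dust
    return FeatureScaler(sub.mean(axis=0), sds)


def transform(
    table: GenusTable, features: FeatureSet, scaler: FeatureScaler
) -> np.ndarray:
    """Standardize a genus table onto the retained-genus feature space.

    Genera in the feature set but absent from ``table`` (e.g. degraded or
    ancient inputs) are imputed as zero abundance before standardization; a
    warning lists them. Zero-variance genera map to 0.
    """
    if len(features.retained_genera) != len(scaler.genus_means):
        raise ValueError("scaler was not fitted on this feature set")
    frame = table.to_frame()
    missing = [g for g in features.retained_genera if g not in frame.columns]
    if missing:
        logger.warning(
            "input table lacks %d model genera, imputed as 0 abundance: %s",
            len(missing),
            ", ".join(missing),
        )
    n = table.n_samples
    X = np.zeros((n, len(features.retained_genera)))
    for j, g in enumerate(features.retained_genera):
        raw = frame[g].to_numpy() if g in frame.columns else np.zeros(n)
        sd = scaler.genus_sds[j]
        if sd > 0:
            X[:, j] = (raw - scaler.genus_means[j]) / sd
        # sd == 0: constant genus is inert, column stays 0
    return X


def select_target_families(stool: FamilyTable, k: int) -> TargetSchema:
    """The k families with the largest median abundance, ties by input order.

    The shipped model uses the fixed default schema; this is the retraining
    path for new cohorts.
    """
    candidates = [f for f in stool.families if f != OTHER]
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} available families")
    frame = stool.to_frame()
    medians = frame[candidates].median(axis=0).to_numpy()
    # stable sort on descending median preserves input order among ties
    order = np.argsort(-medians, kind="stable")[:k]
    chosen = sorted(order)  # keep input order in the schema
    return TargetSchema([candidates[i] for i in chosen])


def build_targets(stool: FamilyTable, schema: TargetSchema) -> FamilyTable:
    """Project raw stool percentages onto the schema and close with "Other".

    Families absent from the input are filled with 0; ``Other`` is the
    percentage remaining to reach 100, clamped at 0.
    """
    frame = stool.to_frame()
    n = stool.n_samples
    cols = np.zeros((n, schema.n_outputs))
    for j, fam in enumerate(schema.family_names):
        if fam in frame.columns:
            cols[:, j] = frame[fam].to_numpy()
    sums = cols[:, :-1].sum(axis=1)
    over = np.flatnonzero(sums > 100 + 1e-6)
    if over.size:
        raise ValueError(
            f"schema families sum to {sums[over[0]]:.6f} > 100 for sample "
            f"{stool.sample_ids[over[0]]!r}"
        )
    cols[:, -1] = np.clip(100.0 - sums, 0.0, None)
    # snap float residue so the closed-table invariant holds exactly
    cols[:, -1] += 100.0 - cols.sum(axis=1)
    return FamilyTable(list(stool.sample_ids), schema.output_names, cols)


class OralFeatureTransformer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: GenusTable -> standardized feature matrix.

    Combines the prevalence/abundance genus filter with genus-wise
    standardization, fitted on a training table and applicable to any new
    table (missing genera are zero-imputed).
    """

    def __init__(self, min_samples: int = 4, min_abundance: float = 0.001):
        self.min_samples = min_samples
        self.min_abundance = min_abundance

    def fit(self, table: GenusTable, y=None) -> "OralFeatureTransformer":
        self.feature_set_ = filter_genera(
            table, min_samples=self.min_samples, min_abundance=self.min_abundance
        )
        if not self.feature_set_.retained_genera:
            raise ValueError("no genus survives the prevalence/abundance filter")
        self.scaler_ = fit_scaler(table, self.feature_set_)
        self.n_features_out_ = len(self.feature_set_)
        return self

    def transform(self, table: GenusTable) -> np.ndarray:
        return transform(table, self.feature_set_, self.scaler_)
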