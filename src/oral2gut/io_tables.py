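"""Reading, validation and writing of taxon relative-abundance tables.

Two table layouts are handled, both plain TSV with taxa in the rows and
samples in the columns (the layout conventional for amplicon/shotgun
profiling pipelines):

* genus-level oral tables — Greengenes-style taxonomy strings
  (``k__...;p__...;...;g__...``) in the first column, relative abundances as
  fractions in ``[0, 1]``;
* family-level stool tables — family names (or taxonomy strings ending at
  ``f__``) in the rows, abundances in percent.

In-memory containers are thin dataclasses around a numpy matrix oriented
samples x taxa, which is the orientation every downstream estimator expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GREENGENES_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")
_RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus")


class TableFormatError(ValueError):
    """Raised when an input table violates the expected format."""


@dataclass(frozen=True)
class TaxonomyPath:
    """A Greengenes-style semicolon-joined taxonomy string, parsed by rank.

    ``ranks`` maps each canonical rank prefix (``k__`` ... ``g__``) present in
    the label to its payload (possibly empty, e.g. an unresolved ``g__``).
    """

    raw_string: str
    ranks: tuple[tuple[str, str], ...]  # ((prefix, payload), ...) in order

    @classmethod
    def parse(cls, raw: str) -> "TaxonomyPath":
        parts = [p.strip() for p in raw.strip().split(";")]
        parsed: list[tuple[str, str]] = []
        last_idx = -1
        for part in parts:
            if part == "":
                continue
            prefix = part[:3]
            if prefix not in GREENGENES_PREFIXES:
                raise TableFormatError(
                    f"taxonomy rank {part!r} in row {raw!r} lacks a "
                    f"Greengenes prefix (k__/p__/c__/o__/f__/g__)"
                )
            idx = GREENGENES_PREFIXES.index(prefix)
            if idx <= last_idx:
                raise TableFormatError(
                    f"taxonomy prefixes out of canonical order in row {raw!r}"
                )
            last_idx = idx
            parsed.append((prefix, part[3:].strip()))
        if not parsed:
            raise TableFormatError(f"empty taxonomy row {raw!r}")
        return cls(raw_string=raw, ranks=tuple(parsed))

    def _payload(self, prefix: str) -> str:
        for p, payload in self.ranks:
            if p == prefix:
                return payload
        return ""

    def genus_name(self) -> str:
        return self._payload("g__")

    def family_name(self) -> str:
        return self._payload("f__")

    def deepest_label(self) -> str:
        """Deepest non-empty rank payload, or the raw string as fallback."""
        for _, payload in reversed(self.ranks):
            if payload:
                return payload
        return self.raw_string

    def feature_label(self) -> str:
        """The label used to key this row as a model feature.

        Rows that do not resolve to a genus are kept under a synthetic
        ``unclassified:`` label so they remain addressable.
        """
        g = self.genus_name()
        if g:
            return g
        return f"unclassified:{self.deepest_label()}"


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TableFormatError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass
class GenusTable:
    """Samples x oral genera relative abundances, as fractions in [0, 1]."""

    sample_ids: list[str]
    genera: list[TaxonomyPath]
    values: np.ndarray  # shape (n_samples, n_genera)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.genera)):
            raise TableFormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.genera)} genera"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.genus_labels, "genus label")
        bad = np.argwhere((self.values < 0) | (self.values > 1))
        if bad.size:
            i, j = bad[0]
            raise TableFormatError(
                f"abundance {self.values[i, j]!r} outside [0, 1] for sample "
                f"{self.sample_ids[i]!r}, row {self.genera[j].raw_string!r}"
            )
        sums = self.values.sum(axis=1)
        over = np.flatnonzero(sums > 1 + 1e-6)
        if over.size:
            raise TableFormatError(
                f"per-sample abundance sum {sums[over[0]]:.6f} exceeds 1 for "
                f"sample {self.sample_ids[over[0]]!r}"
            )

    @property
    def genus_labels(self) -> list[str]:
        return [g.feature_label() for g in self.genera]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Samples x genera DataFrame keyed by feature label."""
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.genus_labels
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenusTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [pos[s] for s in sample_ids]
        return GenusTable(list(sample_ids), list(self.genera), self.values[idx])


@dataclass
class FamilyTable:
    """Samples x stool families in percent.

    When ``closed`` is true (the default — predictions and training targets),
    the last family must be ``"Other"`` and every row must sum to 100.
    Raw stool input read from disk is carried with ``closed=False``.
    """

    sample_ids: list[str]
    families: list[str]
    values: np.ndarray  # shape (n_samples, n_families), percent
    closed: bool = field(default=True)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.families)):
            raise TableFormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.families)} families"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.families, "family name")
        bad = np.argwhere((self.values < 0) | (self.values > 100))
        if bad.size:
            i, j = bad[0]
            raise TableFormatError(
                f"abundance {self.values[i, j]!r} outside [0, 100] for sample "
                f"{self.sample_ids[i]!r}, family {self.families[j]!r}"
            )
        if self.closed:
            if not self.families or self.families[-1] != "Other":
                raise TableFormatError(
                    'closed family table must end with the "Other" feature'
                )
            sums = self.values.sum(axis=1)
            off = np.flatnonzero(np.abs(sums - 100) > 1e-6)
            if off.size:
                raise TableFormatError(
                    f"per-sample percentages sum to {sums[off[0]]:.8f} != 100 "
                    f"for sample {self.sample_ids[off[0]]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.families
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FamilyTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [pos[s] for s in sample_ids]
        return FamilyTable(
            list(sample_ids), list(self.families), self.values[idx], self.closed
        )


def _read_tsv_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Parse a taxa-in-rows TSV; returns (sample_ids, row_labels, rows x samples)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise TableFormatError(f"{path}: header has no sample columns")
        sample_ids = [h.strip() for h in header[1:]]
        _check_unique(sample_ids, f"sample column in {path.name}")
        row_labels: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"got {len(cells)}"
                )
            row_labels.append(cells[0].strip())
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}:{lineno}: non-numeric abundance ({exc})"
                ) from None
    if not rows:
        raise TableFormatError(f"{path}: no data rows")
    return sample_ids, row_labels, np.asarray(rows, dtype=float)


def read_genus_table(path: str | Path) -> GenusTable:
    """Read a genus-level oral relative-abundance TSV.

    Samples are in the columns, Greengenes-style taxonomy strings in the
    rows; values are fractions in [0, 1]. Rows that do not resolve to a genus
    are retained under a synthetic ``unclassified:<deepest rank>`` label.
    """
    sample_ids, row_labels, matrix = _read_tsv_matrix(path)
    genera = [TaxonomyPath.parse(lab) for lab in row_labels]
    return GenusTable(sample_ids, genera, matrix.T)


def read_family_table(
    path: str | Path, closed: bool = False
) -> FamilyTable:
    """Read a family-level stool TSV (families in rows, percent values).

    Row labels may be bare family names or taxonomy strings ending at
    ``f__``; the family payload is used either way.
    """
    sample_ids, row_labels, matrix = _read_tsv_matrix(path)
    families: list[str] = []
    for lab in row_labels:
        if "__" in lab:
            families.append(TaxonomyPath.parse(lab).family_name() or lab)
        else:
            families.append(lab)
    return FamilyTable(sample_ids, families, matrix.T, closed=closed)


def write_family_predictions(table: FamilyTable, path: str | Path) -> None:
    """Write a family table as TSV, families in rows, 4 decimal places."""
    df = table.to_frame().T  # families x samples
    df.index.name = "family"
    df.to_csv(path, sep="\t", float_format="%.4f")


def plot_family_histograms(
    table: FamilyTable, out_dir: str | Path
) -> list[Path]:
    """One bar chart of family percentages per sample; returns image paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for i, sid in enumerate(table.sample_ids):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(range(len(table.families)), table.values[i], color="#4878a8")
        ax.set_xticks(range(len(table.families)))
        ax.set_xticklabels(table.families, rotation=90, fontsize=7)
        ax.set_ylabel("relative abundance (%)")
        ax.set_title(str(sid))
        fig.tight_layout()
        safe = "".join(c if c.isalnum() or c in "-_." else "_" for c in str(sid))
        out = out_dir / f"{safe}.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        paths.append(out)
    return paths
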