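"""Paired oral/stool cohort simulator with a known shared latent structure.

Each subject carries a latent state ``z`` (standard normal, ``latent_dim``
components). Oral genus and stool family log-intensities are independent
linear readouts of the same ``z`` (loadings ``A``/``B`` and intercepts
drawn once per cohort from the seed), perturbed by log-scale Gaussian noise
and pushed through a softmax, so each oral row is a composition summing to 1
and each stool row a percent composition summing to 100. ``coupling`` scales
the shared signal: 0 makes the two niches statistically independent, larger
values make the oral profile increasingly informative about the stool one.

A fraction of genera is made sporadically present (per-genus presence
probabilities spanning near-0 to 1), so genus prevalence varies and some
genera fail the default prevalence filter — exercising both the filter and
the zero-imputation path on degraded inputs.

The simulator emulates compositional dominance structure and a tunable
cross-niche dependence only; it makes no claim of biological realism
(no sequencing depth, read noise, phylogenetic correlation or aDNA damage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .io_tables import FamilyTable, GenusTable, TaxonomyPath
from .preprocess import DEFAULT_FAMILIES, OTHER

# Common oral genera with plausible Greengenes lineages, used so parsers and
# the schema path see realistic labels; padded with synthetic placeholders.
_ORAL_LINEAGES: tuple[tuple[str, ...], ...] = (
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Veillonellaceae", "Veillonella"),
    ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "Neisseria"),
    ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Haemophilus"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Micrococcaceae", "Rothia"),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Actinomycetaceae", "Actinomyces"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Porphyromonas"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae", "Granulicatella"),
    ("Firmicutes", "Bacilli", "Gemellales", "Gemellaceae", "Gemella"),
    ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Capnocytophaga"),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Leptotrichiaceae", "Leptotrichia"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Corynebacteriaceae", "Corynebacterium"),
    ("Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Campylobacteraceae", "Campylobacter"),
    ("Spirochaetes", "Spirochaetes", "Spirochaetales", "Spirochaetaceae", "Treponema"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Aggregatibacter"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Veillonellaceae", "Selenomonas"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Peptostreptococcaceae", "Peptostreptococcus"),
)


@dataclass
class SimulationConfig:
    """Cohort-simulation parameters.

    Defaults reproduce the package's reference study conditions: 380 paired
    subjects, 60 oral genera, the 12-family stool schema plus "Other", a
    5-dimensional shared latent state with coupling 2, and log-scale noise
    sd 0.3 on both niches.
    """

    n_samples: int = 380
    n_genera: int = 60
    n_families: int = 12
    latent_dim: int = 5
    coupling: float = 2.0
    noise_sd_oral: float = 0.3
    noise_sd_stool: float = 0.3
    sparse_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_genera < self.latent_dim:
            raise ValueError("n_genera must be >= latent_dim")
        if self.coupling < 0:
            raise ValueError("coupling must be nonnegative")
        if self.noise_sd_oral < 0 or self.noise_sd_stool < 0:
            raise ValueError("noise sds must be nonnegative")
        if not 0 <= self.sparse_fraction < 1:
            raise ValueError("sparse_fraction must be in [0, 1)")


def _genus_taxa(n_genera: int) -> list[TaxonomyPath]:
    taxa = []
    for i in range(n_genera):
        if i < len(_ORAL_LINEAGES):
            p, c, o, f, g = _ORAL_LINEAGES[i]
        else:
            p, c, o = "SynthPhylum", "SynthClass", "SynthOrder"
            f, g = f"SynthFamily{i:03d}", f"SynthGenus{i:03d}"
        taxa.append(
            TaxonomyPath.parse(
                f"k__Bacteria;p__{p};c__{c};o__{o};f__{f};g__{g}"
            )
        )
    return taxa


def _family_names(n_families: int) -> list[str]:
    if n_families <= len(DEFAULT_FAMILIES):
        return list(DEFAULT_FAMILIES[:n_families])
    extra = [
        f"SynthStoolFamily{i:03d}" for i in range(n_families - len(DEFAULT_FAMILIES))
    ]
    return list(DEFAULT_FAMILIES) + extra


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def simulate_paired_cohort(
    config: SimulationConfig,
) -> tuple[GenusTable, FamilyTable, dict[str, Any]]:
    """Simulate a paired oral/stool cohort; bit-identical for a given seed.

    Returns the oral genus table (rows sum to 1), the closed stool family
    table (rows sum to 100, last feature "Other"), and a ground-truth record
    with the latent states and loadings.
    """
    rng = np.random.default_rng(config.seed)
    n, g, d = config.n_samples, config.n_genera, config.latent_dim
    n_out = config.n_families + 1

    # Loading and intercept scales are calibrated for compositional realism:
    # at the default coupling the per-taxon logit sd is ~1.6 (oral) / ~1.1
    # (stool), and intercept spreads put taxon mean shares between ~0.5% and
    # ~25%, matching the dominance structure of real genus/family tables
    # rather than winner-takes-all compositions.
    A = rng.normal(0.0, 0.35, (g, d))
    a0 = rng.normal(0.0, 1.75, g)  # heterogeneous intercepts -> dominance
    B = rng.normal(0.0, 0.25, (n_out, d))
    b0 = rng.normal(0.0, 1.25, n_out)

    # sporadically present genera: presence probabilities spanning ~0 to 1
    n_sparse = int(round(config.sparse_fraction * g))
    presence_prob = np.ones(g)
    if n_sparse:
        sparse_idx = rng.choice(g, size=n_sparse, replace=False)
        presence_prob[sparse_idx] = np.geomspace(0.005, 0.6, n_sparse)

    z = rng.normal(0.0, 1.0, (n, d))
    oral_logits = (
        config.coupling * z @ A.T
        + a0
        + rng.normal(0.0, config.noise_sd_oral, (n, g))
    )
    present = rng.random((n, g)) < presence_prob
    # every sample keeps at least one genus
    empty = ~present.any(axis=1)
    present[empty, 0] = True
    oral_logits = np.where(present, oral_logits, -np.inf)
    oral = _softmax_rows(oral_logits)
    oral[~present] = 0.0

    stool_logits = (
        config.coupling * z @ B.T
        + b0
        + rng.normal(0.0, config.noise_sd_stool, (n, n_out))
    )
    stool = _softmax_rows(stool_logits) * 100.0
    stool[:, -1] += 100.0 - stool.sum(axis=1)  # snap float residue

    sample_ids = [f"subject_{i:04d}" for i in range(n)]
    oral_table = GenusTable(sample_ids, _genus_taxa(g), oral)
    stool_table = FamilyTable(
        list(sample_ids), [*_family_names(config.n_families), OTHER], stool
    )
    truth = {
        "config": config,
        "A": A,
        "a0": a0,
        "B": B,
        "b0": b0,
        "z": z,
        "presence_prob": presence_prob,
    }
    return oral_table, stool_table, truth


def degrade_to_ancient(
    oral: GenusTable, keep_fraction: float, seed: int
) -> GenusTable:
    """Randomly drop whole genus rows, mimicking partial ancient profiles.

    Surviving abundances are not renormalized: absent genera are simply
    missing, so downstream standardization exercises its zero-imputation
    path exactly as with real degraded inputs.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n_keep = int(round(keep_fraction * len(oral.genera)))
    if n_keep == 0:
        raise ValueError("keep_fraction would drop every genus")
    if n_keep == len(oral.genera):
        return GenusTable(
            list(oral.sample_ids), list(oral.genera), oral.values.copy()
        )
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(oral.genera), size=n_keep, replace=False))
    return GenusTable(
        list(oral.sample_ids),
        [oral.genera[i] for i in keep],
        oral.values[:, keep],
    )
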