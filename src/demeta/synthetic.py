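"""Synthetic inputs with controlled ground truth.

Every analysis module in this package consumes tabular inputs that in
production come from dozens of re-analysed public datasets.  This
module generates stand-ins for all of them — DEA table collections with
planted shared-DE features, scored interactomes, homology maps, miRNA
target maps, pro-fibrotic panels, and block-structured co-expression
module data — so the whole pipeline is testable without downloads.

The generative model for a DEA collection is deliberately simple:

* null features draw a Uniform(0, 1) nominal p-value and a small
  symmetric log2 fold-change noise (sd 0.2);
* planted features share one direction across datasets, with
  per-dataset log2 fold changes Normal(±2, 0.3) and p-values from a
  left-skewed Beta(0.1, 1);
* adjusted p-values are Benjamini–Hochberg within each table.

No attempt is made to mimic platform-specific microarray noise or
RNA-seq count distributions.  All randomness flows from one seeded
``numpy.random.Generator``; a fixed seed reproduces outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .benchmark import ProFibroticPanel
from .consensus import HomologyMap, TargetMap
from .coexpr_subnet import ModuleData
from .data_model import (
    DEATable,
    DatasetMeta,
    bh_adjust,
    parse_comparison_label,
)
from .ppi_network import InteractionTable, ProteinAnnotation

#: Conventional comparison label per species (treated fibrotic vs control).
DEFAULT_COMPARISON = {"human": "IPF_vs_Ctrl", "mouse": "BleomD14_vs_Ctrl"}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic DEA-table collection."""

    n_datasets: int = 4
    n_features: int = 2000
    planted_fraction: float = 0.05
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.3
    null_log2fc_sd: float = 0.2
    alt_p_alpha: float = 0.1     # Beta(alpha, beta) alternative p model,
    alt_p_beta: float = 1.0      # heavily left-skewed by default
    species: str = "human"
    biotype_scope: str = "coding"
    feature_prefix: str = "G"
    comparison: str | None = None
    n_samples_range: tuple[int, int] = (6, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError(f"planted_fraction outside [0, 1]: {self.planted_fraction}")
        for name in ("effect_log2fc_sd", "null_log2fc_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_datasets < 1 or self.n_features < 1:
            raise ValueError("n_datasets and n_features must be positive")
        if self.alt_p_alpha <= 0 or self.alt_p_beta <= 0:
            raise ValueError("Beta parameters must be positive")
        lo, hi = self.n_samples_range
        if not 3 <= lo <= hi:
            raise ValueError(f"n_samples_range must satisfy 3 <= lo <= hi: {self.n_samples_range}")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks against pipeline output."""

    #: planted feature -> (direction, per-dataset log2 fold changes)
    planted: dict[str, tuple[str, tuple[float, ...]]] = field(default_factory=dict)
    #: planted anticorrelated (miRNA, target) pairs
    mirna_pairs: tuple[tuple[str, str], ...] = ()
    #: planted 1:1 (human, mouse) homology pairs
    homology_pairs: tuple[tuple[str, str], ...] = ()

    def to_dict(self) -> dict:
        return {
            "planted": {f: {"direction": d, "log2fc": list(fc)}
                        for f, (d, fc) in self.planted.items()},
            "mirna_pairs": [list(p) for p in self.mirna_pairs],
            "homology_pairs": [list(p) for p in self.homology_pairs],
        }


def generate_dea_collection(config: SimulationConfig) -> tuple[list[DEATable], GroundTruth]:
    """Generate a collection of DEA tables with planted shared-DE features."""
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_features)))
    features = [f"{config.feature_prefix}{i:0{width}d}" for i in range(1, config.n_features + 1)]
    n_planted = int(round(config.planted_fraction * config.n_features))
    planted_idx = rng.choice(config.n_features, size=n_planted, replace=False)
    planted_dir = rng.choice([1.0, -1.0], size=n_planted)

    comparison = config.comparison or DEFAULT_COMPARISON[config.species]
    lo, hi = config.n_samples_range
    tables: list[DEATable] = []
    effects: dict[str, list[float]] = {features[i]: [] for i in planted_idx}

    for d in range(config.n_datasets):
        log2fc = rng.normal(0.0, config.null_log2fc_sd, size=config.n_features)
        p = rng.uniform(0.0, 1.0, size=config.n_features)
        planted_fc = planted_dir * rng.normal(
            config.effect_log2fc_mean, config.effect_log2fc_sd, size=n_planted
        )
        log2fc[planted_idx] = planted_fc
        p[planted_idx] = rng.beta(config.alt_p_alpha, config.alt_p_beta, size=n_planted)
        padj = bh_adjust(p)

        technology = "microarray" if d % 2 == 0 else "rnaseq"
        meta = DatasetMeta(
            dataset_id=f"SYN{d + 1:02d}",
            species=config.species,
            technology=technology,
            platform=f"synth-{technology}",
            tissue="lung",
            comparison=parse_comparison_label(comparison),
            n_samples=int(rng.integers(lo, hi + 1)),
            biotype_scope=config.biotype_scope,
        )
        df = pd.DataFrame(
            {"log2fc": log2fc, "p_nominal": p, "p_adjusted": padj},
            index=pd.Index(features, name="feature"),
        )
        tables.append(DEATable(meta=meta, data=df))
        for i, fc in zip(planted_idx, planted_fc):
            effects[features[i]].append(float(fc))

    truth = GroundTruth(planted={
        features[i]: ("up" if planted_dir[j] > 0 else "down", tuple(effects[features[i]]))
        for j, i in enumerate(planted_idx)
    })
    return tables, truth


def generate_panel(
    feature_ids: Sequence[str],
    species: str,
    n_genes: int = 25,
    seed: int = 0,
) -> ProFibroticPanel:
    """Draw a synthetic pro-fibrotic panel from a feature universe."""
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(feature_ids, dtype=object),
                        size=min(n_genes, len(feature_ids)), replace=False)
    return ProFibroticPanel(species=species, genes=frozenset(str(g) for g in chosen))


def generate_homology_map(
    human_genes: Sequence[str],
    mouse_genes: Sequence[str],
    n_one_to_many: int = 0,
    seed: int = 0,
) -> HomologyMap:
    """Pair human and mouse gene lists positionally; optionally plant
    one-to-many entries (first ``n_one_to_many`` human genes each gain a
    second mouse partner) that 1:1 filtering must discard."""
    rng = np.random.default_rng(seed)
    n = min(len(human_genes), len(mouse_genes))
    pairs = {(str(human_genes[i]), str(mouse_genes[i])) for i in range(n)}
    for i in range(min(n_one_to_many, n)):
        pairs.add((str(human_genes[i]), f"extra_{rng.integers(10**6)}_{i}"))
    return HomologyMap(pairs=frozenset(pairs))


def generate_target_map(
    mirnas: Sequence[str],
    genes: Sequence[str],
    targets_per_mirna: int = 5,
    seed: int = 0,
) -> TargetMap:
    """Random miRNA -> target assignments."""
    rng = np.random.default_rng(seed)
    genes = [str(g) for g in genes]
    edges = {}
    for m in mirnas:
        size = min(targets_per_mirna, len(genes))
        chosen = rng.choice(np.asarray(genes, dtype=object), size=size, replace=False)
        edges[str(m)] = frozenset(str(g) for g in chosen)
    return TargetMap(edges=edges)


def generate_interactome(
    n_proteins: int = 30,
    edge_density: float = 0.3,
    seed: int = 0,
    unreviewed_fraction: float = 0.2,
    multi_gene_fraction: float = 0.1,
) -> tuple[InteractionTable, dict[str, ProteinAnnotation]]:
    """Random scored interactome plus protein->gene annotation.

    Scores are uniform integers on [1, 1000].  A ``multi_gene_fraction``
    of proteins receive a secondary coding gene (the primary stays
    first) and an ``unreviewed_fraction`` are flagged unreviewed, to
    exercise the annotation rules.
    """
    if not 0.0 < edge_density <= 1.0:
        raise ValueError(f"edge_density must lie in (0, 1]: {edge_density}")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:03d}" for i in range(1, n_proteins + 1)]
    records = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            if rng.random() < edge_density:
                records.append((a, b, int(rng.integers(1, 1001))))
    table = InteractionTable.from_records(records)

    annotation = {}
    for p in proteins:
        genes = [f"G_{p}"]
        if rng.random() < multi_gene_fraction:
            genes.append(f"G_{p}_alt")
        annotation[p] = ProteinAnnotation(
            protein_id=p,
            reviewed=bool(rng.random() >= unreviewed_fraction),
            coding_genes=tuple(genes),
        )
    return table, annotation


def generate_module_data(
    n_genes: int = 20,
    n_modules: int = 2,
    seed: int = 0,
    within_tom: tuple[float, float] = (0.5, 0.9),
    between_tom: tuple[float, float] = (0.0, 0.2),
) -> ModuleData:
    """Block-structured module data: TOM high within modules, low between.

    MM and GS are drawn uniformly on (0, 1) so every gene has a distinct
    rank, making percentile cut-offs unambiguous in tests.
    """
    if n_genes < n_modules:
        raise ValueError("n_genes must be >= n_modules")
    rng = np.random.default_rng(seed)
    genes = [f"M{i:03d}" for i in range(1, n_genes + 1)]
    module_of = {g: f"mod{(i % n_modules) + 1}" for i, g in enumerate(genes)}

    tom = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            same = module_of[genes[i]] == module_of[genes[j]]
            lo, hi = within_tom if same else between_tom
            tom[i, j] = tom[j, i] = rng.uniform(lo, hi)
    np.fill_diagonal(tom, 1.0)

    return ModuleData(
        module_of=module_of,
        mm={g: float(rng.uniform(0.0, 1.0)) for g in genes},
        gs={g: float(rng.uniform(0.0, 1.0)) for g in genes},
        tom=pd.DataFrame(tom, index=genes, columns=genes),
    )
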