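"""Consensus differential expression by vote counting.

A feature is *consensus DE* within one species when it is called DE in
the same direction in at least half of the selected datasets (``k``, a
user-tunable support floor defaulting to ``ceil(n/2)``) and is not
called DE in the opposite direction in any of the rest.  The consensus
fold change is the arithmetic mean of the log2 fold changes over the
supporting datasets only.  No p-value combination or effect-size model
is involved: the method is pure vote counting, which keeps it
applicable across microarray and RNA-seq results that share nothing
but harmonised DEA statistics.

Cross-species integration runs the same rule per species independently
and then pairs human/mouse consensus features of matching direction
through a strict one-to-one homology map.  miRNA–mRNA integration
pairs consensus miRNAs with consensus targets of the *opposite*
direction (the expected signature of repression).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_GENE_THRESHOLDS,
    DEATable,
    DEThresholds,
    DOWN,
    NON_DE,
    UP,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Evidence:
    """One dataset's statistics for a consensus feature."""

    dataset_id: str
    log2fc: float
    p_nominal: float
    p_adjusted: float
    call: str


@dataclass(frozen=True)
class ConsensusFeature:
    """A feature consistently deregulated across datasets."""

    feature_id: str
    direction: str            # "up" or "down"
    consensus_log2fc: float   # mean log2fc over supporting datasets
    n_support: int            # datasets DE in the consensus direction
    n_selected: int           # datasets integrated
    evidence: tuple[Evidence, ...]

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")


def default_k(n: int) -> int:
    """'At least half' of n datasets: ceil(n/2)."""
    return math.ceil(n / 2)


def consensus_features(
    tables: Sequence[DEATable],
    thresholds: DEThresholds = DEFAULT_GENE_THRESHOLDS,
    k: int | None = None,
) -> list[ConsensusFeature]:
    """Same-species consensus calling over ``n`` selected datasets.

    A feature is consensus-up iff called up in >= k tables and down in
    none (symmetrically for down).  Features absent from a table
    contribute neither support nor veto there, but k is always judged
    against n, the number of selected datasets.  Output is sorted by
    feature id.
    """
    if not tables:
        raise ValueError("no tables selected for integration")
    species = {t.meta.species for t in tables}
    if len(species) > 1:
        raise ValueError(f"mixed-species integration not allowed here: {sorted(species)}")
    n = len(tables)
    if k is None:
        k = default_k(n)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")

    calls = pd.concat(
        [t.classify(thresholds).rename(t.meta.dataset_id) for t in tables],
        axis=1,
    )  # union of features; NaN where a feature is absent from a table
    log2fc = pd.concat(
        [t.data["log2fc"].rename(t.meta.dataset_id) for t in tables], axis=1
    )
    up_n = (calls == UP).sum(axis=1)
    down_n = (calls == DOWN).sum(axis=1)
    partial = calls.isna().any(axis=1)
    if partial.any():
        logger.info(
            "%d feature(s) absent from some of the %d selected tables; "
            "support still judged against k=%d of n=%d",
            int(partial.sum()), n, k, n,
        )

    consensus_up = (up_n >= k) & (down_n == 0)
    consensus_down = (down_n >= k) & (up_n == 0)

    out: list[ConsensusFeature] = []
    for feature in sorted(calls.index[consensus_up | consensus_down]):
        direction = UP if consensus_up.loc[feature] else DOWN
        row_calls = calls.loc[feature]
        support = row_calls[row_calls == direction].index
        cfc = float(log2fc.loc[feature, support].mean())
        evidence = []
        for t in tables:
            stat = t.get(feature)
            if stat is None:
                continue
            evidence.append(Evidence(
                dataset_id=t.meta.dataset_id,
                log2fc=stat.log2fc,
                p_nominal=stat.p_nominal,
                p_adjusted=stat.p_adjusted,
                call=str(row_calls[t.meta.dataset_id]),
            ))
        out.append(ConsensusFeature(
            feature_id=feature,
            direction=direction,
            consensus_log2fc=cfc,
            n_support=int(up_n.loc[feature] if direction == UP else down_n.loc[feature]),
            n_selected=n,
            evidence=tuple(evidence),
        ))
    return out


# ---------------------------------------------------------------------------
# cross-species integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologyMap:
    """Human<->mouse homology pairs."""

    pairs: frozenset[tuple[str, str]]  # (human_gene, mouse_gene)

    def one_to_one(self) -> "HomologyMap":
        """Keep only pairs whose human and mouse genes each occur once."""
        human_counts: dict[str, int] = {}
        mouse_counts: dict[str, int] = {}
        for h, m in self.pairs:
            human_counts[h] = human_counts.get(h, 0) + 1
            mouse_counts[m] = mouse_counts.get(m, 0) + 1
        kept = frozenset(
            (h, m) for h, m in self.pairs
            if human_counts[h] == 1 and mouse_counts[m] == 1
        )
        return HomologyMap(pairs=kept)


def load_homology(path: str | Path) -> HomologyMap:
    """Read a two-column tab-delimited homology file (human, mouse)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (human_gene, mouse_gene)")
    pairs = frozenset(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return HomologyMap(pairs=pairs)


@dataclass(frozen=True)
class CrossSpeciesConsensus:
    """A 1:1 homologous pair consensus-DE in the same direction in both species."""

    human_gene: str
    mouse_gene: str
    direction: str
    human: ConsensusFeature
    mouse: ConsensusFeature


def cross_species_consensus(
    human_tables: Sequence[DEATable],
    mouse_tables: Sequence[DEATable],
    homology: HomologyMap,
    thresholds: DEThresholds = DEFAULT_GENE_THRESHOLDS,
    k_human: int | None = None,
    k_mouse: int | None = None,
) -> list[CrossSpeciesConsensus]:
    """Across-species consensus through strict 1:1 homology.

    The complete same-species rule (including the opposite-direction
    veto) is applied within each species; pairs are then reported only
    when both members are consensus in the same direction and form a
    retained one-to-one homology pair.  Consensus fold changes are
    reported per species, not pooled.  Exclusively non-coding datasets
    are rejected.
    """
    if not human_tables or not mouse_tables:
        raise ValueError("both species need at least one selected dataset")
    for t in (*human_tables, *mouse_tables):
        if t.meta.biotype_scope == "noncoding":
            raise ValueError(
                f"non-coding dataset {t.meta.dataset_id} cannot enter "
                "cross-species integration"
            )
    if not homology.pairs:
        logger.warning("empty homology map: cross-species consensus is empty")
        return []

    human_hits = {f.feature_id: f
                  for f in consensus_features(human_tables, thresholds, k_human)}
    mouse_hits = {f.feature_id: f
                  for f in consensus_features(mouse_tables, thresholds, k_mouse)}

    out = []
    for h, m in sorted(homology.one_to_one().pairs):
        hf, mf = human_hits.get(h), mouse_hits.get(m)
        if hf is not None and mf is not None and hf.direction == mf.direction:
            out.append(CrossSpeciesConsensus(
                human_gene=h, mouse_gene=m, direction=hf.direction,
                human=hf, mouse=mf,
            ))
    return out


# ---------------------------------------------------------------------------
# miRNA--mRNA anticorrelation integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetMap:
    """miRNA -> predicted target gene ids."""

    edges: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, targets in self.edges.items():
            if not mirna:
                raise ValueError("empty miRNA id in target map")
            if mirna in targets:
                raise ValueError(f"self-edge in target map: {mirna}")
            if any(not t for t in targets):
                raise ValueError(f"empty target id for {mirna}")


def load_target_map(path: str | Path) -> TargetMap:
    """Read a two-column tab-delimited miRNA->target file."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (mirna, target)")
    edges: dict[str, set[str]] = {}
    for mirna, target in zip(df.iloc[:, 0], df.iloc[:, 1]):
        edges.setdefault(mirna, set()).add(target)
    return TargetMap(edges={m: frozenset(t) for m, t in edges.items()})


def mirna_mrna_integration(
    mirna_consensus: Sequence[ConsensusFeature],
    mrna_consensus: Sequence[ConsensusFeature],
    targets: TargetMap,
) -> list[tuple[ConsensusFeature, ConsensusFeature]]:
    """Pair consensus miRNAs with opposite-direction consensus targets.

    Returns exactly the (miRNA, mRNA) pairs where the gene is a
    predicted target of the miRNA and the two consensus directions are
    opposite.  The miRNA consensus is conventionally built with
    FDR-adjusted thresholds (``use_adjusted=True``).
    """
    gene_by_id = {f.feature_id: f for f in mrna_consensus}
    pairs = []
    for mf in sorted(mirna_consensus, key=lambda f: f.feature_id):
        for target in sorted(targets.edges.get(mf.feature_id, ())):
            gf = gene_by_id.get(target)
            if gf is not None and gf.direction != mf.direction:
                pairs.append((mf, gf))
    return pairs
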