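"""Query-centred two-shell protein interaction networks.

Given a scored, undirected interaction edge list (STRING-style combined
scores on 0–1000), a network is grown around one queried protein in two
shells: shell 1 holds at most nine high-confidence partners of the
query (score strictly above 700 by default), ranked by score; shell 2
holds, for each shell-1 protein, its two most confident interactors
that are neither the query nor already in shell 1.  All edges of the
input table among included nodes are retained with the score as
weight.  Score ties are broken lexicographically by protein id so the
construction is deterministic.

Nodes are then annotated with a consensus deregulation label derived
from the expression of each protein's primary coding gene across the
user-selected datasets: ``Upregulated``/``Downregulated``/``NonDE``,
or ``Unknown`` for unreviewed (TrEMBL-like) proteins and proteins
missing from the annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .data_model import (
    DEFAULT_GENE_THRESHOLDS,
    DEATable,
    DEThresholds,
    FeatureStat,
    classify_de,
    DOWN,
    NON_DE,
    UP,
)

logger = logging.getLogger(__name__)

LABEL_UNKNOWN = "Unknown"
LABEL_NON_DE = "NonDE"
LABEL_UP = "Upregulated"
LABEL_DOWN = "Downregulated"
LABELS = (LABEL_UNKNOWN, LABEL_NON_DE, LABEL_UP, LABEL_DOWN)

_DIRECTION_LABEL = {UP: LABEL_UP, DOWN: LABEL_DOWN}


@dataclass(frozen=True)
class InteractionTable:
    """Undirected scored protein interactions (scores 0–1000)."""

    edges: dict[tuple[str, str], int]  # key is the sorted protein pair

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "InteractionTable":
        edges: dict[tuple[str, str], int] = {}
        for a, b, score in records:
            if not a or not b:
                raise ValueError("empty protein id in interaction record")
            if a == b:
                raise ValueError(f"self-loop not allowed: {a}")
            if not 0 <= int(score) <= 1000:
                raise ValueError(f"score outside [0, 1000] for ({a}, {b}): {score}")
            key = (a, b) if a < b else (b, a)
            if key in edges:
                raise ValueError(f"duplicate record for unordered pair {key}")
            edges[key] = int(score)
        return cls(edges=edges)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for pair in self.edges for p in pair)

    def neighbors(self, protein: str) -> list[tuple[str, int]]:
        """Partners of ``protein`` with scores, unordered."""
        out = []
        for (a, b), score in self.edges.items():
            if a == protein:
                out.append((b, score))
            elif b == protein:
                out.append((a, score))
        return out

    def score(self, a: str, b: str) -> int | None:
        return self.edges.get((a, b) if a < b else (b, a))


def load_interactions(path: str | Path) -> InteractionTable:
    """Read a 3-column tab-delimited edge list (protein_a, protein_b, combined_score)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (protein_a, protein_b, combined_score)")
    return InteractionTable.from_records(
        (str(a), str(b), int(s)) for a, b, s in df.itertuples(index=False)
    )


@dataclass(frozen=True)
class ProteinAnnotation:
    """Protein -> coding gene(s); first gene is the primary one."""

    protein_id: str
    reviewed: bool
    coding_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.reviewed and not self.coding_genes:
            raise ValueError(f"reviewed protein {self.protein_id} needs >= 1 coding gene")

    @property
    def primary_gene(self) -> str | None:
        return self.coding_genes[0] if self.coding_genes else None


def load_annotations(path: str | Path) -> dict[str, ProteinAnnotation]:
    """Read a tab-delimited annotation table: protein, reviewed (true/false),
    comma-separated coding genes with the primary gene first."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"protein", "reviewed", "genes"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    out = {}
    for row in df.itertuples(index=False):
        genes = tuple(g for g in str(row.genes).split(",") if g and g != "nan")
        out[row.protein] = ProteinAnnotation(
            protein_id=row.protein,
            reviewed=str(row.reviewed).strip().lower() in ("true", "1", "yes"),
            coding_genes=genes,
        )
    return out


@dataclass
class ShellNetwork:
    """A two-shell interaction graph centred on a query protein.

    ``graph`` is an undirected networkx graph; every node carries a
    ``shell`` attribute (0 = query, 1, 2) and, after annotation, a
    ``label`` attribute and the per-dataset statistics used.
    Edge ``weight`` is the interaction score.
    """

    query: str
    graph: nx.Graph = field(repr=False)

    def shell(self, k: int) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["shell"] == k)

    @property
    def labels(self) -> dict[str, str]:
        return {n: d.get("label") for n, d in self.graph.nodes(data=True)}

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"protein": n, "shell": d["shell"],
             "label": d.get("label", ""), "gene": d.get("gene", "")}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"protein_a": min(a, b), "protein_b": max(a, b), "score": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows).sort_values(["protein_a", "protein_b"]).reset_index(drop=True)

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            d.pop("evidence", None)  # GraphML holds scalar attributes only
            for k, v in list(d.items()):
                if v is None:
                    d[k] = ""
        nx.write_graphml(g, path)


def build_two_shell_network(
    query: str,
    interactions: InteractionTable,
    max_first_shell: int = 9,
    per_node_second: int = 2,
    min_score: int = 700,
    second_shell_min_score: int | None = None,
    known_proteins: Iterable[str] = (),
) -> ShellNetwork:
    """Grow the two-shell network around ``query``.

    Shell 1: the top ``max_first_shell`` partners of the query with
    score strictly above ``min_score``, ranked by score descending
    (ties by protein id).  Shell 2: per shell-1 protein, its top
    ``per_node_second`` partners excluding the query and shell-1
    members; duplicates across parents merge into one node.  The
    confidence floor applies to shell 1 only unless
    ``second_shell_min_score`` is set.  A query with no qualifying
    partner yields the single-node network.
    """
    universe = interactions.proteins | set(known_proteins)
    if query not in universe:
        raise KeyError(f"unknown query protein: {query!r}")

    def ranked(partners: list[tuple[str, int]]) -> list[tuple[str, int]]:
        return sorted(partners, key=lambda ps: (-ps[1], ps[0]))

    shell1 = [
        p for p, s in ranked(
            [(p, s) for p, s in interactions.neighbors(query) if s > min_score]
        )
    ][:max_first_shell]

    excluded = {query, *shell1}
    shell2: set[str] = set()
    for parent in shell1:
        candidates = [
            (p, s) for p, s in interactions.neighbors(parent)
            if p not in excluded
            and (second_shell_min_score is None or s > second_shell_min_score)
        ]
        shell2.update(p for p, _ in ranked(candidates)[:per_node_second])

    g = nx.Graph()
    g.add_node(query, shell=0)
    for p in shell1:
        g.add_node(p, shell=1)
    for p in sorted(shell2):
        g.add_node(p, shell=2)
    nodes = set(g.nodes)
    for (a, b), score in interactions.edges.items():
        if a in nodes and b in nodes:
            g.add_edge(a, b, weight=score)
    return ShellNetwork(query=query, graph=g)


# ---------------------------------------------------------------------------
# condition-specific consensus labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneEvidence:
    """One dataset's statistics for a gene, with the dataset's size."""

    dataset_id: str
    n_samples: int
    n_detected: int
    stat: FeatureStat


def _biggest(entries: list[tuple[str, GeneEvidence]]) -> str:
    """Direction of the biggest DE dataset: largest n_samples, then
    largest n_detected, then smallest dataset_id."""
    best = min(entries, key=lambda e: (-e[1].n_samples, -e[1].n_detected, e[1].dataset_id))
    return best[0]


def consensus_label(
    gene_stats: Sequence[GeneEvidence],
    thresholds: DEThresholds = DEFAULT_GENE_THRESHOLDS,
    reviewed: bool = True,
) -> str:
    """Summarise per-dataset DE calls into one node label.

    Unreviewed (TrEMBL-like) proteins are ``Unknown``.  Otherwise:
    no DE call anywhere -> ``NonDE``; one DE dataset, or two agreeing
    -> that direction; two disagreeing -> the bigger dataset's
    direction; three or more -> the most frequent direction, falling
    back to the biggest DE dataset's direction on a tie.
    """
    if not reviewed:
        return LABEL_UNKNOWN
    de: list[tuple[str, GeneEvidence]] = []
    for ev in gene_stats:
        call = classify_de(ev.stat, thresholds)
        if call != NON_DE:
            de.append((call, ev))
    if not de:
        return LABEL_NON_DE
    directions = [d for d, _ in de]
    if len(de) == 1:
        return _DIRECTION_LABEL[directions[0]]
    if len(de) == 2:
        if directions[0] == directions[1]:
            return _DIRECTION_LABEL[directions[0]]
        return _DIRECTION_LABEL[_biggest(de)]
    n_up = directions.count(UP)
    n_down = directions.count(DOWN)
    if n_up > n_down:
        return LABEL_UP
    if n_down > n_up:
        return LABEL_DOWN
    return _DIRECTION_LABEL[_biggest(de)]


def annotate_network(
    net: ShellNetwork,
    tables: Sequence[DEATable],
    annotation: Mapping[str, ProteinAnnotation],
    thresholds: DEThresholds = DEFAULT_GENE_THRESHOLDS,
) -> ShellNetwork:
    """Label every node of ``net`` via its primary gene's statistics.

    ``tables`` should already be filtered to the experimental
    parameters of interest (species/tissue/comparison).  The per-node
    statistics used are retained in the ``evidence`` node attribute,
    including the FDR-adjusted p-values, for reporting.  Nodes absent
    from the annotation are labelled Unknown with a warning.
    """
    g = net.graph.copy()
    for node in g.nodes:
        ann = annotation.get(node)
        if ann is None:
            logger.warning("protein %s absent from annotation; labelled Unknown", node)
            g.nodes[node]["label"] = LABEL_UNKNOWN
            g.nodes[node]["gene"] = None
            g.nodes[node]["evidence"] = []
            continue
        gene = ann.primary_gene
        evidence = []
        if gene is not None:
            for t in tables:
                stat = t.get(gene)
                if stat is not None:
                    evidence.append(GeneEvidence(
                        dataset_id=t.meta.dataset_id,
                        n_samples=t.meta.n_samples,
                        n_detected=len(t),
                        stat=stat,
                    ))
        g.nodes[node]["label"] = consensus_label(evidence, thresholds, ann.reviewed)
        g.nodes[node]["gene"] = gene
        g.nodes[node]["evidence"] = [
            {"dataset_id": e.dataset_id, "log2fc": e.stat.log2fc,
             "p_nominal": e.stat.p_nominal, "p_adjusted": e.stat.p_adjusted}
            for e in evidence
        ]
    return ShellNetwork(query=net.query, graph=g)
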