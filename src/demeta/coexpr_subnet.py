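"""Visualization subnetworks from precomputed co-expression modules.

Module detection itself (WGCNA: biweight midcorrelation, signed TOM,
module merging, eigengene–trait correlation) is upstream of this
package; its products arrive as :class:`ModuleData` — a gene→module
assignment, per-gene module membership (MM, correlation of the gene
with its module eigengene) and gene significance (GS, correlation with
the phenotype trait), plus the topological overlap matrix (TOM).

Around one queried gene, the extraction rule keeps the members of the
query's module whose MM *and* GS lie strictly above the module's 60th
percentile (both tunable), draws edges between retained genes whose
TOM lies strictly above the module's third TOM quartile, drops
zero-degree genes (the query is the only node allowed to be
edge-less), and computes a maximum-TOM spanning forest (equivalently,
a minimum spanning forest under the 1−TOM distance) over what remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class ModuleData:
    """Precomputed co-expression module products.

    ``tom`` is a square symmetric frame over (at least) all genes that
    have a module assignment, entries in [0, 1]; the diagonal is
    ignored.  MM and GS are on the correlation scale [−1, 1].
    """

    module_of: dict[str, str]
    mm: dict[str, float]
    gs: dict[str, float]
    tom: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        genes = set(self.module_of)
        for name, table in (("mm", self.mm), ("gs", self.gs)):
            missing = genes - set(table)
            if missing:
                raise ValueError(f"{name} undefined for gene(s): {sorted(missing)[:5]}")
        tom_genes = set(self.tom.index)
        if not genes <= tom_genes or not (self.tom.index == self.tom.columns).all():
            raise ValueError("TOM must be square over all module genes")
        values = self.tom.to_numpy(dtype=float)
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("TOM must be symmetric")
        off = values[~np.eye(len(values), dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("TOM entries must lie in [0, 1]")

    def module_genes(self, module: str) -> list[str]:
        return sorted(g for g, m in self.module_of.items() if m == module)


def load_module_data(nodes_path: str | Path, tom_path: str | Path) -> ModuleData:
    """Read the gene attribute table (gene, module, mm, gs) and the TOM matrix."""
    nodes = pd.read_csv(nodes_path, sep="\t", comment="#",
                        dtype={"gene": str, "module": str})
    required = {"gene", "module", "mm", "gs"}
    if not required.issubset(nodes.columns):
        raise ValueError(
            f"{nodes_path}: expected columns {sorted(required)}, found {list(nodes.columns)}"
        )
    tom = pd.read_csv(tom_path, sep="\t", index_col=0, comment="#")
    tom.index = tom.index.astype(str)
    tom.columns = tom.columns.astype(str)
    return ModuleData(
        module_of=dict(zip(nodes.gene, nodes.module)),
        mm=dict(zip(nodes.gene, nodes.mm.astype(float))),
        gs=dict(zip(nodes.gene, nodes.gs.astype(float))),
        tom=tom,
    )


def write_module_data(data: ModuleData, nodes_path: str | Path, tom_path: str | Path) -> None:
    genes = sorted(data.module_of)
    pd.DataFrame({
        "gene": genes,
        "module": [data.module_of[g] for g in genes],
        "mm": [data.mm[g] for g in genes],
        "gs": [data.gs[g] for g in genes],
    }).to_csv(nodes_path, sep="\t", index=False)
    data.tom.loc[genes, genes].to_csv(tom_path, sep="\t")


@dataclass
class Subnetwork:
    """The extracted visualization subnetwork around a query gene."""

    query: str
    graph: nx.Graph = field(repr=False)          # nodes + TOM-weighted edges
    spanning_tree: frozenset[tuple[str, str]]    # maximum-TOM spanning forest

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": min(a, b), "gene_b": max(a, b), "tom": d["weight"],
             "in_spanning_tree": (min(a, b), max(a, b)) in self.spanning_tree}
            for a, b, d in self.graph.edges(data=True)
        ]
        return (pd.DataFrame(rows, columns=["gene_a", "gene_b", "tom", "in_spanning_tree"])
                .sort_values(["gene_a", "gene_b"]).reset_index(drop=True))

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": sorted(self.graph.nodes),
            "is_query": [g == self.query for g in sorted(self.graph.nodes)],
        })


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value < 1.0:
        raise ValueError(f"{name} must lie in [0, 1), got {value}")


def tune_thresholds(
    data: ModuleData,
    module: str,
    mm_pct: float = 0.60,
    gs_pct: float = 0.60,
) -> frozenset[str]:
    """Apply the node filter of ``extract_subnetwork`` to one module.

    Keeps module members whose MM and GS both lie strictly above the
    module's respective percentiles (linear-interpolation quantiles).
    Monotone: raising either percentile never adds a gene.
    """
    _check_fraction("mm_pct", mm_pct)
    _check_fraction("gs_pct", gs_pct)
    members = data.module_genes(module)
    if not members:
        raise KeyError(f"unknown module: {module!r}")

    def cut(values: list[float], pct: float) -> float:
        # percentile 0 disables the filter entirely (the whole module is
        # retained); any positive percentile is a strict ">" cut-off
        if pct == 0.0:
            return float("-inf")
        return float(np.quantile(values, pct, method="linear"))

    mm_cut = cut([data.mm[g] for g in members], mm_pct)
    gs_cut = cut([data.gs[g] for g in members], gs_pct)
    return frozenset(g for g in members if data.mm[g] > mm_cut and data.gs[g] > gs_cut)


def extract_subnetwork(
    query: str,
    data: ModuleData,
    mm_pct: float = 0.60,
    gs_pct: float = 0.60,
    tom_q: float = 0.75,
) -> Subnetwork:
    """Extract the visualization subnetwork around ``query``.

    Candidate nodes are the query's module members strictly above the
    module's ``mm_pct`` MM percentile and ``gs_pct`` GS percentile,
    plus the query itself; edges connect candidate pairs whose TOM is
    strictly above the ``tom_q`` quantile of the module's off-diagonal
    TOM values.  Zero-degree non-query nodes are dropped, and a
    maximum-TOM spanning forest of the retained graph is returned
    alongside the full edge set.
    """
    _check_fraction("mm_pct", mm_pct)
    _check_fraction("gs_pct", gs_pct)
    _check_fraction("tom_q", tom_q)
    module = data.module_of.get(query)
    if module is None:
        raise KeyError(f"query gene {query!r} is not assigned to any module")
    members = data.module_genes(module)
    candidates = set(tune_thresholds(data, module, mm_pct, gs_pct)) | {query}

    tom = data.tom.loc[members, members].to_numpy(dtype=float)
    off = tom[np.triu_indices(len(members), k=1)]
    tom_cut = float(np.quantile(off, tom_q, method="linear")) if off.size else float("inf")

    g = nx.Graph()
    g.add_node(query)
    ordered = sorted(candidates)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            w = float(data.tom.at[a, b])
            if w > tom_cut:
                g.add_edge(a, b, weight=w)
    # candidates without a surviving edge never enter the graph, which
    # drops zero-degree nodes; the query was added up front and is the
    # only node allowed to remain edge-less

    forest = frozenset(
        (min(a, b), max(a, b))
        for a, b, _ in nx.maximum_spanning_edges(g, algorithm="kruskal", data=True)
    )
    return Subnetwork(query=query, graph=g, spanning_tree=forest)
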