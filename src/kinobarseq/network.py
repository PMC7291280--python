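"""Kinase genetic-interaction network from ortholog-mapped suppressors.

A yeast gene whose deletion suppresses a human kinase's toxicity defines a
human–yeast genetic interaction; translating the yeast gene to its human
ortholog(s) yields kinase → human-gene edges.  Interactions are counted at
the yeast-suppressor level (one per (kinase, yeast gene, human ortholog)
triple), while the drawn graph deduplicates to one edge per
(kinase, human gene), retaining the yeast provenance on the edge.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .screen import SUPPRESSOR

EDGE_COLUMNS = ["kinase", "human_gene", "yeast_gene", "z", "edge_type"]
GENETIC_INTERACTION = "genetic_interaction"


class OrthologTable:
    """Yeast gene → set of human gene symbols (possibly empty, one-to-many)."""

    def __init__(self, pairs: Mapping[str, Iterable[str]]):
        self.pairs: dict[str, set[str]] = {
            str(y): {str(h) for h in hs} for y, hs in pairs.items()
        }

    def orthologs(self, yeast_gene: str) -> set[str]:
        return self.pairs.get(yeast_gene, set())

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologTable":
        """Two-column TSV (yeast_gene, human_gene), multi-row per yeast gene."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("yeast_gene", "human_gene"):
            if col not in df.columns:
                raise ValueError(f"ortholog table {path} is missing column {col!r}")
        pairs: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            pairs.setdefault(row.yeast_gene, set()).add(row.human_gene)
        return cls(pairs)


class AnnotationTable:
    """Gene symbol → single primary functional-category label."""

    def __init__(self, categories: Mapping[str, str]):
        self.categories: dict[str, str] = {str(g): str(c) for g, c in categories.items()}

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def labels(self) -> set[str]:
        return set(self.categories.values())

    def get(self, gene: str) -> str | None:
        return self.categories.get(gene)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("gene", "category"):
            if col not in df.columns:
                raise ValueError(f"annotation table {path} is missing column {col!r}")
        return cls(dict(zip(df["gene"], df["category"])))


def map_orthologs(
    calls: pd.DataFrame, table: OrthologTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Translate suppressor calls into kinase → human-gene interaction edges.

    ``calls`` is the long call table from the screen fit; only rows with
    label == 'suppressor' contribute.  Returns (edges, tally):

    * edges — one row per (kinase, yeast suppressor, human ortholog) triple
      with the suppressor's Z-score; yeast genes with several orthologs
      contribute several rows.
    * tally — per kinase, n_suppressors (all suppressor calls) and
      n_with_ortholog (interaction edges, i.e. suppressor-derived triples).
    """
    sup = calls[calls["label"] == SUPPRESSOR] if "label" in calls.columns else calls
    rows = []
    tally_rows = []
    for kinase, grp in sup.groupby("kinase", sort=False):
        n_edges = 0
        for rec in grp.itertuples(index=False):
            for human in sorted(table.orthologs(rec.yeast_gene)):
                rows.append(
                    {
                        "kinase": kinase,
                        "human_gene": human,
                        "yeast_gene": rec.yeast_gene,
                        "z": rec.z,
                        "edge_type": GENETIC_INTERACTION,
                    }
                )
                n_edges += 1
        tally_rows.append(
            {"kinase": kinase, "n_suppressors": len(grp), "n_with_ortholog": n_edges}
        )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    tally = pd.DataFrame(
        tally_rows, columns=["kinase", "n_suppressors", "n_with_ortholog"]
    )
    return edges, tally


def total_interactions(tally: pd.DataFrame) -> int:
    """Total genetic interactions: sum of per-kinase suppressor-level edges."""
    return int(tally["n_with_ortholog"].sum())


class InteractionNetwork:
    """Undirected kinase–gene interaction graph plus per-kinase tallies.

    Nodes carry ``is_kinase`` and ``degree`` attributes (and ``category``
    once annotated); duplicate (kinase, human gene) pairs arising from
    several yeast suppressors collapse into one edge whose provenance lists
    every contributing (yeast_gene, z).
    """

    def __init__(self, graph: nx.Graph, tally: pd.DataFrame | None = None):
        self.graph = graph
        self.tally = (
            tally
            if tally is not None
            else pd.DataFrame(columns=["kinase", "n_suppressors", "n_with_ortholog"])
        )

    @property
    def kinases(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("is_kinase")]

    @property
    def partners(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d.get("is_kinase")]

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def annotate(self, annot: AnnotationTable) -> None:
        for node in self.graph.nodes:
            cat = annot.get(node)
            if cat is not None:
                self.graph.nodes[node]["category"] = cat

    # -- exports ---------------------------------------------------------
    def to_edge_tsv(self, path: str | Path) -> None:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            kinase, gene = (u, v) if self.graph.nodes[u].get("is_kinase") else (v, u)
            for yeast_gene, z in d["provenance"]:
                rows.append(
                    {
                        "kinase": kinase,
                        "human_gene": gene,
                        "yeast_gene": yeast_gene,
                        "z": z,
                        "edge_type": d.get("edge_type", GENETIC_INTERACTION),
                    }
                )
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)

    def to_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v, d in self.graph.edges(data=True):
                fh.write(f"{u}\t{d.get('edge_type', GENETIC_INTERACTION)}\t{v}\n")

    def to_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _u, _v, d in g.edges(data=True):
            # GraphML attributes must be scalars
            d["provenance"] = ";".join(f"{y}:{z:.4g}" for y, z in d["provenance"])
        nx.write_graphml(g, path)

    def tally_to_tsv(self, path: str | Path) -> None:
        self.tally.to_csv(path, sep="\t", index=False)


def build_network(
    edges: pd.DataFrame, tally: pd.DataFrame | None = None
) -> InteractionNetwork:
    """Assemble the interaction graph from a suppressor-level edge table.

    Kinase–kinase edges arise naturally when a kinase gene is itself the
    ortholog target of a yeast suppressor.  An empty edge table yields an
    empty network with a warning.
    """
    if len(edges) == 0:
        warnings.warn("empty edge list: building an empty interaction network")
    g = nx.Graph()
    kinases = set(edges["kinase"]) if len(edges) else set()
    if tally is not None:
        kinases |= set(tally["kinase"])
    for kinase in kinases:
        g.add_node(kinase, is_kinase=True)
    for rec in edges.itertuples(index=False):
        if rec.human_gene not in g:
            g.add_node(rec.human_gene, is_kinase=False)
        if g.has_edge(rec.kinase, rec.human_gene):
            g.edges[rec.kinase, rec.human_gene]["provenance"].append(
                (rec.yeast_gene, float(rec.z))
            )
        else:
            g.add_edge(
                rec.kinase,
                rec.human_gene,
                provenance=[(rec.yeast_gene, float(rec.z))],
                edge_type=rec.edge_type,
            )
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return InteractionNetwork(g, tally)


def subnetwork(
    net: InteractionNetwork, categories: set[str], annot: AnnotationTable
) -> InteractionNetwork:
    """Induced subgraph on kinases plus partners in the given categories.

    Kinases survive only if they retain at least one edge.  Unknown
    category labels are rejected with the known labels listed.
    """
    if not categories:
        raise ValueError("categories must be non-empty")
    unknown = set(categories) - annot.labels
    if unknown:
        raise ValueError(
            f"unknown categories {sorted(unknown)}; known: {sorted(annot.labels)}"
        )
    kinases = set(net.kinases)
    keep_partners = {
        n for n in net.partners if annot.get(n) in categories
    }
    sub = net.graph.subgraph(kinases | keep_partners).copy()
    # drop kinases left without interactions (unless they are themselves
    # category-matching partners of another kinase)
    isolated = [
        n
        for n in list(sub.nodes)
        if sub.nodes[n].get("is_kinase") and sub.degree(n) == 0
    ]
    sub.remove_nodes_from(isolated)
    for node in sub.nodes:
        sub.nodes[node]["degree"] = sub.degree(node)
    tally = net.tally[net.tally["kinase"].isin(set(sub.nodes))].reset_index(drop=True)
    return InteractionNetwork(sub, tally)


def category_percentages(
    net: InteractionNetwork, annot: AnnotationTable
) -> dict[str, float]:
    """Percent of annotated network members per primary category.

    Percentages are over the network genes (kinases and partners) present
    in the annotation table and sum to 100.
    """
    members = [n for n in net.graph.nodes if annot.get(n) is not None]
    if not members:
        raise ValueError("no network gene is covered by the annotation table")
    counts: dict[str, int] = {}
    for gene in members:
        cat = annot.get(gene)
        counts[cat] = counts.get(cat, 0) + 1
    return {cat: 100.0 * n / len(members) for cat, n in sorted(counts.items())}
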