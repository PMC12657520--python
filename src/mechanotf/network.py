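"""Tripartite Protein-TF-RNA regulatory network construction.

Node classes follow the screen's convention: transcriptional regulators
that also appear in the protein-protein interaction (PPI) data are *TF
nodes*, remaining PPI proteins are *Protein nodes*, and target-gene
transcripts are *RNA nodes*. PPI edges carry cost ``-log(score/1000)``;
TF->target edges carry cost zero. RNA-node prizes are the average of the
absolute log2 fold changes of the gene in the two contrasts (up under
load, down under ERK inhibition); Protein/TF node values are the load
log2 fold changes of the up-regulated genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from mechanotf.io import InteractionRecord, TFTargetRecord

logger = logging.getLogger("mechanotf")

RNA_SUFFIX = ":rna"


@dataclass(frozen=True)
class Node:
    id: str
    gene: str
    node_class: str  # "Protein" | "TF" | "RNA"
    prize: float

    def __post_init__(self):
        if self.prize < 0:
            raise ValueError(f"negative prize on node {self.id}")
        if self.node_class not in ("Protein", "TF", "RNA"):
            raise ValueError(f"unknown node class {self.node_class!r}")


@dataclass(frozen=True)
class Edge:
    u: str
    v: str
    cost: float
    edge_class: str  # "PPI" | "TF_target"

    def __post_init__(self):
        if self.cost < 0:
            raise ValueError(f"negative cost on edge {self.u}-{self.v}")
        if self.edge_class == "TF_target" and self.cost != 0:
            raise ValueError("TF_target edges must have cost 0")


@dataclass
class RegulatoryNetwork:
    """Tripartite weighted graph; the pre-optimization superset handed
    to the PCST solver."""

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    def validate(self) -> None:
        ids = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.u not in ids or e.v not in ids:
                raise ValueError(f"dangling edge {e.u}-{e.v}")
            key = (e.u, e.v) if e.u < e.v else (e.v, e.u)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            cu, cv = self.nodes[e.u].node_class, self.nodes[e.v].node_class
            if e.edge_class == "PPI" and ("RNA" in (cu, cv)):
                raise ValueError(f"PPI edge touches RNA node: {e.u}-{e.v}")
            if e.edge_class == "TF_target" and not (
                (cu == "TF" and cv == "RNA") or (cu == "RNA" and cv == "TF")
            ):
                raise ValueError(f"TF_target edge must run TF->RNA: {e.u}-{e.v}")

    def to_graph(self) -> nx.Graph:
        """Undirected view for the solver: node attribute ``prize``,
        edge attribute ``cost``."""
        g = nx.Graph()
        for n in self.nodes.values():
            g.add_node(n.id, prize=n.prize, node_class=n.node_class, gene=n.gene)
        for e in self.edges:
            g.add_edge(e.u, e.v, cost=e.cost, edge_class=e.edge_class)
        return g

    def nodes_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n.id, n.gene, n.node_class, n.prize) for n in self.nodes.values()],
            columns=["id", "gene", "node_class", "prize"],
        ).sort_values("id", ignore_index=True)

    def edges_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.u, e.v, e.cost, e.edge_class) for e in self.edges],
            columns=["u", "v", "cost", "edge_class"],
        ).sort_values(["u", "v"], ignore_index=True)


def edge_cost(score: int, log_base: str = "10") -> float:
    """Cost of a PPI edge: ``-log(score/1000)``.

    Monotone decreasing in the confidence score; a maximal score of 1000
    is free. The base (10 or e) rescales all PPI costs by a constant.
    """
    if score <= 0:
        raise ValueError("score must be > 0 (zero score gives infinite cost)")
    if score > 1000:
        raise ValueError("score must be <= 1000")
    if log_base == "10":
        return -math.log10(score / 1000.0)
    if log_base == "e":
        return -math.log(score / 1000.0)
    raise ValueError(f"log_base must be '10' or 'e', got {log_base!r}")


def select_target_genes(
    up_load: pd.DataFrame,
    down_inhibitor: pd.DataFrame,
    padj_threshold: float = 0.05,
) -> dict[str, float]:
    """Prized target genes: up-regulated under load AND down-regulated
    under the ERK inhibitor, both at ``padj < padj_threshold``.

    The prize is the average of the two absolute log2 fold changes.
    Returns an empty map (with a warning) when the intersection is
    empty.
    """
    up = up_load[(up_load["log2fc"] > 0) & (up_load["padj"] < padj_threshold)]
    down = down_inhibitor[
        (down_inhibitor["log2fc"] < 0) & (down_inhibitor["padj"] < padj_threshold)
    ]
    up_fc = dict(zip(up["gene"], up["log2fc"]))
    prizes: dict[str, float] = {}
    for gene, fc_down in zip(down["gene"], down["log2fc"]):
        if gene in up_fc:
            prizes[gene] = (abs(up_fc[gene]) + abs(fc_down)) / 2.0
    if not prizes:
        logger.warning("select_target_genes: empty up/down intersection")
    return prizes


def assign_node_values(
    up_load: pd.DataFrame, padj_threshold: float = 0.05
) -> dict[str, float]:
    """Protein/TF node values: the load log2 fold change of each
    significantly up-regulated gene."""
    up = up_load[(up_load["log2fc"] > 0) & (up_load["padj"] < padj_threshold)]
    return dict(zip(up["gene"], up["log2fc"]))


def build_network(
    ppi: Iterable[InteractionRecord],
    tf_targets: Iterable[TFTargetRecord],
    target_prizes: Mapping[str, float],
    node_values: Mapping[str, float],
    log_base: str = "10",
) -> RegulatoryNetwork:
    """Assemble the tripartite network.

    A regulator becomes a TF node only when it also has PPI information;
    regulators absent from the PPI table are unusable and logged. RNA
    nodes are created (namespaced with ``:rna``) only for prized target
    genes reached by at least one usable TF, so the network never has
    dangling endpoints.
    """
    ppi = list(ppi)
    tf_targets = list(tf_targets)
    ppi_genes = sorted({r.gene_a for r in ppi} | {r.gene_b for r in ppi})
    all_tfs = {r.tf for r in tf_targets}
    usable_tfs = all_tfs & set(ppi_genes)
    unusable = sorted(all_tfs - usable_tfs)
    if unusable:
        logger.info(
            "build_network: %d regulator(s) without PPI information are unusable: %s",
            len(unusable), ", ".join(unusable[:10]),
        )

    net = RegulatoryNetwork()
    for gene in ppi_genes:
        cls = "TF" if gene in usable_tfs else "Protein"
        net.nodes[gene] = Node(gene, gene, cls, float(node_values.get(gene, 0.0)))

    for r in sorted(ppi, key=lambda r: (r.gene_a, r.gene_b)):
        net.edges.append(Edge(r.gene_a, r.gene_b, edge_cost(r.score, log_base), "PPI"))

    tf_edges = sorted(
        {
            (r.tf, r.target)
            for r in tf_targets
            if r.tf in usable_tfs and r.target in target_prizes
        }
    )
    for tf, target in tf_edges:
        rna_id = target + RNA_SUFFIX
        if rna_id not in net.nodes:
            net.nodes[rna_id] = Node(rna_id, target, "RNA", float(target_prizes[target]))
        net.edges.append(Edge(tf, rna_id, 0.0, "TF_target"))

    net.validate()
    return net
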