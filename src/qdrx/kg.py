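"""Typed biomedical knowledge graph and anchor sets.

The graph holds three node kinds (gene, drug, disease) and four relation
types on an undirected :class:`networkx.Graph`:

* ``targets`` — drug–gene target edges,
* ``interacts`` — gene–gene interaction edges,
* ``associated_with`` — gene–disease edges,
* ``indicated_for`` — drug–disease edges.

Anchor sets name the known disease genes and known disease drugs used to
anchor the embedding spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

GENE = "gene"
DRUG = "drug"
DISEASE = "disease"

REL_TARGETS = "targets"
REL_INTERACTS = "interacts"
REL_GENE_DISEASE = "associated_with"
REL_DRUG_DISEASE = "indicated_for"

_VALID_KINDS = (GENE, DRUG, DISEASE)
_VALID_RELATIONS = (REL_TARGETS, REL_INTERACTS, REL_GENE_DISEASE, REL_DRUG_DISEASE)


@dataclass(frozen=True)
class AnchorSets:
    """Known disease-associated genes and drugs (the 'positive' anchors)."""

    genes: tuple[str, ...]
    drugs: tuple[str, ...]


@dataclass
class KnowledgeGraph:
    """Wrapper around an undirected networkx graph with typed nodes/edges."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    # -- construction -----------------------------------------------------
    def add_entity(self, node_id: str, kind: str) -> None:
        if kind not in _VALID_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        self.graph.add_node(node_id, kind=kind)

    def add_relation(self, src: str, relation: str, dst: str) -> None:
        if relation not in _VALID_RELATIONS:
            raise ValueError(f"unknown relation {relation!r}")
        if src not in self.graph or dst not in self.graph:
            raise ValueError(f"relation endpoints must exist: {src}, {dst}")
        self.graph.add_edge(src, dst, relation=relation)

    # -- queries ----------------------------------------------------------
    def _of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == kind)

    def genes(self) -> list[str]:
        return self._of_kind(GENE)

    def drugs(self) -> list[str]:
        return self._of_kind(DRUG)

    def diseases(self) -> list[str]:
        return self._of_kind(DISEASE)

    def kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def drug_targets(self, drug_id: str) -> frozenset[str]:
        """Gene targets of one drug (its gene interaction set)."""
        if drug_id not in self.graph or self.kind(drug_id) != DRUG:
            raise KeyError(f"not a drug node: {drug_id}")
        return frozenset(
            v
            for v in self.graph.neighbors(drug_id)
            if self.graph.edges[drug_id, v]["relation"] == REL_TARGETS
        )

    def target_counts(self) -> dict[str, int]:
        """Per-drug gene-target count (drug–gene degree, not global degree)."""
        return {d: len(self.drug_targets(d)) for d in self.drugs()}

    def edges_of(self, relation: str) -> list[tuple[str, str]]:
        return sorted(
            (min(u, v), max(u, v))
            for u, v, r in self.graph.edges(data="relation")
            if r == relation
        )

    # -- derived graphs for the encoders ----------------------------------
    def gene_context_graph(self, hub_cap: int = 30) -> nx.Graph:
        """Graph over genes: direct gene–gene edges plus genes co-incident to
        a shared drug or disease (the non-gene neighbor projected out).

        Non-gene nodes with more than ``hub_cap`` gene neighbors are skipped
        in the projection so promiscuous hubs do not create quadratic cliques.
        """
        g = nx.Graph()
        g.add_nodes_from(self.genes())
        for u, v in self.edges_of(REL_INTERACTS):
            g.add_edge(u, v)
        for node in self.graph.nodes:
            if self.kind(node) == GENE:
                continue
            gene_nb = sorted(
                n for n in self.graph.neighbors(node) if self.kind(n) == GENE
            )
            if len(gene_nb) > hub_cap:
                continue
            for i, a in enumerate(gene_nb):
                for b in gene_nb[i + 1 :]:
                    g.add_edge(a, b)
        return g

    def drug_projection_graph(self) -> nx.Graph:
        """Graph over drugs, connecting drugs that share >= 1 target gene."""
        g = nx.Graph()
        g.add_nodes_from(self.drugs())
        by_gene: dict[str, list[str]] = {}
        for d in self.drugs():
            for t in self.drug_targets(d):
                by_gene.setdefault(t, []).append(d)
        for ds in by_gene.values():
            ds = sorted(ds)
            for i, a in enumerate(ds):
                for b in ds[i + 1 :]:
                    g.add_edge(a, b)
        return g

    # -- serialization -----------------------------------------------------
    def to_tsv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame(
            [(n, d["kind"], n) for n, d in sorted(self.graph.nodes(data=True))],
            columns=["id", "type", "label"],
        )
        edges = pd.DataFrame(
            sorted(
                (u, r, v) for u, v, r in self.graph.edges(data="relation")
            ),
            columns=["src", "relation", "dst"],
        )
        nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)

    @classmethod
    def from_tsv(cls, in_dir: str | Path) -> "KnowledgeGraph":
        inp = Path(in_dir)
        nodes = pd.read_csv(inp / "nodes.tsv", sep="\t")
        edges = pd.read_csv(inp / "edges.tsv", sep="\t")
        kg = cls()
        for _, row in nodes.iterrows():
            kg.add_entity(str(row["id"]), str(row["type"]))
        for _, row in edges.iterrows():
            kg.add_relation(str(row["src"]), str(row["relation"]), str(row["dst"]))
        return kg


def write_anchors(anchors: AnchorSets, path: str | Path) -> None:
    rows = [(g, GENE) for g in anchors.genes] + [(d, DRUG) for d in anchors.drugs]
    pd.DataFrame(rows, columns=["id", "type"]).to_csv(path, sep="\t", index=False)


def read_anchors(path: str | Path) -> AnchorSets:
    df = pd.read_csv(path, sep="\t")
    return AnchorSets(
        genes=tuple(df.loc[df["type"] == GENE, "id"].astype(str)),
        drugs=tuple(df.loc[df["type"] == DRUG, "id"].astype(str)),
    )
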