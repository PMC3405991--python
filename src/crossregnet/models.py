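"""Core containers for the integrated transcription-splicing network.

The network joins three groups of human regulatory proteins — splicing
factors (SF), transcription factors (TF) and kinases — with two kinds of
directed edges: *splicing* edges (an SF's conserved binding motif near an
alternative-splicing event of the target gene) and *transcription* edges
(a TF's conserved motif in the target's promoter). SFs and TFs act as both
regulators and targets; kinases are targets only.

All genomic intervals are 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx

GROUPS = ("SF", "TF", "KINASE")
EDGE_TYPES = ("splicing", "transcription")
EVENT_TYPES = ("cassette", "alt3", "alt5")
DATASETS = ("A", "B")

#: which group emits each edge type
EDGE_SOURCE_GROUP = {"splicing": "SF", "transcription": "TF"}

Interval = tuple[int, int]


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event of a gene.

    ``event_type`` is one of ``cassette`` (exon skipping), ``alt3``
    (alternative 3' splice site) or ``alt5`` (alternative 5' splice site).
    The flanking introns are stored as genomic intervals; ``alt3`` events
    carry only the transcript-upstream search intron and ``alt5`` only the
    downstream one. ``dataset`` tags the event-calling source (the two
    independent event sets: splicing-sensitive microarrays vs RNA-seq).
    """

    event_type: str
    event_exon: Interval
    upstream_intron: Interval | None
    downstream_intron: Interval | None
    dataset: str

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown AS event type: {self.event_type!r}")
        if self.dataset not in DATASETS:
            raise ValueError(f"unknown dataset tag: {self.dataset!r}")
        if self.event_type == "alt3" and self.downstream_intron is not None:
            raise ValueError("alt3 events have no downstream search intron")
        if self.event_type == "alt5" and self.upstream_intron is not None:
            raise ValueError("alt5 events have no upstream search intron")


@dataclass
class GeneModel:
    """A gene with its group label, coordinates, exons and AS events.

    ``tss`` is the 0-based position of the first transcribed base: the first
    exon's start on the + strand, the last exon's final base on the − strand.
    """

    gene_id: str
    group: str
    chrom: str
    strand: str
    tss: int
    exons: list[Interval]
    as_events: list[ASEvent] = field(default_factory=list)

    @property
    def is_regulator(self) -> bool:
        return self.group in ("SF", "TF")

    @property
    def length(self) -> int:
        return self.exons[-1][1] - self.exons[0][0]

    def events(self, dataset: str | None = None) -> list[ASEvent]:
        if dataset is None:
            return list(self.as_events)
        return [e for e in self.as_events if e.dataset == dataset]

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.gene_id}: unknown group {self.group!r}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
        expected_tss = self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1
        if self.tss != expected_tss:
            raise ValueError(
                f"{self.gene_id}: TSS {self.tss} inconsistent with strand "
                f"{self.strand} (expected {expected_tss})"
            )


@dataclass(frozen=True)
class MotifHit:
    """A conserved binding-motif hit of a regulator on the genome (BED-like)."""

    factor_id: str
    chrom: str
    start: int
    end: int
    conserved: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"motif hit with non-positive length: {self}")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass
class RegulatoryEdge:
    """A typed directed edge; parallel motif evidence is collapsed here."""

    source: str
    target: str
    edge_type: str
    evidence: tuple[MotifHit, ...] = ()

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.edge_type)


class RegulatoryNetwork:
    """Typed directed graph over gene models, with layer classification.

    Layers follow the three-row architecture: nodes with outedges only are
    ``source``, with both in- and outedges ``mixed``, with inedges only
    ``sink``, otherwise ``isolated``. Kinases, having no outedges by
    construction, can only be sink or isolated.
    """

    def __init__(self, genes: Sequence[GeneModel], edges: Iterable[RegulatoryEdge]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id: {g.gene_id}")
            self.genes[g.gene_id] = g
        # collapse on (source, target, type), merging evidence
        collapsed: dict[tuple[str, str, str], RegulatoryEdge] = {}
        for e in edges:
            if e.source not in self.genes or e.target not in self.genes:
                raise ValueError(f"edge endpoint not among genes: {e.key}")
            if self.genes[e.source].group != EDGE_SOURCE_GROUP[e.edge_type]:
                raise ValueError(
                    f"{e.edge_type} edge with {self.genes[e.source].group} source: {e.key}"
                )
            if e.key in collapsed:
                prev = collapsed[e.key]
                prev.evidence = tuple(prev.evidence) + tuple(e.evidence)
            else:
                collapsed[e.key] = RegulatoryEdge(
                    e.source, e.target, e.edge_type, tuple(e.evidence)
                )
        self.edges: list[RegulatoryEdge] = sorted(
            collapsed.values(), key=lambda e: e.key
        )

    # -- basic counts ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {e.key for e in self.edges}

    def group_members(self, group: str) -> list[str]:
        return [gid for gid, g in self.genes.items() if g.group == group]

    def group_sizes(self) -> dict[str, int]:
        return {grp: len(self.group_members(grp)) for grp in GROUPS}

    def inedge_counts(
        self, edge_type: str | None = None, include_self_loops: bool = True
    ) -> dict[str, int]:
        counts = {gid: 0 for gid in self.genes}
        for e in self.edges:
            if edge_type is not None and e.edge_type != edge_type:
                continue
            if not include_self_loops and e.source == e.target:
                continue
            counts[e.target] += 1
        return counts

    def outedge_counts(self, edge_type: str | None = None) -> dict[str, int]:
        counts = {gid: 0 for gid in self.genes}
        for e in self.edges:
            if edge_type is None or e.edge_type == edge_type:
                counts[e.source] += 1
        return counts

    def targets_of(self, factor_id: str, edge_type: str) -> set[str]:
        return {
            e.target
            for e in self.edges
            if e.source == factor_id and e.edge_type == edge_type
        }

    # -- layers ----------------------------------------------------------
    @cached_property
    def layers(self) -> dict[str, str]:
        ins = self.inedge_counts()
        outs = self.outedge_counts()
        out = {}
        for gid in self.genes:
            i, o = ins[gid], outs[gid]
            if o > 0 and i == 0:
                out[gid] = "source"
            elif o > 0 and i > 0:
                out[gid] = "mixed"
            elif i > 0:
                out[gid] = "sink"
            else:
                out[gid] = "isolated"
        return out

    # -- projections -----------------------------------------------------
    def to_directed_multigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for gid, gene in self.genes.items():
            g.add_node(gid, group=gene.group)
        for e in self.edges:
            g.add_edge(e.source, e.target, key=e.edge_type, edge_type=e.edge_type)
        return g

    def to_undirected_simple(self) -> nx.Graph:
        """Undirected simple projection: directions, edge types and
        self-loops dropped. This is the graph the clustering coefficient is
        computed on."""
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for e in self.edges:
            if e.source != e.target:
                g.add_edge(e.source, e.target)
        return g

    def subset(self, node_ids: Iterable[str]) -> "RegulatoryNetwork":
        keep = set(node_ids)
        unknown = keep - set(self.genes)
        if unknown:
            raise KeyError(f"nodes not in network: {sorted(unknown)}")
        genes = [self.genes[gid] for gid in self.genes if gid in keep]
        edges = [e for e in self.edges if e.source in keep and e.target in keep]
        return RegulatoryNetwork(genes, edges)

    def __repr__(self) -> str:
        sizes = self.group_sizes()
        return (
            f"RegulatoryNetwork(N={self.n_nodes} "
            f"[SF={sizes['SF']}, TF={sizes['TF']}, KINASE={sizes['KINASE']}], "
            f"E={self.n_edges})"
        )
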