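"""Plain-text readers and writers for every pipeline artifact.

Formats: gene models and AS events as TSV, motif hits as 6-column BED
(name = factor id, score = conservation flag), expression atlas as a TSV
matrix, protein annotations as TSV, sequence sets as FASTA, networks as a
typed edge-list TSV plus a node table, ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annot import ProteinAnnotation
from .enrich import SequenceSet
from .models import ASEvent, GeneModel, MotifHit, RegulatoryEdge, RegulatoryNetwork
from .tissue import ExpressionAtlas


def _fmt_interval(iv) -> str:
    return f"{iv[0]}-{iv[1]}" if iv is not None else "."


def _parse_interval(s: str):
    if s == ".":
        return None
    a, b = s.split("-")
    return (int(a), int(b))


# -- gene models + AS events -------------------------------------------------

def write_gene_models(genes: Sequence[GeneModel], genes_path, events_path) -> None:
    gene_rows = [
        {
            "gene_id": g.gene_id,
            "group": g.group,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "exon_starts": ",".join(str(s) for s, _ in g.exons),
            "exon_ends": ",".join(str(e) for _, e in g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(gene_rows).to_csv(genes_path, sep="\t", index=False)
    event_rows = [
        {
            "gene_id": g.gene_id,
            "event_type": ev.event_type,
            "dataset": ev.dataset,
            "event_exon": _fmt_interval(ev.event_exon),
            "upstream_intron": _fmt_interval(ev.upstream_intron),
            "downstream_intron": _fmt_interval(ev.downstream_intron),
        }
        for g in genes
        for ev in g.as_events
    ]
    pd.DataFrame(
        event_rows,
        columns=[
            "gene_id", "event_type", "dataset", "event_exon",
            "upstream_intron", "downstream_intron",
        ],
    ).to_csv(events_path, sep="\t", index=False)


def read_gene_models(genes_path, events_path) -> list[GeneModel]:
    gdf = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str})
    try:
        edf = pd.read_csv(events_path, sep="\t", dtype={"gene_id": str})
    except pd.errors.EmptyDataError:
        edf = pd.DataFrame(columns=["gene_id"])
    events_by_gene: dict[str, list[ASEvent]] = {}
    for _, row in edf.iterrows():
        events_by_gene.setdefault(row["gene_id"], []).append(
            ASEvent(
                row["event_type"],
                _parse_interval(row["event_exon"]),
                _parse_interval(row["upstream_intron"]),
                _parse_interval(row["downstream_intron"]),
                row["dataset"],
            )
        )
    genes = []
    for _, row in gdf.iterrows():
        starts = [int(x) for x in str(row["exon_starts"]).split(",")]
        ends = [int(x) for x in str(row["exon_ends"]).split(",")]
        g = GeneModel(
            row["gene_id"], row["group"], row["chrom"], row["strand"],
            int(row["tss"]), list(zip(starts, ends)),
            events_by_gene.get(row["gene_id"], []),
        )
        g.validate()
        genes.append(g)
    return genes


# -- motif hits (BED6) -------------------------------------------------------

def write_motif_hits(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            score = 1 if h.conserved else 0
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.factor_id}\t{score}\t+\n")


def read_motif_hits(path) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 BED fields")
            chrom, start, end, name, score = fields[:5]
            hits.append(MotifHit(name, chrom, int(start), int(end), score not in ("0", "0.0")))
    return hits


# -- expression atlas --------------------------------------------------------

def write_atlas(atlas: ExpressionAtlas, path) -> None:
    atlas.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_atlas(path) -> ExpressionAtlas:
    return ExpressionAtlas(pd.read_csv(path, sep="\t", index_col="gene_id"))


# -- protein annotations -----------------------------------------------------

def write_annotations(annotations: Sequence[ProteinAnnotation], path) -> None:
    rows = [
        {
            "protein_id": a.protein_id,
            "group": a.group,
            "length": a.length,
            "phospho_positions": ",".join(map(str, sorted(a.phospho_positions))) or ".",
            "disorder_scores": ",".join(f"{x:.17g}" for x in a.disorder_scores)
            if a.disorder_scores is not None
            else ".",
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[ProteinAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out = []
    for _, row in df.iterrows():
        pos = row["phospho_positions"]
        positions = (
            frozenset(int(x) for x in str(pos).split(",")) if pos != "." else frozenset()
        )
        sc = row["disorder_scores"]
        scores = (
            np.array([float(x) for x in str(sc).split(",")]) if sc != "." else None
        )
        out.append(
            ProteinAnnotation(row["protein_id"], row["group"], int(row["length"]), positions, scores)
        )
    return out


# -- sequence sets (FASTA) ---------------------------------------------------

def write_sequences(seqs: SequenceSet, bound_path, control_path) -> None:
    for path, label, items in (
        (bound_path, "bound", seqs.bound),
        (control_path, "control", seqs.control),
    ):
        records = [
            SeqRecord(Seq(s), id=f"{label}_{i:05d}", description="")
            for i, s in enumerate(items)
        ]
        SeqIO.write(records, path, "fasta")


def read_sequences(bound_path, control_path) -> SequenceSet:
    bound = [str(r.seq) for r in SeqIO.parse(bound_path, "fasta")]
    control = [str(r.seq) for r in SeqIO.parse(control_path, "fasta")]
    return SequenceSet(bound, control)


def read_fasta(path) -> list[str]:
    return [str(r.seq) for r in SeqIO.parse(path, "fasta")]


# -- networks ----------------------------------------------------------------

def write_network(network: RegulatoryNetwork, edges_path, nodes_path) -> None:
    pd.DataFrame(
        [
            {"source": e.source, "target": e.target, "edge_type": e.edge_type}
            for e in network.edges
        ],
        columns=["source", "target", "edge_type"],
    ).to_csv(edges_path, sep="\t", index=False)
    layers = network.layers
    pd.DataFrame(
        [
            {"gene_id": gid, "group": g.group, "layer": layers[gid]}
            for gid, g in network.genes.items()
        ]
    ).to_csv(nodes_path, sep="\t", index=False)


def read_network(
    edges_path, nodes_path, genes: Sequence[GeneModel] | None = None
) -> RegulatoryNetwork:
    """Rebuild a network from its edge list and node table.

    When full gene models are not supplied, placeholder coordinates are used
    (density, correlation, clustering and pair stages only need ids, groups
    and edges).
    """
    ndf = pd.read_csv(nodes_path, sep="\t", dtype={"gene_id": str})
    try:
        edf = pd.read_csv(edges_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        edf = pd.DataFrame(columns=["source", "target", "edge_type"])
    if genes is None:
        genes = [
            GeneModel(row["gene_id"], row["group"], f"chr_{row['gene_id']}", "+", 0, [(0, 1)])
            for _, row in ndf.iterrows()
        ]
    edges = [
        RegulatoryEdge(row["source"], row["target"], row["edge_type"])
        for _, row in edf.iterrows()
    ]
    return RegulatoryNetwork(genes, edges)


# -- ground truth / reports --------------------------------------------------

def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
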