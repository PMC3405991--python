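"""Wiring rules for the integrated network.

Splicing edges: an SF regulates a gene if the gene carries an alternative
splicing event and a conserved binding motif of the SF overlaps the event's
search regions — up to 100 nt of the immediate upstream intron, the entire
event exon, and up to 100 nt of the flanking downstream intron (cassette
exons use all three; alternative 3' events search the upstream intron window
plus the exon; alternative 5' events the exon plus the downstream window).

Transcription edges: a TF regulates a gene if a conserved motif of the TF
falls in the gene's promoter, the 5 kb strictly upstream of the TSS.

Overlap means non-empty interval intersection; coordinates are 0-based
half-open throughout. Self-edges (autoregulation) are allowed.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .models import (
    ASEvent,
    GeneModel,
    Interval,
    MotifHit,
    RegulatoryEdge,
    RegulatoryNetwork,
)

DEFAULT_WINDOW_NT = 100
DEFAULT_PROMOTER_NT = 5000


def _intersects(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _intron_window(intron: Interval, exon: Interval, window_nt: int) -> Interval:
    """The ``window_nt`` of the intron adjacent to the event exon.

    Side selection is purely geometric: an intron genomically left of the
    exon contributes its rightmost window, a right intron its leftmost.
    This is equivalent to the transcript-orientation rule on either strand
    and truncates naturally when the intron is shorter than the window.
    """
    s, e = intron
    if e <= exon[0]:  # intron left of exon
        return (max(s, e - window_nt), e)
    if s >= exon[1]:  # intron right of exon
        return (s, min(e, s + window_nt))
    raise ValueError(f"intron {intron} overlaps event exon {exon}")


def splicing_search_regions(
    event: ASEvent, window_nt: int = DEFAULT_WINDOW_NT
) -> list[Interval]:
    """Genomic intervals searched for SF motifs around one AS event."""
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    regions: list[Interval] = []
    if event.event_type in ("cassette", "alt3"):
        if event.upstream_intron is None:
            raise ValueError(f"{event.event_type} event missing upstream intron")
        regions.append(_intron_window(event.upstream_intron, event.event_exon, window_nt))
    regions.append(event.event_exon)
    if event.event_type in ("cassette", "alt5"):
        if event.downstream_intron is None:
            raise ValueError(f"{event.event_type} event missing downstream intron")
        regions.append(_intron_window(event.downstream_intron, event.event_exon, window_nt))
    return [r for r in regions if r[1] > r[0]]


def promoter_interval(gene: GeneModel, promoter_nt: int = DEFAULT_PROMOTER_NT) -> Interval:
    """The promoter span: ``promoter_nt`` bases strictly upstream of the TSS
    in transcript orientation, the TSS base itself excluded."""
    if promoter_nt <= 0:
        raise ValueError("promoter_nt must be > 0")
    if gene.strand == "+":
        return (max(0, gene.tss - promoter_nt), gene.tss)
    return (gene.tss + 1, gene.tss + 1 + promoter_nt)


def _index_hits(
    hits: Iterable[MotifHit],
    genes: Mapping[str, GeneModel],
    expected_group: str,
    require_conserved: bool,
) -> dict[str, list[MotifHit]]:
    """Hits grouped by chromosome, after factor validation."""
    unknown = sorted({h.factor_id for h in hits if h.factor_id not in genes})
    if unknown:
        raise KeyError(f"motif hits reference unknown factors: {unknown}")
    wrong = sorted(
        {h.factor_id for h in hits if genes[h.factor_id].group != expected_group}
    )
    if wrong:
        raise ValueError(
            f"expected {expected_group} hits, got other groups for: {wrong}"
        )
    by_chrom: dict[str, list[MotifHit]] = defaultdict(list)
    for h in hits:
        if require_conserved and not h.conserved:
            continue
        by_chrom[h.chrom].append(h)
    return by_chrom


def build_splicing_edges(
    genes: Sequence[GeneModel],
    hits: Iterable[MotifHit],
    window_nt: int = DEFAULT_WINDOW_NT,
    require_conserved: bool = True,
    dataset: str | None = None,
) -> list[RegulatoryEdge]:
    """SF → gene splicing edges from motif hits overlapping AS-event windows.

    A single qualifying hit near any one event suffices; edges are collapsed
    per (SF, gene) with all supporting hits as evidence.
    """
    gene_map = {g.gene_id: g for g in genes}
    by_chrom = _index_hits(hits, gene_map, "SF", require_conserved)
    edges: dict[tuple[str, str], list[MotifHit]] = defaultdict(list)
    for gene in genes:
        chrom_hits = by_chrom.get(gene.chrom)
        if not chrom_hits:
            continue
        regions: list[Interval] = []
        for event in gene.events(dataset):
            regions.extend(splicing_search_regions(event, window_nt))
        if not regions:
            continue
        for h in chrom_hits:
            if any(_intersects(h.interval, r) for r in regions):
                edges[(h.factor_id, gene.gene_id)].append(h)
    return [
        RegulatoryEdge(src, tgt, "splicing", tuple(ev))
        for (src, tgt), ev in sorted(edges.items())
    ]


def build_transcription_edges(
    genes: Sequence[GeneModel],
    hits: Iterable[MotifHit],
    promoter_nt: int = DEFAULT_PROMOTER_NT,
    require_conserved: bool = True,
) -> list[RegulatoryEdge]:
    """TF → gene transcription edges from motif hits in promoters."""
    gene_map = {g.gene_id: g for g in genes}
    by_chrom = _index_hits(hits, gene_map, "TF", require_conserved)
    edges: dict[tuple[str, str], list[MotifHit]] = defaultdict(list)
    for gene in genes:
        chrom_hits = by_chrom.get(gene.chrom)
        if not chrom_hits:
            continue
        promoter = promoter_interval(gene, promoter_nt)
        for h in chrom_hits:
            if _intersects(h.interval, promoter):
                edges[(h.factor_id, gene.gene_id)].append(h)
    return [
        RegulatoryEdge(src, tgt, "transcription", tuple(ev))
        for (src, tgt), ev in sorted(edges.items())
    ]


def assemble_network(
    genes: Sequence[GeneModel],
    splicing_edges: Iterable[RegulatoryEdge] = (),
    transcription_edges: Iterable[RegulatoryEdge] = (),
) -> RegulatoryNetwork:
    """Assemble the typed network and classify nodes into layers."""
    for g in genes:
        g.validate()
    return RegulatoryNetwork(genes, list(splicing_edges) + list(transcription_edges))


def build_network(
    genes: Sequence[GeneModel],
    sf_hits: Iterable[MotifHit],
    tf_hits: Iterable[MotifHit],
    window_nt: int = DEFAULT_WINDOW_NT,
    promoter_nt: int = DEFAULT_PROMOTER_NT,
    require_conserved: bool = True,
    dataset: str | None = None,
) -> RegulatoryNetwork:
    """Convenience wrapper: wire both edge types and assemble."""
    sp = build_splicing_edges(genes, sf_hits, window_nt, require_conserved, dataset)
    tr = build_transcription_edges(genes, tf_hits, promoter_nt, require_conserved)
    return assemble_network(genes, sp, tr)
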