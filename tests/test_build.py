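"""Edge-wiring rules: splicing windows, promoters, network assembly."""

import numpy as np
import pytest

from crossregnet import (
    ASEvent,
    GeneModel,
    GeneratorConfig,
    MotifHit,
    assemble_network,
    build_network,
    build_splicing_edges,
    build_transcription_edges,
    generate_gene_models,
    generate_motif_hits,
    promoter_interval,
    splicing_search_regions,
)
from crossregnet.build import _intersects


def make_gene(gene_id="G1", group="SF", strand="+", events=()):
    exons = [(8000, 8200), (9000, 9100), (10000, 10300)]
    tss = 8000 if strand == "+" else 10299
    return GeneModel(gene_id, group, f"chr_{gene_id}", strand, tss, exons, list(events))


def cassette_event(dataset="A"):
    return ASEvent("cassette", (9000, 9100), (8200, 9000), (9100, 10000), dataset)


# ---------------------------------------------------------------------------
# search regions
# ---------------------------------------------------------------------------

def test_cassette_regions_are_window_exon_window():
    ev = ASEvent("cassette", (1000, 1100), (800, 1000), (1100, 1400), "A")
    assert splicing_search_regions(ev, 100) == [(900, 1000), (1000, 1100), (1100, 1200)]


def test_alt3_has_no_downstream_region():
    ev = ASEvent("alt3", (1000, 1100), (800, 1000), None, "A")
    regions = splicing_search_regions(ev, 100)
    assert regions == [(900, 1000), (1000, 1100)]
    assert all(r[0] < 1100 for r in regions)


def test_alt5_has_no_upstream_region():
    ev = ASEvent("alt5", (1000, 1100), None, (1100, 1400), "A")
    assert splicing_search_regions(ev, 100) == [(1000, 1100), (1100, 1200)]


def test_short_intron_window_truncates_to_whole_intron():
    ev = ASEvent("cassette", (1000, 1100), (960, 1000), (1100, 1400), "A")
    assert splicing_search_regions(ev, 100)[0] == (960, 1000)


def test_minus_strand_alt3_searches_genomically_right_intron():
    # on -, the transcript-upstream intron lies genomically right of the exon
    ev = ASEvent("alt3", (1000, 1100), (1100, 1400), None, "A")
    assert splicing_search_regions(ev, 100) == [(1100, 1200), (1000, 1100)]


def test_unknown_event_type_rejected():
    with pytest.raises(ValueError):
        ASEvent("exitron", (0, 10), None, None, "A")


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def test_promoter_plus_strand_strictly_upstream():
    g = make_gene(strand="+")
    assert promoter_interval(g, 5000) == (3000, 8000)


def test_promoter_minus_strand_excludes_tss_base():
    g = make_gene(strand="-")
    assert promoter_interval(g, 5000) == (10300, 15300)


def test_promoter_clipped_at_chromosome_start():
    exons = [(1000, 1200), (2000, 2200)]
    g = GeneModel("G", "TF", "chrG", "+", 1000, exons)
    assert promoter_interval(g, 5000) == (0, 1000)


# ---------------------------------------------------------------------------
# splicing edges
# ---------------------------------------------------------------------------

def test_no_as_event_means_no_splicing_inedges():
    sf = make_gene("SF1", "SF", events=[cassette_event()])
    target = make_gene("T1", "TF")  # no events
    hit = MotifHit("SF1", "chr_T1", 9010, 9017, True)
    assert build_splicing_edges([sf, target], [hit]) == []


def test_hit_inside_event_exon_yields_edge():
    sf = make_gene("SF1", "SF")
    target = make_gene("T1", "TF", events=[cassette_event()])
    hit = MotifHit("SF1", "chr_T1", 9010, 9017, True)
    (edge,) = build_splicing_edges([sf, target], [hit])
    assert edge.key == ("SF1", "T1", "splicing")


def test_hit_beyond_intron_window_yields_no_edge():
    sf = make_gene("SF1", "SF")
    target = make_gene("T1", "TF", events=[cassette_event()])
    # upstream intron is (8200, 9000); window covers (8900, 9000)
    hit = MotifHit("SF1", "chr_T1", 8850, 8857, True)
    assert build_splicing_edges([sf, target], [hit]) == []


def test_one_nt_overlap_suffices():
    sf = make_gene("SF1", "SF")
    target = make_gene("T1", "TF", events=[cassette_event()])
    hit = MotifHit("SF1", "chr_T1", 8894, 8901, True)  # last base at 8900
    assert len(build_splicing_edges([sf, target], [hit])) == 1


def test_nonconserved_hit_filtered_unless_flag_dropped():
    sf = make_gene("SF1", "SF")
    target = make_gene("T1", "TF", events=[cassette_event()])
    hit = MotifHit("SF1", "chr_T1", 9010, 9017, conserved=False)
    assert build_splicing_edges([sf, target], [hit]) == []
    assert len(build_splicing_edges([sf, target], [hit], require_conserved=False)) == 1


def test_dataset_filter_separates_networks():
    sf = make_gene("SF1", "SF")
    target = make_gene("T1", "TF", events=[cassette_event(dataset="B")])
    hit = MotifHit("SF1", "chr_T1", 9010, 9017, True)
    assert build_splicing_edges([sf, target], [hit], dataset="A") == []
    assert len(build_splicing_edges([sf, target], [hit], dataset="B")) == 1


def test_unknown_factor_raises_with_id():
    sf = make_gene("SF1", "SF", events=[cassette_event()])
    with pytest.raises(KeyError, match="GHOST"):
        build_splicing_edges([sf], [MotifHit("GHOST", "chr_SF1", 9010, 9017, True)])


def test_autoregulation_self_loop_allowed():
    sf = make_gene("SF1", "SF", events=[cassette_event()])
    hit = MotifHit("SF1", "chr_SF1", 9010, 9017, True)
    (edge,) = build_splicing_edges([sf], [hit])
    assert edge.source == edge.target == "SF1"


# ---------------------------------------------------------------------------
# transcription edges
# ---------------------------------------------------------------------------

def test_hit_deep_in_promoter_yields_edge():
    tf = make_gene("TF1", "TF")
    target = make_gene("T1", "SF")
    hit = MotifHit("TF1", "chr_T1", 3001, 3011, True)  # 4999 nt upstream
    (edge,) = build_transcription_edges([tf, target], [hit])
    assert edge.key == ("TF1", "T1", "transcription")


def test_hit_starting_at_tss_is_not_promoter():
    tf = make_gene("TF1", "TF")
    target = make_gene("T1", "SF")  # + strand, tss 8000, promoter [3000, 8000)
    assert build_transcription_edges([tf, target], [MotifHit("TF1", "chr_T1", 8000, 8007, True)]) == []
    # overlapping the boundary from upstream still counts
    assert len(build_transcription_edges([tf, target], [MotifHit("TF1", "chr_T1", 7997, 8004, True)])) == 1


# ---------------------------------------------------------------------------
# assembly and layers
# ---------------------------------------------------------------------------

def test_layer_classification(network):
    ins = network.inedge_counts()
    outs = network.outedge_counts()
    for gid, layer in network.layers.items():
        i, o = ins[gid], outs[gid]
        expected = (
            "source" if o > 0 and i == 0
            else "mixed" if o > 0 and i > 0
            else "sink" if i > 0
            else "isolated"
        )
        assert layer == expected
        if network.genes[gid].group == "KINASE":
            assert layer in ("sink", "isolated")


def test_empty_edge_sets_all_isolated():
    genes = [make_gene("A", "SF"), make_gene("B", "TF"), make_gene("C", "KINASE")]
    net = assemble_network(genes)
    assert net.n_edges == 0
    assert set(net.layers.values()) == {"isolated"}


def test_duplicate_gene_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        assemble_network([make_gene("A"), make_gene("A")])


# ---------------------------------------------------------------------------
# oracle equivalence and invariants
# ---------------------------------------------------------------------------

def brute_force_edges(genes, hits, window_nt=100, promoter_nt=5000, dataset=None):
    """Independent oracle: scan all (hit, gene, region) triples directly."""
    edges = set()
    gmap = {g.gene_id: g for g in genes}
    for h in hits:
        if not h.conserved:
            continue
        group = gmap[h.factor_id].group
        for g in genes:
            if g.chrom != h.chrom:
                continue
            if group == "SF":
                for ev in g.events(dataset):
                    for r in splicing_search_regions(ev, window_nt):
                        if _intersects((h.start, h.end), r):
                            edges.add((h.factor_id, g.gene_id, "splicing"))
            elif group == "TF":
                if _intersects((h.start, h.end), promoter_interval(g, promoter_nt)):
                    edges.add((h.factor_id, g.gene_id, "transcription"))
    return edges


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_builder_matches_brute_force_scan(seed):
    cfg = GeneratorConfig(seed=seed, n_sf=6, n_tf=8, n_kinase=10)
    genes = generate_gene_models(cfg)
    hits, _ = generate_motif_hits(cfg, genes)
    # scatter extra random hits (not only planted ones) over the gene loci
    rng = np.random.default_rng(seed)
    regs = [g.gene_id for g in genes if g.is_regulator]
    for g in genes:
        for _ in range(3):
            start = int(rng.integers(0, g.exons[-1][1] + 6000))
            hits.append(
                MotifHit(regs[int(rng.integers(len(regs)))], g.chrom, start, start + 7,
                         bool(rng.random() < 0.8))
            )
    gmap = {g.gene_id: g for g in genes}
    sf_hits = [h for h in hits if gmap[h.factor_id].group == "SF"]
    tf_hits = [h for h in hits if gmap[h.factor_id].group == "TF"]
    net = build_network(genes, sf_hits, tf_hits, dataset="A")
    assert net.edge_keys() == brute_force_edges(genes, hits, dataset="A")


def test_edge_set_independent_of_hit_order(bundle, network, default_config):
    net2 = build_network(
        bundle.genes,
        list(reversed(bundle.sf_hits)),
        list(reversed(bundle.tf_hits)),
        dataset=default_config.dataset,
    )
    assert net2.edge_keys() == network.edge_keys()


def test_wider_windows_never_remove_edges(bundle, default_config):
    narrow = build_network(bundle.genes, bundle.sf_hits, bundle.tf_hits,
                           window_nt=50, promoter_nt=2500, dataset=default_config.dataset)
    wide = build_network(bundle.genes, bundle.sf_hits, bundle.tf_hits,
                         window_nt=200, promoter_nt=8000, dataset=default_config.dataset)
    assert narrow.edge_keys() <= wide.edge_keys()


def test_planted_edges_recovered_exactly(bundle, network):
    planted = {tuple(e) for e in bundle.ground_truth["planted_edges"]}
    assert network.edge_keys() == planted
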