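"""Generator: determinism, planted structure, analytic expectations."""

import json

import numpy as np
import pytest

from crossregnet import (
    GeneratorConfig,
    build_network,
    expected_inedge_means,
    generate_bundle,
    generate_expression_atlas,
    generate_gene_models,
    generate_motif_hits,
    generate_protein_annotations,
    generate_sequence_sets,
    inedge_density,
    tissue_filter,
)
from crossregnet.enrich import hit_fraction


def small_cfg(**kw):
    defaults = dict(seed=3, n_sf=6, n_tf=10, n_kinase=12, n_background=50,
                    n_random_proteins=30, n_bound=30, n_control=50,
                    above_mean_counts={"heart": {"SF": 3, "TF": 5, "KINASE": 4},
                                       "smooth_muscle": {"SF": 2, "TF": 6, "KINASE": 4}})
    defaults.update(kw)
    return GeneratorConfig(**defaults)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def test_gene_models_are_valid_and_grouped(default_config, bundle):
    groups = [g.group for g in bundle.genes]
    assert groups.count("SF") == default_config.n_sf
    assert groups.count("TF") == default_config.n_tf
    assert groups.count("KINASE") == default_config.n_kinase
    for g in bundle.genes:
        g.validate()  # exons sorted/disjoint, TSS strand-consistent


def test_zero_as_rate_gives_zero_events_and_edges():
    cfg = small_cfg(as_rate={g: {"A": 0.0, "B": 0.0} for g in ("SF", "TF", "KINASE")})
    genes = generate_gene_models(cfg)
    assert all(not g.as_events for g in genes)
    hits, planted = generate_motif_hits(cfg, genes)
    assert not any(t == "splicing" for _, _, t in planted)


def test_seed_determinism_byte_level(tmp_path):
    from crossregnet import io

    paths = []
    for run in ("a", "b"):
        cfg = small_cfg()
        b = generate_bundle(cfg)
        out = tmp_path / run
        out.mkdir()
        io.write_gene_models(b.genes, out / "genes.tsv", out / "events.tsv")
        io.write_motif_hits(b.hits, out / "hits.bed")
        io.write_atlas(b.atlas, out / "atlas.tsv")
        io.write_annotations(b.annotations, out / "annot.tsv")
        io.write_sequences(b.sequences, out / "bound.fa", out / "control.fa")
        io.write_json(b.ground_truth, out / "truth.json")
        paths.append(out)
    for f in sorted(p.name for p in paths[0].iterdir()):
        assert (paths[0] / f).read_bytes() == (paths[1] / f).read_bytes()


def test_configured_as_event_ordering_holds_across_seeds():
    # SFs must stochastically dominate TFs and kinases in AS events per gene
    wins = 0
    n_seeds = 30
    for seed in range(n_seeds):
        cfg = GeneratorConfig(seed=seed, n_sf=60, n_tf=60, n_kinase=60)
        genes = generate_gene_models(cfg)
        means = {}
        for grp in ("SF", "TF", "KINASE"):
            means[grp] = np.mean(
                [len(g.as_events) for g in genes if g.group == grp]
            )
        if means["SF"] > means["TF"] and means["SF"] > means["KINASE"]:
            wins += 1
    assert wins >= 0.95 * n_seeds


def test_kinase_genes_longer_with_more_exons():
    cfg = GeneratorConfig(seed=0, n_sf=150, n_tf=150, n_kinase=150)
    genes = generate_gene_models(cfg)
    by = lambda grp, f: np.median([f(g) for g in genes if g.group == grp])
    assert by("KINASE", lambda g: g.length) > by("SF", lambda g: g.length)
    assert by("KINASE", lambda g: len(g.exons)) > by("TF", lambda g: len(g.exons))


def test_zero_group_with_positive_rate_rejected():
    with pytest.raises(ValueError, match="size 0"):
        GeneratorConfig(n_sf=0).validate()


# ---------------------------------------------------------------------------
# motif hits / planted edges
# ---------------------------------------------------------------------------

def test_zero_p_matrix_gives_empty_network():
    cfg = small_cfg(p_edge={"splicing": dict.fromkeys(("SF", "TF", "KINASE"), 0.0),
                            "transcription": dict.fromkeys(("SF", "TF", "KINASE"), 0.0)})
    genes = generate_gene_models(cfg)
    hits, planted = generate_motif_hits(cfg, genes)
    assert hits == [] and planted == []


def test_saturated_splicing_probability_counts():
    # p[splicing][SF] = 1: every AS-eligible SF receives exactly n_sf inedges
    cfg = small_cfg(
        as_rate={"SF": {"A": 30.0, "B": 0.0}, "TF": {"A": 0.0, "B": 0.0},
                 "KINASE": {"A": 0.0, "B": 0.0}},
        p_edge={"splicing": {"SF": 1.0, "TF": 0.0, "KINASE": 0.0},
                "transcription": dict.fromkeys(("SF", "TF", "KINASE"), 0.0)},
    )
    genes = generate_gene_models(cfg)
    hits, planted = generate_motif_hits(cfg, genes)
    sf_ids = [g.gene_id for g in genes if g.group == "SF"]
    assert all(g.events("A") for g in genes if g.group == "SF")  # rate 30 => eligible
    net = build_network(genes, hits, [], dataset="A")
    counts = net.inedge_counts("splicing")
    assert all(counts[gid] == cfg.n_sf for gid in sf_ids)


def test_saturated_transcription_probability_counts():
    cfg = small_cfg(
        p_edge={"splicing": dict.fromkeys(("SF", "TF", "KINASE"), 0.0),
                "transcription": {"SF": 0.0, "TF": 1.0, "KINASE": 0.0}},
    )
    genes = generate_gene_models(cfg)
    hits, _ = generate_motif_hits(cfg, genes)
    net = build_network(genes, [], hits, dataset="A")
    counts = net.inedge_counts("transcription")
    for g in genes:
        assert counts[g.gene_id] == (cfg.n_tf if g.group == "TF" else 0)


def test_inedge_means_match_analytic_expectation():
    """Binomial calibration: mean inedges per group ~ p x n_reg x eligibility."""
    n_rep = 40
    sums = {("splicing", "SF"): 0.0, ("splicing", "TF"): 0.0}
    expected = {("splicing", "SF"): 0.0, ("splicing", "TF"): 0.0}
    cfg0 = GeneratorConfig()
    for seed in range(n_rep):
        cfg = GeneratorConfig(seed=seed)
        genes = generate_gene_models(cfg)
        hits, _ = generate_motif_hits(cfg, genes)
        gmap = {g.gene_id: g.group for g in genes}
        sf_hits = [h for h in hits if gmap[h.factor_id] == "SF"]
        net = build_network(genes, sf_hits, [], dataset="A")
        dens = inedge_density(net, "splicing")
        exp = expected_inedge_means(cfg, genes)
        for grp in ("SF", "TF"):
            sums[("splicing", grp)] += dens[grp].mean
            expected[("splicing", grp)] += exp[("splicing", grp)]
    for key in sums:
        grp = key[1]
        n = {"SF": cfg0.n_sf, "TF": cfg0.n_tf}[grp]
        p = cfg0.p_edge["splicing"][grp]
        # binomial se of the grand mean over n_rep x n genes x n_sf trials
        se = np.sqrt(p * (1 - p) * cfg0.n_sf / (n * n_rep))
        assert sums[key] / n_rep == pytest.approx(expected[key] / n_rep, abs=3 * se)


# ---------------------------------------------------------------------------
# expression atlas
# ---------------------------------------------------------------------------

def test_atlas_planting_is_exact(bundle, network, default_config):
    for tissue, counts in default_config.above_mean_counts.items():
        kept = tissue_filter(bundle.atlas, network, tissue)
        assert sorted(kept) == bundle.ground_truth["atlas_above_mean"][tissue]
        kept_groups = {g: 0 for g in ("SF", "TF", "KINASE")}
        for gid in kept:
            kept_groups[network.genes[gid].group] += 1
        assert kept_groups == counts


def test_atlas_all_above_or_below():
    cfg = small_cfg(tissues=("t0",), above_mean_counts={"t0": {"SF": 6, "TF": 10, "KINASE": 12}})
    genes = generate_gene_models(cfg)
    atlas, planted = generate_expression_atlas(cfg, genes)
    mean = atlas.tissue_mean("t0")
    assert all(atlas.values.loc[g.gene_id, "t0"] > mean for g in genes)
    cfg2 = small_cfg(tissues=("t0",), above_mean_counts={"t0": {}})
    atlas2, _ = generate_expression_atlas(cfg2, genes)
    mean2 = atlas2.tissue_mean("t0")
    assert all(atlas2.values.loc[g.gene_id, "t0"] < mean2 for g in genes)


def test_atlas_mean_is_over_all_genes(bundle):
    for t in bundle.atlas.tissues:
        col = bundle.atlas.values[t]
        assert bundle.atlas.tissue_mean(t) == pytest.approx(col.mean())
        assert len(col) == len(bundle.genes) + bundle.config.n_background


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def test_zero_phospho_rate_gives_no_sites():
    cfg = small_cfg(phospho_prob=dict.fromkeys(("SF", "TF", "KINASE"), 0.0))
    genes = generate_gene_models(cfg)
    annots = generate_protein_annotations(cfg, genes)
    assert all(not a.phospho_positions for a in annots if a.group != "RANDOM")


def test_disorder_scores_respect_cutoff_band():
    cfg = small_cfg()
    genes = generate_gene_models(cfg)
    annots = generate_protein_annotations(cfg, genes)
    for a in annots[:20]:
        assert a.disorder_scores.min() >= 0.0
        assert a.disorder_scores.max() <= 1.0
        assert len(a.disorder_scores) == a.length


def test_kinase_phospho_ordering_across_seeds():
    from crossregnet import phospho_summary

    wins = 0
    n_seeds = 25
    for seed in range(n_seeds):
        cfg = GeneratorConfig(seed=seed, n_sf=50, n_tf=50, n_kinase=50,
                              n_random_proteins=0)
        genes = generate_gene_models(cfg)
        annots = generate_protein_annotations(cfg, genes)
        summ = phospho_summary(annots).set_index("group")
        if summ.loc["KINASE", "frac_with_site"] == summ["frac_with_site"].max():
            wins += 1
    assert wins >= 0.95 * n_seeds


# ---------------------------------------------------------------------------
# sequence sets
# ---------------------------------------------------------------------------

def test_planted_hit_indicator_is_exact():
    cfg = small_cfg(q_bound=1.0, q_control=0.0, n_bound=20, n_control=20)
    seqs, planted = generate_sequence_sets(cfg)
    assert hit_fraction(seqs.bound, cfg.motif) == 1.0
    assert hit_fraction(seqs.control, cfg.motif) == 0.0
    assert planted == {"bound": 20, "control": 0}


def test_bound_hit_fraction_matches_planting_rate():
    cfg = GeneratorConfig(seed=9, n_bound=4000, n_control=10)
    seqs, _ = generate_sequence_sets(cfg)
    # binomial se at q=0.75, n=4000 is ~0.007
    assert hit_fraction(seqs.bound, cfg.motif) == pytest.approx(0.75, abs=0.025)


def test_overlong_motif_rejected():
    with pytest.raises(ValueError, match="motif"):
        GeneratorConfig(motif="A" * 42).validate()


def test_ground_truth_json_serializable(bundle):
    assert json.loads(json.dumps(bundle.ground_truth)) is not None
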