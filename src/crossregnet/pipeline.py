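"""End-to-end orchestration: generate (or load) → build → analyze → report.

One global seed fans out to per-stage child seeds, so the full run is
reproducible and stages can be re-run in isolation. The run report is a
plain nested dict (JSON-serializable, fully deterministic under a fixed
seed); per-stage tables are written as TSV when an output directory is
given.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .annot import disorder_summary, phospho_summary
from .build import build_network
from .density import (
    inedge_density,
    mann_whitney,
    random_group_control,
    splicing_transcription_correlation,
)
from .enrich import fisher_enrichment, hit_fraction
from .models import GROUPS, GeneModel, RegulatoryEdge, RegulatoryNetwork
from .pairs import pair_coregulation_scan, pair_coverage, significant_pairs
from .props import clustering_coefficient, null_zscore, sparseness
from .synth import GeneratorConfig, SyntheticBundle, generate_bundle
from .tissue import induce_subnetwork, tissue_filter

logger = logging.getLogger("crossregnet")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    dataset: str = "A"
    null_model: str = "degree_swap"
    n_random: int = 1000
    alpha: float = 1e-16
    n_control_iter: int = 100
    seed: int = 0
    outdir: str | None = None


def _log10(p: float) -> float:
    return math.log10(p) if p > 0 else -math.inf


def _density_section(network: RegulatoryNetwork) -> dict:
    section: dict = {"means": {}, "mw_tests": {}, "correlations": {}}
    counts = {}
    for edge_type in ("splicing", "transcription"):
        dens = inedge_density(network, edge_type)
        for grp, d in dens.items():
            section["means"][f"{edge_type}:{grp}"] = {
                "mean": d.mean, "sem": d.sem, "n": len(d.per_node_counts),
            }
            counts[(edge_type, grp)] = d.counts
    comparisons = [
        ("splicing", "SF", "TF"), ("splicing", "SF", "KINASE"),
        ("transcription", "TF", "SF"), ("transcription", "TF", "KINASE"),
    ]
    for edge_type, a, b in comparisons:
        res = mann_whitney(counts[(edge_type, a)], counts[(edge_type, b)])
        section["mw_tests"][f"{edge_type}:{a}_vs_{b}"] = {
            "U": res.U, "p": res.p, "log10_p": _log10(res.p), "method": res.method,
        }
    for grp in GROUPS:
        c = splicing_transcription_correlation(network, grp)
        section["correlations"][grp] = {"rho": c.rho, "n": c.n}
    return section


def run_pipeline(config: PipelineConfig, bundle: SyntheticBundle | None = None) -> dict:
    """Run every stage on a generated (or supplied) bundle; return the report."""
    gen = config.generator
    if bundle is None:
        logger.info("generating synthetic bundle (seed=%d)", gen.seed)
        bundle = generate_bundle(gen)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "config": {
            "seed": config.seed,
            "generator_seed": gen.seed,
            "dataset": config.dataset,
            "null_model": config.null_model,
            "n_random": config.n_random,
            "alpha": config.alpha,
        }
    }
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    # build ---------------------------------------------------------------
    logger.info("building network (dataset %s)", config.dataset)
    network = build_network(
        bundle.genes, bundle.sf_hits, bundle.tf_hits,
        window_nt=gen.window_nt, promoter_nt=gen.promoter_nt,
        dataset=config.dataset,
    )
    layer_counts = pd.Series(network.layers).value_counts().to_dict()
    report["network"] = {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "n_splicing_edges": sum(e.edge_type == "splicing" for e in network.edges),
        "n_transcription_edges": sum(e.edge_type == "transcription" for e in network.edges),
        "layers": {k: int(v) for k, v in sorted(layer_counts.items())},
    }

    # props ---------------------------------------------------------------
    logger.info("network properties (%s null, n_random=%d)", config.null_model, config.n_random)
    ens = null_zscore(
        network, null_model=config.null_model,
        n_random=config.n_random, seed=stage_seeds[0],
    )
    report["properties"] = {
        "clustering_coefficient": ens.observed_stat,
        "clustering_null_mean": ens.null_mean,
        "clustering_null_sd": ens.null_sd,
        "clustering_z": ens.z,
        "clustering_empirical_p": ens.empirical_p,
        "sparseness": {
            conv: sparseness(network, conv)
            for conv in ("typed_bipartite", "simple_n2", "e_squared")
        },
    }

    # density + control ---------------------------------------------------
    logger.info("inedge densities and group comparisons")
    report["density"] = _density_section(network)
    control = random_group_control(
        network, n_iter=config.n_control_iter, seed=stage_seeds[1]
    )
    report["random_group_control"] = {
        f"{row.pseudo_group}:{row.edge_type}": {"mean": row.mean, "sd": row.sd}
        for row in control.summary.itertuples()
    }

    # combinatorial pairs -------------------------------------------------
    logger.info("combinatorial pair scan (alpha=%g)", config.alpha)
    results = pair_coregulation_scan(network, alpha=config.alpha)
    report["pairs"] = {
        "n_significant": {
            cls: len(significant_pairs(results, cls))
            for cls in ("SF-SF", "TF-TF", "SF-TF")
        },
        "coverage": {grp: pair_coverage(results, network, grp) for grp in GROUPS},
    }

    # tissue --------------------------------------------------------------
    if bundle.atlas is not None:
        report["tissues"] = {}
        for t in bundle.atlas.tissues:
            kept = tissue_filter(bundle.atlas, network, t)
            sub, table = induce_subnetwork(network, kept)
            groups_kept = sub.group_sizes()
            report["tissues"][t] = {
                "n_nodes": sub.n_nodes,
                "n_sf": groups_kept["SF"],
                "n_tf": groups_kept["TF"],
                "densities": {
                    f"{row.edge_type}:{row.group}": {"mean": row.mean, "sem": row.sem}
                    for row in table.itertuples()
                },
            }
            if outdir:
                table.to_csv(outdir / f"tissue_{t}_density.tsv", sep="\t", index=False)
    else:
        report["tissues"] = None
        logger.info("no expression atlas: tissue stage skipped")

    # sequence enrichment -------------------------------------------------
    if bundle.sequences is not None:
        enr = fisher_enrichment(
            bundle.sequences.bound, bundle.sequences.control, gen.motif
        )
        report["enrichment"] = {
            "motif": gen.motif,
            "bound_hit_fraction": hit_fraction(bundle.sequences.bound, gen.motif),
            "control_hit_fraction": hit_fraction(bundle.sequences.control, gen.motif),
            "fisher_p": enr.p,
            "fisher_log10_p": enr.log10_p,
            "odds_ratio": enr.odds_ratio,
        }
    else:
        report["enrichment"] = None

    # annotations ---------------------------------------------------------
    if bundle.annotations:
        net_annot = [a for a in bundle.annotations if a.group != "RANDOM"]
        ph = phospho_summary(net_annot)
        dis = disorder_summary(
            net_annot, random_pool=bundle.random_proteins, seed=stage_seeds[2]
        )
        report["annotations"] = {
            "phospho": {
                row.group: {
                    "frac_with_site": row.frac_with_site,
                    "frac_high_coverage": row.frac_high_coverage,
                    "mean_site_density": row.mean_site_density,
                }
                for row in ph.itertuples()
            },
            "disorder": {
                row.group: {
                    "mean_disordered_fraction": row.mean_disordered_fraction,
                    "frac_long_disordered": row.frac_long_disordered,
                }
                for row in dis.itertuples()
            },
        }
    else:
        report["annotations"] = None

    # outputs -------------------------------------------------------------
    if outdir:
        io.write_network(network, outdir / "edges.tsv", outdir / "nodes.tsv")
        pd.DataFrame(
            [
                {
                    "factor_a": r.factor_a, "factor_b": r.factor_b,
                    "pair_class": r.pair_class, "k_overlap": r.k_overlap,
                    "K_a": r.K_a, "n_b": r.n_b, "log10_p": r.log10_p,
                    "significant": r.significant,
                }
                for r in results
            ]
        ).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        control.summary.to_csv(outdir / "random_group_control.tsv", sep="\t", index=False)
        io.write_json(report, outdir / "report.json")
    return report


# ---------------------------------------------------------------------------
# supplementary-table recomputation path
# ---------------------------------------------------------------------------

@dataclass
class SupplementaryData:
    """A per-node inedge table, optionally with full regulator identities.

    ``capabilities`` marks which downstream stages the file supports:
    counts-only exports enable density/correlation/MW recomputation, while
    identity-list exports additionally enable clustering and pair tests via
    the reconstructed network.
    """

    counts: pd.DataFrame  # index gene_id; columns group, splicing_inedges, transcription_inedges
    network: RegulatoryNetwork | None
    capabilities: frozenset[str]


def load_supplementary_network(path) -> SupplementaryData:
    """Load a per-node inedge TSV (spreadsheet export) in either dialect.

    Counts dialect: columns ``gene_id, group, splicing_inedges,
    transcription_inedges``. Identity dialect: ``gene_id, group,
    splicing_regulators, transcription_regulators`` with semicolon-separated
    regulator ids ('.' for none); counts are derived and a network is built.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    bad_group = df.index[~df["group"].isin(GROUPS)].tolist()
    if bad_group:
        raise ValueError(f"{path}: invalid group labels on rows {[i + 2 for i in bad_group]}")

    identity = {"splicing_regulators", "transcription_regulators"} <= set(df.columns)
    counts_only = {"splicing_inedges", "transcription_inedges"} <= set(df.columns)
    if not identity and not counts_only:
        raise ValueError(
            f"{path}: need either regulator-identity or inedge-count columns"
        )

    genes = [
        GeneModel(row["gene_id"], row["group"], f"chr_{row['gene_id']}", "+", 0, [(0, 1)])
        for _, row in df.iterrows()
    ]
    if identity:
        known = {g.gene_id for g in genes}
        edges, bad_rows = [], []
        for i, row in df.iterrows():
            for col, edge_type in (
                ("splicing_regulators", "splicing"),
                ("transcription_regulators", "transcription"),
            ):
                cell = row[col]
                if pd.isna(cell) or cell == ".":
                    continue
                for reg in str(cell).split(";"):
                    reg = reg.strip()
                    if not reg:
                        continue
                    if reg not in known:
                        bad_rows.append((i + 2, reg))
                        continue
                    edges.append(RegulatoryEdge(reg, row["gene_id"], edge_type))
        if bad_rows:
            raise ValueError(f"{path}: unknown regulator ids at rows {bad_rows}")
        network = RegulatoryNetwork(genes, edges)
        sp = network.inedge_counts("splicing")
        tr = network.inedge_counts("transcription")
        counts = pd.DataFrame(
            {
                "group": {g.gene_id: g.group for g in genes},
                "splicing_inedges": sp,
                "transcription_inedges": tr,
            }
        )
        caps = frozenset({"density", "correlation", "mw", "control", "clustering", "pairs"})
        return SupplementaryData(counts, network, caps)

    try:
        counts = pd.DataFrame(
            {
                "group": df.set_index("gene_id")["group"],
                "splicing_inedges": df.set_index("gene_id")["splicing_inedges"].astype(int),
                "transcription_inedges": df.set_index("gene_id")["transcription_inedges"].astype(int),
            }
        )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed inedge counts ({exc})") from exc
    if (counts[["splicing_inedges", "transcription_inedges"]] < 0).any().any():
        raise ValueError(f"{path}: negative inedge counts")
    caps = frozenset({"density", "correlation", "mw", "control"})
    return SupplementaryData(counts, None, caps)


def recompute_from_counts(counts: pd.DataFrame) -> dict:
    """Density means ± sem, the MW group comparisons and Spearman
    correlations, recomputed directly from a per-node inedge table."""
    from scipy import stats

    out: dict = {"means": {}, "mw_tests": {}, "correlations": {}}
    cols = {"splicing": "splicing_inedges", "transcription": "transcription_inedges"}
    by_group = {
        grp: counts[counts["group"] == grp] for grp in GROUPS
    }
    for edge_type, col in cols.items():
        for grp, sub in by_group.items():
            vals = sub[col].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
            out["means"][f"{edge_type}:{grp}"] = {
                "mean": float(vals.mean()), "sem": sem, "n": len(vals),
            }
    for edge_type, a, b in [
        ("splicing", "SF", "TF"), ("splicing", "SF", "KINASE"),
        ("transcription", "TF", "SF"), ("transcription", "TF", "KINASE"),
    ]:
        col = cols[edge_type]
        if len(by_group[a]) and len(by_group[b]):
            res = mann_whitney(by_group[a][col], by_group[b][col])
            out["mw_tests"][f"{edge_type}:{a}_vs_{b}"] = {
                "U": res.U, "p": res.p, "method": res.method,
            }
    for grp, sub in by_group.items():
        x = sub["splicing_inedges"].to_numpy(dtype=float)
        y = sub["transcription_inedges"].to_numpy(dtype=float)
        if len(x) >= 2 and len(set(x)) > 1 and len(set(y)) > 1:
            rho = float(stats.spearmanr(x, y).statistic)
        else:
            rho = math.nan
        out["correlations"][grp] = {"rho": rho, "n": len(x)}
    return out
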