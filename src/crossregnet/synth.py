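"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates every external resource the pipeline consumes:
gene models with group-specific length/exon/AS-event distributions, conserved
motif-hit tables with plantable cross-regulation vs cross-talk enrichment,
a gene × tissue expression atlas with plantable above-mean factors, residue-
level protein annotations (phosphorylation sites, disorder scores), and
41-nt bound/control sequence sets with a plantable motif.

Distributional choices: gene lengths are log-normal, exon counts shifted
negative-binomial and AS-event counts Poisson, each with group-specific
parameters chosen so that kinase genes are the longest with the most exons
while SF genes carry the most AS events. Regulatory edges are planted
independently per (regulator, eligible target) pair with probability
``p_edge[edge_type][target_group]``; hits are placed strictly inside the
target's eligible region (AS-event search windows for SFs, the promoter for
TFs), so the network builder recovers exactly the planted edge set. Because
a splicing edge requires the target to carry an AS event, the expected mean
splicing inedges of a group is p × n_SF × (eligible fraction of the group).

All coordinates are 0-based half-open on one synthetic chromosome per gene.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .annot import ProteinAnnotation
from .build import promoter_interval, splicing_search_regions
from .enrich import SequenceSet, _motif_regex
from .models import ASEvent, DATASETS, GROUPS, GeneModel, MotifHit
from .tissue import ExpressionAtlas

_STAGE = {"genes": 0, "hits": 1, "atlas": 2, "annotations": 3, "sequences": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STAGE[stage])))


def _groups_dict(sf, tf, kinase) -> dict[str, float]:
    return {"SF": sf, "TF": tf, "KINASE": kinase}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generator.

    Defaults reproduce the composition of the real network (20 SFs, 90 TFs,
    147 kinases) and plant edge probabilities matching the reported group
    inedge means divided by the number of regulators of each type.
    """

    seed: int = 0
    n_sf: int = 20
    n_tf: int = 90
    n_kinase: int = 147

    # gene architecture, per group
    length_log_mean: dict = field(
        default_factory=lambda: _groups_dict(math.log(25_000), math.log(25_000), math.log(60_000))
    )
    length_log_sd: dict = field(default_factory=lambda: _groups_dict(0.6, 0.6, 0.6))
    exon_count_mean: dict = field(default_factory=lambda: _groups_dict(11.0, 10.0, 16.0))
    exon_count_shape: float = 5.0  # negative-binomial dispersion (larger = tighter)

    # AS events per gene: Poisson rate per group and dataset tag
    as_rate: dict = field(
        default_factory=lambda: {
            "SF": {"A": 3.0, "B": 3.5},
            "TF": {"A": 1.5, "B": 1.8},
            "KINASE": {"A": 1.2, "B": 1.4},
        }
    )
    event_type_probs: tuple = (0.6, 0.2, 0.2)  # cassette, alt3, alt5

    # motif planting: p_edge[edge_type][target_group]
    p_edge: dict = field(
        default_factory=lambda: {
            "splicing": _groups_dict(0.20, 0.05, 0.05),
            "transcription": _groups_dict(0.059, 0.092, 0.037),
        }
    )
    dataset: str = "A"  # dataset whose event windows receive planted SF hits
    promoter_nt: int = 5000
    window_nt: int = 100
    motif_hit_len: int = 7

    # expression atlas
    tissues: tuple = ("heart", "smooth_muscle")
    above_mean_counts: dict = field(
        default_factory=lambda: {
            "heart": {"SF": 14, "TF": 33, "KINASE": 60},
            "smooth_muscle": {"SF": 11, "TF": 40, "KINASE": 60},
        }
    )
    default_above_prob: float = 0.4
    n_background: int = 1000

    # protein annotations
    protein_log_mean: float = math.log(500.0)
    protein_log_sd: float = 0.4
    phospho_prob: dict = field(default_factory=lambda: _groups_dict(0.49, 0.42, 0.77))
    phospho_rate: dict = field(default_factory=lambda: _groups_dict(0.12, 0.05, 0.10))
    disorder_frac: dict = field(
        default_factory=lambda: {"SF": 0.50, "TF": 0.55, "KINASE": 0.25, "RANDOM": 0.30}
    )
    disorder_seg_len: dict = field(
        default_factory=lambda: {"SF": 45.0, "TF": 45.0, "KINASE": 12.0, "RANDOM": 20.0}
    )
    n_random_proteins: int = 400

    # sequence sets
    motif: str = "CTCTCT"
    q_bound: float = 0.75
    q_control: float = 0.02
    n_bound: int = 200
    n_control: int = 1000

    def validate(self) -> None:
        for name in ("n_sf", "n_tf", "n_kinase", "n_background", "n_bound", "n_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        sizes = _groups_dict(self.n_sf, self.n_tf, self.n_kinase)
        for grp in GROUPS:
            if sizes[grp] == 0 and any(r > 0 for r in self.as_rate[grp].values()):
                raise ValueError(
                    f"group {grp} has size 0 but positive AS-event rate"
                )
        for t, row in self.p_edge.items():
            for grp, p in row.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"p_edge[{t}][{grp}]={p} outside [0,1]")
        for q in (self.q_bound, self.q_control, self.default_above_prob):
            if not 0.0 <= q <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.dataset not in DATASETS:
            raise ValueError(f"unknown dataset tag {self.dataset!r}")
        if abs(sum(self.event_type_probs) - 1.0) > 1e-9:
            raise ValueError("event_type_probs must sum to 1")
        if len(self.motif) > 41:
            raise ValueError("motif longer than the 41-nt sequence length")

    def group_sizes(self) -> dict[str, int]:
        return _groups_dict(self.n_sf, self.n_tf, self.n_kinase)


@dataclass
class SyntheticBundle:
    """Everything one pipeline run needs, plus the planted ground truth."""

    config: GeneratorConfig
    genes: list[GeneModel]
    hits: list[MotifHit]
    atlas: ExpressionAtlas
    annotations: list[ProteinAnnotation]  # network groups + RANDOM pool
    sequences: SequenceSet
    ground_truth: dict

    @property
    def sf_hits(self) -> list[MotifHit]:
        sf_ids = {g.gene_id for g in self.genes if g.group == "SF"}
        return [h for h in self.hits if h.factor_id in sf_ids]

    @property
    def tf_hits(self) -> list[MotifHit]:
        tf_ids = {g.gene_id for g in self.genes if g.group == "TF"}
        return [h for h in self.hits if h.factor_id in tf_ids]

    @property
    def random_proteins(self) -> list[ProteinAnnotation]:
        return [a for a in self.annotations if a.group == "RANDOM"]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_UPSTREAM_PAD = 8000  # room left of the gene for a 5 kb promoter


def _gene_ids(config: GeneratorConfig) -> list[tuple[str, str]]:
    ids = []
    ids += [(f"SF{i:03d}", "SF") for i in range(config.n_sf)]
    ids += [(f"TF{i:03d}", "TF") for i in range(config.n_tf)]
    ids += [(f"KIN{i:03d}", "KINASE") for i in range(config.n_kinase)]
    return ids


def _sample_events(
    rng: np.random.Generator,
    config: GeneratorConfig,
    group: str,
    strand: str,
    exons: list[tuple[int, int]],
    introns: list[tuple[int, int]],
) -> list[ASEvent]:
    events = []
    n_exons = len(exons)
    for dataset in DATASETS:
        k = rng.poisson(config.as_rate[group][dataset])
        for _ in range(k):
            etype = ("cassette", "alt3", "alt5")[
                rng.choice(3, p=np.asarray(config.event_type_probs))
            ]
            if etype == "cassette" and n_exons < 3:
                etype = "alt3" if rng.random() < 0.5 else "alt5"
            # pick an exon with the introns the event type searches
            if etype == "cassette":
                idx = int(rng.integers(1, n_exons - 1))
            else:
                needs_right_gap = (etype == "alt3") == (strand == "-")
                # alt3 searches the transcript-upstream intron, alt5 the
                # downstream one; which genomic gap that is depends on strand
                idx = int(rng.integers(0, n_exons - 1)) if needs_right_gap else int(
                    rng.integers(1, n_exons)
                )
            left = introns[idx - 1] if idx > 0 else None
            right = introns[idx] if idx < n_exons - 1 else None
            up, down = (left, right) if strand == "+" else (right, left)
            if etype == "alt3":
                down = None
            elif etype == "alt5":
                up = None
            events.append(ASEvent(etype, exons[idx], up, down, dataset))
    return events


def generate_gene_models(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Gene models with group-specific length, exon-count and AS-event
    distributions, one synthetic chromosome per gene."""
    config.validate()
    rng = rng or _stage_rng(config.seed, "genes")
    genes = []
    for gene_id, group in _gene_ids(config):
        n_exons = 2 + int(
            rng.negative_binomial(
                config.exon_count_shape,
                config.exon_count_shape
                / (config.exon_count_shape + config.exon_count_mean[group] - 2),
            )
        )
        exon_lens = np.clip(
            np.round(rng.lognormal(math.log(150), 0.5, size=n_exons)), 20, 2000
        ).astype(int)
        target_len = rng.lognormal(
            config.length_log_mean[group], config.length_log_sd[group]
        )
        n_introns = n_exons - 1
        leftover = max(0.0, target_len - exon_lens.sum() - 300 * n_introns)
        extra = (
            rng.multinomial(int(leftover), np.full(n_introns, 1.0 / n_introns))
            if n_introns > 0 and leftover >= 1
            else np.zeros(n_introns, dtype=int)
        )
        intron_lens = 300 + extra

        strand = "+" if rng.random() < 0.5 else "-"
        pos = _UPSTREAM_PAD
        exons, introns = [], []
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_introns:
                introns.append((pos, pos + int(intron_lens[i])))
                pos += int(intron_lens[i])
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        events = _sample_events(rng, config, group, strand, exons, introns)
        gene = GeneModel(gene_id, group, f"chr_{gene_id}", strand, tss, exons, events)
        gene.validate()
        genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# motif hits
# ---------------------------------------------------------------------------

def generate_motif_hits(
    config: GeneratorConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[list[MotifHit], list[tuple[str, str, str]]]:
    """Plant conserved motif hits realizing independent Bernoulli edges.

    For each ordered (regulator, target) pair an edge is planted with
    probability ``p_edge[edge_type][target_group]``; splicing edges only for
    targets carrying at least one AS event of ``config.dataset``. Each
    planted edge is realized by one hit placed strictly inside an eligible
    region, so the builder recovers exactly the planted edge set. Returns
    (hits, planted edges as (source, target, edge_type) tuples).
    """
    rng = rng or _stage_rng(config.seed, "hits")
    sfs = [g.gene_id for g in genes if g.group == "SF"]
    tfs = [g.gene_id for g in genes if g.group == "TF"]
    hlen = config.motif_hit_len
    hits: list[MotifHit] = []
    planted: list[tuple[str, str, str]] = []
    for gene in genes:
        events = gene.events(config.dataset)
        p_sp = config.p_edge["splicing"][gene.group]
        p_tr = config.p_edge["transcription"][gene.group]
        for sf in sfs:
            if events and rng.random() < p_sp:
                event = events[int(rng.integers(len(events)))]
                regions = [
                    r
                    for r in splicing_search_regions(event, config.window_nt)
                    if r[1] - r[0] >= hlen
                ]
                region = regions[int(rng.integers(len(regions)))]
                start = int(rng.integers(region[0], region[1] - hlen + 1))
                hits.append(MotifHit(sf, gene.chrom, start, start + hlen, True))
                planted.append((sf, gene.gene_id, "splicing"))
        if p_tr > 0:
            promoter = promoter_interval(gene, config.promoter_nt)
            for tf in tfs:
                if rng.random() < p_tr:
                    start = int(rng.integers(promoter[0], promoter[1] - hlen + 1))
                    hits.append(MotifHit(tf, gene.chrom, start, start + hlen, True))
                    planted.append((tf, gene.gene_id, "transcription"))
    return hits, planted


def expected_inedge_means(
    config: GeneratorConfig, genes: Sequence[GeneModel]
) -> dict[tuple[str, str], float]:
    """Analytic expected mean inedges per group given the realized genes.

    Transcription: p × n_TF. Splicing: p × n_SF × (fraction of the group's
    genes carrying ≥1 AS event of the planting dataset).
    """
    out = {}
    for grp in GROUPS:
        members = [g for g in genes if g.group == grp]
        elig = (
            sum(bool(g.events(config.dataset)) for g in members) / len(members)
            if members
            else 0.0
        )
        out[("splicing", grp)] = config.p_edge["splicing"][grp] * config.n_sf * elig
        out[("transcription", grp)] = config.p_edge["transcription"][grp] * config.n_tf
    return out


# ---------------------------------------------------------------------------
# expression atlas
# ---------------------------------------------------------------------------

def generate_expression_atlas(
    config: GeneratorConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionAtlas, dict[str, list[str]]]:
    """Atlas over network + background genes with plantable above-mean sets.

    The per-tissue mean is defined over *all* atlas genes, as on the array.
    Planted factors are placed at 1.3-3× the final tissue mean, the rest at
    0.05-0.9×; the construction solves for the mean analytically so planting
    is exact. Returns (atlas, planted above-mean gene ids per tissue).
    """
    rng = rng or _stage_rng(config.seed, "atlas")
    net_ids = [g.gene_id for g in genes]
    bg_ids = [f"BG{i:04d}" for i in range(config.n_background)]
    n_total = len(net_ids) + len(bg_ids)
    columns = {}
    planted: dict[str, list[str]] = {}
    for tissue in config.tissues:
        bg_vals = rng.lognormal(math.log(100.0), 1.0, size=len(bg_ids))
        above: set[str] = set()
        if tissue in config.above_mean_counts:
            for grp, count in sorted(config.above_mean_counts[tissue].items()):
                members = [g.gene_id for g in genes if g.group == grp]
                if count > len(members):
                    raise ValueError(
                        f"cannot plant {count} above-mean {grp} genes in {tissue}: "
                        f"only {len(members)} present"
                    )
                above |= set(rng.choice(members, size=count, replace=False))
        else:
            above = {gid for gid in net_ids if rng.random() < config.default_above_prob}
        factors = np.where(
            np.isin(net_ids, sorted(above)),
            rng.uniform(1.3, 3.0, size=len(net_ids)),
            rng.uniform(0.05, 0.9, size=len(net_ids)),
        )
        mu = bg_vals.sum() / (n_total - factors.sum())
        if mu <= 0:
            raise ValueError("atlas construction infeasible: too many planted genes")
        columns[tissue] = np.concatenate([factors * mu, bg_vals])
        planted[tissue] = sorted(above)
    values = pd.DataFrame(columns, index=net_ids + bg_ids)
    return ExpressionAtlas(values), planted


# ---------------------------------------------------------------------------
# protein annotations
# ---------------------------------------------------------------------------

def _disorder_scores(
    rng: np.random.Generator, length: int, frac: float, seg_len: float
) -> np.ndarray:
    """Alternating geometric runs of disordered/ordered residues; disordered
    residues score uniform [0.75, 1), ordered uniform [0, 0.75)."""
    if frac <= 0:
        return rng.uniform(0.0, 0.75, size=length)
    if frac >= 1:
        return rng.uniform(0.75, 1.0, size=length)
    seg_ord = seg_len * (1 - frac) / frac
    state = rng.random() < frac
    mask = np.empty(length, dtype=bool)
    i = 0
    while i < length:
        run = 1 + rng.geometric(1.0 / (seg_len if state else seg_ord))
        mask[i : i + run] = state
        i += run
        state = not state
    scores = np.where(
        mask, rng.uniform(0.75, 1.0, size=length), rng.uniform(0.0, 0.75, size=length)
    )
    return scores


def generate_protein_annotations(
    config: GeneratorConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> list[ProteinAnnotation]:
    """Residue-level annotations for network proteins plus a RANDOM pool.

    Phosphorylation uses a two-component model: with group-specific
    probability the protein is phospho-regulated and receives sites at a
    group-specific per-residue rate, otherwise none — reproducing both the
    fraction of proteins with ≥1 site and the heavy site-coverage of the
    regulated subset.
    """
    rng = rng or _stage_rng(config.seed, "annotations")
    rand_phospho_prob, rand_phospho_rate = 0.30, 0.04
    out = []
    entries = [(g.gene_id, g.group) for g in genes] + [
        (f"RND{i:04d}", "RANDOM") for i in range(config.n_random_proteins)
    ]
    for pid, grp in entries:
        length = int(np.clip(round(rng.lognormal(config.protein_log_mean, config.protein_log_sd)), 40, 3000))
        p_prob = config.phospho_prob.get(grp, rand_phospho_prob) if grp != "RANDOM" else rand_phospho_prob
        p_rate = config.phospho_rate.get(grp, rand_phospho_rate) if grp != "RANDOM" else rand_phospho_rate
        if rng.random() < p_prob:
            positions = frozenset(np.flatnonzero(rng.random(length) < p_rate).tolist())
        else:
            positions = frozenset()
        scores = _disorder_scores(
            rng, length, config.disorder_frac[grp], config.disorder_seg_len[grp]
        )
        out.append(ProteinAnnotation(pid, grp, length, positions, scores))
    return out


# ---------------------------------------------------------------------------
# sequence sets
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq_without(rng: np.random.Generator, pattern: re.Pattern) -> str:
    while True:
        s = "".join(rng.choice(_BASES, size=41))
        if not pattern.search(s):
            return s


def generate_sequence_sets(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[SequenceSet, dict[str, int]]:
    """Bound/control 41-nt sets with the motif planted at rates q_b / q_c.

    Non-planted sequences are rejection-sampled to be motif-free, so the
    realized hit indicator equals the planting indicator exactly. Returns
    (sequence set, planted counts per set).
    """
    rng = rng or _stage_rng(config.seed, "sequences")
    pattern = _motif_regex(config.motif)
    motif = config.motif.upper().replace("U", "T")

    def make(n: int, q: float) -> tuple[list[str], int]:
        seqs, n_planted = [], 0
        for _ in range(n):
            s = _random_seq_without(rng, pattern)
            if rng.random() < q:
                pos = int(rng.integers(0, 41 - len(motif) + 1))
                s = s[:pos] + motif + s[pos + len(motif):]
                n_planted += 1
            seqs.append(s)
        return seqs, n_planted

    bound, nb = make(config.n_bound, config.q_bound)
    control, nc = make(config.n_control, config.q_control)
    return SequenceSet(bound, control), {"bound": nb, "control": nc}


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def generate_bundle(config: GeneratorConfig) -> SyntheticBundle:
    """Generate all pipeline inputs from one config, deterministically.

    Each stage draws from its own child stream of ``config.seed``, so stages
    can be regenerated in isolation with identical results.
    """
    config.validate()
    genes = generate_gene_models(config)
    hits, planted_edges = generate_motif_hits(config, genes)
    atlas, planted_above = generate_expression_atlas(config, genes)
    annotations = generate_protein_annotations(config, genes)
    sequences, planted_seq = generate_sequence_sets(config)
    ground_truth = {
        "seed": config.seed,
        "dataset": config.dataset,
        "p_edge": config.p_edge,
        "planted_edges": sorted(planted_edges),
        "atlas_above_mean": planted_above,
        "sequence_planted_counts": planted_seq,
        "expected_inedge_means": {
            f"{t}:{g}": v for (t, g), v in expected_inedge_means(config, genes).items()
        },
    }
    return SyntheticBundle(config, genes, hits, atlas, annotations, sequences, ground_truth)
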