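# Methods

`crossregnet` reconstructs and analyzes an integrated human regulatory
network in which the nodes are three groups of regulatory proteins —
splicing factors (SF), transcription factors (TF) and kinases — and the
directed edges are two regulatory modalities: alternative-splicing (AS)
regulation (SF → gene) and transcriptional regulation (TF → gene). SFs and
TFs are both regulators and targets; kinases are targets only. The central
question the statistics address is whether *cross-regulation* (regulation of
a group by its own modality, e.g. splicing edges into SFs) dominates
*cross-talk* (regulation across modalities).

## Network model and wiring rules

All genomic coordinates are 0-based half-open; overlap means non-empty
interval intersection (one shared base suffices). The source never states a
coordinate convention, so this one is fixed here and used consistently by
the generator and the builder.

**Splicing edges.** An edge SF_i → gene_j exists iff gene_j carries at least
one AS event (cassette exon, alternative 3′ or alternative 5′ splice site)
and a conserved binding motif of SF_i overlaps at least one of the event's
search regions. The regions are: up to `window_nt` (default 100 nt) of the
transcript-upstream intron adjacent to the event exon, the entire event
exon, and up to `window_nt` of the downstream intron. Cassette events use
all three; alt-3′ events omit the downstream intron; alt-5′ events omit the
upstream one. Intron windows truncate when the intron is shorter than the
window. Window-side selection is implemented geometrically (an intron
genomically left of the exon contributes its rightmost window, a right
intron its leftmost), which is strand-safe and equivalent to the
transcript-orientation phrasing. A single qualifying hit near any one event
suffices; multiple events or hits collapse into one edge carrying all
evidence. Self-edges (autoregulation) are allowed and counted, matching the
documented SF autoregulatory loops.

**Transcription edges.** An edge TF_i → gene_j exists iff a conserved motif
of TF_i overlaps the promoter, defined as `promoter_nt` (default 5,000 nt)
strictly upstream of the TSS in transcript orientation. The TSS is stored as
the first transcribed base (first exon start on +, last exon's final base on
−); the promoter is `[TSS−5000, TSS)` on + and `[TSS+1, TSS+5001)` on −, so
the TSS base itself never counts. A hit straddling the promoter boundary
counts if the intersection is non-empty.

Two AS-event sources are kept separate throughout (dataset tags A and B,
emulating microarray-derived vs RNA-seq-derived event calls); a network is
wired from exactly one tag, never a mixture.

**Layers.** Nodes are classified by degree: `source` (outedges only),
`mixed` (both), `sink` (inedges only), `isolated`. Kinases emit no edges, so
they can only be sink or isolated.

## Network statistics

**Clustering.** The global clustering coefficient (transitivity) is
3 × triangles / connected triples, computed on the undirected simple
projection: directions, edge types and self-loops are dropped. This matches
the behavior of igraph's transitivity, which the original analyses used; the
choice is not stated in the source and is documented here. Local
coefficients (triangles through a node over C(deg, 2), zero when deg < 2)
are available too.

**Sparseness.** S = E / E_max under three conventions, because the printed
definition of E_max (the number of edges squared) reduces to S = 1/E and
cannot reproduce a sparseness of 0.1 for a network of this size. The default
`typed_bipartite` convention counts wirable typed pairs,
E_max = Σ_type (#regulators of the type × N), which respects the role
constraints (only SFs emit splicing edges, only TFs transcription edges);
`simple_n2` (E/N²) and `e_squared` (1/E) are provided and none is
asserted as the original intent.

**Null ensembles.** Two null models are exposed because the source describes
the randomization in two non-equivalent ways ("similar degree distribution"
vs "same average number of edges"). `degree_swap` (default) applies directed
double-edge swaps within each edge type — 10 swap attempts per edge per
replicate, rejecting swaps that would duplicate a typed edge — preserving
every node's typed in- and out-degree exactly. `density_matched` draws a
uniform random typed edge set of the same size under the same role
constraints, preserving only the edge count. The observed statistic is
compared to the ensemble via z = (obs − mean)/sd and the add-one empirical
tail probability (r+1)/(n_random+1), whose lower bound 1/(n_random+1) avoids
zero p-values. When the null sd is zero the z-score is reported as NaN while
the empirical p remains valid. API default is 1,000 replicates (the original
scale); the analysis drivers and acceptance script use 300, which already
estimates a z-score to well under one unit of noise.

## Group statistics

**Inedge densities** are per-node incoming-edge counts of one type,
summarized per group as mean ± sem (sem, not sd, because the reported
±values are consistent with standard errors at the group sizes). Self-loops
count by default (configurable). Group contrasts use the Mann-Whitney U
test, two-sided by default (sidedness is never stated in the source). The
implementation resolves the method automatically: full enumeration over all
C(n_a+n_b, n_a) label assignments when that count is ≤ 2×10⁵ (exact even
with ties; the null distribution of U is symmetric, so the two-sided p
doubles the smaller tail), scipy's tie-free exact recurrence when both
samples have ≤ 20 observations without ties, and the tie-corrected normal
approximation otherwise.

**Correlations** between splicing and transcription inedge counts within a
group use Spearman's rank correlation with average ranks for ties; a
constant count vector yields an undefined (NaN) rho rather than a value.

**Randomized-group control.** Pseudo-groups of the original sizes
(20/90/147) are drawn without replacement from the pooled nodes — the most
literal reading of the published procedure — 100 times; per-iteration
pseudo-group inedge means are aggregated to mean ± sd. Under random grouping
the pseudo-group means are statistically indistinguishable, in contrast to
the true functional groups.

**Combinatorial pairs.** For each unordered factor pair, the shared-target
count k is tested against the hypergeometric upper tail
P(X ≥ k | N, K, n), with K and n the two factors' target-set sizes and N the
universe. SF-SF pairs compare splicing target sets, TF-TF transcription
target sets, SF-TF the SF's splicing targets against the TF's transcription
targets. The universe defaults to all network nodes for every class (the
original choice is unspecified; restricting the splicing universe to
AS-event-bearing genes is flag-controlled). The tail is evaluated in log
space from log-gamma binomial coefficients so that the significance cutoff
α = 1e-16 — at the floor of linear double precision — compares meaningfully;
significance is decided on log10 p. Factors with no targets give p = 1 by
convention and all pairs are reported. Coverage is the fraction of a group's
genes that are targets of *both* members of at least one significant pair.

**Tissue subnetworks.** A factor enters a tissue subnetwork when its
expression is strictly greater than the tissue mean, the mean taken over all
atlas genes (network plus background), mirroring normalization against the
whole array; ties at the mean are excluded (measure-zero on real arrays).
The subnetwork is the induced subgraph (both endpoints retained) and the
SF/TF density table is recomputed on it.

**Sequence enrichment.** Motif hits are exact or IUPAC-degenerate substring
matches on 41-nt sequences (U and T equivalent); the hit fraction and a
one-tailed Fisher exact test on the 2×2 hit-by-set table quantify enrichment
of bound over control sequences, with the Haldane half-count correction for
odds ratios when a cell is zero. Motif-hit string matching stands in for the
upstream motif-scoring algorithm, which is an input provider here, not part
of this package's scope. `term_enrichment` applies the same upper-tail
hypergeometric per annotation term with optional Benjamini-Hochberg
adjustment; it is a plain hypergeometric, deliberately not the modified
score of dedicated GO servers, whose exact values are a non-goal.

**Annotation summaries.** Phosphorylation-site coverage is sites/length,
with "high coverage" meaning strictly above 10%. A residue is disordered
when its score is ≥ 0.75 (inclusive; the source does not state inclusivity —
flag-controlled) and a protein is long-disordered with ≥ 30 consecutive
disordered residues. The random baseline averages 10 draws of 250 proteins
from a supplied random-protein pool.

## The synthetic-data generator

The generator emulates every external input so the full pipeline is testable
without downloads. What it reproduces, and what it does not:

* **Gene architecture.** Lengths are log-normal, exon counts shifted
  negative-binomial, AS-event counts Poisson, all with group-specific
  parameters: kinase genes are the longest (median ≈ 60 kb vs 25 kb) with
  the most exons, while SFs carry the most AS events (Poisson rates per
  dataset 3.0/3.5 for SFs vs 1.5/1.8 for TFs and 1.2/1.4 for kinases). The
  source reports only medians and test directions for these distributions,
  so the calibration is qualitative: heavy-tailed shapes and the correct
  orderings, not exact quantiles. Each gene sits on its own synthetic
  chromosome with introns ≥ 300 nt, so planted windows rarely truncate.
* **Edge planting.** For each ordered (regulator, target) pair an edge is
  planted independently with probability p[edge_type][target group];
  splicing edges only when the target carries an AS event of the planting
  dataset. Each planted edge is realized by exactly one conserved hit placed
  strictly inside an eligible region, so the builder recovers the planted
  edge set exactly — the key identifiability property the build tests rely
  on. Defaults encode the reported group densities divided by regulator
  counts: splicing (0.20, 0.05, 0.05) into (SF, TF, kinase) and
  transcription (0.059, 0.092, 0.037). Because splicing requires
  eligibility, the expected mean splicing inedges of a group is
  p × n_SF × (fraction of the group with ≥ 1 event); ground truth records
  this expectation. Real networks have dependent edges; independence is
  chosen to keep expectations analytic, and it implies two departures from
  the real data that the tests exploit rather than hide: no factor pair
  passes the 1e-16 co-regulation cutoff (a null calibration), and the
  splicing-vs-transcription Spearman correlations are ≈ 0 rather than the
  reported 0.3/−0.25/−0.18, which arise from dependence the generator does
  not emulate.
* **Expression atlas.** Background genes (default 1,000) are log-normal;
  network genes are planted above or below the final tissue mean by solving
  for the mean analytically, so planting is exact: the heart tissue plants
  33 TFs and 14 SFs above the mean, smooth muscle 40 TFs and 11 SFs (the
  published tissue compositions); kinase counts, which the source does not
  give, default to 60 per tissue.
* **Protein annotations.** Phosphorylation uses a two-component model —
  with group probability (0.49, 0.42, 0.77) for (SF, TF, kinase) the protein
  is phospho-regulated and receives per-residue sites at rate (0.12, 0.05,
  0.10) — reproducing both the fraction of proteins with ≥ 1 site and the
  heavy coverage of regulated SFs. Disorder scores come from alternating
  geometric runs (disordered residues score uniform [0.75, 1), ordered
  [0, 0.75)) with group-specific disorder fraction and segment length, so
  SFs/TFs are more disordered than kinases with long runs common.
* **Sequences.** 41-nt bound/control sets; non-planted sequences are
  rejection-sampled motif-free, so the hit indicator equals the planting
  indicator exactly (bound planting 0.75, control 0.02, control size 1,000).

Passing tests on this generator therefore demonstrate that the statistics
detect exactly the effects planted at realistic sizes and stay calibrated
under the null — not that the pipeline reproduces any particular real-data
value, which depends on external genomic resources outside this package.

## Reproducibility and numerical choices

Every stochastic stage draws from a child stream of a single seed
(`SeedSequence((seed, stage))`), so stages regenerate identically in
isolation and the full pipeline is byte-identical across runs. Degenerate
inputs are defined rather than crashed on: empty networks give zero
densities and sparseness 0, constant vectors give NaN correlations, zero
null sd gives NaN z with a valid empirical p, factors without targets give
p = 1, an unswappable degree sequence returns copies with a warning.

Problem sizes in the shipped drivers and acceptance checks are desk-scale
choices: 300-replicate null ensembles, 100 control iterations, 200 seeds for
the planted-effect power runs, and a reduced (10/30/40)-node network for the
null-calibration sweep; all are parameters with study-scale defaults in the
API.

## Known limitations

* Motif hits are consumed, never predicted: no motif scanning, scoring,
  conservation computation or lift-over.
* The generator plants edges independently, so dependence-driven statistics
  (correlations, pair co-regulation) can only be validated for calibration
  and for explicitly planted positives.
* The supplementary-table loader supports counts-only and
  regulator-identity TSV dialects; counts-only exports enable only the
  density/correlation/MW stages.
* GO-server p-values are out of scope; `term_enrichment` is a plain
  hypergeometric stand-in.
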