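# crossregnet

Reconstruction and analysis of an integrated human transcription–splicing
regulatory network.

Gene expression is regulated at multiple coupled layers: transcription
factors (TFs) control transcription through promoter binding sites, splicing
factors (SFs) control alternative splicing (AS) through short motifs near
splice sites, and kinases modulate both through phosphorylation. This
package wires those layers into one typed directed network over three node
groups (SF, TF, kinase) and asks how regulation is distributed across them:
is a group predominantly regulated by the modality it conducts
(*cross-regulation* — splicing edges into SFs, transcription edges into TFs)
or by the other modality (*cross-talk*)?

Edges follow two rules. A splicing edge SF_i → gene_j requires gene_j to
carry an AS event (cassette exon, alternative 3′ or 5′ splice site) and a
conserved motif of SF_i overlapping the event's search regions — 100 nt of
the adjacent upstream intron, the event exon, and 100 nt of the downstream
intron. A transcription edge TF_i → gene_j requires a conserved motif of
TF_i in the 5 kb promoter strictly upstream of gene_j's TSS. On the wired
network the package computes:

* global clustering C = 3·triangles/triples and sparseness S = E/E_max,
  with significance (z-score, empirical p) against degree-preserving and
  density-matched random ensembles;
* per-group inedge densities (mean ± sem) with Mann–Whitney contrasts and
  Spearman ρ between splicing and transcription inedges per node;
* a randomized-group control (pseudo-groups of the original sizes);
* hypergeometric co-regulation tests P(X ≥ k | N, K, n) for every SF-SF,
  TF-TF and SF-TF pair, evaluated in log space against an α = 1e-16 cutoff,
  with per-group coverage by significant pairs;
* tissue subnetworks induced by an above-average expression filter;
* Fisher-exact motif enrichment in bound vs control 41-nt sequence sets and
  a generic hypergeometric term-enrichment test;
* phosphorylation-site and intrinsic-disorder summaries per group
  (site density normalized to length; disorder at score ≥ 0.75 with
  ≥ 30-residue runs defining long-disordered proteins).

A first-class synthetic-data generator (`crossregnet.synth`) emulates every
input — gene models, AS events, motif-hit tables, an expression atlas,
residue-level annotations, sequence sets — with plantable effect sizes and
exact ground truth, so the entire pipeline is testable end to end without
external downloads. See `docs/methods.md` for the model, parameter defaults
and what the synthetic conditions do and do not demonstrate.

## Worked example

The numbered scripts under `analysis/` run the full study on a generated
bundle (seed 1), writing tables under `results/`:

```
python analysis/01_generate_data.py
python analysis/02_build_network.py
python analysis/04_inedge_density.py
```

prints

```
RegulatoryNetwork(N=257 [SF=20, TF=90, KINASE=147], E=1614)
layers: {'mixed': 110, 'sink': 142, 'isolated': 5}
planted edge set recovered exactly: True
    edge_type  group   n     mean      sem
     splicing     SF  20 3.950000 0.380270
     splicing     TF  90 0.944444 0.106424
     splicing KINASE 147 0.625850 0.072375
transcription     SF  20 5.800000 0.531136
transcription     TF  90 8.411111 0.314007
transcription KINASE 147 3.299320 0.152149
MW splicing SF vs TF: p = 1.15e-10
MW transcription TF vs SF: p = 0.000551
```

Read: the 257-node network wires 110 SFs/TFs as both regulators and targets
(mixed layer) over a sink layer of targets-only nodes, and recovers exactly
the edges the generator planted. Splicing inedges are ~4× denser into SFs
than into TFs or kinases while transcription inedges concentrate on TFs —
the cross-regulation-over-cross-talk signature, highly significant by
Mann–Whitney. Script 05 shows that no factor pair passes the 1e-16
co-regulation cutoff under independent planting (null calibration) and that
a planted pair sharing 40 targets is detected at log10 p ≈ −31; script 06
recovers the planted tissue compositions (heart: 14 SFs, 33 TFs above the
tissue mean) and recomputes densities on the induced subnetworks.

The same stages are scriptable through a thin CLI:

```
crossregnet generate --seed 1 --outdir data/
crossregnet build --genes data/genes.tsv --events data/events.tsv \
    --sf-hits data/sf_hits.bed --tf-hits data/tf_hits.bed --dataset A --outdir net/
crossregnet props --edges net/edges.tsv --nodes net/nodes.tsv --null degree-swap
crossregnet run-all --seed 1 --outdir out/
```

## Layout

```
src/crossregnet/   library: synth, build, props, density, pairs, tissue,
                   enrich, annot, io, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    model, parameters, design decisions, limitations
```
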