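#!/usr/bin/env python
"""Generate the synthetic input bundle all later steps consume.

Emulates the study's inputs at its composition — 20 splicing factors, 90
transcription factors, 147 kinases — with cross-regulation planted above
cross-talk (splicing planting 0.2 into SFs vs 0.05 elsewhere; transcription
planting proportional to the reported group means). Writes gene models, AS
events, motif hits (BED), the expression atlas, protein annotations,
sequence sets and the planted ground truth under results/data/.
"""

from pathlib import Path

from crossregnet import GeneratorConfig, generate_bundle
from crossregnet import io

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    cfg = GeneratorConfig(seed=SEED)
    bundle = generate_bundle(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_gene_models(bundle.genes, OUT / "genes.tsv", OUT / "events.tsv")
    io.write_motif_hits(bundle.sf_hits, OUT / "sf_hits.bed")
    io.write_motif_hits(bundle.tf_hits, OUT / "tf_hits.bed")
    io.write_atlas(bundle.atlas, OUT / "atlas.tsv")
    io.write_annotations(bundle.annotations, OUT / "annotations.tsv")
    io.write_sequences(bundle.sequences, OUT / "bound.fasta", OUT / "control.fasta")
    io.write_json(bundle.ground_truth, OUT / "ground_truth.json")
    n_events = sum(len(g.as_events) for g in bundle.genes)
    print(f"generated {len(bundle.genes)} genes, {n_events} AS events, "
          f"{len(bundle.hits)} planted motif hits -> {OUT}")


if __name__ == "__main__":
    main()
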