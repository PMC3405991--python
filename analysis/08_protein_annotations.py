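#!/usr/bin/env python
"""Phosphorylation and disorder summaries per regulatory group.

Kinases carry the densest predicted phosphorylation (the group most
regulated by the modality it conducts), while SFs and TFs are the most
intrinsically disordered — disorder defined as score >= 0.75 per residue and
a protein counted long-disordered with a >= 30-residue run. The random
baseline averages 10 draws of 250 proteins from the random pool.
"""

from pathlib import Path

from crossregnet import disorder_summary, mann_whitney, phospho_summary
from crossregnet import io
from crossregnet.annot import disorder_fraction

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
SEED = 1


def main() -> None:
    annotations = io.read_annotations(DATA / "annotations.tsv")
    net = [a for a in annotations if a.group != "RANDOM"]
    pool = [a for a in annotations if a.group == "RANDOM"]

    ph = phospho_summary(net)
    ph.to_csv(ROOT / "phospho_summary.tsv", sep="\t", index=False)
    print(ph.to_string(index=False))

    dis = disorder_summary(net, random_pool=pool, seed=SEED)
    dis.to_csv(ROOT / "disorder_summary.tsv", sep="\t", index=False)
    print(dis.to_string(index=False))

    sf = [disorder_fraction(a, 0.75) for a in net if a.group == "SF"]
    kin = [disorder_fraction(a, 0.75) for a in net if a.group == "KINASE"]
    res = mann_whitney(sf, kin)
    print(f"MW disorder SF vs kinase: p = {res.p:.3g}")


if __name__ == "__main__":
    main()
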