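"""Motif enrichment in bound vs control sequences, and term enrichment.

This is the validation procedure applied to cross-linking immunoprecipitation
(CLIP/PAR-CLIP) binding data: all sequences are 41-nt windows, a motif hit is
an exact or IUPAC-degenerate substring match, and enrichment of hits in the
experimentally bound set relative to a control set (by default 1,000 random
intronic windows) is assessed with a one-tailed Fisher exact test.

``term_enrichment`` is the analogous one-tailed hypergeometric test for
annotation-term membership among a target gene set versus a background set,
with optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pairs import log_hypergeom_sf

SEQ_LENGTH = 41

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class SequenceSet:
    """Bound and control sequence sets, uniform 41-nt length."""

    bound: list[str]
    control: list[str]

    def __post_init__(self) -> None:
        for name, seqs in (("bound", self.bound), ("control", self.control)):
            for s in seqs:
                if len(s) != SEQ_LENGTH:
                    raise ValueError(f"{name} sequence of length {len(s)} != {SEQ_LENGTH}")


def _motif_regex(motif: str) -> re.Pattern:
    motif = motif.upper().replace("U", "T")
    try:
        return re.compile("".join(IUPAC[c] for c in motif))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in motif: {exc}") from exc


def has_hit(sequence: str, motif: str | re.Pattern) -> bool:
    pat = motif if isinstance(motif, re.Pattern) else _motif_regex(motif)
    return pat.search(sequence.upper().replace("U", "T")) is not None


def hit_fraction(sequences: Sequence[str], motif: str) -> float:
    """Fraction of sequences containing at least one motif match."""
    if not sequences:
        raise ValueError("empty sequence set")
    if len(motif) > SEQ_LENGTH:
        raise ValueError(f"motif longer than {SEQ_LENGTH} nt")
    pat = _motif_regex(motif)
    return sum(has_hit(s, pat) for s in sequences) / len(sequences)


@dataclass
class EnrichmentResult:
    """2×2 hit table (a,b: bound hit/no-hit; c,d: control hit/no-hit)."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    sides: str

    @property
    def log10_p(self) -> float:
        return math.log10(self.p) if self.p > 0 else -math.inf


def fisher_enrichment(
    bound: Sequence[str],
    control: Sequence[str],
    motif: str,
    sides: str = "greater",
) -> EnrichmentResult:
    """Fisher exact test of motif hits in bound vs control sequences.

    The odds ratio uses the Haldane half-count correction when any cell is
    zero.
    """
    if not bound or not control:
        raise ValueError("bound and control sets must be nonempty")
    pat = _motif_regex(motif)
    a = sum(has_hit(s, pat) for s in bound)
    b = len(bound) - a
    c = sum(has_hit(s, pat) for s in control)
    d = len(control) - c
    alternative = {"greater": "greater", "less": "less", "two": "two-sided"}[sides]
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(a, b, c, d, float(odds), float(p), sides)


@dataclass
class TermEnrichmentResult:
    term: str
    k_targets: int  # term members among targets
    n_targets: int
    K_background: int  # term members in background
    N_background: int
    p: float
    p_adjusted: float | None = None


def term_enrichment(
    target_set: Iterable[str],
    background_set: Iterable[str],
    annotation_table: Mapping[str, Iterable[str]],
    adjust: bool = True,
) -> list[TermEnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each annotation term among
    targets vs background, with optional Benjamini-Hochberg adjustment.

    ``annotation_table`` maps gene id → term ids. Terms with no member in the
    background are skipped with a warning; targets are implicitly clipped to
    the background universe.
    """
    background = set(background_set)
    targets = set(target_set) & background
    if not targets:
        return []
    term_members: dict[str, set[str]] = {}
    for gene, terms in annotation_table.items():
        for t in terms:
            term_members.setdefault(t, set()).add(gene)
    results = []
    for term, members in sorted(term_members.items()):
        bg_members = members & background
        if not bg_members:
            warnings.warn(f"term {term!r} absent from background; skipped", stacklevel=2)
            continue
        k = len(members & targets)
        log_p = log_hypergeom_sf(k, len(background), len(bg_members), len(targets))
        results.append(
            TermEnrichmentResult(
                term, k, len(targets), len(bg_members), len(background),
                float(math.exp(log_p)),
            )
        )
    if adjust and results:
        _, adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    return results
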