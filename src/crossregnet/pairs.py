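"""Combinatorial co-regulation: hypergeometric pair tests and coverage.

For every unordered pair of factors the shared-target count is tested
against the hypergeometric null: with N genes in the universe, K targets of
the first factor and n of the second, the upper-tail probability of sharing
at least k targets is P(X ≥ k) with X ~ Hypergeom(N, K, n). SF-SF pairs
compare splicing target sets, TF-TF transcription target sets, and SF-TF
pairs the SF's splicing targets against the TF's transcription targets.

The tail is evaluated in log space with log-gamma binomials so p-values far
below double-precision epsilon remain meaningful — the significance cutoff
is alpha = 1e-16, at the floor of linear double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp

from .models import RegulatoryNetwork

PAIR_CLASSES = ("SF-SF", "TF-TF", "SF-TF")
DEFAULT_ALPHA = 1e-16


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def log_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """log P(X ≥ k) for X ~ Hypergeom(N, K, n), by log-sum-exp over the
    upper-tail terms. Returns 0.0 (p = 1) for k ≤ 0."""
    if min(N, K, n) < 0 or K > N or n > N:
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k <= 0:
        return 0.0
    upper = min(K, n)
    if k > upper:
        return -math.inf
    denom = _log_comb(N, n)
    terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - denom
        for i in range(k, upper + 1)
    ]
    return float(min(0.0, logsumexp(terms)))


@dataclass
class PairTestResult:
    factor_a: str
    factor_b: str
    pair_class: str
    N_universe: int
    K_a: int
    n_b: int
    k_overlap: int
    log10_p: float
    significant: bool

    @property
    def p(self) -> float:
        return 10.0 ** self.log10_p


def pair_coregulation_scan(
    network: RegulatoryNetwork,
    alpha: float = DEFAULT_ALPHA,
    universe: str = "all",
    include_empty: bool = True,
) -> list[PairTestResult]:
    """Hypergeometric co-regulation test for every factor pair.

    ``universe='all'`` uses every network node as the target universe for all
    pair classes; ``universe='as_genes'`` restricts the splicing universe to
    genes carrying at least one AS event. Factors without targets give p = 1
    by convention (excluded entirely when ``include_empty`` is false).
    """
    sfs = sorted(network.group_members("SF"))
    tfs = sorted(network.group_members("TF"))
    all_nodes = set(network.genes)
    if universe == "all":
        sp_universe = all_nodes
    elif universe == "as_genes":
        sp_universe = {gid for gid, g in network.genes.items() if g.as_events}
    else:
        raise ValueError(f"unknown universe: {universe!r}")

    sp_targets = {f: network.targets_of(f, "splicing") & sp_universe for f in sfs}
    tr_targets = {f: network.targets_of(f, "transcription") for f in tfs}

    def scan(pairs, targets_a, targets_b, pair_class, universe_set):
        results = []
        N = len(universe_set)
        for a, b in pairs:
            ta, tb = targets_a[a], targets_b[b]
            if not include_empty and (not ta or not tb):
                continue
            k = len(ta & tb)
            if not ta or not tb:
                log_p = 0.0
            else:
                log_p = log_hypergeom_sf(k, N, len(ta), len(tb))
            log10_p = log_p / math.log(10)
            results.append(
                PairTestResult(a, b, pair_class, N, len(ta), len(tb), k, log10_p, False)
            )
        return results

    out = []
    out += scan(combinations(sfs, 2), sp_targets, sp_targets, "SF-SF", sp_universe)
    out += scan(combinations(tfs, 2), tr_targets, tr_targets, "TF-TF", all_nodes)
    out += scan(
        ((sf, tf) for sf in sfs for tf in tfs),
        sp_targets, tr_targets, "SF-TF", all_nodes,
    )
    # significance via log-space comparison, robust below double epsilon
    log10_alpha = math.log10(alpha)
    for r in out:
        r.significant = r.log10_p < log10_alpha
    return out


def significant_pairs(
    results: list[PairTestResult], pair_class: str | None = None
) -> list[PairTestResult]:
    return [
        r
        for r in results
        if r.significant and (pair_class is None or r.pair_class == pair_class)
    ]


def pair_coverage(
    results: list[PairTestResult],
    network: RegulatoryNetwork,
    group: str,
) -> dict[str, float]:
    """Fraction of genes in ``group`` that are shared targets of at least one
    significant pair, per pair class plus the union over classes.

    Shared-target membership requires the gene to be a target of *both*
    factors in the pair (splicing targets for SFs, transcription for TFs).
    """
    members = network.group_members(group)
    if not members:
        return {c: math.nan for c in PAIR_CLASSES} | {"union": math.nan}
    member_set = set(members)
    covered: dict[str, set[str]] = {c: set() for c in PAIR_CLASSES}
    for r in results:
        if not r.significant:
            continue
        type_a = "splicing" if r.pair_class[:2] == "SF" else "transcription"
        type_b = "splicing" if r.pair_class[-2:] == "SF" else "transcription"
        shared = (
            network.targets_of(r.factor_a, type_a)
            & network.targets_of(r.factor_b, type_b)
            & member_set
        )
        covered[r.pair_class] |= shared
    out = {c: len(s) / len(members) for c, s in covered.items()}
    out["union"] = len(set.union(*covered.values())) / len(members)
    return out
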