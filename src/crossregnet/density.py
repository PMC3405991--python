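"""Group-wise inedge densities and the nonparametric comparisons on them.

Inedge density is the number of incoming edges of one type per node,
summarized per target group (mean ± sem). Cross-regulation (e.g. splicing
edges into SFs) is contrasted with cross-talk (splicing edges into TFs or
kinases) by Mann-Whitney U tests; the splicing-vs-transcription relationship
within a group is measured by Spearman rank correlation; and the
randomized-group control re-draws pseudo-groups of the original sizes from
the pooled nodes to show the group contrast is not expected by chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .models import GROUPS, RegulatoryNetwork

EXACT_ENUM_LIMIT = 200_000  # max C(n_a+n_b, n_a) for full enumeration


@dataclass
class GroupDensity:
    group: str
    edge_type: str
    per_node_counts: dict[str, int]
    mean: float
    sem: float

    @property
    def counts(self) -> np.ndarray:
        return np.array(list(self.per_node_counts.values()), dtype=float)


def inedge_density(
    network: RegulatoryNetwork,
    edge_type: str,
    include_self_loops: bool = True,
) -> dict[str, GroupDensity]:
    """Per-group inedge counts of one edge type, with mean ± sem."""
    counts = network.inedge_counts(edge_type, include_self_loops)
    out = {}
    for grp in GROUPS:
        members = network.group_members(grp)
        per_node = {gid: counts[gid] for gid in members}
        vals = np.array(list(per_node.values()), dtype=float)
        if len(vals) == 0:
            mean, sem = math.nan, math.nan
        else:
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out[grp] = GroupDensity(grp, edge_type, per_node, mean, sem)
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

@dataclass
class MWResult:
    U: float
    p: float
    sides: str
    method: str


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def _exact_enumeration(a: np.ndarray, b: np.ndarray, sides: str) -> tuple[float, float]:
    """Full enumeration of U over all C(n_a+n_b, n_a) label assignments.

    Average ranks make this valid with ties; the null distribution of U is
    symmetric about n_a·n_b/2, so the two-sided p doubles the smaller tail
    (capped at 1).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    us = np.array(
        [
            _u_statistic(ranks[list(pos)], n_a)
            for pos in combinations(range(n_a + n_b), n_a)
        ]
    )
    total = len(us)
    tol = 1e-9
    p_greater = np.sum(us >= u_obs - tol) / total
    p_less = np.sum(us <= u_obs + tol) / total
    if sides == "greater":
        p = p_greater
    elif sides == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    return u_obs, float(p)


def mann_whitney(
    counts_a, counts_b, sides: str = "two", method: str = "auto"
) -> MWResult:
    """Mann-Whitney U test of ``counts_a`` vs ``counts_b``.

    ``method='auto'`` resolves to full enumeration when C(n_a+n_b, n_a) is
    small enough (ties handled exactly), to the tie-free exact recurrence
    when both samples have ≤ 20 observations and no ties, and to the
    tie-corrected normal approximation otherwise. ``sides`` is ``two``,
    ``greater`` (a tends larger) or ``less``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if sides not in ("two", "greater", "less"):
        raise ValueError(f"unknown sides: {sides!r}")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size

    if method == "auto":
        if comb(a.size + b.size, a.size) <= EXACT_ENUM_LIMIT:
            method = "exact"
        elif a.size <= 20 and b.size <= 20 and not has_ties:
            method = "exact"
        else:
            method = "normal_tie_corrected"

    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sides]
    if method == "exact":
        if comb(a.size + b.size, a.size) <= EXACT_ENUM_LIMIT:
            u, p = _exact_enumeration(a, b, sides)
        else:
            if has_ties:
                raise ValueError("exact method with ties only via enumeration")
            u, p = stats.mannwhitneyu(a, b, alternative=alternative, method="exact")
        return MWResult(float(u), float(p), sides, "exact")
    u, p = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return MWResult(float(u), float(p), sides, "normal_tie_corrected")


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float  # nan when undefined (constant vector)
    n: int


def splicing_transcription_correlation(
    network: RegulatoryNetwork, group: str
) -> CorrelationResult:
    """Spearman rho between splicing and transcription inedge counts within
    one target group (ties by average ranks)."""
    members = network.group_members(group)
    if not members:
        raise ValueError(f"group {group!r} is empty")
    sp = network.inedge_counts("splicing")
    tr = network.inedge_counts("transcription")
    x = np.array([sp[g] for g in members], dtype=float)
    y = np.array([tr[g] for g in members], dtype=float)
    if len(members) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(math.nan, len(members))
    rho = stats.spearmanr(x, y).statistic
    return CorrelationResult(float(rho), len(members))


# ---------------------------------------------------------------------------
# randomized-group control
# ---------------------------------------------------------------------------

@dataclass
class RandomGroupControl:
    per_iteration: pd.DataFrame  # iteration, pseudo_group, edge_type, mean
    summary: pd.DataFrame  # pseudo_group, edge_type, mean, sd


def random_group_control(
    network: RegulatoryNetwork,
    sizes: dict[str, int] | None = None,
    n_iter: int = 100,
    seed: int | None = None,
) -> RandomGroupControl:
    """Pseudo-groups of the original sizes drawn without replacement from all
    nodes; per-iteration splicing/transcription inedge means, then aggregate
    mean ± sd. Under random grouping the pseudo-group means are
    indistinguishable, unlike the true functional groups."""
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = network.group_sizes()
    if sum(sizes.values()) > network.n_nodes:
        raise ValueError("pseudo-group sizes exceed the number of nodes")
    nodes = np.array(sorted(network.genes))
    sp = network.inedge_counts("splicing")
    tr = network.inedge_counts("transcription")
    rows = []
    order = [g for g in GROUPS if g in sizes]
    for it in range(n_iter):
        perm = rng.permutation(nodes)
        start = 0
        for grp in order:
            chunk = perm[start : start + sizes[grp]]
            start += sizes[grp]
            for edge_type, counts in (("splicing", sp), ("transcription", tr)):
                rows.append(
                    {
                        "iteration": it,
                        "pseudo_group": grp,
                        "edge_type": edge_type,
                        "mean": float(np.mean([counts[g] for g in chunk])),
                    }
                )
    per_iter = pd.DataFrame(rows)
    summary = (
        per_iter.groupby(["pseudo_group", "edge_type"])["mean"]
        .agg(["mean", "std"])
        .rename(columns={"std": "sd"})
        .reset_index()
    )
    return RandomGroupControl(per_iter, summary)
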