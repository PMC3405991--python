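"""Global network properties and significance against randomized ensembles.

The clustering coefficient (transitivity) is computed on the undirected
simple projection of the typed network: C = 3 × triangles / connected
triples. Sparseness S = E / E_max is provided under three denominator
conventions because the formula's printed denominator (E_max = E²) cannot
reproduce a sparseness of 0.1 for any network with more than ten edges:

* ``typed_bipartite`` (default): E_max = Σ_type (#regulators of that type × N),
  the number of wirable typed pairs (self-loops allowed);
* ``simple_n2``: E_max = N²;
* ``e_squared``: E_max = E², i.e. S = 1/E.

Observed statistics are compared against two null ensembles: ``degree_swap``
(double-edge swaps preserving every node's typed in/out degree) and
``density_matched`` (uniform typed edge sets with the same edge count and
the same regulator/target role constraints).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .models import EDGE_SOURCE_GROUP, EDGE_TYPES, RegulatoryEdge, RegulatoryNetwork


def clustering_coefficient(
    network: RegulatoryNetwork | nx.Graph, scope: str = "global"
) -> float | dict:
    """Transitivity of the undirected simple projection.

    ``scope='global'`` returns 3×triangles/triples; ``scope='local'`` the
    per-node coefficients (0 where degree < 2).
    """
    g = network.to_undirected_simple() if isinstance(network, RegulatoryNetwork) else network
    if scope == "global":
        return nx.transitivity(g)
    if scope == "local":
        return nx.clustering(g)
    raise ValueError(f"unknown scope: {scope!r}")


def sparseness(network: RegulatoryNetwork, convention: str = "typed_bipartite") -> float:
    e = network.n_edges
    if e == 0:
        return 0.0
    if convention == "typed_bipartite":
        sizes = network.group_sizes()
        emax = sum(
            sizes[EDGE_SOURCE_GROUP[t]] * network.n_nodes for t in EDGE_TYPES
        )
        return e / emax
    if convention == "simple_n2":
        return e / network.n_nodes**2
    if convention == "e_squared":
        return 1.0 / e
    raise ValueError(f"unknown sparseness convention: {convention!r}")


# ---------------------------------------------------------------------------
# null ensembles
# ---------------------------------------------------------------------------

def _degree_swap_edges(
    edges: list[tuple[str, str]], rng: np.random.Generator, n_attempts: int
) -> list[tuple[str, str]]:
    """Directed double-edge swaps on one edge type.

    A swap takes (a→b, c→d) to (a→d, c→b), preserving all in/out degrees;
    it is rejected when it would duplicate an existing edge. Self-loops may
    appear or disappear, as in the observed network.
    """
    edges = list(edges)
    m = len(edges)
    if m < 2:
        return edges
    present = set(edges)
    idx = rng.integers(0, m, size=(n_attempts, 2))
    for i, j in idx:
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if b == d or a == c:
            continue
        e1, e2 = (a, d), (c, b)
        if e1 in present or e2 in present:
            continue
        present.discard((a, b))
        present.discard((c, d))
        present.add(e1)
        present.add(e2)
        edges[i], edges[j] = e1, e2
    return edges


def _density_matched_edges(
    regulators: Sequence[str],
    nodes: Sequence[str],
    n_edges: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Uniform sample of ``n_edges`` distinct (regulator, target) pairs."""
    total = len(regulators) * len(nodes)
    if n_edges > total:
        raise ValueError("more edges requested than wirable pairs")
    flat = rng.choice(total, size=n_edges, replace=False)
    n = len(nodes)
    return [(regulators[k // n], nodes[k % n]) for k in flat]


def randomize_network(
    network: RegulatoryNetwork,
    null_model: str = "degree_swap",
    n_random: int = 1000,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: int = 10,
) -> list[RegulatoryNetwork]:
    """Ensemble of randomized networks preserving the null model's invariants."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = list(network.genes.values())
    by_type = {
        t: [(e.source, e.target) for e in network.edges if e.edge_type == t]
        for t in EDGE_TYPES
    }
    nodes = sorted(network.genes)
    regs = {t: sorted(network.group_members(EDGE_SOURCE_GROUP[t])) for t in EDGE_TYPES}
    out = []
    for _ in range(n_random):
        edges: list[RegulatoryEdge] = []
        for t in EDGE_TYPES:
            obs = by_type[t]
            if null_model == "degree_swap":
                new = _degree_swap_edges(obs, rng, swaps_per_edge * len(obs))
            elif null_model == "density_matched":
                new = _density_matched_edges(regs[t], nodes, len(obs), rng)
            else:
                raise ValueError(f"unknown null model: {null_model!r}")
            edges.extend(RegulatoryEdge(s, tg, t) for s, tg in new)
        out.append(RegulatoryNetwork(genes, edges))
    return out


@dataclass
class NullEnsembleResult:
    """Observed statistic vs a randomized ensemble."""

    observed_stat: float
    null_mean: float
    null_sd: float
    z: float  # nan when null_sd == 0
    empirical_p: float  # (r+1)/(n+1), upper tail
    n_random: int
    seed: int | None
    null_model: str

    def __repr__(self) -> str:
        return (
            f"NullEnsembleResult(obs={self.observed_stat:.4g}, "
            f"null={self.null_mean:.4g}±{self.null_sd:.4g}, z={self.z:.3g}, "
            f"p={self.empirical_p:.3g}, n={self.n_random}, {self.null_model})"
        )


def null_zscore(
    network: RegulatoryNetwork,
    stat: Callable[[RegulatoryNetwork], float] | None = None,
    null_model: str = "degree_swap",
    n_random: int = 1000,
    seed: int | None = None,
) -> NullEnsembleResult:
    """Observed statistic (default: global clustering) vs the null ensemble.

    The empirical p uses the add-one estimator (r+1)/(n_random+1), so its
    lower bound is 1/(n_random+1) rather than zero.
    """
    if stat is None:
        stat = lambda net: clustering_coefficient(net, "global")
    observed = float(stat(network))
    ensemble = randomize_network(network, null_model, n_random, seed)
    vals = np.array([stat(net) for net in ensemble], dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n_random > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else math.nan
    r = int(np.sum(vals >= observed))
    return NullEnsembleResult(
        observed_stat=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        empirical_p=(r + 1) / (n_random + 1),
        n_random=n_random,
        seed=seed if isinstance(seed, int) else None,
        null_model=null_model,
    )
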