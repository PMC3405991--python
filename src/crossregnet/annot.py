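"""Residue-level annotation summaries: phosphorylation and disorder.

Predictor outputs are inputs here: per-protein phosphorylation-site calls
and per-residue disorder propensity scores in [0,1]. Summaries follow the
field's conventions — site density normalized to protein length with a 10%
coverage threshold, and a protein counted as (long-)disordered when it has
at least one run of ≥30 consecutive residues at or above the 0.75 score
cutoff. A random-protein baseline is computed as the mean over repeated
draws (default 10 × 250 proteins) from a supplied pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import GROUPS

DISORDER_CUTOFF = 0.75
MIN_DISORDER_RUN = 30
COVERAGE_THRESHOLD = 0.10


@dataclass
class ProteinAnnotation:
    protein_id: str
    group: str  # SF | TF | KINASE | RANDOM
    length: int
    phospho_positions: frozenset[int] = frozenset()
    disorder_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.protein_id}: non-positive protein length")
        if any(p < 0 or p >= self.length for p in self.phospho_positions):
            raise ValueError(f"{self.protein_id}: phospho position out of range")
        if self.disorder_scores is not None:
            self.disorder_scores = np.asarray(self.disorder_scores, dtype=float)
            if len(self.disorder_scores) != self.length:
                raise ValueError(f"{self.protein_id}: score vector length mismatch")
            if np.any((self.disorder_scores < 0) | (self.disorder_scores > 1)):
                raise ValueError(f"{self.protein_id}: disorder scores outside [0,1]")


def longest_true_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def phospho_summary(
    annotations: Sequence[ProteinAnnotation],
    coverage_threshold: float = COVERAGE_THRESHOLD,
    groups: Sequence[str] = GROUPS,
) -> pd.DataFrame:
    """Per-group phosphorylation summary.

    Columns: fraction of proteins with ≥1 predicted site; among those, the
    fraction whose site count per residue exceeds ``coverage_threshold``
    (strictly); and the mean site density (sites / length) over all proteins.
    """
    rows = []
    for grp in groups:
        prots = [a for a in annotations if a.group == grp]
        if not prots:
            raise ValueError(f"no annotations for group {grp!r}")
        n_with = [a for a in prots if a.phospho_positions]
        frac_with = len(n_with) / len(prots)
        if n_with:
            frac_high = (
                sum(len(a.phospho_positions) / a.length > coverage_threshold for a in n_with)
                / len(n_with)
            )
        else:
            frac_high = 0.0
        density = float(np.mean([len(a.phospho_positions) / a.length for a in prots]))
        rows.append(
            {
                "group": grp,
                "n": len(prots),
                "frac_with_site": frac_with,
                "frac_high_coverage": frac_high,
                "mean_site_density": density,
            }
        )
    return pd.DataFrame(rows)


def disorder_fraction(a: ProteinAnnotation, cutoff: float, inclusive: bool = True) -> float:
    scores = a.disorder_scores
    mask = scores >= cutoff if inclusive else scores > cutoff
    return float(mask.mean())


def is_long_disordered(
    a: ProteinAnnotation,
    cutoff: float = DISORDER_CUTOFF,
    min_run: int = MIN_DISORDER_RUN,
    inclusive: bool = True,
) -> bool:
    scores = a.disorder_scores
    mask = scores >= cutoff if inclusive else scores > cutoff
    return longest_true_run(mask) >= min_run


def disorder_summary(
    annotations: Sequence[ProteinAnnotation],
    cutoff: float = DISORDER_CUTOFF,
    min_run: int = MIN_DISORDER_RUN,
    inclusive: bool = True,
    random_pool: Sequence[ProteinAnnotation] | None = None,
    n_draws: int = 10,
    draw_size: int = 250,
    seed: int | None = None,
    groups: Sequence[str] = GROUPS,
) -> pd.DataFrame:
    """Per-group disorder summary, with an optional random-pool baseline.

    Columns: mean fraction of residues at or above the cutoff, and the
    fraction of proteins with at least one run of ``min_run`` consecutive
    disordered residues. When ``random_pool`` is given, a ``RANDOM`` row is
    appended: the mean over ``n_draws`` draws of ``draw_size`` proteins.
    """
    rows = []
    for grp in groups:
        prots = [a for a in annotations if a.group == grp]
        if not prots:
            continue
        rows.append(
            {
                "group": grp,
                "n": len(prots),
                "mean_disordered_fraction": float(
                    np.mean([disorder_fraction(a, cutoff, inclusive) for a in prots])
                ),
                "frac_long_disordered": float(
                    np.mean(
                        [is_long_disordered(a, cutoff, min_run, inclusive) for a in prots]
                    )
                ),
            }
        )
    if random_pool is not None:
        rng = np.random.default_rng(seed)
        pool = list(random_pool)
        if len(pool) < draw_size:
            raise ValueError("random pool smaller than draw size")
        fracs, longs = [], []
        for _ in range(n_draws):
            idx = rng.choice(len(pool), size=draw_size, replace=False)
            draw = [pool[i] for i in idx]
            fracs.append(np.mean([disorder_fraction(a, cutoff, inclusive) for a in draw]))
            longs.append(
                np.mean([is_long_disordered(a, cutoff, min_run, inclusive) for a in draw])
            )
        rows.append(
            {
                "group": "RANDOM",
                "n": draw_size * n_draws,
                "mean_disordered_fraction": float(np.mean(fracs)),
                "frac_long_disordered": float(np.mean(longs)),
            }
        )
    return pd.DataFrame(rows)
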