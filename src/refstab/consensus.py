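"""Comprehensive rank consensus and optimal reference-gene selection.

The consensus follows the RefFinder recipe: each candidate gene receives one
rank per stability method, and the comprehensive stability value is the
geometric mean of those ranks (lower = more stable). The number of reference
genes to use comes from the geNorm pairwise-variation curve (smallest n with
V_n below the cutoff, conventionally 0.15), while the *identity* of the genes
comes from the consensus ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stability import PairwiseVariationCurve, StabilityTable

__all__ = ["ConsensusRanking", "Recommendation", "reffinder_geomean", "select_optimal"]


@dataclass
class ConsensusRanking:
    """Per-gene method ranks, their geometric mean, and the final ordering."""

    ranks: pd.DataFrame  # genes x methods
    geomean: pd.Series
    final_rank: pd.Series  # 1..k, total order
    methods_used: list[str]

    def ordered_genes(self) -> list[str]:
        return list(self.final_rank.sort_values().index)


@dataclass
class Recommendation:
    """Single best gene and the optimal combination for normalization."""

    single_best: str
    optimal_n: int
    combination: list[str]
    v_used: float
    fallback: bool

    def as_dict(self) -> dict:
        return {
            "single_best": self.single_best,
            "optimal_n": self.optimal_n,
            "combination": list(self.combination),
            "v_used": self.v_used,
            "fallback": self.fallback,
        }


def reffinder_geomean(
    ranks_by_method: Mapping[str, Mapping[str, float]] | Mapping[str, StabilityTable],
) -> ConsensusRanking:
    """Geometric mean of per-method ranks with a deterministic total order.

    ``ranks_by_method`` maps method name to either a
    :class:`~refstab.stability.StabilityTable` or a gene -> rank mapping.
    Every gene must carry a rank from every method. The final ordering is
    ascending by geomean, ties broken by arithmetic mean rank, then by gene
    name.
    """
    if len(ranks_by_method) < 2:
        raise ValueError("need ranks from >=2 methods")
    cols = {}
    for method, ranks in ranks_by_method.items():
        if isinstance(ranks, StabilityTable):
            cols[method] = ranks.ranks.astype(float)
        else:
            cols[method] = pd.Series(ranks, dtype=float)
    ranks = pd.DataFrame(cols)
    for method in ranks.columns:
        missing = ranks.index[ranks[method].isna()]
        if len(missing):
            raise ValueError(
                f"gene {missing[0]!r} has no rank from method {method!r}"
            )
    geomean = pd.Series(
        np.exp(np.log(ranks.to_numpy()).mean(axis=1)), index=ranks.index, name="geomean"
    )
    arith = ranks.mean(axis=1)
    order = sorted(ranks.index, key=lambda g: (geomean[g], arith[g], g))
    final_rank = pd.Series(
        {g: float(i + 1) for i, g in enumerate(order)}, name="final_rank"
    ).reindex(ranks.index)
    return ConsensusRanking(
        ranks=ranks,
        geomean=geomean,
        final_rank=final_rank,
        methods_used=list(ranks.columns),
    )


def select_optimal(
    c: ConsensusRanking, v: PairwiseVariationCurve
) -> Recommendation:
    """Choose how many and which reference genes to use.

    ``optimal_n`` is the smallest n whose V_n falls below the curve's cutoff;
    if none does, the argmin of the curve is used and the fallback flag set.
    The combination is the top ``optimal_n`` genes of the consensus ordering.
    """
    n, v_used, fallback = v.optimal_n()
    ordered = c.ordered_genes()
    if n > len(ordered):
        raise ValueError(
            f"optimal n={n} exceeds the {len(ordered)} ranked genes"
        )
    combination = ordered[:n]
    return Recommendation(
        single_best=ordered[0],
        optimal_n=n,
        combination=combination,
        v_used=v_used,
        fallback=fallback,
    )
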