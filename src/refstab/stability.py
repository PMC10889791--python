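"""The four reference-gene stability algorithms.

Each algorithm maps a complete, aggregated :class:`~refstab.ct_data.CtTable`
to a per-gene stability value where *lower means more stable*:

- **Delta-Ct** (comparative ΔCt): mean, over all partner genes, of the
  standard deviation of the pairwise Ct difference across samples. Units:
  cycles.
- **geNorm**: the M value — mean pairwise variation (SD of log2 quantity
  ratios) of a gene against every other candidate — plus the iterative
  worst-gene exclusion ranking and the V_n/V_{n+1} pairwise-variation curve
  used to choose how many reference genes are enough.
- **NormFinder**: a model-based decomposition of log-quantities into sample
  and gene effects; the stability value is the estimated gene-specific
  standard deviation, or with experimental groups a combination of intragroup
  variation and shrunken intergroup bias.
- **BestKeeper**: descriptive screen on raw Ct — SD (or mean absolute
  deviation), percent CV, and the Pearson correlation of each gene with the
  BestKeeper index (per-sample geometric mean Ct over all candidates).

Delta-Ct, geNorm and NormFinder operate on log-scale quantities and are
therefore invariant to per-sample loading offsets (a constant added to every
gene of one sample); BestKeeper is not, which is the methodological contrast
between the two families.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtTable, relative_quantities

__all__ = [
    "StabilityTable",
    "GenormTrace",
    "PairwiseVariationCurve",
    "delta_ct_stability",
    "genorm_m",
    "genorm_rank",
    "pairwise_variation",
    "normfinder_stability",
    "bestkeeper_stats",
    "run_all_methods",
    "METHODS",
]

METHODS = ("delta_ct", "genorm", "normfinder", "bestkeeper")


def _rank(values: pd.Series, ties: str = "average") -> pd.Series:
    """Ascending ranks, average (default) or min tie handling."""
    method = {"average": "average", "min": "min"}[ties]
    return pd.Series(
        stats.rankdata(values.to_numpy(), method=method), index=values.index
    )


@dataclass
class StabilityTable:
    """Per-gene stability values and ranks for one method."""

    method: str
    table: pd.DataFrame  # columns: value, rank (+ extras for bestkeeper)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def values(self) -> pd.Series:
        return self.table["value"]

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]

    def ordered_genes(self) -> list[str]:
        """Genes from most to least stable (rank ascending, name tiebreak)."""
        t = self.table.copy()
        t["_name"] = t.index
        return list(t.sort_values(["rank", "_name"]).index)


@dataclass
class GenormTrace:
    """Exclusion history of the iterative geNorm ranking."""

    removal_order: list[str]  # first removed = least stable
    m_at_removal: dict[str, float]
    final_pair: tuple[str, str]

    def all_genes(self) -> set[str]:
        return set(self.removal_order) | set(self.final_pair)


@dataclass
class PairwiseVariationCurve:
    """V_n values for n = 2..k-1 with the decision cutoff (default 0.15)."""

    v: pd.Series  # index: n (int), value: V_n
    cutoff: float = 0.15

    def optimal_n(self) -> tuple[int, float, bool]:
        """Smallest n with V_n < cutoff; fallback to argmin (flagged)."""
        below = self.v[self.v < self.cutoff]
        if len(below):
            n = int(below.index[0])
            return n, float(self.v.loc[n]), False
        n = int(self.v.idxmin())
        return n, float(self.v.loc[n]), True


def _require_complete(t: CtTable, op: str) -> None:
    if t.has_missing():
        raise ValueError(f"{op} requires a complete (aggregated) CtTable")


# ---------------------------------------------------------------------------
# Delta-Ct
# ---------------------------------------------------------------------------

def delta_ct_stability(t: CtTable, ties: str = "average") -> StabilityTable:
    """Comparative ΔCt stability: mean SD of pairwise Ct differences.

    For each ordered gene pair (i, j) the per-sample difference
    ``D_s = Ct[i, s] - Ct[j, s]`` has a sample SD (denominator n-1);
    ``stability(i)`` is the mean of SD(D) over all j != i.
    """
    _require_complete(t, "delta_ct_stability")
    k, n = len(t.genes), t.n_samples
    if k < 2:
        raise ValueError("delta_ct_stability needs >=2 genes")
    if n < 3:
        raise ValueError("delta_ct_stability needs >=3 samples")
    ct = t.ct.to_numpy()
    vals = np.empty(k)
    for i in range(k):
        diffs = ct[i][None, :] - ct  # (k, n)
        sds = np.std(diffs, axis=1, ddof=1)
        vals[i] = (sds.sum() - sds[i]) / (k - 1)  # SD of self-diff is 0
    values = pd.Series(vals, index=t.genes, name="value")
    table = pd.DataFrame({"value": values, "rank": _rank(values, ties)})
    return StabilityTable(method="delta_ct", table=table)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _log_quantities(t: CtTable) -> pd.DataFrame:
    q = relative_quantities(t)
    return np.log2(q)


def genorm_m(t: CtTable, subset: Sequence[str] | None = None) -> pd.Series:
    """geNorm M value for each gene of ``subset`` (default: all genes).

    With ``L[g, s] = log2 Q[g, s]``, the pairwise variation
    ``V_ij = SD_s(L[i, .] - L[j, .])`` and ``M(i)`` is the mean of V_ij over
    the other subset genes.
    """
    _require_complete(t, "genorm_m")
    genes = list(subset) if subset is not None else t.genes
    if len(genes) < 2:
        raise ValueError("genorm_m needs a subset of >=2 genes")
    L = _log_quantities(t.subset_genes(genes)).to_numpy()
    k = len(genes)
    m = np.empty(k)
    for i in range(k):
        diffs = L[i][None, :] - L
        sds = np.std(diffs, axis=1, ddof=1)
        m[i] = (sds.sum() - sds[i]) / (k - 1)
    return pd.Series(m, index=genes, name="M")


def genorm_rank(t: CtTable, ties: str = "average") -> tuple[GenormTrace, StabilityTable]:
    """Iterative geNorm ranking by repeated worst-gene exclusion.

    At each step the gene with the largest M on the surviving subset is
    removed (ties broken by removing the lexicographically last name) until
    two genes remain. A gene's stability value is its M at the step it was
    excluded; the final pair both carry the M of the two-gene step and take
    ranks 1 and 2 ordered by their M in the last three-gene step.
    """
    _require_complete(t, "genorm_rank")
    genes = list(t.genes)
    if len(genes) < 2:
        raise ValueError("genorm_rank needs >=2 genes")
    if len(genes) == 2:
        _warnings.warn(
            "genorm_rank on 2 genes: no exclusion possible, both rank 1-2",
            stacklevel=2,
        )
        m = genorm_m(t, genes)
        order = sorted(genes, key=lambda g: (m[g], g))
        table = pd.DataFrame(
            {"value": m, "rank": pd.Series({order[0]: 1.0, order[1]: 2.0})}
        ).reindex(genes)
        trace = GenormTrace([], {g: float(m[g]) for g in genes}, tuple(order))
        return trace, StabilityTable(method="genorm", table=table)

    current = list(genes)
    removal_order: list[str] = []
    m_at_removal: dict[str, float] = {}
    last3: pd.Series | None = None
    while len(current) > 2:
        m = genorm_m(t, current)
        if len(current) == 3:
            last3 = m.copy()
        worst_val = m.max()
        candidates = sorted(m.index[m == worst_val])
        victim = candidates[-1]  # lexicographically last among ties
        removal_order.append(victim)
        m_at_removal[victim] = float(m[victim])
        current.remove(victim)
    m2 = genorm_m(t, current)
    for g in current:
        m_at_removal[g] = float(m2[g])
    assert last3 is not None
    pair = sorted(current, key=lambda g: (float(last3[g]), g))
    final_pair = (pair[0], pair[1])

    # ranks follow the removal procedure: a strict permutation (the procedure
    # itself breaks ties deterministically, so no rank averaging applies here)
    rank_map: dict[str, float] = {final_pair[0]: 1.0, final_pair[1]: 2.0}
    r = 3.0
    for g in reversed(removal_order):
        rank_map[g] = r
        r += 1.0
    table = pd.DataFrame(
        {
            "value": pd.Series(m_at_removal).reindex(genes),
            "rank": pd.Series(rank_map).reindex(genes),
        }
    )
    trace = GenormTrace(removal_order, m_at_removal, final_pair)
    return trace, StabilityTable(method="genorm", table=table)


def pairwise_variation(
    t: CtTable, ranking: Sequence[str] | None = None, cutoff: float = 0.15
) -> PairwiseVariationCurve:
    """geNorm V_n curve for n = 2..k-1 along a best-to-worst ranking.

    ``NF_n[s]`` is the geometric mean of the relative quantities of the n
    best-ranked genes in sample s; ``V_n`` is the SD over samples of
    ``log2(NF_n / NF_{n+1})``. A small V_n means the (n+1)-th gene adds
    nothing, so the conventional reading takes the smallest n with
    V_n < 0.15.
    """
    _require_complete(t, "pairwise_variation")
    if ranking is None:
        ranking = genorm_rank(t)[1].ordered_genes()
    ranking = list(ranking)
    k = len(ranking)
    if k < 3:
        raise ValueError("pairwise_variation needs >=3 ranked genes")
    logq = _log_quantities(t.subset_genes(ranking))
    log_nf = {}
    for n in range(2, k + 1):
        log_nf[n] = logq.iloc[:n].mean(axis=0)  # log2 of geometric mean
    v = {}
    for n in range(2, k):
        ratio = log_nf[n] - log_nf[n + 1]
        v[n] = float(np.std(ratio.to_numpy(), ddof=1))
    return PairwiseVariationCurve(v=pd.Series(v), cutoff=cutoff)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _groupwise_unbiased_var(x: np.ndarray, k: int) -> np.ndarray:
    """Bias-corrected gene-specific variances after gene-mean subtraction.

    ``x`` is a (k, n) matrix of sample-centered log quantities (one group).
    Subtracting each gene's own mean and pooling squared residuals gives raw
    variances ``v_g`` that are biased because the sample-centering step mixed
    every gene's noise into every residual; the correction solves
    ``v_g = (1 - 2/k) * sigma2_g + T / k**2`` with ``T = sum_g v_g / (1 - 1/k)``.
    """
    n = x.shape[1]
    r = x - x.mean(axis=1, keepdims=True)
    v = (r**2).sum(axis=1) / (n - 1)
    total = v.sum() / (1.0 - 1.0 / k)
    sigma2 = (v - total / k**2) / (1.0 - 2.0 / k)
    return np.maximum(sigma2, 0.0)


def normfinder_stability(
    t: CtTable, groups: Sequence[str] | None = None, ties: str = "average"
) -> StabilityTable:
    """NormFinder model-based stability on log2 relative quantities.

    Without groups the stability value is the estimated gene-specific SD
    after removing sample (loading) and gene effects, with a bias correction
    for the gene-mean subtraction. With groups it combines the shrunken
    absolute intergroup difference with the intragroup standard error:
    ``rho_g = mean_gamma(|d_g,gamma * w| + sqrt(sigma2_g,gamma / n_gamma))``.
    """
    _require_complete(t, "normfinder_stability")
    k = len(t.genes)
    if k < 3:
        raise ValueError("normfinder_stability needs >=3 genes")
    z = _log_quantities(t).to_numpy()
    x = z - z.mean(axis=0, keepdims=True)  # sample-centered

    if groups is None:
        labels = None
    else:
        labels = pd.Series(list(groups))
        if len(labels) != t.n_samples:
            raise ValueError("groups must have one label per sample")

    if labels is None:
        sigma2 = _groupwise_unbiased_var(x, k)
        values = pd.Series(np.sqrt(sigma2), index=t.genes, name="value")
    else:
        uniq = list(dict.fromkeys(labels))
        G = len(uniq)
        if G < 2:
            # one group degenerates to the ungrouped estimator
            sigma2 = _groupwise_unbiased_var(x, k)
            values = pd.Series(np.sqrt(sigma2), index=t.genes, name="value")
        else:
            means = np.empty((k, G))
            sig2 = np.empty((k, G))
            n_g = np.empty(G)
            for j, gl in enumerate(uniq):
                mask = (labels == gl).to_numpy()
                n_g[j] = mask.sum()
                if n_g[j] < 2:
                    raise ValueError(f"group {gl!r} has fewer than 2 samples")
                block = x[:, mask]
                means[:, j] = block.mean(axis=1)
                sig2[:, j] = _groupwise_unbiased_var(block, k)
            d = means - means.mean(axis=1, keepdims=True)
            var_of_mean = sig2 / n_g[None, :]
            gamma_hat = max(
                (d**2).sum() / (k * (G - 1)) - var_of_mean.mean(), 0.0
            )
            denom = gamma_hat + var_of_mean
            with np.errstate(invalid="ignore"):
                w = np.where(denom > 0, gamma_hat / np.where(denom > 0, denom, 1.0), 0.0)
            rho = (np.abs(d * w) + np.sqrt(var_of_mean)).mean(axis=1)
            values = pd.Series(rho, index=t.genes, name="value")

    table = pd.DataFrame({"value": values, "rank": _rank(values, ties)})
    return StabilityTable(method="normfinder", table=table)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper_stats(
    t: CtTable, deviation: str = "sd", ties: str = "average"
) -> StabilityTable:
    """BestKeeper descriptive stability on raw Ct.

    Per gene: n, geometric and arithmetic mean Ct, min, max, the chosen
    deviation (sample SD or mean absolute deviation from the mean), percent
    CV (100 * deviation / mean Ct), and the Pearson correlation of the gene's
    Ct with the BestKeeper index (per-sample geometric mean Ct over all
    candidate genes). Ranking is ascending by deviation, ties broken by CV
    then gene name.
    """
    _require_complete(t, "bestkeeper_stats")
    if deviation not in {"sd", "mad"}:
        raise ValueError("deviation must be 'sd' or 'mad'")
    if t.n_samples < 3:
        raise ValueError("bestkeeper_stats needs >=3 samples")
    ct = t.ct.to_numpy()
    if (ct <= 0).any():
        raise ValueError("BestKeeper requires strictly positive Ct")
    index = np.exp(np.log(ct).mean(axis=0))  # geometric mean per sample
    rows = {}
    for i, g in enumerate(t.genes):
        v = ct[i]
        mean = float(v.mean())
        if deviation == "sd":
            dev = float(np.std(v, ddof=1))
        else:
            dev = float(np.mean(np.abs(v - mean)))
        if np.std(v) == 0 or np.std(index) == 0:
            r = math.nan  # correlation undefined for a constant series
        else:
            r = float(stats.pearsonr(v, index)[0])
        rows[g] = {
            "n": int(v.size),
            "geo_mean_ct": float(np.exp(np.log(v).mean())),
            "mean_ct": mean,
            "min": float(v.min()),
            "max": float(v.max()),
            "value": dev,
            "cv_pct": 100.0 * dev / mean,
            "r_index": r,
        }
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(t.genes)
    # rank by deviation, ties by CV then name
    order = sorted(
        t.genes, key=lambda g: (table.at[g, "value"], table.at[g, "cv_pct"], g)
    )
    strict = pd.Series({g: float(i + 1) for i, g in enumerate(order)})
    if ties == "average":
        key = table.apply(lambda r: (r["value"], r["cv_pct"]), axis=1)
        table["rank"] = strict.reindex(t.genes).groupby(key).transform("mean")
    else:
        table["rank"] = strict.reindex(t.genes)
    return StabilityTable(method="bestkeeper", table=table)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_all_methods(
    t: CtTable,
    groups: Sequence[str] | None = None,
    methods: Sequence[str] = METHODS,
    deviation: str = "sd",
    ties: str = "average",
) -> dict[str, StabilityTable]:
    """Run the requested stability methods and return them keyed by name."""
    out: dict[str, StabilityTable] = {}
    for m in methods:
        if m == "delta_ct":
            out[m] = delta_ct_stability(t, ties=ties)
        elif m == "genorm":
            out[m] = genorm_rank(t, ties=ties)[1]
        elif m == "normfinder":
            out[m] = normfinder_stability(t, groups=groups, ties=ties)
        elif m == "bestkeeper":
            out[m] = bestkeeper_stats(t, deviation=deviation, ties=ties)
        else:
            raise ValueError(f"unknown method {m!r}")
    return out
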