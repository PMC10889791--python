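"""Multi-reference 2^-ddCt relative quantification and group statistics.

The target gene's expression is normalized to the arithmetic mean Ct of the
chosen reference genes (equivalent, at equal amplification factors, to
dividing by the geometric mean of the reference quantities) and calibrated to
the mean of a designated calibrator group:

    dCt[s]  = Ct[target, s] - mean_r Ct[r, s]
    ddCt[s] = dCt[s] - mean over calibrator samples of dCt
    fold[s] = 2 ** (-ddCt[s])

An efficiency-corrected variant raises each gene's own amplification factor
to the -Ct power instead of assuming perfect doubling.

Group comparisons follow the study's conventions: a pooled-variance Student's
t test for two groups, and one-way ANOVA with Tukey's HSD and a compact
letter display for three or more.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtTable

__all__ = [
    "ExpressionResult",
    "TwoGroupTest",
    "AnovaTukeyResult",
    "ddct_expression",
    "two_group_test",
    "anova_tukey",
    "compact_letters",
]


@dataclass
class ExpressionResult:
    """Per-sample fold changes and per-group summaries for one target gene."""

    target: str
    reference_set: list[str]
    calibrator_group: str
    per_sample: pd.DataFrame  # sample_id, group, delta_ct, ddct, fold
    group_summary: pd.DataFrame  # group x (n, mean_fold, se_fold)


@dataclass
class TwoGroupTest:
    statistic: float
    pvalue: float
    df: int
    degenerate: bool = False


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # group_a, group_b, p_adj, significant
    letters: dict[str, str]
    alpha: float


def ddct_expression(
    t: CtTable,
    target: str,
    refs: Sequence[str],
    calibrator_group: str,
    efficiency_corrected: bool = False,
) -> ExpressionResult:
    """Relative expression of ``target`` against a reference-gene set.

    With ``efficiency_corrected=True`` each gene's amplification factor
    enters the exponent (Pfaffl-style); otherwise perfect doubling (A = 2)
    is assumed and the computation is the textbook 2^-ddCt.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("refs must be non-empty")
    for g in [target, *refs]:
        if g not in t.ct.index:
            raise KeyError(f"gene {g!r} not in table")
    groups = t.samples["group"]
    cal_mask = (groups == calibrator_group).to_numpy()
    if not cal_mask.any():
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    if t.has_missing():
        raise ValueError("ddct_expression requires a complete table")

    if efficiency_corrected:
        # per-sample log2 ratio: target quantity over geometric mean of refs
        a_t = float(t.amp_factor[target])
        log2_target = -t.ct.loc[target].to_numpy() * math.log2(a_t)
        log2_refs = np.mean(
            [
                -t.ct.loc[r].to_numpy() * math.log2(float(t.amp_factor[r]))
                for r in refs
            ],
            axis=0,
        )
        neg_dct = log2_target - log2_refs  # -dCt on the log2 scale
        dct = -neg_dct
    else:
        ref_mean = t.ct.loc[refs].mean(axis=0).to_numpy()
        dct = t.ct.loc[target].to_numpy() - ref_mean
    ddct = dct - dct[cal_mask].mean()
    fold = 2.0 ** (-ddct)

    per_sample = pd.DataFrame(
        {
            "sample_id": t.samples["sample_id"].to_numpy(),
            "group": groups.to_numpy(),
            "delta_ct": dct,
            "ddct": ddct,
            "fold": fold,
        }
    )
    rows = []
    for g in dict.fromkeys(groups):
        f = fold[(groups == g).to_numpy()]
        n = f.size
        sd = float(np.std(f, ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "group": g,
                "n": n,
                "mean_fold": float(f.mean()),
                "se_fold": sd / math.sqrt(n) if n else math.nan,
            }
        )
    summary = pd.DataFrame(rows).set_index("group")
    return ExpressionResult(
        target=target,
        reference_set=refs,
        calibrator_group=calibrator_group,
        per_sample=per_sample,
        group_summary=summary,
    )


def two_group_test(values: Sequence[float], groups: Sequence[str]) -> TwoGroupTest:
    """Two-sided pooled-variance Student's t test between exactly two groups."""
    values = np.asarray(values, dtype=float)
    labels = pd.Series(list(groups))
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"two_group_test needs exactly 2 groups, got {len(uniq)}")
    a = values[(labels == uniq[0]).to_numpy()]
    b = values[(labels == uniq[1]).to_numpy()]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 values")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / df
    if pooled == 0:
        if a.mean() == b.mean():
            return TwoGroupTest(0.0, 1.0, df, degenerate=True)
        return TwoGroupTest(
            math.copysign(math.inf, a.mean() - b.mean()), 0.0, df, degenerate=True
        )
    res = stats.ttest_ind(a, b, equal_var=True)
    return TwoGroupTest(float(res.statistic), float(res.pvalue), df)


def compact_letters(
    means_desc: Sequence[str], sig_pairs: Sequence[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb on the significance graph.

    ``means_desc`` lists the groups from largest to smallest mean;
    ``sig_pairs`` are the significantly different pairs. Two groups share a
    letter iff they are not significantly different; letters run
    alphabetically from the group with the largest mean.
    """
    groups = list(means_desc)
    columns: list[set[str]] = [set(groups)]
    for a, b in sig_pairs:
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop duplicates and proper subsets
        absorbed: list[set[str]] = []
        for col in new_cols:
            if any(col <= other for other in absorbed):
                continue
            absorbed = [o for o in absorbed if not (o <= col)]
            absorbed.append(col)
        columns = absorbed
    pos = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(pos[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def anova_tukey(
    values: Sequence[float], groups: Sequence[str], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letter display.

    The Tukey adjusted p-values come from the studentized-range
    distribution; groups sharing no letter differ at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(list(groups))
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 3:
        raise ValueError("anova_tukey needs >=3 groups (use two_group_test)")
    arrays = []
    for g in uniq:
        arr = values[(labels == g).to_numpy()]
        if len(arr) < 2:
            raise ValueError(f"group {g!r} needs >=2 values")
        arrays.append(arr)
    f_stat, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    rows = []
    sig_pairs = []
    for i, j in itertools.combinations(range(len(uniq)), 2):
        p_adj = float(tukey.pvalue[i, j])
        significant = p_adj < alpha
        if significant:
            sig_pairs.append((uniq[i], uniq[j]))
        rows.append(
            {
                "group_a": uniq[i],
                "group_b": uniq[j],
                "p_adj": p_adj,
                "significant": significant,
            }
        )
    means = {g: arr.mean() for g, arr in zip(uniq, arrays)}
    order = sorted(uniq, key=lambda g: -means[g])
    letters = compact_letters(order, sig_pairs)
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        pvalue=float(p),
        pairwise=pd.DataFrame(rows),
        letters=letters,
        alpha=alpha,
    )
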