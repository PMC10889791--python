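"""Ct data model, I/O, technical-replicate aggregation and descriptive statistics.

The central container is :class:`CtTable`: a rectangular matrix of
cycle-threshold (Ct) values, genes in rows and samples in columns, carrying
per-sample metadata (treatment group, biological and technical replicate) and a
per-gene amplification factor ``A`` (``A = 1 + E/100`` where ``E`` is the
amplification efficiency in percent; ``A = 2`` is perfect doubling).

All stability algorithms downstream consume an *aggregated* table: one column
per biological sample, technical replicates averaged, no missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CT_RANGE",
    "AMP_FACTOR_RANGE",
    "CtTable",
    "AggregationWarning",
    "read_ct_table",
    "write_ct_table",
    "aggregate_technical_replicates",
    "summarize_ct",
    "relative_quantities",
]

#: Valid Ct interval (open at 0, closed at 45); 40-cycle protocols with margin.
CT_RANGE = (0.0, 45.0)

#: Plausible per-gene amplification-factor interval.
AMP_FACTOR_RANGE = (1.5, 2.3)

#: Cell contents treated as a missing Ct on input (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "n/a", "nan", "undetermined", "undet", "-"})

META_COLUMNS = ("sample_id", "group", "bio_rep", "tech_rep")


@dataclass
class AggregationWarning:
    """One (sample, gene) cell whose technical replicates disagreed."""

    sample_id: str
    gene: str
    tech_sd: float
    n_reps: int

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "gene": self.gene,
            "tech_sd": self.tech_sd,
            "n_reps": self.n_reps,
        }


@dataclass
class CtTable:
    """Genes x samples Ct matrix with sample metadata and amplification factors.

    Parameters
    ----------
    ct
        DataFrame indexed by gene name; columns are consecutive integers
        aligned with the rows of ``samples``. NaN marks a missing measurement
        (only legal before technical-replicate aggregation).
    samples
        One row per column of ``ct`` with columns ``sample_id``, ``group``
        (may be empty string), ``bio_rep`` and ``tech_rep`` (positive ints).
    amp_factor
        Per-gene amplification factor ``A``; defaults to 2.0 for every gene.
    """

    ct: pd.DataFrame
    samples: pd.DataFrame
    amp_factor: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        self.ct.columns = pd.RangeIndex(self.ct.shape[1])
        self.samples = self.samples.reset_index(drop=True)
        if self.amp_factor is None:
            self.amp_factor = pd.Series(2.0, index=self.ct.index)
        else:
            self.amp_factor = pd.Series(self.amp_factor, dtype=float).reindex(
                self.ct.index
            )
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.ct.index.has_duplicates:
            dup = self.ct.index[self.ct.index.duplicated()][0]
            raise ValueError(f"duplicate gene name: {dup!r}")
        if self.ct.shape[1] != len(self.samples):
            raise ValueError(
                f"matrix has {self.ct.shape[1]} columns but metadata lists "
                f"{len(self.samples)} samples"
            )
        for col in META_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
        key = list(zip(self.samples["sample_id"], self.samples["tech_rep"]))
        if len(set(key)) != len(key):
            seen = set()
            for k in key:
                if k in seen:
                    raise ValueError(f"duplicate (sample_id, tech_rep): {k}")
                seen.add(k)
        vals = self.ct.to_numpy()
        finite = vals[~np.isnan(vals)]
        lo, hi = CT_RANGE
        if finite.size and ((finite <= lo) | (finite > hi)).any():
            bad = finite[(finite <= lo) | (finite > hi)][0]
            raise ValueError(f"Ct value {bad} outside ({lo}, {hi}]")
        if self.amp_factor.isna().any():
            raise ValueError("amp_factor missing for some gene")
        alo, ahi = AMP_FACTOR_RANGE
        if ((self.amp_factor < alo) | (self.amp_factor > ahi)).any():
            g = self.amp_factor[(self.amp_factor < alo) | (self.amp_factor > ahi)].index[0]
            raise ValueError(
                f"amp_factor for {g!r} outside [{alo}, {ahi}]: {self.amp_factor[g]}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def n_samples(self) -> int:
        return self.ct.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]

    def has_missing(self) -> bool:
        return bool(self.ct.isna().any().any())

    def is_aggregated(self) -> bool:
        """True when every sample_id appears exactly once (tech reps merged)."""
        return not self.samples["sample_id"].duplicated().any()

    def subset_genes(self, genes: Sequence[str]) -> "CtTable":
        missing = [g for g in genes if g not in self.ct.index]
        if missing:
            raise KeyError(f"genes not in table: {missing}")
        return CtTable(
            ct=self.ct.loc[list(genes)].copy(),
            samples=self.samples.copy(),
            amp_factor=self.amp_factor.loc[list(genes)].copy(),
        )

    def copy(self) -> "CtTable":
        return CtTable(self.ct.copy(), self.samples.copy(), self.amp_factor.copy())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_ct_cell(raw, where: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    s = str(raw).strip()
    if s.lower() in MISSING_TOKENS:
        return math.nan
    try:
        val = float(s)
    except ValueError:
        return math.nan  # unparseable text records as missing
    lo, hi = CT_RANGE
    if not (lo < val <= hi):
        raise ValueError(f"Ct {val} outside ({lo}, {hi}] at {where}")
    return val


def read_ct_table(
    path: str | Path,
    layout: str = "long",
    schema: Mapping[str, str] | None = None,
    amp_factor: Mapping[str, float] | None = None,
) -> CtTable:
    """Read a delimited Ct file in ``long`` or ``wide`` layout.

    Long layout needs columns ``sample_id, gene, ct`` (``group``, ``bio_rep``,
    ``tech_rep`` optional, defaulting to ``""``/1/1); wide layout needs
    ``sample_id`` plus one column per gene. ``schema`` maps canonical column
    names to the file's actual headers. ``Undetermined``/``NA``-style cells
    become missing values; Ct outside (0, 45] is a hard error naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in {"long", "wide"}:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    if layout == "long":
        required = {"sample_id", "gene", "ct"}
        missing = required - set(raw.columns)
        if missing:
            raise ValueError(f"long layout requires columns {sorted(missing)}")
        for col, default in (("group", ""), ("bio_rep", "1"), ("tech_rep", "1")):
            if col not in raw.columns:
                raw[col] = default
        raw["bio_rep"] = raw["bio_rep"].fillna("1").astype(int)
        raw["tech_rep"] = raw["tech_rep"].fillna("1").astype(int)
        raw["group"] = raw["group"].fillna("")
        dup_key = raw[["sample_id", "tech_rep", "gene"]].apply(tuple, axis=1)
        if dup_key.duplicated().any():
            first = dup_key[dup_key.duplicated()].iloc[0]
            raise ValueError(f"duplicate (sample_id, tech_rep, gene) row: {first}")
        raw["_ct"] = [
            _parse_ct_cell(v, f"row {i + 2}")  # +2: header + 1-based
            for i, v in zip(raw.index, raw["ct"])
        ]
        # column order: first appearance of (sample_id, tech_rep)
        sample_key = raw[["sample_id", "group", "bio_rep", "tech_rep"]].drop_duplicates(
            subset=["sample_id", "tech_rep"]
        )
        genes = list(dict.fromkeys(raw["gene"]))
        col_index = {
            (sid, tr): j
            for j, (sid, tr) in enumerate(
                zip(sample_key["sample_id"], sample_key["tech_rep"])
            )
        }
        mat = np.full((len(genes), len(sample_key)), np.nan)
        gidx = {g: i for i, g in enumerate(genes)}
        for sid, tr, g, v in zip(
            raw["sample_id"], raw["tech_rep"], raw["gene"], raw["_ct"]
        ):
            mat[gidx[g], col_index[(sid, tr)]] = v
        ct = pd.DataFrame(mat, index=genes)
        samples = sample_key.reset_index(drop=True)
    else:
        if "sample_id" not in raw.columns:
            raise ValueError("wide layout requires a sample_id column")
        for col, default in (("group", ""), ("bio_rep", "1"), ("tech_rep", "1")):
            if col not in raw.columns:
                raw[col] = default
        raw["bio_rep"] = raw["bio_rep"].fillna("1").astype(int)
        raw["tech_rep"] = raw["tech_rep"].fillna("1").astype(int)
        raw["group"] = raw["group"].fillna("")
        genes = [c for c in raw.columns if c not in META_COLUMNS]
        dup_key = raw[["sample_id", "tech_rep"]].apply(tuple, axis=1)
        if dup_key.duplicated().any():
            first = dup_key[dup_key.duplicated()].iloc[0]
            raise ValueError(f"duplicate (sample_id, tech_rep) row: {first}")
        mat = np.full((len(genes), len(raw)), np.nan)
        for i, g in enumerate(genes):
            mat[i] = [
                _parse_ct_cell(v, f"row {j + 2}, column {g!r}")
                for j, v in zip(raw.index, raw[g])
            ]
        ct = pd.DataFrame(mat, index=genes)
        samples = raw[list(META_COLUMNS)].reset_index(drop=True)

    af = None
    if amp_factor is not None:
        af = pd.Series({g: amp_factor.get(g, 2.0) for g in ct.index})
    return CtTable(ct=ct, samples=samples, amp_factor=af)


def write_ct_table(t: CtTable, path: str | Path, layout: str = "long") -> None:
    """Write a CtTable as delimited text (inverse of :func:`read_ct_table`).

    Full float precision is preserved so a round trip reproduces the matrix
    exactly.
    """
    path = Path(path)
    sep = _sep_for(path)
    if layout == "long":
        rows = []
        for j, meta in t.samples.iterrows():
            for g in t.genes:
                v = t.ct.at[g, j]
                rows.append(
                    {
                        "sample_id": meta["sample_id"],
                        "group": meta["group"],
                        "bio_rep": meta["bio_rep"],
                        "tech_rep": meta["tech_rep"],
                        "gene": g,
                        "ct": "" if math.isnan(v) else repr(float(v)),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        out = t.samples.copy()
        for g in t.genes:
            out[g] = [
                "" if math.isnan(v) else repr(float(v)) for v in t.ct.loc[g]
            ]
        out.to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


# ---------------------------------------------------------------------------
# Aggregation and summaries
# ---------------------------------------------------------------------------

def aggregate_technical_replicates(
    t: CtTable,
    max_tech_sd: float = 0.5,
    drop_incomplete_samples: bool = False,
) -> tuple[CtTable, list[AggregationWarning]]:
    """Average technical replicates per biological sample.

    Each (sample_id, gene) cell becomes the arithmetic mean of its non-missing
    technical-replicate Ct values. A warning record is emitted for any cell
    whose technical SD exceeds ``max_tech_sd`` (default 0.5 cycles). The
    result must be complete: a cell with *all* replicates missing is an error,
    and a sample left with any missing gene is either dropped
    (``drop_incomplete_samples=True``) or an error.
    """
    warnings: list[AggregationWarning] = []
    order = list(dict.fromkeys(t.samples["sample_id"]))
    cols, metas, dropped = [], [], []
    for sid in order:
        mask = (t.samples["sample_id"] == sid).to_numpy()
        block = t.ct.loc[:, mask]
        meta = t.samples[mask].iloc[0]
        means = np.full(len(t.genes), np.nan)
        incomplete = False
        for i, g in enumerate(t.genes):
            vals = block.loc[g].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                if drop_incomplete_samples:
                    incomplete = True
                    continue
                raise ValueError(
                    f"all technical replicates missing for sample {sid!r}, gene {g!r}"
                )
            means[i] = vals.mean()
            if vals.size >= 2:
                sd = float(np.std(vals, ddof=1))
                if sd > max_tech_sd:
                    warnings.append(AggregationWarning(sid, g, sd, int(vals.size)))
        if incomplete:
            dropped.append(sid)
            continue
        cols.append(means)
        metas.append(
            {
                "sample_id": sid,
                "group": meta["group"],
                "bio_rep": meta["bio_rep"],
                "tech_rep": 1,
            }
        )
    if not cols:
        raise ValueError("no complete samples after aggregation")
    ct = pd.DataFrame(np.column_stack(cols), index=t.genes)
    out = CtTable(ct=ct, samples=pd.DataFrame(metas), amp_factor=t.amp_factor.copy())
    if dropped:
        warnings.append(AggregationWarning(";".join(dropped), "<dropped samples>", math.nan, 0))
    return out, warnings


def summarize_ct(t: CtTable) -> pd.DataFrame:
    """Per-gene descriptive Ct statistics: n, mean, SD, SE, min, max, median."""
    if t.has_missing():
        raise ValueError("summarize_ct requires an aggregated, complete table")
    rows = {}
    for g in t.genes:
        v = t.ct.loc[g].to_numpy(dtype=float)
        n = v.size
        sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
        rows[g] = {
            "n": n,
            "mean": float(v.mean()),
            "sd": sd,
            "se": sd / math.sqrt(n) if n else math.nan,
            "min": float(v.min()),
            "max": float(v.max()),
            "median": float(np.median(v)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.reindex(t.genes)


def relative_quantities(t: CtTable) -> pd.DataFrame:
    """Linear-scale relative quantities Q = A**(minCt - Ct), per gene.

    The most abundant sample of each gene (its minimum Ct) is the calibrator,
    so Q lies in (0, 1] with max exactly 1 per gene. ``A`` is the gene's
    amplification factor (2.0 unless a standard curve supplied one).
    """
    if t.has_missing():
        raise ValueError("relative_quantities requires a complete table")
    q = np.empty_like(t.ct.to_numpy())
    for i, g in enumerate(t.genes):
        row = t.ct.loc[g].to_numpy(dtype=float)
        a = float(t.amp_factor[g])
        q[i] = a ** (row.min() - row)
    return pd.DataFrame(q, index=t.genes, columns=t.ct.columns)
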