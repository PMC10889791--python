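"""Standard-curve fitting and amplification-efficiency arithmetic.

A qPCR standard curve regresses Ct against log10 of the template's relative
concentration over a dilution series. The slope converts to per-cycle
amplification efficiency by

    E(%) = (10**(-1/slope) - 1) * 100

so a slope of -log2(10) = -3.3219 corresponds to perfect doubling (E = 100%,
amplification factor A = 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "StandardCurveFit",
    "fit_standard_curve",
    "efficiency_from_slope",
    "slope_from_efficiency",
    "read_dilution_series",
    "fit_curves_table",
]

#: Default 5-fold dilution series used when none is supplied.
DEFAULT_DILUTIONS = (1 / 5, 1 / 25, 1 / 125, 1 / 625, 1 / 3125)


@dataclass
class DilutionSeries:
    """A dilution series for one gene: (relative concentration, Ct) pairs."""

    gene: str
    concentrations: Sequence[float]
    ct: Sequence[float]

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.concentrations.shape != self.ct.shape:
            raise ValueError("concentrations and ct must have equal length")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be strictly positive")

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.concentrations))


@dataclass
class StandardCurveFit:
    """OLS fit of Ct vs log10(concentration) with derived efficiency."""

    gene: str
    slope: float
    intercept: float
    r2: float
    efficiency_pct: float = field(init=False)
    amp_factor: float = field(init=False)
    valid: bool = field(init=False)

    def __post_init__(self) -> None:
        self.valid = self.slope < 0
        self.efficiency_pct = efficiency_from_slope(self.slope)
        self.amp_factor = 1.0 + self.efficiency_pct / 100.0


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency from a standard-curve slope.

    ``E = (10**(-1/slope) - 1) * 100``. Exact (unrounded); round only for
    presentation.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def slope_from_efficiency(efficiency_pct: float) -> float:
    """Inverse of :func:`efficiency_from_slope`: -1/log10(1 + E/100)."""
    if efficiency_pct <= -100:
        raise ValueError("efficiency must exceed -100%")
    return -1.0 / math.log10(1.0 + efficiency_pct / 100.0)


def fit_standard_curve(d: DilutionSeries) -> StandardCurveFit:
    """Ordinary least squares of Ct on log10(relative concentration).

    Replicate Ct values at a dilution enter as individual points. ``r2`` is
    the squared Pearson correlation of observed Ct with log10 concentration
    (identical to the OLS coefficient of determination in simple regression).
    A non-negative slope yields a fit flagged invalid but still reported.
    """
    if d.n_distinct < 3:
        raise ValueError(
            f"need >=3 distinct concentrations, got {d.n_distinct} for {d.gene!r}"
        )
    x = np.log10(np.asarray(d.concentrations, dtype=float))
    y = np.asarray(d.ct, dtype=float)
    res = stats.linregress(x, y)
    return StandardCurveFit(
        gene=d.gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


# ---------------------------------------------------------------------------
# Tabular interface (CLI plumbing)
# ---------------------------------------------------------------------------

def read_dilution_series(path: str | Path) -> list[DilutionSeries]:
    """Read `gene,concentration,ct` (or `gene,dilution,ct` with dilution = 1/x)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "concentration" in df.columns:
        conc = df["concentration"].astype(float)
    elif "dilution" in df.columns:
        conc = 1.0 / df["dilution"].astype(float)
    else:
        raise ValueError("need a 'concentration' or 'dilution' column")
    if "gene" not in df.columns or "ct" not in df.columns:
        raise ValueError("need 'gene' and 'ct' columns")
    out = []
    for gene in dict.fromkeys(df["gene"]):
        m = df["gene"] == gene
        out.append(DilutionSeries(gene=gene, concentrations=conc[m], ct=df.loc[m, "ct"]))
    return out


def fit_curves_table(series: Sequence[DilutionSeries]) -> pd.DataFrame:
    """Fit every series; one row per gene with slope, r2, E% and A."""
    rows = []
    for d in series:
        f = fit_standard_curve(d)
        rows.append(
            {
                "gene": f.gene,
                "slope": f.slope,
                "intercept": f.intercept,
                "r2": f.r2,
                "efficiency_pct": f.efficiency_pct,
                "amp_factor": f.amp_factor,
                "valid": f.valid,
            }
        )
    return pd.DataFrame(rows)
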