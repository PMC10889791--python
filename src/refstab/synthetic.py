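"""Seeded simulation of RT-qPCR Ct datasets with known stability structure.

The generative model mirrors a standard reference-gene screening design:

    Ct[g, group, bio, tech] = baseline_g + delta[g, group] + a[group, bio] + eps

- ``delta ~ Normal(0, condition_sd_g)``, drawn once per (gene, group): the
  treatment-driven dysregulation that makes a gene a *bad* reference. A gene
  with ``condition_sd = 0`` is truly stable.
- ``a ~ Normal(0, sample_loading_sd)``, drawn once per biological sample and
  shared by all genes: the RNA-input/loading offset that log-ratio methods
  cancel out.
- ``eps ~ Normal(0, tech_sd)`` per well: technical (pipetting/instrument)
  noise.

The ground-truth stability ordering is therefore the ordering of
``condition_sd`` (ties broken by name), which parameter-recovery tests can
check against every algorithm's output.

The ``paper_like`` preset emulates a 15-candidate screen: gene baselines
spread over 17-31 cycles, six treatment groups, 3 biological x 3 technical
replicates, loading SD 0.5 cycles and technical SD 0.3 cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ct_data import CtTable
from .standard_curve import DEFAULT_DILUTIONS, DilutionSeries, slope_from_efficiency

__all__ = [
    "GeneSpec",
    "GroupSpec",
    "TargetSpec",
    "SimulationSpec",
    "simulate_ct",
    "simulate_dilution_series",
    "paper_like",
    "PAPER_LIKE_GENES",
]

#: Candidate reference genes commonly screened in hemipteran insects.
PAPER_LIKE_GENES = (
    "beta-actin",
    "EF1a",
    "EF2",
    "Ferritin",
    "GAPDH",
    "alpha-TUB",
    "beta-TUB",
    "AK",
    "GST",
    "RPL8",
    "RPL10",
    "RPL32",
    "RPS11",
    "RPS15",
    "RPS20",
)

#: Clipping bounds for generated Ct values (cycles).
CT_CLIP = (5.0, 45.0)


@dataclass
class GeneSpec:
    name: str
    baseline_ct: float
    condition_sd: float = 0.0
    amp_factor: float = 2.0

    def __post_init__(self) -> None:
        if not (10.0 < self.baseline_ct < 35.0):
            raise ValueError(f"baseline_ct must be in (10, 35), got {self.baseline_ct}")
        if self.condition_sd < 0:
            raise ValueError("condition_sd must be >= 0")


@dataclass
class GroupSpec:
    label: str
    n_bio: int = 3

    def __post_init__(self) -> None:
        if self.n_bio < 1:
            raise ValueError("n_bio must be >= 1")


@dataclass
class TargetSpec:
    """Optional target gene with fixed per-group log2 fold effects."""

    name: str
    baseline_ct: float
    group_log2_fold: Mapping[str, float] = field(default_factory=dict)
    amp_factor: float = 2.0


@dataclass
class SimulationSpec:
    genes: Sequence[GeneSpec]
    groups: Sequence[GroupSpec]
    n_tech: int = 3
    sample_loading_sd: float = 0.5
    tech_sd: float = 0.3
    seed: int = 0
    target: TargetSpec | None = None

    def __post_init__(self) -> None:
        if self.n_tech < 1:
            raise ValueError("n_tech must be >= 1")
        if self.sample_loading_sd < 0 or self.tech_sd < 0:
            raise ValueError("SDs must be >= 0")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")


@dataclass
class GroundTruth:
    """What the generator knows: per-gene condition SD and its ordering."""

    condition_sd: dict[str, float]
    clipped_wells: int

    def stability_order(self) -> list[str]:
        """Genes from most to least stable (ascending condition SD)."""
        return sorted(self.condition_sd, key=lambda g: (self.condition_sd[g], g))

    def as_dict(self) -> dict:
        return {
            "condition_sd": dict(self.condition_sd),
            "stability_order": self.stability_order(),
            "clipped_wells": self.clipped_wells,
        }


def simulate_ct(spec: SimulationSpec) -> tuple[CtTable, GroundTruth]:
    """Draw one Ct dataset from the generative model; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    gene_names = [g.name for g in genes]
    k = len(genes)
    n_groups = len(spec.groups)

    delta = rng.normal(0.0, 1.0, size=(k, n_groups))
    for i, g in enumerate(genes):
        delta[i] *= g.condition_sd

    target = spec.target
    if target is not None and target.name in gene_names:
        raise ValueError(f"target {target.name!r} collides with a candidate gene")

    cols: list[np.ndarray] = []
    metas: list[dict] = []
    target_rows: list[np.ndarray] = []
    clipped = 0
    for j, grp in enumerate(spec.groups):
        for b in range(1, grp.n_bio + 1):
            loading = rng.normal(0.0, spec.sample_loading_sd)
            for tech in range(1, spec.n_tech + 1):
                eps = rng.normal(0.0, spec.tech_sd, size=k)
                ct = np.array([g.baseline_ct for g in genes]) + delta[:, j] + loading + eps
                lo, hi = CT_CLIP
                n_bad = int(((ct < lo) | (ct > hi)).sum())
                clipped += n_bad
                ct = np.clip(ct, lo, hi)
                col = ct
                if target is not None:
                    fold = float(target.group_log2_fold.get(grp.label, 0.0))
                    shift = -fold / np.log2(target.amp_factor)
                    tct = (
                        target.baseline_ct
                        + loading
                        + shift
                        + rng.normal(0.0, spec.tech_sd)
                    )
                    tct = float(np.clip(tct, lo, hi))
                    target_rows.append(np.array([tct]))
                cols.append(col)
                metas.append(
                    {
                        "sample_id": f"{grp.label}_b{b}",
                        "group": grp.label,
                        "bio_rep": b,
                        "tech_rep": tech,
                    }
                )
    mat = np.column_stack(cols)
    names = list(gene_names)
    amp = {g.name: g.amp_factor for g in genes}
    if target is not None:
        mat = np.vstack([mat, np.concatenate(target_rows)[None, :]])
        names.append(target.name)
        amp[target.name] = target.amp_factor
    table = CtTable(
        ct=pd.DataFrame(mat, index=names),
        samples=pd.DataFrame(metas),
        amp_factor=pd.Series(amp),
    )
    truth = GroundTruth(
        condition_sd={g.name: g.condition_sd for g in genes},
        clipped_wells=clipped,
    )
    return table, truth


def simulate_dilution_series(
    true_efficiency_pct: float,
    intercept: float = 30.0,
    noise_sd: float = 0.0,
    dilutions: Sequence[float] = DEFAULT_DILUTIONS,
    reps: int = 1,
    seed: int = 0,
    gene: str = "gene",
) -> DilutionSeries:
    """Simulate a dilution series with a known true efficiency.

    Ct follows the ideal line ``intercept + slope * log10(c)`` with
    ``slope = -1 / log10(1 + E/100)`` plus Gaussian noise.
    """
    if not (50.0 < true_efficiency_pct <= 120.0):
        raise ValueError("true_efficiency_pct must be in (50, 120]")
    dilutions = np.asarray(dilutions, dtype=float)
    if (dilutions <= 0).any():
        raise ValueError("dilutions must be positive")
    rng = np.random.default_rng(seed)
    slope = slope_from_efficiency(true_efficiency_pct)
    conc = np.repeat(dilutions, reps)
    ct = intercept + slope * np.log10(conc) + rng.normal(0.0, noise_sd, size=conc.size)
    return DilutionSeries(gene=gene, concentrations=conc, ct=ct)


def paper_like(
    seed: int = 0,
    condition_sd: Sequence[float] | None = None,
    sample_loading_sd: float = 0.5,
    tech_sd: float = 0.3,
    groups: Sequence[str] | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
    target: TargetSpec | None = None,
) -> SimulationSpec:
    """Preset emulating a 15-candidate insect reference-gene screen.

    Baselines are spread evenly over 17-31 cycles. By default the candidate
    genes receive a graded condition SD from 0.0 to 1.4 cycles (step 0.1) in
    listed order, giving the dataset a known stability gradient; pass an
    explicit ``condition_sd`` vector (e.g. all zeros) to override.
    """
    if groups is None:
        groups = (
            "control",
            "imidacloprid",
            "thiamethoxam",
            "lambda-cyhalothrin",
            "abamectin",
            "matrine",
        )
    k = len(PAPER_LIKE_GENES)
    baselines = np.linspace(17.0, 31.0, k)
    if condition_sd is None:
        condition_sd = [0.1 * i for i in range(k)]
    if len(condition_sd) != k:
        raise ValueError(f"condition_sd must have length {k}")
    genes = [
        GeneSpec(name=n, baseline_ct=float(b), condition_sd=float(s))
        for n, b, s in zip(PAPER_LIKE_GENES, baselines, condition_sd)
    ]
    return SimulationSpec(
        genes=genes,
        groups=[GroupSpec(label=g, n_bio=n_bio) for g in groups],
        n_tech=n_tech,
        sample_loading_sd=sample_loading_sd,
        tech_sd=tech_sd,
        seed=seed,
        target=target,
    )
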