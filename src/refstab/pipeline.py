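"""End-to-end analysis driver: read -> aggregate -> stability -> consensus.

Produces the plain-text report bundle the CLI writes: one TSV per stability
method (gene, value, rank), the geNorm V-curve TSV, the consensus TSV, a
recommendation JSON and a JSON run log (version, config echo, warnings).
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus import Recommendation, reffinder_geomean, select_optimal
from .ct_data import aggregate_technical_replicates, read_ct_table
from .stability import METHODS, genorm_rank, pairwise_variation, run_all_methods

__all__ = ["RunConfig", "PipelineError", "run_full_analysis"]


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input: str
    out_dir: str
    layout: str = "long"
    group_column: str | None = None  # None: use the file's group field
    methods: tuple[str, ...] = METHODS
    deviation: str = "sd"
    cutoff: float = 0.15
    ties: str = "average"
    max_tech_sd: float = 0.5
    drop_incomplete_samples: bool = False
    use_groups: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must be in (0, 1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the full stability workflow and write the report bundle.

    Returns a dict with the in-memory results (stability tables, V-curve,
    consensus, recommendation, warnings) for programmatic use.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    read = _stage("read")(read_ct_table)
    table = read(cfg.input, layout=cfg.layout)

    agg = _stage("aggregate")(aggregate_technical_replicates)
    table, warnings = agg(
        table,
        max_tech_sd=cfg.max_tech_sd,
        drop_incomplete_samples=cfg.drop_incomplete_samples,
    )

    groups = None
    if cfg.use_groups:
        g = table.groups
        if (g != "").any():
            groups = list(g)

    run = _stage("stability")(run_all_methods)
    tables = run(
        table, groups=groups, methods=cfg.methods, deviation=cfg.deviation, ties=cfg.ties
    )

    vcurve = None
    if "genorm" in cfg.methods and len(table.genes) >= 3:
        gv = _stage("genorm_v")(
            lambda: pairwise_variation(
                table,
                ranking=genorm_rank(table, ties=cfg.ties)[1].ordered_genes(),
                cutoff=cfg.cutoff,
            )
        )
        vcurve = gv()

    consensus = None
    recommendation: Recommendation | None = None
    if len(tables) >= 2:
        cons = _stage("consensus")(reffinder_geomean)
        consensus = cons(tables)
        if vcurve is not None:
            sel = _stage("select")(select_optimal)
            recommendation = sel(consensus, vcurve)

    _stage("write")(_write_bundle)(
        out_dir, cfg, tables, vcurve, consensus, recommendation, warnings
    )
    return {
        "table": table,
        "stability": tables,
        "v_curve": vcurve,
        "consensus": consensus,
        "recommendation": recommendation,
        "warnings": warnings,
    }


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(lambda v: f"{v:.6g}" if isinstance(v, float) else v)


def _write_bundle(out_dir, cfg, tables, vcurve, consensus, recommendation, warnings):
    for name, st in tables.items():
        out = st.table.copy()
        out.insert(0, "gene", out.index)
        _fmt(out).to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    if vcurve is not None:
        vdf = pd.DataFrame({"n": vcurve.v.index, "v": vcurve.v.to_numpy()})
        _fmt(vdf).to_csv(out_dir / "genorm_v.tsv", sep="\t", index=False)
    if consensus is not None:
        cdf = consensus.ranks.copy()
        cdf.columns = [f"rank_{m}" for m in cdf.columns]
        cdf["geomean"] = consensus.geomean
        cdf["final_rank"] = consensus.final_rank
        cdf = cdf.loc[consensus.ordered_genes()]
        cdf.insert(0, "gene", cdf.index)
        _fmt(cdf).to_csv(out_dir / "consensus.tsv", sep="\t", index=False)
    if recommendation is not None:
        (out_dir / "recommendation.json").write_text(
            json.dumps(recommendation.as_dict(), indent=2) + "\n"
        )
    log = {
        "refstab_version": __version__,
        "python": sys.version.split()[0],
        "config": asdict(cfg),
        "aggregation_warnings": [w.as_dict() for w in warnings],
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
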