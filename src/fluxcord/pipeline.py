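"""End-to-end orchestration: models + scenarios + counts → concordance reports.

For every (model, scenario) pair the pipeline solves the parsimonious
FBA problem, classifies each reaction against the expressed gene set of
the configured sample condition, aggregates per-pathway category counts,
and compares alternative scenarios of the same species for equal
support.  All outputs are TSV; a JSON manifest records every threshold
and an sha256 checksum of every input and output so a run can be
reproduced and verified.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import (
    ConcordanceReport,
    DEFAULT_EQUIVALENCE_MARGIN,
    classify,
    compare_scenarios,
    read_lumping,
    summarize,
    write_model_summary,
    write_pathway_matrix,
    write_reaction_calls,
)
from .expression import (
    DEFAULT_EXPRESSION_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    ExpressionTable,
    fold_change,
    read_counts,
)
from .fba import DEFAULT_FLUX_TOL, call_active_anyopt, solve_fba
from .model_core import read_model, read_scenarios

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "fold_change_report"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from YAML."""

    species: list[dict]  # each: {"model": path, "scenarios": path}
    counts: str
    recA_map: str | dict[str, str]
    outdir: str = "results"
    sample: str = "CCc"
    flux_tol: float = DEFAULT_FLUX_TOL
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    equivalence_margin: float = DEFAULT_EQUIVALENCE_MARGIN
    lumping: str | None = None
    active_if: str = "point"  # or "anyopt"
    quantile: bool = True
    seed: int = 0
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        payload = yaml.safe_load(path.read_text())
        known = {f for f in cls.__dataclass_fields__ if f != "base_dir"}
        unknown = set(payload) - known
        if unknown:
            raise PipelineError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(base_dir=path.parent, **payload)

    def _resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q

    def validate(self) -> None:
        for t, label in (
            (self.flux_tol, "flux_tol"),
            (self.expression_threshold, "expression_threshold"),
            (self.pseudocount, "pseudocount"),
            (self.equivalence_margin, "equivalence_margin"),
        ):
            if t < 0:
                raise PipelineError(f"{label} must be >= 0")
        if self.active_if not in ("point", "anyopt"):
            raise PipelineError("active_if must be 'point' or 'anyopt'")
        paths = [self._resolve(self.counts)]
        if isinstance(self.recA_map, str):
            paths.append(self._resolve(self.recA_map))
        if self.lumping:
            paths.append(self._resolve(self.lumping))
        for entry in self.species:
            paths.append(self._resolve(entry["model"]))
            paths.append(self._resolve(entry["scenarios"]))
        missing = [str(p) for p in paths if not p.exists()]
        if missing:
            raise PipelineError(f"missing input file(s): {missing}")

    def load_recA_map(self) -> dict[str, str]:
        if isinstance(self.recA_map, dict):
            return dict(self.recA_map)
        df = pd.read_csv(self._resolve(self.recA_map), sep="\t")
        return dict(zip(df["bin_id"], df["gene_id"]))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> list[ConcordanceReport]:
    """Run the full analysis; write TSV reports and a manifest under outdir.

    Stages per (model, scenario): parsimonious FBA → activity calls →
    five-category classification against the configured sample's
    expressed genes → summary → pathway aggregation; then scenario
    comparison per species.  Any stage error aborts the run and removes
    partial outputs.
    """
    config.validate()
    outdir = config._resolve(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()
    try:
        logger.info("loading counts from %s", config.counts)
        table = read_counts(config._resolve(config.counts))
        recA_map = config.load_recA_map()
        expr = ExpressionTable.from_counts(
            table,
            recA_map,
            pseudocount=config.pseudocount,
            threshold=config.expression_threshold,
            quantile=config.quantile,
        )
        if config.sample not in expr.expressed.columns:
            raise PipelineError(
                f"sample {config.sample!r} not among {list(expr.expressed.columns)}"
            )
        expressed = expr.expressed_genes(config.sample)
        lumping = read_lumping(config._resolve(config.lumping)) if config.lumping else None

        reports: list[ConcordanceReport] = []
        comparisons = []
        for entry in config.species:
            model = read_model(config._resolve(entry["model"]),
                               dialect=entry.get("dialect", "tabular"))
            scenarios = read_scenarios(config._resolve(entry["scenarios"]))
            t_species = time.time()
            model_reports = []
            for scen in scenarios:
                profile = solve_fba(model, scen, tol=config.flux_tol)
                if config.active_if == "anyopt":
                    profile.active = call_active_anyopt(model, scen, tol=config.flux_tol)
                calls = classify(model, profile, expressed)
                report = summarize(calls, model, expressed, scenario_name=scen.name)
                if lumping is not None:
                    report.per_pathway = {
                        tag: counts
                        for tag, counts in _lumped(calls, model, lumping).items()
                    }
                model_reports.append(report)
            if len(model_reports) >= 2:
                comparisons.append(
                    compare_scenarios(model_reports, margin=config.equivalence_margin)
                )
            reports.extend(model_reports)
            logger.info(
                "scored %s (%d scenarios) in %.2fs",
                model.species_name, len(scenarios), time.time() - t_species,
            )

        summary_path = outdir / "model_summary.tsv"
        calls_path = outdir / "reaction_calls.tsv"
        pathway_path = outdir / "pathway_matrix.tsv"
        written.extend([summary_path, calls_path, pathway_path])
        write_model_summary(reports, summary_path)
        write_reaction_calls(reports, calls_path)
        write_pathway_matrix(reports, pathway_path)
        if comparisons:
            comp_path = outdir / "scenario_comparison.tsv"
            written.append(comp_path)
            pd.concat(comparisons, ignore_index=True).to_csv(
                comp_path, sep="\t", index=False
            )

        manifest = {
            "version": __version__,
            "sample": config.sample,
            "thresholds": {
                "flux_tol": config.flux_tol,
                "expression_threshold": config.expression_threshold,
                "pseudocount": config.pseudocount,
                "equivalence_margin": config.equivalence_margin,
            },
            "active_if": config.active_if,
            "quantile": config.quantile,
            "seed": config.seed,
            "inputs": {
                str(config.counts): _sha256(config._resolve(config.counts)),
            },
            "outputs": {p.name: _sha256(p) for p in written},
            "runtime_s": round(time.time() - t0, 3),
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return reports
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _lumped(calls, model, lumping):
    from .concordance import aggregate_pathways

    return aggregate_pathways(calls, model, lumping)


def fold_change_report(
    config: RunConfig,
    cond_pairs: list[tuple[str, str]],
    top_n: int = 10,
) -> pd.DataFrame:
    """Descriptive fold changes (recA-scaled, pseudocounted) for sample pairs.

    Returns per-gene fold changes for each requested pair plus a per-bin
    rank within the first pair, mirroring top-N gene tables.  Ranks break
    ties by gene id, so the ranking is stable under input reordering.
    """
    config.validate()
    table = read_counts(config._resolve(config.counts))
    expr = ExpressionTable.from_counts(
        table,
        config.load_recA_map(),
        pseudocount=config.pseudocount,
        threshold=config.expression_threshold,
        quantile=config.quantile,
    )
    for c1, c2 in cond_pairs:
        for c in (c1, c2):
            if c not in expr.rpkm_recA.columns:
                raise PipelineError(f"unknown sample {c!r}")
    out = pd.DataFrame(index=expr.rpkm_recA.index)
    out["bin_id"] = table.genes["bin_id"]
    for c1, c2 in cond_pairs:
        out[f"fc_{c1}_vs_{c2}"] = fold_change(
            expr.rpkm_recA, c1, c2, config.pseudocount
        )
    first = f"fc_{cond_pairs[0][0]}_vs_{cond_pairs[0][1]}"
    # sort by gene id first so the stable fold-change sort breaks ties deterministically
    out = out.sort_index().sort_values(first, ascending=False, kind="mergesort")
    out["rank_in_bin"] = out.groupby("bin_id")[first].rank(
        method="first", ascending=False
    ).astype(int)
    if top_n is not None:
        out = out[out["rank_in_bin"] <= top_n]
    out.index.name = "gene_id"
    return out
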