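"""Flux–expression concordance: five-category reaction calls and summaries.

Every gene-associated reaction of a model is placed in exactly one of
four flux-vs-expression categories, with gapfilled (gene-free) reactions
forming a fifth:

  i    active_supported     active and ≥1 associated gene expressed
  ii   inactive_unexpressed inactive and all associated genes unexpressed
  iii  inactive_expressed   inactive but ≥1 associated gene expressed
  iv   active_unexpressed   active but no associated gene expressed
  v    gapfilled_nogene     gapfilled, no genes, any flux

Categories i and ii are agreement between model and transcriptome; iii
and iv are disagreement.  Non-gapfilled reactions that carry no genes
(exchanges, spontaneous reactions) fit none of the five classes and are
kept in a separate bookkeeping bucket.

Gene associations are evaluated with any-gene semantics: a reaction is
"supported" as soon as one associated gene is actively expressed; no
boolean gene–protein–reaction structure is consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fba import FluxProfile
from .model_core import MetabolicModel, gene_universe

__all__ = [
    "Category",
    "CATEGORIES",
    "ReactionCall",
    "ConcordanceReport",
    "ConcordanceError",
    "classify",
    "summarize",
    "aggregate_pathways",
    "compare_scenarios",
    "format_support_percent",
    "format_group_percents",
    "DEFAULT_EQUIVALENCE_MARGIN",
]

DEFAULT_EQUIVALENCE_MARGIN = 2.0  # percentage points


class Category:
    ACTIVE_SUPPORTED = "active_supported"
    INACTIVE_UNEXPRESSED = "inactive_unexpressed"
    INACTIVE_EXPRESSED = "inactive_expressed"
    ACTIVE_UNEXPRESSED = "active_unexpressed"
    GAPFILLED_NOGENE = "gapfilled_nogene"
    # bookkeeping bucket outside the five-way scheme
    ORPHAN_NOGENE = "orphan_nogene"


CATEGORIES: tuple[str, ...] = (
    Category.ACTIVE_SUPPORTED,
    Category.INACTIVE_UNEXPRESSED,
    Category.INACTIVE_EXPRESSED,
    Category.ACTIVE_UNEXPRESSED,
    Category.GAPFILLED_NOGENE,
)


class ConcordanceError(ValueError):
    pass


@dataclass(frozen=True)
class ReactionCall:
    reaction_id: str
    category: str
    flux: float
    active: bool
    n_genes: int
    n_expressed_genes: int


@dataclass
class ConcordanceReport:
    """Per-(model, scenario) support summary — the shape of a results table row."""

    model_id: str
    scenario_name: str
    calls: list[ReactionCall]
    active_with_genes: int
    total_with_genes: int
    supported: int
    expressed_genes: int
    total_genes: int
    category_counts: dict[str, int]
    n_orphan: int
    per_pathway: dict[str, tuple[int, int, int, int, int]] = field(default_factory=dict)

    @property
    def support_percent(self) -> float | None:
        """100 × supported / active_with_genes, or None when no reaction is active."""
        if self.active_with_genes == 0:
            return None
        return 100.0 * self.supported / self.active_with_genes

    @property
    def active_fraction_str(self) -> str:
        return f"{self.active_with_genes}/{self.total_with_genes}"

    @property
    def supported_fraction_str(self) -> str:
        return f"{self.supported}/{self.active_with_genes}"

    @property
    def expressed_genes_str(self) -> str:
        return f"{self.expressed_genes}/{self.total_genes}"


def classify(
    model: MetabolicModel,
    profile: FluxProfile,
    expressed: set[str],
) -> list[ReactionCall]:
    """Label every reaction of ``model`` by the five-way flux/expression rule.

    ``expressed`` is the set of actively expressed gene ids for one
    sample condition.  Gapfilled reactions are category v regardless of
    flux; gene-free non-gapfilled reactions get the orphan bucket.
    """
    missing = [rid for rid in model.reactions if rid not in profile.fluxes]
    if missing:
        raise ConcordanceError(
            f"flux profile {profile.scenario_name!r} lacks reactions {missing[:5]}"
        )
    calls: list[ReactionCall] = []
    for rid, rxn in model.reactions.items():
        flux = profile.fluxes[rid]
        active = profile.active[rid]
        n_expr = len(rxn.gene_ids & expressed)
        if rxn.gapfilled:
            category = Category.GAPFILLED_NOGENE
        elif not rxn.gene_ids:
            category = Category.ORPHAN_NOGENE
        elif active:
            category = (
                Category.ACTIVE_SUPPORTED if n_expr >= 1 else Category.ACTIVE_UNEXPRESSED
            )
        else:
            category = (
                Category.INACTIVE_EXPRESSED if n_expr >= 1 else Category.INACTIVE_UNEXPRESSED
            )
        calls.append(
            ReactionCall(
                reaction_id=rid,
                category=category,
                flux=flux,
                active=active,
                n_genes=len(rxn.gene_ids),
                n_expressed_genes=n_expr,
            )
        )
    return calls


def summarize(
    calls: Sequence[ReactionCall],
    model: MetabolicModel,
    expressed: set[str],
    scenario_name: str = "",
) -> ConcordanceReport:
    """Aggregate calls into a support-summary row.

    supported = |cat i|; active_with_genes = |cat i| + |cat iv|;
    total_with_genes = |i|+|ii|+|iii|+|iv|; the support percentage is
    100 × supported / active_with_genes (undefined when nothing with
    genes is active).
    """
    counts = {c: 0 for c in CATEGORIES}
    n_orphan = 0
    for call in calls:
        if call.category == Category.ORPHAN_NOGENE:
            n_orphan += 1
        else:
            counts[call.category] += 1
    universe = gene_universe(model)
    report = ConcordanceReport(
        model_id=model.species_name,
        scenario_name=scenario_name,
        calls=list(calls),
        active_with_genes=counts[Category.ACTIVE_SUPPORTED]
        + counts[Category.ACTIVE_UNEXPRESSED],
        total_with_genes=sum(counts[c] for c in CATEGORIES[:4]),
        supported=counts[Category.ACTIVE_SUPPORTED],
        expressed_genes=len(universe & expressed),
        total_genes=len(universe),
        category_counts=counts,
        n_orphan=n_orphan,
    )
    report.per_pathway = aggregate_pathways(calls, model)
    return report


def aggregate_pathways(
    calls: Sequence[ReactionCall],
    model: MetabolicModel,
    lumping: Mapping[str, str] | None = None,
) -> dict[str, tuple[int, int, int, int, int]]:
    """Category-count 5-tuples per pathway category.

    ``lumping`` maps pathway tags to supercategories (e.g. merging the
    reductive TCA and Wood-Ljungdahl carbon-fixation tags into a single
    "CO2 fixation" class); identity by default.  Orphan (gene-free,
    non-gapfilled) reactions are excluded, so each pathway's tuple sums
    to its number of five-way-classified reactions.
    """
    if lumping is not None:
        tags = {model.reactions[c.reaction_id].pathway for c in calls}
        unmapped = sorted(t for t in tags if t not in lumping)
        if unmapped:
            raise ConcordanceError(f"pathway tags missing from lumping map: {unmapped}")
    index = {c: i for i, c in enumerate(CATEGORIES)}
    out: dict[str, list[int]] = {}
    for call in calls:
        if call.category == Category.ORPHAN_NOGENE:
            continue
        tag = model.reactions[call.reaction_id].pathway
        if lumping is not None:
            tag = lumping[tag]
        out.setdefault(tag, [0] * 5)[index[call.category]] += 1
    return {tag: tuple(v) for tag, v in sorted(out.items())}


# ---------------------------------------------------------------------------
# percentage formatting and scenario comparison
# ---------------------------------------------------------------------------


def format_support_percent(supported: int, active: int, decimals: int = 0) -> str:
    """Format 100 × supported/active to the requested number of decimals."""
    if active == 0:
        return "NA"
    return f"{100.0 * supported / active:.{decimals}f}"


def format_group_percents(pairs: Sequence[tuple[int, int]]) -> list[str]:
    """Format support percentages for one model's group of scenarios.

    Integer rounding by default; if two scenarios of the group would
    collide at integer precision, the whole group switches to one
    decimal place so near-equal alternative scenarios stay
    distinguishable (76 vs. 75.8/75.9 style).
    """
    ints = [format_support_percent(s, a, 0) for s, a in pairs]
    informative = [v for v in ints if v != "NA"]
    if len(informative) != len(set(informative)):
        return [format_support_percent(s, a, 1) for s, a in pairs]
    return ints


def compare_scenarios(
    reports: Sequence[ConcordanceReport],
    margin: float = DEFAULT_EQUIVALENCE_MARGIN,
) -> pd.DataFrame:
    """Rank alternative scenarios of one model by expression support.

    Returns one row per scenario pair with both support percentages,
    their absolute difference in percentage points, and an
    ``equally_supported`` flag for pairs within ``margin``.  Near-equal
    support for two hypothesized roles indicates the transcriptome
    cannot discriminate between them (or that the organism performs
    both).
    """
    if len(reports) < 2:
        raise ConcordanceError("compare_scenarios needs >= 2 reports")
    models = {r.model_id for r in reports}
    if len(models) > 1:
        raise ConcordanceError(
            f"reports mix models {sorted(models)}; compare one model at a time"
        )
    if margin < 0:
        raise ConcordanceError("equivalence margin must be >= 0")
    rows = []
    for i, a in enumerate(reports):
        for b in reports[i + 1 :]:
            pa, pb = a.support_percent, b.support_percent
            if pa is None or pb is None:
                raise ConcordanceError(
                    "cannot compare scenarios with no active gene-associated reactions"
                )
            rows.append(
                {
                    "model_id": a.model_id,
                    "scenario_1": a.scenario_name,
                    "scenario_2": b.scenario_name,
                    "support_pct_1": pa,
                    "support_pct_2": pb,
                    "abs_difference_pp": abs(pa - pb),
                    "equally_supported": abs(pa - pb) <= margin,
                    "better": a.scenario_name
                    if pa > pb
                    else (b.scenario_name if pb > pa else "tie"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def write_reaction_calls(
    reports: Iterable[ConcordanceReport], path: str | Path
) -> None:
    rows = [
        {
            "model_id": rep.model_id,
            "scenario": rep.scenario_name,
            "reaction_id": c.reaction_id,
            "flux": c.flux,
            "active": int(c.active),
            "n_genes": c.n_genes,
            "n_expressed": c.n_expressed_genes,
            "category": c.category,
        }
        for rep in reports
        for c in rep.calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_model_summary(reports: Sequence[ConcordanceReport], path: str | Path) -> None:
    """Support-summary TSV, one row per (model, scenario), a/b strings plus floats."""
    by_model: dict[str, list[ConcordanceReport]] = {}
    for rep in reports:
        by_model.setdefault(rep.model_id, []).append(rep)
    rows = []
    for model_id, group in by_model.items():
        pcts = format_group_percents(
            [(r.supported, r.active_with_genes) for r in group]
        )
        for rep, pct in zip(group, pcts):
            rows.append(
                {
                    "species": rep.model_id,
                    "scenario": rep.scenario_name,
                    "active_reactions": rep.active_fraction_str,
                    "supported_reactions": rep.supported_fraction_str,
                    "support_pct": pct,
                    "expressed_genes": rep.expressed_genes_str,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pathway_matrix(
    reports: Sequence[ConcordanceReport], path: str | Path
) -> None:
    """Pathway × five-category count matrix, stacked-bar ready."""
    rows = []
    for rep in reports:
        for tag, counts in rep.per_pathway.items():
            row = {
                "model_id": rep.model_id,
                "scenario": rep.scenario_name,
                "pathway": tag,
            }
            row.update(dict(zip(CATEGORIES, counts)))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_lumping(path: str | Path) -> dict[str, str]:
    """Two-column TSV pathway_tag → supercategory."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pathway", "supercategory"])
    return dict(zip(df["pathway"], df["supercategory"]))
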