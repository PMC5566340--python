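"""Species-level metabolic models: types, validation, and tabular I/O.

A model is a set of reactions over metabolites in two compartments
(cytosol ``c`` and extracellular ``e``), each reaction carrying flux
bounds, an associated gene set, a gapfill flag, and a pathway-category
tag.  Gapfilled reactions are reactions added during draft-model curation
to restore network feasibility; by definition they have no supporting
gene, and the validator enforces that.

The native serialization is a pair of TSV tables (reactions +
metabolites) plus a small YAML header, written in a canonical order so
that fixtures diff cleanly.  Models exported by other tools in the
standard XML exchange format can be imported (read-only) through the
``sbml-import`` dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "CYTOSOL",
    "EXTRACELLULAR",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Scenario",
    "ModelValidationError",
    "ModelParseError",
    "read_model",
    "write_model",
    "gene_universe",
    "read_scenarios",
    "write_scenarios",
]

CYTOSOL = "c"
EXTRACELLULAR = "e"
_COMPARTMENT_ALIASES = {
    "c": CYTOSOL,
    "cytosol": CYTOSOL,
    "cytoplasm": CYTOSOL,
    "e": EXTRACELLULAR,
    "extracellular": EXTRACELLULAR,
    "extracellular space": EXTRACELLULAR,
}


class ModelValidationError(ValueError):
    """A model or scenario violates a structural invariant."""


class ModelParseError(ValueError):
    """A model file could not be parsed."""


@dataclass(frozen=True)
class Metabolite:
    """One compound in one compartment; ``id`` carries a ``[c]``/``[e]`` suffix."""

    id: str
    name: str = ""
    compartment: str = CYTOSOL

    def __post_init__(self) -> None:
        comp = _COMPARTMENT_ALIASES.get(str(self.compartment).lower())
        if comp is None:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        object.__setattr__(self, "compartment", comp)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with bounds, genes, gapfill flag and pathway tag.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced).  Flux units follow the
    usual mmol·gDW⁻¹·h⁻¹ convention but are arbitrary.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gene_ids: frozenset[str] = frozenset()
    gapfilled: bool = False
    pathway: str = "unassigned"

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.gapfilled and self.gene_ids:
            raise ModelValidationError(
                f"reaction {self.id!r}: gapfilled reactions carry no genes "
                f"(found {sorted(self.gene_ids)})"
            )


@dataclass
class MetabolicModel:
    """All reactions and metabolites of one species bin."""

    species_name: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: str | None = None

    def is_exchange(self, reaction: Reaction) -> bool:
        """Exchange reactions move a single extracellular metabolite across the boundary."""
        if len(reaction.stoichiometry) != 1:
            return False
        (met_id,) = reaction.stoichiometry
        met = self.metabolites.get(met_id)
        return met is not None and met.compartment == EXTRACELLULAR

    @property
    def exchange_reaction_ids(self) -> list[str]:
        return [rid for rid, r in self.reactions.items() if self.is_exchange(r)]

    def validate(self) -> None:
        problems: list[str] = []
        for rid, rxn in self.reactions.items():
            if rid != rxn.id:
                problems.append(f"reaction key {rid!r} != reaction id {rxn.id!r}")
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    problems.append(
                        f"reaction {rid!r} references unknown metabolite {met_id!r}"
                    )
            if len(rxn.stoichiometry) == 1:
                (met_id,) = rxn.stoichiometry
                met = self.metabolites.get(met_id)
                if met is not None and met.compartment != EXTRACELLULAR:
                    problems.append(
                        f"reaction {rid!r} is single-metabolite but {met_id!r} "
                        "is not extracellular; exchange reactions must move an "
                        "extracellular metabolite"
                    )
        if not any(self.is_exchange(r) for r in self.reactions.values()):
            problems.append("model has no exchange reaction")
        if (
            self.biomass_reaction_id is not None
            and self.biomass_reaction_id not in self.reactions
        ):
            problems.append(
                f"biomass_reaction_id {self.biomass_reaction_id!r} not in reactions"
            )
        if problems:
            raise ModelValidationError(
                f"model {self.species_name!r}: " + "; ".join(problems)
            )

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn


@dataclass(frozen=True)
class Scenario:
    """A hypothesized metabolic role: medium (exchange bounds) plus objective.

    ``exchange_bounds`` overrides the model's default bounds on the named
    exchange reactions, defining what the cell may take up or secrete;
    ``objective`` weights reactions whose combined flux is optimized.
    """

    name: str
    exchange_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    objective: Mapping[str, float] = field(default_factory=dict)
    sense: str = "maximize"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "exchange_bounds",
            {k: (float(lo), float(hi)) for k, (lo, hi) in dict(self.exchange_bounds).items()},
        )
        object.__setattr__(self, "objective", dict(self.objective))
        if self.sense not in ("maximize", "minimize"):
            raise ModelValidationError(
                f"scenario {self.name!r}: sense must be maximize/minimize"
            )
        if not any(w != 0 for w in self.objective.values()):
            raise ModelValidationError(
                f"scenario {self.name!r}: objective has no nonzero weight"
            )
        for rid, (lo, hi) in self.exchange_bounds.items():
            if lo > hi:
                raise ModelValidationError(
                    f"scenario {self.name!r}: bounds for {rid!r} have lb > ub"
                )

    def validate_against(self, model: MetabolicModel) -> None:
        missing = [
            rid
            for rid in list(self.exchange_bounds) + list(self.objective)
            if rid not in model.reactions
        ]
        if missing:
            raise ModelValidationError(
                f"scenario {self.name!r}: unknown reaction ids {sorted(set(missing))} "
                f"for model {model.species_name!r}"
            )


# ---------------------------------------------------------------------------
# reaction-equation syntax:  "2 co2[c] + 4 h2[c] => 1 ac[c]"  /  "1 ac[e] <=>"
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:([0-9.eE+-]+)\s+)?(\S+)\s*$")


def _format_coef(x: float) -> str:
    s = format(float(x), ".12g")
    return s


def format_equation(rxn: Reaction) -> str:
    """Canonical equation string: substrates sorted by id, then products."""
    left = sorted((m, -c) for m, c in rxn.stoichiometry.items() if c < 0)
    right = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<=>" if rxn.lower_bound < 0 else "=>"
    fmt = lambda side: " + ".join(f"{_format_coef(c)} {m}" for m, c in side)
    return f"{fmt(left)} {arrow} {fmt(right)}".strip()


def parse_equation(text: str, reaction_id: str = "?") -> dict[str, float]:
    """Parse an equation string into a signed stoichiometry map."""
    m = re.search(r"<=>|<=|=>", text)
    if m is None:
        raise ModelParseError(
            f"reaction {reaction_id!r}: no arrow (=>, <=>) in equation {text!r}"
        )
    left, right = text[: m.start()], text[m.end() :]
    stoich: dict[str, float] = {}
    for side_text, sign in ((left, -1.0), (right, 1.0)):
        side_text = side_text.strip()
        if not side_text:
            continue
        for term in side_text.split(" + "):
            tm = _TERM_RE.match(term)
            if tm is None:
                raise ModelParseError(
                    f"reaction {reaction_id!r}: cannot parse term {term!r}"
                )
            coef = float(tm.group(1)) if tm.group(1) is not None else 1.0
            met = tm.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef
    return {m: c for m, c in stoich.items() if c != 0.0}


# ---------------------------------------------------------------------------
# tabular dialect: <dir>/reactions.tsv, <dir>/metabolites.tsv, <dir>/model.yaml
# ---------------------------------------------------------------------------

_REACTION_COLS = [
    "reaction_id",
    "equation",
    "lower_bound",
    "upper_bound",
    "genes",
    "gapfilled",
    "pathway",
]
_METABOLITE_COLS = ["id", "name", "compartment"]


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as canonical TSV tables under directory ``path``.

    Reactions are emitted sorted by id with a fixed column order, so two
    structurally equal models serialize byte-identically.
    """
    model.validate()
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(_REACTION_COLS)]
    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        lines.append(
            "\t".join(
                [
                    r.id,
                    format_equation(r),
                    _format_coef(r.lower_bound),
                    _format_coef(r.upper_bound),
                    ",".join(sorted(r.gene_ids)),
                    "1" if r.gapfilled else "0",
                    r.pathway,
                ]
            )
        )
    (outdir / "reactions.tsv").write_text("\n".join(lines) + "\n")

    mlines = ["\t".join(_METABOLITE_COLS)]
    for mid in sorted(model.metabolites):
        m = model.metabolites[mid]
        mlines.append("\t".join([m.id, m.name, m.compartment]))
    (outdir / "metabolites.tsv").write_text("\n".join(mlines) + "\n")

    header = {
        "species_name": model.species_name,
        "biomass_reaction_id": model.biomass_reaction_id,
    }
    (outdir / "model.yaml").write_text(
        yaml.safe_dump(header, default_flow_style=False, sort_keys=True)
    )


def _read_tabular(path: Path) -> MetabolicModel:
    rxn_path = path / "reactions.tsv"
    met_path = path / "metabolites.tsv"
    meta_path = path / "model.yaml"
    for p in (rxn_path, met_path):
        if not p.exists():
            raise ModelParseError(f"missing model table {p}")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    model = MetabolicModel(
        species_name=meta.get("species_name", path.name),
        biomass_reaction_id=meta.get("biomass_reaction_id"),
    )

    mlines = met_path.read_text().splitlines()
    if not mlines or mlines[0].split("\t") != _METABOLITE_COLS:
        raise ModelParseError(f"{met_path}: bad header, expected {_METABOLITE_COLS}")
    for lineno, line in enumerate(mlines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_METABOLITE_COLS):
            raise ModelParseError(f"{met_path}:{lineno}: expected 3 columns")
        model.add_metabolite(Metabolite(id=parts[0], name=parts[1], compartment=parts[2]))

    rlines = rxn_path.read_text().splitlines()
    if not rlines or rlines[0].split("\t") != _REACTION_COLS:
        raise ModelParseError(f"{rxn_path}: bad header, expected {_REACTION_COLS}")
    for lineno, line in enumerate(rlines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_REACTION_COLS):
            raise ModelParseError(
                f"{rxn_path}:{lineno}: expected {len(_REACTION_COLS)} columns, "
                f"got {len(parts)}"
            )
        rid, equation, lb, ub, genes, gapfilled, pathway = parts
        if gapfilled not in ("0", "1"):
            raise ModelParseError(f"{rxn_path}:{lineno}: gapfilled must be 0 or 1")
        try:
            rxn = Reaction(
                id=rid,
                stoichiometry=parse_equation(equation, rid),
                lower_bound=float(lb),
                upper_bound=float(ub),
                gene_ids=frozenset(g for g in genes.split(",") if g),
                gapfilled=gapfilled == "1",
                pathway=pathway,
            )
        except ModelValidationError as exc:
            raise ModelValidationError(f"{rxn_path}:{lineno}: {exc}") from exc
        except ValueError as exc:
            raise ModelParseError(f"{rxn_path}:{lineno}: {exc}") from exc
        model.add_reaction(rxn)
    model.validate()
    return model


def _read_sbml(path: Path) -> MetabolicModel:
    """Import a model from the standard XML exchange format (read-only)."""
    try:
        from cobra.io import read_sbml_model
    except ImportError as exc:  # pragma: no cover - import guard
        raise ModelParseError(
            "sbml-import requires the optional 'cobra' dependency"
        ) from exc

    cb = read_sbml_model(str(path))
    model = MetabolicModel(species_name=cb.id or path.stem)
    ext_compartments = {"e", "e0", "extracellular", "extracellular space"}
    for met in cb.metabolites:
        comp = (
            EXTRACELLULAR
            if str(met.compartment).lower() in ext_compartments
            else CYTOSOL
        )
        model.add_metabolite(Metabolite(id=met.id, name=met.name or "", compartment=comp))
    for rxn in cb.reactions:
        model.add_reaction(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: c for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gene_ids=frozenset(g.id for g in rxn.genes),
                gapfilled=False,
                pathway=rxn.subsystem or "unassigned",
            )
        )
    objective_rxns = [r.id for r in cb.reactions if r.objective_coefficient]
    if len(objective_rxns) == 1:
        model.biomass_reaction_id = objective_rxns[0]
    model.validate()
    return model


def read_model(path: str | Path, dialect: str = "tabular") -> MetabolicModel:
    """Read and validate a model from ``path`` under the named dialect."""
    path = Path(path)
    if not path.exists():
        raise ModelParseError(f"model path {path} does not exist")
    if dialect == "tabular":
        return _read_tabular(path)
    if dialect == "sbml-import":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'tabular' or 'sbml-import'")


def gene_universe(model: MetabolicModel) -> set[str]:
    """Union of gene ids over all reactions; the denominator for expressed-gene counts."""
    out: set[str] = set()
    for rxn in model.reactions.values():
        out |= rxn.gene_ids
    return out


# ---------------------------------------------------------------------------
# scenario YAML
# ---------------------------------------------------------------------------


def write_scenarios(scenarios: Iterable[Scenario], path: str | Path) -> None:
    payload = [
        {
            "name": s.name,
            "sense": s.sense,
            "exchange_bounds": {k: [lo, hi] for k, (lo, hi) in sorted(s.exchange_bounds.items())},
            "objective": dict(sorted(s.objective.items())),
        }
        for s in scenarios
    ]
    Path(path).write_text(yaml.safe_dump(payload, default_flow_style=False, sort_keys=False))


def read_scenarios(path: str | Path) -> list[Scenario]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, list):
        raise ModelParseError(f"{path}: scenario file must be a YAML list")
    out = []
    for entry in payload:
        out.append(
            Scenario(
                name=entry["name"],
                exchange_bounds={k: (v[0], v[1]) for k, v in entry.get("exchange_bounds", {}).items()},
                objective=entry.get("objective", {}),
                sense=entry.get("sense", "maximize"),
            )
        )
    return out
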