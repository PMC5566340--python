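"""Synthetic three-species community with known ground truth.

The generator emulates the statistical structure of a microbial
electrosynthesis community at desk scale: an acetogen fixing CO₂ to
acetate through a linear Wood-Ljungdahl-like pathway, a species with two
alternative metabolic modes (CO₂ reduction via an rTCA-like chain
vs. acetate oxidation), and a species converting CO₂/H₂ to formate or
consuming acetate.  Each species gets a small mass-balanced metabolic
model whose scenarios have unique, analytically known parsimonious
active sets, plus background reaction chains, gapfilled reactions, and
per-gene transcript counts with configurable noise.

Every quantity is a pure function of the community spec (including its
seed), so fixtures regenerate byte-identically and planted parameters
(expression support probability, bin abundances) are recoverable by the
pipeline within stated statistical tolerances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import CountTable, write_counts
from .model_core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    Scenario,
    write_model,
    write_scenarios,
)

__all__ = [
    "CommunitySpec",
    "SpeciesSpec",
    "SpeciesBuild",
    "CountsResult",
    "trio_spec",
    "generate_models",
    "generate_counts",
    "write_fixture",
    "PATHWAY_PALETTE",
    "DEFAULT_SAMPLES",
]

DEFAULT_SAMPLES = ("CCc", "CCs", "OCc", "OCs")

# fixed six-category pathway palette; carbon-fixation cores always use the first
PATHWAY_PALETTE = (
    "CO2 fixation",
    "Central carbon metabolism",
    "Amino acid biosynthesis",
    "Nucleotide metabolism",
    "Cofactor and vitamin biosynthesis",
    "Transport",
)
_BACKGROUND_TAGS = PATHWAY_PALETTE[1:5]

_RECA_LENGTH_BP = 1040  # ~350 aa single-copy marker


@dataclass(frozen=True)
class SpeciesSpec:
    """One synthetic species: core pathway shape plus background size."""

    name: str
    core_pathway: str  # linear_fixation | two_mode | converter
    n_background_reactions: int = 30
    gapfill_fraction: float = 0.1
    n_nonmodel_genes: int = 20

    def __post_init__(self) -> None:
        if self.core_pathway not in ("linear_fixation", "two_mode", "converter"):
            raise ValueError(f"unknown core_pathway {self.core_pathway!r}")
        if not 0.0 <= self.gapfill_fraction <= 1.0:
            raise ValueError("gapfill_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions for one synthetic community.

    ``support_prob`` is the probability that a truly active reaction's
    genes are expressed in a sample; ``leak_prob`` the same for inactive
    reactions (constitutive background transcription).  ``mean_depth``
    is the expected count for an expressed 1 kb gene at relative
    abundance 1.
    """

    seed: int
    species: tuple[SpeciesSpec, ...]
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    abundance: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    support_prob: float = 0.76
    leak_prob: float = 0.3
    count_noise: str = "negative_binomial"  # or "poisson"
    dispersion: float = 0.2
    mean_depth: float = 100.0
    # unexpressed genes emit at this fraction of the expressed level; kept two
    # orders of magnitude below the expression floor so that drawn truth labels
    # stay recoverable even at the tail of the gene-level distribution
    basal_rate: float = 0.001
    # sigma of the per-gene log-normal expression level (0 = all genes equal);
    # real transcript abundances span orders of magnitude, and a continuous
    # level distribution keeps quantile normalization well-behaved
    expr_level_sd: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(
            self,
            "abundance",
            {k: tuple(float(x) for x in v) for k, v in dict(self.abundance).items()},
        )
        for p, label in ((self.support_prob, "support_prob"), (self.leak_prob, "leak_prob")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be in [0, 1]")
        if self.count_noise not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown count_noise {self.count_noise!r}")
        for kind in ("two_mode", "converter"):
            if sum(s.core_pathway == kind for s in self.species) > 1:
                raise ValueError(f"at most one {kind} species per community")
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("species names must be unique")
        for name, row in self.abundance.items():
            if len(row) != len(self.samples):
                raise ValueError(f"abundance row for {name!r} has wrong length")
            if any(x <= 0 for x in row):
                raise ValueError(f"abundance must be > 0 (bin {name!r})")

    def abundance_of(self, bin_id: str, sample: str) -> float:
        if bin_id in self.abundance:
            return self.abundance[bin_id][self.samples.index(sample)]
        return 1.0


def trio_spec(seed: int = 42, n_background_reactions: int = 30) -> CommunitySpec:
    """The default three-species preset mirroring the study's community trio."""
    return CommunitySpec(
        seed=seed,
        species=(
            SpeciesSpec("Acetobacterium_sp_SYN1", "linear_fixation", n_background_reactions),
            SpeciesSpec("Sulfurospirillum_sp_SYN2", "two_mode", n_background_reactions),
            SpeciesSpec("Desulfovibrio_sp_SYN3", "converter", n_background_reactions),
        ),
        abundance={
            "Acetobacterium_sp_SYN1": (1.0, 0.9, 0.5, 0.45),
            "Sulfurospirillum_sp_SYN2": (0.6, 0.5, 0.8, 0.7),
            "Desulfovibrio_sp_SYN3": (0.25, 0.3, 0.35, 0.3),
        },
    )


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


@dataclass
class SpeciesBuild:
    """A generated species: model, scenarios, and per-scenario ground truth."""

    model: MetabolicModel
    scenarios: list[Scenario]
    # scenario name -> reaction ids carrying flux in the unique parsimonious optimum
    active_truth: dict[str, frozenset[str]]
    gene_lengths: dict[str, int]
    gene_reaction: dict[str, str | None]
    recA_gene: str

    @property
    def bin_id(self) -> str:
        return self.model.species_name


class _Builder:
    """Accumulates metabolites/reactions and per-scenario bound overrides."""

    def __init__(self, name: str):
        self.model = MetabolicModel(species_name=name)
        # scenario name -> {exchange id: (lb, ub)}
        self.scenario_bounds: dict[str, dict[str, tuple[float, float]]] = {}
        self.scenario_objective: dict[str, dict[str, float]] = {}
        self.active: dict[str, set[str]] = {}

    def met(self, mid: str, compartment: str) -> str:
        if mid not in self.model.metabolites:
            self.model.add_metabolite(Metabolite(id=mid, compartment=compartment))
        return mid

    def rxn(self, rid: str, stoich: dict[str, float], lb: float = 0.0,
            ub: float = 1000.0, pathway: str = "Transport") -> str:
        self.model.add_reaction(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                     pathway=pathway)
        )
        return rid

    def exchange(self, species_met: str) -> str:
        ext = self.met(f"{species_met}[e]", "e")
        return self.rxn(f"EX_{species_met}", {ext: -1.0}, lb=-1000.0, ub=1000.0)

    def scenario(self, name: str) -> None:
        self.scenario_bounds[name] = {}
        self.scenario_objective[name] = {}
        self.active[name] = set()

    def bound(self, scenario: str, rid: str, lo: float, hi: float) -> None:
        self.scenario_bounds[scenario][rid] = (lo, hi)

    def mark_active(self, scenario: str, *rids: str) -> None:
        self.active[scenario].update(rids)


def _core_linear_fixation(b: _Builder) -> None:
    """WLP-like acetogen: 2 CO2 + 3 H2 -> acetate, one linear route."""
    for m in ("co2", "h2", "ac"):
        b.exchange(m)
    c = lambda m: b.met(f"{m}[c]", "c")
    b.rxn("T_co2", {"co2[e]": -1, c("co2"): 1}, lb=-1000)
    b.rxn("T_h2", {"h2[e]": -1, c("h2"): 1})
    b.rxn("WL_formyl", {c("co2"): -1, c("h2"): -1, c("wl1"): 1}, pathway=PATHWAY_PALETTE[0])
    b.rxn("WL_methyl", {c("wl1"): -1, c("h2"): -1, c("wl2"): 1}, pathway=PATHWAY_PALETTE[0])
    b.rxn("WL_acetyl", {c("wl2"): -1, c("co2"): -1, c("h2"): -1, c("ac"): 1},
          pathway=PATHWAY_PALETTE[0])
    b.rxn("T_ac", {c("ac"): -1, "ac[e]": 1})

    s = "co2_fixation_to_acetate"
    b.scenario(s)
    b.bound(s, "EX_co2", -10, 0)
    b.bound(s, "EX_h2", -40, 0)
    b.bound(s, "EX_ac", 0, 1000)
    b.scenario_objective[s] = {"EX_ac": 1.0}
    b.mark_active(s, "EX_co2", "EX_h2", "EX_ac", "T_co2", "T_h2", "T_ac",
                  "WL_formyl", "WL_methyl", "WL_acetyl")


def _core_two_mode(b: _Builder) -> None:
    """rTCA-like fixation (CO2 + H2 -> fixed carbon) vs. aerobic acetate oxidation."""
    for m in ("co2", "h2", "cfix", "ac", "o2"):
        b.exchange(m)
    c = lambda m: b.met(f"{m}[c]", "c")
    b.rxn("T_co2", {"co2[e]": -1, c("co2"): 1}, lb=-1000)
    b.rxn("T_h2", {"h2[e]": -1, c("h2"): 1})
    b.rxn("T_cfix", {c("cfix"): -1, "cfix[e]": 1})
    b.rxn("T_ac", {"ac[e]": -1, c("ac"): 1})
    b.rxn("T_o2", {"o2[e]": -1, c("o2"): 1})
    b.rxn("RTCA_1", {c("co2"): -1, c("h2"): -2, c("rt1"): 1}, pathway=PATHWAY_PALETTE[0])
    b.rxn("RTCA_2", {c("rt1"): -1, c("co2"): -1, c("h2"): -1, c("rt2"): 1},
          pathway=PATHWAY_PALETTE[0])
    b.rxn("RTCA_3", {c("rt2"): -1, c("h2"): -1, c("cfix"): 1}, pathway=PATHWAY_PALETTE[0])
    b.rxn("AOX_1", {c("ac"): -1, c("o2"): -1, c("aox"): 1, c("co2"): 1},
          pathway=PATHWAY_PALETTE[1])
    b.rxn("AOX_2", {c("aox"): -1, c("o2"): -1, c("co2"): 1}, pathway=PATHWAY_PALETTE[1])

    s1 = "reduction_of_co2"
    b.scenario(s1)
    b.bound(s1, "EX_co2", -10, 0)
    b.bound(s1, "EX_h2", -40, 0)
    b.bound(s1, "EX_cfix", 0, 1000)
    b.bound(s1, "EX_ac", 0, 0)
    b.bound(s1, "EX_o2", 0, 0)
    b.scenario_objective[s1] = {"EX_cfix": 1.0}
    b.mark_active(s1, "EX_co2", "EX_h2", "EX_cfix", "T_co2", "T_h2", "T_cfix",
                  "RTCA_1", "RTCA_2", "RTCA_3")

    s2 = "oxidation_of_acetate"
    b.scenario(s2)
    b.bound(s2, "EX_ac", -10, 0)
    b.bound(s2, "EX_o2", -40, 0)
    b.bound(s2, "EX_co2", 0, 1000)
    b.bound(s2, "EX_h2", 0, 0)
    b.bound(s2, "EX_cfix", 0, 0)
    b.scenario_objective[s2] = {"EX_co2": 1.0}
    b.mark_active(s2, "EX_ac", "EX_o2", "EX_co2", "T_ac", "T_o2", "T_co2",
                  "AOX_1", "AOX_2")


def _core_converter(b: _Builder) -> None:
    """CO2/H2 -> formate, or acetate consumption with sulfate as acceptor."""
    for m in ("co2", "h2", "for", "ac", "so4", "hs"):
        b.exchange(m)
    c = lambda m: b.met(f"{m}[c]", "c")
    b.rxn("T_co2", {"co2[e]": -1, c("co2"): 1}, lb=-1000)
    b.rxn("T_h2", {"h2[e]": -1, c("h2"): 1})
    b.rxn("T_for", {c("for"): -1, "for[e]": 1})
    b.rxn("T_ac", {"ac[e]": -1, c("ac"): 1})
    b.rxn("T_so4", {"so4[e]": -1, c("so4"): 1})
    b.rxn("T_hs", {c("hs"): -1, "hs[e]": 1})
    b.rxn("FDH", {c("co2"): -1, c("h2"): -1, c("for"): 1}, pathway=PATHWAY_PALETTE[0])
    b.rxn("ACU_1", {c("ac"): -1, c("so4"): -1, c("dx"): 1, c("co2"): 1},
          pathway=PATHWAY_PALETTE[1])
    b.rxn("ACU_2", {c("dx"): -1, c("so4"): -1, c("co2"): 1, c("hs"): 2},
          pathway=PATHWAY_PALETTE[1])

    s1 = "conversion_of_co2_to_formate"
    b.scenario(s1)
    b.bound(s1, "EX_co2", -10, 0)
    b.bound(s1, "EX_h2", -40, 0)
    b.bound(s1, "EX_for", 0, 1000)
    for rid in ("EX_ac", "EX_so4", "EX_hs"):
        b.bound(s1, rid, 0, 0)
    b.scenario_objective[s1] = {"EX_for": 1.0}
    b.mark_active(s1, "EX_co2", "EX_h2", "EX_for", "T_co2", "T_h2", "T_for", "FDH")

    s2 = "consumption_of_acetate"
    b.scenario(s2)
    b.bound(s2, "EX_ac", -10, 0)
    b.bound(s2, "EX_so4", -40, 0)
    b.bound(s2, "EX_co2", 0, 1000)
    b.bound(s2, "EX_hs", 0, 1000)
    for rid in ("EX_h2", "EX_for"):
        b.bound(s2, rid, 0, 0)
    b.scenario_objective[s2] = {"EX_co2": 1.0}
    b.mark_active(s2, "EX_ac", "EX_so4", "EX_co2", "EX_hs", "T_ac", "T_so4",
                  "T_co2", "T_hs", "ACU_1", "ACU_2")


_CORES = {
    "linear_fixation": _core_linear_fixation,
    "two_mode": _core_two_mode,
    "converter": _core_converter,
}

# availability of background chains across a species' scenarios; two-mode
# species split their background between shared, mode-specific, and silent
_CHAIN_ROLES_ONE_MODE = (("all", 0.8), ("off", 0.2))
_CHAIN_ROLES_TWO_MODE = (("all", 0.6), ("first", 0.15), ("second", 0.15), ("off", 0.1))


def _add_background_chains(b: _Builder, sp: SpeciesSpec, rng: np.random.Generator) -> None:
    scen_names = list(b.scenario_bounds)
    n_chains = max(1, sp.n_background_reactions // 6)
    roles, probs = zip(*(_CHAIN_ROLES_ONE_MODE if len(scen_names) == 1
                         else _CHAIN_ROLES_TWO_MODE))
    for j in range(n_chains):
        role = rng.choice(roles, p=probs)
        open_in = {
            "all": scen_names,
            "first": scen_names[:1],
            "second": scen_names[1:2],
            "off": [],
        }[role]
        tag = str(rng.choice(_BACKGROUND_TAGS))
        pre = f"bg{j:02d}"
        ex_in = b.exchange(f"{pre}s")
        ex_out = b.exchange(f"{pre}p")
        c = lambda m: b.met(f"{m}[c]", "c")
        chain = [b.rxn(f"T_{pre}s", {f"{pre}s[e]": -1, c(f"{pre}s"): 1})]
        prev = c(f"{pre}s")
        for k in range(int(rng.integers(1, 4))):
            nxt = c(f"{pre}i{k}")
            chain.append(b.rxn(f"C_{pre}_{k}", {prev: -1, nxt: 1}, pathway=tag))
            prev = nxt
        chain.append(b.rxn(f"T_{pre}p", {prev: -1, f"{pre}p[e]": 1}))
        for s in scen_names:
            if s in open_in:
                b.bound(s, ex_in, -1, -1)   # pinned uptake drives the chain
                b.bound(s, ex_out, 0, 1000)
                b.mark_active(s, ex_in, ex_out, *chain)
            else:
                b.bound(s, ex_in, 0, 0)
                b.bound(s, ex_out, 0, 0)


def _assign_genes_and_gapfill(
    b: _Builder, sp: SpeciesSpec, rng: np.random.Generator
) -> tuple[dict[str, int], dict[str, str | None]]:
    """Attach 1–3 synthetic genes to internal reactions; gapfill a background subset.

    Exchange pseudo-reactions stay gene-free (they are bookkeeping fluxes,
    not enzymes) and therefore land in the orphan bucket downstream.
    """
    gene_lengths: dict[str, int] = {}
    gene_reaction: dict[str, str | None] = {}
    counter = 0
    for rid in list(b.model.reactions):
        rxn = b.model.reactions[rid]
        if b.model.is_exchange(rxn):
            continue
        if rid.startswith("C_") and rng.random() < sp.gapfill_fraction:
            b.model.reactions[rid] = Reaction(
                id=rxn.id, stoichiometry=rxn.stoichiometry,
                lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
                gene_ids=frozenset(), gapfilled=True, pathway=rxn.pathway,
            )
            continue
        genes = []
        for _ in range(int(rng.integers(1, 4))):
            gid = f"{sp.name}_g{counter:04d}"
            counter += 1
            length = int(round(math.exp(rng.uniform(math.log(300), math.log(3000)))))
            gene_lengths[gid] = length
            gene_reaction[gid] = rid
            genes.append(gid)
        b.model.reactions[rid] = Reaction(
            id=rxn.id, stoichiometry=rxn.stoichiometry,
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            gene_ids=frozenset(genes), gapfilled=False, pathway=rxn.pathway,
        )
    for j in range(sp.n_nonmodel_genes):
        gid = f"{sp.name}_x{j:03d}"
        gene_lengths[gid] = int(round(math.exp(rng.uniform(math.log(300), math.log(3000)))))
        gene_reaction[gid] = None
    recA = f"{sp.name}_recA"
    gene_lengths[recA] = _RECA_LENGTH_BP
    gene_reaction[recA] = None
    return gene_lengths, gene_reaction


def generate_models(spec: CommunitySpec) -> list[SpeciesBuild]:
    """Build every species' model, scenarios, and ground-truth active sets."""
    builds = []
    for i, sp in enumerate(spec.species):
        rng = np.random.default_rng([spec.seed, i])
        b = _Builder(sp.name)
        _CORES[sp.core_pathway](b)
        _add_background_chains(b, sp, rng)
        gene_lengths, gene_reaction = _assign_genes_and_gapfill(b, sp, rng)
        b.model.validate()
        scenarios = [
            Scenario(
                name=s,
                exchange_bounds=b.scenario_bounds[s],
                objective=b.scenario_objective[s],
                sense="maximize",
            )
            for s in b.scenario_bounds
        ]
        for s in scenarios:
            s.validate_against(b.model)
        builds.append(
            SpeciesBuild(
                model=b.model,
                scenarios=scenarios,
                active_truth={s: frozenset(v) for s, v in b.active.items()},
                gene_lengths=gene_lengths,
                gene_reaction=gene_reaction,
                recA_gene=f"{sp.name}_recA",
            )
        )
    return builds


# ---------------------------------------------------------------------------
# count generation
# ---------------------------------------------------------------------------


@dataclass
class CountsResult:
    table: CountTable
    recA_map: dict[str, str]
    # gene x sample truth of the drawn expression states
    expressed_truth: pd.DataFrame
    # sample -> set of reaction ids whose genes were drawn expressed
    reaction_expressed: dict[str, set[str]]


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, spec: CommunitySpec) -> np.ndarray:
    if spec.count_noise == "poisson":
        return rng.poisson(lam)
    n = 1.0 / spec.dispersion
    p = n / (n + lam)
    return rng.negative_binomial(n, p)


def generate_counts(
    spec: CommunitySpec,
    builds: Sequence[SpeciesBuild],
    scenario_by_sample: Mapping[str, Sequence[str]] | None = None,
    support_prob_by_scenario: Mapping[str, float] | None = None,
) -> CountsResult:
    """Draw a raw count table consistent with the planted ground truth.

    A reaction active under any scenario realized in a sample has its
    genes expressed with probability ``support_prob`` (per-scenario
    overrides via ``support_prob_by_scenario``; a reaction active under
    several realized scenarios uses the largest applicable probability).
    Genes of inactive reactions leak with probability ``leak_prob``.
    Expressed genes receive counts at the bin's reference level, so the
    recA-scaled expression of an expressed gene sits near 1; unexpressed
    genes emit at ``basal_rate`` of that level.  Each bin's recA marker
    is always expressed, keeping recA normalization well-posed.

    ``scenario_by_sample`` maps sample id → realized scenario names
    (default: every scenario of every species is realized in every
    sample, i.e. the community performs all of its hypothesized roles).
    """
    rng = np.random.default_rng([spec.seed, 7919])
    support_over = dict(support_prob_by_scenario or {})
    all_scen = [s.name for b in builds for s in b.scenarios]
    if scenario_by_sample is None:
        scenario_by_sample = {smp: list(all_scen) for smp in spec.samples}
    for smp in spec.samples:
        if smp not in scenario_by_sample:
            raise ValueError(f"scenario_by_sample missing sample {smp!r}")

    gene_rows = []
    for b in builds:
        for gid, length in b.gene_lengths.items():
            gene_rows.append((gid, b.bin_id, length))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "bin_id", "length_bp"])
    genes = genes.set_index("gene_id")
    gene_pos = {gid: i for i, gid in enumerate(genes.index)}

    on = np.zeros((len(genes), len(spec.samples)), dtype=bool)
    reaction_expressed: dict[str, set[str]] = {smp: set() for smp in spec.samples}

    for j, smp in enumerate(spec.samples):
        realized = set(scenario_by_sample[smp])
        for b in builds:
            active_by_scen = {
                s: b.active_truth[s] for s in b.active_truth if s in realized
            }
            for rid, rxn in b.model.reactions.items():
                if not rxn.gene_ids:
                    continue
                scens_with = [s for s, act in active_by_scen.items() if rid in act]
                if scens_with:
                    p = max(support_over.get(s, spec.support_prob) for s in scens_with)
                else:
                    p = spec.leak_prob
                if rng.random() < p:
                    reaction_expressed[smp].add(rid)
                    for gid in rxn.gene_ids:
                        on[gene_pos[gid], j] = True
            for gid, rid in b.gene_reaction.items():
                if rid is None and gid != b.recA_gene:
                    on[gene_pos[gid], j] = rng.random() < 0.5
            on[gene_pos[b.recA_gene], j] = True
    expressed = pd.DataFrame(on, index=genes.index, columns=list(spec.samples))

    # gene-specific expression level, constant across samples; the recA
    # marker stays pinned at the reference level 1
    levels = np.exp(rng.normal(0.0, spec.expr_level_sd, size=len(genes)))
    recA_genes = {b.recA_gene for b in builds}
    levels[[gene_pos[g] for g in recA_genes]] = 1.0

    lengths = genes["length_bp"].to_numpy(dtype=float)
    counts = np.zeros((len(genes), len(spec.samples)), dtype=np.int64)
    bin_ids = genes["bin_id"].to_numpy()
    for j, smp in enumerate(spec.samples):
        ab = np.array([spec.abundance_of(b, smp) for b in bin_ids])
        rate = np.where(on[:, j], 1.0, spec.basal_rate)
        lam = spec.mean_depth * ab * rate * levels * lengths / 1000.0
        counts[:, j] = _draw_counts(rng, lam, spec)
    table = CountTable(
        genes=genes,
        counts=pd.DataFrame(counts, index=genes.index, columns=list(spec.samples)),
    )
    # the single-copy marker must be observed in every sample
    recA_map = {b.bin_id: b.recA_gene for b in builds}
    for b in builds:
        row = table.counts.loc[b.recA_gene]
        table.counts.loc[b.recA_gene] = row.clip(lower=1)
    return CountsResult(
        table=table,
        recA_map=recA_map,
        expressed_truth=expressed,
        reaction_expressed=reaction_expressed,
    )


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------


def write_fixture(spec: CommunitySpec, outdir: str | Path) -> Path:
    """Materialize the complete fixture in the pipeline's input formats.

    Writes per-species model directories and scenario YAMLs, the counts
    TSV, the recA map, a ground-truth JSON, and a ready-to-run pipeline
    config.  Byte-identical across runs with the same spec.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    builds = generate_models(spec)
    result = generate_counts(spec, builds)

    species_cfg = []
    for b in builds:
        model_dir = outdir / "models" / b.bin_id
        write_model(b.model, model_dir)
        scen_path = outdir / "scenarios" / f"{b.bin_id}.yaml"
        scen_path.parent.mkdir(parents=True, exist_ok=True)
        write_scenarios(b.scenarios, scen_path)
        species_cfg.append(
            {
                "model": str(model_dir.relative_to(outdir)),
                "scenarios": str(scen_path.relative_to(outdir)),
            }
        )
    write_counts(result.table, outdir / "counts.tsv")
    recA_lines = ["bin_id\tgene_id"] + [
        f"{b}\t{g}" for b, g in sorted(result.recA_map.items())
    ]
    (outdir / "recA_map.tsv").write_text("\n".join(recA_lines) + "\n")

    truth = {
        "seed": spec.seed,
        "active_truth": {
            b.bin_id: {s: sorted(v) for s, v in sorted(b.active_truth.items())}
            for b in builds
        },
        "expressed_truth": {
            smp: sorted(result.expressed_truth.index[result.expressed_truth[smp]])
            for smp in spec.samples
        },
        "reaction_expressed": {
            smp: sorted(v) for smp, v in sorted(result.reaction_expressed.items())
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))

    config = {
        "species": species_cfg,
        "counts": "counts.tsv",
        "recA_map": "recA_map.tsv",
        "sample": "CCc",
        "flux_tol": 1e-6,
        "expression_threshold": 0.1,
        "pseudocount": 0.1,
        "equivalence_margin": 2.0,
        "outdir": "results",
        "seed": spec.seed,
    }
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config, default_flow_style=False, sort_keys=False)
    )
    return outdir
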