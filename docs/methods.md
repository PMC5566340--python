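# Methods

## Scope and model of the analysis

`fluxcord` scores the agreement between flux-balance predictions of
per-species metabolic activity and metatranscriptome-derived gene
expression in a binned microbial community.  Each species bin carries
its own genome-scale (here: toy-scale) metabolic model; models are
solved independently per scenario — there is no community-coupled FBA,
no dynamic FBA, and no expression-constrained flux fitting (GIMME/iMAT
style).  Expression is used strictly post hoc, to evaluate predictions,
never to shape them.

## Flux balance analysis

Each scenario LP is `optimize c·v s.t. S·v = 0, lb ≤ v ≤ ub`, with the
scenario's exchange bounds overriding the model's defaults.  The solver
is scipy's HiGHS interface with deterministic default pivoting; no
randomized restarts.

**Parsimony.** The optimal face of an FBA problem is typically not a
point; arbitrary members can carry futile cycles that inflate "active"
counts.  We therefore minimize Σ|v| at the optimum (second LP, fluxes
split against auxiliary magnitudes, objective pinned by an exact
equality row) and report that parsimonious solution.  Internal loops
are mitigated only by parsimony; thermodynamic loop-law constraints are
out of scope.

**Activity rule.** A reaction is active iff |v| > tol on the
parsimonious point solution, strictly, with tol = 10⁻⁶ in flux units
(bounds in the usual mmol·gDW⁻¹·h⁻¹ convention).  How the original
analysis operationalized "active" is not documented anywhere we could
follow; the point-solution rule plus a flux-variability diagnostic
(`flux_variability`, objective held at γ × optimum) is this package's
explicit choice.  An alternative rule (`active_if = anyopt`: active if
any optimal solution uses the reaction, via FVA at γ = 1) is exposed in
the run config.

Degenerate cases: infeasible scenarios raise with the pinned exchange
bounds listed; unbounded objectives raise naming the objective
reactions; tol < 0 and γ ∉ [0, 1] are rejected.

## Expression normalization

Order of operations: raw counts → RPKM → recA scaling → quantile
normalization → threshold calls.

- RPKM[g,s] = counts · 10⁹ / (length_bp · total_counts[s]); the total is
  per sample over the whole combined community table, because reads are
  assumed mapped against one combined metagenome.
- recA scaling divides every gene of bin *b* by the RPKM of *b*'s
  designated single-copy recA marker, sample-wise; the marker itself is
  set to exactly 1.0.  This cancels taxon-abundance differences between
  samples, so scaled values track per-cell expression.  If a bin has
  several recA candidates, the copy with the highest mean RPKM is used
  and a warning is issued.
- Quantile normalization replaces rank r in each column with the mean of
  the r-th order statistics across columns.  Ties receive the mean of
  the order statistics their run spans, so tied entries stay tied (the
  same convention as limma's tie-averaging).  Consequence: on data with
  ties the output column distributions are only near-identical — exact
  distribution identity holds on tie-free (continuous) data.  This
  trade-off is inherent to tie averaging and is asserted as such in the
  tests.
- A gene is called expressed when its normalized value is ≥ 0.1
  (inclusive).  The threshold is configurable; 0.1 is the pipeline's
  only floor constant and doubles as the fold-change pseudocount, for
  which fc = (x₁ + 0.1)/(x₂ + 0.1) so that 0/0 → 1.  Whether calls
  should use quantile-normalized or only recA-scaled values is
  configurable (`quantile: false`); quantile-normalized is the default.

## Concordance scoring

Five-way classification per reaction (active/inactive × any-gene
expressed/silent, plus gapfilled-without-genes), with any-gene
semantics throughout — no boolean gene-protein-reaction structure is
evaluated, because the scoring semantics ("at least one associated
gene expressed") never needs it.  Non-gapfilled reactions with no genes
(exchanges, spontaneous reactions) fit none of the five classes and are
kept in a sixth orphan bucket, excluded from all denominators.

Support percentage = 100 · supported / active-with-genes; undefined
(reported "NA", never 0) when nothing gene-associated is active.
Formatting uses integer rounding; when two scenarios of the same
species would collide at integer precision, that species' group
switches to one decimal place so near-equal alternative roles stay
distinguishable.  Tests compare percentages with a 0.1-point tolerance
to absorb round-versus-truncate ambiguity in published tables.

Pathway aggregation produces a five-category count tuple per pathway
tag, with an optional lumping map (e.g. rTCA + Wood-Ljungdahl →
"CO2 fixation"); unmapped tags are an error listing the offenders.
Scenario comparison reports pairwise support differences and flags
pairs within 2 percentage points (configurable) as "equally
supported" — this margin is our operationalization of "nearly equal
agreement" between alternative metabolic roles.

Default scored sample is CCc (closed-circuit cathode); any sample can
be selected.

## Synthetic community generator

The generator emulates the statistical structure of a three-species
electrosynthesis community, not its biochemistry:

- **Species cores.** An acetogen with a linear Wood-Ljungdahl-like
  chain (2 CO₂ + 3 H₂ → acetate, one route, one scenario); a two-mode
  species (rTCA-like CO₂ reduction vs. aerobic acetate oxidation, two
  scenarios sharing the CO₂ transporter/exchange); and a converter
  (CO₂/H₂ → formate vs. acetate consumption with sulfate).  Every core
  is a linear chain, so each scenario's parsimonious active set is
  unique and known by construction; the generator records it and the
  test suite re-derives it by FBA.
- **Background chains.** Independent linear uptake→conversion→export
  chains (4–7 reactions each) driven by pinned exchange bounds, so each
  chain is deterministically on or off per scenario.  Single-mode
  species open 80% of chains; two-mode species split chains 60%
  shared / 15% + 15% mode-specific / 10% silent, mirroring the fact
  that alternative roles of one organism share most of their network.
- **Genes.** Internal reactions get 1–3 unique synthetic genes, lengths
  log-uniform on 300–3000 bp.  Exchange pseudo-reactions carry no genes
  (they are bookkeeping fluxes, not enzymes), which also exercises the
  orphan bucket.  A fraction of background conversions (default 10%)
  is flagged gapfilled with genes stripped.  Each bin gets a recA
  marker (1040 bp) and non-model background genes.
- **Counts.** A reaction active under any scenario realized in a sample
  has its genes expressed with probability `support_prob` (default
  0.76; per-scenario overrides take the maximum over realized roles);
  inactive reactions leak with probability `leak_prob` (default 0.3).
  Expected counts are mean_depth × abundance × level × length/1000,
  with a per-gene log-normal level (σ = 1) held constant across
  samples — real transcript abundances span orders of magnitude, and a
  continuous level distribution keeps quantile normalization
  well-behaved.  Unexpressed genes emit at 0.001 of their expressed
  level: two orders of magnitude below the 0.1 call floor, so drawn
  truth labels remain recoverable even at the tail of the level
  distribution (the module's recoverability contract).  Noise is
  negative binomial with dispersion 0.2 (variance μ + 0.2 μ²,
  over-Poisson as real RNA-seq is); Poisson is available for sharper
  tests.  recA counts are clamped ≥ 1 so the scaling step is always
  well-posed.
- By default every scenario of every species is treated as realized in
  every sample (the community performs all of its hypothesized roles),
  which is what makes alternative scenarios of one species come out
  near-equally supported, as observed in real communities of this kind.
- All generation is a pure function of the community spec including its
  seed; fixtures are byte-identical across runs.

**What passing tests do and do not show.**  The generator plants
reaction-level support as independent Bernoulli draws and builds models
whose active sets are exactly recoverable; real communities violate
both (correlated regulation, operon structure, alternate optima,
mis-binning, multi-copy markers).  Green statistical tests therefore
demonstrate that the pipeline recovers planted parameters under its own
assumptions at the stated sizes — they do not certify accuracy on real
reactor data.

## Problem sizes used in the checks

Deliberate desk-scale choices: the default trio uses ~30 background
reactions per species (models of 40–45 reactions), where support
percentages carry binomial noise of several points.  Parameter-recovery
checks use a single species with ~700 background reactions (≈ 330–400
active gene-associated reactions) and 20 seeds per planted probability,
compared against exact central 95% binomial intervals.  The
scenario-equivalence check uses a two-mode species with ~2000
background reactions (≈ 950 active per scenario, ~20% scenario-
specific), where the 2-point margin separates symmetric support from a
0.9-vs-0.4 split with high probability.

## Numerical choices

LP feasibility tolerances are HiGHS defaults (≈ 10⁻⁹ primal/dual);
activity comparisons use the raw solver solution without rounding.
Stoichiometric coefficients are kept as read, with no normalization.
The canonical model serialization sorts reactions and metabolites by id
and formats numbers with `%.12g`, so write∘read∘write is byte-stable.
Fold-change rankings sort stably by (value, gene id) and are invariant
to input row order.

## Known limitations

Two compartments only (cytosol/extracellular); flat gene sets, no GPR
logic; no replicate-based differential-expression testing (fold changes
are descriptive ratios); no thermodynamic constraints or loop-law
removal; SBML models are import-only and their gapfill status cannot be
recovered from the exchange format (imported reactions default to
non-gapfilled); the 33-category pathway assignment of real models is
treated as input metadata, with only a six-tag palette generated
synthetically.
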