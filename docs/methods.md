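# Methods

This note documents the models, numerical choices and simulation design
behind `genomedecay`, and what the test suite does and does not
demonstrate about real data.

## Stoichiometric models and flux balance

A model is a pair (S, bounds): S is the metabolites × reactions matrix
of rational coefficients, and every flux vector must satisfy S·v = 0
with l ≤ v ≤ u. Two compartments (cytosol, extracellular) are supported.
Exchange reactions are written `EX_<met>` with stoichiometry
{met_e: −1}; **negative exchange flux is uptake, positive is
secretion**. Applying a medium sets each exchange's lower bound to
−uptake_limit for medium nutrients and 0 otherwise; secretion keeps the
stored upper bound. Default uptake_limit is 10 and the generic flux cap
is 1000, in arbitrary consistent flux units.

The six-step analysis runs: (i) growth check on the complete medium and
a biomass floor of `growth_floor_fraction` × the maximum (default 0.1 —
the procedure only needs a nonzero floor, and a fraction of the maximum
is scale-free); (ii) exact minimal-media MILP; (iii–iv) FVA under the
minimal medium with biomass ≥ floor; (v) biomass maximization and
fixing; (vi) parsimonious FBA. Whether classification fixes biomass at
the floor or at its maximum is configurable (`fix_biomass_at`,
default `"floor"`); the floor reading keeps the full range of
growth-compatible flux states visible to the classifier.

Numerical choices:

- LP/MILP are solved with HiGHS via `scipy.optimize.linprog`/`milp`.
- Feasibility tolerance ε_feas = 1e-7 on returned optima; zero-flux
  tolerance ε = 1e-6 (model flux units) in classification and
  flux-capability tests. Networks are built with integer-ish
  stoichiometries and bounds of 10/1000, so attainable flux extremes sit
  far from ε.
- Minimal-media MILP: one binary per exchange with big-M =
  uptake_limit; ties among equal-cardinality optima are broken to the
  lexicographically smallest nutrient-id set by greedily forcing
  nutrients in ascending id order under a fixed-cardinality feasibility
  MILP. Determinism of downstream pipelines depends on this.
- Parsimonious FBA uses standard flux splitting v = p − q, p, q ≥ 0,
  minimizing Σ(p + q) with biomass fixed to its maximum (±1e-9).
  Any futile cycle carrying flux would strictly increase the objective,
  so returned profiles are loop-free.
- Gapfilling is lexicographic two-stage: stage 1 is an exact MILP for
  the minimum number of added database reactions (uniform cost 1; the
  original weighting scheme of template-based reconstruction pipelines
  is unspecified, so no direction or confidence weights are applied);
  stage 2 enumerates *all* cardinality-optimal sets via no-good cuts and
  keeps the one maximizing the number of gene-associated model reactions
  able to carry flux (per-reaction LP max/min with biomass ≥ floor on
  the complete medium), final ties lexicographic. A single-flux-vector
  indicator MILP cannot express "able to carry flux" — different
  reactions may need different flux distributions — hence the
  enumeration, which is exact and cheap at the problem sizes this
  package targets (tens of candidates; a guard caps enumeration at 200
  sets).
- Degenerate inputs: models that cannot produce biomass on the complete
  medium raise an auxotrophy error naming the genome (the cue for
  gapfilling); unbounded biomass raises an error indicating a missing
  exchange constraint.

## Comparative analyses

Reaction prevalence counts a reaction as present in a model only when it
carries a gene association (gapfilled reactions never count). Lineage
cores use "present in at least 75% of models", compared with exact
rationals so the 3-of-4 boundary is inclusive; core models inherit
merged gene associations, are gapfilled on the complete medium, and can
be run through the six-step analysis. The cross-lineage conserved core
is the intersection of gene-associated reaction sets over all models —
one of two defensible readings (the other being a 75% threshold applied
across lineages); the intersection is the stricter and is what
containment fractions are computed against, reported per lineage plus
mean-over-lineages and pooled summaries, since published figures of this
kind do not always state which aggregation was used.

## Occurrence, coevolution, auxotrophy

A pathway is complete when ≥ 90% of its expected roles are annotated
(inclusive, exact rationals: 9 of 10 qualifies — chosen because one
member of a 10-gene pathway, a phosphatase family, is notoriously hard
to annotate and its absence should not flip the call). A bifunctional
role shared by two pathways appears in both expected-role sets and
counts toward both. The coevolution concordance — the fraction of
genomes where focal-gene presence coincides with having at least one
complete dependent pathway — is this package's own quantification of
"tracks with"; no published numeric statistic exists for it, and reports
label it as such. Auxotrophies are read directly off the minimal medium
through a nutrient → pathway map.

## dN/dS

The estimator is Nei–Gojobori-style counting, chosen over
maximum-likelihood codon models because it is self-contained and
verifiable against an enumeration oracle to 1e-9; absolute values are
therefore not comparable to ML estimates (a documented divergence), but
ratios and rank orderings — what the analyses consume — are robust.
Conventions, identical in the engine and the oracle:

- Sites: per codon position, the synonymous fraction of the three
  possible changes; changes creating stops count as nonsynonymous, so
  every sense codon contributes exactly 3 sites. Site totals are
  averaged over the two sequences.
- Differences: averaged over minimal mutational pathways; pathways
  through intermediate stop codons are discarded (all pathways kept,
  stop steps nonsynonymous, in the rare case every pathway is blocked).
- Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3), undefined at
  p ≥ 3/4; gap triplets and ambiguous codons are dropped pairwise.
- Clade ω is the ratio of mean pairwise dN to mean pairwise dS (not the
  mean of ratios), which stays stable when individual pairs have dS ≈ 0;
  saturated pairs are dropped and `n_pairs` reports how many were used.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Universe.** Four linear biosynthesis chains (lengths 10, 7, 5, 4) run
from a single transportable carbon source through a shared central
metabolite to amino-acid end products consumed by biomass. The first two
chains mirror the histidine/tryptophan gene counts and converge on one
bifunctional isomerase role (step 5 of the 10-chain, step 3 of the
7-chain — one role, two reactions). Every end product is also
transportable via a salvage transporter. Because biosynthesis shares the
carbon source while salvage costs one nutrient per pathway, the minimal
medium is *exactly* {carbon} ∪ {end product of every broken pathway},
which is what makes auxotrophy recovery scoreable without ambiguity. One
step of the third chain also has an analogous isoenzyme under a distinct
role, giving redundant routes (and hence "functional" reaction classes)
in intact genomes. Transporter, central-metabolism and isoenzyme roles
are present in every genome and protected from loss — a decayed genome
that lost its salvage transporter would be nonviable, which the decay
model forbids.

**Decay.** 20 genomes in four 5-leaf lineage clades (leaf-to-clade-root
path 1.1 branch-length units; lineages III and IV are sisters).
Environments: lineage II supplies no amino acids (fully protected,
mirroring large intact genomes); I and III each supply one of the
convergent pair plus an auxiliary product; IV supplies everything
(deepest decay). Along each branch lying entirely inside one lineage
clade, each gene of a supplied pathway is lost independently with
probability 1 − exp(−loss_rate·branch_length) (exponential waiting
times, so Monte-Carlo frequencies can be checked against the closed
form); branches spanning lineages are protected. Default loss_rate 2.0
gives ≈ 0.89 cumulative per-gene loss in supplied lineages — deep decay
with residual gene-level variation between genomes. Loss is
irreversible; no gene regain or transfer is modeled.

Truth records two pathway states per genome, which deliberately differ:
**lost** (some chain step has no annotated role — metabolically broken;
this is what auxotrophy predictions are scored against) and **retained**
(role completeness ≥ 90%; this drives the focal-gene rule). A pathway
can be broken yet still "complete", just as a nearly intact pathway with
one unannotatable gene would look in real data. The focal gene is
deleted exactly when both dependent pathways drop below the completeness
call, so focal presence ⇔ ≥ 1 retained pathway holds by construction.
Planted discordances re-add the focal gene to genomes whose two
dependent pathways are both decayed far enough that the addition cannot
re-complete either (adding a gene never endangers viability); with k
plantings among n genomes the concordance is exactly (n−k)/n. Every
emitted genome is verified to grow in its own environment on every run.

**Codon evolution.** A random sense-codon root sequence evolves along
the tree; point mutations are proposed at `mutation_rate` per nucleotide
per unit branch length (Poisson), proposals creating stops are rejected,
synonymous changes fix always, nonsynonymous ones with the governing
clade's ω. No indels, standard genetic code only. Substitution
bookkeeping (proposed/fixed counts per clade) lets tests confirm the
fixation probability equals ω. The selection-regime recovery experiment
uses ω = 0.06/0.09/0.15 across three 8-leaf clades, 300 codons and
mutation rate 1.5 — pairwise divergences around dS ≈ 0.4, deep enough to
discriminate neighboring ω values (28 within-clade pairs each) while
staying well below Jukes–Cantor saturation.

**Homology hits.** The emitted hit table gives every gene a strong
reciprocal hit to same-role genes in other genomes (bit score 200,
e-value 1e-50) — an idealization with no weak or spurious hits, so BBH
threshold behavior is exercised only by the unit fixtures, not the
scenario.

## What the oracles do and do not show

All LP/MILP results are verified exactly against solver-free references
on networks of ≤ 8 reactions: vertex enumeration of {S·v = 0, l ≤ v ≤ u}
for optima and FVA ranges, exhaustive subset search in (cardinality,
lexicographic) order for media and gapfilling, sign-orthant × vertex
enumeration for parsimonious totals, and naive per-codon pathway
enumeration for dN/dS. Passing these batteries shows the engine is a
correct implementation of the stated optimization problems; it does not
show that toy-universe conclusions transfer to genome-scale models,
where degeneracy, alternate optima and thermodynamically infeasible
loops are far more prevalent (loopless FVA is out of scope).

## Known limitations

- The synthetic universe has linear pathways, two compartments, unit-ish
  stoichiometry and a single biomass drain; real reconstructions have
  cofactor coupling, reversible reactions and compartment hierarchies
  that make minimal-media and classification calls less clean.
- Gene-protein-reaction logic is limited to disjunctions of single genes
  or conjunctive pairs.
- The counting dN/dS has no transition/transversion or codon-frequency
  correction; per-clade means over pairs are not phylogenetically
  independent contrasts.
- The decay model forbids regain/HGT and recombination; trees and
  alignments are consumed, never inferred.
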