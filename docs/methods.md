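# Methods

`latentpath` implements a thermodynamics-constrained search for carbon-fixation
pathways that are latent in a heterotroph's native reaction network, together
with the downstream analyses used to characterise the best such pathway — the
GED (Gnd–Entner–Doudoroff) cycle: driving-force evaluation, FBA yield
comparison of pathway variants, positional ¹³C labeling prediction, and
Michaelis–Menten kinetics. This note records the models, the assumptions
behind them, and the design choices made where the design was genuinely open.

## Pathway search (MILP)

**Problem.** Find reaction subsets of a metabolic network that, run in some
direction assignment, convert 3 CO₂ (plus freely regenerated cofactors) into
1 pyruvate at steady state while every reaction retains a positive
thermodynamic driving force for some choice of metabolite concentrations.

**Preprocessing.** Exchange and transport reactions are removed and only
strictly cytoplasmic reactions kept (compartment decided by the BiGG `_c`
suffix). Currency pseudo-reactions are then appended: ATP regeneration from
ADP and from AMP, NADH and NADPH regeneration, and free single-species
exchange of H⁺, H₂O, O₂ and NH₄⁺ (eight in total, all reversible). They are
marked and excluded from pathway size, from thermodynamic constraints, and
from enumerated supports. CO₂ is flagged as a currency species for supply
purposes but is the counted substrate of the search: it carries the −3
net-conversion constraint rather than a free exchange.

**Formulation.** Every non-pseudo reaction is split into forward/backward
arcs with binary indicators z and fluxes v, subject to

* steady state `S v = b` with b = −3 on CO₂, +1 on pyruvate, 0 elsewhere
  (currency species balanced through the pseudo-reaction columns);
* `ε z ≤ v ≤ V z` (ε = 10⁻³, V = 1000) and `z_fwd + z_bwd ≤ 1`;
* big-M driving-force linking
  `−(d·ΔG′° + RT Σ S·d·x) ≥ B − M(1−z)` with M = 2000 kJ/mol, log-scale
  concentrations x bounded to the physiological range, and fixed species
  (dissolved CO₂) pinned;
* a positivity floor `B ≥ 10⁻⁴ kJ/mol`.

The objective maximises `B/RT − w·Σz` (default weight w = 1). After each
optimum the integer cut `Σ_{i∈support} z_i ≤ |support| − 1` is appended and
the MILP re-solved until infeasibility or the solution cap. Because the flux
floor makes indicator supports equal flux supports, and supersets of a
feasible support are both worse in the objective and excluded by the cuts,
the iteration returns exactly the inclusion-minimal directed supports whose
exact MDF is positive — the property the brute-force oracle checks. Each
solution's MDF is re-evaluated with the exact LP (never trusted from the
big-M embedding); a guard aborts if the two disagree at zero.

All reactions are treated as reversible during search regardless of source
bounds; source bounds are honoured only by FBA. Solver: HiGHS through
`scipy.optimize.milp` (deterministic; enumeration order is solver-dependent,
so consumers should compare support sets, not iteration order).

**Ranking.** Pathways are ranked by the Pareto criterion (maximise MDF,
minimise reaction count); exact ties on both coordinates are all kept. We
count reactions, not enzymes: isozymes are indistinguishable at this level.

## Max–min Driving Force

For a directed pathway the MDF is the largest B such that log-concentrations
x within bounds give every reaction `−ΔrG′ = −(ΔG′° + RT Σ s·x) ≥ B` — a
small LP. Conventions:

* T = 298.15 K (RT ≈ 2.479 kJ/mol), matching the vendored ΔG′° table even
  though the organism grows at 37 °C; configurable.
* H₂O and H⁺ are excluded from concentration terms (their activities are
  folded into the transformed energies).
* Default bounds 1 µM – 10 mM; O₂ and NH₄⁺ pinned at 1 mM; dissolved CO₂
  pinned at its Henry's-law level for the configured headspace pressure
  (0.0338 M/bar × 0.2 bar ≈ 6.8 mM at the default 200 mbar).
* Cofactor pairs (ATP/ADP, NAD(P)H/NAD(P)⁺) are free within bounds — no
  fixed ratios. This is permissive: it admits, e.g., a pyruvate-kinase-
  reversal variant of the GED cycle that a fixed ATP/ADP ratio would
  exclude. That variant has a lower MDF than the canonical cycle and never
  enters the Pareto front, so the headline result is insensitive to the
  choice; tightening ratios is available through bound overrides.
* Degenerate optima: only B and the per-reaction ΔrG′ at the optimum are
  contract-stable; the reported concentration vector is one optimal vertex.

`ΔrG′m` values quoted for single reactions use 1 mM reference concentrations
for everything except species with fixed concentrations (CO₂).

## The fixture network

A ~60-reaction desk-scale stand-in for a genome-scale *E. coli*
reconstruction: glycolysis/gluconeogenesis (including PEP synthetase and
FBPase), the ED pathway, both pentose-phosphate branches, glucose/xylose/
ribose uptake, fermentation sinks (lactate, acetate, ethanol, formate), a
lumped P/O = 2 respiratory chain, adenylate kinase, a soluble-type
transhydrogenase, optional PRK/Rubisco and an optional compact TCA arm.
Simplifications a genome-scale model would not make:

* transport is uniport with no proton coupling (transport energetics
  neglected);
* NADPH supply is a reversible soluble-type transhydrogenase rather than
  the proton-translocating membrane enzyme;
* thioester carbon follows the acyl-only convention (free CoA counts 0), so
  carbon balance is exact without tracking the carrier;
* proton stoichiometries are plausible but not charge-audited — only carbon
  balance is asserted.

Consequently, passing fixture tests demonstrates the *algorithms* (search,
MDF, FBA orderings, accounting identities), not genome-scale biology: the
fixture has exactly one positive-MDF Pareto pathway (the GED cycle) by
construction, whereas the full reconstruction also contains a reverse
glycine-cleavage route; reproducing that two-pathway front is an opt-in run
against the real model.

**Vendored thermodynamics.** `data/dg0_prime.tsv` carries one transformed
standard Gibbs energy per reaction (pH 7.5, I = 0.25 M, 25 °C,
component-contribution style). Two entries are exact by construction: Gnd is
+10.9 kJ/mol so that the oxidative decarboxylation at 1 mM reactants and
200 mbar CO₂ evaluates to ≈ −1.5 kJ/mol (the near-equilibrium operating
point that makes reductive carboxylation possible at elevated CO₂ and
strongly favours decarboxylation at ambient CO₂), and the pentose isomerase
carries −RT ln 0.458, the equilibrium constant used in the assay-design
calculation. The lactonase is −25.0 kJ/mol, irreversible within the
concentration range, which keeps the oxidative-PPP-reversal shortcut out of
the feasible set as in the genome-scale network.

**Random networks.** Oracle tests use connected random networks (≤ 12
reactions, integer coefficients in ±2, carbon-balanced by construction,
ΔG′° ~ U(−40, 40) kJ/mol, no currency species). A minimal balanced route
from the 1-carbon substrate to the 3-carbon product is planted in half the
instances so the MILP-vs-brute-force comparison is not vacuously empty.
Everything is seeded; identical specs give identical networks.

## ATP accounting

Cost per mole of product = Σ over support reactions of flux × (ATP→ADP
equivalents + 2 × ATP→AMP equivalents), credited for substrate-level
phosphorylation, with fluxes scaled to 1 mol product. Counting the
PPi-releasing PEP synthetase as 2 equivalents is what separates the GED
cycle (2 PPS × 2 + 2 PGK × 1 = 6) from the RuBP cycle
(3 PRK + 5 PGK − 1 PYK = 7). A reaction that changes the adenylate pool
without conserving ATP+ADP+AMP is rejected (no rule to classify it).

## FBA

Direct LP over the network data model: maximise product secretion subject to
steady state, fixed substrate uptake (xylose 10.8, glucose 13.1 mmol/gDW/h —
measured fermentative rates), fixed non-growth ATP maintenance
(6.86 mmol/gDW/h), unconstrained CO₂ exchange, secretion-only bounds on all
other carbon exchanges, oxygen per the aerobic flag, and hydrogen only when
configured as an extra electron donor (through the irreversible hydrogen
dehydrogenase). Product exchanges are auto-created for cytosolic species
that lack one. Byproducts are secretions above 10⁻⁶ mmol/gDW/h, excluding
CO₂ and carbon-free species. Excess ATP is dissipated by the
PPS/PYK/adenylate-kinase futile cycle, so fixing uptake does not make
ATP-overproducing optima infeasible.

Variants: shunts block PFK, PFK_3, F6PA, G6PDH2r and FBP (ids resolved
through a small synonym map — the fixture names its G6P dehydrogenase ZWF);
GED variants make Gnd reversible; RuBP variants add PRK and Rubisco. The
eight standard curations are applied when their target reactions exist and
are logged otherwise, so the same code path serves toy and genome-scale
models. Figure-level genome-scale yield values are not reproduction targets;
only orderings (GED ≥ RuBP, strictness on ATP-limited products, the effect
of an H₂ donor) and the exact homolactate stoichiometry are asserted.

## ¹³C labeling

Label propagation is exact positional bookkeeping over three atom maps
(pentose → Ru5P order-preserving; carboxylation inserts CO₂ as 6PG C1 and
shifts Ru5P C1–5 to C2–6; ED aldol cleavage splits C3–C4), hard-coded from
the pathway chemistry rather than a reaction database. The pyruvate pool is
an exactly 50:50 Eda/GAP mixture (the ideal shunt stoichiometry; biosynthetic
drains that would perturb "about half" are out of scope). Valine condenses
two independent pool draws with the *acceptor's* carboxyl lost as CO₂ — the
assignment required for the 1:1:1:1 prediction, and a documented symmetry
test shows what the donor-loss alternative would give. Histidine is modelled
as five R5P carbons plus serine's β-carbon; the purine detour of its extra
carbon is not modelled. Natural ¹³C abundance is off by default; no printed
prediction depends on it. All fractions are `fractions.Fraction` — sums to 1
are exact, not approximate.

## Kinetics

`v = kcat·s/(KM + s)`, fitted by unweighted nonlinear least squares
(`scipy.optimize.curve_fit`) with deterministic initialisation (kcat₀ = max
rate; KM₀ = substrate nearest half-max) and standard errors from the
parameter covariance; optional 1/v² weighting. Measured kinetic
parameters are used only as simulation ground truth for recovery tests
(noiseless recovery to 10⁻⁶ relative; < 3% mean bias at n = 15 and 5% CV over
200 replicates), never asserted as measurement reproductions.
`ru5p_equilibrium` partitions a conserved isomer pool,
Ru5P = total × Keq/(1+Keq); the alternative non-conserving reading
(Ru5P = Keq × initial R5P) is rejected because the assay's pentose pool is
closed.

## Henry's-law conversions

Dissolved CO₂ = 0.0338 M/bar × p. The default ambient pressure is
1013.25 mbar; 0.9 mM ↔ ≈ 26.6 mbar ≈ 3% of ambient, and 200 mbar ↔ ≈ 6.8 mM.
Total inorganic carbon speciation (bicarbonate) is not modelled; CO₂ is a
single dissolved species.

## Problem sizes and determinism

Default runs use the fixture network (~40 internal reactions; MILP with ~80
binaries solves in well under a second), 50 random oracle networks of 8–10
reactions, 200-replicate fit recoveries, and 1000-point Pareto checks —
sizes chosen so the whole analysis re-runs from scratch in a few minutes on
one CPU. Every stochastic component takes an explicit seed; LP/MILP solves
are deterministic, and pipeline outputs are byte-identical across runs for a
fixed config.

## Known limitations

* The fixture cannot exhibit the genome-scale two-pathway Pareto front or
  the 15-product yield panel; those require the real reconstruction.
* There is no single canonical choice of concentration bounds and
  cofactor-ratio constraints for genome-scale MDF analyses; the defaults
  here are explicit assumptions surfaced in configuration.
* Periplasmic reactions acting on cytosolic species are pruned by metabolite
  compartment; a pruning keyed on reaction annotation could differ.
* FBA is yield-only (no growth coupling, no flux variability analysis).
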