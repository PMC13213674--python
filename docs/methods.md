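# Methods

## Scope and model

`hydrogem` analyses dark-fermentation hydrogen metabolism with
constraint-based models. A model is a stoichiometric matrix **S** over two
compartments (cytosol `c`, extracellular `e`), flux bounds, GPR rules and an
objective; FBA solves `max cᵀv s.t. S·v = 0, lb ≤ v ≤ ub` through
COBRApy/optlang on GLPK. The flux-vector contract everywhere is on objective
values; whenever a unique vector is reported (knockout screens, FSEOF
trajectories) a parsimonious (minimum-total-flux) secondary objective is
applied so results do not depend on solver vertex choice.

## Biomass equation

The biomass pseudo-reaction drains precursor monomers R_i with coefficients
S_i (mmol gDW⁻¹) and releases byproducts B_j, producing 1 g of biomass X per
unit flux: `Σ S_i R_i → X + Σ S_j B_j` with the closure
`(Σ S_i M_i − Σ S_j M_j)/1000 = 1`.

Per polymer with mass fraction f and monomer mole fractions x_i,
`S_i = 1000 · f · x_i / Σ_k x_k (M_k − M_leaving)`: protein and glycogen
release one water per bond (bonds approximated as one per residue, the usual
lumped-biomass convention), DNA/RNA condensation releases pyrophosphate.
Lipid, cell wall, LPS, ions and the soluble pool enter as lumped
pseudo-species with nominal molar masses (700, 950, 1500, 55, 300 g mol⁻¹);
only the mass they carry matters for closure. All molecular weights are
derived from one element-mass table so that the GAM hydrolysis
(ATP + H₂O → ADP + Pi + H⁺) is exactly mass-neutral; it is therefore
appended after normalisation without disturbing the 1 g/gDW closure, and the
normalisation factor never rescales the maintenance terms.

Defaults: GAM 26.48 mmol ATP gDW⁻¹ inside the biomass reaction; NGAM as the
lower bound (0.81 mmol ATP gDW⁻¹ h⁻¹) of a standalone `ATPM` reaction. The
NGAM figure is treated as an hourly rate; sources that quote it without a
time unit are read the same way, since a maintenance flux is only meaningful
per unit time. DNA/RNA monomer ratios come from coding-sequence FASTA
counts; DNA pools both strands (A=T, G=C enforced), RNA uses the coding
strand with T→U. Measured protein/DNA/RNA/glycogen fractions are inputs; the
shipped example vector (protein 0.55, RNA 0.12, glycogen 0.06, DNA 0.031,
remainder split in iAF1260-like proportions) is a documented default, not a
measurement.

## Gap-filling

Producibility of each biomass precursor is probed with a temporary demand
reaction maximised against the open medium (positive above 10⁻⁶). Species
built on conserved moieties (acetyl-CoA, ATP, NAD(P)H, reduced ferredoxin)
can never show *net* synthesis at steady state, so their probes drain the
loaded form and return the free carrier (acetyl-CoA → CoA, ATP → ADP, …).

Filling is a penalised-flux relaxation: all candidates from a `U_`-namespaced
universal database join the model, total penalised candidate flux (per-
reaction penalty 1 by default) is minimised subject to biomass flux ≥ 0.05
h⁻¹, flux-carrying candidates are retained, and the retained set is greedily
pruned (drop any candidate whose removal keeps growth above threshold),
iterating until stable. Candidate reversibility follows standard Gibbs
energies: |ΔG°′| ≤ 30 kJ mol⁻¹ reversible, strongly exergonic forward-only,
strongly endergonic reverse-only, unknown reversible. Pre-existing model
content is never modified. The LP feasibility tolerance is GLPK's default
(10⁻⁹ scale); retention threshold 10⁻⁶.

## Enzyme constraint (ecGEM)

A single shared enzyme pool (sMOMENT-style, one constraint row) rather than
per-enzyme species: the model is split into irreversible directions
(`id_fwd`/`id_rev`, exchanges exempt, mapping retained in
`model.notes["reversible_split"]`), and each catalysed direction consumes
`MW/(k_cat·3600)` g·h·mmol⁻¹ of a pool pseudo-metabolite whose source
reaction is bounded by `p_tot · f · σ` (defaults p_tot = 0.56 g gDW⁻¹,
σ = 0.5; f is the expression-weight share of model genes). GPR cost rules:
an AND complex sums `subunits · MW` over members and turns over at the
slowest member's k_cat; OR isozymes take the cheapest branch (equivalent
optimum to reaction duplication, simpler bookkeeping); reactions without GPR
stay uncosted. k_cat calibration iteratively doubles the k_cat of the
reaction holding the largest pool share until predicted growth is within 5 %
of the measurement (at most 50 rounds), logging every adjustment.

## Strain design

Knockouts disable exactly the reactions whose GPR evaluates false under the
deletion, then solve lexicographically: maximise growth, fix it, maximise H₂
with the parsimonious tie-break. Default carbon conditions are 5 (low) and
20 (high) mmol glucose gDW⁻¹ h⁻¹.

FSEOF fixes the target exchange on a uniform grid from its value at the
growth optimum up to 90 % of its theoretical maximum (a degenerate
single-point scan when there is no headroom), re-maximises growth at each
level, and classifies each parsimonious trajectory: *amplify* if |v| is
non-decreasing with constant sign, *attenuate* if non-increasing and
strictly lower at the top than at the base, otherwise *mixed*; FVA at each
level (growth ≥ 99 % of the level optimum) brackets the trajectories. FSEOF
is run under constant cultivation conditions, i.e. with substrate uptake
fixed rather than merely capped — with a capped uptake a pool-limited
optimum simply consumes less substrate and the scan collapses onto the
ATP-pinned acetate state.

## The synthetic core network

The fixture emulates an ethanol–acetate-type fermenter: glycolysis, PFOR
(pyruvate + CoA + Fd_ox → acetyl-CoA + CO₂ + Fd_red, Fd carrying 2 e⁻) and
PFL + FHL routes at the pyruvate node, PTA–ACK (substrate-level ATP),
ALDH–ADH (2 NADH per ethanol), LDH, both a ferredoxin-dependent and an
NADH-dependent hydrogenase, and an anaplerotic PEP→OAA→citrate→AKG→
glutamate/glutamine branch (NADPH made by ICDH, consumed by GDH). Every
internal and transport reaction is elementally and charge balanced
(BiGG-style formulas and charges); only exchanges and the toy biomass are
exempt. Electron bookkeeping (degree of reduction γ = 4C + H − 2O − 3N +
5P − charge) fixes the yield anchors: glucose 24 e⁻, acetate 8, ethanol 12,
glutamate/glutamine 18, H₂ 2 — hence 4, 2 and 3 mol H₂ per mol glucose for
the acetate-only, ethanol-coupled and glutamate-diversion scenarios. Yield
scenarios are zero-growth fermentation states (the biomass drain is closed)
so the toy biomass cannot act as a hidden electron sink; `ATPM` stays
active.

Fixture choices, fixed once and documented rather than fitted:

* Toy biomass coefficients (g6p 0.3, pep 0.2, pyr 0.4, accoa 2.5, akg 1.2,
  nadph 1.2, atp 70 mmol gDW⁻¹) give an unconstrained μ_max ≈ 0.5 h⁻¹ at a
  glucose uptake of 10 — an arbitrary anchor, not a strain measurement. ATP
  dominates, so growth is energy-limited and acetate overflow is the
  growth-optimal strategy; the NADPH demand equals the AKG-coupled ICDH
  supply so the network is redox-feasible with or without the GAPN bypass.
* A non-phosphorylating GAPDH (GAPN, NADP⁺) plus transhydrogenase provide an
  ATP-free bypass of the PGK step. Deleting the PGK gene then removes two
  substrate-level ATP per glucose: growth falls and acetate overflow (with
  its co-produced H₂) rises — the energy-rebalancing knockout mechanism.
* The biomass reaction carries a `g_ribo` GPR so the enzyme-constrained
  variant charges growth itself against the pool through a 2000 kDa
  protein-synthesis lump at k_cat 1 s⁻¹. This is what makes the ecGEM
  growth optimum pool-limited (μ ≈ 0.23 h⁻¹ at uptake 10) with ATP demand
  below glycolytic supply, reproducing the regime in which ethanol is the
  cheap NADH sink at the growth optimum and enforced H₂ pulls NADH out of
  ethanol into the (slow, k_cat 1–5 s⁻¹) NADH-hydrogenase — acetate-branch
  amplification, ethanol-branch attenuation.
* Curated reference k_cats are physiological contrasts, not measurements:
  fast ferredoxin hydrogenase (80 s⁻¹), slow NADH-hydrogenase (5 s⁻¹, an
  uphill electron transfer), glycolytic enzymes 20–60 s⁻¹, 55 kDa monomers.
  The random generator draws k_cat log-normally (median 10 s⁻¹, one decade
  sigma), MW uniform 20–200 kDa, Dirichlet expression weights over model
  genes plus ten phantom genes (so f < 1).
* `degrade_model` samples from gene-bearing internal reactions that are
  individually growth-essential, so every degradation verifiably needs
  filling; decoy candidates are either dead-end conversions or redundant
  duplicates, so exact recovery is well-defined.
* Default analysis uptake 10 mmol gDW⁻¹ h⁻¹; knockout conditions 5/20.

## What the generators do and do not emulate

The synthetic tables reproduce the *structure* of real inputs — k_cat spread
over decades, expression-weighted enzyme fractions, composition vectors
summing to one, assay tables with a known label-noise rate — but not the
values of any real organism: the network has ~60 reactions, not ~1000; the
toy biomass is unphysiologically carbon-light and ATP-heavy; transporter
energetics are simplified to uniports. Passing tests therefore demonstrate
the correctness of the algorithms and the qualitative physiology of the
enzyme-constrained trade-offs, not quantitative predictions for any strain.
Genome-scale quantitative figures (e.g. absolute optimal-growth hydrogen
yields) require a released genome-scale model and its kinetic tables, which
are deliberately out of scope here.

## Numerical choices

GLPK; feasibility/optimality at solver defaults; producibility and flux-
retention thresholds 10⁻⁶; reported values rounded at 10⁻⁶. FSEOF
classification tolerance 10⁻⁶ absolute on trajectory differences. Envelope
grids include growth 0 and μ_max; infeasible grid points are recorded as
absent. All generators take integer seeds and are bit-reproducible.

## Problem sizes

The bundled analyses run on the ~60-reaction core network: the full test
suite solves a few thousand small LPs in well under a minute, and the
acceptance script solves two scenarios in seconds. These sizes were chosen
to keep every result exactly checkable against closed-form stoichiometry.

## Known limitations

Single shared pool (no per-enzyme abundance ceilings, no proteomics
integration); isozyme min-cost rule hides which isozyme is used; no
thermodynamic or kinetic rate laws beyond the ΔG°′ reversibility rule; the
knockout screen is single-gene only; calibration doubles k_cats greedily and
may adjust a non-causal reaction when several share the pool bottleneck.
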