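# Methods

## Scope and model philosophy

`methyloflux` analyses methanol-based production of malate, acetone and
isoprene in a methylotrophic yeast (an *Ogataea polymorpha*-type host) by
flux balance analysis (FBA) on a **curated core network** built
programmatically by `methyloflux.network.build_core_model`. The core
network is a desk-scale stand-in for a genome-scale reconstruction: it
contains every pathway the analysis depends on at correct net carbon,
redox and ATP stoichiometry, and nothing else. Absolute growth rates and
the acetone/isoprene optima therefore carry core-model-specific values;
the claims the package tests are the ones that depend only on pathway
structure (ceilings, orderings, scenario contrasts), plus the malate
ceiling, which is a pure carbon-balance statement.

## The core network (64 metabolites, 64 reactions)

Flux units are mmol/gDW/h throughout. Compartments: cytosol,
mitochondrion, peroxisome, extracellular.

* **Methanol oxidation** (peroxisome): alcohol oxidase
  (CH3OH + O2 → HCHO + H2O2) and catalase (H2O2 → H2O + ½O2). No energy is
  conserved in this step, as in methylotrophic yeast biochemistry.
* **XuMP assimilation**: dihydroxyacetone synthase
  (HCHO + Xu5P → DHA + GAP), DHA kinase (1 ATP), and a lumped
  pentose-phosphate rearrangement block
  2 DHAP + 3 GAP + 2 H2O → 3 Xu5P + 2 Pi. The lump conserves carbon
  (5 × C3 = 3 × C5) and phosphate and reproduces the canonical net XuMP
  stoichiometry 3 HCHO + 3 ATP → 1 triose-P. The full transketolase/
  transaldolase detail is irrelevant at net-stoichiometry level.
* **Dissimilation**: HCHO → formate → CO2, each step yielding one NADH.
* **Lower glycolysis** (lumped): GAP + NAD + 2 ADP + Pi →
  pyruvate + NADH + 2 ATP + H2O.
* **PDH bypass** (cytosol): pyruvate decarboxylase, NAD-dependent
  acetaldehyde dehydrogenase, acetyl-CoA synthetase at 2 ATP-equivalents.
  This is the standard yeast route to cytosolic acetyl-CoA and the reason
  the blocked-TCA scenario retains acetone/isoprene production: the
  scenario blocks PDH, citrate synthase, citrate export, ATP-citrate
  lyase and AKG dehydrogenase but not the bypass. The NAD isoform of the
  aldehyde dehydrogenase is used (Ald2/Ald3-like); NADPH is supplied on
  demand by a lumped irreversible NADH→NADPH converter standing in for
  the oxidative PPP/Ald6 contributions.
* **TCA cycle** (mitochondrion): PDH, citrate synthase, aconitase, NAD-IDH,
  a lumped AKG dehydrogenase + succinyl-CoA synthetase (substrate-level
  ATP retained), SDH (FAD), fumarase, MDH; citrate exporter to the
  cytosol; cytosolic ATP-citrate lyase.
* **Glyoxylate shunt** (cytosol): cytosolic aconitase, isocitrate lyase,
  malate synthase; succinate re-enters the mitochondrion.
* **Cytosolic rTCA malate route**: pyruvate carboxylase + cytosolic MDH,
  with a Mae1-style malate exporter. This is the engineered production
  route of the host strain.
* **Acetone pathway**: thiolase, acetoacetyl-CoA hydrolase (cofactor-free
  YbgC-style, the default) or the acetate-dependent CoA-transferase
  (CtfAB-style, `acetone_variant="coa_transferase"`), acetoacetate
  decarboxylase.
* **MVA pathway**: HMG-CoA synthase, HMG-CoA reductase (2 NADPH),
  a lumped mevalonate kinase/phosphomevalonate kinase/diphosphomevalonate
  decarboxylase step (3 ATP, 1 CO2 released), IPP isomerase, isoprene
  synthase, pyrophosphatase.
* **Respiration**: NADH and FADH2 oxidases at configurable P/O ratios
  (defaults 1.5 and 1.0), an irreversible malate–aspartate-shuttle lump
  moving cytosolic NADH into the mitochondrial pool, and an ATP
  maintenance reaction (default lower bound 0; no maintenance value is
  imposed).
* **Biomass**: a lumped draw of 1 GAP + 1 pyruvate + 1 acetyl-CoA +
  1 OAA + 30 ATP + 4 NADPH per unit biomass (formula C12H22O11; the
  GAP-derived phosphate is returned as Pi because the model deliberately
  has no phosphate exchange). The composition is synthetic: absolute
  growth rates are model-specific, and only envelope *shape* claims are
  made.

Two deliberate boundary choices matter for the results. First, **CO2
exchange is efflux-only**: methanol is the sole carbon source, so the
0.25 mol/mol malate ceiling is a carbon ceiling (with free CO2 uptake the
carboxylation route would reach 1/3 mol/mol). Second, CO2, O2, H2O and
the adenylate/phosphate pool are kept in one cytosolic pool shared by
mitochondrial reactions; only carbon skeletons and NAD(H)/FAD(H2) are
compartmentalised. This lumping leaves all carbon and redox accounting
intact while keeping the exchange surface minimal.

### Elemental bookkeeping

Every metabolite carries a neutral C/H/O/N/P/S formula; reduced cofactors
carry their hydrogens explicitly (NADH = NAD·H2, NADPH = NADP·H2,
FADH2 = FAD·H2, ATP + H2O → ADP + Pi exactly). Under this convention every
non-exchange reaction balances to zero in all six elements with no free
protons, which `validate_mass_balance` asserts for the whole network.

## FBA, FVA, envelopes

LPs are solved with HiGHS (`scipy.optimize.linprog`): max/min c·v subject
to S·v = 0 and bounds. Tolerances: bound feasibility 1e-9, steady-state
residual 1e-6, yield comparisons 1e-4. FBA optima are degenerate in the
flux vector, so every optimal solve is followed by a second LP minimizing
total absolute flux at the (inequality-pinned, 1e-9-slack) optimal
objective — parsimonious FBA. This makes the flux vectors entering the
PCA deterministic and is a reproducibility choice of this package; yields
are unaffected. Flux variability is two LP solves per reaction, with
optional objective fixing. Production envelopes fix biomass at each of
`n_points` (default 21) fractions of μmax and maximize the product
exchange; the f = 0 point equals the zero-growth maximum and the f = 1
point is 0 by construction of a growth-optimal flux state.

Molar yield is product efflux divided by |methanol uptake| (both in
mmol/gDW/h), with the COBRA sign convention (negative exchange flux =
uptake). The reference uptake is 10 mmol/gDW/h.

## Scenarios and calibration

The five scenarios (Ref, TCA-, TCA+, GlxStd, GlxVar) are bound-edit
recipes on top of a shared setup (uptake −10, objective = product
exchange); definitions live in `data/scenarios.yaml`. Scenario aliases
(PDHa1, PDHcm, ACLSm, AKGDH1+2, CITtam, CITtap, CSp+m, AKGDam, ICL, MDHm)
resolve through a documented alias map; isozyme/compartment duplicates
merge onto the single core reaction.

Forced bounds are **calibrated on the model**: the extreme feasible flux
of the target reaction is found by FVA without objective fixing and
backed off by a relative slack of 1e-6 so the forced model stays
feasible. Calibration is sequential over a scenario's edit list, so the
variant glyoxylate scenario calibrates its MDH restriction (minimum
feasible flux, used as the upper bound, lower bound −uptake) on the
already-ICL-forced model. Published full-model calibrations (7.8 for the
AKG dehydrogenase, 10 for isocitrate lyase, −10/2.85 for mitochondrial
MDH) are vertices of that reconstruction, not of this one; they are kept
as reference metadata only. Infeasible grid cells would be reported as
status `infeasible` with yield 0 and a warning; with the shipped slack
all 15 cells are feasible, and the forced-TCA optima are zero to within
the slack (≤ 1e-5 mol/mol).

## PCA and clustering

The 15 parsimonious flux vectors are assembled into a 15 × 64 matrix
(zero-fill for absent reactions, sorted columns). PCA is an SVD of the
column-centered matrix — centering without unit-variance scaling is the
default because all entries share units; scaling is available by flag and
drops zero-variance columns first. The sign convention (largest-magnitude
loading of each component positive) makes the decomposition
deterministic; tests compare against independent eigendecomposition and
scikit-learn oracles up to sign.

Cluster structure is diagnosed by single-linkage clustering on Euclidean
distances in score space, cut at the largest gap between successive merge
heights. Three qualitative flux modes are expected: {Ref, TCA-}, {TCA+},
{GlxStd, GlxVar}. On the core model the cut yields **two** clusters:
{TCA+} is sharply separated (forced-cycle fluxes dominate PC1, 84.6 % of
variance), while the reference-like and glyoxylate modes chain together —
the isoprene Ref→TCA- route switch (PDH/citrate-lyase route to PDH
bypass) is as large a flux rearrangement as Ref→GlxStd, so no gap
separates those modes here. `qualitative_cluster_verdict` treats such a
whole-mode merge as a warned outcome rather than a failure; the
well-defined proximity facts (Ref closest to TCA- per product, the two
glyoxylate variants coinciding, TCA+ isolated) hold and are asserted.

## Fermentation arithmetic

Conversions use methanol density 792 g/L (consistent with the
0.5 % v/v ↔ 4 g/L and 1 % ↔ 8 g/L display equivalences) and the usual
molar masses (methanol 32.04, L-malate 134.09, acetone 58.08, isoprene
68.12, succinate 118.09 g/mol). Display rounding (half-up; integers for
percentages, one decimal for g/L/d) is separated from raw values, which
are never rounded internally. The evaporation correction converts daily
flask weight loss to volume loss via an assumed medium density of
1000 g/L (configurable) and rescales each measured titer/OD by the
current-to-initial volume ratio; the correction rule itself is a choice
of this package — the per-timepoint multiplicative form is the simplest
rule consistent with weighing-based evaporation tracking.

## What the core model does and does not show

Reproduced quantitatively: the zero-growth malate ceiling
0.25 mol/mol and its invariance under TCA blockage; zero yields under
maximal forced TCA flux; all cultivation arithmetic. Reproduced
qualitatively: yield drops under glyoxylate forcing, envelope
monotonicity with malate steepest (0.617 vs 0.411 vs 0.247 mol/mol per
1/h), the TCA+ flux-mode isolation. **Not** reproduced: absolute
acetone/isoprene optima of a genome-scale reconstruction (core model:
1/6 and 1/10 mol/mol; a full reconstruction has more recapture routes),
absolute growth rates, and the small nonzero glyoxylate-forced yields of
the full model (the core model's forced-glyoxylate malate optimum is
1/6 mol/mol because the forced shunt itself exports malate). Structural
notes established during development: internal CO2 (from PDC/PDH/TCA) is
refixable by pyruvate carboxylase, so deleting the dissimilatory branch
does *not* lower the malate ceiling; removing pyruvate carboxylase caps
malate at 1/6 mol/mol.

## Problem sizes

The whole analysis is a few hundred LPs of ~64 variables; the complete
test suite and all analysis drivers run in seconds on one CPU. Envelope
resolution (21 points) and the PCA matrix (15 × 64) follow the study
design directly.
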