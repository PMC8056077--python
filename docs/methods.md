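# Methods

## Scope and model structure

`seedflux` couples two layers over the 0–21 DAF (days after fertilization)
span of *Arabidopsis* embryo development, integrated in hours internally.

**Transcript → enzyme.**  Relative mRNA profiles (scaled to 1 at the
zygote stage) drive one linear ODE per enzyme,
dE/dt = k_syn·mRNA(t)·Rb(t) − (k_deg + μ(t))·E.  Degradation constants are
grouped into three classes (fast 0.03, average 0.02, slow 0.01 hr⁻¹;
k_deg = ln2/t½), and k_syn = k_deg + μ₀ with μ₀ = 0.025 hr⁻¹ so that
production and removal balance at the start of development.  Enzymes
without a literature turnover annotation default to the average class.
Because the equilibrium gain is k_syn/(k_deg + μ(t)), enzyme levels are
*not* proportional to transcript levels once growth slows — slow-turnover
enzymes end development up to ~2–3-fold above their transcript-implied
level, which is the intended behavior of the formulation.

Stage profiles are interpolated with shape-preserving monotone cubics
(PCHIP; never overshoots below zero; linear interpolation available), with
constant extrapolation beyond the last stage.  The stage → DAF mapping is
not part of the source data and defaults to zygote 0, octant 1, globular 2,
heart 4, torpedo 6, bent 10, mature 18 DAF (user-overridable).

**Metabolism.**  34 metabolites (two of them clamped maternal-supply pools:
apoplastic sucrose and alanine) and 40 reactions.  Mass balances are
dM/dt = S·v − μ·M; the dilution term applies to intracellular pools but not
to the three cofactor pairs (ATP/ADP, NAD(H), NADP(H)), which are treated
as homeostatically maintained conserved moieties — every reaction that
consumes one form produces the partner, so pair totals are exactly
conserved.  Compartment volumes are assumed equal; transport fluxes carry
no volume corrections.

Kinetics follow v = E·k·f(M,p): irreversible Michaelis–Menten with
Hill-type feedback inhibition (default Hill coefficient 2 for the acyl-ACP
feedbacks, 1 for product-inhibition terms), reversible Michaelis–Menten
(sucrose synthase, GDH, AAT) in a symmetric Haldane-like form
v = E·k·(Γ_f − Γ_r/K_eq)/(1 + Γ_f + Γ_r), an mRNA-proportional law for
storage-protein synthesis, and a mixed growth/non-growth ATP maintenance
α·μ + β guarded by an ATP saturation term.

## Key mechanistic choices

* **Fatty-acid synthesis** is malonyl-ACP-limited: ACCase produces
  malonyl-ACP and the synthase condenses 8 malonyl units per lumped C16
  chain, with reductant demand split 7 NADPH + 7 NADH (ketoacyl reduction
  NADPH-dependent, enoyl reduction NADH-dependent).  Both ACCase and the
  synthase are feedback-inhibited by the short-chain acyl-ACP pool (SCFA),
  which is the mechanism that makes overexpressing them nearly futile while
  downstream "pull" interventions (acyl export, elongation, TAG assembly)
  can raise FA content.
* **Product inhibition** on the plastid import/commitment chain (PEP and
  pyruvate transporters, plastidial pyruvate kinase and PDH, mitochondrial
  PDH, Rubisco-bypass, citrate export, acyl export).  With purely
  irreversible kinetics a chain is supply-driven and downstream demand
  cannot propagate upstream; the product-inhibition terms let intermediate
  pools transmit back-pressure, which is required for any overexpression
  intervention downstream of the committed step to have a positive effect.
* **TAG assembly** consumes three free-FA chains and a triose-derived
  backbone; the elongated (20–22C) acyl pool gates the assembly rate as a
  saturable kinetic factor rather than a consumed substrate.  The pool is
  interpreted as "elongated FA destined for TAG" and counts toward total
  FA.  Total FA = free FA + acyl-ACP + elongated FA + 3 × TAG (glycerol
  backbone excluded); chain lengths are lumped (16–22C, no isomers).
* **Carbon routing**: glycolytic mode only (no gluconeogenesis).  The
  oxidative PPP carries the NADPH load; the non-oxidative return (EPI, with
  3 R5P → 5 triose-P stoichiometry) is a minor shunt, and Rubisco operates
  as the main R5P consumer, refixing CO2 into plastidial PEP.  Classical
  regulatory feedbacks stabilize the system: glucose-6-P inhibition of
  hexokinase, PEP inhibition of PFK, NADPH inhibition of G6PDH.
* **Growth** is logistic.  The curve is parameterized by the early
  (0.025 hr⁻¹) and mature (0.0025 hr⁻¹) specific growth rates and by the
  time the mature rate is reached (13 DAF, matching the observed dry-mass
  plateau); the logistic rate and initial mass fraction are solved from
  these constraints exactly.

## Parameters

~120 parameters: affinity constants (K_m, K_i) carry literature-plausible
defaults in model-relative concentration units (pools are O(0.1–1));
cofactor affinities are shared per cofactor class.  Rate constants of the
irreversible reactions are not free-floating: they are solved at build time
from a documented mid-filling reference flux map (`REFERENCE_FLUXES`,
units hr⁻¹ in model concentration) evaluated at a reference state, in the
spirit of anchoring a kinetic model to flux-analysis estimates.  Reversible
rates, equilibrium constants, maintenance (α = 15, β = 0.2) and feedback
constants were calibrated (the "rough tuning" step) against the study's
physiological read-outs: maximal FA accumulation inside 7–14 DAF, a stable
FA pool over 16–19 DAF, FA turnover ≈ 0.06 d⁻¹ at maturity, a
hexose/sucrose peak at 7–10 DAF, plastid-dominated pyruvate-kinase flux and
a rising ATP/ADP ratio toward maturity — and against the published
single-gene perturbation outcomes.  Every parameter records bounds and a
provenance tag (literature / fitted / default), and the full model
round-trips through YAML.

## Synthetic study conditions

The generator emulates the structure of the study's inputs, not their
values: per-enzyme stage profiles drawn from five shape classes (flat,
early-transient, mid-window peak for the oil program active ~7–14 DAF,
late-up, late-down), 1–3 genes per enzyme with log-normal basal intensities
and multiplicative gene noise, a ~200-gene ribosomal block with ~150 genes
above the 2000-intensity expression threshold, and metabolite
pseudo-observations with 4 biological replicates under multiplicative
log-normal noise (default CV 0.15; the source reports no error model, so
this is the metabolomics-typical choice).  The canonical *noise-free*
templates define the reference (wild-type) expression program; all
stochastic generation takes explicit seeds.

What passing tests on these conditions do **not** show: agreement with any
particular real microarray atlas, absolute concentrations or fluxes (units
are model-relative), isomer- or chain-length-resolved lipid composition, or
transcript/protein discordance caused by post-translational regulation
(explicitly out of scope).

## Numerics

LSODA with rtol 1e-6 / atol 1e-9 and a 0.1-DAF output grid for the
reference simulation; the 400-run dose-response scan uses rtol 1e-5 /
atol 1e-8 (identical for wild-type and perturbed runs; 20-DAF read-outs
shift by <0.01%).  Negative state excursions beyond 1e-6 abort with the
offending metabolite named; smaller excursions are clamped to zero inside
the rate laws.  Ratios use a 1e-9 denominator floor.  Halving tolerances
changes total FA at 20 DAF by <0.1%, and cofactor-pair totals drift by
<1e-10 over the full run (conservation is structural).  The enzyme layer is
integrated once as a diagonal linear system and interpolated into the
metabolic right-hand side.

Calibration minimizes weighted squared residuals of log10(observable +
1e-6) — observables span orders of magnitude across development — with
bounded trust-region least squares from Latin-hypercube multi-starts
(default 20, seeded, optimizing log-parameters).  Identifiability profiles
re-optimize the remaining parameters along a parameter grid; a profile
whose relative objective span stays below 5% flags the parameter
non-identifiable.  The full model is deliberately under-determined; the
recovery and identifiability tests therefore run on the reduced fixture
network (8 metabolites, 10 reactions, one feedback), where ground truth is
known.

The "FA plateau" metric is the net relative change |ln FA(19)/FA(16)|/3 d:
synthesis, oxidation and dilution all remain individually active in the
window, and stability refers to the pool, not to the terms.

## Perturbation analysis

Knockout multiplies a target's transcript profile by 0.01 (a floor rather
than exact zero avoids structural singularities), knockdown divides and
overexpression multiplies by the fold factor, constitutively from t = 0.
Reactions without gene input (maintenance, oxidative phosphorylation) scale
their rate constant instead.  The published-comparison table uses ×10
overexpression unless the experiment states otherwise (plastidial ACCase:
×15 for the reported 10–20-fold line; PDH-kinase loss: ×2.5 PDH activity),
and the two heart-stage rows (epimerase, cytosolic ACCase) are read out as
TAG at 4 DAF to match the corresponding mutant measurements; all other rows
are total FA at 20 DAF.  A dose-response profile is "asymmetric" when its
overexpression arm never gains more than +5% FA while its knockdown arm
loses more than 10% — an operationalization of "moderate or no increase vs
significant decrease"; both thresholds are configurable.

## Known limitations

* The exact published stoichiometry and parameter values live in
  supplementary tables that are not part of the source text; the
  reconstruction here encodes the described topology with its own
  calibration.  Signed directions of the published perturbation predictions
  are reproduced for 10 of 12 interventions; magnitudes agree within a few
  percentage points for about half of the rows, and summary statistics that
  depend on the full parameterization (mean knockout effect, asymmetric
  profile count) deviate more strongly — the model's supply chain is less
  redundant than the published one.
* Two sign disagreements are structural: mitochondrial pyruvate uptake is
  lumped into mitochondrial PDH, so raising PDH activity steals cytosolic
  pyruvate from the plastid transporter; and no PPP wiring consistent with
  the main text makes an epimerase knockout strongly *increase* heart-stage
  TAG.
* Cofactors are single whole-cell pools; compartment-resolved redox states
  are not represented.  Concentrations and fluxes are model-relative,
  suitable for ratios and percent changes, not absolute quantification.
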