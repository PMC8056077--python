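# seedflux

A dynamic, gene-expression-coupled kinetic model of carbon and energy
metabolism in the developing *Arabidopsis thaliana* embryo, built to ask a
genetic-engineering question: **which single genes control seed fatty-acid
(FA) content, and by how much?**

Seed oil accumulates during a narrow developmental window while the
expression of the underlying enzymes changes by an order of magnitude, so
steady-state flux methods cannot attribute control to genes.  `seedflux`
couples a transcript-to-enzyme layer to a compartmented kinetic network and
simulates the whole of seed development (0–21 days after fertilization,
DAF), then performs systematic in-silico knockout/overexpression scans of
every reaction.

## The model

**Expression layer.**  For each enzyme *i*, stage-resolved microarray
intensities are summed over the encoding genes and scaled to 1 at the first
stage (mRNAᵢ(t)); a weighted ribosomal-gene signal Rb(t) tracks translation
capacity.  Enzyme levels follow

```
dEᵢ/dt = k_syn,i · mRNAᵢ(t) · Rb(t) − (k_deg,i + μ(t)) · Eᵢ
```

with three turnover classes (k_deg = 0.03/0.02/0.01 hr⁻¹) and synthesis
balanced against removal at the early growth rate (k_syn = k_deg + μ₀,
μ₀ = 0.025 hr⁻¹, giving 0.055/0.045/0.035 hr⁻¹).

**Metabolic layer.**  34 metabolites and 40 reactions across cytosol,
plastid and mitochondrion: sucrose unloading and hexose uptake, a lumped
glycolysis (with an NADPH-producing non-phosphorylating bypass), the
oxidative pentose-phosphate pathway with an epimerase return route and a
carbon-conserving Rubisco bypass into the plastid, plastidial FA synthesis
under acyl-ACP (SCFA) feedback inhibition of ACCase and FA synthase, FA
elongation and TAG assembly/oxidation, a TCA cycle with anaplerotic
exchanges (PEPC, malic enzyme, GDH, AAT, ATP-citrate lyase), storage
products (starch, sucrose, storage protein) and maintenance (proton leak,
oxidative stress, growth/non-growth ATP cost).  Mass balances are

```
dM/dt = S·v(M, E(t)) − μ(t)·M          vᵢ = Eᵢ · kᵢ · f(M, p)
```

with Michaelis–Menten saturation, Hill feedback inhibition and reversible
Michaelis–Menten kinetics; seed growth is logistic and cofactor pairs
(ATP/ADP, NAD(H), NADP(H)) are conserved moieties.

**Perturbation layer.**  A perturbation multiplies a target's transcript
input at every stage (knockout = ×0.01 floor, overexpression = ×10 by
default, plus 1.5/2.5/5/10-fold scans in both directions) and reports the
percent change of total FA at 20 DAF and of the target's flux over
10–20 DAF.

## Worked example

```python
import seedflux as sf

model = sf.build_default_model()          # 34 metabolites, 40 reactions
expr  = sf.reference_expression(model)    # canonical 7-stage program
traj  = sf.simulate(model, expr)          # stiff ODE solve over 0-21 DAF

print(round(sf.fa_accumulation_peak_daf(traj), 1))   # 13.1
print(round(sf.fa_turnover(traj), 3))                # 0.068
print(round(sf.physiological_ratios(traj).hex_suc_peak_daf, 1))  # 7.7

res = sf.fa_response(
    model, expr, sf.PerturbationSpec(("PKp",), "knockout"), wt_traj=traj
)
print(round(res.delta_fa_pct, 1))                    # -95.2
```

The numbers mean: the maximal FA accumulation rate falls at 13.1 DAF
(inside the 7–14 DAF window in which the FA-synthesis, elongation and TAG
genes are expressed); the mature-stage FA turnover rate is ≈0.07 d⁻¹; the
hexose/sucrose ratio peaks at 7.7 DAF; and knocking out plastidial pyruvate
kinase abolishes FA accumulation (−95.2%), the model's sharpest single-gene
effect alongside the sugar-supply steps.

The same pipeline is scriptable from the shell:

```bash
seedflux simulate --out runs/wt
seedflux perturb --target PKp --mode ko --out runs/pkp
seedflux scan --folds 1.5,2.5,5,10 --out runs/scan
seedflux synth --seed 1 --out runs/synthetic
seedflux report --out runs/full
```

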