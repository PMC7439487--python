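# lipidflux

Kinetic modelling and flux-correlation analysis of *Escherichia coli*
membrane lipid synthesis.

Growing *E. coli* must match phospholipid (PL) and lipopolysaccharide (LPS)
production to its growth rate µ, yet the concentrations of the pathway
enzymes barely change across conditions. `lipidflux` is built for systems
biologists studying this problem. It couples

* a reduced kinetic ODE model of the saturated fatty-acid, PL and LPS
  pathways — irreversible Michaelis–Menten reactions with end-product
  feedback of the long-chain acyl-ACPs (C16:0, C18:0) on acetyl-CoA
  carboxylase (ACC) and posttranslational ppGpp inhibition of the
  acyltransferase PlsB, over a conserved ACP pool — with
* the steady-state analyses that locate the pathway's control point:
  Vmax scans, metabolic control analysis (flux control coefficients
  C^J = ∂ln J/∂ln Vmax, with ΣC^J = 1), predicted concentration-vs-flux
  trends, perturbation time courses, and Pearson correlation of LC/MS-style
  condition tables against the operational PL flux (total-PE signal × µ),
  with two-tailed significance from t = r√(n−2)/√(1−r²).

A seeded synthetic-data generator emulates a 6-condition steady-state
growth series (3-fold µ range, 2 biological × 3 sampling replicates,
lognormal noise) with planted ground truth, so the correlation pipeline is
testable end-to-end without any measured data.

The model's central result: with strong acyl-ACP feedback on ACC and an
unsaturated PlsB, pathway flux scales as √(V_ACC·V_PlsB) — a 4-fold change
of either Vmax moves PE and LPS flux 2-fold in parallel, no other enzyme
carries appreciable flux control, and PlsB- versus ACC-driven flux changes
are distinguishable by the *sign* of the long-chain acyl-ACP trends.

## Worked example

```python
import lipidflux as lf

model = lf.default_model()

scan = model.scan("PLSB", [1.0, 4.0])
print(f"PE flux ratio:  {scan.pe_flux[1] / scan.pe_flux[0]:.3f}")
print(f"LPS flux ratio: {scan.lps_flux[1] / scan.lps_flux[0]:.3f}")

cc = model.control_coefficients()
lumped = cc.lumped("pe")
print(f"C_PE(ACC)  = {lumped['ACC']:.3f}")
print(f"C_PE(PlsB) = {lumped['PLSB']:.3f}   sum = {cc.pe_sum:.4f}")

table, truth = lf.generate_steady_state_dataset(lf.SyntheticSpec(seed=3))
fit = lf.FluxCorrelation.from_dataframe(table).fit()
print(fit.summary())
```

prints

```
PE flux ratio:  1.988
LPS flux ratio: 1.988
C_PE(ACC)  = 0.478
C_PE(PlsB) = 0.515   sum = 1.0000
Pearson correlation with PL flux (two-tailed significance)
analyte             n        r          P  excluded
holo_acp           12   -0.299      0.346  -
malonyl_acp        12    0.913   3.42e-05  -
c14_oh_acp         12    0.942   4.83e-06  -
c14_acp            12    0.345      0.272  -
c16_acp            12   -0.854   0.000411  -
c18_acp            12   -0.949   2.58e-06  -
lpa                12    0.957   1.11e-06  -
pa                 12    0.945   3.76e-06  -
cdp_dag            12    0.947   3.13e-06  -
ps                 12    0.931   1.06e-05  -
```

Quadrupling PlsB Vmax doubles both output fluxes (the √-law); ACC and PlsB
split the PE-flux control between them and the coefficients sum to 1
(summation theorem). In the synthetic growth series the fatty-acid
precursors malonyl-ACP and C14:0-OH-ACP and all PL intermediates correlate
positively with PL flux while the PlsB substrates C16:0-/C18:0-ACP
correlate negatively — the signature of PlsB-level (demand-side) control
rather than supply-side control, which would drag the long-chain pools up
with the flux.

The same analyses are available from a shell:

```sh
lipidflux scan --target PLSB --factors 0.25,0.5,1,2,4
lipidflux control
lipidflux dynamics --event "t=0:ppgpp=100" --t-end 60 --dt 0.5
lipidflux synth --seed 1 && lipidflux correlate --data lipidflux_out/synthetic_conditions.tsv
```

Each command writes a TSV of result rows and a JSON summary with a
provenance record (package version, seed, config hash).

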