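# Methods

## The model

`lipidflux` implements a deliberately reduced kinetic model of *E. coli*
membrane lipid synthesis, built to answer one question: which enzyme's
activity sets total phospholipid (PL) synthesis flux during steady-state
growth, and how is that flux naturally coupled to lipopolysaccharide (LPS)
synthesis?

Ten dynamic species are tracked (µM): the six ACP-carrying species — holo-ACP,
malonyl-ACP, C14:0-OH-ACP (3-hydroxy-myristoyl-ACP, the LPS branch point),
C14:0-ACP, C16:0-ACP, C18:0-ACP — and the PL intermediates LPA, PA, CDP-DAG
and PS. Twelve irreversible reactions connect them (several lumping
multi-enzyme steps):

| reaction | chemistry | rate law |
|---|---|---|
| ACC | acetyl-CoA + holo-ACP → malonyl-ACP | two-substrate MM, competitive inhibition by C16:0-/C18:0-ACP on the acetyl-CoA site |
| ELONG_C14OH | malonyl-ACP → C14:0-OH-ACP | MM (lumped early elongation cycles) |
| FABZ | C14:0-OH-ACP → C14:0-ACP | MM (lumped FabZ/FabI) |
| LPXC | C14:0-OH-ACP → LPS sink + holo-ACP | MM (lumped LpxA/LpxC) |
| ELONG_C16 / C18 | acyl-ACP + malonyl-ACP → longer acyl-ACP + holo-ACP | two-substrate MM |
| PLSB_C16 / C18 | acyl-ACP + G3P → LPA + holo-ACP | two-substrate MM × 1/(1 + ppGpp/Ki) |
| PLSC → CDSA → PSSA → PSD | LPA → PA → CDP-DAG → PS → PE sink | MM (PlsC uses fixed C16:1-ACP as acyl donor) |

Acetyl-CoA, G3P, C16:1-ACP and ppGpp are fixed boundary concentrations. PE
flux (the PL output) is the Psd rate; LPS flux is the LpxC rate. The six
ACP species form a closed pool: every reaction that removes an acyl chain
returns holo-ACP, so the column sums of the stoichiometry restricted to
ACP carriers vanish and total ACP is conserved exactly — a structural
invariant the test suite checks to relative 1e-6 along every trajectory.
PlsC's consumption of C16:1-ACP (and its holo-ACP release) is treated as a
boundary exchange so the dynamic pool stays closed. The PE/PG branch,
cardiolipin, cyclopropyl lipids, reversible kinetics and enzyme
synthesis/turnover are out of scope.

Modelling choices that the underlying biology leaves open: the competitive
feedback acts on the first substrate's Km (the standard competitive form);
C18:0-ACP is given a PlsB channel as its sink (otherwise it accumulates
without bound); both PlsB channels share one Vmax scale, so "PlsB Vmax"
scans move both; direct ppGpp inhibition of PlsB is a modelling choice —
the inhibition could equally be indirect via an unknown regulator, which
steady-state behaviour cannot distinguish.

## Default parameters

Units are µM and min⁻¹. The default parameter set is constructed
steady-state-first (see `scripts/calibrate_defaults.py`, which rebuilds and
verifies it): a self-consistent baseline operating point is designed (PE
flux 2 µM/min, LPS flux 0.5 µM/min, holo-ACP 60 µM of a 69.5 µM ACP pool,
intermediates 1–2.5 µM), Km values are set of the order of the baseline
concentrations, and each Vmax is derived as flux/saturation so the designed
point is an exact fixed point. Three regime choices fix the control
structure rather than any numeric fit:

* strong end-product feedback (Ki = 0.1 µM for C16:0-/C18:0-ACP on ACC, far
  below their ~1–2 µM baseline), making the ACC rate ≈ inversely
  proportional to the long-chain pool;
* PlsB unsaturated in acyl-ACP (Km = 50 µM), making PlsB flux ≈ proportional
  to that pool;
* every other enzyme at ≤ ~20% saturation, with headroom to pass a 2-fold
  flux change without becoming controlling.

Balancing supply against demand, V_acc/x ≈ V_plsb·x for long-chain pool x,
gives pathway flux ≈ √(V_acc·V_plsb): a 4-fold Vmax change of either enzyme
moves PE flux ≈2-fold, ACC and PlsB carry flux control coefficients near
0.5 each, and the downstream PL enzymes carry none. ppGpp's Ki on PlsB is
10 µM; dynamic ppGpp inputs are naturally expressed in multiples of it
(steady-state analyses use ppGpp = 0).

## Steady states, scans and control analysis

Steady states are found by a root solve on the derivative map with the ACP
conservation law substituted for the holo-ACP balance (Powell hybrid,
warm-started along scans), falling back to stiff integration (LSODA) to
quiescence followed by refinement when the warm start is poor. Convergence
means max|dx/dt| ≤ 1e-9 µM·min⁻¹ within a 1e6 min horizon; failures return
a flagged result rather than raising. The two routes — plain long
integration and root refinement — are compared to relative 1e-6 on the
default and 20 randomly perturbed parameter sets in the test suite.

Flux control coefficients C^J = d ln J/d ln Vmax use centred finite
differences with a 1% log-space step; because every rate law is homogeneous
of degree 1 in its Vmax, the summation theorem ΣC^J = 1 holds to 1e-3 and
serves as an internal consistency check. Trend curves report each species'
log2 concentration against log2 PE flux over a 16-fold driver grid
(9 points, 0.25–4), with the least-squares slope's sign as the trend sign
(dead-band 1e-6 for flat species such as C14:0-ACP). The robustness
analysis rescales every kinetic parameter independently by a log-uniform
factor within a 4-fold span (seeded, reproducible) and reports the fraction
of converged samples preserving each baseline trend sign under the PlsB
driver; with 100 samples the negative C16:0-/C18:0-ACP trends persist in
≈98–100% of samples.

## Perturbation dynamics

Time courses integrate piecewise between boundary-input step events with
exact restarts; depletion times are interpolated linearly between grid
points (default threshold: half of the pre-event baseline). A saturating
ppGpp step reproduces the expected cascade — long-chain acyl-ACP
accumulation, feedback depletion of malonyl-ACP, PE-flux collapse, and PL
intermediates draining in pathway order LPA → PA → CDP-DAG → PS. Known
limitation: the experimentally observed *late rise* of holo-ACP after
strong PlsB inhibition is not reproduced, because in this reduced network
C18:0-ACP is a terminal reservoir when PlsB is blocked and slowly absorbs
the pool; a C18-consuming escape reaction would be needed to release it.

## Flux-correlation analysis

PL flux is defined operationally as the internal-standard-corrected,
per-OD total-PE signal multiplied by µ. Analyte signals are IS-corrected,
expressed per OD (soluble species, enzymes) or per total-PE signal
(membrane-bound PL intermediates), averaged within pooling groups, log2
transformed and centred by subtracting the mean log value (so each series
has mean exactly 0; equivalently, normalisation to the geometric mean).
Replicate pooling is a switch: average sampling replicates and keep
biological replicates as points (default, n = conditions × biological
replicates = 12), collapse to condition means (n = 6), or keep every
sampling replicate (n = 18 per series). Per-analyte condition exclusions
(e.g. G3P in glycerol medium, where catabolism inflates G3P 20-fold without
changing flux) are applied before centring, to both the analyte and the
flux series.

Significance is the two-tailed p-value of t = r√(n−2)/√(1−r²) with n−2
degrees of freedom — implemented from the formula and cross-checked in
tests against `scipy.stats.pearsonr` and against a 10,000-draw permutation
null (agreement within 0.01 at n = 12). p-values are reported raw, without
multiple-testing correction, matching the convention of small targeted
panels.

## Synthetic data

The generator emulates the steady-state study design: 6 conditions spanning
a 3-fold µ range (0.33–1.0 h⁻¹, log-spaced), 2 biological replicate series
× 3 sampling replicates. µ maps to a PlsB Vmax factor log-linearly spanning
4-fold, so the model's PE flux spans ≈2-fold across the series — the
empirical flux–growth relationship — and total-PE-per-OD declines mildly
with µ as a consequence. Model steady-state concentrations become true
analyte levels; counts are true level × per-analyte response factor
(log-uniform, recorded) × OD (uniform 0.25–0.55) × lognormal measurement
noise (CV 0.1) × a lognormal biological-series factor (CV 0.05);
membrane-bound analytes scale with the sampled membrane amount (the row's
total-PE signal) instead of OD. Internal-standard counts are constant, so
the IS step is an exact pass-through; real IS variation would add noise the
ratio removes by design. Optional "null" analytes with flat true levels
provide flux-independent controls for false-positive-rate calibration.

`PlantedTruth` records two correlations per analyte. The *noiseless* r of
the 6-condition series is ≈±1 for any monotone species regardless of
amplitude and is therefore uninformative about detectability. The
*planted* r is the population correlation the generative process implies:
the noiseless r attenuated by the known log-scale noise variances of the
analyte and flux series (closed form, computed before any data are drawn).
Holo-ACP illustrates the difference: its trend is genuinely negative but
its log2 amplitude (~0.15) sits below the noise floor, so its noiseless r
is −0.91 while its planted r is ≈−0.14 and its sign is recovered in only
~70% of datasets — an inherent property of the design, not a pipeline
defect. Every analyte with planted |r| ≥ 0.7 has its sign recovered in
≈100% of 100 seeded datasets, and the null-analyte rejection rate at the 5%
level is ≈5% over 1000 datasets.

What passing these tests does and does not show: the generator draws from
the same model family the pipeline assumes (multiplicative lognormal noise,
no missingness, no drift, no chromatographic artifacts, perfectly known
replicate structure), so recovery here demonstrates the pipeline's
correctness, not its robustness to the failure modes of real LC/MS data.

## Problem sizes and determinism

Analyses run at desk scale by design: steady-state solves take milliseconds,
scans use 2–9 points, control analysis 24 perturbed solves, robustness 100
parameter samples × 3-point trend scans, recovery 100 datasets, and
false-positive calibration 1000 single-analyte datasets. All stochastic
components (robustness sampling, synthetic noise, dataset seeds) derive
from explicit seeds; fixed seeds give bit-identical outputs, which the test
suite asserts.
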