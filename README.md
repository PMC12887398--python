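# stemopen

Quantitative analyses of protein-driven RNA hairpin remodeling.

A 15-nucleotide fragment of bacterial 23S rRNA (RNA15, `ACGGAAAGACCCCGU`)
folds into a stem–loop hairpin whose closed conformation is required for
recognition by the innate-immune receptor TLR13. A nucleic-acid-binding
protein such as HMGB1 can bind this hairpin with nanomolar affinity and
remodel it into a stem-open state, silencing the receptor's ligand. This
package implements the analysis chain by which that conclusion is reached
from biophysical and simulation data, together with seeded synthetic-data
generators that encode exactly the statistical structure each analysis
assumes — so every stage is testable end to end without any experimental
download.

## What it computes

**Binding (`stemopen.binding`).** Single-site equilibrium binding with
ligand depletion. Because the labelled probe concentration (40 nM) is
comparable to K_d, the bound fraction comes from the exact mass balance:

    fb = [(P + L + K_d) − sqrt((P + L + K_d)² − 4 P L)] / (2 L)

evaluated in the cancellation-safe conjugate form. Observables (fluorescence
anisotropy or FRET intensity) are linear mixes of free/bound endpoint
values; `fit_kd` recovers (K_d, endpoints) by nonlinear least squares with
asymptotic standard errors. A Hill-form fit is available for comparison.

**Thermal melts (`stemopen.melt`).** Two-state van't Hoff model,
fu(T) = 1/(1 + exp[(ΔH/R)(1/T − 1/T_m)]), on linear folded/unfolded
baselines with a multiplicative fluorophore-quenching ramp. T_m is read
primarily from the Savitzky–Golay-smoothed first derivative (with a
"no transition" flag for fully opened probes) and secondarily from a full
model fit; `amplitude_vs_dose` shows the transition amplitude tracking the
folded fraction 1 − fb(dose).

**NMR shift perturbations (`stemopen.csp`).** Combined amide perturbation
CSP = sqrt(ΔδH² + ΔδN²/36), titration tracking across RNA:protein ratios
(fast exchange), and perturbed-residue flagging by an iterated
mean + n·SD rule.

**Structural collective variables (`stemopen.structure`).** Kabsch
superposition RMSD over the RNA backbone; the stem coordination number
CN = Σ_{i∈bases 1–4} Σ_{j∈bases 12–15} s(r_ij) with the rational switching
function s(r) = [1 − ((r−d0)/r0)⁶]/[1 − ((r−d0)/r0)¹²], r0 = 3.0 Å; and
per-base-pair interstrand distances. PDB I/O via biotite; COLVAR-dialect
text output.

**Well-tempered metadynamics (`stemopen.metad`).** Gaussian hills
(w0 = 1.0 kJ/mol every 0.2 ps of toy time, widths 0.5 Å and 10, bias factor
γ = 15, 300 K) with heights tempered as w = w0·exp(−V/k_B(γ−1)T), deposited
along an overdamped Langevin trajectory of the two CVs on analytic toy
landscapes; bit-reproducible per seed, HILLS-dialect logs.

**Free-energy surfaces (`stemopen.fes`).** Bias reconstruction by separable
hill summation, the well-tempered estimator F(s) = −[γ/(γ−1)]·V(s)
(reported in kcal/mol, min-shifted), persistence-merged basin detection
with steepest-descent watersheds, and the hairpin/stem-open basin gap ΔG
with a minima-difference (default) or Boltzmann-integrated convention.

## Worked example

```python
import numpy as np
from stemopen import *

# anisotropy titration of a 40 nM hairpin probe, planted Kd = 23.7 nM
truth = BindingTruth(kd=23.7, probe_total=40.0, obs_free=0.079, obs_bound=0.040)
concs = np.concatenate([[0.0], np.geomspace(0.3, 237.0, 15)])
series = gen_titration(truth, concs, NoiseSpec(sd=0.002, seed=11))
fit = fit_kd(series)
print(f"Kd = {fit.kd:.1f} +/- {fit.kd_stderr:.1f} nM")

# melt of the same probe, planted Tm = 71.5 C
curve = gen_melt(MeltTruth(tm=71.5, dh_vh=50.0), np.arange(25.0, 95.5, 1.0),
                 NoiseSpec(sd=5.4, seed=11))
print(f"Tm (derivative) = {derivative_tm(curve).tm:.1f} C")

# shift tables perturbed at a planted interface; flag it back
tables = gen_shift_tables(ShiftPerturbationSpec(), gen_apo_shifts(seed=11))
ref = next(t for t in tables if t.state == "1.9")
print("flagged residues:", sorted(compute_csp(tables[0], ref).flagged))

# metadynamics on a two-well landscape built with a 9.86 kcal/mol gap
result = recover_delta_g(ToyPotential.hairpin_landscape(delta_g_kcal=9.86),
                         MetadParams(), LangevinSettings(seed=1))
print(f"basin gap = {result['delta_g_kcal']:.2f} kcal/mol")
```

Output:

```
Kd = 24.0 +/- 7.7 nM
Tm (derivative) = 71.7 C
flagged residues: [84, 85, 86, 100, 101]
basin gap = 9.54 kcal/mol
```

The fitted K_d recovers the planted 23.7 nM within its standard error; the
derivative T_m lands within a grid step of the planted midpoint; flagging
returns exactly the perturbed interface residues; and the basin analysis
recovers the constructed free-energy gap within the stochastic accuracy of
a desk-scale run.

A command-line front end mirrors the library
(`stemopen demo --seed 1 --out-dir out` runs every stage and writes a
manifest with per-file hashes; see `stemopen --help`).

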