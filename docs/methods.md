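# Methods

This note documents the models behind each stemopen stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## Binding isotherms

The binding stage models a 1:1 probe–protein equilibrium. With total
protein P (titrant), total probe L and dissociation constant K_d, the
fraction of probe bound solves the mass balance exactly:

    fb = [(P + L + K_d) − sqrt((P + L + K_d)² − 4PL)] / (2L).

The depletion form is mandatory here: the assays use a 40 nM probe against
a low-nanomolar K_d, where the free-ligand approximation fails badly. The
implementation uses the conjugate form `fb = 2P / (b + sqrt(b² − 4PL))`
(`b = P + L + K_d`), which avoids catastrophic cancellation at P ≫ L and
reduces continuously to the hyperbola P/(P + K_d) at L → 0. Note the
residual difference from the hyperbola at small but finite L is physical —
the first-order depletion term L·P·K_d/(P + K_d)³ — not rounding error.

Observables are population-weighted linear mixes of the free and saturated
endpoint values. For anisotropy this ignores quantum-yield reweighting; the
direction of the titration response (a *decrease* for a hairpin probe whose
terminal label gains rotational freedom on opening, an *increase* for a
duplex probe that simply gains mass) is carried entirely by the endpoint
values, which is all the single-site fit needs.

`fit_kd` initialises deterministically — endpoints from the first/last
observed values, K_d from the titrant concentration at half signal change —
and minimises by Levenberg–Marquardt with K_d bounded positive. Standard
errors come from the asymptotic covariance (common practice for such
single-curve fits; a bootstrap would add little at these noise levels and
costs determinism). Flat responses and bound-pinned fits return
`converged=False` rather than numbers. A Hill (free-ligand logistic) model
is provided for comparison because concentration–response fitting software
is often used interchangeably; depletion remains the default.

## Thermal melts

Two-state van't Hoff model in kelvin: fu(T) = 1/(1 + exp[(ΔH_vH/R)(1/T −
1/T_m)]), superposed on linear folded/unfolded baselines with a
multiplicative quench ramp `1 − q·(T − T_min)` emulating the intrinsic
temperature dependence of fluorescein emission. No ΔCp term and no
multi-transition deconvolution (out of scope for a 15-mer hairpin).

T_m is reported primarily from the first-derivative extremum, mirroring how
melt panels are usually read: Savitzky–Golay smoothing (moving quadratic,
odd window, default 5 — derivative estimation from noisy data needs
regularisation), central differences, most prominent strictly-interior
peak, parabolic sub-grid refinement. A curve with no qualifying peak — flat
or monotonically quenched, the saturating-protein regime — returns a
"no transition" flag. The flag logic assumes transitions rise (FRET
opening); a `direction` switch covers falling transitions. With heavy noise
and no transition, a spurious noise peak can still qualify; the
relative-prominence threshold (default 0.25) is config-exposed.

The full model fit is the secondary T_m estimate; on a single curve the
quench slope is supplied, not fitted (degenerate with baseline slopes).
Amplitude is defined as the baseline gap at the midpoint, Bu(T_m) − Bf(T_m).
For dose series, the zero-dose fit fixes T_m and ΔH for all other doses so
the amplitude stays identifiable down to nearly transitionless curves; the
relative amplitude is compared against the folded fraction 1 − fb(dose)
from the binding stage.

## Chemical-shift perturbations

CSP = sqrt(ΔδH² + ΔδN²/36): the 1/36 factor scales the ¹⁵N axis by its
~6-fold larger dispersion, making the CSP the Euclidean norm of
(ΔδH, ΔδN/6). The reference titration point defaults to the 1.9:1
RNA:protein ratio. Perturbed residues are flagged at mean + n·SD (n = 1
default) with one outlier-rejection pass — standard CSP practice when no
explicit significance criterion is available. Missing residues (prolines,
unassigned, broadened) propagate as missing; zero-imputation would fake
"unperturbed". Exchange-regime classification and per-residue K_d fits from
shift trajectories are out of scope.

The generator applies fast-exchange population averaging, δ_obs =
δ_apo + fb·Δδ_bound, with fb from the depletion isotherm at each point's
total RNA concentration (ratio × 68 µM protein). Fast exchange is the
appropriate regime for shifts that are *tracked* continuously across a
titration. The default generator noise is zero: tracked peak positions of
unperturbed residues reproduce between spectra at the digital resolution,
and a mean+1·SD rule over a genuinely Gaussian background would otherwise
flag ~16% of residues regardless of the noise scale. Noise remains
configurable for robustness exercises.

## Structural collective variables

Conformers carry a minimal named-atom set: backbone P, O5', C5', C4', C3',
O3' plus one base-centroid pseudo-atom ("BC") per residue. The toy hairpin
builder is deterministic parametric geometry, not a force field: the CV
operators only need controllable contact/separation structure, not A-form
realism. Closed: stem residues 1–4 paired with 15–12 at ~3 Å inter-residue
contacts; open: the 3' strand displaced 30 Å.

RMSD uses the Kabsch SVD solution with the determinant-sign correction
(proper rotations only), matched one-to-one by (residue, atom name) over
the backbone set. The coordination number sums the switching function over
all cross-group atom pairs of residues 1–4 × 12–15 (all heavy atoms by
default; a base-only selection is config-exposed, since which atoms the
original group definitions contained is not determinable). d0 = 0 Å — the
conventional default when only the cutoff r0 = 3.0 Å is stated. The
switching function is implemented via the exact simplification
(1 − x⁶)/(1 − x¹²) = 1/(1 + x⁶), which returns the analytic limit 1/2 at
x = 1 without a branch; r ≤ d0 counts as a full contact. Base-pair
distances are measured between the BC pseudo-atoms (the defining atom pair
is otherwise arbitrary).

## Well-tempered metadynamics on toy landscapes

All-atom dynamics is replaced by overdamped Langevin motion of the two CVs
on an analytic potential; the biasing mathematics — the actual subject — is
untouched by that substitution. Hills follow the study protocol: w0 =
1.0 kJ/mol per 0.2 ps of toy time (pace 100 at dt = 2 fs-equivalent),
widths (0.5 Å, 10), γ = 15, 300 K, separable (no cross-term) Gaussians.
Heights temper as w = w0·exp(−V/k_B(γ−1)T) with V the bias already at the
deposition point.

Sampler parametrisation: per-CV mobilities μ (drift μ·F·dt, noise
sqrt(2μk_BT·dt)), so T → 0 is exact gradient descent; defaults
μ = (0.802, 80.2), i.e. diffusion constants (2 Å²/ps, 200 /ps) at 300 K,
fast enough that deposition stays near quasi-equilibrium. Bias forces
during propagation come from an internal grid (spacing σ/5, nearest node);
deposition-time bias is computed analytically over all prior hills by
default, so logged heights are re-derivable from the log to machine
precision (an O(1) grid-interpolated mode exists for runs with hundreds of
thousands of hills, accurate to ~10⁻³ of a hill height). Dynamics reflect
at the domain walls; leaving the box by >10 widths aborts with a
diagnostic. Runs are bit-reproducible per seed, and chunked runs are
identical to single-shot runs of the same length.

The default two-well "hairpin landscape" places the hairpin basin at low
RMSD/high CN (center (3 Å, 95), σ (2, 20), depth 20 kJ/mol) and the
stem-open basin at high RMSD/low CN (center (11 Å, 25), σ (2.5, 22), depth
20 kJ/mol + the requested gap), on a ((0,18) Å × (0,150)) domain. The well
widths are deliberately ≥2× the hill widths on each axis: the deposited
bias is built from finite-width Gaussians and systematically misreads the
depth of any feature it cannot resolve, so a landscape with hill-sized
wells would bias the recovered ΔG by up to ~1 kcal/mol.

## Free-energy surfaces and basins

F(s) = −[γ/(γ−1)]·V(s), converted to kcal/mol (1 kcal = 4.184 kJ) and
min-shifted to zero. Because the instantaneous estimate carries hill-scale
ripples, the default reconstruction averages the bias over 11 checkpoints
spanning the last half of the deposition history — the estimator's additive
constant is uniform over the grid, so averaging preserves relative free
energies; by linearity it reduces to a single weighted hill sum. Grids
default to 200×200 over the hill-center range padded by 5 widths.

Basins: 8-neighbour local minima on the grid, merged by topographic
persistence (saddle < `min_barrier`, default 1 kcal/mol, above the
shallower minimum), watershed regions by steepest descent with
lowest-index tie-breaking — fully deterministic. ΔG between the hairpin
(higher-CN) and open (lower-CN) basins is the difference of basin minima by
default, matching how a single number is read off a 2D PMF figure; a
Boltzmann-integrated basin free energy is available behind a flag since the
figure convention cannot be determined. Both are labelled in the report.

Convergence is monitored by a last-half versus full comparison: the FES RMS
difference over the region the half-time log has already sampled, and the
change in basin ΔG. `recover_delta_g` extends the run in 200k-step chunks
until the ΔG change falls below 0.25 kcal/mol (cap 12 chunks). At these
desk scales a seeded recovery of a 9.86 kcal/mol gap lands within ±0.45
kcal/mol across seeds; the FES RMS diagnostic itself keeps growing for much
longer (bias growth is not yet spatially uniform at γ = 15), which is why
the ΔG change, not the RMS, is the stopping rule.

## Problem sizes

Synthetic studies use 100 replicate titrations/melts per condition
(16-point log-spaced titrant grids; 1 °C melt grids, 25–95 °C), 0.2–2M-step
metadynamics runs (2–20k hills) for gap recovery, and an 8M-step
gentle-hill schedule (w0 = 0.5, γ = 4, pace 50, grid heights) for the
harmonic-well closed-form comparison, where the agreement is assessed as
the RMS deviation over the central ±2σ region after offset alignment —
the quantity that reflects reconstruction quality rather than the extreme
node of a stochastic ripple field.

## What the generators do not emulate

Real titrations carry correlated pipetting errors and photobleaching
drifts, not i.i.d. Gaussian noise; melt baselines can curve; NMR
backgrounds contain weak long-range perturbations rather than exactly-zero
shifts; the toy hairpin has no realistic geometry, sequence thermodynamics,
or solvent; and CV-space Langevin dynamics has no molecular kinetics — so
passing tests validate the estimators and their statistical calibration
under the stated models, not force-field accuracy or instrument
systematics. Multi-site binding, competition fits, multiple walkers,
transition-tempered variants and observable reweighting are out of scope.
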