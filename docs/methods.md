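# Methods

`ventric` reimplements, at desk scale, a cardiac electrophysiology analysis
pipeline for studying how endocardial anatomical detail (trabeculae and
false tendons) and sex-specific ion-channel expression shape ventricular
activation, repolarization, the pseudo-ECG, and ventricular-tachycardia
inducibility.  This note records the models, the numerical choices, and —
explicitly — what the synthetic fixtures do and do not establish.

## Membrane model

The myocyte is the O'Hara–Rudy human ventricular formulation (41 state
variables) with the later conductance recalibration of IKr, IKs, IK1,
late INa and ICaL exposed as the default `"dutta"` preset.  Three
transmural variants (endo / mid / epi) follow the published conductance
ratios; the wall is labeled endocardial (inner 30%), mid-myocardial
(middle 40%) and epicardial (outer 30%) by the transmural coordinate.
Apex-to-base heterogeneity scales g_Ks linearly from 1.0 at the apex to a
configurable 0.8 at the base (only the linear decay, not its magnitude, is
constrained by the source data).

Sex phenotypes are multiplicative channel sub-unit expression factors on
the male baseline, shipped as an overridable YAML table
(`ventric/data/sex_phenotype.yaml`): the female heart down-regulates the
repolarizing potassium currents (Ito ×0.64, IKr ×0.80, IKs ×0.83, IK1
×0.85) and up-regulates Na+/Ca2+ exchange (×1.15).  With all factors at
1.0 the male phenotype reproduces the baseline model exactly.  Verified
behavior of this implementation: resting potential −87.8 mV with <0.1 mV
drift per second, AP peak ≈ +40 mV, endocardial APD90 ≈ 267 ms at a
1000-ms cycle; female APD90 exceeds male APD90 for every cell type.

Single cells integrate with Rush–Larsen exponential updates for all gates
and forward Euler for concentrations and voltage at dt = 5e-3 ms.  The
limit-cycle search paces until the root-mean-square difference of
consecutive intracellular-calcium transients, resampled on a 1-ms grid,
falls below 1e-7 mmol (the male endocardial cell needs ≈190 beats at a
600-ms cycle).

## Tissue model

Propagation is the monodomain reaction–diffusion equation with an
orthotropic tensor D = D_f f⊗f + D_t s⊗s + D_n n⊗n, discretized with
linear tetrahedral finite elements (lumped mass, zero-flux boundaries) and
operator splitting: explicit Rush–Larsen/Euler reaction per node, backward
Euler diffusion, dt = 0.01 ms by default.  Diffusivities (cm²/ms):
myocardium (5.8e-3, 1.9e-3, 1.9e-3); fast endocardial layer (1.7e-2,
5.8e-3, 5.8e-3), one element thick over the apical two thirds of each
cavity and extended over the trabecular/false-tendon network, standing in
for the Purkinje system; border zone isotropic at the normal transverse
value; dense scar non-excitable at 10% of the transverse value (fully
insulating, D = 0, in the reentry fixture — insulating elements are
removed from both stiffness and mass, since an insulator carries neither
flux nor capacitive load).

Local activation time is the first upstroke crossing of 0 mV;
repolarization time is the first return below 90% of the local AP
amplitude.  Markers: TAT (= max LAT), TAT10/TAT90 (volume-weighted times
to 10%/90% activation), EDI (volume-weighted LAT standard deviation),
apparent CV (mode of the face-area-weighted epicardial surface CV
histogram, 2 cm/s bins, ties to the lower bin).

**Discretization limit.** The sodium-driven upstroke stops propagating on
linear tetrahedra coarser than ≈0.04 cm under the myocardial diffusion
above — the same element size (0.35–0.4 mm) the full-scale study used.
This limit, not accuracy, dictates every fixture size below.

## Conduction-velocity calibration

On a 2-cm cable at the reference 0.04-cm element size the myocardial fiber
diffusion yields 80 cm/s, inside the adult physiological band of
41–87 cm/s; halving the element gives 88.7 cm/s (a 10.7% shift), and
Richardson extrapolation suggests ≈91 cm/s in the dx→0 limit — i.e. the
parameterization meets the band at its calibration discretization and
slightly exceeds the upper edge when fully grid-converged.  The
longitudinal/transverse CV ratio matches the √(D_f/D_t) ≈ 1.75 cable
scaling within 10%.

## Synthetic anatomy

The generator emulates paired detailed/smoothed biventricular geometries
on a shared structured tetrahedral grid: a truncated-ellipsoid two-cavity
shell (smoothed twin) plus endocardial semi-cylindrical ridges and
free-running false-tendon chords ≥1 cm (detailed twin).  Ridge depth is
tuned by bisection so the added volume matches a target trabecular
fraction within two percentage points; targets spanning the cohort range
8.7–16.3% are achievable.  Transmural Φ and apicobasal z are Laplace
solves (endo 0 / epi 1; apex 0 / base 1); sub-structures inherit Φ ≈ 0
from the cavity Dirichlet data, which is precisely what makes their
transmural gradient vanish for trabecula detection.  Five sinus
initial-activation regions are placed at fixed anatomical analogues (two
RV free wall, high anterior para-septal LV, mid left septal surface,
posterior para-septal LV at one third of the apex–base distance), at the
same physical coordinates for both members of a pair.  Generation is
bit-reproducible given (config, seed).

The default heart is deliberately small (LV radius 0.8 cm, height 1.5 cm,
wall 0.28 cm at h = 0.075 cm, ≈9k nodes), and fixture tissue runs scale
all diffusivities ×3.5 — the smallest configuration at which discrete
propagation is robust on one CPU within a test-suite budget.  Anisotropy
ratios and the fast-layer/myocardium contrast are preserved, so relative
anatomy effects (shortcuts, fractionation, pair differences) are
meaningful while absolute TAT/QRS durations are compressed roughly 3–4×
relative to a human heart.  Fixture tissue runs use dt = 0.02 ms (CV
shift <1% vs the default).

Layer labels partition the wall at Φ = 0.3/0.7 (thickness semantics, as
in the source layering).  On a curved thick wall the outer layers hold
more *volume* than their thickness share, and the harmonic Φ is not
arc-length, so volume shares are ≈23/30/47 rather than 30/40/30 — an
intrinsic property of thickness-based layering, not an implementation
artifact.

## Fiber rules

The compact wall follows the transmural helix rule α = α_endo + (α_epi −
α_endo)·Φ with α_endo = +60°, α_epi = −60°, zero transverse angle.
Trabecula detection: t = min(‖∇Φ‖/T, 1) with T = 0.1 per mm of the
normalized coordinate; fibers blend as α = 90°(1 − t) + α_wall·t toward
the structure's long axis (stored by the generator for false tendons;
apicobasal for ridges).  The detection parameter is smoothed by two
neighbor-averaging passes, which keeps the nodal helix-angle jump below
15° across the trabecula–wall junction on the ridge fixture.

## Pseudo-ECG and intervals

Field potentials are the infinite-homogeneous-medium integral
φ_e(x′) = −Σ_e vol_e [D∇V_m]·∇(1/‖x−x′‖) at element centroids, at three
torso-like field points (RA, LA, LL) placed at configurable offsets of the
mesh bounding box (identical physical coordinates across a pair); no
torso conductivity is modelled, so amplitudes are "model mV" and only
comparative quantities matter.  Limb leads obey Einthoven closure
bit-exactly by construction.  QRS and QT both end at the last return of
all three leads into a baseline band of 2% of each lead's peak-to-peak
amplitude (baseline = pre-stimulus mean), within a 200-ms depolarization
window for QRS and the full beat for QT; the landmarks are from the
source definitions, the tolerances are this package's choices.

## Statistics

Group comparisons use Welch's unequal-variance t-test (two-tailed, α =
0.05) with the Welch–Satterthwaite degrees of freedom; zero-variance
equal-mean degenerate input returns p = 1 by convention.  Difference
markers: QT_diff/QRS_diff = female − male on the same geometry; G-diffs =
detailed − smoothed for the same sex.  The packaged reference cohort
tables reproduce every published aggregate (trabecular percentages, mean
QT prolongations 35.00/40.25 ms, mean TAT G-diff 3.35 ms, lead RMSD means
2.0/4.9/4.3 mV, event rates 14%/6%); one printed QT_diff cell (heart B,
smoothed: 63 ms vs the 32 ms recomputable from its QT columns) is stored
as printed and flagged by a test, and the event-rate arithmetic follows
the table (female-smoothed 3/29 ≈ 10%) where the running text says 1%.

## Programmed stimulation and the reentry substrate

The inducibility protocol is the clinical S1–S2–S3–S4 scheme: a drive
train at a 400-ms basic cycle length (2 S1 beats by default at desk
scale; clinically 6–8), then decremental extrastimuli (10-ms steps,
180-ms floor); each extrastimulus level starts at the previous level's
effective refractory period plus a 20-ms margin, and a branch stops on
sustained VT.  Sustained VT is three or more reentrant full-tissue
activations (≥90% of excitable volume per cycle) after the final
stimulus; one or two are a non-sustained reentry; re-activations below
30% are logged as wavelets.  Beats are counted at a reference region —
the excitable tissue farthest from the pacing site — because a
continuously circulating wave never re-activates most of the tissue
inside a window shorter than its rotation period.

A literal desk-scale copy of the whole-heart scar protocol is impossible:
the reentrant wavelength CV × ERP is ≈12 cm for this membrane model, and
coarse grids add 50–100 ms of post-repolarization refractoriness, so no
affordable slab can host a figure-of-eight.  The canonical substrate is
instead an **annular protected circuit**: a closed loop of surviving
tissue (width 0.24 cm, radius 2.7 cm) embedded in insulating dense scar —
the idealization of a scar-encircled channel.  Two fixture myocytes make
the loop inducible at this scale: a loop cell whose APD is shortened to
≈70 ms through instantaneous currents (ICaL ×0.1, late INa ×0.05, IK1 ×3,
NCX ×0.4, mild IKr ×2, INa ×1.5 for premature-beat safety) — shortening
through IKr alone fails, because its seconds-scale deactivation leaves a
standing outward current that blocks any premature beat — and a
border-zone "gate" arc (ICaL ×0.45, late INa ×0.2, IK1 ×2, INa ×2, APD ≈
150 ms) clockwise of the pacing segment.  An S2 at ≈140 ms after S1 finds
the gate refractory and the loop recovered: it blocks clockwise, conducts
counterclockwise, re-enters through the recovered gate and circulates
(observed: sustained VT, ≥3 reactivations, cycle lengths 156–178 ms,
circulating until the simulation ends; opening the loop with a scar gap
abolishes induction under the identical plan).  These parameter sets are
fixture designs for the desk scale, not physiological phenotypes, and the
straight-channel scar operation (`insert_scar`) remains available for
user-supplied geometries.

## What the fixtures do and do not show

Passing tests establish that the implementation reproduces the published
in-table arithmetic exactly; that the stated diffusion parameterization
yields physiological conduction velocities at the study's own
discretization; that the cellular sex phenotype propagates into tissue-
and ECG-level QT prolongation; that endocardial sub-structures produce
local activation shortcuts and QRS fractionation relative to a smoothed
twin; and that the protocol machinery detects, classifies and localizes
reentry with clean sensitivity/specificity on a protected circuit.  They
do **not** show quantitative agreement with whole-heart activation times,
interval durations or inducibility rates: the fixtures are 3–4× smaller,
run with rescaled diffusivities, and the reentry substrate uses
reduced-wavelength myocytes.  The published whole-heart values live in
the packaged reference tables and are compared only through quantities
that are scale-free or recomputable from the tables themselves.

## Numerical details and degenerate inputs

Simulation problem sizes: cable 204–404 nodes; biventricular pair ≈8–9k
nodes per twin (80-ms sinus beats); transmural slab ≈360 nodes (full
420–470-ms beats for QT); ring substrate ≈6.5k nodes (≈3.7k excitable;
840-ms trials).  The diffusion solve reuses one sparse LU factorization
per (mesh, dt).  Blow-up (|V| > 300 mV) raises with the offending node
and time.  Gates are bounded in [0,1] by the exponential update's
construction; concentrations stay positive at the default steps.
Degenerate fiber frames (vanishing ∇Φ) fall back to the structure axis,
then to the apicobasal direction, with a logged warning.  Meshes travel
as ASCII VTU, tables as CSV, histories as HDF5, configs as YAML; all
stochastic generation is governed by a single integer seed and is
bit-reproducible.
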