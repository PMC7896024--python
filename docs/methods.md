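# Model and methods

`fibertopo` is a coarse-grained model of nucleosome fibers built to study
how the linker length L controls the topology of the two-start ("zigzag")
chromatin fiber.  Its central claim is structural: regular fibers with
L ≈ 10n base pairs fold into one topological family (T2, with a DNA
linking-number change of ΔLk ≈ −1.5 per nucleosome) and fibers with
L ≈ 10n+5 into another (T1, ΔLk ≈ −1.0), because adding half a helical
turn of linker DNA flips the rotational setting of successive
nucleosomes.  This note records the model, its parameters, the numerical
choices, and what the package's tests do and do not establish.

## DNA representation

Duplex DNA is a chain of rigid base-pair frames connected by six step
parameters (tilt, roll, twist; shift, slide, rise).  The step transform
uses the symmetric mid-step convention: rotation
`Rz(twist/2)·Rbend(tilt, roll)·Rz(twist/2)`, displacement applied in the
mid-step frame.  Relaxed B-DNA is twist 34.3°/step (10.5 bp/turn) and
rise 0.34 nm; this defines the twist reference state ΔTw = 0.  Angles
are degrees and coordinates nm at every interface; chains are
re-orthonormalized during compounding, and extracting step parameters
from a built chain reproduces the chain to < 1e−6 nm.

## Nucleosome core template

The wrapped core is an idealized left-handed superhelix with the
crystallographic radius 4.18 nm and pitch 2.39 nm, carrying relaxed
intrinsic twist (so the wrap contributes no ΔTw).  The effective wrap is
**1.525 turns** rather than the nominal 1.65: in real core particles the
terminal ~10 bp on each side leave the superhelical ramp nearly
straight, so the *entry/exit tangent geometry* — which is all the fiber
model sees — corresponds to fewer turns than the full wrap.  This single
number anchors the template to the tetranucleosome crystal fact that
10n-class linkers form the face-stacked two-start fiber with essentially
straight, torsionally relaxed linkers.  With a 1.65-turn smooth
superhelix that anchor is unreachable: exhaustive searches place the
cheapest stacked 10n fiber more than +250 kT of linker strain away.
Radius, pitch, wrap turns and core twist are all exposed in
`CoreTemplate`.

Bookkeeping: a linker of L free base pairs is joined to its two cores by
L+1 steps, so one repeat carries NRL = L_NCP + L steps of twist and
adding 5 bp of relaxed linker rotates the next nucleosome by ~171.5°
(the cis/trans flip).

## Energy function

Three terms, in units of kT:

* **Linker elasticity** — harmonic in the step-parameter deviation,
  default diagonal stiffness from persistence lengths: bending 50 nm
  (k ≈ 0.043 kT/deg² per step), torsion 75 nm (k ≈ 0.06 kT/deg²), stiff
  translations (50 kT/nm²).  A full 6×6 matrix can be supplied.
* **Nucleosome stacking** — a face-to-face attractive well between core
  pairs.  The separation vector is decomposed along the mean
  superhelical axis: a Gaussian well at 5.7 nm axial distance (width
  0.5 nm), a lateral Gaussian (width 2.75 nm) requiring the faces to
  overlap, and a |cos θ| axis-alignment factor.  Decomposing the
  distance is essential: a well on the raw center distance rewards
  laterally interpenetrating discs.  The default depth is **7.5 kT**,
  calibrated so that Metropolis ensembles of 12-mer T2 fibers at 1 kT
  retain ~60–70% stacked nucleosomes over the standard 2×10⁵-step
  protocol (see below).
* **Excluded volume** — hard constraints: (i) non-adjacent core
  cylinders (radius 5.5 nm, half-height 2.75 nm, modeled as an oblate
  set of nine spheres) may not overlap; (ii) linker base pairs may not
  enter a foreign histone-octamer cylinder (3.2 × 2.3 nm) nor come
  within 2×(DNA radius) of a foreign core's wrapped-DNA proxy points;
  (iii) wrapped DNA of sequence-adjacent cores may not interpenetrate;
  (iv) linker segments separated by ≥ 8 steps of contour may not
  approach below 2×(DNA radius).  The octamer-plus-wrap representation
  (rather than the full 5.5 nm cylinder) is what makes crossing-linker
  two-start fibers sterically possible at all, matching the crystal
  geometry where linkers pass ~2.3 nm from the neighboring stack's
  wrapped DNA.  Hard checks carry a 0.1 nm contact tolerance; the
  optimizer uses a smooth quadratic overlap penalty.

Electrostatics, salt, histone tails and linker histones are not modeled;
the published knowledge-based DNA potential is replaced by the declared
harmonic form above, which is why all topological tolerances are set at
±0.15–0.2 turns.

## Topology

Writhe is the Gauss double integral over the base-pair origin curve,
evaluated per segment pair with the exact spherical-quadrilateral solid
angle (two van Oosterom–Strackee triangles; branch-free) — the
`levitt_le_bret` method — or by midpoint quadrature (`gauss_pairs`); the
two agree to 0.02 on ≥200-vertex curves.  Twist is accumulated from step
parameters; ΔLk = ΔTw + Wr.  The asin-based per-pair formula often
quoted for this computation was found to mis-branch on fiber-plus-
closure curves (jumps of tens of turns under segment subdivision) and is
not used.  The implementation is validated by an exact discrete
Călugăreanu–White identity: for random framed closed ribbons, the Gauss
linking number of axis and offset strand equals ribbon twist plus axis
writhe to 4 decimals, and stays pinned under non-crossing deformations.

Open fibers are closed by a distant return path (radial escape legs plus
a far arc, clearance ≥ 3 fiber diameters, carrying no twist).  Because
any closure contributes an O(1) end term, the **per-nucleosome** ΔLk of
a regular fiber is taken as the slope of the closed-chain ΔLk over
n ∈ {4, 6, 8} nucleosomes, which cancels end effects exactly for a
regular repeat; dividing a single closed 12-mer by 12 agrees to ~0.03.

## Regular-fiber optimization

A regular fiber is parameterized by one shared linker step (6 degrees of
freedom); nucleosome i+1 follows from i by a fixed screw transform.  The
stacked two-start basin is narrow (the axial well is 0.5 nm wide), so
plain descent from random starts never finds it.  The search therefore
proceeds in stages from a deterministic twist/bend grid of starts
(jittered beyond the grid): (1) Levenberg–Marquardt continuation on
stacking-geometry residuals — axial i,i±2 gap to 5.8 nm, lateral face
offset, axis misalignment, an across-fiber floor on adjacent-core
separation, and the excluded-volume overlap — with increasing weight;
(2) small-step coordinate-descent polish on the true energy with the
soft overlap penalty; (3) a hard feasibility check.  Steps outside the
rigid-base-pair validity window (|bend| ≤ 45°, twist within ±45° of
relaxed, |shift|, |slide| ≤ 0.8 nm, rise 0.05–0.6 nm) are rejected.
Minima are deduplicated by step parameters, energy (0.5 kT) and ΔLk
(0.05) and labeled T2 iff ΔLk/nucleosome ≤ −1.25.

Outcome at the defaults: 10n linkers give a face-stacked two-start fiber
(axial i,i±2 separation ≈ 5.7 nm, stacking ≈ −36 to −48 kT, nearly
relaxed linkers) with ΔLk/nucleosome ≈ −1.39…−1.51; 10n+5 linkers give
an open two-start zigzag ladder (ΔLk ≈ −0.85…−0.96) whose stacked
counterpart exists but lies ~+40 kT of torsional strain per linker
higher (the half-turn twist shift), so under the harmonic potential the
optimal T1 is unstacked.  The scan over L = 10–70 bp reports up to three
minima per L; the package's range statement (≈ −1.8 to −0.67 per
nucleosome at 2-bp stride, mildly seed-dependent at the deep end) is
taken over the energetically optimal conformation per L, since strained
metastable minima extend the raw range unphysically.

## Monte Carlo

Metropolis sampling relaxes regularity: every step of every linker is an
independent degree of freedom; one move perturbs one uniformly chosen
parameter of one step (symmetric proposal, so detailed balance holds),
rebuilds that linker and rigidly transports everything downstream.
Temperature 1 kT, default move sizes 3° / 0.06 nm (acceptance ~0.7),
burn-in 20% of recorded snapshots, fixed seed giving bit-identical
trajectories.  Equipartition check: with stacking and excluded volume
off, the sampled linker-twist variance matches kT/k within 5% at
4×10⁵ steps.

Stacking-depth calibration: the stacked T2 fiber melts cooperatively —
for depths of 6–7 kT the stacking fraction decays without reaching a
plateau within 3×10⁵ steps and individual seeds bifurcate between
largely stacked and fully melted trajectories.  At 7.5 kT the decay is
slow enough that the standard protocol (2×10⁵ steps, 20% burn-in) reads
a reproducible 0.69 ± 0.07 across seeds, and at 8 kT the fiber stays
~89% stacked.  The default is 7.5 kT.  T1 ensembles started from the
optimal (unstacked) ladder reach only ~5–10% at any depth, because the
stacked T1 basin is separated by the half-turn torsional barrier — a
known limitation of the harmonic stand-in; the robust statement is the
family gap (T2 exceeds T1 by >40 percentage points).

## Observables

* **Fragment-length distributions** — FLD(n) = mean over bp pairs
  (i, i+n) of exp(−d/λ), λ = 4.0 nm, with 1 nt identified with 1 bp of
  chain separation and distances between duplex-axis points.  Peaks are
  local maxima after a 5-nt moving average with ≥5% prominence.  The
  optimal T2 fiber at NRL 187 shows the two zigzag peaks at 275 and
  369 nt (~two repeats minus one gyre, and ~two repeats); in the stacked
  T1 fold the lower-position region is suppressed relative to the upper,
  reproducing the family asymmetry.
* **Contacts** — a close contact is a core-center pair within 11 nm
  (one core diameter), binned by neighbor offset; stacked requires
  additionally |cos θ| > 0.7 and axial face distance inside the stacking
  well; flip-out is a radial excursion beyond 1.5× the median distance
  from the local fiber axis, where the local axis is a least-squares
  line through sliding 5-nucleosome centroids (a line fit, because the
  raw centroid polyline wobbles with the two-start alternation).
* **Sedimentation** — Kirkwood double sum
  s/s_mono = 1 + (2 R_eff/n) Σ 1/d_ij over core centers, s_mono = 11.1 S,
  R_eff = 5.5 nm.  A single nucleosome sediments at exactly s_mono;
  compression increases s; T2 ensembles at NRL 187 sediment faster than
  T1 ensembles at NRL 182.

## What the tests show — and do not

All inputs are generated by the package itself (fiber construction,
closed-form curves, seeded Monte Carlo); there is no experimental data
in the loop.  Passing tests therefore establish the *model's* internal
claims — the topology machinery is exact, the two families emerge with
the stated linking numbers, and the observables behave as described —
for idealized, perfectly regular arrays of identical nucleosomes.  They
do not establish anything about sequence effects, partial unwrapping,
linker histones, salt dependence, or irregular spacing in real
chromatin.  Desk-scale problem sizes are used throughout: 8-mers for
optimization (per-nucleosome quantities are n-independent for regular
fibers), 12-mers for observables, 2×10⁵ MC steps × 3 seeds, and a 2-bp
scan stride (5-bp in the test suite).

## Known limitations

* The optimal 10n+5 fiber is unstacked under the harmonic potential;
  the T1 ensemble stacking fraction (~5–10%) falls short of the ~30%
  seen with knowledge-based DNA energetics, though the T1 topology
  (ΔLk ≈ −0.9) is unaffected.
* The closure construction makes the single-structure ΔLk well-defined
  only up to an O(1) end term; per-nucleosome values should always be
  taken from the n-slope (the default) or from long arrays.
* Circular fiber specs are carried through the data model, but exact
  ring closure of the repeat transform is not enforced; circular
  topology is analyzed via closure-completed open chains.
* The excluded-volume bodies are coarse (sphere-set cylinders, 16 wrap
  proxy points); contacts are resolved to ~0.3 nm, absorbed in the
  0.1 nm contact tolerance.
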