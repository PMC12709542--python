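# Methods

## The system and the coarse-grained model

An (mQQ)ₙ DNA-mimic foldamer is a single-stranded aromatic oligoamide
helix in which each two-residue mQQ unit contributes ~3.5 Å of rise (one
aromatic ring thickness) and ~36° of twist, so the charged phosphonate
side chains trace a double exo-helical array matching the phosphate
positions of B-DNA. The analysis reduces each conformation to:

* **ring centers** — the geometric (unweighted) center of each residue's
  aromatic ring atoms;
* **unit ring centers** `vᵢ` — the mean of a unit's two ring centers;
* **axis centers** `aᵢ` — the geometric center of the selected heavy atoms
  of four consecutive residues, windows advancing by two residues. A chain
  of n residues yields n/2 − 1 axis centers.

From the axis polyline: rise `rᵢ = |aᵢ₊₁ − aᵢ|` (Å), twist
`φᵢ = dihedral(vᵢ, aᵢ, aᵢ₊₁, vᵢ₊₁)` (degrees, positive for a right-handed
helix), bend `θⱼ` = the angle between consecutive axis segments. Twist
step i pairs axis segment i with `vᵢ, vᵢ₊₁`; trailing unit ring centers
beyond the segment count are unused — any consistent pairing returns 36°
on the ideal helix, so consistency rather than convention is what matters.

**Axis atom selection.** The default selection is backbone+ring heavy
atoms, excluding side-chain atoms: side-chain flexing dominates the RMSF
and would contaminate the axis. An `all-heavy` option implements the
literal "heavy atoms of two consecutive units" reading; the choice is
recorded in reports.

## Flexibility estimators

Statistics are taken over unmasked frames; frames whose heavy-atom RMSD to
the start structure exceeds a threshold (default 6 Å) are excluded, since
those are the kinking transitions analyzed separately. The exclusion
applies to ensemble statistics and RMSF, **not** to kink detection.

* **Mean twist / mean rise** — grand means over frames and steps.
* **Bending persistence** `L_b = −L / ln⟨u_start · u_end⟩`, with
  `u_start`, `u_end` the unit tangents of the first and last axis segments
  and contour length `L = (n_axis − 2)·⟨rise⟩` (the step count separating
  those segments). `⟨·⟩ ≥ 1` is reported as infinite (rigid);
  `⟨·⟩ ≤ 0` is flagged unreliable — the chain is shorter than its
  decorrelation length assumption allows. An independent per-step
  estimator `L_b = −⟨rise⟩/ln⟨cos θ⟩` is provided as a cross-check; the
  two agree within a few percent on worm-like-chain ensembles.
* **Twist persistence** `L_t = ⟨rise⟩ / var(δφ)` with δφ the per-step
  twist fluctuation in radians (per-step means removed, pooled). The
  quantity is reported in simulation studies of these helices without a
  printed definition; this discrete torsional-stiffness relation is the
  standard choice and is flagged as an assumption in reports. A
  cumulative-twist-decay estimator (`⟨cos Σδφ⟩ = e^(−jσ²/2)` fitted over
  separations j) is available as an alternative.
* **Rise fluctuations** — pooled per-step variance (Å² per step), i.e.
  variance across frames after removing per-step means. Interpreted as
  per-axis-step (not per unit time).
* **Exo-helix periodicity** — `360°/⟨φ⟩` units per turn, with a value
  rounded to the nearest 0.5 unit also reported (10 at the crystal twist
  of 36°; larger when the helix unwinds).
* **Fluctuation covariance** — `cov(x_center, x_center+o)` for twist and
  bend separately, per signed offset o, after removing per-step means; the
  offset-0 value equals the sample variance at the center step.
* **RMSD / RMSF** — optimal-superposition (Kabsch) RMSD to a reference
  frame; RMSF about the ensemble mean structure, each frame superposed to
  a provisional mean and the mean recomputed once. Both run in double
  precision end to end: common single-precision kernels carry ~10⁻⁶
  errors, which matter for the exactness contracts below.

**Geometric twist-bend coupling.** Measuring twist as a dihedral about a
bent axis picks up a first-order contribution from bending (the same
covariation of local twist and bend fluctuations that the simulations
show). Consequently var(δφ) on a strongly bent ensemble overestimates the
intrinsic torsional noise, and twist-persistence validation is done on
straight-axis ensembles; on real trajectories `L_t` should be read as an
effective (coupled) stiffness.

## Kink detection

Backbone dihedrals α…ζ along one repeat unit are computed per frame with
the standard signed convention, wrapped to (−180°, 180°]. An event at a
unit opens when |γ − circular mode(γ)| exceeds `gamma_threshold` for at
least `min_dwell_frames`, and closes when it returns below; runs separated
by less than the dwell merge. The reference is the **circular mode** over
the whole (unmasked) trajectory per unit — robust to slow drift, unlike
the start value. An event is **major** when the δ excursion exceeds
`delta_threshold` *or* the local axis bend exceeds `bend_threshold`, *and*
its lifetime reaches `major_min_lifetime`; otherwise **minor**.

Defaults: γ 45° (below the <60° scale of minor-kink dihedral shifts, so
minors are caught), δ 90° (a flip), bend 30° (below the ~40° major-kink
angle), dwell 2 frames, major lifetime 10% of the trajectory span. These
are phenomenological thresholds, exposed on the CLI and logged in reports;
kink *counts* on real trajectories are threshold-dependent.

Unstacking events are detected on neighbor-unit ring-center distances
exceeding `factor` (default 1.8) times the per-pair median — an unstacked
step approximately doubles the spacing, and the median is outlier-robust.
Phosphonate hydrogen bonds use the distance-only criterion
d(H···O) < 2.5 Å between *different* phosphonate groups (no angle term, by
design); the per-frame bonded fraction counts groups in at least one bond,
as donor or acceptor.

## Handedness-inversion kinetics

CD re-equilibration traces are fitted by nonlinear least squares to
`y(t) = y∞ + A·e^(−kt)` with free `y∞` (an optional flag fixes it), A of
either sign, and `t½ = ln2/k` exactly. Initial guesses: tail mean for
`y∞`, first point for A, log-linear regression for k. Instrument lag (the
sample reaching the measurement temperature) is removed by `trim_lag`:
the automatic mode fits suffixes starting at each of the first third of
points and keeps the longest whose residual signs pass a Wald–Wolfowitz
runs test (α = 0.05; numerically exact fits pass outright) — a
reproducible surrogate for the visual "trim until exponential" rule.

## The synthetic generator

The generator defines the study conditions; it is validated, first-class
code, not a fixture.

**Pseudo-atom chemistry.** Each residue is a planar hexagonal "ring" of
carbons (radius 0.7 Å) whose centroid sits `ring_radius` = 2.5 Å from the
axis, a matching "backbone" polygon of nitrogens mirrored across the axis,
and a 5-atom phosphonate group (P, 3 acceptor O, 1 donor H) at
`side_radius` = 9.5 Å — the B-DNA-like phosphate radius, chosen so that
inter-phosphonate H-bonding is transient (per-frame bonded fractions of
roughly 0.2–0.8 on fluctuating ensembles) rather than saturated. The
mirror construction puts each residue's backbone+ring centroid exactly on
the helix axis, which makes the analyzer's window centroids *exactly* the
intended axis nodes; without it, the exactness contracts (rise 3.5 Å,
twist 36°, bend 0, all to 10⁻⁶ on the ideal helix) are unattainable by
construction. The dihedral quadruples are defined on these pseudo-atoms;
γ and δ terminate on dedicated probe atoms so a kink injection can offset
one dihedral by rotating a single atom.

**Ensembles.** Each frame is re-grown independently: per-step twist
`τᵢ = τ₀ + N(0, σ_twist²)`, rise `rᵢ = r₀ + N(0, σ_rise²)`, and a
fixed-magnitude tangent tilt with uniform random azimuth, with
`cos(tilt) = e^(−r₀/L_p)` so the tangent autocorrelation is exactly
`⟨tᵢ·tᵢ₊ⱼ⟩ = e^(−j·r₀/L_p)` at every lag. Residue centers are then solved
(pseudoinverse of the window-averaging operator, smooth initial guess from
the axis polyline) so the analyzer recovers the generated axis nodes
exactly — ground truth is exact at the analyzer level, and estimator
validation measures only estimator error plus sampling noise. Frames are
temporally independent by default (ensemble statistics need no memory); an
AR(1) frame-memory parameter exists for event-lifetime studies.

**Kink injection** operates in path space: within the frame window the
axis downstream of the chosen unit is rotated about a transverse axis
through the corner node and the window frames are rebuilt, so the analyzer
sees the full kink angle at a single junction (a rigid block rotation
cannot do this: the overlapping 4-residue windows would smear the corner
over three junctions). γ/δ offsets then rotate the probe atoms. Frames
outside the window are bit-identical to the input. Injection requires
generator-produced trajectories (it uses their stored path metadata).

**CD traces.** `y(t) = y∞ + A·e^(−k(t−lag))` for t ≥ lag with a flat
plateau at the initial signal before the lag — continuous, and the
simplest detectable violation of exponentiality for the trimming logic —
plus Gaussian noise, all seeded.

**What the generator does not emulate.** No energetics or force field; no
temporal correlation by default (so lifetimes, not rates of spontaneous
events, are meaningful only with AR(1) memory); pseudo-atoms carry correct
centroids, distances and dihedrals but not real quinoline geometry,
hydrogen-bond directionality, or solvent. Passing tests therefore
demonstrate that the estimators recover known elastic/kinetic ground
truth under the stated noise model — not that any particular real
trajectory has those parameters. Reproducing the reported
microsecond-simulation flexibility values themselves would require the
original force field and trajectories and is out of scope.

## Numerical choices

* Angles in degrees at API boundaries, radians internally; twists wrapped
  to (−180°, 180]; right-handed helices have positive twist; mirror
  images negate twist and preserve rise and bend.
* Dihedrals and Kabsch superpositions are computed in float64; bend
  angles use atan2(|u×v|, u·v), which keeps precision near 0° where
  arccos loses half its digits.
* Degenerate twist steps (ring center on the axis) give NaN for that step
  rather than failing the frame; NaNs are excluded from pooled statistics.
* Indexing is 0-based half-open internally; reports and CLI output are
  1-based.
* Problem sizes used in validation: persistence-length recovery uses
  5000-frame, 18-unit ensembles (sampling error of the end-to-end
  estimator ≈ 2–5%); kinetics bias studies use 120-point traces over five
  half-lives and 200 replicates at 2% amplitude noise. These sizes make
  the estimator checks decisive at the stated tolerances while keeping the
  suite fast.

## Known limitations

* The twist-persistence definition and the contour length of the
  end-to-end bending estimator are stated assumptions (see above); both
  are flagged in reports.
* `L_b` from the end-to-end estimator is unreliable when the chain is
  longer than a few persistence lengths (⟨u_start·u_end⟩ → 0); the
  per-step estimator is the fallback.
* Kink classification thresholds are phenomenological; counts should be
  reported together with the thresholds that produced them.
* XYZ files carry atom names but no residue labels; analyses needing a
  topology should use multi-model PDB or supply the sequence explicitly.
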