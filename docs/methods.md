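# Methods

## Scope and model

`mitoflip` simulates lateral protein mobility in the nuclear envelope of a
dividing budding-yeast cell, treated as two static snapshots: early
anaphase (EA, budded nucleus) and late anaphase (LA, dumbbell nucleus).  A
virtual FLIP experiment continuously bleaches a small region while the
unbleached fraction in the mother and daughter lobes is recorded; the ratio
of the times the two lobes take to lose 30% of their initial fluorescence
is the degree of compartmentalization (°CP), the headline statistic.  The
package asks how three ingredients shape that statistic: specialised
(sphingolipid-like) lipid domains, immobile protein rings, and the nuclear
geometry itself.

## Geometry

Both nuclear membranes are closed surfaces of revolution about the division
axis x (mother at x < 0).  EA lobes are prolate ellipsoids truncated at a
shared neck circle; the neck aperture radius defaults to 150 nm (half the
canonical 300 nm domain width) so that membrane paths between the lobes
exist — whether the original tip-to-tip join was a point contact or a
finite aperture is not recorded, so the aperture is a configuration
parameter.  LA lobes are teardrops from the one-parameter family

    rho(s)^2 = C * s^(1 + 2*dev) * (L - s),    s in [0, L],

which is exactly a sphere of diameter L at dev = 0 and the pear-shaped
quartic b² y² = x³ (a − x) at dev = 1; `C` is set by the requested maximal
lobe radius.  This family was chosen because the named teardrop curve comes
without a published parametrization; the blend makes "deviation from a
sphere" a single number and keeps the sphere limit exact.  Lobes join a
constant-diameter cylindrical bridge at hard junction planes; the INM is
built from the same generating curves with the perinuclear-space thickness
subtracted (defaults 22 nm at lobes, 13 nm at the bridge, from
transmission-EM measurements).

Each surface is represented by its meridian polyline resampled to uniform
arc length (8000 vertices by default).  Slope discontinuities at the neck
and the lobe–bridge junctions are rounded over a 50 nm arc (`fillet`):
a hard concave crease makes closest-point projection focus Brownian mass
onto the crease circle and biases inter-lobe flux by tens of percent,
whereas a lipid bilayer cannot form a crease in the first place.  Region
bookkeeping (mother lobe / neck / bridge / daughter lobe) still references
the exact junction planes.  Resolution matters: at 1000 vertices the
discrete surface measurably biases lobe occupancy (~8%), at 8000 vertices
the bias is below the Monte-Carlo noise of every test in the suite.

## Brownian dynamics

Surface species (ONM and INM reporters; the NPC as an envelope-spanning
particle on the ONM/INM mid-surface with two lateral degrees of freedom)
take isotropic Gaussian steps of variance 2 D Δt per tangent axis in the
local tangent plane, then are projected back to the surface by closest
point on the meridian polyline.  Volume species (nucleoplasmic reporters,
perinuclear diffusers) take 3-D Gaussian steps with specular reflection at
the enclosing surfaces.  The default step follows Δt = Δx²/(2 d D); the
canonical setting of 40 µs corresponds to ~7 nm resolution for a membrane
species at 0.3 µm²/s.  The governing species is an explicit parameter
because "fastest species" and "7 nm" single out different reporters.  Tests
and the acceptance script use coarser steps (0.1–2 ms, i.e. 8–50 nm); a
dedicated oracle confirms that the equilibrium behaviour of the barrier
rules is timestep-robust at exactly these scales.

The core inner loop is compiled with numba; a vectorised numpy
implementation of every elementary operation remains the reference and the
two are held to the same statistical behaviour by the test suite.  Each run
consumes one seeded numpy Generator, so traces are bit-reproducible.

## Barrier rules

**Lipid domains.**  Domain membership is a pure function of the axial
coordinate (one ring, 3/5/7 parallel rings, or junction-to-junction).  A
proposed displacement whose endpoint changes membership is accepted with
the per-encounter probability P_in (entering) or P_out (exiting, 100% by
default); inside the domain the species diffuses at D_in (a three-fold drag
increase, i.e. D_in = D_eff/3, unless configured otherwise).  Because entry
and exit steps are drawn with different variances, a naive accept/reject
rule partitions particles into the slow phase even at P_in = P_out — a pure
viscosity change must not create partitioning.  The crossing acceptance
therefore carries the Metropolis–Hastings factor for the proposal-density
change, and rejected crossings keep their old position.  This makes the
equilibrium surface-concentration ratio exactly K_p = P_in/P_out,
independent of D_in and of Δt (verified at Δt and Δt/2 in the acceptance
suite).  One caveat is inherited from the per-encounter definition itself:
the *kinetics* of domain passage scale like P·sqrt(D/Δt), so fitted P_in
values are comparable only between runs at the same Δt — which is how the
grid fitter uses them.

**Protein rings.**  Rings are immobile hard spheres (11 nm default
diameter, matching septin/actin filament thickness and the Bud6 diameter)
placed on a surface circle with up to 15% neighbour overlap to mimic
polymerisation; packing capacity is floor(C/(d·(1−overlap))) per circle and
doubles for the septin-style double ring (two 4 nm circles 8 nm apart).
Displacements whose straight segment passes within the contact radius of an
obstacle are rejected.  The straight-chord test is exact only where the
surface is locally flat on the scale of one step; across the sharply curved
neck throat a coarse step can hop the ring crest, so blocking experiments
place the ring on a locally flat band or use steps below ~10 nm.

**Permeable planes.**  A virtual plane crossed with fixed probability P,
otherwise reflected; used as the phenomenological one-number barrier.  Note
that at desk scale the plane only becomes rate-limiting for °CP when P is
small (≲ a few %): above that, diffusion to the bleach spot dominates.

**Bleaching.**  Inside the cigar-shaped spot (capsule; default radius
0.25 µm and length 1 µm — invented defaults, the source geometry being
unpublished) unbleached particles convert irreversibly with the exact
per-step probability 1 − exp(−k Δt), k = 150 s⁻¹ by default, so coarse
steps remain unbiased.  The spot is placed at the lateral edge of the
mother lobe on the envelope, or at a configurable fraction of the bridge
length (0% = mother junction, 100% = daughter junction, eleven positions by
default in scans).

## Analysis

Traces are smoothed with a 5-sample moving average (the first sample is
anchored at 1) before the 30%-loss time is found by linear interpolation;
°CP = t30(daughter)/t30(mother).  The deviation between a simulation and a
reference trace is the mean over time and over both lobes of the absolute
difference of normalised fluorescence, reported in percentage points (a
fraction scale is available).  Grid fitting averages this deviation over
reference cells and replicates and takes the argmin, ties toward the
smaller parameter value.  The partition coefficient is measured before any
bleaching as the time-averaged ratio of surface concentrations inside and
outside the domain, and the transmission (permeability) coefficient is
k = K_p · D_in / δ with δ the barrier thickness — which is why a tenfold
thickening from a 300 nm EA neck domain to a 2.85 µm LA bridge domain
drops k by 9.5× at equal K_p and D_in.  The °CP/°CP⁻¹ bridge scans are
summarised by the width of the region where |log °CP| falls below a
quarter of its maximum: a narrow central ring yields one sharp crossing
near the 50% position, a distributed domain an extended overlap.

## Synthetic data

The population generator draws LA bridge lengths from the measured
2.85 ± 0.83 µm normal distribution, truncated to the window (1.2–5.7 µm for
300 nm rings) in which a 3/5/7-ring layout satisfies the inter-ring gap
rule (between half and twice the ring width), and perinuclear thicknesses
from the TEM distributions.  Lobe dimensions use plausible defaults —
the source figures print no numbers — and every distribution is
configurable.  Reference FLIP data are simulated with known ("sealed")
barrier parameters plus i.i.d. Gaussian noise on the normalised
fluorescence (sd 0.03 by default; the true experimental noise model is
unpublished).  The generator emulates cell-to-cell geometric heterogeneity
and observation noise; it does not emulate fluorophore maturation,
microscope point-spread blurring, nuclear growth during acquisition, or
correlated noise, so passing recovery tests demonstrate identifiability
of barrier parameters under the model, not robustness to those effects.

## Problem sizes

Full-scale runs (thousands of particles at Δt = 40 µs for hundreds of
seconds) are cluster work.  The test suite and `scripts/acceptance.py` use
reduced scales chosen once: 120–300 membrane particles, Δt = 0.1–2 ms,
simulated spans of 20–240 s, reduced LA nuclei (1.2–2 µm lobes and bridges)
for kinetics-limited experiments, three to five synthetic cells and one
replicate for grid fits, and 10⁴ particles × 10³ steps for the
free-diffusion oracles.  At these sizes the whole suite runs in roughly a
quarter hour on one CPU.

## Known limitations

* Per-encounter crossing probabilities make passage kinetics
  Δt-dependent (equilibrium properties are Δt-robust); compare fitted
  P_in values only at matched Δt.
* Closest-point projection on a discretised surface leaves residual
  density biases of a few percent near regions whose curvature radius is
  comparable to one step; they shrink with smaller steps and finer
  polylines.
* Geometries are static snapshots; nuclear growth during an acquisition is
  not modelled.
* Excluded volume between diffusing particles is a simple bounce-back and
  is off by default; photophysics beyond first-order bleaching is not
  modelled.
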