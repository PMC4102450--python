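# mitoflip

Virtual FLIP (Fluorescence Loss In Photobleaching) experiments on the
dividing nucleus of budding yeast, with configurable models of the nuclear
diffusion barrier.

During closed mitosis the *S. cerevisiae* nucleus stays intact while it
reshapes dramatically: in early anaphase (EA) the mother lobe buds a
daughter lobe, two prolate ellipsoids joined tip-to-tip at the bud neck; in
late anaphase (LA) the nucleus is a dumbbell, two teardrop lobes connected
by a long thin membrane bridge (measured mean length 2.85 ± 0.83 µm).
Membrane reporters at the outer and inner nuclear membranes (ONM, INM) are
laterally compartmentalized between the lobes, and candidate mechanisms are
specialised (sphingolipid-like) membrane domains, immobile protein rings,
and the elongated geometry itself.  `mitoflip` simulates these hypotheses
directly: seeded Brownian dynamics of reporter particles on realistic EA/LA
nuclear-envelope geometries, a photobleaching reaction confined to a
cigar-shaped spot, and an analysis layer that turns the resulting decay
curves into barrier statistics.

## Models

* **Geometry** — ONM and INM as surfaces of revolution about the division
  axis: prolate lobes joined at a finite neck aperture (EA), or teardrop
  lobes (a one-parameter sphere-to-piriform blend,
  ρ²(s) = C·s^(1+2·dev)·(L−s)) joined by a cylindrical bridge (LA).  The
  INM is the ONM minus the TEM-measured perinuclear-space thickness
  (22 ± 6 nm at lobes, 13 ± 4 nm at the bridge).
* **Barriers** — a specialised lipid domain that a particle enters with
  per-encounter probability P_in and leaves with P_out (100% by default),
  diffusing inside at a reduced D_in; layouts: one ring, 3/5/7 parallel
  rings spanning the bridge, or a homogeneous junction-to-junction domain.
  Immobile protein rings of 11 nm hard spheres (15% packing overlap, single
  or septin-style double ring), and virtual permeable planes.
* **Hydrodynamics** — Saffman–Delbrück,
  D = k_BT/(4π µ_s)·[ln(2/ε) − γ], and the Petrov–Schwille rational
  approximation valid for any reduced radius ε = r(µ_top+µ_bot)/µ_s;
  Einstein–Smoluchowski drags; surface-viscosity inversion from measured
  diffusion coefficients.
* **Statistics** — the degree of compartmentalization
  °CP = t₃₀(daughter)/t₃₀(mother) (times to lose 30% of initial
  fluorescence), bleach-position scans along the bridge, mean-absolute
  deviation between simulated and reference decay profiles, grid fitting,
  and the barrier transmission (permeability) coefficient k = K_p·D_in/δ
  with K_p the equilibrium partition coefficient.

## Worked example

A reduced-scale LA nucleus with a homogeneous sphingolipid-like domain on
the INM bridge (the fitted GFP-Src1 entry probability P_in = 35%,
three-fold slower diffusion inside), bleached at 20% of the bridge length
from the mother junction:

```python
from mitoflip import (LobeParams, Species, FlipProtocol, LipidDomainConfig,
                      build_la_geometry, run_flip,
                      degree_of_compartmentalization)

mother = LobeParams(piriform_scale=1.4, piriform_deviation=0.5)
daughter = LobeParams(piriform_scale=1.2, piriform_deviation=0.5,
                      orientation="daughter")
nucleus = build_la_geometry(mother, daughter, bridge_length=2.0,
                            bridge_diameter=0.3)

src1 = Species(name="Src1", enclosure="INM", D_eff=0.3, copy_number=200,
               D_in_domain=0.1)
domain = LipidDomainConfig(layout="homogeneous_bridge", surfaces="INM",
                           P_in=35.0)
protocol = FlipProtocol(placement="bridge_fraction", bridge_fraction=0.2,
                        t_total=150.0, sampling_dt=1.0)

trace = run_flip(nucleus, src1, [domain], protocol, dt=1e-3, seed=3)
cp = degree_of_compartmentalization(trace)
print(f"t30 mother = {cp.t30_mother:.1f} s, t30 daughter = {cp.t30_daughter:.1f} s")
print(f"degree of compartmentalization = {cp.cp:.2f}")
```

prints

```
t30 mother = 18.1 s, t30 daughter = 74.3 s
degree of compartmentalization = 4.10
```

The mother lobe, next to the bleach spot, loses 30% of its fluorescence in
18 s; the daughter lobe, shielded by the domain-covered bridge, takes 74 s,
so the run reports °CP ≈ 4.1 — the asymmetry a FLIP experiment would
attribute to the diffusion barrier plus geometry.

A CLI mirrors the library: `mitoflip simulate|scan|fit|hydro|synth|validate`
(see `mitoflip --help`); all outputs embed the config hash and seed.  Ready
to-run YAML configs, including this worked example, live in `examples/`.

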