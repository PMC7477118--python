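# Methods

## The physical model

A single *Jatropha curcas* xylem vessel is modelled as an axisymmetric
fluid domain: axial coordinate z ∈ [0, L + 2·l_ext] increasing inlet →
outlet, radial coordinate r ∈ [0, R]. The measured anatomy provides the
defaults (all µm): vessel length L = 200, inner diameter 2R = 55, pit
chamber diameter 8, pit aperture 2.6, pit depth 4.6, membrane thickness
0.2 with 15 % open area, simple perforation plate of width 3 and height 3
(tilt 45°), and smooth extensions l_ext = 25 at both ends so entrance and
exit effects stay out of the vessel proper.

Three nested tiers isolate the structures. The smooth tier is the bare
55 µm lumen. The wall-thickening tier adds the pitted secondary wall: a
solid layer of thickness equal to the pit depth lines the vessel span and
narrows the open lumen to R − pit_depth; bordered pits pierce it, each an
aperture neck (30 % of the depth, a documented profile choice) opening into
a chamber whose base is the pit membrane at the primary wall. The tie
between pit depth and open lumen radius is deliberate: the reported effects
of pit depth on total resistance (tens of percent) and its positive effect
on radial efficiency are only obtainable if a deeper pit means a thicker
thickening layer and hence a narrower lumen; a pit carved outward from a
fixed lumen produces neither. The full tier adds the plate as an annular
constriction of the stated height and width at mid-length; pit rows that
would intersect it are dropped and logged. At plate height → 0 the full
tier reduces exactly to the wall-thickening tier, and the three tiers nest
as feature sets.

The axisymmetric reduction turns pit rows into annular cavities. The true
azimuthal arrangement is kept as metadata — pits per row from the same
pitch rule as the axial placement (pitch = pit diameter + spacing, spacing
defaulting to one pit diameter; 12 axial rows × 8 azimuthal pits at the
defaults) — and the membrane conductance is scaled by the circumferential
open fraction so the radial leak area matches the true pit area. The
cavity *friction*, by contrast, is that of an annular groove; this is the
main fidelity cost of the reduction and one reason absolute component
splits differ from a full 3-D computation. A `SECTOR_3D` reduction is
described at the geometry level (azimuthal count, tilt retained) but is not
meshed or solved; the plate tilt therefore never enters the computation.

## Flow problem and discretization

Steady incompressible flow of water (ρ = 998.2 kg m⁻³,
µ = 1.003×10⁻³ Pa s at 20 °C; configurable — the fluid is not otherwise
constrained by the anatomy) is driven by a velocity inlet with mean
0.3 mm s⁻¹ and a zero-pressure outlet. The vessel Reynolds number is
≈ 0.016, firmly in the creeping regime.

Finite volumes on the staggered (MAC) arrangement of a feature-aligned
tensor mesh: axial velocity on z-normal faces, radial velocity on r-normal
faces, pressure at cell centres; all feature coordinates are mesh edges,
and solid cells are blanked. Face areas carry the axisymmetric metric, and
the radial momentum equation includes the −v/r² curvature term. No-slip
walls use half-cell distances; the axis is a symmetry line. Two solution
paths share these operators:

* **direct Stokes** (default): the linear saddle-point system
  [[A, G], [D, 0]] solved by sparse LU — deterministic, iteration-free,
  mass-conservative to machine precision;
* **SIMPLEC**: under-relaxed momentum solves (α_u = 0.9) with the SIMPLEC
  pressure-correction coefficient d = A_face/(a_P/α − Σa_nb), iterated to a
  normalized residual of 10⁻⁸ (defaults; the residual history is carried on
  the returned field, and non-convergence raises with that history).
  Convective terms, when enabled, enter by Picard-linearized first-order
  upwinding; at Re ≈ 0.016 they shift the pressure drop by ~10⁻⁴ %, far
  below the grid-independence criterion, so the Stokes path is the
  production default.

The solver works in nondimensional variables (lengths in µm, velocities in
units of the inlet velocity, pressure in units of µ·u_in/1 µm), which keeps
the matrix well conditioned without equilibration.

### Inlet profile

The inlet velocity profile defaults to the fully developed parabola with
the stated mean. A uniform plug profile is also available, but it meets
the no-slip wall in a stress singularity at the inlet corner, and the
inlet-plane pressure — hence the extended-domain Δp — then grows without
bound under refinement (measured: the apparent resistance climbs from +9 %
to +21 % above Hagen–Poiseuille between refinement levels 0 and 3, with no
convergence). A grid-independent pressure drop is impossible under that
condition, so the developed profile is the default; with it the smooth-tier
solution converges to Hagen–Poiseuille to < 0.1 %. Users of the plug
profile should read `pressure_drop_vessel` (measured between the
vessel-proper planes, where the flow is developed) instead of the
extended-domain drop; both are always reported.

### Pit membranes

Membrane faces are porous jumps: normal face velocity
v = κ·(p_cell − p_ext), with the external side at the outlet pressure (the
neighbouring conduit). The per-area conductance κ follows a Sampson–Dagan
pore law — per-pore resistance 3µ/a³ + 8µt/(πa⁴), pore areal density
φ/(πa²) — scaled by the circumferential open fraction of the annularised
row. The pore radius a is not part of the measured anatomy; the default
0.3 µm represents the coarse, microscopy-visible porosity of this species'
membranes and was fixed before any downstream comparison. It sets the
absolute magnitude of the radial efficiencies (≈ 1–5 % across the sweeps at
the defaults) but none of the monotone trends. Zero permeability makes the
faces exact walls (the degrees of freedom are removed, so sealed-membrane
fluxes are identically zero, not merely small).

### Resistance bookkeeping

A reported resistance is Δp divided by the *total delivered* flux — axial
outlet flux plus membrane efflux — which equals the inlet flux by mass
conservation (checked to < 0.1 %, actually ~10⁻¹³ for the direct path).
Counting only the axial outlet flux would make a leakier membrane look
*more* resistive even as it relieves the pressure drop, inverting the
reported permeability trend; the axial and membrane components are reported
separately in every summary because their split is a material modelling
distinction. Pressure drops are area-averaged plane pressures; the inlet
plane value is linearly extrapolated from the first two cell layers.

## Meshing and grid independence

Target cell sizes are assigned per feature region (aperture: ≥ 4 cells
across; plate: ≥ 6; chamber shoulders ≤ 0.8 µm; radial grading through the
chamber so the membrane-adjacent cell never exceeds the membrane
thickness) and all sizes halve per refinement level, so cell counts grow
strictly and patch areas are refinement-invariant. A mesh that cannot
resolve an aperture or the plate opening with at least two cells raises a
refinement error naming the feature. Grid independence uses a 0.5 %
successive-change criterion on Δp; the smooth tier meets it at level 1
(0.34 % → 0.09 % → 0.02 % over levels 0–3), and the coarse level-0 mesh —
used for the sweep and trend studies — is itself within 0.5 % of the
closed form for the smooth tier. Production problem sizes are modest by
construction: ~1 000–6 000 cells at level 0 (tier studies, sweeps),
~4 000–40 000 at levels 1–2 (verification), chosen as the scale at which
every verified quantity is already grid-converged.

## The closed-form network oracle

An independent series/parallel estimate cross-checks the solver: extensions
and vessel as Hagen–Poiseuille segments (at the primary and thickened
radii), the plate as a short narrower segment plus a Sampson end
correction, and the pit pathway lumped as a single mid-length shunt to the
outlet (per pit: aperture pore in series with its membrane pores; all pits
in parallel). It is an order-of-magnitude oracle: exact for the smooth
tier (where it *is* the closed form), within a few percent of the solver
for the thickened tier, and agreeing with the solver on the sign of every
parameter-sweep trend — which is what it is used to certify.

## Synthetic inputs

No external data accompanies the model; the fixtures module draws
anatomically plausible parameter sets uniformly within the documented
ranges (diameter 52–61 µm, pit depth 2.6–5.6 µm, permeability 0–30 %,
plate height/width 2–5 µm — the measured anatomy ± the published sweep
spans; uniform because no distributional information exists), plus
degenerate cases at the closed limits (sealed membrane, vanishing plate,
shallow pits, fully open membrane). Smooth-tier cases carry their
Hagen–Poiseuille triples as bundled references. What passing these checks
shows is that the discretization, bookkeeping and trends are right; it does
not certify absolute resistances of real vessels, whose pit fields,
non-circular sections and wall sculpturing the generator does not emulate.

## Numerical and design choices, in brief

* Percent changes take the denominator convention as a required argument;
  the published comparisons mix both conventions and the package ships the
  claim-by-claim mapping (`xylemflow.reference.PRINTED_COMPARISONS`) with
  per-claim rounding tolerances propagated from the 4-digit printed
  endpoints. Two published sentences are flagged there as not encodable
  (one direction typo, one endpoint-inconsistent percentage).
* The efficiency quantities are named `r_axial_only` / `r_with_radial` to
  keep resistances and resistance *fractions* — which share a symbol in the
  published tables — from ever colliding in code.
* Efficiency pairs are always solved on the same mesh (membranes walled vs
  open) so meshing differences cannot contaminate the difference.
* Sweeps hold every other parameter at the defaults; axial pit placement is
  diameter-independent by construction, while the azimuthal count follows
  the circumference through the pitch rule. Sweep grids default to the
  published four-value grids, endpoints included.
* Reports echo the publication style (×10¹² scaling, rounded fractions)
  while every stored value retains full precision; CSV serialization uses a
  fixed float format so identical runs are byte-identical.

## Known limitations

* Absolute resistances and component fractions differ from the published
  3-D computation (coarse-mesh fractions ≈ 51/45/4 % vs the printed
  66.2/30.2/3.6 %): the annular-cavity reduction, the plate-tilt omission
  and the entrance-singularity treatment all act on the wall-thickening
  share. Orderings, trends and the resistance calculus are the supported
  claims.
* The pit membrane is rigid: no aspiration, cavitation or air-seeding
  physics, and no fluid–structure interaction.
* Steady state only; no transients.
* The 3-D sector mode is descriptive geometry only.
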