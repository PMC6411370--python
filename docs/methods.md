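# Model and methods

`agarcolony` simulates the establishment of a dense colony of non-motile,
non-EPS-producing rod-shaped bacteria growing on hard agar, driven purely by
the physical force of cell growth, and provides the analysis layer used to
extract the colony-scale observables (radial/vertical expansion speeds,
buckling width, growth-zone thickness, verticalization).

## Units and scales

Internal units are micrometres, hours, and grams of cell dry weight.
Nutrient concentrations are carried as mass concentrations (g/µm³), because
the consumption term ρλ/Y couples them to biomass; published values in
mM/µM are converted at load time using the substrate molar mass (default
glucose, 180 g/mol).  Forces are measured in units of γ_surf·w₀: the
saturated cell-level surface-tension force is then π, and per-cell pressures
come out directly in the natural pressure unit P₀ = γ_surf/w₀.  Because all
force-generating terms (elastic, frictional, surface tension) are expressed
in this unit, results reported in P₀ are independent of the absolute value
assigned to γ_surf.

## Cells, growth, division

Each cell is a spherocylinder (cylinder length l, cap diameter w₀ = 1 µm)
with center r, unit director n, velocity v and angular velocity ω.  The
local mass growth rate is the Monod readout of the nutrient concentration at
the cell center, λ = λ_S·C/(C+K_S) with K_S = 20 µM and batch rate λ_S
(default 1/h).  The cylinder length grows exponentially at rate σλ and the
cell divides at l_div = 3 µm into two daughters whose outer cap centers
coincide with the mother's cap centers.

Two physiological choices deserve note:

* **Elongation factor σ.**  The caps contribute an l-independent volume, so
  exponential length growth is not exponential mass growth cell-by-cell.
  What is observable, and what the nutrient sink assumes, is the population
  rate: in steady state the division cycle takes ln(l_div/l₀)/(σλ), so the
  count and total biomass grow at rate σλ·ln2/ln(l_div/l₀).  The default
  σ = ln(l_div/l₀)/ln 2 ≈ 1.585 makes this rate exactly λ; with
  l₀ = (l_div−w₀)/2 = 1 µm the predicted early-colony count rate at
  C_s = 0.5 mM is 0.962/h, which the simulation reproduces.

* **Division noise without birth overlap.**  Daughter lengths are
  anti-correlated, l_A = l₀(1+u), l_B = l₀(1−u) with u uniform in ±5%, so
  the pair always tiles the mother's footprint exactly.  Independent draws
  would frequently create ~0.1 µm of instantaneous daughter–daughter
  overlap, i.e. an elastic force spike several times the surface-tension
  hold-down, which artificially ejects newborn cells from the monolayer.
  Directors are perturbed in a 2° cone and angular velocities receive
  uniform kicks of ±0.05/h — enough to break lattice artifacts without
  tilting cells against the surface-tension confinement.

## Mechanics

Forces follow granular-DEM practice.  Cell–cell contacts (overlap
δ = w₀ − d from the segment–segment distance) carry a Hertzian normal force
F_elas = k_n·δ^{3/2} with k_n = (2/3)E*·√(w₀/2), plus a normal dissipation
−γ_n√δ·v_n; the tangential force is the static (viscous) branch
γ_cc,t·δ·v_t capped by the dynamic-friction yield criterion μ·F_elas, which
is independent of the sliding speed.  The same forms act at the two
hemispherical caps against the agar surface, whose height fluctuates by a
static, seeded, per-bin offset of amplitude h_ran = 0.1 µm (this roughness
breaks planar symmetry and seeds buckling).  A weak Stokes drag −η·v (and
rotational drag −η_rot·ω) acts on every cell.  The standard friction set is
μ_ca = 0.8, μ_cc = 0.1, γ_cc,t = 10⁴ µm⁻¹h⁻¹.  At physically realised
sliding speeds the static branch always exceeds the cap, so the tangential
force is the velocity-independent dynamic friction — the regime responsible
for the growth-rate-proportional radial expansion speed.

**Cell-level surface tension.**  The colony height h(x,y) is the per-bin
(1 µm) upper envelope of cell tops, smoothed with a 3×3 mean over *occupied
bins only* (so the film hugs the colony and h ≡ 0 outside the footprint);
the liquid level is h_w = h + δh.  A cell whose top exceeds h_w by δz feels
a restoring force normal to the smoothed liquid surface, ramping linearly
from 0 to π·γ_surf·w₀ over 0 < δz < w₀/10 and saturated beyond.  The force
is applied at the centroid of the protruding part of the cell axis: the
center for a level cell, near the tip for a tilted one.  (Applying it at an
end cap of a level protruding cell would act as a see-saw and lever the
other end out of the monolayer.)

### Calibrated constants

Quantities with no published value are fixed once by explicit criteria:

| constant | default | criterion |
|---|---|---|
| E* (k_n = 424) | 900 γ_surf/w₀² | overlap under the saturated surface-tension load ≤ 0.05 w₀ |
| γ_n | 2.0 | growth-driven contact separation speed k_n·δ/γ_n ≫ elongation speed (~3 µm/h) at quasi-static overlaps, while keeping contacts near critically damped |
| M (fictitious mass) | 10⁻³ | contact oscillation period ~100 inner steps; damping ratio ζ ≈ 0.85 with γ_n above |
| I | M·l_div²/12 | consistent rod inertia |
| η, η_rot | 0.01 | drag ≪ friction at colony speeds (the paper's stated regime) |
| δh (film thickness) | 0.05 µm | hard-agar regime: half the roughness amplitude, so only cells riding high bumps are pressed down; sets the monolayer's frictional anchoring and hence the buckling width |

The damping choice is the one genuinely delicate point: if the normal
dissipation is too strong, newly divided cells cannot separate as fast as
they elongate, overlaps grow without bound and the contact normal of the
nearly collinear pair eventually rotates vertical, ejecting cells from the
monolayer hours too early.  The criterion above removes this failure mode
without affecting the quasi-static force balance.  All viscous contact-force
branches are additionally clamped to m_eff|v|/(2dt) so a dissipative force
can never reverse a relative velocity within one timestep; the dynamic
friction caps are unaffected.

## Nutrient field

The quasi-static concentration solves ∂C/∂t = 0 for D(r)ΔC − ρ₀λ(C)/Y with
D₋ = 600 µm²/s in the agar (z < 0), D₊ = 90 µm²/s in the colony region
(density-thresholded at 0.1 ρ_cell above the agar, air pockets filled), no
flux on all boundaries except C = C_s on the lateral agar wall, and
concentration/flux continuity at the agar–colony interface via harmonic-mean
face diffusivities.  ρ₀ = 0.68·ρ_cell is the constant-density approximation
of the colony biomass.  The nonlinear Monod sink is handled by Picard
iteration with a lagged coefficient (sink linearized as s(C_prev)·C, an SPD
system solved by Jacobi-preconditioned conjugate gradients), warm-started
from the previous outer loop, to a tolerance of 10⁻⁶·C_s.  A two-level mode
(coarse global grid + fine window around the colony with boundary values
interpolated from the coarse solution, cycled twice) stands in for fully
adaptive multi-resolution grids; the uniform-grid mode is the tested
default.

## Time integration

Velocity Verlet on Newton's law with the fictitious mass/inertia above, in
an inner loop of dt = 10⁻⁴ h; every `inner_per_outer` = 500 inner steps an
outer loop re-classifies the colony region, re-solves the nutrient field and
re-reads every cell's growth rate (a per-inner-step re-read from the static
field is available as `lambda_readout="inner"`; on early-colony runs the two
differ by well under 1%).  The height field is rebuilt every 20 inner steps
(cells move ≪ w₀ in between).  A per-step displacement guard (> w₀/2 raises
an error) catches instability.  One seeded generator drives all stochastic
draws in a documented order, so runs are bit-reproducible at fixed seed.

## Reduced models

The 1D vertical nutrient problem D₊C″ = ρ₀λ_S C/((C+K_S)Y) with C(0) given
and no flux at the top is solved in dimensionless form (u = C/K_S,
ζ = z/ℓ, u″ = u/(1+u)) by a collocation BVP solver; ℓ = √(Y·D₊·K_S/(ρ₀λ_S))
≈ 2.5 µm at defaults.  The profile drops quadratically while C ≫ K_S and
exponentially (length ℓ) once C ≪ K_S; the crossover C(H_S) = K_S defines
the growth-zone thickness (H_S ≈ 8.5 µm for a bottom concentration of
0.3·C_s — the ~10 µm growth-zone scale), and rescaling z by √λ_S collapses
profiles for different growth rates.  The vertical-speed estimate is VH = κ·H_S·λ_S with κ = 0.6 frozen
against the standard full run; the monolayer law Vr(Δr) = λ_S(W_b + Δr),
clipped at the inner edge, encodes mass conservation in the peripheral
annulus.

## Analysis conventions

Layers are center-height slabs of thickness w₀.  The colony edge is
azimuth-local: 36 sectors, edge radius = outermost bottom-layer center
+ w₀/2 per sector; signed edge distances Δr are measured from it.  R(t) is
the sector-mean bottom-layer envelope; H(t) is the smoothed height field at
the colony centroid; buckling time is the first time H > 1.5 w₀; W_b is the
mean of r₁ − r₂ over the fit window; fit windows default to the longest
suffix with linear-fit R² > 0.995.  Coarse fields use 4 µm boxes, cells
assigned by center: mass density, mass-weighted velocity, the principal axis
of the nematic tensor Q = ⟨n⊗n − I/3⟩ (headless), and the volume-weighted
virial pressure P_i = V_i⁻¹ΣF_ji·r_ji.  A cell is vertical when its director
is within 45° (inclusive) of the z axis.

## Image analysis

Height maps from intensity stacks threshold at a configurable fraction
(default 0.5) of the stack's maximum fluorescence; per column the height is
the topmost voxel above threshold.  Early-colony layer classification uses
the 5×5 stencil rule: n = above-threshold pixels in the truncated 5×5
neighborhood; type 1 (single layer) for 3 ≤ n < 16, type 2 (multi-layer)
for n ≥ 16; layer radii r_inner = s·√(N₂/π), r_outer = s·√((N₁+N₂)/π) with
s the µm-per-pixel scale (0.84 for the reference optics).  A synthetic
renderer rasterizes snapshots into stacks for round-trip testing; no
experimental images are required.

## Problem sizes

Simulation-backed checks use a desk-scale computational box (L = 100 µm,
agar depth 48 µm, headspace 32 µm, uniform 4 µm grid) — ample for colonies
up to the buckling transition (radius ≲ 50 µm, ≲10³ cells), where nutrient
depletion is marginal and the box mainly sets solver cost.  The packaged
defaults (L = 500, a = 250, b = 150 µm) match the full-study geometry;
`scripts/workstation_validation.py` runs the hours-long 20 h studies
(expansion-speed fits, growth-rate sweeps, dynamic-vs-static friction
discrimination) on that geometry.

## What the synthetic data do and do not show

The fixture generators (monolayer disks, cone colonies, linear
trajectories, stencil images, rod lattices) embed their ground truth by
construction, so analysis-layer tests are exact; they do not exercise
emergent mechanics.  The simulation tests do: monolayer persistence,
buckling onset near 7 h, and the early exponential count rate are emergent
outcomes of the standard parameter set, not programmed values.  What desk
runs do not probe: the linear-expansion era (t ≳ 12 h), large-colony
verticalization (~250 µm radii), and nutrient-limited interiors; those
belong to the workstation script.

## Known limitations

No cell death or lysis, no EPS, no agar deformation, no oxygen/pH
chemistry (the late, t > 24 h regime is out of scope).  The growth-rate
dependence of the division length is an exponential stand-in law normalized
to 3 µm at λ_S = 1/h.  The colony-height smoothing scale (1 µm bins, 3×3
mean) is the minimal "macroscopic" film; coarser smoothing would weaken the
short-wavelength restoring force.  Agreement of the 1D vertical reduction
with the 3D solver is geometry-limited (~10% on-axis for wide uniform
colonies).
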