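# Methods

`synthchip` models a chip-scale DNA-writing platform whose two pillars
are (i) a DRAM-like addressing IC that gives 10⁷ electrodes individual
voltage control through 145 pins, and (ii) a static-droplet-array (SDA)
microfluidic layer that traps one aqueous droplet over every electrode
so that electrochemically generated protons cannot reach neighbouring
synthesis sites.  This note records the models, their assumptions, the
tunable parameters and the numerical choices, in enough detail to judge
what a passing test does and does not demonstrate.

## 1. Addressing fabric

The array is `n_rows x n_cols = 3163 x 3163` electrode units at a
3.16 µm pitch (10⁷ units, ≈10⁷/cm²).  A 12-bit row decoder drives one
word line; 128 block decoders, each serving 25 columns, share a 5-bit
offset bus — 12 + 128 + 5 = 145 external pins.  One *instance* (one
charge interval, default 80 ns) can therefore energise at most 128
units: one per enabled block, all in one row, all at the same
within-block offset.

`schedule_mask` compiles an arbitrary boolean activation mask into an
ordered list of instances by iterating (row, offset) lexicographically
and enabling exactly the blocks whose unit is active.  Because every
column belongs to a unique (block, offset) pair, the schedule is an
exact cover: each active unit is selected exactly once.  A full-array
refresh takes `3163 x 25 = 79,075` instances = 6.326 ms at 80 ns each
(reported as 6.3 ms at the 2-significant-figure convention used for the
headline numbers).  Decoder sizing is fully parameterised so that a
10 x 10 test array exercises the same code paths as the full chip.

Indexing is 0-based throughout; the design's own worked example
(row bits `0b001010011010` = 666; block 44 with offset 11 selecting
column 44·25+11 = 1111) requires block indices to start at 0.  The
column decode space (128·25 = 3200) exceeds the 3163 physical columns;
the surplus outputs are treated as unconnected, so enabling them is a
silent no-op on decode and an error on encode.

## 2. Electrode capacitor dynamics

Each unit is a 1 pF storage capacitor behind an access transistor,
abstracted as an ideal switch in series with an on-resistance.  The
single time constant is **calibrated, not assumed**: from the design's
printed operating point — 3 V reached in 80 ns from a 5 V supply —
follows `tau_on = 80 ns / ln(5/2) = 87.31 ns` (R_on = 87.31 kΩ at
1 pF).  The same single-pole model then reproduces the second printed
point (≈1 V after 20 ns: the model gives 1.02 V) with no further
freedom, which is the main evidence the abstraction is adequate.
Programming the charge duration between 0 and 80 ns programs the
electrode between 0 and 3 V.

Off-state leakage is not quantified in the design; the default
`R_off = 2.5·10¹¹ Ω` gives tau_off = 0.25 s and hence a droop of
`1 − exp(−6.326 ms / 0.25 s) = 2.5 %` over one full-array refresh
period, comfortably inside the 5 % design bound, and is config-exposed.

Refresh is modelled as *charge-to-target*: the pulse ends when the
electrode reaches the programmed voltage.  A fixed-length 80 ns pulse
at 5 V applied to a partly charged capacitor would overshoot 3 V and
ratchet the periodic steady state toward the supply rail; holding a
designated level, as the design describes, implies the controller
terminates at the set-point.  With this model the refresh waveform has
identical peaks from the first cycle on and the peak-to-trough ripple
is exactly `1 − exp(−t_off/tau_off)`.

Electrode voltage is taken equal to capacitor voltage and the
electrochemical load current is neglected (it is not quantified in the
design); droop under load is therefore outside the model.

## 3. Synthesis-cycle orchestration

Phosphoramidite synthesis extends each site one base per cycle; within
a cycle the four nucleotides flow in fixed A→C→G→T sub-steps.
`cycle_plan` puts every unfinished site in exactly the mask of its next
required base, so the four masks are pairwise disjoint and their union
is the unfinished-site set (an exact cover that the tests verify by
brute force).  For uniform-random sequences each mask holds N/4 sites
in expectation — the regime behind the design's 2.5·10⁶-of-10⁷
activation estimate.  `run_synthesis` drives the scheduler for each
sub-step, loops the schedule as a refresh for the whole electrochemical
hold time (default 60 s, a typical deprotection duration; config), and
its bookkeeping identity — synthesized product equals target at every
site — is asserted in tests.  `confinement_audit` applies the
droplet-confinement rule: a site deprotects iff activated *and* its
chamber holds a confined droplet; in the no-droplet ("unconfined")
mode activation flags the four neighbours as at-risk, a qualitative
crosstalk indicator only.

## 4. Two-phase flow in the static droplet array

### Physical model

2D incompressible two-phase flow of FC-3283 (continuous; µ = 1.365
mPa·s, ρ = 1820 kg/m³) and water (dispersed; 1.0 mPa·s, 1000 kg/m³)
with interfacial tension σ = 0.040 N/m (not a measured device property;
a typical surfactant-free fluorocarbon/water value, config-exposed) and
a static 135° contact angle (measured through the water) on all walls.
At the unit scale (µm) and injection speed (3 mm/s) the dimensionless
groups are Re ≈ 4·10⁻³ and Ca ≈ 1.0·10⁻⁴: creeping, strongly
capillarity-dominated flow.  The momentum equation is therefore solved
as unsteady Stokes (convection dropped); density enters only through
the negligible transient term and is taken constant.

### Discretisation

MAC staggered grid, uniform cells (default 32 per 3.16 µm pitch ≈
0.1 µm; 64 for the fine mode).  Interface: conservative level-set
volume fraction with minmod-limited conservative advection and
Olsson–Kreiss compression–diffusion re-sharpening (ε = 0.7 h, two
pseudo-steps per step).  Surface tension: continuum-surface-force at
faces, `f = (σ/ ...) κ ∇φ`, with curvature computed from a twice
box-smoothed φ, clipped at the grid-resolvable 0.5/h, and averaged
along the interface band weighted by |∇φ|² (three passes) — the
smoothing that keeps parasitic currents from shredding droplets at
Ca ~ 10⁻⁴.  The contact angle enters through ghost values of φ in wall
cells (`∂φ/∂n = cosθ |∇_t φ|`), written double-buffered so the sweep
order cannot bias the ghosts.

Time integration is an IMEX pressure-correction scheme:

* implicit backward-Euler viscosity, with a Hysing-type interfacial
  viscosity `β = (σ Δt/µ_c U) |∇φ|` added to the operator — the
  semi-implicit surface-tension stabilisation that removes the explicit
  capillary time-step limit (which would be ~ns here);
* **incremental** pressure correction (the current pressure gradient is
  in the momentum solve and the projection solves for the increment).
  This matters at creeping flow: the non-incremental form has an
  O(Δt/Re) splitting error that destroys both the steady state and the
  discrete CSF/pressure balance.  With the incremental form a static
  droplet admits the exact discrete equilibrium ∇p = f and the computed
  Young–Laplace jump converges to within a few % of σ/R;
* a direct sparse factorisation of the pressure Poisson operator,
  refactorised only when a capillary check valve opens or closes;
* adaptive Δt = min(0.25 h, 0.3 h/|u|_max).

Jacobi-preconditioned CG solves the velocity systems (tolerance 1e-7).

### Sub-grid capillary features

The 0.2 µm capillary valve and its drain slot are 1–3 cells wide — far
below what the interface scheme can hold a meniscus against — while
their theoretical aqueous entry pressure (2σ|cosθ|/w ≈ 2.8·10⁵ Pa)
exceeds any pressure the device develops (the neck yields at about
half that first).  The drain is therefore modelled as a capillary
check valve: dispersed-phase fluxes never cross its faces (it passes
only oil), and the moment the aqueous front seals its chamber-side
mouth all its faces become walls — in the viscous solve, in the
advection, *and in the pressure projection* — so the injected flux is
rerouted instead of being forced through it.  It reopens if the water
retreats.  The neck (0.3 µm, ~3 cells) is left hydrodynamically free;
at this resolution its discrete entry pressure is lower than the
theoretical value, a known under-representation discussed under
limitations.

### Interface hygiene

Three standard interface-capturing safeguards keep the dispersed mass
honest: fragments smaller than 5 cells are deleted periodically (they
carry grid-scale curvature and inject force noise); φ over/undershoots
are folded back into neighbouring cells by a local mass-conserving
redistribution before any clipping; velocities are capped at 60 U (far
above the ~15 U physical maximum) to contain the transient when a
valve toggles.  Deleted debris and residual clipping are accumulated
and reported; the global audit (area + outlet flux vs initial area)
closes to within a few percent on the 4×4 run, with the residual
dominated by clipping at barrier faces during the violent fill and
severing events.

### Geometry and its calibration

One SDA unit per 3.16 µm tile: a seam corridor (height = `mouth_width`)
runs along the top of the reaction chamber — a pocket open to the
corridor over its full width — with the neck rising from the corridor's
upstream corner into the bypass leg that crosses the tile and descends
into the next seam, and the oil drain (valve + slot) leaving the
chamber's bottom corner.  Filling is sequential: the advancing aqueous
front pours into the chamber (the widest opening, lowest entry
barrier), the displaced oil leaves through the drain until the front
seals it, the pressure rises until the neck admits the water into the
bypass, and the process repeats one unit downstream.  When the plug
tail recedes, the through-path hugs the cavity's top strip, the thread
severs there, and the chamber keeps its droplet.

The reference design prints the pitch, the valve width and the fluid
conditions,
but not the chamber, mouth, neck or channel dimensions.  Those were
calibrated against the printed steady droplet areas (1.99 µm² first
column, 1.74 µm² later columns) in the same spirit as the R_on
calibration in §2: the robust, flux-driven part of the fill delivers a
fixed dispersed volume per chamber at the stated conditions, so the
chamber area is chosen to make that volume the right fraction of it.
Defaults: chamber 1.78 × 1.3 µm, mouth 0.4 µm, neck 0.3 µm, channel
0.6 µm, bypass leg 0.4 µm, walls 0.2 µm, dispersed plug 3× the total
chamber volume.  All are config-exposed.

### What the simulation does and does not show

The model reproduces, from the resolved physics plus the documented
sub-grid valve rule: sequential capillary filling, oil venting, thread
severing at the tail, one confined stationary droplet per chamber with
area a stable fraction of the chamber, and clear bypass channels at
steady state.  It is a 2D model on a coarse (0.1 µm) grid: meniscus
pressures of features narrower than ~5 cells are under-resolved, the
post-formation droplets still creep by ~1 %/flush-through from residual
interface noise, and effects that depend on depth, on surfactants, on
electrowetting or on proton chemistry are outside the model entirely.
Reproduction of the printed droplet areas is therefore assessed with a
±15 % band, and the relative ordering of the column means (the
design's slightly larger first column) is sensitive to unprinted
geometry and protocol details.

### Problem sizes used

The acceptance-scale droplet run is the design's 4×4 array at 32 cells
per pitch with an injection channel sized to the plug, integrated for
up to 16 nondimensional time units (≈5.3 ms of physical time, two
flush-throughs past the tail exit); validation oracles (Young–Laplace,
Poiseuille, rigid advection) run on 32–128-cell grids, and the grid
refinement check compares a single unit at 32 and 64 cells per pitch
over the formation transient.

## 5. Synthetic inputs

`fixtures` generates all test inputs programmatically: Bernoulli
activation masks (fraction 0.25 emulates one base sub-step of a
uniform-random oligo set), uniform-random A/C/G/T oligo sets, and
synthetic droplet censuses (labelled as such) for exercising the
orchestrator without a flow run.  Generators are pure functions of
(spec, seed); per-module streams are split from one master seed with
`numpy.random.SeedSequence`.  These fixtures emulate composition, not
biology: no GC bias, no synthesis errors, no length heterogeneity
beyond what a test constructs explicitly.
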