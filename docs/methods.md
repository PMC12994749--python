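# Methods

## Model overview

`blebsim` simulates a single cell that moves by blebbing — pressure-driven
membrane protrusions nucleated by local loss of membrane–cortex cohesion —
either swimming freely in a viscous or viscoelastic medium, or combining
blebs with transient substrate adhesions (the hybrid amoeboid–mesenchymal
mode). The model is two-dimensional and built so that the cell exchanges
momentum with its surroundings consistently: every internal force appears in
an equal-and-opposite pair, and the body force handed to the fluid solver
integrates to zero over the domain at every step (checked, not assumed).
Only substrate adhesions break this symmetry, deliberately: their reaction
is absorbed by the substrate and reported as traction.

### Fluid

The intracellular and extracellular spaces form one incompressible,
inertialess fluid on a periodic square grid,

    eta_f lap(v) - grad(p) + div(sigma_p) + F = 0,      div(v) = 0,

solved spectrally (FFT projection, zero-mean velocity and pressure; Nyquist
modes are annihilated so the discrete divergence vanishes identically).
Periodicity approximates an unbounded medium; the default box is four cell
diameters so image interactions are small. The viscoelastic stress follows
FENE-P: a conformation tensor `kappa_p` per grid node with relaxation time
`lambda_p(x)` and polymer viscosity `eta_p(x)` assigned inside/outside the
membrane polygon (smoothed indicator, one-cell band), evolved with explicit
relaxation/stretching and semi-Lagrangian advection. SPD-ness and the
extensibility bound `tr(kappa) < L_p^2` are enforced by an eigenvalue floor
(1e-8) and trace ceiling ((1-1e-6) L_p^2); every clamp is counted on the
state. Setting `eta_p = 0` (or `newtonian: true`) recovers a Newtonian
medium.

### Membrane, cortex, linkers, osmosis

The membrane is a closed chain of nodes carrying Hookean segment tension,
a quadratic-curvature bending force, Hookean linker forces toward the
paired cortex node, and an osmotic force `(Pi_in - Pi_out) n ds`. The
cortex is a second closed chain with per-node actin (`n_act`) and myosin
(`n_myo`) amounts: segment elasticity `kappa_c * n_act_seg * (L - L0)`,
active contractile tension `f_myo * n_myo_seg * S_osc(t) * (1 - v_short/v_myo)`
(linear force–velocity, clamped to [0, 1.5] stall), and a cytoplasmic drag
`Gamma = gamma0 * n_act` representing flow through the porous meshwork. The
cortex is massless: `Gamma (v_c - v_f) = F_el + F_act + F_linker` gives its
velocity, and the same right-hand side is the force it transmits to the
fluid, so cortex–fluid momentum exchange is exactly antisymmetric. Because
this balance becomes stiff when the drag is small, cortex positions are
sub-cycled (8 substeps per fluid step) with frozen fluid velocity.

Both chains couple to the grid through the 4-point Peskin kernel; the same
kernel is used for spreading and interpolation, so spreading conserves
total force to round-off and interpolation is exact on linear fields. The
membrane is advected with the no-slip interpolated velocity plus an
optional osmotic water flux `permeability * (Pi_in - Pi_out -
balance_offset) n`, which reproduces osmotic swelling/shrinkage experiments
(with zero permeability, enclosed area is conserved to discretization
error). `Pi_in` can be fixed (swimming protocols) or van 't Hoff,
`osmolyte / area` (osmotic protocols).

### Stochastic kinetics

Linkers bind force-independently at `k_adh_on` per free site (optionally
polarised by `1 + 0.2 sin(theta_c)`) and unbind by Bell's law
`k_off0 * exp(F/F_b)` evaluated at the current per-linker tensile force.
Updates are fixed-step tau-leaps (binomial removals, Poisson additions)
synchronized with the fluid step; passing no RNG selects the mean-field
(expected-value) limit used by the deterministic single-bleb protocol.
Attached cortex nodes undergo birth–death turnover around `n_act_bar`;
myosin binds from a finite cell pool in proportion to local actin. Detached
cortex decays first-order with no assembly, at its own rate `k_act_decay`;
this is deliberately faster than the attached turnover because the two
rates pace different phases of the bleb cycle — cortex clearance ends
expansion, cortex regrowth paces retraction — and the biological
counterparts (bleb cortex disassembly within a second; myosin II
recruitment over several seconds) are far apart. All kinetic rates scale as
`1/K_tau`, so larger `K_tau` means slower cortex turnover throughout.

A nucleation event is logged when a contiguous fully-detached membrane arc
first exceeds a threshold (3 nodes), with a 0.5 s refractory window and an
overlap rule preventing double counting; the event angle is the
centroid-relative polar angle of the arc midpoint.

### The bleb cycle

At equilibrium the intracellular osmotic excess (`Pi_in - Pi_out`, set to
the Laplace pressure of the resting active cortical tension) loads the
linkers. Breaking an arc of linkers (by hand in the single-bleb protocol,
by Bell-law escape in the stochastic ones) lets the pressurized cytoplasm
inflate a bleb at several um/s; the orphaned cortex is dragged inward and
disassembles; after a recruitment delay a fresh cortex seeds beneath the
bleb membrane (`seed_fraction * n_act_bar`, chosen safely above the death
threshold so reseeded nodes survive their first steps), regrows, re-binds
linkers and hauls the membrane back. In a Newtonian medium the cycle is
nearly reciprocal and the settled net displacement is a small fraction of
the peak in-cycle displacement (the scallop theorem); a viscoelastic
medium breaks this reversibility and leaves a larger net displacement.

## Parameters

Lengths in um, time in s, force in pN; viscosities are depth-integrated 2D
values (eta_f in pN s/um^2). The polymer parameters printed with the
reference single-bleb protocol are `eta_p = 1`, `lambda_p_in = 100 s`,
`lambda_p_out = 10 s`. Parameters with no published value (fluid viscosity,
membrane and linker stiffnesses, kinetic rate constants, `L_p`, cortex
porosity drag) were calibrated once so the resting cell is mechanically
balanced and the single-bleb cycle operates at the reported scales — bleb
expansion 5–10 um/s, cycle ~2.5 s, cortical tension a few hundred pN/um —
and then frozen in the preset files. Key defaults:

| parameter | value | meaning |
|---|---|---|
| radius | 10 um | resting cell radius |
| domain | 80 um, 128^2 (single-bleb) / 96^2 (swim) | periodic box |
| eta_f | 0.25–0.5 | solvent viscosity |
| kappa_c | 0.1 pN/um per actin | cortical stiffness per unit actin |
| n_act_bar | 2e4 | actin units per cortical node |
| f_myo | 4–8 pN | stall force per myosin motor |
| v_myo | 0.5 um/s | unloaded shortening speed |
| gamma0 | 1e-3 pN s/um per actin | cortex porosity drag |
| k_act_decay | 8 /s | detached-cortex disassembly |
| k_act_on/off, k_myo_on/off | 1 /s | attached turnover |
| K_tau | 1 (physiological); 4 in the single-bleb/hybrid presets | turnover factor |

The stochastic protocols coarse-grain the linkers into 5 clusters per node
of 40 pN/um each (same total stiffness as 20 x 10 pN/um): with 20
independent weak linkers the per-node occupancy noise never crosses the
Bell runaway threshold at tractable resolutions, and no blebs nucleate;
five clusters reproduce the fluctuation scale that makes nucleation a
stochastic barrier-crossing. The Bell parameters (`F_b ~ 0.7 pN`,
`k_off0 ~ 0.01-0.02 /s`) are set so the stationary occupancy sits just
above the runaway threshold computed from the measured equilibrium
per-linker load (~2.8 pN).

## Protocols

* `single_bleb` — mean-field kinetics (deterministic), 1 s pre-equilibration,
  forced detachment over a 36 deg arc at t = 0, run to the duration cap.
  Net cycle displacement is read at the end of the run, after the
  post-retraction relaxation; the bleb-area < 5% marker only flags cycle
  completion. End of expansion is detected causally as the first
  few-percent decline of the 20 ms-smoothed bleb area from its running
  maximum; the peak bleb-front speed is the 20 ms backward difference of
  the front radius over the expansion phase (window chosen above the
  numerical noise scale, below the physical burst duration).
* `stochastic_swim` — tau-leap kinetics, Newtonian fluid, optional square-wave
  contractility signal S_osc (period 10 s, duty 0.5, low level 0.2). "No
  oscillation" means S_osc held at the high level (sustained high
  contractility), which is the comparison the oscillation experiments make.
* `hybrid` — single-bleb machinery plus adhesion clutches anchored over the
  bleb arc (or rear/uniform) when the bleb front speed falls below 5% of its
  peak; clutch/substrate springs in series; exponential unbinding (3 s mean);
  the substrate reaction is removed from the fluid force as a uniform
  density and recorded as traction.

## What the synthetic data do and do not show

The track/event fixtures (Brownian and ballistic tracks with known D or v,
Poisson event logs with uniform angles) validate the estimators exactly:
MSD, origin-constrained D_eff (slope/4, 16 s window), nu_bleb, wrapped
p_bleb, first-passage walking speeds. They contain no localization noise,
no drift, no track gaps and no segmentation errors, so passing them says
the estimators are correct, not that they are robust to imaging artifacts.
Simulated cells are 2D and nucleus-free; absolute motility coefficients are
upper bounds on what the same mechanics would do in 3D against a nucleus.

## Numerical choices

Explicit first-order operator splitting; dt is limited by the membrane
spring relaxation (eta_f h / k_t, kept >= 3 dt) and the kinetic tau-leap
condition (fastest rate x dt < 0.1, validated at config load). Membrane
spacing is kept inside [0.5h, 2h] (checked every 25 steps; violation is an
error, never a silent remesh). Self-intersection after advection rejects
the step and retries with up to 3 substep halvings. The conformation
update counts every SPD/FENE clamp. Reported problem sizes for routine
testing are 64^2–96^2 grids with 48–64 membrane nodes, short horizons and
small ensembles; the presets carry the full-resolution settings.

## Known limitations

* 2D; no nucleus, no confinement, no walls or steric contacts.
* The net viscoelastic single-cycle displacement is sensitive to the
  unpublished solvent/polymer parameter split and to grid resolution: the
  implemented medium gives a robust sign (viscoelastic > Newtonian net
  displacement at physiological turnover; Newtonian net < 1% of the peak
  in-cycle displacement) but the magnitude varies severalfold between the
  64^2 and 128^2 grids. Grid-refinement consistency of the single-bleb net
  displacement is not achieved and is checked nowhere; treat absolute
  displacement magnitudes as order-of-magnitude.
* Peak bleb-front expansion speeds at the test resolution are ~2 um/s,
  slower than the few-um/s bursts the mechanism is thought to produce;
  pushing the driving higher destabilizes the explicit membrane coupling.
* Sustained high contractility in this model keeps producing effective bleb
  cycles indefinitely (the osmotic drive never depletes and the cortex
  reseeds), so the model swims persistently without contractility
  oscillations; oscillations are not required here, unlike the motivating
  phenomenology.
* Bleb nucleation frequency decreases monotonically with cortical stiffness
  over the numerically stable range; the stiff-cortex rupture mode that
  would make it biphasic is not captured, and kappa_c >~ 1 pN/um per actin
  destabilizes the explicit cortex integration.
* Bleb nucleation statistics at coarse membrane resolution depend on the
  linker clustering granularity; frequencies are tuning-sensitive.
* Adhesion clutches form instantaneously at end-of-expansion; no
  force-dependent clutch unbinding by default.
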