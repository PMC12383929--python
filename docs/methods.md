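# Methods

## Scope and structure

`tearsim` couples four layers, each usable on its own:

1. **geometry** — five prism subregions (upper/lower fornical sacs,
   upper/lower menisci, exposed tear film) plus two cylindrical canaliculi,
   discretized into a connected Q3D segment network;
2. **blink_dynamics / evaporation** — per-region water and osmole balance
   through interblink → closure → deposition phases under a piecewise
   timestep policy;
3. **drainage** — the deformable-tube canalicular radius PDE with
   phase-switched boundary conditions and the volume-difference drainage
   rate;
4. **species_transport / eye_pk** — suspension instillation, dissolution,
   network convection–diffusion, and a 17-compartment whole-eye sink.

## Geometry

Derived quantities: initial tear-film volume `V_TF0 = SA_exp · w_TF`
(220 mm² × 18.59 µm = 4.09 µL), depth `d = L_lid/2 = 28.5 mm`, film height
`h_TF = SA_exp/d = 7.72 mm`. Meniscus volumes are cross-section × depth
(`SA_UM·d`, `SA_LM·d`). Fornical-sac volumes are not tabulated anywhere we
know of; we take height × base width × depth (`h·w_BF·d`), consistent with
the prism construction, and the sac cross-section tapers linearly from
`w_BF` to `w_LA` toward the lid margin (the two tabulated widths admit no
more detailed profile). Basal volume ratios normalize the five region
volumes and double as the post-blink redistribution rule. The five-region
basal total is 17.37 µL with these assumptions — higher than the ~7 µL
often quoted for the precorneal tear volume because the sac construction is
generous; all downstream behavior is driven by ratios and fluxes, not the
absolute total.

Flow orientation follows the physiological path: sacs → menisci → tear
film, menisci → canaliculi; cells are indexed from the upstream end.
Tear-film segment counts of 10–20 resolve concentration gradients without
measurable cost; counts outside that band only warn.

## Blink-cycle balance

Phases: interblink 5.5 s, closure 0.04 s, deposition 0.18 s (cycle 5.72 s).
The full antecedent water/salt-balance equation set is not reproduced here;
we implement the minimal balance that yields every asserted qualitative
behavior: secretion (default `Q_lacrimal` = 1.0 µL/min at `C_iso` =
302 mOsM — basal physiological values, chosen so secretion ≈ drainage +
evaporation) enters the sacs and passes through to the menisci; drainage
withdraws from the menisci at local osmolarity; evaporation (constant
0.2 µL/min, the literature mean for dry-eye patients) removes water only
from the exposed film during the interblink and is zeroed while the lids
cover the film. Closure pools all five regions into one well-mixed
osmolarity ("mix completely"); deposition repartitions total volume by
basal ratios. Both operations conserve volume and osmoles exactly.

Cycle-averaged drainage is withdrawn during the interblink scaled by
`t_blinkcycle/t_interblink`, so each cycle's drained volume equals the
drainage model's Eq.-1 value.

**Limit cycle.** With constant rates the per-cycle volume change would be a
constant drift. The coupled runs therefore scale each meniscus curvature
radius with its fill fraction (`R_m,i ∝ V_i/V_i,basal`, clipped to
[0.2, 5]): an underfilled meniscus has a tighter curvature, pulls harder on
the canaliculus, and refills it less, reducing drainage. This closes a
stabilizing feedback loop whose equilibrium drainage is
`Q_lacrimal − Q_evap ≈ 0.8 µL/min`, inside the 0.7–0.9 band, and makes the
cycle-boundary states contract geometrically onto a limit cycle.

**Timestep policies.** A policy is a set of `(t_start, t_end, dt)` windows
tiling one cycle. The scheduler walks each window with `ceil(span/dt)`
uniform steps; a step straddling a phase boundary is split internally for
the physics but counts as one accepted step (so a one-step-per-cycle policy
is well defined). The uniform 1 ms baseline takes exactly 5720 steps per
cycle. The printed step totals of some benchmark schedules cannot be
reproduced from their window definitions by direct enumeration (the
window/rounding semantics behind those totals are unstated); only the
uniform baseline count is asserted. All benchmark policies agree with the
baseline's cycle-boundary volumes and osmolarities to ~1e-9 relative —
far inside the 1% preservation requirement — because the interblink
dynamics they coarsen are mild.

## Canalicular drainage

Wall law `p = p_ext + bE (R − R_0)/R_0²` with `bE = 2.57 Pa·m` (porcine
zero-frequency elastic estimate), lubrication (Poiseuille) flow
`q = −(πR⁴/8µ) ∂p/∂x`, and cross-section conservation give

    ∂R/∂t = (bE / (16 µ R_0²)) (1/R) ∂/∂x (R⁴ ∂R/∂x).

The printed general form of this equation is typographically ambiguous in
its exponent grouping; the Newtonian reduction above (n = 1, K = µ) is the
one used for all default results, and a general power-law flux
(`q ∝ R^(3+1/n) |∂p/∂x|^(1/n−1) ∂p/∂x`) is available behind an explicit
adaptive-substep path flagged experimental.

Sign convention: transmural pressures that contract the duct are negative.
The blink phase applies the squeeze magnitude `p0 − psac` (400 Pa) as a
contracting external load with the punctum blocked (`q(0)=0`) and the sac
end open (`p(L_c)=0`); the interblink applies meniscus suction `−σ/R_m` at
the punctum with the sac end closed. Both steady radii then sit below
`R_0 = 0.25 mm`, the only convention compatible with the reported
0.240–0.248 mm range. We read `p0` as the blink squeeze magnitude (its
"initial pressure" reading reproduces no sub-`R_0` blink radius).

**Calibration.** σ and `R_m` are not tabulated. We fix σ = 0.0445 N/m
(literature tear surface tension) and calibrate the two meniscus curvature
radii once — `R_m` = 0.14 mm (upper), 0.15 mm (lower) — so that the
interblink steady radii (0.2423/0.2428 mm) and the summed Eq.-1 drainage
(0.861 µL/min) sit inside the reported bands with the larger, slacker lower
meniscus draining more (0.48 vs 0.38 µL/min). These values live in the
default config and were not revisited.

**Numerics.** Second-order central differences on 51 nodes (default),
backward-Euler in time with lagged nonlinear coefficients (unconditionally
stable tridiagonal solve via `scipy.linalg.solve_banded`). The diffusivity
scale `bE·R_0/16µ ≈ 0.027 m²/s` equilibrates the 12 mm duct in ~10 ms, so
each phase reaches its analytic steady state; the integrator detects this
(per-step drift < 1e-13 m) and freezes the profile for the remainder of the
phase, making multi-cycle runs cheap and exactly periodic from cycle 2. A
phase that ends unsettled warns with the residual norm. End-of-phase
profiles match the analytic steadies to ≲1e-6 relative (asserted at 0.1%);
transient profiles converge at second order in the grid spacing
(Richardson ratio ≈ 4).

**Monotonicity.** Drainage is non-increasing in `bE` (stiffer walls deform
less; this holds below the analytic turning point `1/(a+b)` in compliance,
which default parameters satisfy) and non-increasing in `σ/R_m`: stronger
suction holds the duct more contracted during refill, shrinking
`V_interblink − V_blink`. The intuition "stronger suction drains more" is
not what the steady-state structure implies, and the numerical grid test
confirms the decreasing direction.

## Species transport and dissolution

Instillation (default 35 µL / 35 µg of 0.1% dexamethasone suspension,
solution phase saturated at `Cs`) triggers reflex-blink mixing: drop and
resident tears pool, volume above `V_max` = 25 µL leaves as spillover at
the post-mixing uniform composition (drug mass in proportion), and the
retained volume repartitions by basal ratios.

Dissolution is diffusion-limited shrinking-sphere (Sherwood number 2)
kinetics for a monodisperse population (r = 1.5 µm, ρ = 1300 kg/m³):
`dM/dt = 3 M D (Cs − C)/(ρ r²)`, capped so `C ≤ Cs` and `M ≥ 0`, with
`r ∝ M^(1/3)` at fixed particle number. The closed form under a perfect
sink is `r²(t) = r0² − 2 D Cs t/ρ`, frozen as the test oracle. Molecular
diffusivity comes from a Stokes–Einstein estimate at 35 °C
(≈ 6e-10 m²/s for MW 392.5) and is config-exposed. Excipients enter only
through the excipient-enhanced solubility `Cs` = 100 µg/mL; there is no
separate excipient species.

Drug amounts are stored as per-segment masses, so dilution by secretion
and concentration by evaporation fall out of the water balance; transport
is upwind finite-volume advection along the network flows plus Fickian
neighbor exchange, explicitly stepped with a CFL bound that includes both
advective and diffusive conductances. Particles advect and mix like
solutes and drain freely at the punctum (the 2 µm duct entrance versus
3 µm particle diameter is borderline; a config switch disables particle
drainage). In the large-diffusivity limit the network trajectory matches a
single stirred-tank washout oracle to <0.5%.

After instillation the tear concentration reaches the solubility plateau
within ~25 s and sits just under `Cs` (secretion continuously dilutes;
particles replenish) until the particle reservoir is exhausted by
dissolution and washout (~1 h), then decays exponentially with the tear
turnover time — plateau-then-decay, monotone after the peak over the
six-hour window.

## Whole-eye model

Seventeen compartments (3 cornea layers, conjunctiva, aqueous humor, lens,
iris–ciliary body, vitreous, choroid, sclera, and the 7 retinal layers NFL
→ RPE chained linearly) exchange by permeability-limited first-order
kinetics `J = PS (C_a − C_b/K)`. The tear film feeds the corneal
epithelium using the tear–epithelium distribution coefficient `K_D` = 2.5
(its exact interface assignment is ambiguous in the source material; we
apply it at the cornea), and the fornical sacs feed the conjunctiva. The
PS, volume and clearance values shipped are order-of-magnitude placeholders
(e.g. aqueous turnover 2.5 µL/min, choroidal clearance 10 µL/min) intended
for recalibration against user data: the simulator's quantitative surface
is the tear film, and the eye functions as a conservative, calibratable
sink. Melanin/protein binding and metabolism are omitted. Mass across tear
film + eye + sinks is conserved to 1e-9 relative.

## Validation metrics and synthetic data

`r_squared` (1 − SS_res/SS_tot), `rmse`, and `aard`
(100·mean|pred−obs|/obs) operate on paired series with an optional time
window (clinical validation is typically restricted to ≤6 h, where late
samples are above the assay floor). The clinical dexamethasone series used
for published validation is not redistributable, so the package ships a
SYNTHETIC generator (`metrics.synthetic_observed_series`): plateau at the
solubility limit, first-order decay (half-life 1 h), lognormal noise
(CV 25%) on the standard 0.25–24 h sampling grid. It mimics only the
profile shape — not between-subject correlation or assay error structure —
so metric tests exercised on it demonstrate the computational path, not
clinical agreement. Users supply their own observed CSV
(`time_h, conc_ug_per_mL[, sd]`) via `tearsim fit-metrics`.

## Problem sizes and determinism

Default runs: 51 canaliculus nodes, 16 Q3D segments (12 tear-film), 4–10
blink cycles for drainage summaries, and a coarse two-window policy
(0.25 s interblink / 0.02 s blink steps) for multi-hour dosing runs — a
six-hour dosed simulation takes about a minute on one CPU, and the
acceptance script a few seconds. The physics path uses no random numbers;
repeated runs are bit-identical. Randomness exists only in the synthetic
fixture generator and is fully seed-controlled.

## Known limitations

- Lid motion is a discrete three-phase regime, not continuous kinematics.
- Evaporation is a calibrated constant, not a physics-based flux model;
  the two calibration coefficients are carried as metadata only.
- The viscoelastic (frequency-dependent) canalicular wall is reduced to
  its zero-frequency elastic modulus; no lacrimal-sac back-pressure.
- Single-layer aqueous film: no lipid/mucin partitioning.
- Eye-model parameters are placeholders pending user calibration; no
  systemic (whole-body) linkage.
- The general-n power-law drainage path is experimental; all shipped
  results use the Newtonian reduction.
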