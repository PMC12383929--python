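# tearsim

A fast-running, mechanistic simulator of the blinking human tear film,
coupled to a whole-eye compartmental pharmacokinetic model. It is aimed at
ocular drug-delivery modellers who need spatially resolved precorneal
kinetics — instillation, spillover, suspension dissolution, blink mixing,
nasolacrimal drainage and evaporation — without the cost of a full 3-D
finite-element model.

## What it models

The ocular tear fluid is represented as a quasi-3D (Q3D) network: five
prism subregions (upper/lower fornical sacs, upper/lower menisci, exposed
tear film) discretized into 10–20 segments, resolved along the flow axis
and well-mixed transversely, plus two cylindrical canaliculi that drain the
menisci toward the lacrimal sac.

**Blink cycle.** Each cycle is interblink (5.5 s), lid closure (0.04 s) and
deposition (0.18 s), i.e. $t_{\text{cycle}} = 5.72$ s. During the
interblink, lacrimal secretion $Q_{\text{lac}}$ enters the sacs and passes
to the menisci, drainage withdraws from the menisci, and evaporation
removes water (not osmoles) from the exposed film at a calibrated constant
0.2 µL/min. Closure pools all regions to a single well-mixed composition;
deposition repartitions the total volume by the basal volume ratios.
Integration uses piecewise-constant timestep policies tiled over the cycle
(fine steps around the blink, coarse during the interblink); all supplied
policies reproduce the uniform-1-ms baseline to well within 1%.

**Canalicular drainage.** Each canaliculus is an elastic tube with wall law
$p = bE\,(R - R_0)/R_0^2$ and lubrication flow, giving the nonlinear
diffusion equation

$$\frac{\partial R}{\partial t} = \frac{bE}{16\,\mu R_0^2}\,
\frac{1}{R}\frac{\partial}{\partial x}\!\left(R^4
\frac{\partial R}{\partial x}\right)$$

with phase-switched boundary conditions: the blink squeeze
($q(0)=0$, $p(L_c)=0$) contracts the duct toward
$R_b = R_0\,(1 - (p_0 - p_{sac})R_0/bE)$, and meniscus suction during the
interblink ($p(0) = -\sigma/R_m$, $q(L_c)=0$) lets it refill to
$R_{ib} = R_0\,(1 - (\sigma/R_m)R_0/bE)$. The per-cycle drainage rate is

$$Q_{\text{drainage}} = \frac{V_{\text{interblink}} - V_{\text{blink}}}
{t_{\text{blinkcycle}}}.$$

**Drug transport.** A suspension drop (default: 0.1% dexamethasone,
35 µL / 35 µg) is instilled with reflex-blink mixing; volume above the
25 µL holding capacity is lost to spillover with its proportional drug
mass. Particles dissolve by Noyes–Whitney shrinking-sphere kinetics
($\dot M \propto N r (C_s - C)$, capped at the solubility limit
$C_s = 100$ µg/mL), the dissolved phase moves through the Q3D network by
upwind convection–diffusion, and a 17-compartment eye model (3 cornea
layers, conjunctiva, aqueous humor, lens, iris–ciliary body, vitreous,
choroid, sclera, 7 retinal layers) acts as a permeability-limited
absorption sink.

## Worked example

```bash
$ tearsim count-steps --policy A --cycles 10
policy A: 57200 steps over 10 cycles

$ tearsim drainage-only --cycles 3
{
 "Q_total_uL_min": 0.8612215722088394,
 "Q_upper_uL_min": 0.3811870839325987,
 "Q_lower_uL_min": 0.48003448827624073,
 "radius_min_mm": 0.24027237354085604,
 "radius_max_mm": 0.24278534370946553
}
```

The summed nasolacrimal drainage rate settles at 0.86 µL/min — inside the
0.7–0.9 µL/min band and the physiological 0.1–4 µL/min window — with the
lower canaliculus draining more than the upper one, and end-of-phase steady
radii between 0.240 mm (squeezed) and 0.243 mm (refilled), below the
undeformed 0.25 mm radius.

Dosing from Python:

```python
from tearsim import run_simulation, load_config

cfg = load_config()
cfg["dosing"] = "formulation"          # 35 µL drop of the default suspension
cfg["simulation"]["n_cycles"] = 200    # ~19 min of simulated time
res = run_simulation(cfg)
print(res.summary["peak_tear_conc_ug_mL"])   # 99.679...
print(res.summary["drainage_rate_uL_min"]["periodic"])  # 0.8612...
```

The tear-film averaged dissolved concentration climbs to the 100 µg/mL
solubility plateau within ~25 s (the drop's saturated solution phase is
diluted on mixing, then the particle reservoir replenishes it) and decays
monotonically as particles wash out and secretion dilutes the film.
`res.frames["timeseries"]` holds the full per-region volume, osmolarity and
concentration traces; `SimulationResult.write(outdir)` exports CSVs and a
JSON summary including mass-, water- and osmole-balance residuals.

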