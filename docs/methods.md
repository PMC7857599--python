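# Methods

## Model

Two state vectors evolve in continuous time within each batch-culture
growth interval: species densities `S_i` (cells/ml) and mediator
concentrations `C_j` (fmole/ml). Mediators are produced at constant
per-cell rates `β_ij` (fmole·cell⁻¹·hr⁻¹), taken up with Monod-type
saturating kinetics at per-cell rate `α_ij`, and modulate growth rates with
a signed saturating term of amplitude `r_ij` (hr⁻¹):

```
dC_i/dt = Σ_j [ β_ij − α_ij · C_i/(C_i + K_ji) ] · S_j
dS_i/dt = [ r_i0 + Σ_j r_ij · C_j/(C_j + K_ij) ] · S_i
```

A single half-saturation matrix `K` (species × mediator) serves both the
uptake and the influence terms; the uptake term, indexed (mediator,
species), reads it transposed. The model assumes well-mixed batch culture
(no spatial structure), deterministic dynamics (no demographic noise), and
interactions carried exclusively by released chemicals.

The **resource variant** adds one shared substrate `R`: every species'
growth bracket is multiplied by `R/(R + K_R,i)` and
`dR/dt = −Σ_i α_R,i · g_i(t) · S_i` where `g_i` is the full realised growth
rate — resource consumption is proportional to realised growth. `R` is not
produced by anyone and is reset to the fresh-medium supply at every
transfer. As printed, the consumption law lets a species with a (transiently)
negative growth bracket release resource; with the default parameters this
does not occur in practice because the resource factor suppresses the whole
bracket before densities shrink appreciably.

### Units

Concentrations are fmole/ml internally; 1 nM = 1000 fmole/ml. This closes
the mediator balance dimensionally (fmole·cell⁻¹·hr⁻¹ × cells/ml =
fmole·ml⁻¹·hr⁻¹). Half-saturation constants quoted in nM are converted on
construction.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `n_species`, `n_mediators` | 20, 10 | pool size and mediator count |
| `r_i0` | U(0.08, 0.12) hr⁻¹ | basal net growth rate |
| `|r_ij|` | U(0, 0.2) hr⁻¹ | influence amplitude; sign facilitative with prob. `f_fac` |
| `β_ij` | U(0.05, 0.15) | per-cell production rate |
| `α_ij` | U(0.25, 0.75) | per-cell uptake rate |
| `K_ij` | U(50, 150) nM | shared half-saturation |
| `q_p`, `q_c` | 0.3, 0.3 | production / influence link probabilities |
| `f_fac`, `f_fac,inv` | 0.5, 0.5 | facilitative sign fractions (resident, invader); most experiment presets set `f_fac,inv` = 0.1 |
| `N_inoc → N_dil` | 10⁴ → 10⁷ cells/ml | growth range per cycle |
| `N_ext` | 0.1 cells/ml | extinction threshold, applied after each dilution |
| `N_gen` | 200 | generation target for assembly and for the assay |
| propagule fraction | 0.003 (grid 10⁻⁴–0.99, 20 log-spaced points) | invader inoculum relative to residents |
| `r_0,inv/r_0,res` | 1.5 | invader basal-rate advantage |
| `R_0` | 10⁶ fmole/ml (grid 10⁵–10⁷) | fresh-medium resource supply |
| `α_R,i` | U(5, 15) per cell | resource consumption coefficient |
| `K_R,i` | U(0.5, 1.5)×10⁶ fmole/ml | resource half-saturation |

Design notes on the less obvious choices:

* **Consumption topology.** A species takes up exactly the mediators that
  influence its growth (consumption links = influence links), with `α`
  drawn independently of the influence amplitude. Only two connectivity
  parameters (`q_p`, `q_c`) define the topology; uptake of a chemical one
  is insensitive to would add free parameters the model does not use.
  Production, consumption and influence rates are stored separately, so
  each channel can still be ablated independently.
* **Resource half-saturation.** `K_R,i` is drawn around the fresh-medium
  supply (mean 10⁶ fmole/ml). Taken literally on a molar scale instead,
  `R/(R+K_R)` would start below 10⁻³ and doubling times would exceed the
  80-hour cycle cap by orders of magnitude; placing the half-saturation at
  the supply scale puts the culture in the intended regime in which the
  population depletes the resource within a cycle while still growing
  measurably.
* **Invader.** Drawn over the *same* mediator set (no new chemicals), with
  the resident connectivities, its own facilitative sign fraction
  `f_fac,inv`, and a basal rate sampled from the resident distribution and
  scaled by the advantage ratio — preserving resident-scale variability
  around the stated average advantage. Saturation constants are redrawn
  from the same range. Ablation flags zero the effective production,
  consumption and/or influence vectors without touching the stored rates,
  so all eight keep/remove combinations derive from one drawn invader.

## Batch growth–dilution protocol

Each cycle integrates the ODEs until total density reaches `N_dil`
(resource variant: or until 80 h, whichever comes first), then dilutes all
species *and mediators* by `N_inoc / total` — fresh medium replaces the
rest, and mediator carryover through the bottleneck is retained rather than
zeroed — and resets the resource to the fresh supply. After each dilution,
species below `N_ext` are set to zero permanently. Dilution never
concentrates: if a (resource-starved) culture ends a cycle below `N_inoc`,
the factor is capped at 1.

**Generations** are doublings of total community density, accrued per
growth interval as `log2(end/start)`; the per-cycle contributions sum
exactly to the cumulative count. A run ends at the first cycle end at which
the cumulative count reaches the target, so the harvest state sits at the
dilution threshold (pre-dilution). In the basic model one cycle contributes
log2(1000) ≈ 9.97 generations and 200 generations take 20–21 cycles; in the
resource variant the number of cycles adjusts automatically to however much
growth the supply permits.

Degenerate inputs are guarded rather than looped on: a basic-model cycle
whose mean growth rate falls below (slowest basal rate)/10 is flagged
`stalled` (in this model that indicates community collapse, e.g. a
self-poisoning culture), a community with zero total density is flagged
`collapsed`, and a whole run is capped at 10 × target-generations cycles.

## Integration

Forward Euler with a fixed step of one tenth of the shortest achievable
doubling time, `dt = ln 2 / max_i(r_i0 + Σ_j max(r_ij, 0)) / 10` — the
bound counts every facilitative amplitude at saturation, so it is
conservative. After every step, negative densities/concentrations are
clamped to zero and the event counted; clamps arise essentially only from
mediator overshoot in the uptake term and affect well under 0.1 % of steps
at default parameters.

Accuracy, measured against an adaptive reference integrator (LSODA at
rtol 10⁻¹⁰) on random 3-species/2-mediator instances and compared at the
common threshold-crossing event: the default step gives relative errors of
order 10⁻² over one 1000-fold growth cycle, a 16-fold refinement gives
order 10⁻³ (median 1.9×10⁻³, worst 5.8×10⁻³), and the error ratio between
the two (~16) confirms clean first-order convergence. This is the expected
behaviour of a first-order method: the global relative error over a cycle
scales as `T·r²·dt/2`. Outcome classification operates on far coarser
features (survival above thresholds separated by orders of magnitude), and
halving the step does not change assay outcomes; the discretisation bias is
documented here so nobody mistakes the trajectories for reference-quality
solutions.

## Community assembly

A pool is inoculated at `N_inoc` split equally, mediators at zero, and run
to the generation target; survivors (> `N_ext`) form the resident
community. Because a species with a small growth-rate deficit crosses the
extinction bar (fraction 10⁻⁵ at a transfer) only after more than the ~21
cycles of a single pass, a raw 200-generation harvest is often still
sorting: in measurement, 35–55 % of single-pass harvests lose at least one
member when re-simulated without any invader, which would corrupt any assay
that attributes richness loss to the invader. Enrichment therefore repeats
200-generation passes — re-inoculating the harvest into fresh medium
exactly as the invasion assay later will — until one pass completes with
unchanged richness, and returns the state *entering* that verifying pass.
The harvested community's own invader-free continuation has then been
observed to keep every member, so richness loss during an assay is
invader-attributable by construction (after this change the invader-free
control loses 0/60 communities across facilitation fractions 0.1–0.9).
Pools still sorting after 5 passes, or losing everything, are flagged
collapsed; experiments regenerate such instances from fresh child seeds and
report the regeneration count. `check_stability` offers a stricter optional
filter (fixed extra generations plus a 1 % absolute bound on end-of-cycle
composition drift over the final three cycles).

## Invasion assay and classification

Residents are re-inoculated at `N_inoc` in their harvest proportions;
the invader is added on top at `propagule × N_inoc` (propagule size is
measured relative to the resident total) at the start of a cycle, matching
the experimental analogy of adding cells at a transfer; mediators carry
over diluted; the resource is fresh. After a further 200 generations the
outcome is the 2×2 of invader persistence × resident richness maintenance.

Persistence uses one rule for everyone: final density above `N_ext`.
Because classification happens at the pre-dilution harvest (total ~10⁷),
this bar is lenient for the invader — a slowly declining invader at
fraction 10⁻⁵–10⁻³ still counts as maintained even though it is heading to
extinction on a longer horizon. This inflates the augmentation category by
a few percent at the 200-generation protocol (extending to 400 generations
resolves most such cases). The rule is kept because it is the single
numeric criterion the protocol defines; results that need a stricter
reading can recompute outcomes from the recorded `invader_final_fraction`
(e.g. maintained only if the final fraction is at least the introduced
fraction). Invaders introduced below `N_ext` are flagged sub-detectable;
once below the bar at a transfer, an invader is permanently extinct, the
same as a resident.

## Experiments, seeding, statistics

Ten preset sweeps cover propagule size (20 log-spaced points, 10⁻⁴–0.99),
invader basal-rate ratio, `f_fac,inv`, `f_fac`, all eight invader-channel
ablations, invader influence/production connectivity, invader
production/consumption rate scaling, and resource supply (10⁵–10⁷
fmole/ml, resource model). Grids that the protocol does not pin (the
ratio and facilitation axes) default to 7–9 evenly spaced points. Each
replicate regenerates pool, community and invader (no cohort reuse, though
an assembly cohort can be serialised and reused deliberately).

Replicate `i` at grid point `g` of experiment `name` under root seed `s`
derives its generator from `SeedSequence((s, crc32(name), g, i, attempt))`;
`attempt` increments only when a collapsed community must be regenerated.
Every replicate is therefore reproducible in isolation and results are
independent of execution order or worker count.

Outcome counts per grid point get exact Clopper–Pearson intervals
(Beta-quantile form, 80 % by default, with the conventional closures at
k = 0 and k = n). Trend assertions in the acceptance tests use one-sided
Fisher exact tests between grid points at matched seeds with α = 0.05,
plus two-sided tests at α = 0.01 where the claim is *absence* of an
effect (propagule insensitivity); replicate counts there are 200 per
condition, reduced from the full-scale 1000–10 000.

## What the generator does and does not emulate

The synthetic pools reproduce the statistical structure of the study
conditions — uniform rate distributions, binomial link topologies, tunable
facilitation fractions — not any particular microbiota: there are no
mediator classes, no taxonomy, no measured metabolite identities, and the
uniform ranges make all species statistically exchangeable. Passing tests
therefore demonstrate properties of this model class (e.g. that facilitated
invaders displace residents), not predictions for a specific real
community.

## Known limitations

* Deterministic dynamics: no demographic noise, so bistable cases resolve
  by initial condition rather than stochastic switching, and "extinction"
  is a threshold crossing.
* First-order integration with the documented O(dt) bias; the reference
  integrator exists only as a test oracle.
* Single invader, single introduction; no repeated pulses, no coalescence,
  no host feedback, no spatial structure.
* The 200-generation assay horizon leaves a small fraction of slow
  transients unresolved at classification time (quantified above).
* The resource law ties consumption to realised (post-saturation) growth;
  maintenance metabolism and growth-independent uptake are absent.
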