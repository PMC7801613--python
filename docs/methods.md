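# Methods

`angiosim` is a hybrid discrete–continuum simulator of early tumour
growth and sprouting angiogenesis in a cubic tissue domain, with the
angiopoietin-1/angiopoietin-2 balance gating both the initiation of new
sprouts and the regression of young ones, and with an anti-VEGF drug
(bevacizumab-like) field for in-silico dosing experiments.

## Model structure

Six dimensionless chemical concentrations live on a shared cubic lattice
(`points_per_axis`³ points over `domain_edge` cm): oxygen `n`, carbon
dioxide `w`, VEGF `c`, angiopoietin-1 `a1`, angiopoietin-2 `a2` and the
drug `d`. Each obeys a reaction–diffusion–convection equation

    df/dt = D ∇²f − ∇·(u f) + sources − sinks

advanced by explicit forward Euler with a 7-point Laplacian and
first-order upwind convection. Dirichlet conditions on all six faces are
re-imposed after every step (`n=1, w=0, c=0, d=0, a1=1, a2=0`) and fields
are clamped non-negative. The convection velocity is the Darcy
interstitial flow `u = −K ∇p`, with `p` the tissue pressure (below) and
`K` a mobility (`darcy_mobility`, grid-step²·mmHg⁻¹·day⁻¹). We use a
velocity proportional to the *negative* gradient because convecting
solutes *up* a pressure gradient concentrates mass at pressure maxima,
which is anti-diffusive; the mobility default (0.1) keeps the advective
CFL number well below one.

Two agent containers share the lattice under a strict
one-cell-per-point exclusivity rule:

* **Tumour cells** (active / quiescent / necrotic) with activity
  `A = n/(n+1)·exp(−5(w−1)⁴)`: a cell is active when `A ≥ 0.5`, which
  requires local oxygen above the tissue baseline (`n ≥ 1`) *and* a waste
  level near the normalisation point `w = 1`. Cell Vital Energy `V`
  integrates `A/(A+1)·k_active` while active and drains at `k_quiescent`
  while quiescent; `V > t_CVE` triggers division into the
  lowest-pressure free Moore-26 neighbour, `V ≤ 0` triggers irreversible
  necrosis.
* **Vessel nodes**, a forest anchored on a pre-existing vasculature.
  Ordinary nodes become branch candidates with probability
  `p_BH = (l/l_max)^f · k_BH0 · α_BH^log10(c)`; candidates express Ang2
  (and keep expressing it for as long as they exist); a candidate sprouts
  a tip endothelial cell (TEC) once `a2 > h·a1` at its location; tips
  climb the VEGF field one lattice step per extension cycle
  `τ = k_v·α_v^(p_V − p)`; and once a sprout is older than 3 days, while
  `a2 > h·a1` holds at its branch point, the distal branch is pruned with
  probability `p_rg = (1−l/l_max)^g · k_rg0 · α_rg^log10(c)` evaluated at
  the tip. `l` is the distance from the initial tumour centroid and
  `l_max` the distance to the farthest domain corner.

Pressure is the sum of a cell-induced part (CTP) and a vascular part
(VTP): each is a box-kernel sum over the `(2k+1)³` cube — `p0/N` (`pV/N`)
per occupied point, so a fully packed cube produces exactly `p0`
(`pV`) at its centre. The kernel form is a package choice (the model
family only fixes "a sum over neighbouring cells"); it is uniform here
and pluggable. The trans-wall factor `W = max(p_V − p, 0)/p_V` scales
all exchange across vessel walls (O₂ and drug release, CO₂ clearance).

Per step the engine executes: pressure → fields (all sources computed
from the pre-step snapshot) → angiogenesis (candidate marking → Ang-gated
sprouting → τ-gated tip extension → Ang-gated regression) → tumour
(activity, CVE, divisions) → metrics. One `numpy.random.Generator`,
seeded once, serves every stochastic draw in a fixed order (candidates in
lexicographic node order, then sprouts, extensions, regressions,
divisions), so a single integer seed reproduces a trajectory bit for bit.

## Why the three-phase length curve emerges

With `α_BH > 1` and `α_rg < 1`, rising VEGF simultaneously promotes
branching and shields sprouts from regression. Early on, VEGF from the
five hypoxic seed cells recruits the first sprout cohort (proliferative
phase). Branch points accumulate Ang2 where they stand, so a few days
after sprouting the destabilisation condition holds broadly; sprouts
whose tips sit in low-VEGF territory are then pruned en masse
(regressive phase). Once vessels feed the tumour, the growing hypoxic
rim floods the domain with VEGF, `p_rg` collapses, and net growth
resumes (re-proliferative phase). Disabling the angiopoietin machinery
removes both the gate and the pruning: every candidate sprouts at once
and the length series is monotone and an order of magnitude higher.

The same couplings produce the dose-timing effect: binding the VEGF
field (B = min(dc, d, c), removed synchronously from both `c` and `d`)
stops tip migration and candidate creation *and* strips the VEGF shield
from existing sprouts, so the vasculature regresses during treatment.
Early administration (days 30–40) interrupts vascular establishment and
the tumour stays small; late administration (days 50–60) arrives after
the tumour has been perfused for weeks and is markedly less effective.

## Initial conditions (the synthetic study)

The generator reproduces the study conditions: uniform `n = 1` and
`a1 = 1`, all other fields zero; five tumour cells at the domain centre
(centre point plus its four axial neighbours in the central plane); and
a pre-existing vasculature of two straight mature vessels running near
two opposite faces at mid-height (the published geometry is not
specified beyond a figure; the fixture is pluggable, including an
explicit node list). The clock is 33 steps per day for 60 days.

What this synthetic setting does *not* emulate: real capillary bed
geometry and anastomosis, blood flow and haemodynamic remodelling, ECM
interaction, lymphatics, and pharmacokinetic clearance of the drug.
Passing the qualitative checks therefore demonstrates that the coupled
mechanisms reproduce the reported *dynamical regimes*, not that the
parameter values are physiological.

## Parameters

Published values: grid 200³ over 1 cm³ (lattice spacing 50 µm), 33
steps/day, 60 days, `p0 = 60 mmHg`, `pV = 30 mmHg`, boundary values as
above, 3-day regression immunity, five initial tumour cells. All other
rate constants below are package defaults: the study's supplementary
parameter table is not available to us, so they were calibrated once, as
a set, to reproduce the reported qualitative dynamics (three-phase
length curve; monotone and ≥10× faster ungated growth; Ang2/Ang1 onset
before length onset; early-dosing superiority), and are exposed in the
configuration for sensitivity work.

Diffusion coefficients are expressed in grid-step²/day (the lattice
convention of the normalised model) and converted with `spacing²` at
solve time; explicit stability requires `D·dt ≤ 1/6` in those units,
checked on every step (`StabilityError`, with an `allow_unstable`
escape).

| symbol | meaning | default | units |
|---|---|---|---|
| `D_n, D_w, D_c` | O₂/CO₂/VEGF diffusion | 5, 5, 4 | step²/day |
| `D_a1, D_a2` | angiopoietin diffusion (paracrine, short-range) | 0.05, 0.01 | step²/day |
| `rho_n0, lambda_n0` | O₂ supply / consumption | 60, 500 | /day |
| `rho_w0, rho_w1, lambda_w0` | CO₂ glycolytic / respiratory / clearance | 20, 20, 20 | /day |
| `rho_c0, lambda_c0` | VEGF secretion / TEC uptake | 150, 50 | /day |
| `k_AR1, k_AR2` | mature radius, radius half-saturation age | 1, 2 | –, days |
| `rho_a1_0, lambda_a1_0` | Ang1 secretion / relaxation | 10, 10 | /day |
| `rho_a2_0, lambda_a2_0` | Ang2 secretion / decay | 40, 0.1 | /day |
| `k_BH_0, alpha_BH, f` | branching scale, VEGF gain, distance exponent | 0.004, 3, 1 | /step, –, – |
| `h` | wall-destabilisation threshold | 3 | – |
| `k_rg_0, alpha_rg, g` | regression scale, VEGF shield, distance exponent | 0.6, 0.03, 1 | /step, –, – |
| `k_v, alpha_v` | extension cycle scale, pressure sensitivity | 0.25, 0.98 | days, – |
| `c_ext_min` | minimal VEGF for tip migration | 0.05 | – |
| `k_active, k_quiescent` | CVE gain / drain | 0.8, 0.015 | /day |
| `t_cve, v_init, daughter_v` | division threshold, initial and daughter CVE | 1, 1, 0.5 | – |
| `darcy_mobility` | interstitial mobility | 0.1 | step²/(mmHg·day) |
| `D_d, lambda_d` | drug diffusion / decay | 4, 1 | step²/day, /day |
| `dose_rate` | drug release scale dv(t) (experiment presets) | 40 | /day |

Notable functional-form decisions, made where the model family fixes
only the process list:

* **CO₂ secretion** has a glycolytic term `rho_w0·max(0, 1−n)` plus a
  respiratory term `rho_w1·n/(1+n)`. A purely activity-proportional
  source cannot bootstrap: activity needs `w ≈ 1`, and `w` would need
  activity to rise. The respiratory term is activity-independent and
  lets well-perfused cells reach the activity window; it also acts as a
  negative feedback that parks `w` near the window edge.
* **Ang2 expression is persistent**: a node that has once been marked as
  a branch point keeps secreting Ang2 while it exists. This is what
  makes the branch-point Ang2/Ang1 ratio grow over the run and lets the
  destabilisation condition hold when sprouts come of age; if secretion
  stopped at sprouting, anchors would decay just below threshold and
  regression would never fire.
* **Regression gate location**: the destabilisation condition for
  regression is evaluated at the sprout's branch point (where Ang2
  accumulates in place), while the regression probability uses the VEGF
  and distance at the tip. A migrating tip permanently outruns its own
  Ang2 trail, so a tip-local gate cannot fire for fast sprouts.
* **`alpha_v < 1`**: high external pressure impedes tip invasion
  (`τ` grows as `p` exceeds `p_V`). The opposite sign lets near-tumour
  tips extend tens of steps per day and the network diverges.
* **Division energetics**: daughters start with `daughter_v = 0.5`
  (half the division threshold); a zero-energy daughter placed in a
  quiescent spot would necrose on its first update and lineages could
  never establish. Parents pay `t_CVE` per division; a boxed-in cell's
  energy is capped at `t_CVE`.
* **VEGF secretion support**: applied at all alive tumour cells (the
  hypoxia factor `1−n` already silences well-oxygenated cells);
  `vegf_source="quiescent_only"` restricts it to quiescent cells.
* **Log base** in the probability laws is 10 (configurable); VEGF below
  `c_floor = 1e−12` yields `p_BH = 0`. Probabilities are interpreted per
  simulation step and clamped to [0, 1].

## Numerical and implementation choices

* Forward Euler throughout; CVE integration is exact for the piecewise
  constant rates. Field updates within a step all read the same
  pre-step snapshot; binding `B` is computed once per step from the
  pre-step `d` and `c` and subtracted from both.
* Neighbourhood sums (CTP, VTP, EC/TEC densities) use a zero-padded box
  mean (`scipy.ndimage.uniform_filter`); brute-force loop oracles verify
  them in the test suite, as they do the Laplacian, upwind advection and
  pressure gradient.
* Ties (equal-pressure division targets, equal-VEGF extension or sprout
  targets) break uniformly at random from the run's generator, keeping
  trajectories seed-reproducible.
* Checkpoints (HDF5) store fields, agents, network, clock and RNG state
  and resume bit-exactly.
* Desk problem sizes: the packaged study presets run 32³ for 60 days
  (about one minute per run on one core), with the ungated-growth arm
  compared at day 45, the published comparison horizon. The full 200³
  geometry is expressed by `paper_scale()` and is compute-bound, not
  code-bound. Quantities with physical units (vessel length in mm)
  scale through the lattice spacing, so desk-scale magnitudes are not
  comparable to full-scale ones; directions and regime structure are.

## Limitations

* The vasculature is a forest: no anastomosis, no flow network, no
  co-option; vessel "perfusion" is the local wall factor `W`.
* Tumour cells neither migrate nor deform; invasion and metastasis are
  out of scope.
* A single TAF (VEGF) stands in for the angiogenic factor milieu; the
  drug model is release–diffusion–binding–decay without plasma
  pharmacokinetics.
* The calibrated defaults are one point in a large parameter space;
  conclusions from this package are about mechanism structure, not
  quantitative physiology.
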