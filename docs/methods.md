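# Methods

`oncolattice` simulates vascular tumour growth as a hybrid multiscale
system: discrete cell agents on a 3D cubic lattice with 26-neighbour
(Moore) interactions, five continuum chemical fields advanced by explicit
finite differences, subcellular signalling surrogates integrated at
sub-hour resolution, and a per-cell phenotype-decision engine based on
Q-learning with a kernel-regression value approximator.  One macro step
represents one hour; the default lattice is 40×40×40 sites at 20 µm
spacing (one cell diameter), simulated for 504 h (21 days).

## The lattice and its occupancy rules

A site holds either one tissue cell (healthy or cancerous), a permanent
necrotic-debris marker, or up to four endothelial cells.  All cells
propose actions simultaneously each macro step; contested empty sites go
to a cancerous claimant over a healthy one and otherwise to a uniform
draw from the run's seeded generator.  Losers stay put.  Necrotic debris
blocks a site forever.

## Continuum fields

Oxygen, glucose, TGFα, TNFα and VEGF evolve by

    C(t+dt) = C + D (dt/ΔS²) Lap₂₆(C) − U + S [− W],

where Lap₂₆ is the 26-neighbour stencil (sum of neighbours minus 26 C).
Boundaries are no-flux: a missing neighbour mirrors the centre value.
This was chosen because the domain is a tissue block whose vessels sit at
its faces; the convention is isolated in one function so a periodic
variant can be swapped in.  Each macro step is split into the smallest
number of equal sub-steps satisfying the explicit-stability bound
D·dt/ΔS² ≤ 1/26; a step that violates the bound is refused rather than
silently damped.  Negative concentrations produced by the explicit update
are clamped to zero and counted.

Oxygen and glucose enter through the walls of perfused vessels
(2πR·Pe·(ρ−C) per site, with R the vessel radius and ρ the intravascular
concentration, 1.0 arterial / 0.8 venous in normalised units) and are
consumed by cells: cancer cells at β_c scaled by 1, ½, ¼, ⅙, ⅛ for the
proliferation, migration, quiescence, hypoxia and necrosis phenotypes,
healthy cells at α_n.  The uptake schedule is read as monotone decreasing
with metabolic activity; debris consuming at β_c/8 is kept as specified by the uptake
schedule but can be switched off (`agents.necrotic_uptake`).  VEGF is secreted by
live cancer cells on the reversed schedule (the more stressed, the more
VEGF; a cell whose phenotype is necrosis is a cell in the act of dying —
debris itself secretes nothing), taken up by perfused vessels, and decays
everywhere at rate ω.

### Transport constants

All constants are implementation defaults, not measured values, and live
in the config.  The oxygen/glucose diffusivity (200 µm²/h) together with
the normal uptake rate (0.05/h) sets a supply length √(D/α_n) ≈ 60 µm ≈ 3
sites around a perfused vessel, so nutrient landscapes are genuinely
heterogeneous at cell scale.  Cancer cells consume ten times faster than
normal cells (β_c = 0.5/h vs α_n = 0.05/h), so a growing tumour drains
its surroundings and must recruit vasculature.  The policy thresholds sit
at physiological fractions of the arterial concentration: hypoxia below
8%, the glucose active/dead thresholds at 15%/2%.  Healthy cells are
initialised with their division budget already spent — normal tissue is
homeostatic, it holds its ground, wanders and dies but does not expand —
which keeps the ~30% interstitial space open for the tumour, whose cells
win every simultaneous competition for an empty site.

## Signalling surrogates

The pathway contract is input/output: EGFR turns local TGFα
into a PLCγ level that arbitrates migrate-versus-proliferate, and the TNF
pathway turns local TNFα into a death signal.  The exact ODE systems
behind those cascades are not reproduced here; a documented surrogate —
mass-action receptor binding (dB/dt = k_on·L(1−B) − k_off·B) feeding a
saturating Hill activation stage — sits behind a pluggable interface, so
a different right-hand side can be registered without touching any other
module.  Both surrogates are monotone in their ligand by construction.
PLCγ settles to a dose-dependent fixed point with a closed form used as a
test oracle; the death signal accumulates without decay, and its
parameters are calibrated so that one hour above the TNFα policy
threshold (0.3) crosses the death threshold (1.0) while the ambient TNFα
level that dense tissue settles at (secretion/consumption ≈ 0.02) stays
harmless over any simulated horizon.  Signalling integrates once per
macro step with an adaptive Runge-Kutta method over all cells at once;
the TGFα/TNFα it consumes is removed from the fields site by site, so the
coupling conserves mass.

## Phenotype semantics

Actions per type: cancerous {proliferation, migration, quiescence,
hypoxia, necrosis}; healthy {proliferation, migration, quiescence,
apoptosis}; stalk {quiescence, branch, sprout}; tip {quiescence, branch,
expansion}.  Site selection for migration, daughter placement and
sprouting is the two-stage nutrient rule: a candidate neighbourhood is
preferred when its maximum exceeds its mean by more than three standard
deviations for any relevant nutrient (oxygen/glucose for tissue cells,
VEGF for vessel cells), and the final draw is proportional to the summed
neighbourhood-mean concentrations — applied uniformly whether zero, one
or many candidates pass the preference test.

Two readings of quiescence coexist deliberately.  For tissue cells it is
the absorbing exit from the cell cycle: once chosen (or forced by a
blocked division), the cell never selects another phenotype.  For
endothelial cells "quiescence" is a per-step rest — the vasculature must
be able to respond when VEGF arrives hours or days after initialisation,
and an absorbing reading would freeze every vessel cell while VEGF is
still zero.  Quiescent tissue cells are not immortal: nutrient
deprivation (oxygen below the hypoxia threshold or glucose below its
dead threshold for longer than the type's tolerance — 72 h for
hypoxia-adapted cancer cells, 24 h for healthy cells) and a TNF death
signal past its threshold kill a cell regardless of its phenotype, as
environment-forced transitions.  The deprivation counter is
environment-driven: it rises each hour spent underfed and resets on
recovery.

Division respects an oxygen floor (`prolif_o2_min`): below it the
division is postponed and the delay counter grows (feeding policy rule
4).  Healthy cells count their divisions; past the division limit the
quiescence bias rises (rule 3).  A tip cell that expands leaves a fresh
stalk cell in its vacated site, spliced into the sprout lineage; a stalk
cell that sprouts starts a new tip.  Sprout class is inherited from the
rooting side (arteriole from arteries, venule from veins), and perfusion
is recomputed from scratch every step: an artery-rooted path is perfused
exactly while its tip touches the Moore neighbourhood of a vein-side
segment.  Only perfused vessels exchange material with the fields.

## Policies, rewards, learning

Each policy rule contributes a reward term RF_p(x) = direction ·
tanh((x − threshold)/gradient); the cell's reward is the mean of the
applicable terms, hence bounded in (−1, 1).  The same terms drive action
selection as multiplicative biases exp(±strength·RF) on the favoured and
disfavoured actions (strength 3.0 by default, so a fully triggered rule
outweighs a neutral one by e³ ≈ 20 — favourable conditions drive
near-deterministic phenotype choice, which is what sustains growth
curves with an early exponential phase).  Three quantification choices
deserve note.  The mid-glucose drift into quiescence applies to healthy
cells only, as stated by the glucose rule — hypoxic cancer cells keep
cycling through the hypoxia response instead of resting.  The
hypoxia-duration rule's protective side is applied at double weight:
starvation-driven death is meant to follow *sustained* deprivation, so
while the counter is short of its limit the suppression outweighs the
instantaneous low-oxygen/low-glucose death drives.  And two rules are
hard gates: migration requires more than two tissue neighbours, and all
vessel growth actions (sprout, branch, expansion) require VEGF above the
angiogenic threshold (0.005 — above the ambient zero, below the
0.01–0.02 a stressed tumour raises at the parent vessels).

In the train phase each agent's Q values for all allowed actions come
from the kernel ensemble; an action is sampled with weight proportional
to shifted-non-negative Q — an exploration floor of 0.05 is added to
every weight, because plain Q/ΣQ starves unexplored zero-Q actions
forever and demonstrably prevents convergence on even a 3-state chain —
*times* its policy-bias weight.  The rules shift selection probability
directly, and the modulation keeps one immature ensemble fit (whose
predictions for actions absent from the window are pure extrapolation)
from momentarily assigning death phenotypes a fifth of the probability
mass and wiping out the tissue.  The test phase picks the argmax of Q
alone, ties broken by the seeded generator.

After the world advances, the reward is evaluated on the successor state
and Q is updated with the one-step rule (η = 0.3, γ = 0.9); experiences
with reward strictly above θ = 0 enter a 200-sample FIFO window per agent
category.  Two transitions get special successor terms, as the MDP
semantics require: a cell that died of its own chosen phenotype is a
terminal transition (no future term; its pre-action state carries the
experience), and a cell absorbed into quiescence bootstraps from
Q(s′, quiescence) only, since resting is its entire future.  Before the
first ensemble exists (cold start), actions are sampled from the policy
biases directly.  The ensemble is refitted every 50 macro steps rather
than every step; refitting is by far the most expensive operation and its
cadence is a config knob (`learning.refit_interval`).

## The value approximator

One SVR per kernel family (RBF, polynomial, sigmoid), each with
(C, ε, γ) selected by NSGA-II — fast non-dominated sorting, crowding
distance, binary tournament, SBX crossover, polynomial mutation —
maximising 3-fold cross-validated recall, precision and F-measure on the
window.  F-measure for a regressor is defined through sign-agreement
binarisation of Q (a k-bin variant is available).  From the final front
one configuration is taken by highest F-measure, ties by crowding
distance.  The fitted kernels vote with weights equal to their training
F-measure; the vote is clipped to [−1, 1].  A window whose labels are
one-sided can make every F-measure zero; the ensemble then falls back to
equal voting weights rather than dying.  Separate learners serve the
tissue and vessel agent categories, whose state layouts differ (the
per-category feature layouts are versioned in the dataset exports).

## Growth-law validation

Three reference laws close the loop at the population level:

* Gompertz tumour growth n(t) = n0·exp[(α/β)(1 − e^{−βt})], fitted in log
  space (the model is linear in α/β there) with multi-start nonlinear
  least squares; the fitted α, β are flagged against the biological
  ranges [0.005, 0.016] and [0.121, 0.390] per hour reported for real
  tumours.
* Sigmoid vessel growth g(t) = g0 + α/(1 + e^{−(t − t_half)/β}) for total
  vascular length (vessel-occupied sites × ΔS).
* Exponential branching b(t) = b0 + α·e^{βt} for cumulative branch
  events, with the experimentally determined (α, β) = (2.62, 0.105) as
  the reference parameter set.

Errors are reported as RMSE, MAD (read as the mean absolute deviation of
the errors, the usual forecast-accuracy triple alongside RMSE and MAPE)
and MAPE in percent, with zero actuals skipped for MAPE.

A structural note on the Gompertz ranges: any Gompertz fit satisfies
α/β = ln(n∞/n0).  A simulated tumour that grows from ~90 seed cells to
thousands of sites has ln(n∞/n0) ≈ 4, while α ≤ 0.016 with β ≥ 0.121
implies ln(n∞/n0) ≤ 0.13, i.e. total growth under 14%.  The two range
checks therefore cannot both hold for any strongly growing series; the
fitted β of a scaled-down run lands in or near its range while the fitted
α sits far above its own.  The package reports the honestly fitted values
and the range flags; it does not adjust the fit to the flags.

## What the scaled-down runs do and do not show

The acceptance-scale simulations use a 20×20×20 lattice over the full
504 h horizon.  At this size the growth curve keeps its qualitative
shape — early exponential expansion of the seed through the interstitial
space, VEGF-gated sprouting and perfusion, deceleration and a plateau as
local space and nutrients run out — but the box is small relative to the
spacing of the eight parent vessels, so healthy tissue near the vessels
persists rather than regressing wholesale, the tumour saturates at
roughly ten times its seed size instead of filling the lattice, and no
macroscopic necrotic core forms.  Absolute counts, vascular densities
and the time of saturation are therefore not comparable to a 40³ run,
and no claim is made about real tissue beyond the shape of the curves.
The
synthetic initial state (70% occupancy, 60 µm seed sphere, Gaussian
nutrient profiles around eight parent vessels) emulates a vascularised
tissue block; it has no cell-cycle heterogeneity, no stroma, no immune
compartment, and a vasculature reduced to straight parent lines plus
lattice sprouts.

## Numerical and reproducibility choices

All randomness derives from a single config seed through named streams
(initialisation, the world, action sampling per phase, the genetic
search), so a run is bit-reproducible from its resolved config.  Runs
write the resolved config, the seed, a per-step trace table, periodic
snapshots and the experience dataset; re-running with the same inputs
reproduces the trace byte for byte.  SVR solves are capped at 20,000
iterations (an unbounded solver can stall for minutes at pathological
hyper-parameter candidates proposed early in the genetic search).  The
per-step engine is vectorised across agents; the scalar single-agent
operations remain the reference semantics and the batch path is pinned to
them by unit tests.

## Known limitations

* The signalling surrogates reproduce the reference pathways' interface
  and monotonicity, not their trajectories.
* Policy-bias magnitudes are direction-faithful but quantified by a
  single strength constant; the rules themselves specify direction only.
* Perfusion is binary connectivity, with no haemodynamics.
* Blocked divisions freeze a tissue cell permanently (the contact-
  inhibited resting-phase rule taken literally); combined with the absorbing
  quiescence this makes saturated regions inert, which is intended, but
  it also means a rescued region cannot re-enter the cycle.
* Tissue architecture is a fixed grid; no mechanics, adhesion or
  deformation.
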