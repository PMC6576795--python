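# Methods

This note documents the model as implemented: its assumptions, numerical
scheme, time-base conventions, stochastic protocols, win classification,
and the choices made where the underlying model description leaves room.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model summary

Two bacterial strains occupy an `M × M` toroidal lattice: a producer **B**
(antibiotic-producing, resistant, growth cost `c`) and a parasite **P**
(non-producing, sensitive). Two nonnegative scalar fields live on the
lattice: extracellular antibiotic `A_ext` (defined at every site) and
intracellular antibiotic `A_int` (pinned to 0 at empty sites). Chemistry
advances in substeps of length `Δt`; every `u` substeps one *cellular
generation* updates `round(ε·N)` randomly drawn sites by a death–birth
rule. Default rate constants follow the reference experiment regimes that
ship as preset files; the spatial resolution is one lattice cell (`Δx = 1`,
not tunable).

## Chemistry: numerical scheme

Per substep, in this order:

1. **Diffusion** of `A_ext` by the explicit five-point stencil over von
   Neumann neighbours. The stencil is stable only for `D·Δt/Δx² ≤ 1/4`;
   for larger `D·Δt` the operator is transparently subcycled into
   `ceil(4·D·Δt)` equal Jacobi micro-steps (e.g. 20 for `D = 50`,
   `Δt = 0.1`). The subcycle count is reported in `ChemistryStepReport`.
2. **Reaction**, applied once per substep with weight `Δt`, evaluated on
   the *start-of-substep* fields (Jacobi-style, so results are independent
   of site visitation order): occupied sites exchange
   `ρ_ξ(t) + β_ξ·A_int − α_ξ·A_ext` with the environment and integrate
   `α_ξ·A_ext − (β_ξ + γ_ξ)·A_int` internally; `ρ_P = 0` always.

Decisions embedded here:

* **Decay acts everywhere.** Environmental decay `−φ·A_ext` applies at
  empty sites too — physically, decay cannot depend on occupancy. The
  strictly site-gated variant is available as `decay_occupied_only` for
  comparison.
* **`A_ext` persists at empty sites.** Only `A_int` is voided when a site
  empties. Without an extracellular field on vacant surface there could be
  no antibiotic halo beyond the colony edge, and diffusion itself would be
  meaningless.
* **Clamping.** A reaction step that would drive a concentration negative
  clamps it to zero and counts the event; with the shipped rate sets and
  the stability subcycling no clamping occurs (asserted in tests).
* The compiled kernel and a literal loop-based transcription of the update
  agree to 1e-12 over 10 substeps on mixed occupancies (tested), and pure
  diffusion conserves mass to < 1e-8 relative over 10⁴ substeps.

## Demography

Reproduction rates: `r_B = r_B0·g(t) − c` (g = private growth boost) and
`r_P = r_P0 − a/(1 + exp(−k·(A_int − T)))`. The sigmoid is evaluated
overflow-safely (saturates, never NaN).

* **Zero-clamping.** Strong poisoning can push `r_P` below zero; selection
  weights must be nonnegative, so rates are clamped at 0. A clamped cell
  can still die but never reproduces. Cells with `r_P < 0.05` are the
  "poisoned" class in renderings.
* **Focal sites are drawn from all sites**, occupied or empty, uniformly
  with replacement (`round(ε·N)` draws per generation; a without-
  replacement switch exists). An occupied focal dies, then the eight Moore
  neighbours compete to refill the site with probability proportional to
  their rates; an empty focal is contested the same way. Updating only
  occupied sites could never colonise empty space, so uncontested growth
  (which saturates the habitat logistically) fixes this reading.
* **Sequential (asynchronous) updates** within a generation, in draw
  order: later draws see earlier outcomes. If no neighbour has positive
  rate the site stays empty. Newborns inherit type only; `A_int` starts
  at 0 (no antibiotic inheritance).
* RNG consumption order is fixed (focal indices, then selection uniforms),
  making every run bit-reproducible given its seed.

## Time bases

All scheduling quantities — `τ` (private-resource expiry), `κ` (first
arrival time), the win-holdout window, `max_generations` — are measured in
**cellular generations**. The reference regimes quote `τ` up to 2000
against runs of 10⁵ generations; on the substep clock those values would
expire before the colony could grow at all.

The **arrival lottery** ticks on the **antibiotic-substep clock** by
default: one Bernoulli(`f`) trial per update step, i.e. Binomial(`u`, `f`)
propagules per generation (≈ 1 per generation at `f = 0.01`, `u = 100`).
This is the literal reading of an arrival probability "per update step"
when `u` update steps elapse per generation, and it supplies enough
invasion pressure for empty space to be contested while it exists — with
one trial per generation (mean waiting time 100 generations), transient
empty regions close before parasites ever sample them, and the
size-triggered experiment degenerates. The per-generation clock remains
available as `arrival_clock = "generation"`.

## Invasion protocols

A propagule of `n_Pt` parasites lands around a uniformly chosen focal site
and grows as an edge-connected cluster, empty frontier sites taken (in
uniformly random order) before occupied ones.

* **Test 1** (time-limited resource): arrivals from `κ`; crowded
  surroundings may be overwritten when no empty frontier remains (an
  overwritten cell's `A_int` is voided). Under `PROTECTED_GROWTH`,
  placement inside the protected region is blocked before `τ` (a blocked
  focal kills the whole propagule); with `s₊ = 1` arrivals are effectively
  impossible before `τ`.
* **Test 2** (size-triggered): arrivals begin once the producer holds
  `round(CSI·N)` sites (and `t ≥ κ`); the trigger latches. Parasites
  invade **empty places only** — no overwriting. This is what
  distinguishes the size-triggered experiment: invasion is colonisation
  of the remaining vacant surface, so a fully colonised habitat can never
  be invaded again.

The protected region and the founder colony are deterministic quasi-discs
(rings of increasing Chebyshev radius, ties broken by distance then
coordinates; every growth prefix is edge-connected) centred on the grid;
the model description shows a single founding colony but fixes neither
geometry, so a reproducible compact patch was chosen (uniform-random
founder placement is available as a flag).

## Win classification

A run ends when the verdict can no longer change:

* Producer extinct → parasite wins (producers never re-immigrate).
* Parasite absent, no arrivals possible, habitat fully colonised →
  producer wins.
* Under *ongoing* arrival pressure a strict "no parasite present" rule
  would never fire: freshly landed, instantly poisoned cells linger
  (they die at rate ≈ ε per generation) while new propagules keep coming.
  The producer is therefore declared **invasion-proof** when, with
  arrivals enabled and at least one propagule landed, *no parasite has
  reproduced* for a holdout window of `W = 500` consecutive generations,
  the private resource has lapsed, and producers outnumber parasites.
  A parasite population that cannot reproduce can only dwindle, so
  further arrivals cannot change the verdict.
* At `max_generations` the winner is the sole surviving strain, else
  UNRESOLVED (with final fractions reported). "Mixed" colours in phase
  diagrams are replicate-frequency mixtures, never within-run coexistence.

## Experiments layer

Sweeps are full-factorial over two named parameters with per-(cell,
replicate) RNG streams derived from a master seed via `SeedSequence` spawn
keys — reproducible, order-independent, resumable from an on-disk cache
keyed by configuration hash. MSC estimation scans CSI values ascending and
returns the smallest with majority producer wins, assuming (and checking,
when asked to scan exhaustively) monotonicity of win frequency in CSI;
optional bisection refines the bracket. Replicate batches can stop early
once a majority verdict is decided, which cannot change a majority-vote
summary.

## Problem sizes and what the tests show

The reference experiment scale is `N = 10⁴` sites and 10⁵ generations per run; the package's default experiment scale is a 50×50 torus with runs
capped at 20 000 generations and 3 replicates per point, which resolves
each MSC point in seconds to tens of seconds on one core. The test suite
additionally shrinks drift/selection checks to 20×20 chemistry-free
lattices and property checks to 5×5–24×24 grids.

**Grid-size sensitivity of the low-diffusion MSC.** With a centrally
founded colony, the vacant region remaining at occupancy fraction `q` is a
margin of width ≈ `M·(1 − √q)/2` cells. Parasites can only establish
where that margin is wider than the antibiotic halo (decay length
`√(D/φ)`, ≈ 1.6 cells at `D = 0.5`, `φ = 0.2`, widened by field lag behind
the advancing front). On a 100×100 torus the margin at 90% occupancy is
≈ 2.6 cells and contested (parasites establish and fight; producers are
safe only near-full occupancy, consistent with a low-diffusion MSC above
95%). On a 50×50 torus the same margin is ≈ 1.3 cells — inside the halo —
so producers already resist from 80% occupancy, and the measured
low-diffusion MSC at this scale is 80% rather than above 95%. The
intermediate-diffusion MSC (≈ 10%) and the non-monotonicity in `D` are
insensitive to this geometry and reproduce at the default scale.

## Known limitations

* Exactly two strain archetypes; no mutation, age structure, nutrient
  fields, or multiple antibiotics.
* Explicit (subcycled) diffusion only; adequate at these grid sizes, not
  intended for very large `D·Δt`.
* The win-holdout rule and the substep arrival clock are reasoned
  reconstructions of under-specified protocol details (switches expose
  the alternatives); absolute trajectories are not expected to match any
  particular prior realisation, only the model's phenomena.
* Low-diffusion MSC values are grid-size-bound (see above) and should be
  compared across scales, not read as universal percentages.
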