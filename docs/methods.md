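# Methods

## The model

`ferrodyn` studies a feedback loop between the growth of an adherent cell
population and the lipid reactive-oxygen burden of its members. The state
is two-dimensional: `n`, the confluence fraction of the culture surface
(0 to roughly the carrying capacity `K`), and `r`, the average lipid ROS
per live cell in arbitrary reporter-calibrated units. The dynamics are

    dn/dt = alpha * n * (1 - n/K) - beta * n * sigma(r)
    dr/dt = a * alpha * (1 - n/K) - b*r + c*r

with the Hill death switch

    sigma(r) = r^h / (r0^h + r^h).

The terms encode the loop's biology:

* logistic growth at basal per-capita division rate `alpha` toward `K`;
* ROS production proportional to the per-capita division rate — rapidly
  dividing sparse cultures generate the most ROS per cell (`a` units per
  division);
* first-order clearance at rate `b` per molecule by the cell's
  scavenging/repair machinery (GPX4 and co.), opposed by autocatalytic
  Fenton amplification at rate `c` (`b > c` is enforced so net clearance
  keeps `r` bounded);
* ferroptotic death at a per-capita rate approaching `beta` once `r`
  crosses the threshold `r0` at which peroxidation outpaces repair.
  `sigma` is half-maximal exactly at `r0` and saturates at 1. An
  idealised hard step `1[r > r0]` is available behind the `hard_switch`
  flag for fidelity checks; the smooth form (default steepness `h = 4`)
  is what the fitter differentiates through.

Because growth feeds ROS and ROS feeds death, the long-term fate is
bistable over a wide parameter range: a confluent, low-ROS,
ferroptosis-resistant state at `(n = K, r = 0)` coexists with a sparse,
high-ROS, ferroptosis-sensitive state (high turnover, large cumulative
death). Which one a culture reaches depends only on its initial
`(n, r)` — the basins of attraction. Treatments are modelled as parameter
moves: GPX4 inhibition (RSL3) multiplies `r0` by 0.4 (default), forcing
OXPHOS with galactose medium multiplies `a` by 1.8, and a graded
RSL3 dose `d` (ng per percent confluence) maps to an `r0` multiplier
`1/(1 + d/1.2)`, calibrated so the emulated low-density dose of
1.8 ng/%conf reproduces the default 0.4. These effect sizes are package
choices; only their directions are established biology.

### Default parameters

| parameter | meaning | unit | default |
| --- | --- | --- | --- |
| `alpha` | basal per-capita division rate | 1/h | 0.05 |
| `K` | carrying capacity (confluence fraction) | – | 1.0 |
| `beta` | maximal ferroptotic death rate | 1/h | 0.04 |
| `a` | lipid ROS per cell division | ROS units | 4.0 |
| `b` | ROS clearance rate per molecule | 1/h | 0.10 |
| `c` | Fenton autocatalysis rate | 1/h | 0.02 |
| `r0` | death threshold | ROS units | 0.5 |
| `h` | death-switch steepness | – | 4.0 |

Under these defaults the model has exactly four steady states: the two
stable ones at `(1, 0)` and `(0.203, 1.992)`, an interior saddle at
`(0.866, 0.335)` whose stable manifold is the basin boundary, and a
saddle on the extinction line at `(0, a*alpha/(b-c)) = (0, 2.5)`.

## Numerical choices

* **Integration.** `scipy`'s LSODA with `rtol 1e-8`, `atol 1e-10` for
  `simulate`; states are clipped at zero afterwards and a clip beyond
  `1e-6` raises instead of silently repairing a bad solve. The fitting
  path relaxes to `rtol 1e-7`, `atol 1e-9` (the objective is dominated by
  measurement noise long before solver error matters), and basin
  labelling to `rtol 1e-6` since only the attractor identity is needed.
* **Fixed points.** Multi-start Newton (hybrid Powell) from a 20 x 20
  lattice plus the axes; roots deduplicated at `1e-5`, residual tolerance
  `1e-8`; classification by the sign pattern of Jacobian eigenvalue real
  parts with a `1e-9` zero band — eigenvalues inside the band yield
  `"unclassified"` rather than a guess. The Jacobian is analytic (the
  Hill derivative at `r = 0` is zero for `h > 1`).
* **Basins.** 60 x 60 grid over `r in [0, 4*r0]`, `n in [1e-3, 1.1K]` by
  default; each node is integrated in geometric stages (10%, 25%, 50%,
  100% of the 2000 h horizon) and matched to a stable attractor with
  tolerance 0.02 in scaled coordinates `(r/r_max, n/K)`. Nodes that never
  match stay labelled unresolved; they are never silently assigned. No
  separatrix continuation is attempted — the boundary is reported as the
  label interface, which is what shaded basin maps show.
* **Weighted least squares.** Residuals are `weight * (observed -
  predicted)` over all records. Weights are per-observable reciprocal
  pooled replicate standard deviations: the replicate variance at each
  (condition, time) is pooled over times and conditions, floored at the
  10th percentile of all positive per-time variances so no observable
  receives unbounded weight. When no replicate variance exists (single
  replicate, noiseless data) each observable falls back to a `1/rms`
  scale so the three channels still contribute comparably.
* **Optimisation.** Bounded trust-region least squares
  (`scipy.optimize.least_squares`, `trf`), rate-like parameters
  (`alpha, beta, a, b, c, r0, ros_scale`) on a log scale, 16 jittered
  multistarts by default (uniform jitter of 25% of the internal box
  around the base values), seeded and recorded in the result. Parameter
  vectors that violate model invariants during a line search return a
  large constant residual instead of crashing the solver. Fitting `a`
  and `ros_scale` together is refused: under the affine observation map
  `ratio = ros_baseline + ros_scale * r` only their product is
  identifiable.
* **Initial states for fitting.** `n0` from the earliest observed
  confluence / 100, `r0` by inverting the observation map on the earliest
  ratio; both per condition.
* **Dead-cell observable.** The dead count is cumulative — the nuclear
  dye marks a cell once and the count accrues — so `D(t) = integral of
  beta * n * sigma(r)` is integrated as a third state and reported as
  `D/n`, matching how live-cell imagers report dead counts normalised to
  confluence.

## The synthetic world

The generator emulates the experimental designs the model was built
around: fibroblasts seeded at three densities in multi-well plates,
imaged every 2 h for 72 h (37 time points), three replicates, under
vehicle control or GPX4 inhibition, glucose or galactose medium, and a
restricted-growth-space variant (same cell number in half the area,
implemented as doubled initial confluence).

* **Seeding fractions.** The emulated counts are 25k / 55k / 120k cells
  per well. At ~1260 cells per percent confluence — a spread-fibroblast
  footprint of roughly 1500 um^2 in a 1.9 cm^2 well — these map to
  initial fractions LD = 0.20, MD = 0.44, HD = 0.95. With the default
  parameters this puts LD and MD inside the sensitive basin of the
  RSL3-shifted system and HD inside the resistant basin, reproducing the
  density-dependent ferroptosis phenotype the model exists to explain.
* **Noise model.** Multiplicative lognormal noise (relative sigma 0.05)
  on confluence, additive zero-truncated Gaussian (sigma 0.05) on the
  reporter ratio, and Poisson counting noise on the dead observable at
  400 counts per unit of `D/n`. All randomness flows from the scenario
  seed.
* **Rendered frames.** 512 x 512 px frames place elliptical cells
  (radii 6-10 px) by random sequential adsorption with a guaranteed
  3 px margin between cells, so that dilating the dead mask by the
  default 3 px radius can never eat live-cell pixels. Coverage tracks
  `n(t) + D(t)`, the dead-marked fraction tracks `D/(n+D)`, and the
  ox/red channel intensities encode the reporter ratio of `r(t)`
  (per-cell brightness varies log-normally but cancels in the ratio).
  The margin caps packing near 39% area fraction; denser requests raise
  a packing-limit error rather than degrading silently, so image
  round-trip studies use early/mid time points of sparse conditions.
* **What the generator does not emulate.** Spatial death propagation,
  single-cell heterogeneity, meniscus/oxygen-tension effects,
  photobleaching, background fluorescence, segmentation errors, or cell
  detachment after death. Passing round-trip and recovery tests
  therefore certify the pipeline's internal consistency under the stated
  noise model, not its behaviour on real microscopy.

## Study sizes

The recovery studies fit the MD condition (the single most informative
one: its trajectory traverses a wide range of `n` and crosses the death
threshold, constraining all four default free parameters
`alpha, K, beta, r0`). Noiseless recovery uses one replicate; the noisy
study uses 3 replicates x 37 time points over 20 seeds with 4 multistarts
per fit, and the joint control/RSL3 contrast study (shared parameters,
condition-specific `r0`, true ratio 0.4) uses the same sizes. Basin
sweeps use 21 x 21 grids over a fixed window (`r in [0,2]`,
`n in [1e-3, 1.1]`) so fractions are comparable across parameter values.

## Known limitations

* With the default parameters the sensitive basin covers most of the
  default phase-plane window; even untreated sparse cultures sit inside
  it and decline slowly toward the high-turnover state rather than
  growing to confluence. The model world is therefore harsher than a
  healthy vehicle-control culture; the parameter set was chosen for a
  well-separated bistable structure, not to flatter the control arm.
* The cumulative dead observable makes endpoint `D/n` increase with
  seeding density among dying cultures (a larger dying population
  accrues more marked area), so the generator reproduces the qualitative
  sparse-dies/dense-survives contrast but not a strictly decreasing
  dead-signal ordering across sparse densities.
* `K`, `h` and the observation-map parameters are only weakly identified
  from conditions whose trajectories stay far from carrying capacity or
  never cross the threshold; the fitter reports multistart dispersion,
  and single-condition fits should free only parameters the condition
  actually constrains.
* No confidence intervals are computed — multistart dispersion is the
  only spread reported.
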