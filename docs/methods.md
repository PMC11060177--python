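# Methods

## Reactor model

The forward model treats one flow-through sand–bentonite reactor as a
single stirred tank over its void (porewater-filled) volume `V_v` (cm³).
State variables are dissolved sulfate `S` (mM ≡ µmol cm⁻³), sulfide `HS`
(mM internally, reported in µM), ferrous iron `Fe` (likewise), and the
gypsum sulfate inventory `G` (mmol). With dilution rate `Q/V_v` (flow `Q`
converted from µL min⁻¹ to cm³ day⁻¹):

    dS/dt  = (Q/V_v)(C_in − S) + k_gyp (C_sat − S)·1[G>0] − R_sr
    R_sr   = v_max,sr · b(t) · f(H₂) · S/(K_SO4 + S)
    dHS/dt = R_sr − (Q/V_v)·HS
    dFe/dt = (Q/V_v)(Fe_in − Fe)
    dG/dt  = −k_gyp (C_sat − S)·1[G>0] · V_v/1000

Iron-sulfide precipitation is applied by operator splitting after each
chemistry step: the lesser of dissolved Fe and HS is removed from both
pools instantaneously and credited to a cumulative FeS ledger (Fe:S 1:1,
i.e. mackinawite-like; the classification of measured Fe:S ratios is a
separate, measurement-side operation). Methanogenesis runs at
`v_max,meth` only while `S < so4_gate`, encoding the observation-derived
hypothesis that methanogens are outcompeted until sulfate is depleted.

**H₂ limitation.** The experiment supplies H₂ as one daily pulse and no
dissolved-H₂ measurements exist, so `f(H₂)` is a pulse-budget switch:
activity proceeds (`f = 1`) while the day's cumulative H₂ consumption
(4 mol H₂ per mol sulfate reduced and per mol CH₄) is below `k_h2` times
that day's pulse, and stops otherwise. `k_h2` is the bioavailable fraction
of the pulse (default 1). No gas-phase partitioning or smooth H₂ Monod
term is modelled; this is an explicit assumption, not a fitted law.

**Integration.** Fixed-step classical RK4, default step 0.01 day (the
dynamics are non-stiff at these rates and a fixed step keeps runs
bit-reproducible). The cumulative bookkeeping integrals (consumed,
inflow, outflow, CH₄) are integrated as part of the RK4 state, so sulfur
and iron close to machine precision; the test suite enforces closure to
0.1% of throughput over randomized parameter draws. If gypsum exhausts
mid-step the overshoot is returned to the dissolved pool before pinning
the inventory at zero. Steps large enough to drive any state below −10⁻⁹
abort with advice to reduce the step. The ground truth of a run is the
time-averaged volumetric rate, cumulative sulfate consumed /
(duration × V_v).

**Defaults.** Geometry 942 cm³ interior, 424 cm³ voids (45% porosity);
inflow 15 mM sulfate and 120 µM Fe(II); initial 15 mM / 120 µM; gypsum
8.2 mmol with `C_sat` = 20 mM and `k_gyp` = 0.02 day⁻¹; flow 4 µL min⁻¹
(experimentally observed range 0–32); H₂ pulse 0.5 mmol day⁻¹ (matching
~33–49 mmol totals over 73–108 days); `v_max,sr` = 0.25 µmol day⁻¹ cm⁻³
with `K_SO4` = 0.5 mM, chosen so the outflow sulfate declines visibly
from 15 mM over ~100 days while inflow and gypsum partially replenish it.

**Known limitation.** The only sulfide sinks are washout and precipitation
with *dissolved* iron (~0.1 mM scale), so whenever sulfate declines
visibly, simulated dissolved sulfide accumulates to the same order as
sulfate. Real reactors keep outflow sulfide one to two orders lower,
presumably by scavenging with solid-phase iron in the bentonite, which
this model deliberately excludes. Trajectory shapes for sulfate, iron and
all mole ledgers are faithful to the model; simulated sulfide levels are
not representative of outflow measurements and passing tests say nothing
about solid-phase iron chemistry.

## Observation model and ASV-grid generator

Weekly replicate sampling is emulated by Gaussian noise around the latent
trajectory value, truncated at zero by clipping, with per-analyte SDs
(defaults 0.5 mM sulfate, 10 µM sulfide, 5 µM Fe) and `n` = 3 replicates;
the reported spread is the sample SD (n−1), zero by convention for a
single replicate.

The ASV generator produces the 5×7 post-mortem grid (columns OL, CL, C,
CR, OR; rows 1–7 top to bottom). Expected compositions follow a geometric
rank-abundance curve (ratio 0.9 over 40 ASVs); the designated
hydrogenotroph taxon's expectation is multiplied by
`1 + A·exp(−d/λ)` with distance `d` from the H₂ delivery point (column C,
row 4), amplitude `A` = 4 and decay `λ` = 1.5 grid units. Counts are
negative-binomial (dispersion k = 10) at mean library size 30,000; the
kitome vector is drawn independently (NB, mean 20, k = 5); 16S copies/g
are log-normal (median 5×10⁸, σ_log = 0.7) with a ×3 central-column
enrichment. These defaults represent one realistic MiSeq-scale data set;
real amplicon data additionally carry compositional correlations, taxon
dropout and batch effects that the generator does not emulate, so passing
detection tests demonstrate the *pipeline*, not field-level effect sizes.

## Rate estimators

*Linear regression*: unweighted OLS of mean outflow sulfate vs day;
rate = −slope, reported per cm³ of void volume (mM day⁻¹ and
µmol day⁻¹ cm⁻³ coincide numerically). Slope SE and adjusted R²
(n−2 degrees of freedom) accompany the estimate; a constant series has
slope exactly 0 with undefined (NaN) R²; a rising trend yields a negative
rate rather than an error. Replicate SDs are ignored by default (a
weighted fit is deliberately out of scope since the reference workflow
reports plain adjusted R²).

*Mass balance*: the global balance above, with one convention worth
stating: `V_in_tot` includes the water that initially saturated the voids
(at the initial concentration). Without that term a closed reactor whose
sulfate falls from `c₀` to zero would show zero consumption; including it
makes the closed-system rate `c₀/days` and lets the estimator match the
simulator's exact consumption ledger to machine precision. The gypsum
term defaults to 10 mmol in configuration-driven balances, with the
measured ~8.2 mmol inventory used for supply ledgers. The numerator is
returned as the sulfate budget (mmol); a negative value (net
accumulation) warns instead of raising. The balance is exactly invariant
to how the outflow record is re-binned when bin concentrations are
flow-weighted means.

*Summaries*: arithmetic mean, sample SD (n−1 everywhere — the package
does not switch SD conventions between tables), RSD = 100·SD/mean.

**Validation scenario.** Estimator consistency and parameter recovery are
checked on a closed-system run (no flow, no gypsum, no iron) with a
zero-order rate of 1.75 µmol day⁻¹ cm⁻³, weekly sampling and 0.5 mM
sulfate noise. A 1.75 mM day⁻¹ depletion exhausts a 15 mM pool within
~9 days — too few weekly samples for any regression — so the validation
run starts at 105 mM over 49 days, giving eight weekly points inside the
zero-order regime. This is a stress test of the estimators at the
published rate scale, not an emulation of the monitored reactors (whose
defaults stay at 15 mM). Over 100 noise seeds the median absolute
relative error of the regression estimator is well under 10%, and both
estimators agree with ground truth within 1% noiselessly.

## Budgets and scale-up

Molar H₂:sulfate ratios are reported raw and display-rounded (half-up,
1 decimal). The H₂-oxidation conversion is exactly ×4. Per-backfill-volume
rates use `rate_void × porosity` (µmol cm⁻³ ≡ mol m⁻³); porosity defaults
to 0.45, the unique value reproducing both published void→backfill
endpoint pairs (2→0.9 and 7→3.2 mol day⁻¹ m⁻³) under half-up rounding of
the integer-rounded conversions, and should be overridden explicitly for
any site-specific calculation. The backfill fraction is
100·(inventory/horizon-days)/(rate × volume) with a 365.25-day year
(sensitivity to 365.0 is <0.1%). Fe:S classification uses nearest-target
assignment between pyrite (0.5) and mackinawite (1.0) inside
[0.5 − tol, 1.0 + tol] with default tol 0.25; boundary values, including
the 0.75 midpoint, assign to the lower class.

## Community statistics

Kitome correction subtracts the blank's per-ASV reads from every sample,
clamped at zero with clamped cells flagged. Per-sample normalization
divides by the *post*-subtraction total (this keeps proportions summing
to 1; the pre-subtraction alternative is a one-line change and the
reads-first reactor-level averaging — mean reads, then subtract, then
normalize — is provided separately because the two orders do not
commute). Presence is confirmed only when mean raw reads strictly exceed
the taxon's kitome reads; ties fail. Ordination is a column-centered SVD
of the Hellinger-transformed proportions; explained-variance fractions
are non-increasing and cross-checked against an independent eigenvalue
oracle in the tests.

Column biomass tests compare each off-center column to the center:
a two-sided variance-ratio (F) gate at α = 0.05 selects pooled vs Welch
t-test, then a one-sided test of "off-center < center" (the directional
phrasing of the underlying hypothesis; a two-sided variant is a parameter
away). Raw p-values are reported with **no multiplicity correction**,
matching the reference workflow — flagged here because four comparisons
per reactor inflate the family-wise error. 16S copies/g are analyzed on
the natural scale; a log₁₀ transform can be applied upstream. Realized
type-I error of the compound procedure is ~4–5% at nominal 5% (n = 7 per
column), within the ≤7% acceptance band. Spatial maps interpolate the
7×5 grid bilinearly; up to 50% missing nodes are nearest-neighbor-filled
first, and node values are reproduced exactly.

## Problem sizes and determinism

Test and acceptance runs use 40–60-day simulations at step 0.01–0.02 day,
50 conservation draws, 100 recovery seeds, 2,000 null grids and 200
generated ASV tables — sizes at which every statistical margin in the
suite is comfortably resolved. All randomness flows from explicit
`numpy.random.default_rng` seeds; the chemistry integrator itself is
deterministic, and reports are byte-identical across reruns with the same
configuration.
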