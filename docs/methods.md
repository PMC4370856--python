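# Methods

This note documents the modelling conventions, parameter defaults and
numerical choices behind `landfolio`, and the points where the package's
results deliberately differ from the originally reported figures.

## Valuation

Every land-use option is reduced to one random variable: the annuity of its
net-revenue stream over a 30-year horizon at a 5% discount rate (the rate
customary for tropical farm/forestry appraisal). The annuity factor
(q−1)q^T/(q^T−1) has a removable singularity at d = 0, handled as the
arithmetic-mean limit. Annuities are linear in cash flows, and the annuity
of a level stream equals that level — both properties are tested.

**Establishment timing.** Perennials (banana every 10 years, organic banana
every 10, cocoa every 15) are charged their establishment cost at the
replacement years that fall inside the horizon (t = 10, 20 for banana;
t = 15 for cocoa); the planting at t = 0 is treated as sunk, outside the
annuity window. With the packaged coefficients this gives a deterministic
conventional-banana annuity of ≈1788 US$/ha/yr, matching its documented
mean return (1786) — the alternative of also charging t = 0 gives ≈1604 and
is available as `establishment_timing="cycle_start"`. The same convention is
applied uniformly to all options; see "Known discrepancies" for its
consequences for organic banana and cocoa.

**Forestry.** Stand arithmetic follows the management plans: per-tree volume
is a form-factor (0.70) cylinder over the DBH disc; 20% of planted seedlings
(833/ha) die; each intervention removes its thinning fraction of the
*currently standing* stems (50% thinning then 100% final felling clears the
stand). The plan's per-cycle revenue and harvesting-cost lumps are allocated
across interventions proportionally to removed volume, establishment is
charged at cycle replacements, and a final cycle cut off by the horizon is
truncated.

## Uncertainty simulation

**Joint-year bootstrap** (crops with a 1970–2009 history). Each of 1000
realizations draws the 30 horizon years independently, with replacement,
from the 40 observed years. A drawn year contributes its own (price, yield)
pair — preserving within-year dependence — and the same drawn calendar years
are used for every crop, carrying the empirical cross-crop dependence into
the joint annuity sample. Year-to-year autocorrelation is deliberately not
modelled. Before resampling, each series is rescaled by mean ratios so its
average price/yield equals the current level; this linear map leaves CVs and
correlations untouched (asserted to 1e-12).

**Monte-Carlo simulation** (no usable history). Organic banana draws
independent per-year normal prices and yields around its current levels
(398 US$/Mg, 15 Mg/ha) using the conventional banana series' CVs (65%
price, 22% yield) as dispersion proxies; timber options draw one normal
price multiplier and one growth multiplier per rotation cycle (CV 10%
each). Draws are truncated at zero by clipping: at the organic price CV of
0.65 about 6% of the mass is clipped, lifting the mean price by ≈1.7%; at
CV ≤ 0.22 the effect is negligible. A per-realization draw mode (one price
level for the whole horizon) is available; it roughly √30-fold widens the
annuity SD and is off by default.

**Low-risk organic price scenario.** The reduced organic price risk is an
absolute SD of ±30 US$/Mg *expressed on the conventional banana raw price
scale* (mean ≈84.5 US$/Mg, i.e. price CV ≈0.355, versus ±55 ≙ CV 0.65 in
the high-risk case). Under this reading the simulated organic return SD
comes out at ≈500–510 US$/ha/yr (CV ≈50%), consistent with the documented
±506; applying ±30 at the organic price level (398) would instead give a
return CV of ≈27% and is *not* what the reduced-risk scenario means. The
reference-statistics route uses ±506 directly.

**Correlation handling.** Pearson correlations are computed from
equal-length paired samples; the published correlation matrix (with the
organic row assumed) ships as packaged reference data with per-entry
provenance flags. Matrices are repaired to PSD by eigenvalue clipping plus
unit-diagonal rescaling only when needed — the reference matrix is already
PD (smallest eigenvalue ≈0.40), so repair is the identity there. A target
correlation between organic and conventional banana returns is imposed by
Gaussian-copula rank matching: a bivariate normal sample supplies the joint
rank pattern and the organic sample is permuted to follow it, leaving both
marginals untouched.

**Normality screening.** Mean–variance analysis summarizes each return
distribution by two moments, so a χ² goodness-of-fit against a fitted
normal is provided: equal-probability bins under the fitted normal,
bin count max(5, n/200), degrees of freedom bins−3 (two fitted
parameters). The binning rule is a package choice; no rule was documented
for the original analysis.

**RNG.** A single root seed (default 20150323) is split into independent
child streams (bootstrap, organic, balsa, laurel, copula) via
`numpy.random.SeedSequence.spawn`; with a fixed seed all outputs are
bit-reproducible, which the suite asserts.

## Optimization

The long-only, fully-invested mean–variance problems are solved exactly by
face enumeration: the optimum of a convex QP lies on a face of the simplex,
where it is the stationary point of the equality-constrained restriction
(a small KKT linear system). All candidates are primal feasible, so the
best candidate is the global optimum — no iterative-solver tolerances enter
the results, and solutions are deterministic by construction (ties resolve
to the first face in a fixed enumeration order). With an active return
floor the KKT solution is affine in the floor, so the per-face solutions are
precomputed once and floor sweeps are cheap. The risk-capped return maximum
is found by bisection on the return floor (60 iterations; σ_min(floor) is
nondecreasing), which also breaks return ties toward lower variance. This
enumeration is exponential in the number of options and intended for the
problem sizes of land-use planning (here 8; practical to ~15).

Budget/nonnegativity tolerances are 1e-8; composition tables report weights
below 5e-4 as zero, matching whole-percent reporting. An exhaustive
simplex-grid search (step 0.01) serves as an independent test oracle on
small instances; the exact solutions dominate the lattice and agree within
lattice resolution.

**Scenario inputs.** The named presets (baseline without organic, organic
high risk, organic low risk, correlation sweep) default to the *published*
per-option statistics and correlations as optimizer inputs: those are the
only inputs under which the documented portfolio compositions are
reproducible, and they make the scenario layer deterministic. A
`stats_source="simulated"` mode feeds the optimizer from the simulation
pipeline instead. The default cap grid runs from ⌈minimum-variance SD⌉ to
the largest single-option SD in steps of 50 US$/ha/yr plus the documented
named caps (50, 52, 500, 650, 700, 900).

## Synthetic data

The generator emulates the statistical shape of national commodity series:
lognormal marginals around linear trends (nonnegativity for free),
Gaussian-copula dependence within years (price–yield), and a configurable
cross-crop price correlation. Requested correlations refer to the generated
values, so the copula correlation is analytically adjusted for lognormal
attenuation; unreachable targets are clamped. Round-trip recovery of means,
CVs, trends and correlations is asserted at n = 10 000 within 3%. What the
generator does **not** emulate: regime breaks (such as the late-1980s
banana price jump in the real series), autocorrelation, and heavy tails —
pipeline tests on synthetic data therefore validate mechanics and moment
logic, not the historical idiosyncrasies of any particular market.

## Known discrepancies from the originally reported return table

The published per-option return table is not internally consistent with its
own stated simulation procedure, and this package does not chase it
crop-by-crop. Concretely, with the paired within-year bootstrap:

* **Conventional banana**: prices and yields trend together
  (corr ≈ +0.33), so joint resampling adds a covariance term and the
  bootstrap mean is ≈2100 US$/ha/yr, not the reported 1786 — the reported
  value equals the *independent-draw* expectation E[p]·E[y] − costs
  (≈1788). The SD (≈950–1000 vs reported 945) is consistent either way.
* **Rice**: the reported mean 486 is not reachable under any draw scheme —
  point inputs give 366 and the paired bootstrap ≈385 (the price–yield
  covariance bonus is only ≈+20); its reported SD (101 vs our ≈90) is
  consistent.
* **Maize** matches independent draws (≈256 vs reported 247), while
  **cocoa** (159) and **organic banana** (1040) match means computed
  *without* establishment deductions (≈157 and ≈1025); with the uniform
  establishment convention this package yields ≈107 and ≈822–925 for them.
* **Forestry**: expanding the management plans under the packaged
  coefficients gives balsa ≈642 and laurel ≈370 US$/ha/yr, both ≈2.4× the
  reported 271/154; no timing convention tried (establishment at or after
  t = 0, harvest-cost placement, revenue at final felling only) closes the
  gap, suggesting the original cash-flow worksheets contained additional
  costs or smaller effective revenues than the published coefficient table.

Because the scenario/optimization layer consumes the published statistics
table directly (shipped as reference data), all portfolio-level results —
minimum-variance composition, risk-capped returns, organic-banana shares
and scenario deltas — reproduce the documented figures to within rounding,
independent of these simulation-level discrepancies.

## Problem sizes and defaults

1000 simulation repetitions (the documented setting) and a 30-year horizon
are the defaults everywhere; convergence-style tests use up to 100 000
repetitions, and synthetic round-trips use 10 000-year series. The full
test suite and all analysis scripts run in well under a minute on one CPU.
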