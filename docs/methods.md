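# Methods

This note documents the models, numerical choices and limitations of the
package, in the order of the analysis chain.

## Leaf-drying curves and minimum conductance

A detached leaf, rehydrated overnight and wax-sealed at the petiole, is
weighed repeatedly while drying on a bench. The record carries the mass
series (leaf + wax), the saturated mass, the oven-dry leaf mass, the wax
mass, and the single projected area at full hydration.

**Relative water deficit.** Leaf water at any weighing is
`W_t = m_t − m_wax − m_dry`; the saturated weighing is assumed to
include the wax seal (sealing precedes the first weighing), so
`W_sat = m_sat − m_wax − m_dry` and `RWD = 1 − W_t/W_sat`, clipped to
[0, 1].

**Driving force.** Conductance needs the leaf-to-air water-vapour
mole-fraction difference `Δw = e_sat(T)(1 − RH)/P`. Saturation vapour
pressure uses Buck's (1981) formulation
`e_sat(T) = 0.61121·exp[(18.678 − T/234.5)·T/(257.14 + T)]` kPa, which
is accurate over the 0–40 °C bench range. Leaf temperature is assumed
equal to air temperature and intercellular air saturated — the standard
assumptions for slow bench drying. Bench conditions default to 25 °C,
RH 0.50, 101.325 kPa; all outputs record the environment used, because
conductance is undefined without it.

**Transpiration and conductance.** First differences of the mass series
are assigned to interval midpoints with no smoothing by default (an
optional width-3 moving median is available):
`E = (Δm/Δt)/(M_w·A_corr)` with `M_w = 18.015 g mol⁻¹` and
`A_corr = 2·A_proj·(1 − loss(RWD_mid))` the double-projected area
(both leaf surfaces transpire) corrected for drying shrinkage;
`g = E/Δw`. Shrinkage models are linear in RWD through the origin,
predictions clamped to [0, 1]; species without their own shrinkage
curves borrow a reference taxon's model through a caller-supplied map.

**Turgor loss point and g_min.** The conductance–RWD curve has two
regimes: a steep stomatal-closure phase and a flat cuticle-dominated
plateau. The TLP is located as the changepoint of a two-segment linear
least-squares fit (each segment its own line, split at an observed
point; the reported TLP is the RWD midpoint across the best split). A
free two-segment fit is used rather than a continuous hinge because a
hinge cannot represent a flat–cliff–flat shape and systematically
places its knot beyond a sharp transition; the free split locates step
changes exactly and behaves identically on smooth curves. The split
must reduce SSE by ≥ 25% relative to a single line, otherwise the
plateau is declared unidentifiable (a flat series, for instance, has no
breakpoint); a fixed RWD threshold can be supplied to bypass detection.
`g_min` is the arithmetic mean of conductance over points with
`TLP < RWD < 0.7` — the upper bound excluding lethal dehydration — and
is reported both in mmol m⁻² s⁻¹ and as a velocity via the molar
density of air `P/(R·T_K)` (R = 8.314 J mol⁻¹ K⁻¹) at the record's own
bench temperature, chosen for self-consistency since conversion
temperature is otherwise arbitrary.

**Succulence.** `DS = W_sat/(2·A_proj)` (g m⁻²),
`SWC = W_sat/m_dry` (g g⁻¹, undefined when the dry mass is zero), and
leaf thickness is a caliper pass-through.

## Titration and ΔH⁺

Free-acid content per gram fresh weight: each technical replicate's
NaOH volume is converted to μmol of acid (`V·C`), scaled from the
aliquot to the whole extract (`×extract/aliquot`), normalised by fresh
mass, and replicates are averaged at the content level (identical to
volume-level averaging under equal masses; stated for determinism).
`ΔH⁺ = morning − evening`, signed: negative values record net overnight
de-acidification and are preserved, not folded into magnitudes. Samples
outside the 50 ± 20 mg protocol window are analysed but flagged.
Evening/morning pairing is by (taxon, individual, group, phase);
unpaired samples are reported as exclusions, never silently dropped,
and duplicate coordinates are an error naming the collision.

## Treatment statistics

The factorial design has six groups (two acclimatisation temperatures ×
{control, drought, temperature-switch}) and three phases
(acclimatisation, treatment, reversal). The effect matrix compares each
taxon's treatment-phase ΔH⁺ against the matching control group's same
phase, and each reversal phase against the same group's treatment
phase, as percent change `100·(x̄_t − x̄_r)/|x̄_r|`. Tests are Welch
(unequal-variance) two-sided t-tests, unpaired across individuals —
replicate numbers differ between taxa, and pairing across phases is not
assumed. Cells with a single replicate report the effect with an `n1`
flag instead of a test; missing references yield a `missing` flag so no
design cell disappears silently. No multiple-testing correction is
applied by default (per-taxon tests are reported as-is); a
Benjamini–Hochberg switch can be layered on the output table.
Cross-species regressions use species-level means; minimum conductance
enters through the natural logarithm (its distribution is approximately
exponential across species; the log base affects only the slope scale,
not p or r²).

## Phylogenetic comparative methods

Under Brownian motion, tip values are multivariate normal with
covariance proportional to shared branch lengths, `x ~ N(μ·1, σ²·C)`.
Pagel's λ multiplies the off-diagonal of `C`; the admissible upper
bound is the minimum over tip pairs of `min(C_ii, C_jj)/C_ij`, capped
at the ultrametric bound 1.0 by default (configurable).

**Estimation.** For fixed λ, μ and σ² have closed-form GLS/ML solutions
(`μ̂ = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x`, `σ̂² = rᵀV⁻¹r/n`); λ is maximised by bounded
scalar search seeded from an 11-point grid to avoid local optima (the
test suite verifies the optimum dominates a 50-point grid). ML, not
REML, is used throughout so nested likelihoods are comparable. With
per-species standard errors, `diag(SE²)` is added to `σ²·V` and σ² is
profiled numerically. Star trees make λ unidentifiable (all
off-diagonals zero); the fit is returned at the lower bound with an
explicit flag. Polytomies need no special handling — the pruning
recursion combines children sequentially, equivalent to zero-length
resolution, which leaves the likelihood unchanged.

**Likelihood-ratio test.** `LRT = 2(logL(λ̂) − logL(0))` is referred to
χ²(1) by default; a 50:50 point-mass/χ²(1) boundary mixture is
available as an option. Because the null λ = 0 lies on the parameter
boundary, λ̂ sticks to zero in well over half of null samples and both
references are conservative in practice (empirical type-I ≈ 1–2% at
nominal 5% on 200-tip trees; the reference R implementation behaves the
same way). The test is therefore valid but not exactly calibrated; this
is a property of the statistic, not a tuning choice.

**PGLS.** GLS regression with `V = C(λ)`, λ either fixed at 1 (BM) or
estimated by ML jointly with the coefficients (the default). Standard
errors use the unbiased residual variance `RSS_gls/(n − p)` and t tests
with `n − p` degrees of freedom, matching `nlme::gls`; with an identity
structure the fit reproduces OLS exactly. Two independent likelihood
code paths (dense Cholesky and Felsenstein pruning) agree to 1e-8 in
the tests, and λ/PGLS estimates are cross-checked against
`phytools::phylosig` and `nlme::gls(corBrownian)`.

**Ancestral states.** ML states under BM at internal nodes are the GLS
conditional expectations `â = μ̂ + cᵀC⁻¹(x − μ̂1)` with `c` the vector
of node–tip shared path lengths; reported variances include the
uncertainty of μ̂. The root state equals μ̂ by construction. The test
suite checks the states against an independent numerical maximiser of
the joint BM likelihood over all node values.

**Pruning and lumping.** Data taxa are mapped onto tree tips through an
explicit lump map (e.g. subspecies pooled into one tip); replicate
values are pooled per tip before species means. Tips without data are
pruned; data taxa with neither tip nor lump rule raise an error listing
every orphan.

## Synthetic data

The generator exists so each analysis stage can be validated by
simulate-then-invert round trips; its defaults describe the study
conditions the package targets.

* **Trees** are pure-birth with exponential waiting times, rescaled to
  unit depth; **traits** are drawn from `N(root·1, σ²·C(λ))` by
  Cholesky factorisation, with optional per-tip observation noise.
* **Drying curves** integrate `dW/dt = −(g_c + g_s0·e^{−t/τ})·Δw·A(RWD)·M_w`
  by explicit Euler with eight sub-steps per weighing interval; stomatal
  closure is a single exponential (τ = 300 s, initial stomatal
  conductance 5 mmol m⁻² s⁻¹), which produces the two-phase curve shape
  without extra parameters. The sampling schedule places geometric
  early points across the stomatal transient and linear points to
  RWD ≈ 0.85. Measurement noise is multiplicative on each per-interval
  water-loss increment (default 1% SD) — endpoint-reading noise that
  keeps the recorded masses monotone; it is not per-reading balance
  noise, which at 1% of leaf mass would exceed the per-interval signal
  itself. A schedule so coarse that one Euler step would lose > 5% of
  the saturated water is refused.
* **The titration design** mirrors the factorial experiment: 36 taxa by
  default, of which nine contribute a single plant assigned to the
  cold-switch group (the one group every taxon undergoes) and the rest
  six plants per group; three phases, evening + morning harvests, three
  technical replicates with 5 μl endpoint noise, 8 μmol g⁻¹ biological
  content noise. Group × phase effect multipliers on the per-taxon
  baseline ΔH⁺ default to: drought 2.5× (cold) / 2.0× (warm), heat
  switch 3.0×, warm→cold switch 0.6×, reversals relaxing to 1.2–1.5×,
  controls 1 — chosen once to represent facultative CAM upregulation
  under drought and heat with partial persistence after stress relief.
* **The full study generator** couples the pieces: species-level
  log g_min evolves under λ-transformed BM (λ = 0.5) spanning
  ≈ 0.07–5 mmol m⁻² s⁻¹, the observed range across the genus; baseline
  ΔH⁺ is `60 − 18·ln(g_min)` plus noise (stronger CAM behind tighter
  cuticles); succulence evolves with λ = 0.8 over ≈ 300–2000 g m⁻² with
  leaf thickness tracking it; climate covariates are built with a set
  phylogenetic correlation to the baseline ΔH⁺. A manifest JSON records
  every true parameter for recovery tests.

What the generator does **not** emulate: real balance drift, leaf-age
and temperature dependence of cuticular conductance, titration endpoint
bias (only unbiased noise), non-linear shrinkage, within-species
phylogenetic structure, or chamber microclimate dynamics. Passing
round-trip tests therefore demonstrates correctness of the inversion
chain under the stated model, not robustness to every field artefact.

## Problem sizes

Unit tests run on 2–100-tip trees and 12-taxon studies; the end-to-end
test and the acceptance script use the full 36-taxon factorial design
with six plants per group and three drying curves per taxon, and λ
calibration uses 60–100 replicates on 200-tip trees (500 for the null
rejection-rate test). These sizes give stable Monte-Carlo summaries
while keeping the whole suite in the low minutes on one CPU.

## Known limitations

* The TLP changepoint assumes a two-regime curve; leaves whose stomata
  close before the first weighing have no identifiable breakpoint and
  are excluded (or need the fixed-threshold override).
* g_min inherits any error in the assumed bench environment linearly
  through Δw; records therefore carry their environment explicitly.
* The λ LRT is conservative near the boundary (see above); its p-values
  are trustworthy as upper bounds.
* PGLS assumes the predictor is measured without phylogenetically
  structured error; measurement-error support exists only for λ
  estimation (via per-species SEs), not for PGLS.
* The ΔH⁺ pairing requires exact design-coordinate matches; fuzzy
  matching (e.g. mislabelled individuals) is out of scope.
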