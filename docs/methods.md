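# Methods

## The mass-balance model

`herbflux` treats a forest stand as a one-pool annual budget for foliage.
Leaves are produced (FP, g m⁻² y⁻¹), a proportion H of their area is eaten
by insect folivores over the leaf lifespan, and the remainder falls into
litter traps (L_H).  Because traps catch only what herbivores left,
production is reconstructed as FP = L_H / (1 − H).  The element mass moving
through folivores is H_c = FP · F_E · H, where F_E is the green-leaf mass
fraction of the element.  Under the steady-state assumption — herbivore
populations and migration roughly stable, so consumption is returned to the
floor within the year as excreta, bodies, moults and fragments — H_c is
also the gross element deposit.  This assumption is documented metadata,
not a computation.

The *net* effect of herbivory on soil inputs arises because folivores eat
green tissue before the tree resorbs nutrients during senescence.
Resorption efficiency is estimated from paired green/litter chemistry with
a senescence mass-loss correction, RE_E = 1 − (c_litter / F_E) · MLCF,
with MLCF = 0.78 for predominantly evergreen and 0.784 for predominantly
deciduous angiosperm forests.  The net flux is H_i = H_c · RE_E.  The
equivalent three-term budget H_i = L_EH + H_c − L_E (observed minus
counterfactual litter flux) is maintained as an exact algebraic identity by
defining the counterfactual flux as L_E = L_EH + FP · H · MLCF · c_litter:
foliage that was eaten would otherwise have senesced (losing mass by MLCF)
and fallen at the litter concentration.  A property test enforces the
identity to 1e-12 relative error.  RE and H_i are defined for C, N and P
only; Si carries a gross flux but no resorption pathway.  RE values outside
[0, 1] — possible with noisy chemistry — are flagged and returned, never
clamped, because clamping would bias the net fluxes.

## Herbivory estimation

Litter leaves are scored into six leaf-area-removal classes (0–1, 1–5,
5–25, 25–50, 50–75, >75 %) or as undamaged; the undamaged count is kept
separate because the lowest class is ambiguous about zero damage.  H is
the interval-midpoint mean (midpoints 0.5, 3, 15, 37.5, 62.5, 87.5 %);
the scheme is configurable so midpoint sensitivity can be probed.
Incidence is the fraction of leaves placed in any damage class.  Within a
year, scan tallies are pooled by summing counts (leaf-weighted); across
the 1–2 collection years the yearly estimates are averaged unweighted.
The pooled-counts order was chosen over per-scan averaging because scans
differ in leaf numbers for sampling reasons only; the per-scan path is
available via `herbivory_rate` on individual tallies.

## Litterfall and coverage

Trap annual litterfall is the summed dry mass over a trap-year divided by
trap area, with no partial-year extrapolation: litterfall is strongly
seasonal, so linear scaling of short series is wrong.  A series must span
at least 300 days unless explicitly flagged as covering the complete
deposition season (the intended path for deciduous stands sampled over the
entire leaf-fall period).  Plot L_H averages traps within a year, then
years unweighted; the SE is across traps.

## Statistical layer

Responses and predictors are transformed (proportions → logit, with exact
0/1 shifted inward by 1e-4 and a warning; fluxes, production and
concentrations → log; climate and stoichiometric predictors untransformed
unless right-skew exceeds 2) and z-scored, so mixed-model coefficients are
standardized effect sizes.  Predictor sets are screened with variance
inflation factors (threshold 2; perfect collinearity reports ∞ and fails).
Models are Gaussian with a random site intercept, fitted by REML through
statsmodels MixedLM.  Confidence intervals are percentile intervals from a
parametric bootstrap (default 1000 simulations) that re-simulates
responses from the fitted model and refits; an effect is significant when
its 95 % interval excludes zero.  Marginal and conditional R² follow the
variance-component decomposition r²m = var_f/(var_f+var_g+var_e),
r²c = (var_f+var_g)/(var_f+var_g+var_e) with var_f the sample variance of
the fixed linear predictor.

Zone contrasts use the tie-corrected k-sample Kruskal–Wallis test with the
χ² reference distribution, followed by Dunn pairwise mean-rank comparisons
(tie-corrected variance) adjusted by Holm (default) or Bonferroni; a
compact-letter display summarizes groupings.  The H statistic is computed
in-module from the rank formula and cross-checked against
`scipy.stats.kruskal` in the tests; the small-sample behaviour of H and
the Dunn z is additionally verified exhaustively against definition-level
brute-force rank computations over every unordered triple of groups with
up to four values from {1..6} (~1.5 million datasets — rank statistics are
invariant under group relabeling, so ordered triples add nothing).

### Numerical choices

* **Bootstrap refits** use an in-module profiled-REML solver for the
  single-random-intercept model: with the variance ratio θ = σ²_u/σ²_e
  profiled, β and σ²_e have closed forms via per-group sums, leaving a 1-D
  bounded minimization.  It agrees with MixedLM to ~1e-4 (unit-tested) and
  runs ~40× faster, which makes thousand-draw bootstraps and replicate
  studies practical.  A boundary solution (log θ at the lower bound) is
  reported as a zero variance component.
* MixedLM occasionally stalls on degenerate inputs (e.g. exact linear
  relations with zero residual variance); `fit_lmm` then falls back to the
  profiled solver with a warning rather than failing.
* Percentile (not BCa) bootstrap intervals; interval type is a convention
  choice and percentile is the simplest defensible one here.
* All stochastic procedures take an explicit seed (package default
  20240717) and are reproducible bit-for-bit under it.

## Synthetic plot networks

The generator emulates the study design the accounting assumes: ~40 sites
with 1–3 plots, mean annual temperature uniform on (−1.4, 26.9) °C and
dryness (PET/MAP) uniform on (0.21, 1.30); latitude zones assigned by MAT
terciles (the analysis consumes zone + MAT, not geography — latitude is
synthesized only as a label); 9–25 litter traps of 0.1–0.5 m² per plot;
quarterly damage scans; one collection year by default (two supported).

Structure, on the transformed scales the analysis uses:

* logit H = logit(0.04) + 0.4 · z(MAT) + site effect (sd 0.3) + plot noise
  (sd 0.1), giving a global mean near 4 % and a plot range of roughly
  1–13 %, with configs that push H outside (0, 0.5) rejected;
* log FP = log 320 + 0.5 · z(MAT) − 0.15 · z(soil C:N) + noise (sd 0.25),
  reproducing the tropical ≫ temperate ≫ boreal production gradient;
* green chemistry drawn per zone (foliar N and P lower in the tropics);
  resorption truths drawn per zone around the published zone means, litter
  chemistry constructed exactly as c_litter = F_E(1 − RE)/MLCF so the RE
  estimator inverts the truth identically;
* per-trap annual mass lognormal (log-sd 0.2, mean-preserving) around
  L_H · area, split into twelve monthly intervals by a phenology-specific
  seasonal profile (autumn-heavy for deciduous stands);
* damage tallies multinomial over {undamaged, six classes}: incidence is
  12 × H capped at 0.95 (bracketing ~49 % of leaves damaged at 4 %
  herbivory), and class probabilities come from a beta severity
  distribution (concentration 2) whose mean is calibrated by a 1-D root
  solve so that the class-midpoint estimator is exactly unbiased for the
  configured H.  Without this calibration the midpoint estimator would
  carry a constant discretization bias and could not converge to the
  generator's truth as leaf counts grow;
* reference inputs are set to the published zone means so
  comparison outputs are on a realistic scale.

All randomness flows from one seed through spawned sub-streams per table;
identical config + seed gives byte-identical bundles.

**What the generator does not emulate** — and hence what passing recovery
tests do and do not show about real data: no outbreak dynamics or temporal
autocorrelation within years, no multi-species leaf pools or species
turnover, no spatial structure beyond the site random effect, no
measurement error in chemistry shared between green and litter samples
(so RE recovery is exact by construction rather than approximate as in the
field), and observer error in damage scoring is absorbed into multinomial
sampling rather than modeled as bias.  Recovery tests therefore validate
the estimators and inference machinery under the model's own assumptions,
not robustness to their violation.

## Problem sizes used in the test suite

Parameter-recovery checks run 20 replicates of a 30-site × 2-plot network
with 200-draw bootstraps for the strong-effect and null scenarios — sizes
chosen to give stable pass/fail behaviour (binomial bounds on 20–40
trials) at desk-scale runtimes.  Estimator-consistency checks use 200
plots with 1000 and 4000 scored leaves per scan.  The exhaustive rank-test
verification covers all ~1.5 million unordered small-sample datasets
described above.

## Known limitations

* The accounting captures folivory only; root herbivores, sap-suckers,
  compensatory growth and herbivore-induced changes in plant communities
  are out of scope.
* Herbivore C allocation between biomass and respiration is not
  partitioned; gross and net C are reported as removed from foliage.
* Nutrient leaching from trapped litter between collections is assumed
  negligible, and herbivores are assumed to feed before resorption begins.
* Zone-level reference inputs (deposition, weathering) are consumed as
  inputs from external models, never recomputed.
* The Dunn letter display uses a greedy set-splitting algorithm; letter
  assignments (not significance calls) can differ from other
  implementations in rare tie-heavy cases.
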