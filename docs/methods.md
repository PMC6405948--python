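# Methods

`saiplan` evaluates whether cheap, plot-level abiotic variables — soil
organic carbon (SOC) stock in particular — can stand in for species survey
data when prioritizing sites for the conservation of threatened plants. It
implements the full chain from raw tables to a Species Accumulation Index
(SAI) surrogacy verdict, and ships a synthetic-landscape generator so the
chain can be exercised and validated end to end without field data.

## The data model

Inputs are three CSVs: a plot × species presence/absence matrix, a plot ×
covariate table whose columns include a designated SOC stock (Mg C ha⁻¹ to
30 cm depth), and a one-column list of threatened species. Validation is
strict: cells must be 0/1, IDs unique, and rows with missing covariate
values are rejected with a report — no imputation is attempted, because none
could be justified from the study design. Categorical covariates (landform
class, depositional environment, …) are indicator-encoded against an
alphabetical reference level so that every downstream stage sees a purely
numeric design matrix and variance inflation factors stay well defined.

## Collinearity screen

VIF_j = 1/(1 − R²_j), with R²_j from an intercept OLS regression of
covariate j on the rest. The reduction is the standard stepwise variant:
drop the single worst covariate while any VIF ≥ 3, ties broken
alphabetically so the retained set is invariant to column order. Exact
linear dependence is reported as an infinite VIF rather than an error so
the offending column can still be ranked and removed. The threshold 3 is
the conventional strict screen and is exposed as a parameter. Generalized
VIF for multi-level factors is out of scope; indicator columns are screened
as ordinary covariates.

## Threatened-presence importance ensemble

Because most plots hold zero or one threatened species, the response is
presence of *any* threatened species per plot. Twenty random-forest
classifiers are fitted, each on an independent uniform 70% plot split
(30% held out). Hyperparameters are pinned rather than left to library
defaults — 500 trees, √p candidate variables per split, unlimited depth —
because defaults drift between ecosystems. Importance is the mean decrease
in Gini impurity, standardized within each run by the run's maximum so the
top predictor scores exactly 1; accuracy is the majority-vote correct
fraction, reported on both the training and held-out plots with both SD and
SE across runs. Single-class training splits (possible at extreme class
imbalance) are redrawn from the next random substream with a logged
warning.

The SOC group comparison is a one-way ANOVA of soil carbon across plots
grouped by their exact threatened-species count, followed by Tukey HSD for
all pairs (scipy implementations). Count groups with fewer than two plots
cannot contribute a within-group variance and are merged into the nearest
adjacent count with a warning.

## Optimal conservation scenario

The greedy complementarity ("species richness") algorithm: repeatedly pick
the plot adding the most not-yet-represented target species, ties broken by
input plot order, stopping at full representation (a site-budget override
exists). The target set defaults to the threatened species — the
conservation object — with an all-species switch. Greedy selection on this
coverage objective is submodular, so marginal gains are nonincreasing; the
test suite verifies first-pick optimality and full-representation
equivalence against exhaustive search on small instances.

Plot importance scores must span 0 (unselected) to 1 (the plot with the
highest richness of unrepresented species). Only those endpoints are
pinned by the protocol; for intermediate plots this package uses marginal
gain normalized by the maximum gain, which is monotone in conservation
contribution and reproduces both endpoints. This is one defensible choice
among several; it is recorded in every output.

## Surrogacy evaluation (SAI)

For each calibration fraction q ∈ {5, …, 60}% and each of `n_models`
repetitions: draw ⌈q%·n⌉ plots; run the greedy selection *within* the
subset and score its plots; fit a random-forest regression (500 trees, p/3
candidates per split) of those scores on the subset's surrogate covariates;
predict scores for all plots; keep the `site_budget` top-ranked; count the
unique target species S they represent. The budget defaults to the size of
the full-data greedy solution, the smallest set representing every
representable target species; O is the species that solution represents at
that budget, and R is the mean over `n_random` uniform draws of
budget-many plots.

Two numerical choices deserve emphasis:

* **Out-of-bag predictions for calibration plots.** Predicting the whole
  planning area with in-bag fits lets the forest memorize its calibration
  plots' scores: a pure-noise surrogate then inherits genuinely good plots
  from its calibration subset and scores SAI ≈ 0.3–0.6 instead of 0. Using
  each calibration plot's out-of-bag prediction removes that leakage; noise
  surrogates then center on 0 (with a small negative residual from the
  usual OOB anti-correlation), which is the behaviour a null surrogate
  must have for SAI to be interpretable.
* **SAI denominator.** The printed formula (S−R)/(O−S) is inconsistent
  with the stated range (−∞, 1] (it diverges as S → O and is undefined at
  the optimum). The default is therefore the range-consistent form
  (S−R)/(O−R), which is 1 exactly at the optimum and 0 at random
  performance; the printed form remains available as the `as_printed`
  variant and every output records which variant produced it.

Curves report the per-repetition SAI values, their mean, and a 95%
percentile interval, and annotate the conventional 0.2 reliability
threshold. `compare_surrogates` evaluates several variable sets on
*identical* calibration draws and forest seeds (they depend only on the
master seed, q and the repetition index), so between-set differences are
paired and duplicated sets are bitwise identical.

## Synthetic landscapes

The generator emulates a Southern-Patagonian permanent-plot network: 145
plots, 470 species, 37 threatened. SOC is log-normal (stocks are
nonnegative and right-skewed; arbitrary units ~45 Mg C ha⁻¹ median),
other covariates are independent standard normals with Fig-2-style labels,
plus configurable near-duplicate columns (r ≈ 0.98) to exercise the VIF
screen. Threatened species follow a logistic occurrence model: within a
species-specific random habitat (15% of plots by default), occurrence is
Bernoulli with logit = logit(b_s) + soc_effect · z(SOC), b_s uniform on
(0.02, 0.10); outside the habitat the species is absent. The habitat masks
matter: with a single shared SOC slope and no species structure, the
highest-carbon plot ends up hosting *every* threatened species and the
optimal scenario collapses to one plot — no field network looks like that.
With the defaults, ~85% of plots hold 0–1 threatened species, each
threatened species occupies 2–6 plots, and the optimal scenario spans
~13–14 plots. Non-threatened species are covariate-independent Bernoulli
draws (an optional mild SOC coupling exists, off by default), so any
surrogacy signal traces to the threatened set by construction.

Species drawn in zero plots are dropped with a warning (non-threatened) or
redrawn (threatened — keeping the threatened set at its configured size;
their realized prevalence is therefore conditioned on presence, a caveat
for marginal-prevalence checks at very low baselines). One master seed is
split into named substreams (covariates / baselines / habitats /
occurrence), so adding a covariate never perturbs the occurrence draws and
identical configurations are bit-for-bit reproducible.

What the generator does *not* emulate: spatial coordinates or
autocorrelation, taxonomy, life-form structure, observation error, and any
real covariate correlation structure beyond the injected collinear pairs.
Passing tests on these landscapes therefore demonstrates that the
*machinery* is correct and that the protocol recovers known planted
signal; they say nothing about effect sizes in real Patagonian data.

## Validation experiments and problem sizes

`saiplan.diagnostics` packages the validation experiments run by the test
suite and `scripts/acceptance.py`: SAI endpoint identities (perfect
surrogate = the optimal score itself; noise surrogate), the random-baseline
enumeration oracle, greedy-versus-brute-force checks, the closed-form VIF
identity (three exactly 0.5-correlated columns → VIF 1.5), soil-carbon
recovery by the importance ensemble, ANOVA/Tukey calibration (pairwise
type-I rate at α = 0.01 under the null; power for a −2 SD shift of the
zero-count group), and the paired three-set surrogate comparison.

The heavy SAI experiments use the q grid {5, 20, 40, 60} with 100 (endpoint)
or 50 (comparison) repetitions per q and 200-tree forests — spanning the protocol's full q range
while keeping each experiment in the minutes range on a single CPU; the
group-test calibration uses 1000 null and 300 alternative simulations at
n = 145 with count-group frequencies 0.45/0.30/0.15/0.10 so every displayed
group is large enough for a pairwise contrast.

A known, quantified limitation: the perfect-surrogate identity (SAI → 1)
holds only once calibration subsets reliably contain optimal-scenario
plots. The perfect covariate is zero outside the ~14 optimal plots, so a
subset with none of them has a constant feature column and an
uninformative forest for that repetition. At q = 5% (8 plots) this happens
with probability (1 − 14/145)⁸ ≈ 0.60 and the mean SAI drops to ≈ 0.25;
at q = 20% the probability is ≈ 0.05 (mean ≈ 0.92); from q = 40% the
identity holds to within 0.05. This is a property of the subset-calibration
protocol itself, not of the implementation, and the corresponding checks at
small q are expected to fail.

## Known limitations

* No spatial optimization, connectivity, or rarity-weighted scoring.
* Generalized VIF for factors is not implemented.
* The importance ensemble models pooled threatened presence, not
  per-species distributions.
* SAI confidence intervals are percentile intervals across repetitions
  sharing one landscape; they do not propagate landscape-level uncertainty.
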