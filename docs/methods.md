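# Methods notes

This note records what the package computes, the defaults it ships
with, and the choices made where the framework leaves room.

## The suitability model

The framework treats predation as trait matching.  A predator's diet,
known only as a binary species list, is translated into a *diet
spectrum*: the frequency of each prey trait category among its prey
species.  DS is therefore a presence/absence summary — it carries no
information about how often individual prey are actually ingested,
and assumes predators sample their prey list without strong
preference among listed species.  Resource suitability multiplies the
predator's affinity by the standardised community-weighted
availability of the category, RS = DS × CWM_std, giving a [0, 1]
score per predator × category × assemblage.  RS is a *likelihood-style
proxy*, not a consumption rate: it says how likely a predator is to
encounter trait-suitable food, nothing about energy flux.

Records are kept per (predator, category, assemblage) rather than
summed over categories, because the trend models treat the trait as a
random factor and need the per-category records.

## Parameters and defaults that matter

| choice | default | why |
| --- | --- | --- |
| CWM standardisation scope | per-category min–max over **all** assemblages (`per_year` optional) | RS values are compared across years; scaling within years would erase the temporal signal |
| constant CWM columns | map to 0 | a category that never varies offers no availability contrast; 0 is the conservative value for RS |
| log offset | 0.01, natural log | regularises log(0) when RS = 0 (log 0.01 ≈ −4.605); z-scoring afterwards removes any base dependence |
| z-scoring scope | pooled over the full record table; per-species models re-scale within species | one community model on pooled standardised values; species models report in units of their own spread |
| FDis space | PCoA of Gower dissimilarity, axes with eigenvalues > 1e-8 | Gower on binary categories = mismatch proportion; `euclidean_raw` offered as a cheaper alternative |
| PCoA negative eigenvalues | sqrt-correction of distances when min eigenvalue < −1e-8 | the square root of a binary mismatch proportion is exactly Euclidean-embeddable |
| clustering | Euclidean distance on raw DS rows, UPGMA; ties broken lexicographically by smallest member label | raw rather than rescaled DS, since all scores share the [0, 1] scale; deterministic output |
| link-existence tolerance | weights > 1e-12 count as links | exact-zero products must not create phantom links in degree counts |
| "sum of interactions" | degree (count of non-zero links); strength (summed weights) always emitted alongside | the gloss "total number of links" reads as a count, but summed weights are the natural weighted analogue — both are reported, neither suppressed |
| PS availability vector | the same standardised CWM row the web was built from | use and availability must refer to the same resource description |
| exposure coding | sheltered = 0, exposed = 1 | the magnitude of the exposure estimate is coding-invariant; only the sign flips |
| estimation | REML (ML optional), year as unordered categorical with the earliest year as baseline | baseline-year intercept makes later-year contrasts directly interpretable |

## Mixed-model machinery

The trend models are Gaussian linear mixed models on the transformed
response.  Crossed random intercepts (site, species, trait) are fitted
through statsmodels' variance-components interface: one
all-encompassing group whose indicator-matrix components are exactly
crossed intercepts.  Fixed-effect p-values use the large-sample normal
approximation to the Wald statistic; with the record counts this
package produces (hundreds to tens of thousands) the difference from
finite-df corrections is immaterial, and the estimates rather than the
p-values are the primary quantities.  One test cross-checks the fixed
effects against lme4's `lmer` on the same data.

Optimisation uses L-BFGS first; when a variance component sits on the
boundary the gradient check can fail to certify convergence, in which
case the fit is polished with a derivative-free Powell step started
from the L-BFGS solution and the refit is recorded in `fit_info`.
Random factors with a single level are dropped (their variance is
unidentifiable); with no usable random factor the model collapses to
OLS on the same fixed design, which also gives the degenerate-input
sanity property (mixed fit = OLS when every grouping is trivial).
Non-convergence is reported as a flag, never an exception.

The FDis → S regression is deliberately implemented from the textbook
closed forms (slope, intercept, t, adjusted R²) rather than delegated,
and is verified against statsmodels OLS in the tests.

## The synthetic generator

The generator emulates the *shape* of a multi-decadal zoobenthos
monitoring design: 16 stations (8 exposed, 8 sheltered) × the years
1973/1989/2000/2013, ~11 predators, a prey pool with one-hot
categorical traits (multi-hot movement, Bernoulli sediment
protrusion), lognormal(μ=1, σ=1) abundances — right-skewed, as grab
counts are; CWM and FDis are invariant to the absolute scale.  Feeding
links follow a logistic trait-match rule with latent predator
affinities, so link probability rises with predator–prey trait match;
zero sharpness gives coin-flip links, large sharpness a deterministic
match rule.

Temporal drift is imposed by exponential tilting: species expressing a
target category have abundance multiplied by `exp(rate·(yi − mid))`,
with `yi` the year index and `mid` the midpoint of the year sequence.
Centring matters: a one-sided tilt concentrates late-year abundance
onto the tilted subset and *lowers* functional dispersion even when
the targets are rare categories, because species concentration
outweighs trait novelty.  With the centred tilt, the study midpoint is
the neutral community, category frequencies still move monotonically
across years in expectation, and the packaged `variety_increasing_drift`
(boosting each trait's rarest category) raises FDis from first to last
year as intended.

What the generator does **not** emulate: population dynamics,
predation feedback, spatial autocorrelation between stations,
taxonomic structure, replicate-level sampling noise (abundances are
already "replicate means"), and observation error in the feeding
links.  Tests passing on synthetic data therefore demonstrate the
correctness and calibration of the computations, not that any
particular field system behaves this way.

## Statistical calibration checks

The acceptance suite checks the community model's frequentist
behaviour on a scaled-down design (8 sites × 4 years × 3 predators ×
6 categories, 576 records — chosen so several hundred fits run in
seconds) whose response is drawn from the model family itself:
crossed random intercepts (sd 0.3 each) plus unit residual noise, with
a +0.5 shift injected on the 2013 term for the recovery check.  The
response is simulated rather than taken from the multiplicative
pipeline because the pipeline response contains assemblage × category
structure outside the fitted model family; calibration (CI coverage,
type-I error) is only a well-posed claim under the model's own
data-generating process.  The qualitative functional-diversity check,
by contrast, runs the full pipeline end to end on drifted bundles.

## Known limitations

* DS weights all listed prey equally; ingestion frequencies,
  size-structured selectivity and ontogenetic diet shifts are outside
  the data the framework consumes.
* Binary trait tables must be complete; missing-value handling in the
  Gower computation is deliberately not implemented.
* Min–max standardisation ties CWM availability to the observed
  assemblage set: adding assemblages can change every standardised
  value.  This is inherent to the definition, not a bug.
* The variance-components p-values are asymptotic; for designs with
  very few sites or traits, treat the per-term significance of the
  mixed models with caution and prefer the estimates.
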