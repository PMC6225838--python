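# predsuit — trait-based predation suitability for changing prey communities

`predsuit` asks a simple ecological question quantitatively: when the
composition of a prey community changes over decades, does the food it
offers become more or less *suitable* for its predators?  It answers
it without stomach-content data, using only binary feeding links from
the literature and a categorical trait classification of the prey —
here benthivorous coastal fish feeding on zoobenthos, though nothing
in the machinery is taxon-specific.

## The framework

Three inputs drive everything:

* **PP** — a binary predator × prey matrix (1 = predator *i* feeds on
  prey *j*), as compiled from published diet records;
* **T** — a binary prey × trait-category matrix over a scheme of 7
  categorical traits with 24 categories in total (maximum size,
  protection, fragility, environmental position, energy content,
  movement mode, sediment protrusion);
* an abundance table of prey assemblages per monitoring site and year
  (means over replicate grab samples), with sites classed as exposed
  or sheltered.

From these the package computes:

1. **Diet spectrum** — for predator *i* and category *k*,

       DS[i,k] = Σ_j PP[i,j]·T[j,k] / Σ_j PP[i,j],

   the fraction of the predator's prey species expressing the
   category (1 = every prey item carries it).  Predators are grouped
   by UPGMA clustering of their DS rows (Newick export included).
2. **Community-weighted means** — CWM[a,k], the abundance fraction of
   assemblage *a* expressing category *k*, min–max standardised to
   [0, 1] per category across all assemblages.
3. **Resource suitability** — RS[i,k,a] = DS[i,k] × CWM_std[a,k], a
   [0, 1] likelihood-style proxy for predator *i* encountering
   suitable prey traits in assemblage *a*.
4. **Functional dispersion (FDis)** — the abundance-weighted mean
   distance of an assemblage's species to their abundance-weighted
   centroid in a PCoA embedding of the Gower (mismatch-proportion)
   trait dissimilarity.
5. **Bipartite linkage indices** — per assemblage, a predator ×
   category web weighted by DS × CWM_std, with per-predator degree,
   strength, and proportional similarity
   PS = 1 − ½ Σ_k |use_k − availability_k|.
6. **Trend models** — a linear mixed model of log(RS + 0.01),
   z-scored, on year (categorical, earliest year as baseline) and
   exposure with crossed random intercepts for site, species and
   trait; per-species analogues; an FDis-on-year mixed model; and a
   closed-form OLS of mean assemblage suitability *S* on FDis.

A seeded synthetic-data generator reproduces the monitoring design
(16 sites × 4 years, 8 exposed / 8 sheltered, 11 predators, lognormal
abundances, controllable trait drift), so the full pipeline is
testable without the original survey data.

## Worked example

Simulate a bundle whose prey community drifts toward rarer trait
categories (rising trait variety), then run the whole pipeline:

```sh
predsuit simulate --seed 1 --preset drifted --out demo/bundle
predsuit run --pp demo/bundle/pp_links.csv \
             --traits demo/bundle/prey_traits.csv \
             --abundance demo/bundle/abundance.csv \
             --out demo/results
```

The run writes the DS/CWM/FDis/RS/network tables, model summaries and
a manifest.  With this seed, `demo/results/community_model.csv` holds
the community trend in transformed suitability:

```
           estimate      se  tvalue  pvalue
Intercept    0.1169  0.2056  0.5684  0.5697
1989         0.0780  0.0185  4.2047  0.0000
2000         0.0804  0.0185  4.3384  0.0000
2013         0.0315  0.0185  1.6976  0.0896
exposure     0.0079  0.0156  0.5053  0.6133
```

— suitability is significantly higher in 1989 and 2000 than in the
1973 baseline, with no exposure effect, as expected when the drift
favours categories many predators have affinity for.  The
`fdis_s_lm.csv` table shows the functional-diversity relationship:

```
           estimate      se  tvalue  pvalue
fdis         5.1690  0.9253  5.5863  0.0000   (adj. R² = 0.32)
```

a significantly positive FDis → S slope: assemblages offering more
trait variety are, on average, more suitable for the predator pool.
Every subcommand (`ds`, `cwm`, `fdis`, `rs`, `networks`, `models`)
also runs one stage on explicit inputs; real survey tables in the
same shapes (links as prey × predator CSV, traits as prey × 24
categories, abundances with `E|S_station_year` row labels) drop in
directly.

## Layout

| module | contents |
| --- | --- |
| `predsuit.types` / `predsuit.io` | validated containers, CSV/TSV readers and writers, prey-list alignment |
| `predsuit.diet` | diet spectra, similarity clustering, Newick export |
| `predsuit.community` | CWM, standardisation, Gower, PCoA, FDis |
| `predsuit.suitability` | RS products, log/z transform, assemblage means |
| `predsuit.networks` | DS-weighted bipartite webs and species-level indices |
| `predsuit.models` | mixed models, per-species models, FDis trend, OLS |
| `predsuit.synthetic` | seeded study-shaped data generator with trait drift |
| `predsuit.pipeline` / `predsuit.cli` | orchestration, manifests, `predsuit` CLI |

See `docs/methods.md` for the modelling choices, defaults and
limitations.
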