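# comindic

Community-level biodiversity indicators for river fish monitoring:
per-species **originality** and **specialization** scores, their
abundance-weighted community aggregates, and a statistical pipeline that
evaluates whether those aggregates respond to a land-use
artificialization gradient — the property that turns an index into a
usable pressure indicator.

The package is aimed at freshwater ecologists and monitoring agencies
working with multi-site, multi-year electrofishing surveys, mixed-type
species trait compilations, and per-site land-cover classes.

## The indices

**Species Originality (SOI).** From a species × traits table with
declared column types, pairwise dissimilarities are computed with
Gower's coefficient (range-normalized differences for ordered traits,
mismatches for categorical ones, pairwise deletion of missing values)
and clustered by UPGMA into an ultrametric dendrogram; rooted
phylogenies in Newick are consumed directly. On a tree, the
**equal-splits** score of tip *i* apportions every branch length down
the tree, divided equally at each split:

```
ES_i = Σ_{edges e on root→i path}  L(e) · Π_{nodes v below e on the path} 1/children(v)
```

so that Σ_i ES_i equals the total branch length. The alternative **QE**
metric returns the weights *p* maximizing Rao's quadratic entropy
*p'Dp* on the probability simplex — rare-state-sensitive where
equal-splits is unique-state-sensitive.

**Species Specialization (SSI).** Sites are clustered on four abiotic
variables (summed Jan–Jun air temperature, longitudinal gradient, log
elevation, slope) into *k* = 7 habitat classes of near-equal size
(correcting headwater oversampling); a species' SSI is the coefficient
of variation (sd/mean) of its mean density across classes: 0 for a
perfect generalist, √k for a single-class specialist.

**Community indices.** For a sampling occasion *t* with densities
*a(i,t)*: `COI_t = Σ a(i,t)·SOI_i / Σ a(i,t)` (likewise CSI with SSI) —
an abundance-weighted mean, bounded by the scores of the species
present, with coverage accounting for unscored species.

**Indicator evaluation.** Mixed-effects linear models (site random
intercept) with AIC selection over year/coordinate/watershed fixed
effects; land-use classes coded relative to the natural reference class
(Forest, coefficient structurally 0); Benjamini–Yekutieli FDR over the
family of class tests; an R² proxy from the same model without the
random effect; robustness across alternative 5/6/7-class land-cover
groupings and across watersheds, plus an outlier-region exclusion rerun.

## Worked example

```sh
comindic simulate --seed 3 --n-sites 60 --n-years 3 \
    --effect Urban=-0.01 --outdir demo
comindic scores --traits demo/traits.csv --schema demo/traits.schema \
    --out demo/soi.csv
comindic community --survey demo/survey.csv --scores demo/scores.csv \
    --out demo/index.csv
comindic sensitivity --index demo/index.csv --context demo/context.csv \
    --landuse CLC5=demo/landuse.csv --out demo/sensitivity.csv
```

`demo/sensitivity.csv` then contains (numbers from this exact run):

```
# model=year+watershed+landuse
# r2_proxy=0.0863598
# n_obs=180
# n_sites=60
class,variant,coef,t,p_raw,p_by
Forest,CLC5,0.0,,,
Meadow,CLC5,0.0011872637652526083,0.26720308614307253,0.7893128001167169,1.0
Farming,CLC5,-0.0007694301718443981,-0.17374384179670843,0.8620667807157707,1.0
Mix,CLC5,-0.0008794768418204161,-0.09997963715917192,0.9203604916254815,1.0
Urban,CLC5,-0.007765193283993433,-1.6990292959311568,0.08931366386822445,0.7442805322352036
```

Reading: the AIC-selected spatio-temporal base model used year plus
watershed; relative to forested sites the community originality index
is about 0.008 lower at urban sites — the injected −0.01 urban shift is
recovered with the right sign, though 60 sites are too few for it to
survive the BY correction (the 300-site runs in
`scripts/acceptance.py` detect it reliably). The same
objects are available as library calls (`gower_distance`, `upgma`,
`equal_splits`, `qe_originality`, `ssi`, `community_index`,
`landuse_sensitivity`, …) with CLI output byte-identical to them.

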