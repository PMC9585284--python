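# fdnull

Functional trait diversity, randomization null models and bounded effect
sizes for plant community assembly analysis.

`fdnull` is aimed at community ecologists asking whether a management regime
(e.g. mowing, tillage or herbicide use in a vineyard) assembles plant
communities by **habitat filtering** (trait convergence) or **limiting
similarity** (trait divergence). Starting from a plot × species percent-cover
matrix, a species × trait table of mixed type, and a per-species
competitiveness (CSR C-dimension) score, it computes:

- **Gower dissimilarities** over quantitative, ordinal and nominal traits
  (multi-trait or single-trait), and a **PCoA** embedding with
  negative-eigenvalue corrections (`sqrt`, Cailliez, Lingoes);
- per-plot **functional diversity indices**: FRic (standardized convex-hull
  volume), FEve (abundance regularity along the minimum spanning tree),
  Rao's quadratic entropy `Q = Σᵢⱼ pᵢ pⱼ dᵢⱼ`, FDis, and community-weighted
  means/variances (CWM/CWV);
- two **null models**: the *independent swap* (checkerboard swaps of the
  binary occurrence matrix, preserving plot richness and species occurrence
  frequency — used for FRic) and the *richness shuffle* (within-plot
  permutation of abundances over the species pool — used for RaoQ);
- the **bounded effect size**

  ```
  p  = (number(NULL < obs) + number(NULL = obs)/2) / n_rand
  ES = (p − 0.5) × 2  ∈ [−1, +1]
  ```

  which locates the observed index in its null distribution without any
  symmetry assumption; ES < 0 indicates trait convergence, ES > 0 divergence;
- normality-gated **convergence/divergence verdicts** (one-sample t-test or
  Wilcoxon signed-rank against zero) per treatment group and trait set, and
  correlations between per-plot ES and the cover of dominant species;
- the community-weighted **competitiveness index** `C_index = Σᵢ pᵢ·Cᵢ` and
  its polynomial (AICc-selected) relationship with multi-trait ES RaoQ;
- a **synthetic community generator** with neutral, filtering and
  limiting-similarity assembly rules and an injectable extreme-trait
  competitor, so every stage of the pipeline — including the inference of
  assembly processes — is testable against known ground truth.

## Worked example

```python
import fdnull
from fdnull.nullmodels import NullSpec

# a synthetic vineyard: mown plots filter for short, small-leaved species,
# a tall large-leaved heavy-seeded competitor dominates irrigated plots
ds = fdnull.generate_dataset(fdnull.mechanism_scenario(seed=2))

spec = NullSpec("richness_shuffle", n_rand=999, seed=3)
es = fdnull.es_battery(ds.community, ds.traits, spec,
                       trait_sets=("multitrait", "PHV", "SM"))
verdicts = fdnull.effectsize.verdicts_by_group(
    es, ds.community.metadata["treatment_class"])
print(verdicts.query("statistic == 'ES_RaoQ_multitrait'")
      [["group", "n", "center", "p_value", "verdict"]].to_string(index=False))
```

prints

```
group  n    center      p_value    verdict
   HI  8  0.869620 3.802201e-09  divergent
   MI  4  0.034034 9.279540e-01    neutral
  MNI  8 -0.424424 1.836580e-03 convergent
   TI  4  0.883383 7.352439e-04  divergent
  TNI  8 -0.134384 4.945052e-01    neutral
```

Herbicide-treated and tilled irrigated plots (HI, TI), where the injected
competitor is abundant, come out divergent (center well above 0); the mown
non-irrigated plots (MNI), assembled through a narrow height/leaf-area
filter, come out convergent; plots with no imposed process (TNI) are
neutral. The center is the group mean under the t-test branch and the median
under the Wilcoxon branch. On the same run, the competitiveness relation

```python
ci = fdnull.c_index_per_plot(ds.community, ds.c_table)
esm = es[es.statistic == "ES_RaoQ_multitrait"].set_index("plot")["es"]
fit = fdnull.es_cindex_relation(ci.loc[esm.index].to_numpy(), esm.to_numpy())
print("degree", fit["degree"], "R2", round(fit["r2"], 2))
```

selects a cubic (`degree 3 R2 0.56`): functional divergence rises with
community competitiveness.

A command-line interface mirrors the library
(`fdnull simulate | fd | null | es | report`); see `fdnull --help`.

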