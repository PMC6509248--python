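# lgbiplot

Mega-environment delineation from **unbalanced multi-year variety trials**
using GGE and location-grouping (LG) biplots.

## The problem

Because of genotype-by-environment interaction (GE), no crop cultivar is best
everywhere: a growing region must be split into *mega-environments* — groups
of test locations that rank genotypes similarly year after year — and
cultivars bred and recommended per group. The data needed for this exist for
every major crop: routine regional variety trials test a common genotype set
across locations *within* a year, but a different set *each* year. The
multi-year table is therefore highly unbalanced and cannot simply be pooled.

The LG-biplot method works around the imbalance by operating on
**correlations instead of yields**:

1. **Per year**, compute the Pearson correlations between test locations
   across the genotypes they share (pairwise-complete, minimum 3 shared
   genotypes). How similarly two locations rank genotypes does not require
   the same genotypes in other years.
2. **Stack** the yearly correlation matrices into one trials × locations
   table (a *trial* is a location-year; a cell is missing when the column
   location was untested that year; a trial's cell under its own location
   is 1).
3. **Impute** the missing cells by iterative rank-2 SVD.
4. **Biplot** the table: with the usual coding of the rank-2 SVD model

   P_ij ≈ (d λ₁^α ζ_i1)(λ₁^(1−α) τ_1j / d) + (d λ₂^α ζ_i2)(λ₂^(1−α) τ_2j / d),

   using *Scaling = 0, Centering = 0* (so inner products approximate the
   correlations themselves) and singular values partitioned entirely to the
   trial vectors. The grand-mean-centered variant (*Centering = 1*) is the
   **LG1 biplot**, a supplement that accentuates dissimilarities.
5. **Place** each location at the mean coordinates of its trials and
   **cluster** the placements (average linkage on cosine dissimilarity) into
   k mega-environments. The scatter of a location's yearly trials around its
   mean placement measures the *unrepeatable* part of GE at that location.

The package also provides the per-year GGE biplot (column-standardized
yields, *Scaling = 1, Centering = 2, SVP = 2*, where the cosine of the angle
between two location markers approximates their correlation), average-
environment-axis mean/stability statistics, a synthetic-trial generator with
known mega-environment structure, figure rendering, and a CLI.

## Worked example

The package ships the published trials-by-locations correlation table from
the 2006–2010 Quebec provincial oat trials (39 trials, 11 locations):

```python
from lgbiplot import load_table1_fixture, run_lg_pipeline

result = run_lg_pipeline(load_table1_fixture(), variant="LG", k=2)
print(f"goodness of fit: {100 * result.model.gof:.1f}%")
for g in sorted(set(result.partition.groups.values())):
    print(g, result.partition.members(g))
```

prints

```
goodness of fit: 84.5%
1 ['CAUS3', 'HEBE3', 'NORM3', 'PINT2', 'PRIN2', 'STAU2']
2 ['LAPO3', 'NDHY1', 'OTT', 'STRO1', 'STS1']
```

Group 2 is the southern oat mega-environment — the Zone-1 locations NDHY1,
STRO1 and STS1 together with Ottawa and, notably, the geographically
northern Zone-3 location La Pocatière (LAPO3); group 1 is the northern
mega-environment (the remaining Zone-2/Zone-3 locations). The 84.5% goodness
of fit is the share of the table's sum of squares captured by the two
plotted components. See `examples/` for runnable walk-throughs of the yearly
GGE biplot, this pipeline, and group recovery from synthetic data, and
`docs/methods.md` for the model details.

The same analysis from a shell:

```
lgbiplot lg --fixture --k 2 --out results/
lgbiplot simulate --seed 1 --out sim/ && lgbiplot lg --trials sim/trials.csv --out sim_lg/
```

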