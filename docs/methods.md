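# Methods

## Model

All biplots in this package are instances of one rank-2 SVD model. A
preprocessed two-way table P (rows i, columns j) is decomposed as

    P_ij = Σ_k λ_k ζ_ik τ_kj ,   λ_1 ≥ λ_2 ≥ … ≥ 0,

and the first two components are displayed with row markers
(d λ_k^α ζ_ik) and column markers (λ_k^(1−α) τ_kj / d), k = 1, 2. The
inner product of a row marker with a column marker reproduces the rank-2
truncation of P regardless of the partitioning exponent α and the balancing
scalar d — only the visual metric changes. Goodness of fit is
(λ₁² + λ₂²) / Σ_k λ_k², computed from the full spectrum.

Preprocessing codes: Scaling 0/1 = none / divide each column by its standard
deviation (n−1 denominator, computed over present cells); Centering 0/1/2 =
none / subtract the grand mean / subtract column means. SVP code 1 sets
α = 1 (rows carry the singular values), code 2 sets α = 0 (columns carry
them). Column standardization plus column-focused partitioning (Scaling = 1,
Centering = 2, SVP = 2) makes each column marker an approximate unit vector
whose pairwise cosines approximate the Pearson correlations between columns;
the approximation degrades with the rank-2 truncation error, which is why
`column_correlation_cosine_check` is offered as a validation, not an
inference, tool.

Two conventions close gaps the model statement leaves open:

- **Sign convention.** The SVD is reflection-invariant; for determinism,
  each component is flipped so that its largest-magnitude column loading is
  positive (first such column in column order wins ties). Rebuilding a model
  from identical input is bit-identical.
- **The scalar d.** The stated goal is that the longest row marker and the
  longest column marker have equal length. With row markers r·d and column
  markers c/d this forces d = sqrt(max‖c‖ / max‖r‖), computed from the
  α-partitioned two-component coordinates. A zero matrix gets d = 1.

## The LG pipeline

Yearly correlations are pairwise-complete Pearson correlations between
location columns of the year's genotype × location matrix, requiring at
least 3 genotypes observed at both locations (a two-point correlation is
always ±1 and carries no information); locations with fewer than 3
observations in a year get an all-missing row/column and a warning.

The stacked LG table has trials (location-years, labelled `LOC_YY`, split on
the final underscore) as rows and locations as columns. A trial's cell under
its own location is set to 1 by definition. A cell is structurally missing
when the column location was untested in the trial's year. After imputation
the table is complete, and imputed cells legitimately occupy structurally
missing positions; validation therefore distinguishes assembled tables
(missing ⇐ untested enforced) from imputed ones.

**Imputation** is EM-style iterative low-rank approximation: fill the
missing cells, then alternate a rank-r (default 2, matching the biplot
model) truncated SVD of the filled table with replacement of the missing
cells by their reconstruction, until the largest change among imputed cells
drops below `tol` (default 1e-8) or `max_iter` (default 500) is reached, in
which case a warning reports the final change. The iteration is non-convex
and, from an unlucky start, can creep toward a completion with inflated
missing entries rather than the generating low-rank structure (observed on
roughly 0.5% of random small exact-rank-2 problems). Four deterministic
starts are therefore run — column-mean fill (the reference), column-mean
fill with a rank-ramped warm start (rank 1 to convergence, then rank 2),
row-mean fill, and zero fill — and the completion whose final rank-r model
best fits the **observed** cells (the method's own objective) is kept, with
ties favoring the reference start. Observed cells are never modified;
imputed correlations are clipped to [−1, 1] at the end.

**LG vs LG1.** The LG biplot applies no scaling and no centering, so its
inner products approximate the correlations themselves, at the cost of a
dominant first component carrying the grand mean of the table. LG1 subtracts
the grand mean first; it separates locations more aggressively but loses the
correlation reading. Operationally LG1 is exactly LG applied to the
grand-mean-centered table. In both, singular values are partitioned entirely
to the trial vectors: internally the SVD is taken in the locations × trials
orientation with SVP = 2 (the orientation in which that annotation is
conventional) and the result presented with trials as rows. With fewer than
4 locations a warning flags the self-correlation artifact: the fixed 1s on
each trial's own location can make every location look like its own group.

**Placement and grouping.** A location is placed at the arithmetic mean of
its trial markers (column markers are plotted but not used for placement).
Placements are clustered by average-linkage hierarchical clustering on
cosine dissimilarity, 1 − cos∠(p_a, p_b) — the biplot's own similarity
semantics, since angles in the uncentered correlation biplot reflect
correlation — and the dendrogram is cut at k groups (k is user-chosen,
default 2; the package deliberately does not choose k automatically).
Locations are processed in lexicographic order and group labels 1..k
assigned by first appearance among sorted locations, so the partition is
deterministic. The mean distance of a location's trials from its mean
placement (`within_location_spread`) indexes the unrepeatable interaction at
that location.

## Synthetic data

The generator emulates the motivating data shape: defaults of 5 years, two
latent groups of 5 and 6 locations, 30 genotypes per year with 40% carried
over between consecutive years, and each location skipping any given year
with probability 0.3 (at least 2 locations per group always retained) —
about the 39-of-55 realized trials of the motivating series. Carry-over
advances the genotypes with the best latent mean (mimicking breeding
advancement; a random policy is available).

Each genotype has one latent merit per group, jointly normal with
correlation `rho_between`; an observation adds a location main effect and
i.i.d. noise of sd `noise_sd`. The latent scale is
s = sqrt(rho_within / (1 − rho_within)), calibrated so that at the reference
noise level (noise_sd = 1, the default) two same-group locations correlate
`rho_within` across genotypes in expectation, and two different-group
locations about `rho_between · rho_within` (≈ −0.12 at the defaults). The
scale is *not* recalibrated when `noise_sd` changes: raising the noise
strictly lowers both correlations, which is the intended dial. What the
generator does not emulate: spatial field-trial error, year main-effect
trends, multi-trait data, or non-normal trait distributions — so passing
recovery tests demonstrate the pipeline's behavior under its own model
assumptions, not robustness to every feature of real trial data.

## Numerical notes and limitations

- Problem sizes in the test and acceptance suites (matrices up to 50×20,
  10×8 imputation tables, 100 pipeline replicates) were chosen as the
  smallest sizes at which each property is informative; the full pipeline on
  a 39×11 table runs in well under a second.
- Exact recovery by rank-2 imputation is only identifiable when every row
  and column retains at least 2 observed cells; recovery tests enforce that
  on their random missingness patterns. The multi-start selection described
  above handles the iteration's drift mode; what remains is occasional slow
  (linear, near-unit-rate) convergence on adversarial patterns — roughly 1
  in 1000 random small cases needs tens of thousands of iterations to reach
  1e-6 accuracy. The non-convergence warning reports the final update size
  in such cases; raising `max_iter` is the remedy. Structurally missing LG
  tables, whose observed cells form dense per-year blocks, showed neither
  behavior.
- The packaged 2006–2010 correlation table was transcribed from a
  typographically damaged source; per-year location lists and within-year
  symmetry resolve every cell except the 2010 NORM3×OTT pair, which is blank
  in the source and kept missing (`TABLE1_UNTRANSCRIBED` lists it). The
  published analysis imputed missing values with an unspecified method, so
  figure coordinates are not expected to reproduce exactly; the recovered
  two-group partition of the 11 locations is the reproducible result.
- All pipeline stages are deterministic; the only randomness in the package
  is the generator's, driven by an explicit seed.
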