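"""Yearly GGE biplot: how did the test locations relate this year?

Simulates one year of a two-group variety trial, fits the column-focused
biplot of location-standardized yields, and prints the goodness of fit plus
the angle/correlation readout for every location pair.
"""

from lgbiplot import (
    ModelSettings,
    SimConfig,
    column_correlation_cosine_check,
    simulate_trials,
    svd_biplot,
    to_ge_matrix,
)

sim = simulate_trials(SimConfig(n_years=2, locations_per_group=(3, 3),
                                genotypes_per_year=40, location_dropout=0.0,
                                noise_sd=0.6, seed=7))
year = sim.trials.years()[0]
matrix = to_ge_matrix(sim.trials, year)

# Scaling=1/Centering=2 turns each location column into z-scores;
# SVP=2 makes the cosine between location markers approximate their
# genotype-ranking correlation.
model = svd_biplot(matrix, ModelSettings(scaling=1, centering=2, svp=2))
print(f"year {year}: {matrix.data.shape[0]} genotypes x "
      f"{matrix.data.shape[1]} locations, goodness of fit {100 * model.gof:.1f}%")

report = column_correlation_cosine_check(model, matrix)
print(report.round(3).to_string(index=False))
print("cosine ~ pearson_r: an acute angle between two location markers means"
      " they ranked the genotypes similarly; an obtuse angle, oppositely.")
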