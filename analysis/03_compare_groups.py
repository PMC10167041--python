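#!/usr/bin/env python
"""Compare the two cohort groups and correlate structure with calcification.

For each structural parameter, a two-sided Mann-Whitney test contrasts group
A against group B (exact p for these sample sizes). Calcified fraction is
then correlated with mean cusp thickness and with cusp volume (Spearman, as
the cohort metrics are not assumed normal). Writes
results/group_comparison.csv and results/correlations.csv.
"""

import os

import pandas as pd

import valve3d as v

here = os.path.dirname(os.path.abspath(__file__))
results = os.path.join(here, os.pardir, "results")

df = pd.read_csv(os.path.join(results, "cusp_metrics.csv"))
a = df[df.group == "A"]
b = df[df.group == "B"]

parameters = ["calc_volume_fraction", "cusp_volume_mm3", "mean_thickness_mm",
              "n_particles", "particles_per_mm3", "largest_particle_mm3",
              "fraction_below_0p7mm"]

rows = []
for param in parameters:
    res = v.mann_whitney(a[param].to_numpy(), b[param].to_numpy())
    rows.append({
        "parameter": param,
        "mean_A": a[param].mean(),
        "mean_B": b[param].mean(),
        "U": res.u,
        "p_two_sided": res.p,
        "method": res.method,
        "stars": res.stars(),
    })
comparison = pd.DataFrame(rows)
comparison.to_csv(os.path.join(results, "group_comparison.csv"), index=False)

corr_rows = []
for target in ["mean_thickness_mm", "cusp_volume_mm3"]:
    rho, p, method = v.correlate(df["calc_volume_fraction"], df[target],
                                 "spearman")
    corr_rows.append({"x": "calc_volume_fraction", "y": target,
                      "coefficient": rho, "p_two_sided": p, "method": method,
                      "stars": v.significance_stars(p)})
correlations = pd.DataFrame(corr_rows)
correlations.to_csv(os.path.join(results, "correlations.csv"), index=False)

print(comparison.to_string(index=False))
print()
print(correlations.to_string(index=False))
print(f"\ntables -> {results}/group_comparison.csv, {results}/correlations.csv")
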