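"""End-to-end run on a synthetic population.

Generates coccolith and coccosphere tables with the observed population
statistics, summarizes them, fits the count-versus-area regression, and
closes the loop with the coverage model.
"""

import coccotopo as ct

ds = ct.generate_dataset(n_coccoliths=1918, n_coccospheres=156, seed=42)
summary = ct.summarize(ds.coccoliths, percentiles=(0.05, 0.95))
print("coccolith summary (1,918 synthetic coccoliths):")
print(summary)

spheres = ds.coccospheres.rename(columns={"total_count": "count"})
print(f"\ncoccospheres: diameter {spheres['diameter'].mean():.2f} um, "
      f"reported count {spheres['count'].mean():.1f} +/- {spheres['count'].std():.1f}")

fit = ct.fit_count_vs_area(spheres[["diameter", "count"]])
print(f"surface area vs count: slope {fit.slope:.2f} um^2 per coccolith, R^2 = {fit.r_squared:.2f}")

sphere_area = ct.mean_sphere_area(spheres["diameter"].to_numpy())
base = (summary["dsl"]["mean"] + summary["dsw"]["mean"]) / 2
cap = ct.spherical_cap_area(ct.SphereCapSpec(float(spheres["diameter"].mean()), base))
est = ct.coverage_estimate(sphere_area, cap, observed_count=float(spheres["count"].mean()))
print(f"coverage model: N-hat = {est.estimated_count:.1f} vs reported mean "
      f"{est.observed_count:.1f} (discrepancy {est.count_discrepancy:.0%})")
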