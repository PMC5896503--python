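"""The surface-coverage chain from population means to coccolith count.

Starting from the observed population means (coccosphere diameter
5.54 ± 0.63 μm; coccolith DSL 3.04, DSW 2.45 μm), compute the mean cell
surface, the coccolith spherical-cap area, and solve the self-consistent
coverage equation N = A_sphere / (A_cap * r(6 - 12/N)) for the number of
coccoliths a fully covered cell needs.
"""

import coccotopo as ct

sphere = ct.mean_sphere_area(summary=(5.54, 0.63))
cap = ct.spherical_cap_area(ct.SphereCapSpec(5.54, (3.04 + 2.45) / 2))
print(f"mean coccosphere surface area : {sphere:7.2f} um^2")
print(f"coccolith spherical-cap area  : {cap:7.2f} um^2")

est = ct.coverage_estimate(sphere, cap, observed_count=15.4)
print(f"self-consistent count N-hat   : {est.estimated_count:7.2f} coccoliths")
print(f"mean edges per coccolith      : {est.mean_edges:7.2f}")
print(f"inscribed-polygon coverage    : {est.coverage_fraction:7.3f}")
print(f"effective area per coccolith  : {est.effective_area:7.2f} um^2")
print(f"overshoot vs observed 15.4    : {est.count_discrepancy:7.1%}"
      " (hemisphere counting hides ~a fifth of interlocked coccoliths)")

n_bar = ct.mean_edges_per_face(15.4)
print(f"\ncoverage-optimal OSW/DSL      : {ct.optimal_osw_ratio(n_bar):7.3f}"
      " (observed ratios: 0.15-0.25, mean 0.19)")
print(f"division of one cell into 4   : {ct.division_area_factor(4) - 1:+7.1%} total surface")
per, ok = ct.daughter_coccolith_budget(12, 2)
print(f"parent with 12 coccoliths, 2 daughters: {per} each, full coverage possible: {ok}")
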