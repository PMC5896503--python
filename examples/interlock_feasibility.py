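"""2D interlocking feasibility around one central coccolith.

Places n equally sized bordering coccoliths around a central one at the
observed shape ratios (DSW/DSL = 0.81, OSW/DSL = 0.19) and applies the
package's feasibility criterion: overlap chords must not transect any
central area, and adjacent borders must stay engaged.  Then scans the
bordering-size ratio at n = 7 for the feasible band, and the shield
width needed for the extreme three-neighbour case.
"""

import coccotopo as ct
from coccotopo.interlock_sim import InterlockCriterion

central = ct.CoccolithOutline.from_ratios(0.81, 0.19, dsl=3.04)
criterion = InterlockCriterion(tightness_threshold=0.2)

print("equal-size neighbours around a mean-shape coccolith:")
for n in range(3, 9):
    rep, _ = ct.evaluate_best_phase(central, [1.0] * n, criterion)
    print(f"  n={n}: {rep.verdict}")
print("(3 always cuts the central area; 8 neighbours cut each other's)")

res = ct.scan_size_ratio_band(7, central, criterion=criterion, resolution=0.01, s_range=(0.4, 1.3))
lo, hi = res.band
print(f"\nn=7 feasible bordering-size band: DSL_BC/DSL_CC in [{lo:.2f}, {hi:.2f}]")
print(f"  below the band: {res.below_band_verdict} (neighbours disengage)")
print(f"  above the band: {res.above_band_verdict} (neighbour overlaps cut central areas)")

thr = ct.scan_min_osw_for_triangle(1.0, size_ratio=1.0, resolution=1e-3)
print(f"\ncircular outline, 3 neighbours: needs OSW/DSL >= {thr:.3f} (closed form: 0.25)")
print("observed OSW/DSL is 0.19 +/- 0.02, so a 3-neighbour interlock is essentially impossible:")
print(f"  P(OSW/DSL >= 0.37) = {ct.normal_tail_probability(0.19, 0.02, 0.37):.2e}")
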