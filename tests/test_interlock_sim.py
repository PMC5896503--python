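import math

import numpy as np
import pytest

import coccotopo as ct
from coccotopo.interlock_sim import (
    CENTRAL_CLEARANCE_ONLY,
    BandScanResult,
    InterlockCriterion,
    PlacementError,
    render_svg,
)


def circle_outline(osw_dsl: float, dsl: float = 2.0) -> ct.CoccolithOutline:
    return ct.CoccolithOutline(dsl, dsl, osw_dsl * dsl)


TABLE1 = ct.CoccolithOutline.from_ratios(0.81, 0.19, dsl=3.04)


class TestBuildConfiguration:
    def test_square_symmetry_on_circle(self):
        cfg = ct.build_configuration(circle_outline(0.19), [1.0] * 4)
        radii = np.hypot(cfg.vertices[:, 0], cfg.vertices[:, 1])
        assert np.ptp(radii) < 1e-12
        centers = np.array([e.center for e in cfg.border_outers])
        assert np.ptp(np.hypot(centers[:, 0], centers[:, 1])) < 1e-9

    def test_phase_invariance_of_margins_on_circle(self):
        reports = []
        for phase in (0.0, 0.3, 1.1):
            cfg = ct.build_configuration(circle_outline(0.19), [1.0] * 5, phase=phase)
            rep = ct.evaluate(cfg, CENTRAL_CLEARANCE_ONLY)
            reports.append(np.sort(rep.chord_central_margins))
        assert np.allclose(reports[0], reports[1]) and np.allclose(reports[0], reports[2])

    def test_vertices_lie_on_central_outline(self):
        cfg = ct.build_configuration(TABLE1, [0.8] * 6, phase=0.4)
        outer = TABLE1.outer()
        assert np.all(np.abs(outer.implicit(cfg.vertices)) < 1e-10)

    def test_chord_is_chord_of_border_outline(self):
        cfg = ct.build_configuration(TABLE1, [0.9] * 5)
        for k in range(5):
            p, q = cfg.chord(k)
            assert abs(cfg.border_outers[k].implicit(p)) < 1e-9
            assert abs(cfg.border_outers[k].implicit(q)) < 1e-9

    def test_unreachable_chord_names_the_border(self):
        with pytest.raises(PlacementError, match="coccolith 0"):
            ct.build_configuration(TABLE1, [0.05] * 3)


class TestEvaluate:
    def test_vanishing_shield_transects_for_every_n(self):
        central = circle_outline(1e-6)
        for n in (3, 4, 5, 6, 7):
            rep = ct.evaluate(ct.build_configuration(central, [1.0] * n), CENTRAL_CLEARANCE_ONLY)
            assert rep.verdict == "transects-central-area"

    def test_circle_margin_matches_closed_form(self):
        """Chord distance on a circle of radius R is R·cos(π/n)."""
        R = 1.0
        for n in (3, 4, 5, 6):
            central = circle_outline(0.19, dsl=2 * R)
            rep = ct.evaluate(ct.build_configuration(central, [1.0] * n), CENTRAL_CLEARANCE_ONLY)
            inner = R - 0.19 * 2 * R
            expected = R * math.cos(math.pi / n) - inner
            assert rep.chord_central_margins == pytest.approx(expected, abs=1e-9)

    def test_equilateral_triangle_clearance_threshold_is_quarter(self):
        """Incircle of an inscribed equilateral triangle has radius R/2."""
        feasible = ct.evaluate(
            ct.build_configuration(circle_outline(0.26), [1.0] * 3), CENTRAL_CLEARANCE_ONLY
        )
        infeasible = ct.evaluate(
            ct.build_configuration(circle_outline(0.24), [1.0] * 3), CENTRAL_CLEARANCE_ONLY
        )
        assert feasible.verdict == "feasible"
        assert infeasible.verdict == "transects-central-area"

    def test_small_neighbours_read_loose_at_default_criterion(self):
        rep = ct.evaluate(ct.build_configuration(TABLE1, [0.5] * 7))
        assert rep.verdict == "loose"

    def test_scale_and_rotation_invariance(self):
        rep1 = ct.evaluate(ct.build_configuration(TABLE1, [0.9] * 5, phase=0.2))
        scaled = ct.CoccolithOutline(TABLE1.dsl * 3.7, TABLE1.dsw * 3.7, TABLE1.osw * 3.7)
        rep2 = ct.evaluate(ct.build_configuration(scaled, [0.9] * 5, phase=0.2))
        assert rep2.verdict == rep1.verdict
        assert rep2.chord_central_margins == pytest.approx(3.7 * rep1.chord_central_margins, rel=1e-8)
        assert rep2.bb_depths == pytest.approx(rep1.bb_depths, abs=1e-6)

    def test_central_margin_grows_with_neighbour_count(self):
        margins = []
        for n in (4, 5, 6, 7):
            rep = ct.evaluate(ct.build_configuration(TABLE1, [1.0] * n), CENTRAL_CLEARANCE_ONLY)
            margins.append(rep.chord_central_margins.min())
        assert np.all(np.diff(margins) > 0)


class TestOswScan:
    def test_circle_oracle(self):
        thr = ct.scan_min_osw_for_triangle(1.0, size_ratio=1.0, resolution=1e-3)
        assert thr == pytest.approx(0.25, abs=2e-3)

    def test_circle_is_the_hardest_outline_for_a_triangle(self):
        """With the polygon phase free, the threshold rises with DSW/DSL:
        shrinking the outline by a fixed OSW makes an eccentric central
        area relatively flatter and easier for chords to avoid, so the
        circular outline needs the widest shield."""
        thresholds = [
            ct.scan_min_osw_for_triangle(r, size_ratio=1.0, resolution=2e-3)
            for r in (0.7, 0.85, 1.0)
        ]
        assert all(t is not None for t in thresholds)
        assert thresholds[0] <= thresholds[1] + 2e-3 <= thresholds[2] + 4e-3

    def test_clearance_feasibility_monotone_in_osw(self):
        """Once the chords clear the central area, a wider shield keeps them clear."""
        verdicts = []
        for x in np.arange(0.05, 0.40, 0.025):
            central = ct.CoccolithOutline.from_ratios(0.81, x)
            rep = ct.evaluate(ct.build_configuration(central, [1.0] * 4), CENTRAL_CLEARANCE_ONLY)
            verdicts.append(rep.feasible)
        first_ok = verdicts.index(True)
        assert all(verdicts[first_ok:])


@pytest.fixture(scope="module")
def band() -> BandScanResult:
    return ct.scan_size_ratio_band(
        7, TABLE1, resolution=0.01, s_range=(0.4, 1.3),
        criterion=InterlockCriterion(tightness_threshold=0.2),
    )


class TestSizeRatioBand:
    def test_band_is_nonempty_and_contiguous(self, band):
        assert band.band is not None
        lo, hi = band.band
        inside = band.table[(band.table.size_ratio >= lo - 1e-9) & (band.table.size_ratio <= hi + 1e-9)]
        assert (inside.verdict == "feasible").all()

    def test_band_edges_bracket_with_published_failure_modes(self, band):
        """Too-small neighbours disengage; too-large neighbours' mutual
        overlaps cut into central areas."""
        assert band.below_band_verdict == "loose"
        assert band.above_band_verdict == "transects-central-area"


class TestNeighborCountRelation:
    def test_identical_population_gives_single_count(self):
        pop = [ct.CoccolithOutline.from_ratios(0.81, 0.19, 3.0)] * 20
        tab = ct.neighbor_count_size_relation(pop, trials=100, seed=3)
        assert len(tab) == 1

    def test_lewis_law_direction_on_observed_population(self, table1_outline_population):
        tab = ct.neighbor_count_size_relation(table1_outline_population, trials=150, seed=11)
        achieved = tab.index[tab.index > 0]
        # geometric bounds: 3 borders transect the central area, 8 transect each other
        assert set(achieved) <= {4, 5, 6, 7}
        assert tab.loc[achieved, "trials"].sum() >= 0.95 * tab["trials"].sum()
        solid = [n for n in achieved if tab.loc[n, "trials"] >= 10]
        means = tab.loc[solid, "mean_central_dsl"].to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            ct.neighbor_count_size_relation([ct.CoccolithOutline.from_ratios(0.81, 0.19)] * 4)


def test_render_svg_writes_wellformed_file(tmp_path):
    cfg = ct.build_configuration(TABLE1, [0.8] * 5)
    out = tmp_path / "config.svg"
    render_svg(cfg, out)
    text = out.read_text(encoding="utf-8")
    assert text.startswith("<svg") and text.rstrip().endswith("</svg>")
    assert text.count("<ellipse") == 12  # central + 5 borders, outer + central area each
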