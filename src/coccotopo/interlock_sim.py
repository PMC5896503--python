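"""2D simulation of coccolith interlocking.

One central coccolith interlocks with ``n`` bordering coccoliths.  The
overlap edges form a polygon inscribed in the central coccolith's outer
ellipse: vertices sit on its circumference at equally spaced parameter
angles (the maximum-inscribed-polygon family), and each bordering
coccolith is placed so that its polygon chord is also a chord of its
own outer ellipse, mirror-symmetric about the chord's perpendicular
bisector with its axes parallel to the chord.  Adjacent bordering
coccoliths then share a polygon vertex, through which both of their
outlines pass.

Feasibility of a configuration is judged by an explicit, configurable
criterion (:class:`InterlockCriterion`); the qualitative principles it
encodes are:

1. no overlap edge may transect a central area — checked for the
   polygon chords against the central coccolith's central area, and for
   the mutual overlap chords of adjacent bordering coccoliths against
   their central areas;
2. neighbours must stay tightly engaged — the adjacent-border overlap
   chord must penetrate each border's shield annulus by at least a
   threshold fraction of the shield width, otherwise the configuration
   is "loose".

Because a larger ellipse through two fixed vertices is flatter, the
central↔border pair geometry alone becomes *shallower* as the bordering
coccoliths grow; it is the border↔border interaction that deepens with
size and produces the transect-when-large / loose-when-small behaviour
of real coccospheres.  All simulation is planar; lengths are μm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .ellipse_geometry import EllipseSpec, line_ellipse_clearance

__all__ = [
    "CoccolithOutline",
    "InterlockCriterion",
    "CENTRAL_CLEARANCE_ONLY",
    "InterlockConfiguration",
    "FeasibilityReport",
    "PlacementError",
    "build_configuration",
    "evaluate",
    "evaluate_best_phase",
    "scan_min_osw_for_triangle",
    "scan_size_ratio_band",
    "BandScanResult",
    "neighbor_count_size_relation",
    "render_svg",
]


class PlacementError(ValueError):
    """A bordering coccolith cannot reach both endpoints of its chord."""


@dataclass(frozen=True)
class CoccolithOutline:
    """Concentric outer (distal shield) and central-area ellipses of one coccolith."""

    dsl: float
    dsw: float
    osw: float

    def __post_init__(self) -> None:
        if not (self.dsl > 0 and 0 < self.dsw <= self.dsl):
            raise ValueError(f"need 0 < dsw <= dsl, got dsl={self.dsl}, dsw={self.dsw}")
        if not (0 < self.osw < self.dsw / 2):
            raise ValueError(f"need 0 < osw < dsw/2, got osw={self.osw}, dsw={self.dsw}")

    @classmethod
    def from_ratios(cls, dsw_dsl: float, osw_dsl: float, dsl: float = 1.0) -> "CoccolithOutline":
        return cls(dsl=dsl, dsw=dsw_dsl * dsl, osw=osw_dsl * dsl)

    @property
    def dsw_dsl(self) -> float:
        return self.dsw / self.dsl

    @property
    def osw_dsl(self) -> float:
        return self.osw / self.dsl

    def outer(self, center=(0.0, 0.0), angle: float = 0.0) -> EllipseSpec:
        return EllipseSpec(self.dsl / 2, self.dsw / 2, center=center, angle=angle)

    def central_area(self, center=(0.0, 0.0), angle: float = 0.0) -> EllipseSpec:
        return EllipseSpec(
            (self.dsl - 2 * self.osw) / 2, (self.dsw - 2 * self.osw) / 2, center=center, angle=angle
        )


@dataclass(frozen=True)
class InterlockCriterion:
    """Explicit feasibility criterion for an interlock configuration.

    ``check_border_areas``
        Gate on adjacent-border overlap chords clearing each border's
        central area (the red-arrow failure of crowded neighbours).
    ``check_chord_vs_border_area``
        Additionally gate on each polygon chord clearing its own
        bordering coccolith's central area (off by default: with fixed
        vertices this check penalises *small* neighbours, the opposite
        regime from the published failure modes).
    ``tightness_threshold``
        Minimum engagement depth of adjacent-border overlaps, as a
        fraction of the narrower shield width; 0 disables the looseness
        check.
    """

    check_border_areas: bool = True
    check_chord_vs_border_area: bool = False
    tightness_threshold: float = 0.9


#: Principle-1 only: polygon chords must clear the central coccolith's
#: central area.  This is the criterion with a closed-form circle oracle
#: (triangle threshold OSW/DSL = 0.25 for a circular outline).
CENTRAL_CLEARANCE_ONLY = InterlockCriterion(
    check_border_areas=False, check_chord_vs_border_area=False, tightness_threshold=0.0
)


@dataclass(frozen=True)
class InterlockConfiguration:
    """A central coccolith with ``n`` placed bordering coccoliths."""

    central: CoccolithOutline
    sizes: tuple[float, ...]  # DSL_BC / DSL_CC per border
    phase: float
    vertices: np.ndarray  # (n, 2) on the central outer ellipse
    border_outers: tuple[EllipseSpec, ...]
    border_centrals: tuple[EllipseSpec, ...]
    border_outline: tuple[CoccolithOutline, ...]

    @property
    def n(self) -> int:
        return len(self.sizes)

    def chord(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices[k], self.vertices[(k + 1) % self.n]


def build_configuration(
    central: CoccolithOutline,
    sizes: Sequence[float],
    phase: float = 0.0,
    border_dsw_dsl: Optional[float] = None,
    border_osw_dsl: Optional[float] = None,
) -> InterlockConfiguration:
    """Place ``len(sizes)`` bordering coccoliths around a central one.

    Vertices are put at parameter angles ``phase + 2πk/n`` on the
    central outer ellipse; border ``k`` spans the chord from vertex
    ``k`` to vertex ``k+1``, centred on its perpendicular bisector on
    the outward side, major axis parallel to the chord.  Border shape
    ratios default to the central coccolith's.  Deterministic.
    """
    n = len(sizes)
    if n < 3:
        raise ValueError(f"need at least 3 bordering coccoliths, got {n}")
    if any(s <= 0 for s in sizes):
        raise ValueError("size fractions must be positive")
    dsw_dsl = central.dsw_dsl if border_dsw_dsl is None else border_dsw_dsl
    osw_dsl = central.osw_dsl if border_osw_dsl is None else border_osw_dsl

    outer = central.outer()
    t = phase + 2 * math.pi * np.arange(n) / n
    verts = outer.point(t)

    outers, centrals, outlines = [], [], []
    for k, s in enumerate(sizes):
        p, q = verts[k], verts[(k + 1) % n]
        chord = q - p
        L = float(np.hypot(*chord))
        u = chord / L
        nhat = np.array([u[1], -u[0]])  # outward for counterclockwise vertex order
        mid = (p + q) / 2
        if float(nhat @ mid) < 0:
            nhat = -nhat
        lith = CoccolithOutline(dsl=s * central.dsl, dsw=dsw_dsl * s * central.dsl, osw=osw_dsl * s * central.dsl)
        A, B = lith.dsl / 2, lith.dsw / 2
        half = L / 2
        if A < half:
            raise PlacementError(
                f"bordering coccolith {k} (size fraction {s}) cannot span its chord: "
                f"semi-major {A:.4g} < half-chord {half:.4g}"
            )
        y0 = B * math.sqrt(1 - (half / A) ** 2)
        center = mid + y0 * nhat
        angle = math.atan2(u[1], u[0])
        outers.append(lith.outer(center=tuple(center), angle=angle))
        centrals.append(lith.central_area(center=tuple(center), angle=angle))
        outlines.append(lith)
    return InterlockConfiguration(
        central=central,
        sizes=tuple(float(s) for s in sizes),
        phase=float(phase),
        vertices=verts,
        border_outers=tuple(outers),
        border_centrals=tuple(centrals),
        border_outline=tuple(outlines),
    )


def _ellipse_intersections(e1: EllipseSpec, e2: EllipseSpec, n_grid: int = 360) -> np.ndarray:
    """Boundary intersection points of two ellipses (frame coordinates).

    Scans e1's boundary for sign changes of e2's implicit function and
    refines each crossing with Brent's method.  Tangencies may be
    missed; for the transversal crossings of interlock configurations
    the grid is ample.
    """
    ts = np.linspace(0.0, 2 * math.pi, n_grid, endpoint=False)
    vals = e2.implicit(e1.point(ts))

    def f(t: float) -> float:
        return float(e2.implicit(e1.point(t)))

    pts = []
    for i in range(n_grid):
        a, b = vals[i], vals[(i + 1) % n_grid]
        if a == 0.0:
            pts.append(e1.point(ts[i]))
            continue
        if a * b >= 0:
            continue
        lo = float(ts[i])
        hi = lo + 2 * math.pi / n_grid
        f_lo, f_hi = f(lo), f(hi)
        if f_lo == 0.0:
            pts.append(e1.point(lo))
        elif f_lo * f_hi < 0:
            root = optimize.brentq(f, lo, hi, xtol=1e-12)
            pts.append(e1.point(root))
        else:
            # grazing crossing at rounding scale: take the grid point
            pts.append(e1.point(lo if abs(f_lo) < abs(f_hi) else hi))
    if not pts:
        return np.empty((0, 2))
    return np.array(pts)


def _shield_depth(p1, p2, outer: EllipseSpec, inner: EllipseSpec) -> tuple[float, float]:
    """(clearance margin vs inner, depth fraction into the shield annulus).

    Both are measured in the chord-normal direction: margin is the
    signed distance of the chord beyond the central-area support
    (negative = transects), depth is how far the chord has penetrated
    inward from the outer rim as a fraction of the shield width.
    """
    margin = line_ellipse_clearance(p1, p2, inner)  # p − h_inner
    outer_margin = line_ellipse_clearance(p1, p2, outer)  # p − h_outer
    shield_width = margin - outer_margin  # h_outer − h_inner
    if shield_width <= 0:  # pragma: no cover - degenerate outline
        return margin, 0.0
    return margin, -outer_margin / shield_width


@dataclass(frozen=True)
class FeasibilityReport:
    """Clearances, engagement depths and the aggregate verdict."""

    criterion: InterlockCriterion
    chord_central_margins: np.ndarray  # (n,) polygon chords vs central's central area, μm
    chord_central_depths: np.ndarray  # (n,) chord depth fraction into central's shield
    chord_border_margins: np.ndarray  # (n,) polygon chord vs its border's central area, μm
    bb_margins: np.ndarray  # (n, 2) adjacent-pair overlap chord vs the two borders' areas
    bb_depths: np.ndarray  # (n, 2) overlap engagement into the two borders' shields
    verdict: str  # "feasible" | "transects-central-area" | "loose"

    @property
    def feasible(self) -> bool:
        return self.verdict == "feasible"

    def score(self) -> float:
        """Scalar feasibility score: positive iff the verdict is feasible.

        The minimum over the gated clearance margins (normalised by the
        central DSL-scale of the configuration) and tightness slacks;
        used for phase optimisation and threshold bisection.
        """
        c = self.criterion
        parts = [self.chord_central_margins]
        if c.check_chord_vs_border_area:
            parts.append(self.chord_border_margins)
        if c.check_border_areas:
            parts.append(self.bb_margins[np.isfinite(self.bb_margins)])
        vals = np.concatenate([np.atleast_1d(p).ravel() for p in parts])
        score = float(vals.min()) if vals.size else math.inf
        if c.tightness_threshold > 0:
            slack = float(np.min(self.bb_depths)) - c.tightness_threshold
            score = min(score, slack)
        return score


def evaluate(config: InterlockConfiguration, criterion: InterlockCriterion = InterlockCriterion()) -> FeasibilityReport:
    """Apply the interlock feasibility criterion to a configuration."""
    n = config.n
    central_inner = config.central.central_area()
    central_outer = config.central.outer()

    chord_margins = np.empty(n)
    chord_depths = np.empty(n)
    chord_border_margins = np.empty(n)
    bb_margins = np.full((n, 2), np.nan)
    bb_depths = np.zeros((n, 2))

    for k in range(n):
        p, q = config.chord(k)
        chord_margins[k], chord_depths[k] = _shield_depth(p, q, central_outer, central_inner)
        chord_border_margins[k] = line_ellipse_clearance(p, q, config.border_centrals[k])

    for k in range(n):
        k2 = (k + 1) % n
        pts = _ellipse_intersections(config.border_outers[k], config.border_outers[k2])
        if len(pts) < 2:
            continue  # neighbours barely touch: zero engagement
        # overlap chord: the farthest-apart pair of boundary crossings
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        if d2[i, j] <= 1e-16:
            continue
        p, q = pts[i], pts[j]
        m1, dep1 = _shield_depth(p, q, config.border_outers[k], config.border_centrals[k])
        m2, dep2 = _shield_depth(p, q, config.border_outers[k2], config.border_centrals[k2])
        bb_margins[k] = (m1, m2)
        bb_depths[k] = (min(dep1, 1.0), min(dep2, 1.0))

    transect = chord_margins.min() < 0
    if criterion.check_chord_vs_border_area and chord_border_margins.min() < 0:
        transect = True
    if criterion.check_border_areas:
        finite = bb_margins[np.isfinite(bb_margins)]
        if finite.size and finite.min() < 0:
            transect = True
    if transect:
        verdict = "transects-central-area"
    elif criterion.tightness_threshold > 0 and float(bb_depths.min()) < criterion.tightness_threshold:
        verdict = "loose"
    else:
        verdict = "feasible"
    return FeasibilityReport(
        criterion=criterion,
        chord_central_margins=chord_margins,
        chord_central_depths=chord_depths,
        chord_border_margins=chord_border_margins,
        bb_margins=bb_margins,
        bb_depths=bb_depths,
        verdict=verdict,
    )


def evaluate_best_phase(
    central: CoccolithOutline,
    sizes: Sequence[float],
    criterion: InterlockCriterion = InterlockCriterion(),
    n_phases: int = 12,
    refine: bool = True,
    **build_kwargs,
) -> tuple[FeasibilityReport, float]:
    """Evaluate over a phase grid and return the best report and its phase.

    The inscribed-polygon phase repeats with period 2π/n up to a
    relabelling of the vertices, so the grid covers one period; a local
    golden-section refinement around the best grid point follows.
    Configurations whose borders cannot span their chords score −∞.
    """
    n = len(sizes)
    period = 2 * math.pi / n

    def score_at(phase: float) -> tuple[float, Optional[FeasibilityReport]]:
        try:
            cfg = build_configuration(central, sizes, phase=phase, **build_kwargs)
        except PlacementError:
            return -math.inf, None
        rep = evaluate(cfg, criterion)
        return rep.score(), rep

    best_phase, (best_score, best_rep) = 0.0, (-math.inf, None)
    for phase in np.linspace(0.0, period, n_phases, endpoint=False):
        s, rep = score_at(float(phase))
        if s > best_score:
            best_phase, best_score, best_rep = float(phase), s, rep
    if refine and best_rep is not None:
        res = optimize.minimize_scalar(
            lambda ph: -score_at(ph)[0],
            bracket=None,
            bounds=(best_phase - period / n_phases, best_phase + period / n_phases),
            method="bounded",
            options={"xatol": period / (50 * n_phases)},
        )
        s, rep = score_at(float(res.x))
        if s > best_score:
            best_phase, best_score, best_rep = float(res.x), s, rep
    if best_rep is None:
        raise PlacementError("no phase admits a valid placement for these sizes")
    return best_rep, best_phase


def scan_min_osw_for_triangle(
    dsw_dsl: float,
    size_ratio: float = 1.0,
    resolution: float = 1e-3,
    criterion: InterlockCriterion = CENTRAL_CLEARANCE_ONLY,
    n_phases: int = 12,
) -> Optional[float]:
    """Minimal OSW/DSL at which a coccolith can interlock with three others.

    Bisection over the central coccolith's OSW/DSL of three-border
    feasibility at the phase that maximises the minimum margin.  The
    result depends on the active criterion and is reported as a
    calibration diagnostic against published thresholds; for a circular
    outline under central-clearance-only it equals 1/4 exactly (the
    incircle of an inscribed equilateral triangle has half the
    circumradius).  Returns ``None`` when no OSW/DSL in the valid range
    is feasible.
    """
    if not 0 < dsw_dsl <= 1:
        raise ValueError(f"need 0 < dsw_dsl <= 1, got {dsw_dsl}")

    def feasible(x: float) -> bool:
        central = CoccolithOutline.from_ratios(dsw_dsl, x)
        try:
            rep, _ = evaluate_best_phase(central, [size_ratio] * 3, criterion, n_phases=n_phases)
        except PlacementError:
            return False
        return rep.feasible

    lo, hi = resolution, dsw_dsl / 2 - 1e-9
    if not feasible(hi):
        return None
    if feasible(lo):
        return lo
    while hi - lo > resolution:
        mid = (lo + hi) / 2
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class BandScanResult:
    """Feasible size-ratio band and the per-value verdicts of the scan."""

    table: pd.DataFrame  # columns: size_ratio, verdict
    band: Optional[tuple[float, float]]  # maximal contiguous feasible interval
    below_band_verdict: Optional[str]
    above_band_verdict: Optional[str]


def scan_size_ratio_band(
    n: int,
    central: CoccolithOutline,
    resolution: float = 0.01,
    s_range: tuple[float, float] = (0.4, 1.3),
    criterion: InterlockCriterion = InterlockCriterion(),
    optimize_phase: bool = False,
    n_phases: int = 8,
) -> BandScanResult:
    """Sweep the common bordering-size fraction and report the feasible band.

    All ``n`` borders share one DSL_BC/DSL_CC value per scan point.  The
    returned band is the maximal contiguous feasible run, bracketed by
    the verdicts just outside it.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    values = np.arange(s_range[0], s_range[1] + resolution / 2, resolution)
    verdicts = []
    for s in values:
        try:
            if optimize_phase:
                rep, _ = evaluate_best_phase(central, [s] * n, criterion, n_phases=n_phases, refine=False)
            else:
                rep = evaluate(build_configuration(central, [s] * n), criterion)
            verdicts.append(rep.verdict)
        except PlacementError:
            verdicts.append("unreachable")
    table = pd.DataFrame({"size_ratio": values, "verdict": verdicts})
    feas = [i for i, v in enumerate(verdicts) if v == "feasible"]
    if not feas:
        return BandScanResult(table, None, None, None)
    runs = []
    start = feas[0]
    prev = feas[0]
    for i in feas[1:]:
        if i != prev + 1:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    a, b = max(runs, key=lambda r: r[1] - r[0])
    below = verdicts[a - 1] if a > 0 else None
    above = verdicts[b + 1] if b + 1 < len(verdicts) else None
    return BandScanResult(table, (float(values[a]), float(values[b])), below, above)


def neighbor_count_size_relation(
    population: Sequence[CoccolithOutline],
    trials: int = 200,
    seed: Optional[int] = None,
    criterion: InterlockCriterion = InterlockCriterion(tightness_threshold=0.2),
    n_range: tuple[int, int] = (3, 7),
    n_phases: int = 6,
    attempts: int = 3,
) -> pd.DataFrame:
    """Monte-Carlo relation between coccolith size and achievable neighbours.

    Each trial draws a central coccolith from the population and, for
    each candidate neighbour count ``n`` from high to low, up to
    ``attempts`` random sets of ``n`` borders (cells select compatible
    partners, so one incompatible draw does not preclude a count); the
    largest feasible ``n`` is recorded (0 if none).  Returns a table
    indexed by achieved ``n`` with the mean central DSL and the trial
    count — the direction expected from Lewis's law and the
    Aboav–Weaire law is a mean central size increasing with ``n``.

    The default criterion uses a moderate engagement threshold (0.2 of
    the shield width) rather than the strict module default: the
    adjacent-border engagement achievable under the idealised
    mirror-symmetric placement varies strongly with ``n``, and a strict
    threshold would reject every count.
    """
    pop = list(population)
    if len(pop) < n_range[1] + 1:
        raise ValueError(f"population must exceed n_max + 1 = {n_range[1] + 1} coccoliths")
    if trials < 100:
        import warnings

        warnings.warn(f"trials={trials} is small; the size-neighbour relation will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(trials):
        central = pop[rng.integers(len(pop))]
        achieved = 0
        for n in range(n_range[1], n_range[0] - 1, -1):
            ok = False
            for _attempt in range(attempts):
                idx = rng.choice(len(pop), size=n, replace=False)
                sizes = [pop[i].dsl / central.dsl for i in idx]
                try:
                    rep, _ = evaluate_best_phase(central, sizes, criterion, n_phases=n_phases, refine=False)
                except PlacementError:
                    continue
                if rep.feasible:
                    ok = True
                    break
            if ok:
                achieved = n
                break
        rows.append({"achieved_n": achieved, "central_dsl": central.dsl})
    df = pd.DataFrame(rows)
    out = df.groupby("achieved_n")["central_dsl"].agg(["mean", "count"])
    out.columns = ["mean_central_dsl", "trials"]
    return out


def render_svg(config: InterlockConfiguration, path, scale: float = 120.0) -> None:
    """Write a simple SVG drawing of a configuration (outlines + chords)."""
    ellipses = [
        (config.central.outer(), "#1f77b4"),
        (config.central.central_area(), "#1f77b4"),
    ]
    for outer, inner in zip(config.border_outers, config.border_centrals):
        ellipses.append((outer, "#2ca02c"))
        ellipses.append((inner, "#2ca02c"))
    pad = 1.2 * max(e.a + math.hypot(*e.center) for e, _ in ellipses)
    size = 2 * pad * scale
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size:.0f}" height="{size:.0f}" '
        f'viewBox="{-pad * scale:.1f} {-pad * scale:.1f} {size:.1f} {size:.1f}">'
    ]
    for e, color in ellipses:
        cx, cy = e.center[0] * scale, -e.center[1] * scale
        parts.append(
            f'<ellipse cx="{cx:.2f}" cy="{cy:.2f}" rx="{e.a * scale:.2f}" ry="{e.b * scale:.2f}" '
            f'transform="rotate({-math.degrees(e.angle):.2f} {cx:.2f} {cy:.2f})" '
            f'fill="none" stroke="{color}" stroke-width="1.5"/>'
        )
    for k in range(config.n):
        p, q = config.chord(k)
        parts.append(
            f'<line x1="{p[0] * scale:.2f}" y1="{-p[1] * scale:.2f}" x2="{q[0] * scale:.2f}" '
            f'y2="{-q[1] * scale:.2f}" stroke="#d62728" stroke-width="1"/>'
        )
    parts.append("</svg>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts))
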