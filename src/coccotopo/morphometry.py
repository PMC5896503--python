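"""Coccolith and coccosphere morphometrics.

Measurement records arrive as numbers (lengths in μm, counts per cell):
per-coccolith distal shield length (DSL), distal shield width (DSW) and
outer distal shield width (OSW, one side of the shield annulus), and
per-coccosphere diameter plus interlocked-coccolith counts.  The module
validates records, produces publication-style summaries (mean ± SD, range,
n, percentiles), derives central-area dimensions, and computes the
probability quantities used in the interlocking analysis: Gaussian tail
probabilities and the probability that all bordering coccoliths of a
central one fall in a given relative-size band.

The central area of a coccolith has axes ``DSL − 2·OSW`` by
``DSW − 2·OSW``: OSW is the one-side shield width, so it is subtracted
from both ends of each axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "CoccolithMorphometry",
    "ProtoCoccolith",
    "CoccosphereRecord",
    "MorphometricSummary",
    "RatioBandResult",
    "read_coccolith_csv",
    "read_coccosphere_csv",
    "summarize",
    "central_area_dimensions",
    "normal_tail_probability",
    "ratio_band_probability",
    "normality_diagnostic",
]


@dataclass(frozen=True)
class CoccolithMorphometry:
    """One measured coccolith: DSL, DSW and optionally OSW, all in μm."""

    dsl: float
    dsw: float
    osw: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.dsl > 0 and 0 < self.dsw <= self.dsl):
            raise ValueError(f"need 0 < dsw <= dsl, got dsl={self.dsl}, dsw={self.dsw}")
        if self.osw is not None and not (0 < self.osw < self.dsw / 2):
            raise ValueError(
                f"need 0 < osw < dsw/2 for a nondegenerate central area, got osw={self.osw}, dsw={self.dsw}"
            )


@dataclass(frozen=True)
class ProtoCoccolith:
    """A proto-coccolith ring: the initial calcite ring of a growing coccolith."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if not (0 < self.width <= self.length):
            raise ValueError(f"need 0 < width <= length, got length={self.length}, width={self.width}")


@dataclass(frozen=True)
class CoccosphereRecord:
    """One coccosphere: diameter (μm) and interlocked-coccolith counts.

    The counting rule for hemisphere SEM images is that the total count
    equals twice the number of fully interlocked coccoliths with a
    visible central area, so ``total_count = 2 × visible_interlocked_count``
    when both are present.
    """

    diameter: float
    visible_interlocked_count: Optional[int] = None
    total_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        for name in ("visible_interlocked_count", "total_count"):
            v = getattr(self, name)
            if v is not None and (v < 0 or v != int(v)):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.visible_interlocked_count is not None and self.total_count is not None:
            if self.total_count != 2 * self.visible_interlocked_count:
                raise ValueError(
                    f"total_count ({self.total_count}) must equal twice the visible interlocked "
                    f"count ({self.visible_interlocked_count})"
                )

    @property
    def count(self) -> Optional[int]:
        """Best available total coccolith count."""
        if self.total_count is not None:
            return self.total_count
        if self.visible_interlocked_count is not None:
            return 2 * self.visible_interlocked_count
        return None


@dataclass(frozen=True)
class MorphometricSummary:
    """Per-variable summary statistics as a DataFrame.

    ``table`` is indexed by variable name with columns ``mean``, ``sd``
    (sample SD, n−1 denominator), ``min``, ``max``, ``n`` and one column
    ``p<q>`` per requested percentile.
    """

    table: pd.DataFrame
    percentiles: tuple[float, ...]

    def __getitem__(self, variable: str) -> pd.Series:
        return self.table.loc[variable]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="variable")

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda x: f"{x:.4g}")


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = list(records)
    if not rows:
        return pd.DataFrame()
    first = rows[0]
    if isinstance(first, CoccolithMorphometry):
        return pd.DataFrame(
            {"dsl": [r.dsl for r in rows], "dsw": [r.dsw for r in rows],
             "osw": [np.nan if r.osw is None else r.osw for r in rows]}
        )
    if isinstance(first, ProtoCoccolith):
        return pd.DataFrame({"length": [r.length for r in rows], "width": [r.width for r in rows]})
    if isinstance(first, CoccosphereRecord):
        return pd.DataFrame(
            {"diameter": [r.diameter for r in rows],
             "count": [np.nan if r.count is None else r.count for r in rows]}
        )
    raise TypeError(f"unsupported record type {type(first).__name__}")


def summarize(records, percentiles: Sequence[float] = (0.05, 0.95)) -> MorphometricSummary:
    """Summary table of measurement records (mean ± SD, range, n, percentiles).

    Accepts a DataFrame or a homogeneous collection of record objects.
    Derived ratio variables (``dsw/dsl``, ``osw/dsl``) are added when the
    inputs permit.  Rows missing OSW contribute to the DSL/DSW statistics
    but are excluded from OSW-derived quantities; non-finite values are
    rejected with their row index.

    Percentiles are linear-interpolation quantiles of the order
    statistics, given as probabilities in [0, 1].
    """
    df = _records_to_frame(records).select_dtypes("number").astype(float)
    if len(df) < 2:
        raise ValueError(f"need at least 2 records to summarize, got {len(df)}")
    for col in df.columns:
        bad = df.index[np.isinf(df[col].to_numpy())]
        if len(bad):
            raise ValueError(f"non-finite value in column {col!r} at row index {bad[0]}")
    if {"dsl", "dsw"} <= set(df.columns):
        df["dsw/dsl"] = df["dsw"] / df["dsl"]
    if {"dsl", "osw"} <= set(df.columns):
        df["osw/dsl"] = df["osw"] / df["dsl"]
    pct = tuple(float(p) for p in percentiles)
    if any(not 0 <= p <= 1 for p in pct):
        raise ValueError(f"percentiles must be probabilities in [0, 1], got {pct}")
    rows = {}
    for col in df.columns:
        x = df[col].dropna().to_numpy()
        if len(x) < 2:
            continue
        row = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "n": len(x),
        }
        for p in pct:
            row[f"p{100 * p:g}"] = float(np.quantile(x, p))
        rows[col] = row
    return MorphometricSummary(pd.DataFrame.from_dict(rows, orient="index"), pct)


def central_area_dimensions(lith: CoccolithMorphometry) -> tuple[float, float]:
    """Central-area axes (length, width) = (DSL − 2·OSW, DSW − 2·OSW), μm.

    These match the measured proto-coccolith ring axes: the proto-ring
    sits at the base of the central tube connecting the two shields.
    """
    if lith.osw is None:
        raise ValueError("central-area dimensions require an OSW measurement")
    length = lith.dsl - 2 * lith.osw
    width = lith.dsw - 2 * lith.osw
    if length <= 0 or width <= 0:
        raise ValueError(f"degenerate central area: length={length}, width={width}")
    return length, width


def normal_tail_probability(
    mean: float, sd: float, threshold: float, side: Literal["upper", "lower"] = "upper"
) -> float:
    """Exact Gaussian tail probability P(X ≥ t) (or ≤ for ``lower``).

    Evaluated through scipy's complementary-error-function survival
    routines, so far tails (e.g. the OSW/DSL ≥ 0.37 event at nine
    standard deviations) retain full relative accuracy.
    """
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    if side == "upper":
        return float(stats.norm.sf(threshold, loc=mean, scale=sd))
    if side == "lower":
        return float(stats.norm.cdf(threshold, loc=mean, scale=sd))
    raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")


@dataclass(frozen=True)
class RatioBandResult:
    """One interpretation's result for the bordering-size band probability."""

    interpretation: str
    analytic: float
    monte_carlo: float
    mc_standard_error: float


def _band_prob_given_central(x: np.ndarray | float, mu: float, sigma: float, lo: float, hi: float):
    """q(x) = P(lo·x ≤ DSL_BC ≤ hi·x) for bordering draws ~ N(mu, sigma)."""
    x = np.asarray(x, dtype=float)
    upper = np.where(x >= 0, hi * x, lo * x)
    lower = np.where(x >= 0, lo * x, hi * x)
    return stats.norm.cdf(upper, mu, sigma) - stats.norm.cdf(lower, mu, sigma)


def ratio_band_probability(
    mu: float,
    sigma: float,
    band: tuple[float, float],
    k: int,
    interpretation: Literal["fixed_central", "shared_central", "independent_ratio"],
    mc_samples: int = 100_000,
    seed: Optional[int] = None,
) -> RatioBandResult:
    """Probability that all k bordering DSLs fall in ``[lo·DSL_CC, hi·DSL_CC]``.

    All sizes are drawn from N(``mu``, ``sigma``); ``band`` is given as
    fractions (lo, hi) of the central coccolith's DSL.  Three readings of
    the event are supported, because the published figure does not pin
    one down:

    ``fixed_central``
        The central DSL is held at the mean: q(μ)^k with q the normal
        band probability (closed form).
    ``shared_central``
        One random central, k independent borders: ∫ φ(x) q(x)^k dx by
        adaptive quadrature.  The Monte-Carlo estimate draws the central
        and averages q(x)^k (Rao-Blackwellised, so tiny probabilities
        keep a usable standard error).
    ``independent_ratio``
        Each of k size ratios is an independent ratio of two normal
        draws: P(lo ≤ X/Y ≤ hi)^k, the ratio probability computed by
        quadrature over the denominator; Monte-Carlo uses paired draws
        with a delta-method standard error for the k-th power.

    Returns both the analytic value and the Monte-Carlo cross-check.
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError(f"band upper bound must exceed lower, got [{lo}, {hi}]")
    if not lo >= 0:
        raise ValueError(f"band bounds must be nonnegative size fractions, got lo={lo}")
    if k < 1:
        raise ValueError(f"need k >= 1 bordering draws, got {k}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if mc_samples < 10_000:
        warnings.warn(
            f"mc_samples={mc_samples} is small; Monte-Carlo cross-check will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    if interpretation == "fixed_central":
        q = float(_band_prob_given_central(mu, mu, sigma, lo, hi))
        analytic = q ** k
        draws = rng.normal(mu, sigma, size=mc_samples)
        inside = ((draws >= lo * mu) & (draws <= hi * mu)).mean()
        se_q = math.sqrt(max(inside * (1 - inside), 1e-300) / mc_samples)
        mc = inside ** k
        se = k * max(inside, 1e-300) ** (k - 1) * se_q
    elif interpretation == "shared_central":
        analytic, _ = integrate.quad(
            lambda x: stats.norm.pdf(x, mu, sigma) * float(_band_prob_given_central(x, mu, sigma, lo, hi)) ** k,
            mu - 10 * sigma,
            mu + 10 * sigma,
        )
        centrals = rng.normal(mu, sigma, size=mc_samples)
        vals = _band_prob_given_central(centrals, mu, sigma, lo, hi) ** k
        mc = float(vals.mean())
        se = float(vals.std(ddof=1) / math.sqrt(mc_samples))
    elif interpretation == "independent_ratio":
        # P(lo <= X/Y <= hi) integrating the normal density of the denominator
        p1, _ = integrate.quad(
            lambda y: stats.norm.pdf(y, mu, sigma) * float(_band_prob_given_central(y, mu, sigma, lo, hi)),
            mu - 10 * sigma,
            mu + 10 * sigma,
        )
        analytic = p1 ** k
        xs = rng.normal(mu, sigma, size=mc_samples)
        ys = rng.normal(mu, sigma, size=mc_samples)
        r = xs / ys
        inside = float(((r >= lo) & (r <= hi)).mean())
        se_p = math.sqrt(max(inside * (1 - inside), 1e-300) / mc_samples)
        mc = inside ** k
        se = k * max(inside, 1e-300) ** (k - 1) * se_p
    else:
        raise ValueError(f"unknown interpretation {interpretation!r}")
    return RatioBandResult(interpretation, float(analytic), float(mc), float(se))


def normality_diagnostic(values: Iterable[float]) -> tuple[float, float]:
    """Omnibus normality test (D'Agostino-Pearson): (statistic, p-value).

    Reported as a diagnostic only; no downstream computation is gated on
    it.
    """
    x = np.asarray(list(values), dtype=float)
    stat, p = stats.normaltest(x)
    return float(stat), float(p)


def read_coccolith_csv(path) -> pd.DataFrame:
    """Read a per-coccolith CSV with columns dsl_um, dsw_um and optional osw_um.

    Returns a validated DataFrame with columns ``dsl``, ``dsw`` and, when
    present, ``osw``; rows violating the morphometric invariants raise.
    """
    df = pd.read_csv(path)
    required = {"dsl_um", "dsw_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coccolith CSV is missing column(s) {sorted(missing)}")
    out = pd.DataFrame({"dsl": df["dsl_um"].astype(float), "dsw": df["dsw_um"].astype(float)})
    if "osw_um" in df.columns:
        out["osw"] = df["osw_um"].astype(float)
    for idx, row in out.iterrows():
        CoccolithMorphometry(row["dsl"], row["dsw"], None if "osw" not in out or pd.isna(row.get("osw")) else row["osw"])
    return out


def read_coccosphere_csv(path) -> pd.DataFrame:
    """Read a per-coccosphere CSV with diameter_um and visible_count or total_count.

    Returns a DataFrame with columns ``diameter`` and ``count`` (total
    coccoliths, doubling the visible hemisphere count when needed).
    """
    df = pd.read_csv(path)
    if "diameter_um" not in df.columns:
        raise ValueError("coccosphere CSV is missing column 'diameter_um'")
    out = pd.DataFrame({"diameter": df["diameter_um"].astype(float)})
    if "total_count" in df.columns:
        out["count"] = df["total_count"].astype(int)
    elif "visible_count" in df.columns:
        out["count"] = 2 * df["visible_count"].astype(int)
    else:
        out["count"] = np.nan
    for idx, row in out.iterrows():
        if row["diameter"] <= 0:
            raise ValueError(f"nonpositive diameter at row index {idx}")
    return out
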