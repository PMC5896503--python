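"""Seeded synthetic coccolith and coccosphere populations.

No raw measurement table is publicly deposited for the analysed strain,
so testing end-to-end requires a generator that emulates the published
population statistics: truncated-normal marginals for distal shield
length (3.04 ± 0.40 μm on 2.05–4.38), the DSW/DSL ratio (0.81 ± 0.07 on
0.62–0.99), the OSW/DSL ratio (0.19 ± 0.02 on 0.15–0.25) and the
coccosphere diameter (5.54 ± 0.63 μm on 3.92–8.04).  DSW and OSW are
generated as ratios of DSL so that both the absolute and the ratio
statistics of the published table are matched at once.

Coccolith counts per coccosphere close the loop with the coverage
model: the true count is the self-consistent coverage estimate for the
cell's own surface area plus integer-rounded Gaussian noise, and the
*reported* count mimics the hemisphere counting rule — a fraction of
interlocked coccoliths has a hidden central area and goes uncounted
(default 22%), and the reported total is twice the visible count.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .coverage_model import estimate_count_fixed_point
from .ellipse_geometry import SphereCapSpec, spherical_cap_area, sphere_surface_area

__all__ = [
    "TruncatedNormalSpec",
    "PopulationParams",
    "SyntheticDataset",
    "generate_coccoliths",
    "generate_coccospheres",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

_VERSION = "0.1.0"


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """A truncated normal marginal: mean and sd of the parent normal, hard range."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not self.lo <= self.mean <= self.hi:
            raise ValueError(f"truncation range [{self.lo}, {self.hi}] must contain the mean {self.mean}")

    def frozen(self):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.frozen().rvs(size=n, random_state=rng)

    @property
    def truncated_sd(self) -> float:
        """SD of the truncated distribution (smaller than the parent sd)."""
        return float(self.frozen().std())


@dataclass(frozen=True)
class PopulationParams:
    """Generator settings emulating the published population.

    ``undercount_fraction`` is the share of interlocked coccoliths whose
    central area is hidden in a hemisphere image; ``count_noise_sd`` is
    the pre-rounding Gaussian jitter on the true count (chosen to put
    the count SD near the observed 3.6).
    """

    dsl: TruncatedNormalSpec = TruncatedNormalSpec(3.04, 0.40, 2.05, 4.38)
    dsw_over_dsl: TruncatedNormalSpec = TruncatedNormalSpec(0.81, 0.07, 0.62, 0.99)
    osw_over_dsl: TruncatedNormalSpec = TruncatedNormalSpec(0.19, 0.02, 0.15, 0.25)
    sphere_diameter: TruncatedNormalSpec = TruncatedNormalSpec(5.54, 0.63, 3.92, 8.04)
    undercount_fraction: float = 0.22
    count_noise_sd: float = 1.5
    min_count: int = 6

    def __post_init__(self) -> None:
        if not 0 <= self.undercount_fraction < 1:
            raise ValueError(f"undercount fraction must be in [0, 1), got {self.undercount_fraction}")
        if self.count_noise_sd < 0:
            raise ValueError(f"count noise sd must be nonnegative, got {self.count_noise_sd}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        kwargs = dict(d)
        for key in ("dsl", "dsw_over_dsl", "osw_over_dsl", "sphere_diameter"):
            kwargs[key] = TruncatedNormalSpec(**kwargs[key])
        return cls(**kwargs)


@dataclass
class SyntheticDataset:
    """Generated tables plus a provenance block (params, seed, version)."""

    coccoliths: pd.DataFrame
    coccospheres: pd.DataFrame
    provenance: dict


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-table generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_coccoliths(params: PopulationParams, n: int, seed: int) -> pd.DataFrame:
    """Per-coccolith table with columns dsl, dsw, osw (μm), deterministic in seed."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    rng = _substreams(seed, 2)[0]
    dsl = params.dsl.sample(n, rng)
    dsw = dsl * params.dsw_over_dsl.sample(n, rng)
    osw = dsl * params.osw_over_dsl.sample(n, rng)
    # ratio truncations guarantee osw < dsw/2 row-wise (0.25 < 0.62/2)
    return pd.DataFrame({"dsl": dsl, "dsw": dsw, "osw": osw})


def _mean_cap_base(params: PopulationParams) -> float:
    """Cap base diameter: population mean of (DSL + DSW)/2."""
    mu_dsl = params.dsl.frozen().mean()
    mu_ratio = params.dsw_over_dsl.frozen().mean()
    return float(mu_dsl * (1 + mu_ratio) / 2)


def generate_coccospheres(params: PopulationParams, n: int, seed: int) -> pd.DataFrame:
    """Per-coccosphere table: diameter, true/visible/reported counts.

    The true count is the coverage-model fixed point for the cell's own
    diameter (cap base at the population mean of (DSL+DSW)/2) with
    Gaussian noise, clipped to the minimum complete coccosphere of 6;
    the reported count is twice the visible count after hiding the
    undercount fraction.
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    rng = _substreams(seed, 2)[1]
    d = params.sphere_diameter.sample(n, rng)
    base = _mean_cap_base(params)
    if base >= params.sphere_diameter.lo:
        raise ValueError("coccolith cap base exceeds the smallest coccosphere diameter")
    model = np.array(
        [
            estimate_count_fixed_point(
                sphere_surface_area(di), spherical_cap_area(SphereCapSpec(di, base))
            )
            for di in d
        ]
    )
    noise = rng.normal(0.0, params.count_noise_sd, size=n) if params.count_noise_sd > 0 else 0.0
    true = np.maximum(np.rint(model + noise).astype(int), params.min_count)
    visible = np.maximum(np.rint(true * (1 - params.undercount_fraction) / 2).astype(int), 3)
    return pd.DataFrame(
        {
            "diameter": d,
            "true_count": true,
            "visible_interlocked_count": visible,
            "total_count": 2 * visible,
        }
    )


def generate_dataset(
    params: Optional[PopulationParams] = None,
    n_coccoliths: int = 1918,
    n_coccospheres: int = 156,
    seed: int = 0,
) -> SyntheticDataset:
    """Full synthetic dataset at the published sample sizes by default."""
    params = params or PopulationParams()
    liths = generate_coccoliths(params, n_coccoliths, seed)
    spheres = generate_coccospheres(params, n_coccospheres, seed)
    prov = {
        "params": params.to_dict(),
        "seed": seed,
        "n_coccoliths": n_coccoliths,
        "n_coccospheres": n_coccospheres,
        "package_version": _VERSION,
    }
    return SyntheticDataset(liths, spheres, prov)


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(dataset: SyntheticDataset, path) -> None:
    """Write liths.csv, spheres.csv and provenance.json under ``path``.

    Coccolith columns use the external schema (dsl_um, dsw_um, osw_um);
    the provenance block records parameters, seed and per-table
    checksums so tampering is detectable on read.
    """
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    liths = dataset.coccoliths.rename(columns={"dsl": "dsl_um", "dsw": "dsw_um", "osw": "osw_um"})
    spheres = dataset.coccospheres.rename(columns={"diameter": "diameter_um"})
    liths.to_csv(p / "liths.csv", index=False)
    spheres.to_csv(p / "spheres.csv", index=False)
    prov = dict(dataset.provenance)
    prov["checksums"] = {
        "liths.csv": _file_checksum(p / "liths.csv"),
        "spheres.csv": _file_checksum(p / "spheres.csv"),
    }
    (p / "provenance.json").write_text(json.dumps(prov, indent=2), encoding="utf-8")


def read_dataset(path) -> SyntheticDataset:
    """Round-trip read of :func:`write_dataset` output.

    A missing osw_um column is tolerated (records measured without OSW);
    a checksum mismatch warns about tampering; a missing required column
    raises naming it.
    """
    p = Path(path)
    liths = pd.read_csv(p / "liths.csv")
    spheres = pd.read_csv(p / "spheres.csv")
    for col in ("dsl_um", "dsw_um"):
        if col not in liths.columns:
            raise ValueError(f"liths.csv is missing required column {col!r}")
    if "diameter_um" not in spheres.columns:
        raise ValueError("spheres.csv is missing required column 'diameter_um'")
    prov = {}
    prov_path = p / "provenance.json"
    if prov_path.exists():
        prov = json.loads(prov_path.read_text(encoding="utf-8"))
        stored = prov.get("checksums", {})
        actual = {name: _file_checksum(p / name) for name in stored if (p / name).exists()}
        for name, digest in stored.items():
            if actual.get(name) != digest:
                warnings.warn(f"checksum mismatch for {name}: file differs from its provenance", stacklevel=2)
    liths = liths.rename(columns={"dsl_um": "dsl", "dsw_um": "dsw", "osw_um": "osw"})
    spheres = spheres.rename(columns={"diameter_um": "diameter"})
    return SyntheticDataset(liths, spheres, prov)
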