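"""Synthetic zone systems with gamma-distributed, age-stratified populations.

A :class:`StudyRegion` is the spatial support for the whole pipeline: an
ordered set of zones, each with a planar centroid and one integer population
count per age stratum.  Zone populations are drawn from a gamma distribution
(right-skewed, strictly positive), which is the distributional shape real
ZIP-code-level census populations exhibit; the moment-matched gamma fit is
also the reference density the diagnostic module compares against.

Coordinates are dimensionless planar units.  Geographic inputs must be
pre-projected; no CRS handling is performed here.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateSampleError

__all__ = [
    "AgeStratum",
    "Zone",
    "StudyRegion",
    "GammaFit",
    "StratumSpec",
    "fit_gamma_moments",
    "gamma_pdf",
    "generate_region",
    "region_to_csv",
    "region_from_csv",
    "region_to_geojson",
]


@dataclass(frozen=True)
class AgeStratum:
    """One age stratum: label, true event rate per 100,000, total population."""

    label: str
    true_rate: float
    total_population: int

    def __post_init__(self):
        if not self.true_rate > 0:
            raise ConfigError(f"true_rate must be > 0, got {self.true_rate}")
        if self.total_population < 1:
            raise ConfigError(
                f"total_population must be >= 1, got {self.total_population}"
            )


@dataclass(frozen=True)
class Zone:
    id: str
    centroid: tuple[float, float]
    population: Mapping[str, int]

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.centroid):
            raise ConfigError(f"zone {self.id}: non-finite centroid {self.centroid}")
        if any(v < 0 for v in self.population.values()):
            raise ConfigError(f"zone {self.id}: negative population count")


@dataclass
class StudyRegion:
    """Ordered zone system with per-stratum populations.

    Arrays are the primary representation (``centroids`` is (n, 2),
    ``populations[label]`` is (n,) integer); :attr:`zones` materialises
    :class:`Zone` views on demand.
    """

    zone_ids: list[str]
    centroids: np.ndarray
    populations: dict[str, np.ndarray]
    strata: list[AgeStratum] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.zone_ids)
        if n < 2:
            raise ConfigError("a region needs at least 2 zones")
        if len(set(self.zone_ids)) != n:
            raise ConfigError("zone ids must be unique")
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (n, 2) or not np.all(np.isfinite(self.centroids)):
            raise ConfigError("centroids must be a finite (n, 2) array")
        for label, pops in self.populations.items():
            pops = np.asarray(pops)
            if pops.shape != (n,) or np.any(pops < 0):
                raise ConfigError(f"stratum {label}: bad population vector")
            self.populations[label] = pops.astype(np.int64)
        for st in self.strata:
            if st.label not in self.populations:
                raise ConfigError(f"stratum {st.label} has no population column")
            total = int(self.populations[st.label].sum())
            if total != st.total_population:
                raise ConfigError(
                    f"stratum {st.label}: zone populations sum to {total}, "
                    f"declared total is {st.total_population}"
                )

    @property
    def n_zones(self) -> int:
        return len(self.zone_ids)

    @property
    def stratum_labels(self) -> list[str]:
        return [s.label for s in self.strata]

    def stratum(self, label: str) -> AgeStratum:
        for s in self.strata:
            if s.label == label:
                return s
        raise ConfigError(f"unknown stratum {label!r}")

    @property
    def zones(self) -> list[Zone]:
        return [
            Zone(
                id=zid,
                centroid=(float(self.centroids[i, 0]), float(self.centroids[i, 1])),
                population={k: int(v[i]) for k, v in self.populations.items()},
            )
            for i, zid in enumerate(self.zone_ids)
        ]


@dataclass(frozen=True)
class GammaFit:
    """Moment-matched gamma parameters: shape k = (mu/sigma)^2, scale = sigma^2/mu."""

    shape: float
    scale: float
    source_mean: float
    source_sd: float

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise ConfigError("gamma shape and scale must be positive")
        if not math.isclose(self.shape * self.scale, self.source_mean, rel_tol=1e-9):
            raise ConfigError("shape * scale must equal the source mean")


def fit_gamma_moments(values: Iterable[float]) -> GammaFit:
    """Fit a gamma distribution by matching the sample mean and SD.

    Uses k = (mu/sigma)^2 and theta = sigma^2/mu with the n-1 (sample) SD.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to fit a gamma by moments")
    if np.any(x < 0):
        raise ValueError("gamma moment fit requires nonnegative values")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError("zero sample variance: gamma fit is degenerate")
    return GammaFit(shape=(mu / sd) ** 2, scale=sd**2 / mu, source_mean=mu, source_sd=sd)


def gamma_pdf(x, fit: GammaFit):
    """Gamma density x^(k-1) e^(-x/theta) / (theta^k Gamma(k)); scalar or array."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("gamma pdf is defined on x >= 0 only")
    out = stats.gamma.pdf(arr, a=fit.shape, scale=fit.scale)
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class StratumSpec:
    """Generation recipe for one stratum.

    ``total_population``, when given, is enforced exactly: after rounding the
    gamma draws, the residual is absorbed by the largest zones (never pushing
    a zone below 1 person).
    """

    label: str
    true_rate_per_100k: float
    gamma_shape: float
    gamma_scale: float
    total_population: int | None = None

    def __post_init__(self):
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ConfigError(f"stratum {self.label}: gamma parameters must be positive")
        if self.true_rate_per_100k <= 0:
            raise ConfigError(f"stratum {self.label}: true rate must be positive")


def _grid_centroids(n: int, rng: np.random.Generator, jitter: float) -> np.ndarray:
    side = math.ceil(math.sqrt(n))
    rows, cols = np.divmod(np.arange(n), side)
    xy = np.column_stack([cols + 0.5, rows + 0.5]).astype(float)
    if jitter > 0:
        xy += rng.uniform(-jitter, jitter, size=xy.shape)
    return xy


def _integer_populations(
    raw: np.ndarray, total: int | None, label: str
) -> np.ndarray:
    """Round gamma draws to integer counts (floor 1), hitting ``total`` exactly.

    Draws are first rescaled multiplicatively to the target total so the
    post-rounding residual is at most ~n/2, then the residual is spread as
    +/-1 adjustments over the largest zones (never pushing a zone below 1).
    Dumping the whole residual into a single zone would distort the sample SD
    and skewness the selectors depend on.
    """
    if total is not None:
        if total < raw.size:
            raise ConfigError(
                f"stratum {label}: total_population {total} below one person per zone"
            )
        raw = raw * (total / raw.sum())
    # round half-up; census-style counts never go below 1 person
    pops = np.floor(raw + 0.5).astype(np.int64)
    np.clip(pops, 1, None, out=pops)
    if total is None:
        return pops
    residual = total - int(pops.sum())
    step = 1 if residual > 0 else -1
    order = np.argsort(pops)[::-1]  # largest zones absorb the +/-1 nudges
    i = 0
    while residual != 0:
        z = order[i % pops.size]
        if step > 0 or pops[z] > 1:
            pops[z] += step
            residual -= step
        i += 1
        if i > 10 * pops.size + abs(residual):  # pragma: no cover - defensive
            raise ConfigError(f"stratum {label}: cannot reach total {total}")
    return pops


def generate_region(
    n_zones: int,
    strata_spec: Sequence[StratumSpec],
    layout: str = "grid",
    seed: int = 0,
    jitter: float = 0.25,
) -> StudyRegion:
    """Generate a synthetic zone system.

    Centroids are placed on a square of side ceil(sqrt(n_zones)) — a jittered
    regular grid by default, or uniformly at random — and per-stratum zone
    populations are drawn from the stratum's gamma distribution, rounded to
    integers with minimum 1.  Deterministic given ``seed``.
    """
    if n_zones < 2:
        raise ConfigError(f"n_zones must be >= 2, got {n_zones}")
    if not strata_spec:
        raise ConfigError("at least one stratum spec is required")
    rng = np.random.default_rng(seed)
    if layout == "grid":
        xy = _grid_centroids(n_zones, rng, jitter)
    elif layout == "uniform_random":
        side = math.ceil(math.sqrt(n_zones))
        xy = rng.uniform(0.0, side, size=(n_zones, 2))
    else:
        raise ConfigError(f"unknown layout {layout!r}")

    width = len(str(n_zones))
    zone_ids = [f"Z{i:0{width}d}" for i in range(1, n_zones + 1)]

    populations: dict[str, np.ndarray] = {}
    strata: list[AgeStratum] = []
    for spec in strata_spec:
        raw = rng.gamma(spec.gamma_shape, spec.gamma_scale, size=n_zones)
        pops = _integer_populations(raw, spec.total_population, spec.label)
        populations[spec.label] = pops
        strata.append(
            AgeStratum(
                label=spec.label,
                true_rate=spec.true_rate_per_100k,
                total_population=int(pops.sum()),
            )
        )
    return StudyRegion(zone_ids, xy, populations, strata)


# ---------------------------------------------------------------------------
# I/O: zone table CSV and centroid GeoJSON


def region_to_csv(region: StudyRegion, path) -> None:
    labels = list(region.populations)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["zone_id", "x", "y"] + [f"pop_{lab}" for lab in labels])
        for i, zid in enumerate(region.zone_ids):
            w.writerow(
                [zid, repr(float(region.centroids[i, 0])), repr(float(region.centroids[i, 1]))]
                + [int(region.populations[lab][i]) for lab in labels]
            )


def region_from_csv(path, strata: Sequence[AgeStratum] | None = None,
                    true_rates: Mapping[str, float] | None = None) -> StudyRegion:
    """Read a zone table written by :func:`region_to_csv`.

    Stratum metadata is rebuilt either from ``strata`` or from a
    label -> true-rate mapping (totals recomputed from the table).
    """
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ConfigError(f"empty zone table: {path}")
    labels = [c[4:] for c in rows[0] if c.startswith("pop_")]
    zone_ids = [r["zone_id"] for r in rows]
    xy = np.array([[float(r["x"]), float(r["y"])] for r in rows])
    populations = {
        lab: np.array([int(r[f"pop_{lab}"]) for r in rows], dtype=np.int64)
        for lab in labels
    }
    if strata is None:
        true_rates = true_rates or {}
        strata = [
            AgeStratum(lab, true_rates.get(lab, 1.0), int(populations[lab].sum()))
            for lab in labels
        ]
    return StudyRegion(zone_ids, xy, populations, list(strata))


def region_to_geojson(region: StudyRegion, path) -> None:
    """Write zone centroids as a Point FeatureCollection (local planar coordinates)."""
    features = []
    for i, zid in enumerate(region.zone_ids):
        props = {"zone_id": zid}
        props.update({f"pop_{k}": int(v[i]) for k, v in region.populations.items()})
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(region.centroids[i, 0]), float(region.centroids[i, 1])],
                },
                "properties": props,
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": "local-planar"}},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
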