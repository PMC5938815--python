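"""Population-threshold adaptive kernel rate estimation.

At every zone centroid a circular kernel grows, swallowing whole zones in
order of centroid distance, until the enclosed population reaches the
threshold; the zone's estimated rate is enclosed cases over enclosed
population (a uniform kernel — no distance decay).  Zone-level rates are
aggregated to a single regional rate by a population-weighted mean, which
makes the threshold -> 0 limit coincide exactly with the replicate's
baseline rate.

Distances are Euclidean on planar coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError
from .geography import StudyRegion
from .simulate import PER_100K, ReplicateCaseSet

__all__ = [
    "NeighborOrdering",
    "RateSurface",
    "build_neighbor_ordering",
    "estimate_rates",
    "state_rate",
    "crude_zone_mean",
    "estimate_state_rates",
    "surface_to_frame",
]


@dataclass
class NeighborOrdering:
    """Per-zone neighbor permutations by ascending centroid distance.

    ``order[z]`` lists zone indices starting with z itself; ``distance`` holds
    the matching sorted distances and ``cum_pop[label]`` the cumulative
    stratum population along each permutation.  Ties in distance are broken
    by ascending zone id (self always first), so the ordering is
    deterministic.
    """

    order: np.ndarray  # (n, n) int32
    distance: np.ndarray  # (n, n) float
    cum_pop: dict[str, np.ndarray]  # label -> (n, n) cumulative population


def build_neighbor_ordering(region: StudyRegion) -> NeighborOrdering:
    n = region.n_zones
    d = squareform(pdist(region.centroids))
    if np.any(d[np.triu_indices(n, k=1)] == 0.0):
        warnings.warn("duplicate zone centroids detected; ties broken by zone id")
    id_rank = np.argsort(np.argsort(np.asarray(region.zone_ids)))
    order = np.empty((n, n), dtype=np.int32)
    for i in range(n):
        not_self = np.ones(n, dtype=np.int8)
        not_self[i] = 0
        # primary key distance, then self-first, then ascending zone id
        order[i] = np.lexsort((id_rank, not_self, d[i]))
    rows = np.arange(n)[:, None]
    distance = d[rows, order]
    cum_pop = {
        label: pops[order].cumsum(axis=1).astype(np.float64)
        for label, pops in region.populations.items()
    }
    return NeighborOrdering(order=order, distance=distance, cum_pop=cum_pop)


@dataclass
class RateSurface:
    """Zone-level adaptive-kernel rate estimates for one (stratum, threshold, replicate)."""

    stratum: str
    threshold: float
    threshold_name: str
    replicate: int
    zone_ids: list[str]
    rate: np.ndarray  # per 100,000; NaN where enclosed population is 0
    radius: np.ndarray
    enclosed_pop: np.ndarray
    enclosed_cases: np.ndarray
    underfilled: np.ndarray  # bool per zone


def _kernel_extent(
    ordering: NeighborOrdering, stratum: str, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Index of the last included neighbor per zone, and the underfilled mask."""
    cp = ordering.cum_pop[stratum]
    n = cp.shape[0]
    total = cp[0, -1]
    if total < threshold:
        return np.full(n, n - 1, dtype=np.int64), np.ones(n, dtype=bool)
    k = np.argmax(cp >= threshold, axis=1).astype(np.int64)
    return k, np.zeros(n, dtype=bool)


def estimate_rates(
    region: StudyRegion,
    cases: ReplicateCaseSet,
    stratum: str,
    threshold: float,
    ordering: NeighborOrdering,
    threshold_name: str | None = None,
) -> RateSurface:
    """Adaptive-kernel rate surface for one replicate, stratum and threshold.

    For each zone, neighbors are included in distance order until the
    cumulative stratum population reaches the threshold; the zone that first
    reaches it is included whole.  If the regional total is below the
    threshold, every zone's kernel covers the whole region and the surface is
    flagged underfilled.
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be positive, got {threshold}")
    if stratum not in ordering.cum_pop:
        raise ConfigError(f"stratum {stratum!r} not present in region")
    n = region.n_zones
    rows = np.arange(n)
    k, underfilled = _kernel_extent(ordering, stratum, threshold)
    case_vec = np.asarray(cases.cases[stratum], dtype=np.float64)
    cum_cases = case_vec[ordering.order].cumsum(axis=1)
    enclosed_pop = ordering.cum_pop[stratum][rows, k]
    enclosed_cases = cum_cases[rows, k]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(enclosed_pop > 0, PER_100K * enclosed_cases / enclosed_pop, np.nan)
    return RateSurface(
        stratum=stratum,
        threshold=float(threshold),
        threshold_name=threshold_name or f"{threshold:g}",
        replicate=cases.replicate_index,
        zone_ids=list(region.zone_ids),
        rate=rate,
        radius=ordering.distance[rows, k],
        enclosed_pop=enclosed_pop,
        enclosed_cases=enclosed_cases,
        underfilled=underfilled,
    )


def state_rate(surface: RateSurface, region: StudyRegion, weighted: bool = True) -> float:
    """Aggregate a zone-level surface to one regional rate per 100,000.

    Population-weighted by default; zones with zero stratum population are
    excluded (their rates are undefined or carry no people).
    """
    pops = region.populations[surface.stratum].astype(float)
    mask = pops > 0
    if not mask.any():
        raise ValueError(f"stratum {surface.stratum}: zero total population")
    rates = surface.rate[mask]
    if weighted:
        w = pops[mask]
        return float(np.sum(w * rates) / w.sum())
    return float(rates.mean())


def crude_zone_mean(
    region: StudyRegion, cases: ReplicateCaseSet, stratum: str
) -> float:
    """Unweighted mean over zones of each zone's own crude rate per 100,000.

    Zones with zero stratum population are excluded.
    """
    pops = region.populations[stratum].astype(float)
    mask = pops > 0
    if not mask.any():
        raise ValueError(f"stratum {stratum}: no zone with positive population")
    c = np.asarray(cases.cases[stratum], dtype=float)[mask]
    return float(np.mean(PER_100K * c / pops[mask]))


def estimate_state_rates(
    region: StudyRegion,
    replicates: Sequence[ReplicateCaseSet],
    stratum: str,
    thresholds: Mapping[str, float],
    ordering: NeighborOrdering,
    weighted: bool = True,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Vectorised state rates for many replicates and thresholds at once.

    The kernel extent per zone depends only on populations, so it is computed
    once per threshold; enclosed case counts for all replicates then follow
    from a single inclusion-matrix product.  Returns (state rates keyed by
    threshold name, each an array over replicates; mean across-zone SD of the
    rate surface keyed by threshold name).
    """
    n = region.n_zones
    rows = np.arange(n)
    pops = region.populations[stratum].astype(float)
    mask = pops > 0
    w = pops[mask] / pops[mask].sum()
    C = np.stack([np.asarray(r.cases[stratum], dtype=np.float64) for r in replicates],
                 axis=1)  # (n, L)
    states: dict[str, np.ndarray] = {}
    zone_sds: dict[str, float] = {}
    for name, t in thresholds.items():
        if t <= 0:
            raise ConfigError(f"threshold {name} must be positive, got {t}")
        k, _ = _kernel_extent(ordering, stratum, t)
        # 0/1 inclusion matrix: row z marks the zones inside z's kernel
        incl = np.zeros((n, n))
        col_mask = np.arange(n)[None, :] <= k[:, None]
        incl[np.repeat(rows, k + 1), ordering.order[col_mask]] = 1.0
        enclosed_cases = incl @ C  # (n, L)
        enclosed_pop = ordering.cum_pop[stratum][rows, k]
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(
                enclosed_pop[:, None] > 0,
                PER_100K * enclosed_cases / enclosed_pop[:, None],
                np.nan,
            )
        rm = rates[mask]
        states[name] = (w @ rm) if weighted else rm.mean(axis=0)
        zone_sds[name] = float(np.nanstd(rates, axis=0, ddof=1).mean())
    return states, zone_sds


def surface_to_frame(surface: RateSurface) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate": surface.replicate,
            "stratum": surface.stratum,
            "threshold_name": surface.threshold_name,
            "zone_id": surface.zone_ids,
            "rate_per_100k": surface.rate,
            "radius": surface.radius,
            "enclosed_pop": surface.enclosed_pop,
            "enclosed_cases": surface.enclosed_cases,
            "underfilled": surface.underfilled,
        }
    )
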