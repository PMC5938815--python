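"""Univariate bandwidth selectors used as population-threshold proposals.

The smoothing parameter of the adaptive rate estimator is a minimum enclosed
population, i.e. a bandwidth on the population-size axis.  Candidate values
are therefore proposed by classical univariate selectors applied to the
per-zone population sample: the sample median, the normal-scale rule, the
two-stage direct plug-in, and smoothed cross-validation, all with the
Gaussian kernel.

All selectors are translation-invariant and scale-equivariant.  Pairwise-sum
functionals are evaluated in chunks so memory stays bounded at large n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ConfigError, DegenerateSampleError, ScvBoundaryWarning, SelectorNumericError
from .geography import StudyRegion

__all__ = [
    "ThresholdSet",
    "threshold_median",
    "threshold_normal_scale",
    "threshold_plug_in",
    "threshold_scv",
    "compute_threshold_set",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_RK_GAUSS = 1.0 / (2.0 * math.sqrt(math.pi))  # roughness R(K) of the Gaussian kernel

_PAIR_CHUNK = 256  # rows of the pairwise-difference matrix per block


def _as_sample(values: Iterable[float], min_n: int) -> np.ndarray:
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    return x


def threshold_median(pops: Iterable[float]) -> float:
    """Sample median (mean of the two middle order statistics for even n)."""
    x = _as_sample(pops, 1)
    return float(np.median(x))


def threshold_normal_scale(pops: Iterable[float]) -> float:
    """Normal-scale rule h_ns = (4 / (3 n))^(1/5) * sd, sample SD with n-1."""
    x = _as_sample(pops, 2)
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError("zero variance: normal-scale bandwidth undefined")
    return (4.0 / (3.0 * x.size)) ** 0.2 * sd


def _norm_deriv(u: np.ndarray, r: int) -> np.ndarray:
    """r-th derivative of the standard normal density (even r only here)."""
    if r == 4:
        he = u**4 - 6.0 * u**2 + 3.0
    elif r == 6:
        he = u**6 - 15.0 * u**4 + 45.0 * u**2 - 15.0
    else:  # pragma: no cover - only even orders 4 and 6 are used
        raise ValueError(f"unsupported derivative order {r}")
    return he * np.exp(-0.5 * u**2) / _SQRT_2PI


def _norm_deriv_at_zero(r: int) -> float:
    # phi^(r)(0) = (-1)^(r/2) r! / (2^(r/2) (r/2)! sqrt(2 pi))
    half = r // 2
    return ((-1) ** half) * math.factorial(r) / (
        2**half * math.factorial(half) * _SQRT_2PI
    )


def _psi_functional(x: np.ndarray, r: int, g: float) -> float:
    """psi_r(g) = n^-2 sum_i sum_j phi_g^(r)(x_i - x_j), diagonal included."""
    n = x.size
    total = 0.0
    # row-block sweep visits every ordered pair (incl. i == j) exactly once
    for start in range(0, n, _PAIR_CHUNK):
        block = x[start : start + _PAIR_CHUNK, None] - x[None, :]
        total += float(_norm_deriv(block / g, r).sum())
    return total / (g ** (r + 1) * n**2)


def _psi_normal_scale(r: int, sd: float) -> float:
    """psi_r under a normal reference: (-1)^(r/2) r! / ((2 sd)^(r+1) (r/2)! sqrt(pi))."""
    half = r // 2
    return ((-1) ** half) * math.factorial(r) / (
        (2.0 * sd) ** (r + 1) * math.factorial(half) * math.sqrt(math.pi)
    )


def threshold_plug_in(pops: Iterable[float]) -> float:
    """Two-stage direct plug-in bandwidth (Gaussian kernel).

    A normal-reference estimate of the 8th-derivative functional psi_8 seeds
    a kernel estimate of psi_6, which seeds psi_4; the final bandwidth is
    h = [R(K) / (psi_4 n)]^(1/5) with mu_2(K) = 1.
    """
    x = _as_sample(pops, 4)
    n = x.size
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError("zero variance: plug-in bandwidth undefined")

    psi8 = _psi_normal_scale(8, sd)
    g6 = (-2.0 * _norm_deriv_at_zero(6) / (psi8 * n)) ** (1.0 / 9.0)
    psi6 = _psi_functional(x, 6, g6)
    if not (np.isfinite(psi6) and psi6 < 0):
        raise SelectorNumericError(
            "plug-in stage psi_6 must be finite and negative",
            {"psi6": psi6, "g6": g6},
        )
    g4 = (-2.0 * _norm_deriv_at_zero(4) / (psi6 * n)) ** (1.0 / 7.0)
    psi4 = _psi_functional(x, 4, g4)
    if not (np.isfinite(psi4) and psi4 > 0):
        raise SelectorNumericError(
            "plug-in stage psi_4 must be finite and positive",
            {"psi4": psi4, "g4": g4},
        )
    return (_RK_GAUSS / (psi4 * n)) ** 0.2


def _pairwise_diffs(x: np.ndarray) -> np.ndarray:
    """Condensed |x_i - x_j| for i < j."""
    n = x.size
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    xs = np.sort(x)
    for i in range(n - 1):
        m = n - 1 - i
        out[pos : pos + m] = xs[i + 1 :] - xs[i]
        pos += m
    return out


def _gauss_sum(diffs: np.ndarray, n: int, s: float) -> float:
    """sum_i sum_j phi_s(x_i - x_j) over all ordered pairs incl. diagonal."""
    dens = np.exp(-0.5 * (diffs / s) ** 2).sum() / (s * _SQRT_2PI)
    return 2.0 * float(dens) + n / (s * _SQRT_2PI)


def threshold_scv(pops: Iterable[float], pilot: float | None = None) -> float:
    """Smoothed cross-validation bandwidth (Gaussian kernel).

    Minimises
    SCV(h) = R(K)/(n h) + n^-2 sum_ij [phi_s1 - 2 phi_s2 + phi_s3](x_i - x_j)
    with s1 = sqrt(2 h^2 + 2 g^2), s2 = sqrt(h^2 + 2 g^2), s3 = sqrt(2 g^2),
    pilot g defaulting to the normal-scale bandwidth, by bounded search on
    [h_ns / 20, 5 h_ns].  If no interior minimum exists in the bracket, the
    bracket endpoint is returned with a :class:`ScvBoundaryWarning`.
    """
    x = _as_sample(pops, 4)
    n = x.size
    h_ns = threshold_normal_scale(x)
    g = pilot if pilot is not None else h_ns
    if g <= 0:
        raise ConfigError("SCV pilot bandwidth must be positive")
    diffs = _pairwise_diffs(x)
    const = _gauss_sum(diffs, n, math.sqrt(2.0) * g) / n**2  # h-independent phi_s3 term

    def objective(h: float) -> float:
        s1 = math.sqrt(2.0 * h * h + 2.0 * g * g)
        s2 = math.sqrt(h * h + 2.0 * g * g)
        cross = (_gauss_sum(diffs, n, s1) - 2.0 * _gauss_sum(diffs, n, s2)) / n**2
        return _RK_GAUSS / (n * h) + cross + const

    lo, hi = h_ns / 20.0, 5.0 * h_ns
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4 * h_ns})
    h = float(res.x)
    span = hi - lo
    if h - lo < 1e-3 * span or hi - h < 1e-3 * span:
        h = lo if h - lo < hi - h else hi
        warnings.warn(
            f"SCV criterion has no interior minimum in [{lo:.4g}, {hi:.4g}]; "
            f"returning bracket endpoint {h:.4g}",
            ScvBoundaryWarning,
        )
    return h


@dataclass
class ThresholdSet:
    """Named candidate thresholds per stratum.

    Selector-derived names are ``h_ns``, ``h_pi``, ``h_scv`` and ``median``;
    shared arbitrary values are named ``arbitrary:<v>``.  ``sample_sizes``
    records how many (positive-population) zones each stratum's selectors saw.
    """

    per_stratum: dict[str, dict[str, float]]
    sample_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for lab, d in self.per_stratum.items():
            for name, v in d.items():
                if not v > 0:
                    raise ConfigError(f"{lab}/{name}: threshold must be positive, got {v}")

    def names(self, stratum: str) -> list[str]:
        return list(self.per_stratum[stratum])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab, d in self.per_stratum.items():
            for name, v in d.items():
                rows.append(
                    {
                        "stratum": lab,
                        "threshold_name": name,
                        "threshold": v,
                        "n_zones": self.sample_sizes.get(lab),
                    }
                )
        return pd.DataFrame(rows)


_SELECTORS = {
    "h_pi": threshold_plug_in,
    "h_scv": threshold_scv,
    "h_ns": threshold_normal_scale,
    "median": threshold_median,
}


def compute_threshold_set(
    region: StudyRegion, arbitrary: Sequence[float] = ()
) -> ThresholdSet:
    """Selector-derived thresholds per stratum plus the shared arbitrary values.

    Each stratum's selectors run on that stratum's per-zone population sample
    (zones with zero population excluded, each zone entering once).  Selectors
    that fail on a degenerate sample are skipped with a warning; the median is
    always available.
    """
    if any(v <= 0 for v in arbitrary):
        raise ConfigError("arbitrary thresholds must be positive")
    per_stratum: dict[str, dict[str, float]] = {}
    sizes: dict[str, int] = {}
    for st in region.strata:
        pops = region.populations[st.label]
        sample = pops[pops > 0].astype(float)
        sizes[st.label] = int(sample.size)
        entries: dict[str, float] = {}
        for name, fn in _SELECTORS.items():
            try:
                entries[name] = float(fn(sample))
            except DegenerateSampleError as exc:
                warnings.warn(f"{st.label}/{name}: {exc}")
        for v in arbitrary:
            entries[f"arbitrary:{v:g}"] = float(v)
        per_stratum[st.label] = entries
    return ThresholdSet(per_stratum=per_stratum, sample_sizes=sizes)
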