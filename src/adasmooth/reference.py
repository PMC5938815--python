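"""Published reference inputs used by the examples and the acceptance script.

Age-specific heart disease death rates for males in Texas, 2009-2013
(CDC NCHS compressed mortality data) and the matching 2010 U.S. Census
male population totals by 10-year age group.  These are public figures,
bundled as plain constants so the simulation study can be reproduced
without network access.
"""

from __future__ import annotations

from .geography import AgeStratum, StratumSpec

__all__ = [
    "TEXAS_MALE_STRATA",
    "DEFAULT_N_ZONES",
    "DEFAULT_ARBITRARY_THRESHOLDS",
    "texas_strata",
    "default_strata_specs",
]

# (label, death rate per 100,000, male population)
TEXAS_MALE_STRATA: tuple[tuple[str, float, int], ...] = (
    ("35-44", 33.87, 1_722_904),
    ("45-54", 115.15, 1_702_639),
    ("55-64", 297.36, 1_256_976),
    ("65+", 1245.93, 1_135_517),
)

# Texas has ~1900 ZCTAs with nonzero male population per age group.
DEFAULT_N_ZONES = 1900

DEFAULT_ARBITRARY_THRESHOLDS: tuple[float, ...] = (50, 100, 500, 1000, 5000, 10000)

# Zone-level census populations are strongly right-skewed; a gamma shape a
# little under 1 reproduces the many-small-zones / long-right-tail pattern
# (zone counts running from 1 up to several thousand).
_DEFAULT_GAMMA_SHAPE = 0.9


def texas_strata() -> list[AgeStratum]:
    return [AgeStratum(lab, rate, pop) for lab, rate, pop in TEXAS_MALE_STRATA]


def default_strata_specs(
    n_zones: int = DEFAULT_N_ZONES, gamma_shape: float = _DEFAULT_GAMMA_SHAPE
) -> list[StratumSpec]:
    """Stratum generation recipes matched to the published stratum totals.

    The gamma scale is set so the mean zone population equals
    total / n_zones; totals are enforced exactly by the generator.
    """
    specs = []
    for lab, rate, pop in TEXAS_MALE_STRATA:
        mean_zone_pop = pop / n_zones
        specs.append(
            StratumSpec(
                label=lab,
                true_rate_per_100k=rate,
                gamma_shape=gamma_shape,
                gamma_scale=mean_zone_pop / gamma_shape,
                total_population=pop,
            )
        )
    return specs
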