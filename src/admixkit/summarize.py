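"""Post-estimation summaries: regional averaging and calendar conversion.

Admixture dates for the populations of one geographic region are combined
by inverse-variance weighting (weights 1/SE^2), the minimum-variance
combination of independent estimates. Dates in generations convert to
years at 29 years per human generation.

``EXAMPLE_DATES`` bundles a published compilation of admixture-LD date
estimates (generations +/- jackknife SE, with matched-simulation bias
where available) for West Eurasian, Levantine and Jewish populations, as
a worked input for the regional-averaging utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DatedPopulation",
    "RegionalAverage",
    "inverse_variance_mean",
    "generations_to_years",
    "regional_averages",
    "EXAMPLE_DATES",
]

YEARS_PER_GENERATION = 29.0


@dataclass
class DatedPopulation:
    """One population's admixture date estimate."""

    population: str
    region: str
    date: float  # generations
    se: float
    bias: float | None = None  # simulation-calibrated bias, if available

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("standard error must be positive")

    @property
    def corrected_date(self) -> float | None:
        return None if self.bias is None else self.date - self.bias


@dataclass
class RegionalAverage:
    """Inverse-variance weighted mean date for a region."""

    region: str
    mean_date: float
    members: list

    @property
    def rounded(self) -> int:
        return int(round(self.mean_date))

    def summary(self) -> str:
        return (
            f"{self.region}: {self.rounded} generations "
            f"(~{generations_to_years(self.mean_date):.0f} years) "
            f"from {len(self.members)} populations"
        )


def inverse_variance_mean(members, use_corrected: bool = False) -> RegionalAverage:
    """Combine member dates with weights 1/SE^2.

    With ``use_corrected``, bias-corrected dates are used where a bias is
    available and uncorrected dates otherwise (the bias correction leaves
    the jackknife SE unchanged).
    """
    members = list(members)
    if not members:
        raise ValueError("no member populations to average")
    dates = np.array(
        [
            m.corrected_date
            if use_corrected and m.corrected_date is not None
            else m.date
            for m in members
        ],
        dtype=float,
    )
    weights = np.array([1.0 / m.se**2 for m in members])
    mean = float(np.sum(weights * dates) / weights.sum())
    regions = {m.region for m in members}
    region = regions.pop() if len(regions) == 1 else "/".join(sorted(regions))
    return RegionalAverage(region=region, mean_date=mean, members=members)


def generations_to_years(
    generations: float, years_per_generation: float = YEARS_PER_GENERATION
) -> float:
    """Convert a date in generations to years before present."""
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return generations * years_per_generation


# Published compilation of admixture-LD dates (generations +/- SE) with
# matched-simulation biases (NaN where the simulator could not accommodate
# the sample size). Regions: SE = Southern Europe, L = Levant,
# I = Northwest Europe, J = Jewish groups.
EXAMPLE_DATES = pd.DataFrame(
    [
        ("African Americans", "n/a", 6, 1, 0.0),
        ("Palestinian", "L", 34, 2, 1.0),
        ("Bedouin-g1", "L", 34, 3, 2.0),
        ("Bedouin-g2", "L", 33, 2, 2.0),
        ("Druze", "L", 54, 7, 10.0),
        ("Spain", "SE", 55, 3, 0.0),
        ("Portugal", "SE", 45, 5, 0.0),
        ("Sardinian", "SE", 96, 28, 25.0),
        ("Southern-Italy", "SE", 62, 6, 0.0),
        ("Northern-Italy", "SE", 154, 27, -26.0),
        ("Swiss-French", "I", 71, 6, np.nan),
        ("Ashkenazi Jews (IBD)", "J", 91, 11, np.nan),
        ("Ashkenazi Jews", "J", 76, 13, 23.0),
        ("Syrian Jews", "J", 99, 23, 27.0),
        ("Iranian Jews", "J", 129, 34, 59.0),
        ("Iraqi Jews", "J", 153, 22, 38.0),
        ("Sephardic Greek Jews", "J", 82, 8, 20.0),
        ("Sephardic Turkey Jews", "J", 89, 11, 16.0),
        ("Italian Jews", "J", 88, 19, 15.0),
    ],
    columns=["population", "region", "date", "se", "bias"],
)


def _members_from_frame(df: pd.DataFrame):
    return [
        DatedPopulation(
            population=r.population,
            region=r.region,
            date=float(r.date),
            se=float(r.se),
            bias=None if pd.isna(r.bias) else float(r.bias),
        )
        for r in df.itertuples(index=False)
    ]


def regional_averages(
    table: pd.DataFrame | None = None, use_corrected: bool = False
) -> dict:
    """Inverse-variance regional averages of a dates table.

    *table* needs columns population/region/date/se and optionally bias;
    defaults to :data:`EXAMPLE_DATES`. Returns
    ``{region: RegionalAverage}`` skipping the "n/a" region.
    """
    if table is None:
        table = EXAMPLE_DATES
    out = {}
    for region, sub in table.groupby("region", sort=False):
        if region == "n/a":
            continue
        out[region] = inverse_variance_mean(
            _members_from_frame(sub), use_corrected=use_corrected
        )
    return out
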