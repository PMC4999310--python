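"""Cross-species derived metrics from cohort summary statistics.

These are the headline ratio quantities of the pipeline: functional
release sites per active zone (mean N_frs over mean N_lm, since each
light-microscopic contact corresponds to one bouton with a single AZ),
AZ membrane area per Katz release site, docking-site occupancy (docked
vesicles per AZ over release sites per AZ), fold changes between cohorts,
and the rat-postnatal-day to human-year age map.

All ratios are computed from unrounded means; presentation rounding (one
decimal, or two significant figures for areas) is applied only in the
report layer.
"""

from __future__ import annotations

from synquant.types import CohortSummary, DerivedReport

__all__ = [
    "sites_per_az",
    "area_per_site",
    "docking_occupancy",
    "fold_change",
    "rat_to_human_age",
    "human_age_to_rat_day",
    "derived_report",
]

# age map anchors: sexual maturity at rat P38 ~ human 12 y; 3.3 rat days
# per human year around that point
_ANCHOR_RAT_DAY = 38.0
_ANCHOR_HUMAN_YEAR = 12.0
_RAT_DAYS_PER_HUMAN_YEAR = 3.3


def sites_per_az(mean_n_frs: float, mean_n_lm: float) -> float:
    """Functional release sites per AZ: mean N_frs / mean N_lm."""
    if mean_n_frs <= 0 or mean_n_lm <= 0:
        raise ValueError("means must be > 0")
    return mean_n_frs / mean_n_lm


def area_per_site(mean_az_area_um2: float, sites_per_az_value: float) -> float:
    """AZ membrane area occupied by one functional release site (um^2)."""
    if sites_per_az_value <= 0:
        raise ValueError("sites per AZ must be > 0")
    if mean_az_area_um2 < 0:
        raise ValueError("area must be >= 0")
    return mean_az_area_um2 / sites_per_az_value


def docking_occupancy(mean_docked_per_az: float,
                      sites_per_az_value: float) -> float:
    """Docked vesicles per AZ divided by release sites per AZ.

    An estimate ratio, not a probability: values above 1 are reported
    as-is (with a warning in the report layer), never clamped.
    """
    if sites_per_az_value <= 0:
        raise ValueError("sites per AZ must be > 0")
    if mean_docked_per_az <= 0:
        raise ValueError("docked count must be > 0")
    return mean_docked_per_az / sites_per_az_value


def fold_change(numerator_mean: float, denominator_mean: float) -> float:
    """Ratio of two cohort means (e.g. human N_frs over rat N_frs)."""
    if denominator_mean <= 0:
        raise ValueError("denominator must be > 0")
    return numerator_mean / denominator_mean


def rat_to_human_age(postnatal_day: float) -> float:
    """Human-equivalent age (years) of a rat of the given postnatal day.

    Linear map anchored at P38 ~ 12 years with 3.3 rat days per human year.
    """
    if postnatal_day <= 0:
        raise ValueError("postnatal day must be > 0")
    return _ANCHOR_HUMAN_YEAR + (postnatal_day - _ANCHOR_RAT_DAY) \
        / _RAT_DAYS_PER_HUMAN_YEAR


def human_age_to_rat_day(years: float) -> float:
    """Inverse of :func:`rat_to_human_age` (exact round trip)."""
    return _ANCHOR_RAT_DAY + (years - _ANCHOR_HUMAN_YEAR) \
        * _RAT_DAYS_PER_HUMAN_YEAR


def derived_report(summary: CohortSummary) -> DerivedReport:
    """Compute the full derived-metrics report for one cohort."""
    spa = sites_per_az(summary.mean_n_frs, summary.mean_n_lm)
    aps = area_per_site(summary.mean_az_area_um2, spa)
    occ = docking_occupancy(summary.mean_docked_per_az, spa)
    notes = []
    if occ > 1:
        notes.append(f"docking-site occupancy {occ:.2f} exceeds 1")
    return DerivedReport(
        species=summary.species,
        sites_per_az=spa,
        area_per_site_um2=aps,
        occupancy=occ,
        notes=notes,
    )
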