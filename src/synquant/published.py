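"""Reported cohort summary statistics for the worked example.

These are the published cohort means of the human and rat paired-recording
/ EM datasets that the derived metrics consume: mean number of functional
release sites per connection (N_frs, from MPFA), mean number of
light-microscopic synaptic contacts per connection (N_lm), mean AZ area
from serial-section reconstructions, and mean docked vesicles per AZ.
Raw recordings and micrographs are not deposited, so the per-pair fits are
not reproducible; these printed means are the inputs of the cross-species
derived quantities.
"""

from synquant.types import CohortSummary

__all__ = ["HUMAN", "RAT", "RAT_FAILURE_EXAMPLE"]

HUMAN = CohortSummary(
    species="human",
    mean_n_frs=20.5,
    mean_n_lm=3.3,
    mean_az_area_um2=0.077,
    mean_docked_per_az=4.2,
)

RAT = CohortSummary(
    species="rat",
    mean_n_frs=4.7,
    mean_n_lm=2.9,
    mean_az_area_um2=0.041,
    mean_docked_per_az=1.3,
)

#: Rat cohort at 1.5 mM [Ca2+]o: mean fitted P_r and the observed failure
#: fraction, used to exercise the failure-rate consistency check.
RAT_FAILURE_EXAMPLE = {
    "p_r": 0.17,
    "observed_failure_fraction": 0.391,
    "n_trials": 75,
}
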