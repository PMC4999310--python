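"""Domain containers shared across the pipeline.

Charges are stored as positive magnitudes in femtocoulombs (EPSCs are
inward currents at -70 mV; the sign only exists at the trace level, where
current is in pA and negative deflections are events).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class QuantalParameters:
    """Ground-truth generative parameters of one synaptic connection.

    Parameters
    ----------
    n_sites
        Number of release sites N (each releases at most one vesicle per
        trial).
    q_fc
        Quantal charge q in fC: the postsynaptic charge produced by one
        released vesicle.
    cv_intra
        Intra-site quantal coefficient of variation: trial-to-trial
        multiplicative variability of the quantum at one site.
    cv_inter
        Inter-site quantal CV: dispersion of the fixed per-site quanta
        around q (drawn once per experiment).
    noise_sd_fc
        SD of additive Gaussian baseline charge noise, fC.
    drift_per_epoch
        Fractional linear multiplicative drift of q across one epoch
        (quantum scaled by 1 + drift at the last trial).
    """

    n_sites: int
    q_fc: float
    cv_intra: float = 0.0
    cv_inter: float = 0.0
    noise_sd_fc: float = 0.0
    drift_per_epoch: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.q_fc <= 0:
            raise ValueError(f"q_fc must be > 0, got {self.q_fc}")
        for name in ("cv_intra", "cv_inter", "noise_sd_fc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Condition:
    """One release-probability condition (set by extracellular Ca2+/Mg2+)."""

    label: str
    ca_mM: float
    p_r: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_r <= 1.0:
            raise ValueError(f"p_r must be in [0, 1], got {self.p_r}")
        if self.ca_mM <= 0:
            raise ValueError(f"ca_mM must be > 0, got {self.ca_mM}")


@dataclass
class Epoch:
    """Ordered per-trial EPSC charges recorded under one condition."""

    condition: Condition
    charges_fc: np.ndarray
    trial_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.charges_fc = np.asarray(self.charges_fc, dtype=float)
        self.trial_times_s = np.asarray(self.trial_times_s, dtype=float)
        if self.charges_fc.shape != self.trial_times_s.shape:
            raise ValueError("charges and trial_times must have equal length")
        if self.n > 1 and not np.all(np.diff(self.trial_times_s) > 0):
            raise ValueError("trial_times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.charges_fc)


@dataclass
class Experiment:
    """A multi-condition recording from one connection (3-5 epochs)."""

    epochs: list[Epoch]
    params_true: QuantalParameters | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = [e.condition.label for e in self.epochs]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


@dataclass
class EPSCTrace:
    """A sampled current trace with a presynaptic stimulus reference."""

    time_ms: np.ndarray
    current_pa: np.ndarray
    stimulus_time_ms: float
    sampling_khz: float

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.time_ms.shape != self.current_pa.shape:
            raise ValueError("time and current must have equal length")
        if not (self.time_ms[0] <= self.stimulus_time_ms <= self.time_ms[-1]):
            raise ValueError("stimulus_time must lie within the trace")


@dataclass
class EPSCEvent:
    """A detected evoked EPSC (or a failure) with kinetic measurements.

    Kinetic fields are None until :func:`synquant.detection.measure_kinetics`
    completes them; failure events never carry kinetics. ``decay_37_ms`` is
    None with ``decay_censored`` set when the trace ends before the current
    relaxes to 37% of peak.
    """

    is_failure: bool
    onset_ms: float | None = None
    peak_ms: float | None = None
    amplitude_pa: float | None = None
    latency_ms: float | None = None
    rise_10_90_ms: float | None = None
    decay_37_ms: float | None = None
    charge_fc: float | None = None
    decay_censored: bool = False


@dataclass
class VarianceMeanPoint:
    """One epoch reduced to the unit of MPFA fitting."""

    mean_fc: float
    pairwise_variance_fc2: float
    n_trials: int
    weight: float
    condition_label: str = ""
    degenerate: bool = False


@dataclass
class MPFAFit:
    """Result of the weighted variance-mean parabola fit sigma^2 = A*m - B*m^2.

    q = A and N_frs = 1/B (when the fitted curvature B is positive);
    per-condition release probability P_r = mean / (N_frs * q), clipped to
    [0, 1] with a warning recorded when clipping occurs. ``n_frs`` is a real
    estimator, never rounded; it is None when the fit shows no curvature.
    """

    q_fc: float
    n_frs: float | None
    coeff_a: float
    coeff_b: float
    p_r_by_condition: dict[str, float]
    se_a: float | None = None
    se_b: float | None = None
    converged: bool = True
    n_iterations: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Vesicle:
    """A synaptic vesicle with its membrane-gap distance and pool label."""

    vesicle_id: int
    distance_nm: float
    label: str = ""


@dataclass
class ActiveZone:
    """An active zone: membrane area plus its classified vesicles."""

    az_id: str
    area_um2: float
    vesicles: list[Vesicle] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError(f"area_um2 must be > 0, got {self.area_um2}")


@dataclass(frozen=True)
class BoutonProfile:
    """Single-section bouton geometry used for spherical volume estimates."""

    largest_cross_section_um2: float
    measured_volume_um3: float | None = None

    def __post_init__(self) -> None:
        if self.largest_cross_section_um2 < 0:
            raise ValueError("cross-section area must be >= 0")


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level means needed for the cross-species derived metrics."""

    species: str
    mean_n_frs: float
    mean_n_lm: float
    mean_az_area_um2: float
    mean_docked_per_az: float

    def __post_init__(self) -> None:
        for name in ("mean_n_frs", "mean_n_lm", "mean_az_area_um2",
                     "mean_docked_per_az"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class DerivedReport:
    """Headline derived quantities for one cohort."""

    species: str
    sites_per_az: float
    area_per_site_um2: float
    occupancy: float
    notes: list[str] = field(default_factory=list)
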