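"""Generative twin of the binomial quantal-release experiment.

The simulator reproduces the statistical structure that MPFA assumes:
N independent release sites, each releasing a quantum q with probability
P_r per trial, with intra-site (per-release, multiplicative) and inter-site
(fixed per-site) quantal variability, additive baseline charge noise, and
an optional slow multiplicative drift across the epoch. It also renders
single-trial current traces (an alpha-function waveform surrogate, since
only kinetic summaries constrain the shape) and synthetic active zones for
the ultrastructure stage.

Seeding: one master seed per experiment; per-epoch streams are spawned with
``numpy.random.SeedSequence`` so each epoch is independently reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from synquant.types import (
    ActiveZone,
    Condition,
    Epoch,
    EPSCTrace,
    Experiment,
    QuantalParameters,
    Vesicle,
)

__all__ = [
    "simulate_trial_charges",
    "theoretical_moments",
    "make_experiment",
    "render_trace",
    "generate_active_zone",
]

#: Vesicles at most this far (nm) from the presynaptic membrane count as
#: docked ("direct contact", with a small allowance for measurement
#: quantization).
CONTACT_TOLERANCE_NM = 0.5
PREDOCKED_MAX_NM = 5.0
POOL_MAX_NM = 100.0
FAR_MAX_NM = 300.0


def _draw_site_quanta(params: QuantalParameters, rng: np.random.Generator) -> np.ndarray:
    """Fixed per-site quanta, drawn once per experiment around q."""
    if params.cv_inter == 0.0:
        return np.full(params.n_sites, params.q_fc)
    quanta = rng.normal(params.q_fc, params.cv_inter * params.q_fc,
                        size=params.n_sites)
    return np.clip(quanta, 0.0, None)


def simulate_trial_charges(
    params: QuantalParameters,
    p_r: float,
    n_trials: int,
    seed: int | np.random.SeedSequence,
    site_quanta: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate per-trial EPSC charges from N independent binomial sites.

    Each trial charge is the sum over sites of Bernoulli(p_r) x site
    quantum, where the site quantum carries inter-site variability (fixed
    for the experiment) and intra-site variability (redrawn per release),
    plus additive Gaussian baseline noise. An optional linear multiplicative
    drift scales the quantum from 1 at the first trial to
    ``1 + drift_per_epoch`` at the last.

    Parameters
    ----------
    params
        Generative parameters of the connection.
    p_r
        Per-site release probability for this condition.
    n_trials
        Number of trials; 0 returns an empty array.
    seed
        Seed or SeedSequence for this epoch's random stream.
    site_quanta
        Per-site quanta drawn once at the experiment level; when None they
        are drawn here from ``seed`` (cv_inter = 0 makes them all equal q).

    Returns
    -------
    numpy.ndarray
        Positive charge magnitudes in fC, one per trial.
    """
    if not 0.0 <= p_r <= 1.0:
        raise ValueError(f"p_r must be in [0, 1], got {p_r}")
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if n_trials == 0:
        return np.empty(0)

    rng = np.random.default_rng(seed)
    if site_quanta is None:
        site_quanta = _draw_site_quanta(params, rng)
    else:
        site_quanta = np.asarray(site_quanta, dtype=float)
        if site_quanta.shape != (params.n_sites,):
            raise ValueError("site_quanta must have one entry per site")

    released = rng.random((n_trials, params.n_sites)) < p_r
    quanta = np.broadcast_to(site_quanta, (n_trials, params.n_sites))
    if params.cv_intra > 0:
        jitter = rng.normal(1.0, params.cv_intra,
                            size=(n_trials, params.n_sites))
        quanta = quanta * np.clip(jitter, 0.0, None)
    charges = np.sum(released * quanta, axis=1)

    if params.drift_per_epoch != 0.0 and n_trials > 1:
        idx = np.arange(n_trials) / (n_trials - 1)
        charges = charges * (1.0 + params.drift_per_epoch * idx)
    if params.noise_sd_fc > 0:
        charges = charges + rng.normal(0.0, params.noise_sd_fc, size=n_trials)
    return charges


def theoretical_moments(
    params: QuantalParameters, p_r: float
) -> tuple[float, float, float]:
    """Closed-form mean, variance and failure probability of a trial charge.

    For the cv_inter = 0 case:

    - mean = N * p * q
    - variance = N*p*(1-p)*q^2 + N*p*q^2*cv_intra^2 + noise_sd^2
    - failure = (1 - p)^N

    Inter-site quantal dispersion is a simulator-only feature and is not
    folded into these moments; the failure probability refers to the
    no-release event and ignores additive recording noise.
    """
    if not 0.0 <= p_r <= 1.0:
        raise ValueError(f"p_r must be in [0, 1], got {p_r}")
    n, q = params.n_sites, params.q_fc
    mean = n * p_r * q
    variance = (
        n * p_r * (1 - p_r) * q**2
        + n * p_r * q**2 * params.cv_intra**2
        + params.noise_sd_fc**2
    )
    failure = (1 - p_r) ** n
    return mean, variance, failure


def make_experiment(
    params: QuantalParameters,
    conditions: list[Condition],
    n_trials_per_epoch: int,
    seed: int,
    inter_trial_s: float = 5.0,
) -> Experiment:
    """Simulate a full multi-condition experiment (one epoch per condition).

    Requires 3-5 conditions with P_r non-decreasing in [Ca2+]o, mirroring
    MPFA eligibility. Trials are spaced ``inter_trial_s`` apart (stimuli at
    5 s intervals by default).
    """
    if not 3 <= len(conditions) <= 5:
        raise ValueError(
            "MPFA requires 3 to 5 conditions, got "
            f"{len(conditions)}"
        )
    ordered = sorted(conditions, key=lambda c: c.ca_mM)
    p_rs = [c.p_r for c in ordered]
    if any(b < a for a, b in zip(p_rs, p_rs[1:])):
        raise ValueError("p_r must be non-decreasing in ca_mM")

    master = np.random.SeedSequence(seed)
    quanta_ss, *epoch_ss = master.spawn(1 + len(conditions))
    site_quanta = _draw_site_quanta(params, np.random.default_rng(quanta_ss))

    times = np.arange(n_trials_per_epoch) * inter_trial_s
    epochs = []
    for cond, ss in zip(conditions, epoch_ss):
        charges = simulate_trial_charges(
            params, cond.p_r, n_trials_per_epoch, ss, site_quanta=site_quanta
        )
        epochs.append(Epoch(condition=cond, charges_fc=charges,
                            trial_times_s=times.copy()))
    return Experiment(epochs=epochs, params_true=params, seed=seed)


def render_trace(
    charge_fc: float,
    onset_latency_ms: float = 1.0,
    tau_ms: float = 0.5,
    sampling_khz: float = 50.0,
    noise_sd_pa: float = 0.0,
    seed: int | None = None,
    stimulus_time_ms: float = 5.0,
    duration_ms: float = 60.0,
) -> EPSCTrace:
    """Render a single-trial current trace carrying the requested charge.

    The waveform is a negative-going alpha function starting at
    ``stimulus_time + onset_latency``::

        I(t') = -A * (t'/tau) * exp(1 - t'/tau),   A = charge / (tau * e)

    so the peak amplitude is A (at t' = tau) and the integral of \\|I\\|
    over an infinite window equals ``charge_fc`` (1 pA*ms = 1 fC).
    Independent Gaussian sample noise of SD ``noise_sd_pa`` is added.
    """
    if tau_ms <= 0:
        raise ValueError(f"tau_ms must be > 0, got {tau_ms}")
    if sampling_khz < 10:
        raise ValueError("sampling rate must be >= 10 kHz")
    n = int(round(duration_ms * sampling_khz)) + 1
    t = np.arange(n) / sampling_khz
    t_rel = t - (stimulus_time_ms + onset_latency_ms)
    amp = charge_fc / (tau_ms * math.e)
    current = np.zeros(n)
    rising = t_rel > 0
    x = t_rel[rising] / tau_ms
    current[rising] = -amp * x * np.exp(1.0 - x)
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd_pa, size=n)
    return EPSCTrace(time_ms=t, current_pa=current,
                     stimulus_time_ms=stimulus_time_ms,
                     sampling_khz=sampling_khz)


def generate_active_zone(
    area_um2: float,
    n_docked: int,
    n_predocked: int,
    n_pool: int,
    n_far: int,
    seed: int | None = None,
    az_id: str = "az0",
) -> ActiveZone:
    """Generate a synthetic active zone with vesicles in each distance class.

    Distances (vesicle outer leaflet to presynaptic inner leaflet, nm) are
    drawn uniformly from the class-defining ranges: docked in contact
    ([0, 0.5]), pre-docked in (0.5, 5], pool in (5, 100], far in (100, 300],
    so downstream classification recovers the requested counts exactly.
    """
    counts = (n_docked, n_predocked, n_pool, n_far)
    if any(c < 0 for c in counts):
        raise ValueError("vesicle counts must be >= 0")
    rng = np.random.default_rng(seed)
    bounds = [
        (0.0, CONTACT_TOLERANCE_NM),
        (CONTACT_TOLERANCE_NM, PREDOCKED_MAX_NM),
        (PREDOCKED_MAX_NM, POOL_MAX_NM),
        (POOL_MAX_NM, FAR_MAX_NM),
    ]
    vesicles: list[Vesicle] = []
    vid = 0
    for count, (lo, hi) in zip(counts, bounds):
        for _ in range(count):
            # open at the lower bound: classes are closed on the upper end
            d = lo + (hi - lo) * (1.0 - rng.random()) if lo > 0 else hi * rng.random()
            vesicles.append(Vesicle(vesicle_id=vid, distance_nm=d))
            vid += 1
    return ActiveZone(az_id=az_id, area_um2=area_um2, vesicles=vesicles)
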