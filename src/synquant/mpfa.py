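"""Multiple-probability fluctuation analysis (MPFA).

Under a binomial release model with N independent sites of quantal size q
and per-condition release probability P_r, the mean and variance of the
response charge obey

    mean     m = N * P_r * q
    variance v = q*m - m^2 / N  =  A*m - B*m^2,   A = q,  B = 1/N

so a weighted parabola through the origin fitted to per-epoch
(mean, variance) points yields q = A, N_frs = 1/B and P_r = m / (N_frs*q)
per condition. Variances are computed with the pairwise (consecutive
difference) estimator, which cancels slow drift; points are weighted by
the inverse theoretical variance of the variance estimate.
"""

from __future__ import annotations

import math
import warnings as _warnings

import numpy as np

from synquant.detection import epoch_stability
from synquant.types import Experiment, MPFAFit, VarianceMeanPoint

__all__ = [
    "pairwise_variance",
    "variance_of_variance",
    "variance_mean_points",
    "fit_parabola",
    "predicted_failure_rate",
    "failure_consistency",
]


def pairwise_variance(x: np.ndarray) -> float:
    """Variance from squared consecutive differences (drift-robust).

    For acquisition-ordered samples x_1..x_n,

        s^2 = sum_{i=1}^{n-1} (x_{i+1} - x_i)^2 / (2*(n-1))

    which is unbiased for iid data and insensitive to slow trends: a pure
    linear ramp of step b contributes exactly b^2/2 regardless of n,
    whereas the ordinary sample variance of the same ramp grows as n^2.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("pairwise variance needs >= 2 ordered samples")
    d = np.diff(x)
    return float(np.sum(d * d) / (2.0 * (len(x) - 1)))


def variance_of_variance(variance: float, n: int) -> float:
    """Gaussian-approximation variance of a sample-variance estimate.

    Var(s^2) = 2 * variance^2 / (n - 1); used as the (inverse) weight of a
    variance-mean point.
    """
    if n < 2:
        raise ValueError("need n >= 2 trials")
    return 2.0 * variance**2 / (n - 1)


def variance_mean_points(
    experiment: Experiment,
    require_stability: bool = True,
    min_conditions: int = 3,
) -> list[VarianceMeanPoint]:
    """Reduce each epoch to a (mean, pairwise variance, n, weight) point.

    Epochs failing the drift-stability screen are dropped (or kept with a
    logged warning when ``require_stability`` is False). Fewer than
    ``min_conditions`` eligible epochs is an error, mirroring MPFA
    eligibility.
    """
    points = []
    for epoch in experiment.epochs:
        slope, stable = epoch_stability(epoch.charges_fc, epoch.trial_times_s)
        if not stable:
            if require_stability:
                _warnings.warn(
                    f"epoch '{epoch.condition.label}' dropped: "
                    f"normalized drift slope {slope:.3f} >= 0.05",
                    stacklevel=2,
                )
                continue
            _warnings.warn(
                f"epoch '{epoch.condition.label}' kept despite drift slope "
                f"{slope:.3f} (stability override)",
                stacklevel=2,
            )
        var = pairwise_variance(epoch.charges_fc)
        vov = variance_of_variance(var, epoch.n)
        degenerate = var == 0.0
        weight = math.inf if degenerate else 1.0 / vov
        points.append(VarianceMeanPoint(
            mean_fc=float(np.mean(epoch.charges_fc)),
            pairwise_variance_fc2=var,
            n_trials=epoch.n,
            weight=weight,
            condition_label=epoch.condition.label,
            degenerate=degenerate,
        ))
    if len(points) < min_conditions:
        raise ValueError(
            f"MPFA requires >= {min_conditions} conditions; "
            f"{len(points)} eligible epochs"
        )
    return points


def _wls(means: np.ndarray, variances: np.ndarray, w: np.ndarray,
         intercept: bool = False):
    """Weighted LSQ of v = [c +] A*m - B*m^2; returns A, B, SEs."""
    cols = [means, -means**2]
    if intercept:
        cols.insert(0, np.ones_like(means))
    X = np.column_stack(cols)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], variances * sw, rcond=None)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    if intercept:
        coef, se = coef[1:], se[1:]
    return float(coef[0]), float(coef[1]), float(se[0]), float(se[1])


def fit_parabola(
    points: list[VarianceMeanPoint],
    reweight: bool = True,
    max_iterations: int = 20,
    rtol: float = 1e-6,
    intercept: bool = False,
) -> MPFAFit:
    """Weighted variance-mean parabola fit; extract q, N_frs and P_r.

    Fits sigma^2 = A*m - B*m^2 through the origin by weighted least squares
    (``intercept`` adds a fitted constant for unsubtracted baseline-noise
    variance).
    With ``reweight`` the point weights are iteratively refreshed from the
    fitted parabola's predicted variances (weight = (n-1) / (2*v_pred^2))
    until the relative parameter change falls below ``rtol`` or
    ``max_iterations`` is reached — this removes the dependence of the
    weights on the noisy per-epoch variance estimates.

    When the fitted curvature B is not positive the data carry no
    information on N (release probabilities too low); the fit is returned
    with q from the initial slope, ``n_frs`` None and a warning.
    """
    if len(points) < 3:
        raise ValueError("parabola fit requires >= 3 variance-mean points")
    means = np.array([p.mean_fc for p in points])
    if len(np.unique(means)) != len(means):
        raise ValueError("duplicate condition means; weights are ill-defined")
    variances = np.array([p.pairwise_variance_fc2 for p in points])
    ns = np.array([p.n_trials for p in points])
    warn: list[str] = []

    w = np.array([p.weight for p in points])
    if np.any(~np.isfinite(w)):
        finite = w[np.isfinite(w)]
        fill = finite.max() if len(finite) else 1.0
        w = np.where(np.isfinite(w), w, fill)
        warn.append("degenerate zero-variance points; weights capped")

    a, b, se_a, se_b = _wls(means, variances, w, intercept)
    n_iter = 0
    converged = True
    if reweight:
        converged = False
        for n_iter in range(1, max_iterations + 1):
            v_pred = np.clip(a * means - b * means**2, 1e-12, None)
            w = (ns - 1) / (2.0 * v_pred**2)
            a_new, b_new, se_a, se_b = _wls(means, variances, w, intercept)
            delta = max(
                abs(a_new - a) / max(abs(a), 1e-12),
                abs(b_new - b) / max(abs(b), 1e-12),
            )
            a, b = a_new, b_new
            if delta < rtol:
                converged = True
                break

    if b <= 0:
        warn.append(
            "no curvature: release probabilities too low to constrain N"
        )
        return MPFAFit(
            q_fc=a, n_frs=None, coeff_a=a, coeff_b=b,
            p_r_by_condition={}, se_a=se_a, se_b=se_b,
            converged=False, n_iterations=n_iter, warnings=warn,
        )

    q = a
    n_frs = 1.0 / b
    p_r = {}
    for i, p in enumerate(points):
        label = p.condition_label or f"point{i}"
        val = p.mean_fc / (n_frs * q)
        if not 0.0 <= val <= 1.0:
            warn.append(f"P_r for '{label}' clipped from {val:.3f}")
            val = min(max(val, 0.0), 1.0)
        p_r[label] = val
    return MPFAFit(
        q_fc=q, n_frs=n_frs, coeff_a=a, coeff_b=b,
        p_r_by_condition=p_r, se_a=se_a, se_b=se_b,
        converged=converged, n_iterations=n_iter, warnings=warn,
    )


def predicted_failure_rate(n_frs: float, p_r: float) -> float:
    """Failure probability (1 - P_r)^N under the binomial model.

    Real (non-integer) ``n_frs`` is permitted: it is an estimator, not a
    count.
    """
    if n_frs <= 0:
        raise ValueError("n_frs must be > 0")
    if not 0.0 <= p_r <= 1.0:
        raise ValueError("p_r must be in [0, 1]")
    return float((1.0 - p_r) ** n_frs)


def failure_consistency(
    fit: MPFAFit,
    observed_failure_fraction_by_condition: dict[str, float],
    n_trials_by_condition: dict[str, int],
    flag_se: float = 3.0,
) -> list[dict]:
    """Compare observed failure fractions with the binomial prediction.

    For each condition the predicted failure rate (1 - P_r)^N_frs is
    compared with the observed fraction using the binomial standard error
    sqrt(f*(1-f)/n) of the prediction; conditions deviating by more than
    ``flag_se`` SEs are flagged. A predicted rate of exactly 0 (P_r = 1)
    with any observed failures is always flagged.
    """
    if fit.n_frs is None:
        raise ValueError("fit did not converge; no N_frs available")
    rows = []
    for label, observed in observed_failure_fraction_by_condition.items():
        if label not in fit.p_r_by_condition:
            raise KeyError(f"condition '{label}' not in fit")
        n = n_trials_by_condition[label]
        predicted = predicted_failure_rate(fit.n_frs,
                                           fit.p_r_by_condition[label])
        se = math.sqrt(predicted * (1 - predicted) / n)
        deviation = abs(observed - predicted)
        if se > 0:
            flagged = deviation > flag_se * se
            n_se = deviation / se
        else:
            flagged = deviation > 0
            n_se = math.inf if deviation > 0 else 0.0
        rows.append({
            "condition": label,
            "predicted": predicted,
            "observed": observed,
            "se": se,
            "n_se": n_se,
            "flagged": flagged,
        })
    return rows
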