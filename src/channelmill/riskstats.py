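"""Safety/efficacy risk model and summary statistics.

The risk model converts a per-patient probability of violating the safety
margin into a per-measurement-point probability via the binomial model: the
~60 mm channel yields n independent measurement points (one per tool
diameter, 1.2 mm), and a per-patient risk r satisfies 1 - (1 - p)^n = r for
the per-point risk p.  Under a zero-mean Gaussian execution-error model the
admissible RMSE for a margin m is m / z(p), with z the one-sided upper
standard-normal quantile: a violation is a signed exceedance beyond the
margin toward the protected structure.  Defaults: margin 1.0 mm, per-patient
risk 0.01% for the safety endpoints (lateral/depth displacement) and 1% for
the efficacy endpoints (width/depth error), reconstruction (segmentation)
error 50 +/- 50 um, test alpha 0.1% and power 95%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RiskModel",
    "n_independent_points",
    "per_point_risk",
    "rmse_limit",
    "min_margin",
    "summarize",
    "specimens_required",
    "simulate_patient_risk",
]


@dataclass
class RiskModel:
    margin: float = 1.0                   # mm
    per_patient_risk_safety: float = 1e-4
    per_patient_risk_efficacy: float = 1e-2
    channel_length: float = 60.0          # mm
    independence_spacing: float = 1.2     # mm, one tool diameter
    segmentation_error_mean: float = 0.05  # mm
    segmentation_error_sd: float = 0.05    # mm
    alpha: float = 0.001
    power: float = 0.95

    def __post_init__(self) -> None:
        for p in (self.per_patient_risk_safety, self.per_patient_risk_efficacy):
            if not 0.0 < p < 1.0:
                raise ValueError("per-patient risks must be in (0, 1)")
        if self.margin <= 0 or self.independence_spacing <= 0:
            raise ValueError("margin and spacing must be positive")

    @property
    def n_points(self) -> int:
        return n_independent_points(self.channel_length, self.independence_spacing)

    def per_point(self, per_patient: float) -> float:
        return per_point_risk(per_patient, self.n_points)

    def rmse_limit_safety(self) -> float:
        return rmse_limit(self.margin, self.per_point(self.per_patient_risk_safety))

    def rmse_limit_efficacy(self) -> float:
        return rmse_limit(self.margin, self.per_point(self.per_patient_risk_efficacy))

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(**d)


def n_independent_points(channel_length: float, spacing: float = 1.2) -> int:
    """Independent measurement points along the channel (round-half-up)."""
    if channel_length <= 0 or spacing <= 0:
        raise ValueError("length and spacing must be positive")
    return int(np.floor(channel_length / spacing + 0.5))


def per_point_risk(per_patient: float, n: int) -> float:
    """Per-point violation probability p with 1 - (1 - p)^n = per_patient."""
    if not 0.0 < per_patient < 1.0:
        raise ValueError("per-patient risk must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(-np.expm1(np.log1p(-per_patient) / n))


def rmse_limit(margin: float, p_point: float) -> float:
    """Admissible RMSE for a margin under the zero-mean Gaussian model.

    One-sided: the per-point event is an exceedance beyond the margin in the
    direction of the protected structure, P(e > margin) = p_point.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if not 0.0 < p_point < 0.5:
        raise ValueError("per-point probability must be in (0, 0.5)")
    return float(margin / stats.norm.isf(p_point))


def min_margin(rmse: float, p_point: float, segmentation: tuple | None = None) -> float:
    """Smallest margin keeping the per-point exceedance below p_point.

    With ``segmentation=(mean, sd)`` the reconstruction error is folded in
    as an independent additive error: its mean shifts the bias budget and
    its SD convolves into the Gaussian width.
    """
    if rmse < 0:
        raise ValueError("rmse must be >= 0")
    z = float(stats.norm.isf(p_point))
    if segmentation is None:
        return z * rmse
    mean, sd = segmentation
    return z * float(np.hypot(rmse, sd)) + float(mean)


def summarize(
    values: np.ndarray,
    spacing: float,
    independence_spacing: float = 1.2,
    ci_level: float = 0.999,
) -> dict:
    """Mean, SD, RMSE with CI, min and max of a measurement series.

    Adjacent samples (every ``spacing`` mm) are correlated over roughly one
    tool diameter; the RMSE confidence interval therefore uses a chi-square
    interval on the sum of squares with the effective sample size
    measured length / ``independence_spacing``.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError("need at least 2 non-missing values")
    rmse = float(np.sqrt(np.mean(values**2)))
    length = len(values) * spacing
    n_eff = max(2.0, length / independence_spacing)
    alpha = 1.0 - ci_level
    lo = rmse * float(np.sqrt(n_eff / stats.chi2.ppf(1 - alpha / 2, n_eff)))
    hi = rmse * float(np.sqrt(n_eff / stats.chi2.ppf(alpha / 2, n_eff)))
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)),
        "rmse": rmse,
        "rmse_ci": [lo, hi],
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "n_effective": n_eff,
    }


def specimens_required(
    sigma_alt: float,
    sigma_null: float,
    alpha: float = 0.001,
    power: float = 0.95,
    points_per_specimen: int = 50,
    max_specimens: int = 1000,
) -> int:
    """Specimens needed for the one-sample variance test to show the
    execution error is below the admissible limit.

    H0: sigma = sigma_null (the admissible RMSE limit) against
    H1: sigma = sigma_alt < sigma_null; the test rejects when the pooled
    (n-1) s^2 / sigma_null^2 statistic falls below the lower-alpha
    chi-square quantile.  Returns the smallest specimen count whose pooled
    measurement count reaches the requested power.
    """
    if not 0 <= sigma_alt < sigma_null:
        raise ValueError("need 0 <= sigma_alt < sigma_null")
    if sigma_alt == 0:
        return 1
    ratio = (sigma_null / sigma_alt) ** 2
    for k in range(1, max_specimens + 1):
        n = k * points_per_specimen
        crit = stats.chi2.ppf(alpha, n - 1)
        achieved = stats.chi2.cdf(crit * ratio, n - 1)
        if achieved >= power:
            return k
    raise RuntimeError("no specimen count up to the cap reaches the power")


def simulate_patient_risk(
    per_patient: float,
    n_points: int = 50,
    margin: float = 1.0,
    n_channels: int = 100_000,
    seed: int = 0,
) -> dict:
    """End-to-end Monte-Carlo validation of the risk chain.

    Simulates channels of ``n_points`` independent Gaussian errors at
    sigma = rmse_limit(margin, per_point_risk) and counts channels with at
    least one exceedance beyond the margin (the one-sided event of the
    model).  Returns the empirical rate, its Monte-Carlo standard error and
    the configured rate.
    """
    p_point = per_point_risk(per_patient, n_points)
    sigma = rmse_limit(margin, p_point)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_channels, int(5e7 // max(n_points, 1))))
    done = 0
    while done < n_channels:
        m = min(chunk, n_channels - done)
        e = rng.normal(0.0, sigma, size=(m, n_points))
        count += int(np.count_nonzero((e > margin).any(axis=1)))
        done += m
    rate = count / n_channels
    se = float(np.sqrt(per_patient * (1 - per_patient) / n_channels))
    return {
        "rate": float(rate),
        "expected": float(per_patient),
        "mc_se": se,
        "sigma": float(sigma),
        "n_channels": n_channels,
    }
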