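"""Targeting-accuracy statistics for automated acquisition at predicted
coordinates.

When high-magnification EM images are acquired blindly at FM-predicted
positions, the deviation of the true feature from the image centre behaves,
to good approximation, as a centred bivariate normal with independent
per-axis standard deviations (sigma_x, sigma_y).  The probability that the
feature lands inside a square field of view of side ``fov`` is then

    P(hit) = [2 Phi(fov / (2 sigma_x)) - 1] * [2 Phi(fov / (2 sigma_y)) - 1]

with Phi the standard normal CDF.  This closed form links a measured
deviation distribution to an expected hit rate, and inversely gives the
smallest FOV that still achieves a desired hit rate — the knob that trades
acquisition magnification against targeting reliability.  A Poisson-scatter
null model gives the probability of catching *some* object by pure chance,
the baseline a targeted hit rate must beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DeviationStats",
    "AcquisitionGeometry",
    "hit_probability",
    "min_fov_for_rate",
    "estimate_deviation_stats",
    "random_hit_probability",
]


@dataclass(frozen=True)
class DeviationStats:
    """Per-axis deviation SDs of targeting error, in nanometres.

    ``normality_pvalue`` is the smaller of the per-axis Shapiro–Wilk
    p-values (conservative: normality is rejected if either axis rejects);
    NaN when the sample is too small for the test.
    """

    sigma_x: float
    sigma_y: float
    n: int
    normality_pvalue: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise ValueError("deviation SDs must be > 0 (degenerate sample?)")
        if self.n < 2:
            raise ValueError("need n >= 2 deviations")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """High-magnification acquisition geometry.

    ``fov`` is the side length of the square field of view in nanometres;
    ``object_density`` (objects per um^2) parameterizes the chance-hit null.
    """

    fov: float
    object_density: float = 0.0

    def __post_init__(self) -> None:
        if not self.fov > 0:
            raise ValueError("fov must be > 0")
        if self.object_density < 0:
            raise ValueError("object_density must be >= 0")


def hit_probability(
    devstats: DeviationStats,
    geom: AcquisitionGeometry,
    method: str = "closed",
    n_draws: int = 1_000_000,
    seed: int | None = None,
) -> float:
    """Probability that the targeted feature falls inside the FOV.

    ``method="closed"`` evaluates the product of per-axis normal interval
    probabilities; ``method="mc"`` draws deviations and counts containment
    (the two agree within Monte-Carlo error, which is how the closed form
    is validated).
    """
    half = geom.fov / 2.0
    if method == "closed":
        px = 2.0 * stats.norm.cdf(half / devstats.sigma_x) - 1.0
        py = 2.0 * stats.norm.cdf(half / devstats.sigma_y) - 1.0
        return float(px * py)
    if method == "mc":
        rng = np.random.default_rng(seed)
        dx = rng.normal(0.0, devstats.sigma_x, size=n_draws)
        dy = rng.normal(0.0, devstats.sigma_y, size=n_draws)
        return float(np.mean((np.abs(dx) <= half) & (np.abs(dy) <= half)))
    raise ValueError(f"unknown method {method!r}")


def min_fov_for_rate(
    devstats: DeviationStats, target_rate: float, tol_nm: float = 1.0
) -> float:
    """Smallest square FOV (nm) whose closed-form hit probability reaches
    ``target_rate``, by bisection to ``tol_nm``.

    The hit probability is strictly increasing in the FOV, so bisection on
    the bracketing interval converges; the returned value is rounded *up*
    to the tolerance grid so that ``hit_probability`` at it is still at
    least the target.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must be in (0, 1)")

    def prob(fov: float) -> float:
        return hit_probability(devstats, AcquisitionGeometry(fov=fov))

    lo = tol_nm
    hi = 8.0 * max(devstats.sigma_x, devstats.sigma_y)
    while prob(hi) < target_rate:
        hi *= 2.0
    if prob(lo) >= target_rate:
        return lo
    while hi - lo > tol_nm:
        mid = 0.5 * (lo + hi)
        if prob(mid) >= target_rate:
            hi = mid
        else:
            lo = mid
    return hi


def estimate_deviation_stats(
    deviations, about_mean: bool = False
) -> DeviationStats:
    """Per-axis deviation SDs from measured (dx, dy) pairs in nanometres.

    By default the SD is the RMS about *zero*: the deviation is measured
    from the intended target, and systematic bias counts as targeting
    error.  ``about_mean=True`` subtracts the sample mean first, which
    separates bias from scatter for diagnosis.
    """
    d = np.asarray(deviations, dtype=float)
    if d.ndim != 2 or d.shape[1] != 2:
        raise ValueError("deviations must be an (n, 2) array of (dx, dy)")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 deviations")
    if about_mean:
        d = d - d.mean(axis=0)
    sigma = np.sqrt(np.mean(d ** 2, axis=0))
    if np.any(sigma == 0):
        raise ValueError("degenerate sample: zero deviation SD on an axis")
    if n >= 3:
        pvals = [stats.shapiro(d[:, k]).pvalue for k in range(2)]
        pvalue = float(min(pvals))
    else:
        pvalue = float("nan")
    return DeviationStats(
        sigma_x=float(sigma[0]), sigma_y=float(sigma[1]), n=n, normality_pvalue=pvalue
    )


def random_hit_probability(geom: AcquisitionGeometry) -> float:
    """Chance of catching *any* object in a randomly placed FOV.

    For objects scattered as a spatial Poisson process with intensity
    ``object_density`` per um^2, the count inside the FOV is Poisson with
    mean ``density * fov^2``, so P(non-empty) = 1 - exp(-density * fov^2).
    """
    area_um2 = (geom.fov / 1000.0) ** 2
    return float(1.0 - np.exp(-geom.object_density * area_um2))
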