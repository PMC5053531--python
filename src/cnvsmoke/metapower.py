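"""Two-cohort fixed-effect meta-analysis and carrier-frequency power curves.

Meta-analysis combines per-study regression coefficients by inverse-variance
weighting (w_i = 1/se_i^2, combined se = 1/sqrt(sum w_i)); a sample-size
weighted Stouffer z alternative is available for studies reported only as
(p, n, direction).  The power simulation mirrors a two-cohort design
comparison: the outcome (log-scale smoking exposure) is drawn as
beta * carrier + Normal(0, sigma) with carriers at a given population
frequency, and the rejection rate of the slope t-test at level alpha is
estimated over a grid of effect sizes for each sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "PowerCurve", "meta_fixed", "stouffer_from_p",
           "power_curve", "analytic_power"]


@dataclass
class MetaResult:
    beta_combined: float
    se_combined: float
    z: float
    p_two_sided: float
    method: str
    per_study_inputs: list[tuple] = field(default_factory=list)


@dataclass
class PowerCurve:
    """Rejection-rate grid: one row per sample size, one column per beta."""

    effect_grid: np.ndarray
    n_values: list[int]
    carrier_frequency: float
    alpha: float
    power: np.ndarray            # |n_values| x |effect_grid|
    n_sims: int
    seed: int
    sigma: float = 0.25


def meta_fixed(per_study, method: str = "inverse_variance") -> MetaResult:
    """Fixed-effect meta-analysis of per-study (beta, se[, n]) tuples.

    ``inverse_variance`` (default) weights effects by 1/se^2.  The
    ``stouffer_sqrt_n`` alternative combines the per-study z = beta/se with
    sqrt(n) weights (each tuple must then carry n); its combined beta is the
    sample-size weighted mean, reported for orientation only.
    """
    studies = [tuple(s) for s in per_study]
    if len(studies) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    betas = np.array([s[0] for s in studies], dtype=float)
    ses = np.array([s[1] for s in studies], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")

    if method == "inverse_variance":
        w = 1.0 / ses ** 2
        beta = float(np.sum(w * betas) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
        z = beta / se
    elif method == "stouffer_sqrt_n":
        if any(len(s) < 3 for s in studies):
            raise ValueError("stouffer_sqrt_n requires (beta, se, n) per study")
        ns = np.array([s[2] for s in studies], dtype=float)
        zi = betas / ses
        z = float(np.sum(np.sqrt(ns) * zi) / np.sqrt(np.sum(ns)))
        beta = float(np.sum(ns * betas) / np.sum(ns))
        se = abs(beta / z) if z != 0 else float("inf")
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(beta_combined=beta, se_combined=se, z=float(z),
                      p_two_sided=p, method=method, per_study_inputs=studies)


def stouffer_from_p(per_study) -> MetaResult:
    """Sample-size weighted Stouffer combination of (p, n, direction) studies.

    Each study contributes z_i = direction * Phi^{-1}(1 - p_i/2), weighted
    by sqrt(n_i); useful when only p-values and effect directions are
    reported.
    """
    studies = [tuple(s) for s in per_study]
    if len(studies) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    ps = np.array([s[0] for s in studies], dtype=float)
    ns = np.array([s[1] for s in studies], dtype=float)
    signs = np.sign([s[2] for s in studies]).astype(float)
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0,1]")
    zi = signs * stats.norm.isf(ps / 2.0)
    z = float(np.sum(np.sqrt(ns) * zi) / np.sqrt(np.sum(ns)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(beta_combined=float("nan"), se_combined=float("nan"),
                      z=z, p_two_sided=p, method="stouffer_sqrt_n",
                      per_study_inputs=studies)


def analytic_power(n: int, freq: float, beta: float, sigma: float,
                   alpha: float = 0.05) -> float:
    """Normal-approximation power of the slope test for a binary carrier.

    Phi(|beta| * sqrt(n f (1-f)) / sigma - z_{1-alpha/2}); the standard
    large-sample approximation used as an independent check of the
    simulation.
    """
    z_crit = stats.norm.isf(alpha / 2.0)
    ncp = abs(beta) * np.sqrt(n * freq * (1.0 - freq)) / sigma
    return float(stats.norm.cdf(ncp - z_crit))


def power_curve(n_values, carrier_frequency: float, effect_grid=None,
                sigma: float = 0.25, alpha: float = 0.05,
                n_sims: int = 1000, seed: int = 0) -> PowerCurve:
    """Simulated power of the carrier slope test over an effect-size grid.

    For each sample size n, carriers and noise are drawn once and shared
    across the whole beta grid (common random numbers); for each beta the
    outcome is beta * carrier + Normal(0, sigma) and the slope t-test at
    level alpha is evaluated from the per-simulation sufficient statistics,
    which are linear in beta.  Rejection fractions are returned as a
    |n_values| x |effect_grid| matrix.
    """
    if n_sims < 200:
        raise ValueError("n_sims must be >= 200")
    if not (0.0 < carrier_frequency < 1.0):
        raise ValueError("carrier_frequency must be in (0,1)")
    if effect_grid is None:
        effect_grid = np.arange(0.0, 1.0 + 1e-9, 0.005)
    grid = np.asarray(effect_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("invalid effect grid")
    n_values = [int(n) for n in n_values]
    if any(n < 4 for n in n_values):
        raise ValueError("each sample size must be >= 4")

    rng = np.random.default_rng(seed)
    power = np.empty((len(n_values), grid.size))
    for i, n in enumerate(n_values):
        x = (rng.random((n_sims, n)) < carrier_frequency).astype(float)
        e = rng.normal(0.0, sigma, size=(n_sims, n))
        xc = x - x.mean(axis=1, keepdims=True)
        ec = e - e.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", xc, xc)
        sxe = np.einsum("ij,ij->i", xc, ec)
        see = np.einsum("ij,ij->i", ec, ec)
        ok = sxx > 0                      # sims with both carrier classes
        t_crit2 = stats.t.isf(alpha / 2.0, n - 2) ** 2
        # y = beta x + e  =>  Sxy = Sxe + beta Sxx, Syy = See + 2 beta Sxe + beta^2 Sxx
        sxy = sxe[:, None] + grid[None, :] * sxx[:, None]
        syy = see[:, None] + 2.0 * grid[None, :] * sxe[:, None] \
            + grid[None, :] ** 2 * sxx[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = syy - sxy ** 2 / sxx[:, None]
            t2 = sxy ** 2 / sxx[:, None] * (n - 2) / np.maximum(rss, 1e-300)
        reject = (t2 > t_crit2) & ok[:, None]
        power[i] = reject.mean(axis=0)
    return PowerCurve(effect_grid=grid, n_values=n_values,
                      carrier_frequency=carrier_frequency, alpha=alpha,
                      power=power, n_sims=n_sims, seed=seed, sigma=sigma)
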