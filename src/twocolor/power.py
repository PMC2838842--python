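"""Analytic power of paired vs two-sample analyses for a direct two-group design.

On an array co-hybridizing the two groups, the with-array-effect (ratio)
analysis is a paired t-test on within-array log2 differences: the array
term cancels exactly, the difference has standard deviation sqrt(2)*sigma_e,
and n_arrays - 1 degrees of freedom remain.  The without-array-effect
(intensity) analysis is a two-sample t-test on the 2*n_arrays single
channels: the array effect is absorbed into the per-channel noise,
sd = sqrt(sigma_a^2 + sigma_e^2), with 2*n_arrays - 2 degrees of freedom.
Both channels of a group are treated as exchangeable observations, which is
the intensity model's assumption.

Power follows from the non-central t-distribution: with critical value
t* = t_{df, 1-alpha/2}, power = P(|T'_{df, ncp}| > t*).  The trade-off the
curves expose: pairing removes sigma_a but halves the degrees of freedom,
so for small sigma_a the two-sample analysis wins at small n and the curves
converge (possibly crossing once) as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-group power comparison.

    delta
        True treatment effect (log2 units).
    sigma_e
        Within-array residual standard deviation (> 0).
    sigma_a
        Between-array (array-effect) standard deviation (>= 0).
    n_arrays
        Number of arrays, each carrying one channel per group (>= 2).
    alpha
        Two-sided test level.
    """

    delta: float
    sigma_e: float
    sigma_a: float = 0.0
    n_arrays: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be > 0")
        if self.sigma_a < 0:
            raise ValueError("sigma_a must be >= 0")
        if self.n_arrays < 2:
            raise ValueError("n_arrays must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _nct_cdf(t: float, df: int, ncp) -> np.ndarray:
    value = stats.nct.cdf(t, df, ncp)
    # scipy's noncentral t loses accuracy for large df x large ncp;
    # fall back to the Johnson-Kotz normal approximation there
    z = (t * (1.0 - 1.0 / (4.0 * df)) - np.asarray(ncp)) / np.sqrt(1.0 + t * t / (2.0 * df))
    return np.where(np.isnan(value), stats.norm.cdf(z), value)


def _noncentral_t_power(ncp, df: int, alpha: float):
    """Two-sided rejection probability; ``ncp`` may be a scalar or vector."""
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = 1.0 - _nct_cdf(tcrit, df, ncp) + _nct_cdf(-tcrit, df, ncp)
    return float(power) if np.isscalar(ncp) else power


def power_with_array_effect(spec: PowerSpec) -> float:
    """Power of the paired (with-array-effect) analysis.

    df = n_arrays - 1; the array term cancels in the within-array
    difference, whose sd is sqrt(2)*sigma_e; ncp = delta / (sqrt(2)*sigma_e
    / sqrt(n_arrays)).
    """
    df = spec.n_arrays - 1
    se = np.sqrt(2.0) * spec.sigma_e / np.sqrt(spec.n_arrays)
    return _noncentral_t_power(spec.delta / se, df, spec.alpha)


def power_without_array_effect(spec: PowerSpec) -> float:
    """Power of the two-sample (without-array-effect) analysis.

    df = 2*n_arrays - 2; per-channel sd = sqrt(sigma_a^2 + sigma_e^2);
    ncp = delta / (sd * sqrt(2 / n_arrays)).
    """
    df = 2 * spec.n_arrays - 2
    sd = np.sqrt(spec.sigma_a**2 + spec.sigma_e**2)
    se = sd * np.sqrt(2.0 / spec.n_arrays)
    return _noncentral_t_power(spec.delta / se, df, spec.alpha)


def power_curves(spec: PowerSpec, n_grid: Sequence[int]) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Evaluate both power functions over a grid of array counts.

    Returns the (n, power_with, power_without) table and the grid intervals
    where power_with - power_without changes sign (the crossing points of
    the two curves).
    """
    n_grid = list(n_grid)
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ValueError("n_grid must be strictly increasing")
    if n_grid and n_grid[0] < 2:
        raise ValueError("all grid values must be >= 2")
    records = []
    for n in n_grid:
        s = replace(spec, n_arrays=int(n))
        records.append(
            {
                "n_arrays": int(n),
                "power_with": power_with_array_effect(s),
                "power_without": power_without_array_effect(s),
            }
        )
    frame = pd.DataFrame(records)
    diff = frame["power_with"] - frame["power_without"]
    sign = np.sign(diff.to_numpy())
    crossings = [
        (n_grid[i], n_grid[i + 1])
        for i in range(len(sign) - 1)
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]
    ]
    return frame, crossings


def average_power(
    effects: Sequence[float],
    sds: Sequence[tuple[float, float]],
    n_arrays: int,
    alpha: float = 0.05,
    min_effect: float = 0.25,
    model: str = "with-array-effect",
) -> float:
    """Mean per-probe power over probes with |delta| > ``min_effect``.

    ``effects`` and ``sds`` are aligned per-probe lists of delta and
    (sigma_e, sigma_a).  The restriction to effects above ``min_effect``
    emulates a gene set carrying differential signal; the mean power is the
    expected fraction of those genes declared significant.
    """
    effects = np.asarray(effects, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if len(effects) != len(sds):
        raise ValueError("effects and sds must be aligned")
    keep = np.abs(effects) > min_effect
    if not keep.any():
        raise ValueError(f"no probes with |delta| > {min_effect}")
    delta = effects[keep]
    sigma_e = sds[keep, 0]
    sigma_a = sds[keep, 1]
    if model == "with-array-effect":
        df = n_arrays - 1
        se = np.sqrt(2.0) * sigma_e / np.sqrt(n_arrays)
    elif model == "without-array-effect":
        df = 2 * n_arrays - 2
        se = np.sqrt(sigma_a**2 + sigma_e**2) * np.sqrt(2.0 / n_arrays)
    else:
        raise ValueError(f"unknown model {model!r}")
    return float(np.mean(_noncentral_t_power(delta / se, df, alpha)))


def estimate_power_inputs(rt_ratio, rt_intensity) -> pd.DataFrame:
    """Estimate per-probe (delta, sigma_e, sigma_a) from a ratio/intensity fit pair.

    sigma_e^2 is the ratio-model residual variance; sigma_a^2 is the excess
    of the intensity-model residual variance over it, floored at zero (the
    intensity model absorbs the array effect into its residual).  delta is
    the (shared) treatment M-value of the first treatment pair.
    """
    if not rt_ratio.frame.index.equals(rt_intensity.frame.index):
        raise ValueError("result tables cover different probes")
    m_cols = [c for c in rt_ratio.frame.columns if c.startswith("M[")]
    if not m_cols:
        raise ValueError("ratio table has no M-value columns")
    sigma_e2 = rt_ratio.frame["sigma2"]
    sigma_a2 = (rt_intensity.frame["sigma2"] - sigma_e2).clip(lower=0.0)
    return pd.DataFrame(
        {
            "delta": rt_ratio.frame[m_cols[0]],
            "sigma_e": np.sqrt(sigma_e2),
            "sigma_a": np.sqrt(sigma_a2),
        }
    )
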