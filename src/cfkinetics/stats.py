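"""Solution-quality statistics for fitted kinetic models.

Covers the coefficient of variation used to judge parameter resolution
across the multi-start solution pool, a nested-model chi-square test for
whether adding the per-dataset time-lag parameter significantly improves the
SSR, and a chi-square goodness-of-fit screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = ["GofConfig", "cov", "nested_significance", "gof_chi2"]

#: Default significance level of the nested time-lag test.
NESTED_ALPHA = 0.001


@dataclass(frozen=True)
class GofConfig:
    """Goodness-of-fit screen configuration.

    ``variance`` is the residual (measurement) variance estimate in mM^2,
    e.g. from replicate noise; ``df`` the chi-square degrees of freedom.
    """

    alpha: float = 0.05
    df: int = 7
    variance: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if self.variance <= 0:
            raise ValueError(f"variance must be > 0 mM^2, got {self.variance}")


def cov(values) -> float:
    """Coefficient of variation: sample standard deviation over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("cov needs at least one value")
    mean = v.mean()
    if mean == 0:
        raise ValueError("cov undefined for zero mean")
    std = v.std(ddof=1) if v.size > 1 else 0.0
    return float(std / mean)


def nested_significance(
    ssr_full: float,
    ssr_reduced: float,
    n_points: int,
    df_added: int = 1,
    alpha: float = NESTED_ALPHA,
) -> tuple:
    """Chi-square test of an added parameter (e.g. the time-lag) in nested
    least-squares fits.

    Statistic: n * ln(SSR_reduced / SSR_full), the Gaussian likelihood-ratio
    form, compared to the chi-square (1 - alpha) quantile with ``df_added``
    degrees of freedom. Returns ``(statistic, significant)``. A reduced-model
    SSR below the full-model SSR (no improvement) yields statistic 0.
    """
    if ssr_full <= 0:
        raise ValueError(f"ssr_full must be > 0, got {ssr_full}")
    if n_points < 1 or df_added < 1:
        raise ValueError("n_points and df_added must be >= 1")
    if ssr_full > ssr_reduced:
        return 0.0, False
    stat = n_points * float(np.log(ssr_reduced / ssr_full))
    threshold = chi2.ppf(1.0 - alpha, df_added)
    return stat, bool(stat > threshold)


def gof_chi2(ssr: float, cfg: GofConfig) -> bool:
    """Chi-square goodness-of-fit screen.

    Passes when ``ssr / variance`` does not exceed the chi-square
    ``1 - alpha`` quantile with ``cfg.df`` degrees of freedom.
    """
    if ssr < 0:
        raise ValueError(f"ssr must be >= 0, got {ssr}")
    return bool(ssr / cfg.variance <= chi2.ppf(1.0 - cfg.alpha, cfg.df))
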