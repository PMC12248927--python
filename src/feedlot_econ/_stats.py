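"""Internal helpers: Student-t conversion between a 95% CI on a mean and the
underlying sample SD.

The study tables report trait means with 95% CIs and the group size n, never
SDs. Assuming the CIs are t-based (two-sided, n-1 df), the animal-level
sample SD is recovered as

    sd = sqrt(n) * halfwidth / t_{0.975, n-1}

which is exact when the CI was built as mean +/- t * sd / sqrt(n).
"""

from __future__ import annotations

import math

from scipy import stats

from .errors import DomainError

__all__ = ["sd_from_halfwidth", "halfwidth_from_sd", "t_quantile"]


def t_quantile(n: int) -> float:
    """Two-sided 97.5% Student-t quantile at n-1 degrees of freedom."""
    if n < 2:
        raise DomainError(f"t quantile needs n >= 2, got n={n}")
    return float(stats.t.ppf(0.975, n - 1))


def sd_from_halfwidth(halfwidth: float, n: int) -> float:
    """Sample SD implied by a 95% t-CI halfwidth on a mean of n units."""
    if halfwidth < 0:
        raise DomainError(f"CI halfwidth must be >= 0, got {halfwidth}")
    return math.sqrt(n) * halfwidth / t_quantile(n)


def halfwidth_from_sd(sd: float, n: int) -> float:
    """95% t-CI halfwidth on a mean of n units with sample SD ``sd``."""
    if sd < 0:
        raise DomainError(f"sd must be >= 0, got {sd}")
    return t_quantile(n) * sd / math.sqrt(n)
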