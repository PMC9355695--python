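"""Sensitivity power analysis for the Pearson correlation test.

Implements the Cohen-style approximation used by standard correlation
power calculators: the critical correlation is derived from the t
distribution with n - 2 degrees of freedom, both the true and critical
correlation are mapped through Fisher's z transform (with the small-sample
bias term r / (2(n - 1)) applied to the true correlation), and power is a
normal tail probability on the z scale with standard error 1 / sqrt(n - 3).

A plain large-sample Fisher-z variant (no bias term, normal critical
value) is available via ``method="fisher"``; it agrees with the default to
about 0.01 for n >= 100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["power_r", "detectable_r", "power_table"]

_TAILS = ("one", "two")


def _check(n: int, alpha: float, tails: str) -> None:
    if n < 4:
        raise ValueError(f"sample size must be at least 4, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if tails not in _TAILS:
        raise ValueError(f"tails must be one of {_TAILS}, got {tails!r}")


def power_r(
    n: int,
    r: float,
    alpha: float = 0.05,
    tails: str = "one",
    method: str = "cohen",
) -> float:
    """Power of the Pearson correlation test of H0: rho = 0.

    Parameters
    ----------
    n : sample size (pairs).
    r : true population correlation, 0 <= r < 1.
    alpha : type-I error rate.
    tails : "one" for a directed test, "two" for two-sided.
    method : "cohen" (default, t-based critical r with Fisher-z bias
        correction) or "fisher" (pure large-sample Fisher-z formula).
    """
    _check(n, alpha, tails)
    if not 0 <= r < 1:
        raise ValueError(f"true correlation must lie in [0, 1), got {r}")
    a = alpha if tails == "one" else alpha / 2.0
    if method == "cohen":
        t_crit = stats.t.isf(a, n - 2)
        r_crit = np.sqrt(t_crit**2 / (t_crit**2 + n - 2))
        z_r = np.arctanh(r) + r / (2.0 * (n - 1))
        z_c = np.arctanh(r_crit)
        power = stats.norm.cdf((z_r - z_c) * np.sqrt(n - 3))
        if tails == "two":  # rejection region in the opposite tail
            power += stats.norm.cdf((-z_r - z_c) * np.sqrt(n - 3))
        return float(power)
    if method == "fisher":
        z_a = stats.norm.isf(a)
        power = stats.norm.cdf(np.arctanh(r) * np.sqrt(n - 3) - z_a)
        if tails == "two":
            power += stats.norm.cdf(-np.arctanh(r) * np.sqrt(n - 3) - z_a)
        return float(power)
    raise ValueError(f"unknown method {method!r}")


def detectable_r(
    n: int,
    target_power: float,
    alpha: float = 0.05,
    tails: str = "one",
    method: str = "cohen",
) -> float:
    """Smallest true correlation detected with ``target_power``.

    Inverts :func:`power_r` by root bracketing; power is strictly
    increasing in r, so the solution is unique.
    """
    _check(n, alpha, tails)
    if not 0 < target_power < 1:
        raise ValueError(f"target power must lie in (0, 1), got {target_power}")
    lo, hi = 1e-12, 0.9999
    f = lambda r: power_r(n, r, alpha, tails, method) - target_power
    if f(hi) < 0:
        raise ValueError(
            f"power {target_power} unattainable at n={n}, alpha={alpha}"
        )
    if f(lo) > 0:
        raise ValueError(
            f"target power {target_power} below the null rejection rate alpha"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def power_table(
    n_values,
    r_grid,
    alpha: float = 0.05,
    tails: str = "one",
    method: str = "cohen",
) -> pd.DataFrame:
    """Rectangular power table, rows indexed by n, columns by true r."""
    n_values = list(n_values)
    r_grid = list(r_grid)
    if not n_values or not r_grid:
        raise ValueError("n_values and r_grid must be non-empty")
    rows = [
        [power_r(n, r, alpha, tails, method) for r in r_grid] for n in n_values
    ]
    return pd.DataFrame(rows, index=pd.Index(n_values, name="n"),
                        columns=pd.Index(r_grid, name="r"))
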