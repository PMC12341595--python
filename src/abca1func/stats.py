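"""Two-sample testing machinery shared by the efflux, surface and rescue stages.

The comparison used throughout is a two-sample t-test assuming equal or unequal
variance depending on the outcome of an F-test for equality of variances: if the
F-test rejects at ``variance_alpha`` the Welch (unequal-variance) statistic is
used, otherwise the pooled-variance statistic. The t statistics are computed
from the textbook formulas with p-values from ``scipy.stats`` distributions;
degenerate zero-variance groups (e.g. a normalized WT reference that is exactly
100 in every experiment) are handled explicitly instead of producing NaNs.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientReplicatesError

Alternative = str  # "two-sided" | "greater" | "less"


def _check_group(values: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientReplicatesError(
            f"group '{label}' has {arr.size} replicate(s); need at least 2"
        )
    return arr


def f_test_equal_variances(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed F-test p-value for H0: var(a) == var(b).

    Both variances zero counts as equal (p = 1); exactly one zero variance is
    maximal inequality (p = 0).
    """
    a = _check_group(a, "a")
    b = _check_group(b, "b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0
    if va == 0.0 or vb == 0.0:
        return 0.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    return float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))


def _p_from_t(t: float, df: float, alternative: Alternative) -> float:
    if alternative == "two-sided":
        return float(2.0 * sps.t.sf(abs(t), df))
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown alternative: {alternative!r}")


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    *,
    equal_var: bool,
    alternative: Alternative = "two-sided",
) -> tuple[float, float, float]:
    """Return (t, df, p) for a two-sample t-test of mean(a) vs mean(b)."""
    a = _check_group(a, "a")
    b = _check_group(b, "b")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = math.sqrt(va / na + vb / nb)
        if se > 0.0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2

    diff = ma - mb
    if se == 0.0:
        # both groups constant: identical means -> no evidence either way
        if diff == 0.0:
            p = 1.0 if alternative == "two-sided" else 0.5
            return 0.0, float(df), p
        t = math.inf if diff > 0 else -math.inf
    else:
        t = diff / se
    return float(t), float(df), _p_from_t(t, df, alternative)


def gated_ttest(
    a: Sequence[float],
    b: Sequence[float],
    *,
    variance_alpha: float = 0.05,
    alternative: Alternative = "two-sided",
) -> tuple[float, bool]:
    """F-test-gated two-sample t-test.

    Returns ``(p_value, equal_var_used)``; ``equal_var_used`` records which
    branch the F-test selected.
    """
    p_f = f_test_equal_variances(a, b)
    equal_var = p_f >= variance_alpha
    _, _, p = two_sample_t(a, b, equal_var=equal_var, alternative=alternative)
    return p, equal_var
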