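"""Equivalence testing of SUV metrics: margin derivation and paired TOST.

The clinical-equivalence margin is derived from an uncertainty budget: if
attenuation correction is the only uncertainty a PET-MR measurement adds to
a PET-CT one, and the two are independent, the total adds in quadrature,

    Delta_total = sqrt(Delta_baseline^2 + Delta_AC^2).

The margin is the largest Delta_AC that keeps the growth of the total below
an allowed increase — with the literature PET-CT SUV repeatability of 12%
and an allowed increase of 0.5%, the margin is 3.5%.

Equivalence of per-lesion percentage differences is assessed with two
one-sided paired t tests (TOST): the reported p is the larger of the two
one-sided p-values, and equivalence is declared when it falls below a
significance level corrected for multiple testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_BASELINE_UNCERTAINTY_PCT = 12.0
DEFAULT_ALLOWED_INCREASE_PCT = 0.5
DEFAULT_BASE_ALPHA = 0.05
DEFAULT_N_TESTS = 8


@dataclass
class EquivalenceResult:
    """One TOST comparison (provenance x GTV kind x metric)."""

    label: str
    n: int
    mean_diff: float  # %
    se_diff: float  # %
    margin: float  # %
    p_value: float
    alpha_corrected: float
    equivalent: bool
    degenerate_se: bool = False


def derive_margin(
    delta_petct: float = DEFAULT_BASELINE_UNCERTAINTY_PCT,
    allowed_increase: float = DEFAULT_ALLOWED_INCREASE_PCT,
) -> float:
    """Largest attenuation-correction uncertainty (in %) that increases the
    quadrature total by at most ``allowed_increase`` over ``delta_petct``."""
    if delta_petct <= 0 or allowed_increase <= 0:
        raise ValueError("uncertainties must be positive")
    return math.sqrt((delta_petct + allowed_increase) ** 2 - delta_petct**2)


def quadrature_total(delta_petct: float, delta_ac: float) -> float:
    """Total uncertainty when two independent components add in quadrature."""
    if delta_petct < 0 or delta_ac < 0:
        raise ValueError("uncertainties must be non-negative")
    return math.hypot(delta_petct, delta_ac)


def tost_from_summary(
    mean_diff: float, se_diff: float, n: int, margin: float
) -> float:
    """TOST p-value from summary statistics of paired differences.

    t_low = (mean + margin)/se tests mean > -margin, t_high =
    (margin - mean)/se tests mean < +margin, both on n-1 degrees of freedom;
    the reported p is the larger of the two upper-tail p-values.
    """
    if n < 2:
        raise ValueError("TOST needs n >= 2")
    if margin <= 0:
        raise ValueError("margin must be positive")
    if se_diff <= 0:
        warnings.warn("degenerate SE = 0; deciding by |mean| vs margin", stacklevel=2)
        return 0.0 if abs(mean_diff) < margin else 1.0
    df = n - 1
    t_low = (mean_diff + margin) / se_diff
    t_high = (margin - mean_diff) / se_diff
    return float(max(stats.t.sf(t_low, df), stats.t.sf(t_high, df)))


def tost_paired(
    diffs,
    margin: float,
    alpha: float | None = None,
    label: str = "",
) -> EquivalenceResult:
    """Paired TOST from per-lesion percentage differences.

    SE is the sample standard deviation (n-1 denominator) over sqrt(n),
    matching the t test's n-1 degrees of freedom.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("TOST needs at least two paired differences")
    if alpha is None:
        alpha = corrected_alpha(DEFAULT_N_TESTS, DEFAULT_BASE_ALPHA)[1]
    n = int(d.size)
    mean = float(d.mean())
    se = float(d.std(ddof=1) / math.sqrt(n))
    degenerate = se == 0.0
    if degenerate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = tost_from_summary(mean, se, n, margin)
    else:
        p = tost_from_summary(mean, se, n, margin)
    return EquivalenceResult(
        label=label,
        n=n,
        mean_diff=mean,
        se_diff=se,
        margin=float(margin),
        p_value=p,
        alpha_corrected=float(alpha),
        equivalent=p <= alpha,
        degenerate_se=degenerate,
    )


def corrected_alpha(
    n_tests: int = DEFAULT_N_TESTS, base_alpha: float = DEFAULT_BASE_ALPHA
) -> tuple[float, float]:
    """Multiple-testing-corrected significance level base_alpha/(n_tests - 1).

    Returns (reported, exact): the reported value is rounded to 3 decimals
    for presentation, the exact value is used for decisions.  The divisor is
    n_tests - 1, not the plain Bonferroni n_tests, matching the correction
    this analysis is defined with.
    """
    if n_tests < 2:
        raise ValueError("n_tests must be >= 2")
    exact = base_alpha / (n_tests - 1)
    return round(exact, 3), exact
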