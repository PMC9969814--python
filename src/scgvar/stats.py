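"""Statistical layer: paired t, Cohen's d, ANOVA, Bland-Altman.

The comparisons mirror how resting-posture and longitudinal feature tables
are usually analyzed: paired two-tailed t-tests between posture pairs with
Cohen's d (pooled-SD, reported as a magnitude) for effect size, one-way
ANOVA across recording sessions, and Bland-Altman bias / limits of
agreement between paired measurement conditions. No multiple-testing
correction is applied. p-values come from scipy's t and F distributions;
the statistics themselves are formed explicitly from their defining
formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

EFFECT_CLASSES = ("small", "medium", "large", "very large")


@dataclass
class StatResult:
    statistic: float
    p_value: float
    df: tuple[int, ...]
    kind: str                      # "t" or "F"
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray              # per-pair means, for plotting
    diffs: np.ndarray


def paired_t(differences: np.ndarray) -> StatResult:
    """Paired t-test from the per-pair differences.

    t = mean(d) * sqrt(n) / sd(d) with the n-1 sample SD; two-tailed p on
    n-1 degrees of freedom. Zero-variance differences leave t undefined
    (``defined=False``) rather than returning an infinity.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least two paired differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        return StatResult(float("nan"), float("nan"), (n - 1,), "t", defined=False)
    t = float(np.mean(d)) * np.sqrt(n) / sd
    p = 2.0 * sst.t.sf(abs(t), df=n - 1)
    return StatResult(float(t), float(p), (n - 1,), "t")


def cohens_d(
    mu1: float, sd1: float, n1: int, mu2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Cohen's d with pooled SD, reported as a magnitude.

    sigma_pooled = sqrt(((n1-1)*sd1^2 + (n2-1)*sd2^2) / (n1+n2-2));
    d = |mu1 - mu2| / sigma_pooled. Returns ``(d, sigma_pooled)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("Cohen's d undefined when both SDs are zero")
    pooled = np.sqrt(
        ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    )
    return float(abs(mu1 - mu2) / pooled), float(pooled)


def cohens_d_from_samples(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_d(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def classify_effect(d: float) -> str:
    """Effect-size class: small (<0.2), medium (<0.5), large (<0.8),
    very large (>=0.8); boundary values fall in the higher class."""
    if d < 0:
        raise ValueError("classify the magnitude; d must be nonnegative")
    if d < 0.2:
        return "small"
    if d < 0.5:
        return "medium"
    if d < 0.8:
        return "large"
    return "very large"


def one_way_anova(groups: list[np.ndarray]) -> StatResult:
    """One-way ANOVA: F = MS_between / MS_within, df = (k-1, N-k).

    When every observation is identical the F statistic is defined as 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    k = len(gs)
    all_vals = np.concatenate(gs)
    n_total = len(all_vals)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n_total - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        f = 0.0 if ms_between == 0 else float("inf")
        p = 1.0 if ms_between == 0 else 0.0
        return StatResult(f, p, (df1, df2), "F", defined=np.isfinite(f))
    f = ms_between / ms_within
    p = float(sst.f.sf(f, df1, df2))
    return StatResult(float(f), p, (df1, df2), "F")


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltman:
    """Agreement between two paired measurement series.

    Differences a_i - b_i give the bias (mean difference); limits of
    agreement are bias +/- 1.96 * SD of the differences. Per-pair means
    are returned for the conventional scatter plot.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        means=(a + b) / 2.0,
        diffs=diffs,
    )
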