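"""Measurement-properties statistics.

The validation battery for a new instrument against a reference device:

* **Agreement** — Bland–Altman analysis of paired features (per-pair
  difference vs per-pair mean, bias, 1.96·SD limits of agreement, a
  one-sample t-test of the differences against zero, and an OLS regression of
  differences on means to detect proportional bias).
* **Validity** — normality-gated correlations (Pearson when both variables
  pass Shapiro–Wilk at α = 0.05, Spearman otherwise) and normality-gated
  group comparisons (Student's t with Cohen's d, or Mann–Whitney with the
  rank-biserial correlation).
* **Reliability** — the same Bland–Altman machinery applied to first vs
  second acquisition instead of device vs device.
* **Accuracy** — ROC analysis with trapezoidal AUC, the Youden-optimal
  cutoff, and the conventional AUC > 0.7 adequacy flag.
* **Planning** — a priori per-group sample size for a two-sample t-test from
  the noncentral-t power function.

p-values are reported raw; no multiplicity correction is applied, and result
tables carry the comparison count so users can adjust if they wish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst
from sklearn.metrics import roc_curve

from .errors import DegenerateSignalError, ParameterError

NORMALITY_ALPHA = 0.05
LOA_MULTIPLIER = 1.96


@dataclass
class BlandAltmanResult:
    """Agreement between two paired measurement series."""

    dif: np.ndarray          # per-pair difference, A − B
    mu: np.ndarray           # per-pair mean, (A + B)/2
    bias: float              # mean difference
    loa_low: float           # bias − 1.96·SD(dif)
    loa_high: float          # bias + 1.96·SD(dif)
    t_stat: float            # one-sample t of dif vs 0
    t_p: float
    pb_slope: float          # proportional bias: OLS of dif on mu
    pb_intercept: float
    pb_p: float              # two-sided slope test
    degenerate: bool         # SD(dif) = 0: t-test and regression undefined
    n: int


def bland_altman(a, b, alternative: str = "two-sided") -> BlandAltmanResult:
    """Bland–Altman agreement of paired series ``a`` (reference) and ``b``.

    ``alternative`` configures the one-sample t-test of the differences
    ("two-sided" by default; "greater" tests whether A systematically exceeds
    B).  When all differences are identical the t-test and the
    proportional-bias regression are undefined; the bias and limits are still
    returned with ``degenerate=True``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired series must be 1-d and equal-length")
    if len(a) < 3:
        raise ParameterError(f"need at least 3 pairs, got {len(a)}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ParameterError("missing pairs are not allowed")
    dif = a - b
    mu = (a + b) / 2.0
    bias = float(np.mean(dif))
    sd = float(np.std(dif, ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        # constant differences: the t-test is undefined, but the
        # proportional-bias picture is unambiguous — a flat difference has
        # slope 0 and no evidence of proportional bias
        t_stat = t_p = float("nan")
        pb_slope, pb_intercept, pb_p = 0.0, bias, 1.0
    else:
        t = sst.ttest_1samp(dif, 0.0, alternative=alternative)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
        if np.std(mu) == 0:
            pb_slope = pb_intercept = pb_p = float("nan")
        else:
            reg = sst.linregress(mu, dif)
            pb_slope, pb_intercept, pb_p = (
                float(reg.slope), float(reg.intercept), float(reg.pvalue),
            )
    return BlandAltmanResult(
        dif=dif, mu=mu, bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd, loa_high=bias + LOA_MULTIPLIER * sd,
        t_stat=t_stat, t_p=t_p,
        pb_slope=pb_slope, pb_intercept=pb_intercept, pb_p=pb_p,
        degenerate=degenerate, n=len(a),
    )


def _both_normal(x: np.ndarray, y: np.ndarray) -> bool:
    return (
        sst.shapiro(x).pvalue > NORMALITY_ALPHA
        and sst.shapiro(y).pvalue > NORMALITY_ALPHA
    )


def correlation_strength(r: float) -> str:
    """Conventional strength label: weak < 0.4 ≤ moderate ≤ 0.7 < strong."""
    a = abs(r)
    if a < 0.4:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"


def correlate(x, y, policy: str = "auto") -> dict:
    """Correlation with a normality gate.

    Under the ``auto`` policy both variables are Shapiro–Wilk tested at
    α = 0.05; Pearson is used only if both pass, Spearman otherwise.  Returns
    the method actually used, r, the p-value, and a strength label.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ParameterError("need equal-length series with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateSignalError("zero variance: correlation undefined")
    if policy == "auto":
        policy = "pearson" if _both_normal(x, y) else "spearman"
    if policy == "pearson":
        res = sst.pearsonr(x, y)
    elif policy == "spearman":
        res = sst.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation policy {policy!r}")
    r = float(res.statistic)
    return {
        "method": policy,
        "r": r,
        "p": float(res.pvalue),
        "strength": correlation_strength(r),
        "n": len(x),
    }


def cohens_d(g1: np.ndarray, g2: np.ndarray) -> float:
    """Cohen's d with the pooled (n−1-weighted) standard deviation."""
    n1, n2 = len(g1), len(g2)
    s_pooled = math.sqrt(
        ((n1 - 1) * np.var(g1, ddof=1) + (n2 - 1) * np.var(g2, ddof=1))
        / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        return 0.0
    return float((np.mean(g1) - np.mean(g2)) / s_pooled)


def group_compare(g1, g2) -> dict:
    """Two-group comparison with a normality gate.

    Student's t-test with Cohen's d when both groups pass Shapiro–Wilk at
    α = 0.05, otherwise Mann–Whitney U with the rank-biserial correlation
    (r = 2·U/(n₁n₂) − 1, positive when g1 tends to exceed g2).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) < 3 or len(g2) < 3:
        raise ParameterError("each group needs n >= 3")
    if np.std(g1) == 0 and np.std(g2) == 0:
        raise DegenerateSignalError("both groups constant: comparison undefined")
    if _both_normal(g1, g2):
        res = sst.ttest_ind(g1, g2)
        return {
            "test": "t-test", "statistic": float(res.statistic),
            "p": float(res.pvalue), "effect_size": cohens_d(g1, g2),
            "effect_type": "cohens_d",
        }
    res = sst.mannwhitneyu(g1, g2, alternative="two-sided")
    u = float(res.statistic)
    rank_biserial = 2.0 * u / (len(g1) * len(g2)) - 1.0
    return {
        "test": "mann-whitney", "statistic": u,
        "p": float(res.pvalue), "effect_size": rank_biserial,
        "effect_type": "rank_biserial",
    }


@dataclass
class RocResult:
    """Accuracy of a score against a binary gold standard."""

    auc: float
    cutoff: float            # Youden-optimal operating threshold (score >= cutoff positive)
    sensitivity: float
    specificity: float
    adequate: bool           # conventional AUC > 0.7 criterion
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_analysis(scores, labels) -> RocResult:
    """ROC analysis: trapezoidal AUC (equal to the tie-corrected concordance
    probability), plus the cutoff maximizing Youden's J = sens + spec − 1.

    Ties in J are broken toward higher sensitivity.  ``adequate`` flags
    AUC > 0.7, the usual minimum for a discriminating test.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ParameterError(f"need exactly two classes, got {classes!r}")
    y = (labels == classes.max()).astype(int)
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    # argmax keeps the first maximum; roc_curve orders thresholds descending,
    # so the first max is the highest-threshold optimum. Break ties in J
    # toward higher sensitivity instead.
    best = max(range(len(j)), key=lambda i: (j[i], tpr[i], -i))
    cutoff = float(thresholds[best])
    return RocResult(
        auc=auc, cutoff=cutoff,
        sensitivity=float(tpr[best]), specificity=float(1 - fpr[best]),
        adequate=auc > 0.7, fpr=fpr, tpr=tpr, thresholds=thresholds,
    )


def _t_power(n: int, d: float, alpha: float, tails: str) -> float:
    """Power of the equal-n two-sample t-test from the noncentral t."""
    df = 2 * n - 2
    ncp = d * math.sqrt(n / 2.0)
    if tails == "one":
        tcrit = sst.t.ppf(1 - alpha, df)
        return float(sst.nct.sf(tcrit, df, ncp))
    tcrit = sst.t.ppf(1 - alpha / 2, df)
    return float(sst.nct.sf(tcrit, df, ncp) + sst.nct.cdf(-tcrit, df, ncp))


def sample_size(
    effect_size: float, power: float = 0.80, alpha: float = 0.05,
    tails: str = "two", n_max: int = 1_000_000,
) -> int:
    """Smallest per-group n whose two-sample t-test attains the requested
    power at effect size ``effect_size`` (Cohen's d).

    ``tails`` must be stated explicitly for planning: one- and two-tailed
    designs can differ by several subjects per group.
    """
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ParameterError("power and alpha must lie in (0, 1)")
    if effect_size <= 0:
        raise ParameterError("effect_size must be positive")
    if tails not in ("one", "two"):
        raise ParameterError(f"tails must be 'one' or 'two', got {tails!r}")
    for n in range(2, n_max + 1):
        if _t_power(n, effect_size, alpha, tails) >= power:
            return n
    raise ParameterError(
        f"requested power {power} unattainable within n <= {n_max}"
    )
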