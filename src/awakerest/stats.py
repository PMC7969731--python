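"""Inferential statistics battery for the cohort analyses.

Everything here is computed from closed forms (sums of squares, exact
binomial tail doubling, Dixon's gap/range ratio, effect sizes); SciPy is
used only for distribution functions (t, F, chi-square, normal).

Contents:

* one- and two-way repeated-measures ANOVA with subject-partitioned error
  terms, Mauchly's sphericity test, Greenhouse-Geisser and Huynh-Feldt
  epsilons, and partial eta squared; the Huynh-Feldt correction is applied
  to the reported p-value only when Mauchly's test rejects at 0.05,
  * polynomial (quadratic) trend contrasts,
* one-sample, paired, independent and Welch t tests with Cohen's d and
  Hedges' g,
* the exact two-sided binomial test at p0 = 0.5 with Cohen's g,
* Dixon's Q test for a single outlier,
* a median-split group comparison, and
* the assumption checks (Kolmogorov-Smirnov normality, Levene's equal
  variance, Mauchly's sphericity) that drive the test-selection policy
  (Welch on Levene failure, Huynh-Feldt on Mauchly failure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "RmAnovaEffect",
    "RmAnovaResult",
    "BinomialTestResult",
    "DixonResult",
    "MedianSplitResult",
    "one_sample_t",
    "paired_t",
    "independent_t",
    "binomial_test_two_sided",
    "rm_anova_one_way",
    "rm_anova_two_way",
    "polynomial_trend_contrast",
    "dixon_q_test",
    "median_split_compare",
    "ks_normality",
    "levene_test",
    "mauchly_test",
    "assumption_checks",
]


# ---------------------------------------------------------------------------
# t tests and effect sizes


@dataclass(frozen=True)
class TTestResult:
    kind: str
    t: float
    df: float
    p: float
    effect_size: float
    effect_kind: str
    mean_diff: float
    ci95: tuple[float, float]


def _t_p(t: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def hedges_correction(df: float) -> float:
    """Small-sample correction factor 1 - 3/(4 df - 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def one_sample_t(x, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t test; Cohen's d = (mean - mu0) / SD."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    diff = x.mean() - mu0
    se = sd / math.sqrt(n)
    t = diff / se
    df = n - 1
    half = sps.t.ppf(0.975, df) * se
    return TTestResult(
        kind="one_sample",
        t=float(t),
        df=float(df),
        p=_t_p(t, df),
        effect_size=float(diff / sd),
        effect_kind="cohens_d_one_sample",
        mean_diff=float(diff),
        ci95=(float(diff - half), float(diff + half)),
    )


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t test; Cohen's d on the paired differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(x - y, 0.0)
    return TTestResult(
        kind="paired",
        t=res.t,
        df=res.df,
        p=res.p,
        effect_size=res.effect_size,
        effect_kind="cohens_d_paired",
        mean_diff=res.mean_diff,
        ci95=res.ci95,
    )


def independent_t(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sided independent-samples t test (pooled or Welch).

    The effect size is Hedges' g: the pooled-SD standardized mean
    difference times the small-sample correction 1 - 3/(4 df - 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance")
    diff = x.mean() - y.mean()
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
        kind = "independent"
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        kind = "welch"
    t = diff / se
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    g = diff / math.sqrt(sp2) * hedges_correction(n1 + n2 - 2)
    half = sps.t.ppf(0.975, df) * se
    return TTestResult(
        kind=kind,
        t=float(t),
        df=float(df),
        p=_t_p(t, df),
        effect_size=float(g),
        effect_kind="hedges_g_independent",
        mean_diff=float(diff),
        ci95=(float(diff - half), float(diff + half)),
    )


# ---------------------------------------------------------------------------
# exact binomial test


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    p0: float
    p: float
    cohens_g: float
    proportion: float


def binomial_test_two_sided(k: int, n: int, p0: float = 0.5) -> BinomialTestResult:
    """Exact two-sided binomial test by tail doubling at p0 = 0.5.

    p = min(1, 2 * P(X >= max(k, n - k))); by the symmetry of the null at
    p0 = 0.5 this equals the usual sum of all outcomes at least as
    extreme.  Cohen's g = |k/n - 0.5|.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if p0 != 0.5:
        raise ValueError("tail doubling is implemented for the symmetric null p0 = 0.5")
    hi = max(k, n - k)
    tail = float(sps.binom.sf(hi - 1, n, 0.5))  # P(X >= hi)
    p = min(1.0, 2.0 * tail)
    return BinomialTestResult(
        k=int(k),
        n=int(n),
        p0=p0,
        p=p,
        cohens_g=abs(k / n - 0.5),
        proportion=k / n,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass(frozen=True)
class RmAnovaEffect:
    name: str
    ss_effect: float
    ss_error: float
    df_num: float
    df_den: float
    F: float
    p_uncorrected: float
    partial_eta_sq: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    hf_epsilon: float
    p_hf: float
    sphericity_violated: bool
    p: float  # the policy p: Huynh-Feldt corrected iff Mauchly rejects


@dataclass(frozen=True)
class RmAnovaResult:
    effects: dict

    def __getitem__(self, name: str) -> RmAnovaEffect:
        return self.effects[name]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (normalized Helmert)."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= math.sqrt(j * (j + 1))
    return c


def _sphericity(z: np.ndarray) -> tuple[float, float, float, float]:
    """Mauchly W and p plus GG and HF epsilons from the contrast scores.

    ``z`` is subjects x p, the effect's orthonormally transformed scores.
    For p = 1 sphericity holds trivially.  Returns (W, p, eps_gg, eps_hf).
    """
    n, p = z.shape
    if p == 1:
        return 1.0, 1.0, 1.0, 1.0
    s = np.cov(z, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    tr = float(np.sum(eig))
    tr2 = float(np.sum(eig**2))
    eps_gg = tr**2 / (p * tr2) if tr2 > 0 else float("nan")
    # Huynh-Feldt, clipped into [1/p, 1]
    denom = p * (n - 1 - p * eps_gg)
    eps_hf = float("nan") if denom <= 0 else (n * p * eps_gg - 2.0) / denom
    if not math.isnan(eps_hf):
        eps_hf = min(1.0, max(eps_hf, 1.0 / p))
    if n - 1 < p or np.any(eig <= 0) or tr <= 0:
        return float("nan"), float("nan"), eps_gg, eps_hf
    w = float(np.prod(eig) / (tr / p) ** p)
    f = 1.0 - (2.0 * p * p + p + 2.0) / (6.0 * p * (n - 1.0))
    chi2 = -(n - 1.0) * f * math.log(max(w, 1e-300))
    df = p * (p + 1) / 2.0 - 1.0
    p_val = float(sps.chi2.sf(chi2, df))
    return w, p_val, eps_gg, eps_hf


def _effect(
    name: str,
    ss_eff: float,
    ss_err: float,
    df_num: float,
    df_den: float,
    z: np.ndarray,
) -> RmAnovaEffect:
    F = (ss_eff / df_num) / (ss_err / df_den) if ss_err > 0 else float("inf")
    p_unc = float(sps.f.sf(F, df_num, df_den))
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    w, w_p, eps_gg, eps_hf = _sphericity(z)
    if math.isnan(eps_hf):
        p_hf = p_unc
    else:
        p_hf = float(sps.f.sf(F, df_num * eps_hf, df_den * eps_hf))
    violated = (not math.isnan(w_p)) and w_p < 0.05
    return RmAnovaEffect(
        name=name,
        ss_effect=float(ss_eff),
        ss_error=float(ss_err),
        df_num=float(df_num),
        df_den=float(df_den),
        F=float(F),
        p_uncorrected=p_unc,
        partial_eta_sq=float(eta),
        mauchly_w=w,
        mauchly_p=w_p,
        gg_epsilon=eps_gg,
        hf_epsilon=eps_hf,
        p_hf=p_hf,
        sphericity_violated=violated,
        p=p_hf if violated else p_unc,
    )


def rm_anova_one_way(data) -> RmAnovaEffect:
    """One-way repeated-measures ANOVA on a subjects x levels matrix.

    The error term is the subject-by-level interaction.  With two levels
    F equals the square of the paired t statistic.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be subjects x levels")
    if np.isnan(y).any():
        raise ValueError("missing cells are not allowed")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 levels")
    grand = y.mean()
    level_m = y.mean(axis=0)
    subj_m = y.mean(axis=1)
    ss_eff = n * np.sum((level_m - grand) ** 2)
    resid = y - level_m[None, :] - subj_m[:, None] + grand
    ss_err = float(np.sum(resid**2))
    z = y @ _orthonormal_contrasts(k)
    return _effect("level", ss_eff, ss_err, k - 1, (k - 1) * (n - 1), z)


def rm_anova_two_way(data, factor_names: tuple[str, str] = ("A", "B")) -> RmAnovaResult:
    """Two-way fully within-subject ANOVA on a subjects x a x b array.

    Each effect (main effect of each factor and their interaction) is
    tested against its own effect-by-subject error term; Mauchly's test
    and the Huynh-Feldt epsilon are computed per effect on the effect's
    orthonormal contrast scores (main effects average over the other
    factor first).  Degenerate single-level factors reduce to the one-way
    decomposition.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("data must be subjects x levelsA x levelsB")
    if np.isnan(y).any():
        raise ValueError("missing cells are not allowed")
    n, a, b = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    na, nb = factor_names
    effects: dict[str, RmAnovaEffect] = {}

    grand = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    y_ia = y.mean(axis=2)
    y_ib = y.mean(axis=1)
    s_i = y.mean(axis=(1, 2))

    if a > 1:
        ss = n * b * np.sum((m_a - grand) ** 2)
        res = y_ia - m_a[None, :] - s_i[:, None] + grand
        ss_err = b * float(np.sum(res**2))
        z = y_ia @ _orthonormal_contrasts(a)
        effects[na] = _effect(na, ss, ss_err, a - 1, (a - 1) * (n - 1), z)
    if b > 1:
        ss = n * a * np.sum((m_b - grand) ** 2)
        res = y_ib - m_b[None, :] - s_i[:, None] + grand
        ss_err = a * float(np.sum(res**2))
        z = y_ib @ _orthonormal_contrasts(b)
        effects[nb] = _effect(nb, ss, ss_err, b - 1, (b - 1) * (n - 1), z)
    if a > 1 and b > 1:
        inter = m_ab - m_a[:, None] - m_b[None, :] + grand
        ss = n * float(np.sum(inter**2))
        res = (
            y
            - y_ia[:, :, None]
            - y_ib[:, None, :]
            + s_i[:, None, None]
            - m_ab[None, :, :]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ss_err = float(np.sum(res**2))
        cm = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
        z = y.reshape(n, a * b) @ cm
        name = f"{na}*{nb}"
        effects[name] = _effect(
            name, ss, ss_err, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), z
        )
    return RmAnovaResult(effects=effects)


def polynomial_trend_contrast(data, order: int = 2) -> RmAnovaEffect:
    """Within-subject orthogonal polynomial trend across ordered levels.

    The trend of the given order (1 = linear, 2 = quadratic, ...) is a
    one-degree-of-freedom contrast; per-subject contrast scores are
    tested against zero, so F equals the square of the paired t on those
    scores.  With three levels the quadratic weights are proportional to
    (1, -2, 1).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be subjects x levels")
    n, k = y.shape
    if k < order + 1:
        raise ValueError(f"need at least {order + 1} levels for order {order}")
    # orthonormal polynomial contrasts via QR of the Vandermonde basis
    t = np.arange(k, dtype=float)
    basis = np.vander(t, order + 1, increasing=True)
    q, _ = np.linalg.qr(basis)
    c = q[:, order]
    scores = y @ c
    sd = scores.std(ddof=1)
    if sd == 0:
        # degenerate identical contrast scores: a mean that is zero up to
        # the floating-point resolution of the inputs counts as zero
        tol = 1e-12 * max(1.0, float(np.abs(y).max()))
        t_stat = 0.0 if abs(scores.mean()) <= tol else float("inf")
    else:
        t_stat = scores.mean() / (sd / math.sqrt(n))
    F = t_stat**2
    df_num, df_den = 1.0, float(n - 1)
    p = float(sps.f.sf(F, df_num, df_den))
    eta = F / (F + df_den) if math.isfinite(F) else 1.0
    return RmAnovaEffect(
        name=f"trend_order_{order}",
        ss_effect=float(n * scores.mean() ** 2),
        ss_error=float((n - 1) * sd**2) if sd > 0 else 0.0,
        df_num=df_num,
        df_den=df_den,
        F=float(F),
        p_uncorrected=p,
        partial_eta_sq=float(eta),
        mauchly_w=1.0,
        mauchly_p=1.0,
        gg_epsilon=1.0,
        hf_epsilon=1.0,
        p_hf=p,
        sphericity_violated=False,
        p=p,
    )


# ---------------------------------------------------------------------------
# Dixon's Q test


# Two-sided critical values of Dixon's r10 ratio at alpha = 0.05
# (Rorabacher 1991, n = 3..30).
_DIXON_R10_05 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
    10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
    16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
    22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
    28: 0.305, 29: 0.301, 30: 0.298,
}


@dataclass(frozen=True)
class DixonResult:
    q_exp: float
    q_crit: float
    outlier: bool
    suspect_value: float
    side: str
    variant: str
    alpha: float


def dixon_q_test(values, variant: str = "r10", alpha: float = 0.05) -> DixonResult:
    """Dixon's Q test for one outlier (variant r10: gap / range).

    Both extremes are examined and the more outlying one (larger gap to
    its neighbor) is the suspect value.  Critical values are tabulated
    for alpha = 0.05 and n = 3..30; other configurations raise.
    """
    if variant != "r10":
        raise ValueError(f"unsupported Dixon variant {variant!r}")
    if alpha != 0.05:
        raise ValueError("critical values are tabulated for alpha = 0.05 only")
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n not in _DIXON_R10_05:
        raise ValueError(f"n = {n} outside the tabulated range 3..30")
    rng = x[-1] - x[0]
    if rng == 0:
        raise ValueError("all values equal: Q is undefined")
    gap_low = x[1] - x[0]
    gap_high = x[-1] - x[-2]
    if gap_high >= gap_low:
        q, suspect, side = gap_high / rng, x[-1], "high"
    else:
        q, suspect, side = gap_low / rng, x[0], "low"
    crit = _DIXON_R10_05[n]
    return DixonResult(
        q_exp=float(q),
        q_crit=crit,
        outlier=bool(q > crit),
        suspect_value=float(suspect),
        side=side,
        variant=variant,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# median split


@dataclass(frozen=True)
class MedianSplitResult:
    lower_idx: np.ndarray
    upper_idx: np.ndarray
    lower_mean: float
    upper_mean: float
    test: TTestResult
    levene_p: float


def median_split_compare(scores, covariate) -> MedianSplitResult:
    """Split subjects at the covariate median and compare their scores.

    The split is on ranks (stable order for ties), so it is invariant to
    monotone transforms of the covariate; with odd n the median subject
    joins the lower group.  Groups are compared with an independent t
    test, switching to Welch when Levene's test rejects equal variances
    at 0.05.
    """
    scores = np.asarray(scores, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if scores.size != cov.size:
        raise ValueError("scores and covariate must have equal length")
    n = scores.size
    if n < 4:
        raise ValueError("need at least 4 subjects to split")
    if np.all(cov == cov[0]):
        raise ValueError("degenerate split: covariate is constant")
    order = np.argsort(cov, kind="stable")
    n_low = (n + 1) // 2
    lower, upper = order[:n_low], order[n_low:]
    lev_p = levene_test(scores[lower], scores[upper]).p
    test = independent_t(scores[lower], scores[upper], equal_var=lev_p >= 0.05)
    return MedianSplitResult(
        lower_idx=lower,
        upper_idx=upper,
        lower_mean=float(scores[lower].mean()),
        upper_mean=float(scores[upper].mean()),
        test=test,
        levene_p=lev_p,
    )


# ---------------------------------------------------------------------------
# assumption checks


@dataclass(frozen=True)
class AssumptionTest:
    name: str
    statistic: float
    p: float


def ks_normality(x, mean: float | None = None, sd: float | None = None) -> AssumptionTest:
    """Kolmogorov-Smirnov goodness of fit against a normal distribution.

    With ``mean``/``sd`` given, the null is fully specified and the exact
    one-sample KS distribution applies; when they are estimated from the
    sample the p-value is conservative (the Lilliefors situation) and
    should be read as an upper bound.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("Kolmogorov-Smirnov normality check needs n >= 4")
    mu = x.mean() if mean is None else mean
    s = x.std(ddof=1) if sd is None else sd
    if s <= 0:
        raise ValueError("zero variance")
    cdf = sps.norm.cdf(x, loc=mu, scale=s)
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))
    p = float(sps.kstwo.sf(d, n))
    return AssumptionTest(name="ks_normality", statistic=d, p=p)


def levene_test(*groups, center: str = "mean") -> AssumptionTest:
    """Levene's test of equal variances: one-way ANOVA on absolute
    deviations from each group's center (mean by default)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("Levene's test needs >= 2 groups with >= 2 observations")
    devs = []
    for g in gs:
        c = np.median(g) if center == "median" else g.mean()
        devs.append(np.abs(g - c))
    n_total = sum(d.size for d in devs)
    k = len(devs)
    grand = np.concatenate(devs).mean()
    ss_between = sum(d.size * (d.mean() - grand) ** 2 for d in devs)
    ss_within = sum(float(np.sum((d - d.mean()) ** 2)) for d in devs)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        return AssumptionTest(name="levene", statistic=float("inf"), p=0.0)
    F = (ss_between / df1) / (ss_within / df2)
    return AssumptionTest(name="levene", statistic=float(F), p=float(sps.f.sf(F, df1, df2)))


def mauchly_test(data) -> AssumptionTest:
    """Mauchly's sphericity test on a subjects x levels matrix."""
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[1] < 3:
        raise ValueError("Mauchly's test needs subjects x levels with >= 3 levels")
    w, p, _, _ = _sphericity(y @ _orthonormal_contrasts(y.shape[1]))
    return AssumptionTest(name="mauchly", statistic=w, p=p)


def assumption_checks(
    data, groups: tuple = (), repeated: np.ndarray | None = None
) -> dict:
    """Run the battery of assumption tests on cohort data.

    ``data`` is checked for normality; ``groups`` (if given) for equal
    variances; ``repeated`` (subjects x levels, if given) for sphericity.
    The caller's test-selection policy: Welch's t when Levene rejects,
    Huynh-Feldt correction when Mauchly rejects.
    """
    out = {"ks_normality": ks_normality(data)}
    if groups:
        out["levene"] = levene_test(*groups)
    if repeated is not None:
        out["mauchly"] = mauchly_test(repeated)
    return out
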