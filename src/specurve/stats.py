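"""Statistical machinery: age residualization, Bayesian and frequentist tests,
effect sizes, Stouffer aggregation, sensitivity analysis, resampling-based FDR
and matched-control subsampling.

Bayes factors follow the JZS family used by the R ``BayesFactor`` package:
for the independent-samples t-test, a Cauchy(0, scale) prior on the
standardized effect (default scale sqrt(2)/2), computed through the
equivalent normal-by-inverse-gamma mixture so the integrand is elementary;
for the Pearson correlation, a stretched-beta prior of width ``w`` on rho
(default 1/3), integrating the exact sampling density of r.  Evidence
categories partition BF10 at 1/10, 1/3, 3 and 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike
from scipy import integrate, optimize, special, stats as sps

__all__ = [
    "BayesResult",
    "EffectSize",
    "MatchingFailureError",
    "residualize",
    "cohens_d",
    "evidence_category",
    "bf_ttest_from_t",
    "bf_ttest_independent",
    "bf_correlation_from_r",
    "bf_correlation",
    "two_sample_test",
    "pearson_test",
    "signed_z_from_p",
    "stouffer_aggregate",
    "detectable_effect_size",
    "resampling_fdr",
    "match_controls",
]

DEFAULT_T_PRIOR_SCALE = math.sqrt(2.0) / 2.0
DEFAULT_R_PRIOR_WIDTH = 1.0 / 3.0


@dataclass(frozen=True)
class BayesResult:
    statistic: float  # t or r
    bf10: float
    n: int
    prior_scale: float
    n2: int | None = None

    @property
    def evidence_category(self) -> str:
        return evidence_category(self.bf10)


@dataclass(frozen=True)
class EffectSize:
    kind: str  # 'cohens_d' | 'pearson_r'
    value: float
    n: int
    n2: int | None = None


class MatchingFailureError(RuntimeError):
    """No acceptable matched control sample found within the iteration budget."""


def evidence_category(bf10: float) -> str:
    """Partition of BF10 at 1/10, 1/3, 3, 10 (no gaps, no overlaps)."""
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    if bf10 < 1.0 / 10.0:
        return "strong_null"
    if bf10 < 1.0 / 3.0:
        return "moderate_null"
    if bf10 <= 3.0:
        return "inconclusive"
    if bf10 <= 10.0:
        return "moderate_alt"
    return "strong_alt"


# ------------------------------------------------------------- basic stats


def residualize(values: ArrayLike, covariate: ArrayLike) -> np.ndarray:
    """Residuals of a simple OLS regression of values on the covariate."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("values and covariate must have equal length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; residualization is degenerate")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def cohens_d(x: ArrayLike, y: ArrayLike) -> EffectSize:
    """Standardized mean difference with the pooled (n1+n2-2) SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return EffectSize(kind="cohens_d", value=float((x.mean() - y.mean()) / math.sqrt(sp2)), n=n1, n2=n2)


# ------------------------------------------------------------ Bayes factors


def bf_ttest_from_t(t: float, n1: int, n2: int, prior_scale: float = DEFAULT_T_PRIOR_SCALE) -> float:
    """Two-sided JZS Bayes factor for an independent-samples t statistic.

    Uses the scale-mixture representation of the Cauchy prior: delta | g ~
    N(0, g), g ~ InvGamma(1/2, scale^2/2), under which the marginal of t
    given g is a scaled central t, leaving a one-dimensional elementary
    integral over g.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    t2 = float(t) ** 2
    r2 = prior_scale**2
    log_null = math.log1p(t2 / nu)

    def integrand(g: float) -> float:
        m = 1.0 + n_eff * g
        log_ratio = math.log1p(t2 / (m * nu)) - log_null
        logpdf = (
            0.5 * math.log(r2 / 2.0)
            - special.gammaln(0.5)
            - 1.5 * math.log(g)
            - r2 / (2.0 * g)
        )
        return math.exp(-0.5 * math.log(m) - 0.5 * (nu + 1) * log_ratio + logpdf)

    val, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(val) or val <= 0 or (val > 0 and err / val > 1e-6):
        raise RuntimeError("Bayes-factor quadrature failed")
    return float(val)


def bf_ttest_independent(
    x: ArrayLike, y: ArrayLike, prior_scale: float = DEFAULT_T_PRIOR_SCALE
) -> BayesResult:
    """JZS Bayes factor for a two-sided independent-samples t-test on data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, _ = two_sample_test(x, y)
    return BayesResult(
        statistic=t,
        bf10=bf_ttest_from_t(t, x.size, y.size, prior_scale),
        n=x.size,
        n2=y.size,
        prior_scale=prior_scale,
    )


def _log_corr_likelihood_ratio(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """log f(r | rho, n) - log f(r | 0, n), exact sampling density of r."""
    c = (rho * r + 1.0) / 2.0
    h = special.hyp2f1(0.5, 0.5, n - 0.5, c)
    h0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return (
        0.5 * (n - 1) * np.log1p(-(rho**2))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(h)
        - np.log(h0)
    )


def bf_correlation_from_r(
    r: float, n: int, prior_width: float = DEFAULT_R_PRIOR_WIDTH
) -> float:
    """Two-sided Bayes factor for a Pearson correlation.

    The prior on rho is the stretched beta: rho = 2*B - 1 with
    B ~ Beta(1/w, 1/w), width w (w=1 is uniform on (-1, 1)).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if prior_width <= 0:
        raise ValueError("prior_width must be positive")
    a = 1.0 / prior_width
    log_prior_norm = -(2.0 * a - 1.0) * math.log(2.0) - special.betaln(a, a)

    def log_integrand(rho: np.ndarray) -> np.ndarray:
        logp = (a - 1.0) * np.log1p(-(rho**2)) + log_prior_norm
        return _log_corr_likelihood_ratio(rho, r, n) + logp

    # normalize in log space: for large n the integrand peaks sharply near
    # rho = r and can overflow a double
    scan = np.linspace(-1 + 1e-9, 1 - 1e-9, 2001)
    offset = float(np.max(log_integrand(scan)))

    def integrand(rho: float) -> float:
        return math.exp(min(log_integrand(np.asarray(rho)) - offset, 700.0))

    val, err = integrate.quad(integrand, -1.0, 1.0, limit=200, points=[0.0, r])
    if not np.isfinite(val) or val <= 0:
        raise RuntimeError("Bayes-factor quadrature failed")
    log_bf = math.log(val) + offset
    if log_bf > 690.0:  # astronomically decisive; keep it finite
        return 1e300
    return float(math.exp(log_bf))


def bf_correlation(
    x: ArrayLike, y: ArrayLike, prior_width: float = DEFAULT_R_PRIOR_WIDTH
) -> BayesResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired data with n >= 4")
    r = float(np.corrcoef(x, y)[0, 1])
    return BayesResult(
        statistic=r,
        bf10=bf_correlation_from_r(r, x.size, prior_width),
        n=x.size,
        prior_scale=prior_width,
    )


# --------------------------------------------------------- frequentist tests


def two_sample_test(x: ArrayLike, y: ArrayLike) -> tuple[float, float]:
    """Pooled-variance (Student) two-sided t-test; returns (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def pearson_test(x: ArrayLike, y: ArrayLike) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-based p-value; returns (r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired data with n >= 4")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def signed_z_from_p(p: float, sign: float) -> float:
    """z = sign * Phi^{-1}(1 - p/2) for a two-sided p-value."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    return float(np.sign(sign) * sps.norm.isf(p / 2.0))


def stouffer_aggregate(p_values: ArrayLike, effect_signs: ArrayLike) -> float:
    """Stouffer aggregate Z = sum(sign_i * z_i) / sqrt(K) over K tests."""
    p = np.asarray(p_values, dtype=float)
    s = np.asarray(effect_signs, dtype=float)
    if p.shape != s.shape or p.size == 0:
        raise ValueError("p_values and effect_signs must have equal nonzero length")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if not np.all(np.isin(s, (-1.0, 0.0, 1.0))):
        raise ValueError("signs must be -1, 0 or +1")
    z = sps.norm.isf(p / 2.0)
    return float(np.sum(s * z) / math.sqrt(p.size))


def detectable_effect_size(
    n1: int, n2: int, alpha: float = 0.05, power: float = 0.95
) -> float:
    """Smallest Cohen's d detectable by a two-tailed two-sample t-test.

    Root-finds the noncentral-t power function with noncentrality
    d*sqrt(n1*n2/(n1+n2)) and df = n1+n2-2 (the sensitivity analysis of
    power calculators such as G*Power).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if not 0.0 < alpha < power < 1.0:
        raise ValueError("need 0 < alpha < power < 1")
    df = n1 + n2 - 2
    tcrit = sps.t.isf(alpha / 2.0, df)
    n_eff = math.sqrt(n1 * n2 / (n1 + n2))

    def achieved_power(d: float) -> float:
        nc = d * n_eff
        val = float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
        if math.isnan(val):  # deep-tail noncentrality: power is numerically 1
            return 1.0
        return val

    lo, hi = 1e-9, 10.0
    if achieved_power(hi) < power:
        raise ValueError("requested power unattainable for d <= 10")
    return float(optimize.brentq(lambda d: achieved_power(d) - power, lo, hi, xtol=1e-10))


# ----------------------------------------------------------- resampling FDR


def resampling_fdr(p_observed: ArrayLike, p_null: ArrayLike) -> np.ndarray:
    """Resampling-based FDR-adjusted p-values.

    ``p_null`` holds per-region p-values from B label-permuted resamples
    (shape B x R).  For each candidate threshold t (the observed p-values)
    the expected false rejections E[V(t)] are estimated as the mean count of
    null p <= t per resample; the estimated FDR(t) = E[V(t)] / max(R(t), 1)
    with R(t) the observed rejections.  The adjusted p of a region is the
    minimum estimated FDR over thresholds >= its own p (hence automatically
    monotone in the raw p), capped at 1.
    """
    p_obs = np.asarray(p_observed, dtype=float)
    null = np.asarray(p_null, dtype=float)
    if null.ndim != 2 or null.shape[1] != p_obs.size:
        raise ValueError(
            f"p_null must have shape (B, {p_obs.size}); got {null.shape}"
        )
    order = np.argsort(p_obs, kind="stable")
    thresholds = p_obs[order]
    n_reject = np.arange(1, p_obs.size + 1, dtype=float)
    # handle ties: rejections at a tied threshold count every p <= t
    for i in range(p_obs.size - 2, -1, -1):
        if thresholds[i] == thresholds[i + 1]:
            n_reject[i] = n_reject[i + 1]
    ev = (null[:, :, np.newaxis] <= thresholds[np.newaxis, np.newaxis, :]).sum(axis=1).mean(axis=0)
    fdr = np.minimum(ev / np.maximum(n_reject, 1.0), 1.0)
    # adjusted p = min FDR over thresholds at or above one's own p
    adj_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    adjusted = np.empty_like(p_obs)
    adjusted[order] = adj_sorted
    return adjusted


# -------------------------------------------------------- matched subsampling


def match_controls(
    cohort: pd.DataFrame,
    subgroup_ids: ArrayLike,
    seed: int = 0,
    bf_threshold: float = 1.0 / 3.0,
    max_iter: int = 1000,
    prior_scale: float = DEFAULT_T_PRIOR_SCALE,
) -> list[str]:
    """Iteratively draw a healthy sample matched in size, dataset, age and gender.

    Each draw takes, per source dataset, as many healthy subjects as the
    subgroup has; the draw is accepted when Bayesian independent-samples
    t-tests on age and on 0/1-coded gender both give BF10 below
    ``bf_threshold`` (moderate evidence for no difference).
    """
    subgroup_ids = list(subgroup_ids)
    sub = cohort[cohort["subject_id"].isin(subgroup_ids)]
    if len(sub) != len(subgroup_ids):
        raise ValueError("subgroup_ids contains unknown subjects")
    healthy = cohort[cohort["group"] == "healthy"]
    if len(healthy) < len(sub):
        raise ValueError(
            f"healthy pool ({len(healthy)}) smaller than subgroup ({len(sub)})"
        )
    counts = sub["dataset"].value_counts().to_dict()
    pools = {ds: healthy[healthy["dataset"] == ds] for ds in sorted(healthy["dataset"].unique())}
    # per-dataset targets, capped by pool size; a deficit (a dataset without
    # enough healthy participants, which the emulated study really has) is
    # reallocated to the datasets with spare capacity, largest pool first
    targets = {ds: min(counts.get(ds, 0), len(pool)) for ds, pool in pools.items()}
    deficit = len(sub) - sum(targets.values())
    for ds in sorted(pools, key=lambda d: -len(pools[d])):
        if deficit <= 0:
            break
        spare = len(pools[ds]) - targets[ds]
        take = min(spare, deficit)
        targets[ds] += take
        deficit -= take
    counts = {ds: k for ds, k in targets.items() if k > 0}
    sub_age = sub["age"].to_numpy(dtype=float)
    sub_gender = (sub["gender"] == "f").to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        chosen = []
        for ds, k in counts.items():
            pool_ids = pools[ds]["subject_id"].to_numpy()
            chosen.extend(rng.choice(pool_ids, size=k, replace=False).tolist())
        samp = healthy[healthy["subject_id"].isin(chosen)]
        bf_age = bf_ttest_independent(sub_age, samp["age"].to_numpy(dtype=float), prior_scale).bf10
        bf_gender = bf_ttest_independent(
            sub_gender, (samp["gender"] == "f").to_numpy(dtype=float), prior_scale
        ).bf10
        if bf_age < bf_threshold and bf_gender < bf_threshold:
            return chosen
    raise MatchingFailureError(
        f"no acceptable matched sample after {max_iter} draws (BF threshold {bf_threshold})"
    )
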