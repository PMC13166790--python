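"""Two-sample MR estimators and diagnostics.

Implements the causal estimators and sensitivity analyses of a standard
two-sample summary-data MR workflow on allele-harmonised effect pairs
(columns ``beta_gx, se_gx, beta_gy, se_gy`` and friends; see
:mod:`mcpmr.sumstats`):

* Wald ratio (single instrument) and inverse-variance weighted (IVW)
  meta-analysis with a multiplicative random-effects variance inflation;
* Cochran's Q heterogeneity statistic;
* Egger regression intercept as the directional-pleiotropy test;
* an MR-PRESSO-style residual-sum global test with per-instrument outlier
  detection by parametric simulation;
* the Steiger directionality test comparing variance explained in exposure
  versus outcome;
* Benjamini-Hochberg FDR adjustment (delegated to statsmodels).

Per-instrument ratio standard errors use the first-order delta
approximation se(beta_gy/beta_gx) ~= se_gy/|beta_gx| by default; a
second-order option adds the exposure-side term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Z975 = 1.959964  # two-sided 95% normal quantile


@dataclass
class MREstimate:
    """Causal effect estimate for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    method: str
    n_snps: int
    beta: float
    se: float
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    pvalue: float = 1.0
    odds_ratio_scale: bool = False

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("MREstimate se must be positive")
        self.ci_low = self.beta - Z975 * self.se
        self.ci_high = self.beta + Z975 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class MRDiagnostics:
    """Heterogeneity, pleiotropy and directionality diagnostics."""

    q_stat: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_pvalue: float | None = None
    presso_global_pvalue: float | None = None
    presso_outlier_ids: list = field(default_factory=list)
    steiger_pvalue: float | None = None
    steiger_correct_direction: bool | None = None


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass
class PressoResult:
    global_pvalue: float
    outlier_ids: list
    outlier_pvalues: dict


def _two_sided_p(z) -> float:
    return float(2.0 * stats.norm.sf(np.abs(z)))


def _ratio_se(beta_gx, se_gx, beta_gy, se_gy, second_order: bool):
    se2 = se_gy**2 / beta_gx**2
    if second_order:
        se2 = se2 + beta_gy**2 * se_gx**2 / beta_gx**4
    return np.sqrt(se2)


def wald_ratio(
    pair,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument causal estimate beta_gy / beta_gx.

    ``pair`` is anything with attributes ``beta_gx, se_gx, beta_gy, se_gy``
    (a ``HarmonizedPair`` or a DataFrame row).
    """
    bx, by = float(pair.beta_gx), float(pair.beta_gy)
    if bx == 0.0:
        raise ValueError("wald_ratio undefined for beta_gx = 0")
    beta = by / bx
    se = float(_ratio_se(bx, float(pair.se_gx), by, float(pair.se_gy),
                         second_order))
    return MREstimate(
        exposure_id=exposure_id, outcome_id=outcome_id, method="wald_ratio",
        n_snps=1, beta=beta, se=se, pvalue=_two_sided_p(beta / se),
    )


def _ratios_weights(pairs: pd.DataFrame, second_order: bool):
    bx = pairs["beta_gx"].to_numpy(dtype=float)
    by = pairs["beta_gy"].to_numpy(dtype=float)
    sx = pairs["se_gx"].to_numpy(dtype=float)
    sy = pairs["se_gy"].to_numpy(dtype=float)
    if np.any(bx == 0.0):
        raise ValueError("beta_gx = 0 in instrument set")
    ratios = by / bx
    se = _ratio_se(bx, sx, by, sy, second_order)
    return ratios, 1.0 / se**2


def ivw(
    pairs: pd.DataFrame,
    model: str = "random",
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    second_order: bool = False,
) -> MREstimate:
    """Inverse-variance weighted meta-analysis of per-SNP Wald ratios.

    ``model="fixed"`` uses se = 1/sqrt(sum w); ``model="random"`` inflates
    the fixed-effect se multiplicatively by sqrt(Q/(k-1)) when Q/(k-1) > 1
    (and is otherwise identical to fixed).  With one instrument both
    degenerate to the Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if len(pairs) == 0:
        raise ValueError("ivw requires at least one instrument")
    if len(pairs) == 1:
        est = wald_ratio(pairs.iloc[0], exposure_id, outcome_id, second_order)
        est.method = f"ivw_{model}"
        return est
    ratios, w = _ratios_weights(pairs, second_order)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if model == "random":
        k = len(ratios)
        q = float(np.sum(w * (ratios - beta) ** 2))
        infl = np.sqrt(q / (k - 1))
        if infl > 1.0:
            se *= infl
    return MREstimate(
        exposure_id=exposure_id, outcome_id=outcome_id, method=f"ivw_{model}",
        n_snps=len(ratios), beta=beta, se=se, pvalue=_two_sided_p(beta / se),
    )


def cochran_q(pairs: pd.DataFrame, second_order: bool = False) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic of the per-SNP ratios around the
    fixed-effect IVW estimate; p from chi-square with k-1 df."""
    if len(pairs) < 2:
        raise ValueError("cochran_q requires at least 2 instruments")
    ratios, w = _ratios_weights(pairs, second_order)
    beta = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - beta) ** 2))
    p = float(stats.chi2.sf(q, len(ratios) - 1))
    return q, p


def egger(
    pairs: pd.DataFrame,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
) -> EggerResult:
    """Egger regression: weighted regression of beta_gy on beta_gx with a
    free intercept (weights 1/se_gy^2) after orienting all beta_gx >= 0.

    A non-zero intercept indicates directional horizontal pleiotropy; the
    intercept is t-tested with k-2 df.
    """
    k = len(pairs)
    if k < 3:
        raise ValueError("egger requires at least 3 instruments")
    bx = pairs["beta_gx"].to_numpy(dtype=float).copy()
    by = pairs["beta_gy"].to_numpy(dtype=float).copy()
    sy = pairs["se_gy"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    w = 1.0 / sy**2
    # weighted least squares with intercept, solved in closed form
    X = np.column_stack([np.ones(k), bx])
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(xtx) * sigma2
    intercept, slope = float(coef[0]), float(coef[1])
    se_i = float(np.sqrt(max(cov[0, 0], 0.0)))
    se_s = float(np.sqrt(max(cov[1, 1], 0.0)))
    # exactly colinear data: zero residual variance, treat as exact fit
    t_i = abs(intercept / se_i) if se_i > 0 else (0.0 if intercept == 0 else np.inf)
    t_s = abs(slope / se_s) if se_s > 0 else (0.0 if slope == 0 else np.inf)
    p_i = float(2.0 * stats.t.sf(t_i, k - 2))
    p_s = float(2.0 * stats.t.sf(t_s, k - 2))
    se_s = se_s if se_s > 0 else np.finfo(float).tiny
    se_i = se_i if se_i > 0 else np.finfo(float).tiny
    slope_est = MREstimate(
        exposure_id=exposure_id, outcome_id=outcome_id, method="egger",
        n_snps=k, beta=slope, se=se_s, pvalue=p_s,
    )
    return EggerResult(slope=slope_est, intercept=intercept,
                       intercept_se=se_i, intercept_pvalue=p_i)


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes (weighted regression through the origin)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso(
    pairs: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO-style global pleiotropy test with outlier detection.

    The observed statistic is the variance-weighted residual sum of squares
    of each instrument around the IVW slope fitted without it.  The null
    distribution comes from ``n_sim`` parametric draws
    beta_gy,j ~ N(slope^(-j) * beta_gx,j, se_gy,j),
    beta_gx,j ~ N(beta_gx,j, se_gx,j); the global p-value is the fraction of
    simulated RSS >= observed (which can be 0 at finite n_sim).  Per-SNP
    outlier p-values compare each observed term with its simulated
    distribution and are flagged at a Bonferroni-corrected threshold.
    """
    k = len(pairs)
    if k < 4:
        raise ValueError("presso requires at least 4 instruments")
    if seed is None:
        raise ValueError("presso requires an explicit seed")
    rng = np.random.default_rng(seed)
    bx = pairs["beta_gx"].to_numpy(dtype=float)
    by = pairs["beta_gy"].to_numpy(dtype=float)
    sx = pairs["se_gx"].to_numpy(dtype=float)
    sy = pairs["se_gy"].to_numpy(dtype=float)
    ids = pairs["SNP"].tolist() if "SNP" in pairs else list(range(k))
    w = 1.0 / sy**2

    loo = _loo_slopes(bx, by, w)
    obs_terms = w * (by - loo * bx) ** 2
    obs_rss = float(np.sum(obs_terms))

    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, k))
    ws = w[None, :]
    sxy = np.sum(ws * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(ws * bx_sim**2, axis=1, keepdims=True)
    loo_sim = (sxy - ws * bx_sim * by_sim) / (sxx - ws * bx_sim**2)
    sim_terms = ws * (by_sim - loo_sim * bx_sim) ** 2
    sim_rss = np.sum(sim_terms, axis=1)

    global_p = float(np.mean(sim_rss >= obs_rss))
    outlier_p = np.mean(sim_terms >= obs_terms[None, :], axis=0)
    flagged = [ids[j] for j in range(k) if outlier_p[j] < outlier_alpha / k]
    return PressoResult(
        global_pvalue=global_p,
        outlier_ids=flagged,
        outlier_pvalues={ids[j]: float(outlier_p[j]) for j in range(k)},
    )


def steiger(
    pairs: pd.DataFrame,
    n_gx: int | None = None,
    n_gy: int | None = None,
) -> tuple[float, bool]:
    """Steiger directionality test over an instrument set.

    Variance explained on each side is summed over instruments using
    R^2 = 2*EAF*(1-EAF)*beta^2 (standardised traits; exposure uses ``eaf``,
    outcome the aligned ``eaf_gy`` when present).  The correlations
    r = sqrt(sum R^2) are compared with Fisher's z transform:
    z = (atanh r_x - atanh r_y) / sqrt(1/(n_gx-3) + 1/(n_gy-3)).

    Returns the two-sided p-value and whether the instruments explain
    strictly more variance in the exposure (ties are conservatively not
    "correct direction").
    """
    if len(pairs) == 0:
        raise ValueError("steiger requires at least one instrument")
    if n_gx is None:
        n_gx = int(np.median(pairs["n_gx"]))
    if n_gy is None:
        n_gy = int(np.median(pairs["n_gy"]))
    if n_gx < 4 or n_gy < 4:
        raise ValueError("steiger requires sample sizes >= 4")
    eaf_x = pairs["eaf"].to_numpy(dtype=float)
    eaf_y = (pairs["eaf_gy"] if "eaf_gy" in pairs else pairs["eaf"]).to_numpy(
        dtype=float
    )
    r2_x = float(np.sum(2 * eaf_x * (1 - eaf_x) * pairs["beta_gx"] ** 2))
    r2_y = float(np.sum(2 * eaf_y * (1 - eaf_y) * pairs["beta_gy"] ** 2))
    if r2_x >= 1.0 or r2_y >= 1.0:
        raise ValueError("summed R^2 >= 1: betas not on standardized scale")
    r_x, r_y = np.sqrt(r2_x), np.sqrt(r2_y)
    denom = np.sqrt(1.0 / (n_gx - 3) + 1.0 / (n_gy - 3))
    z = (np.arctanh(r_x) - np.arctanh(r_y)) / denom
    return _two_sided_p(z), bool(r_x > r_y)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
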