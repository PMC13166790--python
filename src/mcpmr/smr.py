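"""Summary-data-based MR (SMR) and the HEIDI linkage-heterogeneity test.

SMR tests whether a trait's association at a locus is mediated by a
molecular exposure (here, a circulating protein) using only the top
cis-QTL: with z_gx = beta_gx/se_gx and z_gy = beta_gy/se_gy,

    b_smr = beta_gy / beta_gx
    T_smr = z_gx^2 * z_gy^2 / (z_gx^2 + z_gy^2)  ~  chi-square(1).

A significant SMR test cannot distinguish one shared causal variant from
two distinct variants in LD.  HEIDI (heterogeneity in dependent
instruments) tests the latter: under a single shared causal variant every
SNP in LD with the top QTL estimates the same ratio b_i, so the deviations
d_i = b_i - b_top are jointly zero-mean.  Their covariance follows from
first-order error propagation plus the LD-induced correlation of marginal
z-scores; the test statistic sum_i (d_i/sd_i)^2 is referred to the
distribution of the corresponding quadratic form in correlated normals
(eigenvalue-weighted chi-square mixture, Imhof's method, with a
Satterthwaite fallback).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .sumstats import LDMatrix

logger = logging.getLogger(__name__)

HEIDI_DEFAULTS = dict(r2_min=0.05, r2_max=0.9, max_snps=20, p_expo_max=1.57e-3)


@dataclass
class SMRResult:
    """SMR estimate at the top cis-QTL, with optional HEIDI p-value.

    ``heidi_p`` is None when fewer than the minimum number of eligible LD
    SNPs exist (reported as "NA" in text output)."""

    probe_id: str
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    heidi_p: float | None = None
    n_heidi_snps: int = 0


def mixture_chi2_sf(q: float, lambdas: np.ndarray) -> float:
    """Upper tail P(sum_i lambda_i * chi2_1 > q) by Imhof's method.

    Falls back to a two-moment Satterthwaite approximation when the
    numerical integration fails."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    if q <= 0:
        return 1.0
    # equal weights: the mixture is an exactly scaled chi-square
    if np.ptp(lam) <= 1e-10 * lam.max():
        return float(stats.chi2.sf(q / lam.mean(), lam.size))

    def imhof_integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(imhof_integrand, 0, np.inf,
                                      limit=800, epsabs=1e-12)
        p = 0.5 + val / np.pi
        if np.isfinite(p) and err < 1e-4:
            return float(min(max(p, 0.0), 1.0))
    except Exception:  # pragma: no cover - defensive
        pass
    logger.debug("Imhof integration failed; Satterthwaite fallback")
    a = np.sum(lam**2) / np.sum(lam)
    d = np.sum(lam) ** 2 / np.sum(lam**2)
    return float(stats.chi2.sf(q / a, d))


def smr_test(pair, probe_id: str = "probe") -> SMRResult:
    """SMR test at the top QTL (no HEIDI).

    ``pair`` carries ``beta_gx, se_gx, beta_gy, se_gy`` and optionally
    ``SNP``."""
    bx, by = float(pair.beta_gx), float(pair.beta_gy)
    sx, sy = float(pair.se_gx), float(pair.se_gy)
    if bx == 0.0:
        raise ValueError("smr_test undefined for beta_gx = 0")
    z_gx, z_gy = bx / sx, by / sy
    b_smr = by / bx
    denom = z_gx**2 + z_gy**2
    t_smr = (z_gx**2 * z_gy**2 / denom) if denom > 0 else 0.0
    p_smr = float(stats.chi2.sf(t_smr, 1))
    se_smr = abs(b_smr) / np.sqrt(t_smr) if t_smr > 0 else np.inf
    top = str(getattr(pair, "SNP", getattr(pair, "snp_id", "top")))
    return SMRResult(probe_id=probe_id, top_snp=top, b_smr=b_smr,
                     se_smr=float(se_smr), p_smr=p_smr)


def _heidi_covariance(bx, sx, by, sy, r):
    """Covariance of the per-SNP ratio estimates b_i = beta_gy,i/beta_gx,i.

    Two-sample design: exposure and outcome errors independent; marginal
    z-score correlation across SNPs equals the signed allelic LD r_ij on
    each side.  First-order delta propagation of b = y/x gives

        cov(b_i, b_j) = r_ij * [ sy_i*sy_j + b_i*b_j*sx_i*sx_j ] / (x_i*x_j)
    """
    b = by / bx
    num = np.outer(sy, sy) + np.outer(b, b) * np.outer(sx, sx)
    return r * num / np.outer(bx, bx)


def heidi_test(
    locus: pd.DataFrame,
    ld: LDMatrix,
    top_snp: str,
    r2_min: float = HEIDI_DEFAULTS["r2_min"],
    r2_max: float = HEIDI_DEFAULTS["r2_max"],
    max_snps: int = HEIDI_DEFAULTS["max_snps"],
    p_expo_max: float = HEIDI_DEFAULTS["p_expo_max"],
    min_snps: int = 3,
) -> tuple[float | None, int]:
    """HEIDI test around ``top_snp`` on a harmonised locus frame.

    Eligible SNPs have r2_min < r^2(snp, top) < r2_max and exposure
    p < ``p_expo_max``; up to ``max_snps`` are kept, most significant
    exposure association first.  Returns ``(heidi_p, n_used)``;
    ``heidi_p`` is None (test not performable) when fewer than ``min_snps``
    SNPs are eligible.
    """
    if top_snp not in set(locus["SNP"]):
        raise ValueError(f"top SNP {top_snp!r} not in locus")
    if top_snp not in ld:
        raise ValueError(f"top SNP {top_snp!r} not in LD matrix")

    cand = locus.loc[locus["SNP"] != top_snp].copy()
    cand = cand.loc[[s in ld for s in cand["SNP"]]]
    if cand.empty:
        return None, 0
    r2_top = np.array([ld.r2(s, top_snp) for s in cand["SNP"]])
    z_gx = cand["beta_gx"] / cand["se_gx"]
    p_expo = 2 * stats.norm.sf(np.abs(z_gx))
    cand = cand.loc[(r2_top > r2_min) & (r2_top < r2_max) & (p_expo < p_expo_max)]
    if len(cand) < min_snps:
        return None, len(cand)
    cand = cand.assign(_absz=np.abs(cand["beta_gx"] / cand["se_gx"]))
    cand = cand.sort_values(["_absz", "SNP"], ascending=[False, True],
                            kind="mergesort").head(max_snps)

    snps = [top_snp] + cand["SNP"].tolist()
    top_row = locus.loc[locus["SNP"] == top_snp].iloc[0]
    bx = np.concatenate([[top_row.beta_gx], cand["beta_gx"].to_numpy(float)])
    sx = np.concatenate([[top_row.se_gx], cand["se_gx"].to_numpy(float)])
    by = np.concatenate([[top_row.beta_gy], cand["beta_gy"].to_numpy(float)])
    sy = np.concatenate([[top_row.se_gy], cand["se_gy"].to_numpy(float)])
    r = ld.subset(snps).r

    cov_b = _heidi_covariance(bx, sx, by, sy, r)
    k = len(snps) - 1
    # d_i = b_i - b_top, i = 1..k
    b = by / bx
    d = b[1:] - b[0]
    cov_d = (
        cov_b[1:, 1:]
        - cov_b[1:, [0]]
        - cov_b[[0], 1:]
        + cov_b[0, 0]
    )
    sd = np.sqrt(np.diag(cov_d))
    t = float(np.sum((d / sd) ** 2))
    corr = cov_d / np.outer(sd, sd)
    lam = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    p = mixture_chi2_sf(t, lam)
    return p, k


def smr_heidi(
    locus: pd.DataFrame,
    ld: LDMatrix,
    probe_id: str = "probe",
    p_top_threshold: float = 5e-8,
    **heidi_kwargs,
) -> SMRResult:
    """Run SMR at the most significant exposure SNP of a locus, then HEIDI.

    Raises ``ValueError`` when no SNP reaches ``p_top_threshold`` on the
    exposure (no top QTL to test)."""
    z = (locus["beta_gx"] / locus["se_gx"]).abs()
    p_expo = 2 * stats.norm.sf(z)
    if not np.any(p_expo < p_top_threshold):
        raise ValueError(f"no exposure SNP reaches p < {p_top_threshold}")
    top_idx = int(np.argmax(z.to_numpy()))
    top_row = locus.iloc[top_idx]
    res = smr_test(top_row, probe_id=probe_id)
    heidi_p, n_used = heidi_test(locus, ld, str(top_row.SNP), **heidi_kwargs)
    res.heidi_p = heidi_p
    res.n_heidi_snps = n_used
    return res
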