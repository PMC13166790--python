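"""Cis-pQTL instrument selection and instrument-strength statistics.

A genetic instrument for a circulating protein is a cis-acting pQTL:
genome-wide significant (default p < 5e-8), within 1 Mb of the transcription
start site of the protein-coding gene, outside the MHC region
(chr6 26-34 Mb, whose long-range LD confounds colocalisation), pruned to
near-independence by greedy LD clumping (r^2 < 0.001 within a 10 Mb window)
and strong enough to avoid weak-instrument bias (F > 10).

Instrument strength uses the standard approximations for a
variance-standardised quantitative trait:

    R^2 = 2 * EAF * (1 - EAF) * beta^2        (variance explained)
    F   = R^2 * (N - 2) / (1 - R^2)

so BETA must be on a standardised-trait scale for R^2 to be a variance
fraction; callers assert this via the ``standardized`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, VariantAssociation

logger = logging.getLogger(__name__)

MHC_REGION = ("6", 26_000_000, 34_000_000)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene location: chromosome and transcription start site (1-based bp)."""

    gene_id: str
    chrom: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"tss {self.tss} < 1")


@dataclass(frozen=True)
class Instrument:
    """A selected instrument with its strength statistics."""

    variant: VariantAssociation
    r2: float
    f_stat: float
    is_cis: bool


def read_gene_annotation(path) -> dict[str, GeneAnnotation]:
    """Read a tab-separated ``gene_id  chrom  tss`` table."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return {
        row.gene_id: GeneAnnotation(row.gene_id, str(row.chrom), int(row.tss))
        for row in df.itertuples(index=False)
    }


def compute_strength(eaf, beta, n) -> tuple:
    """Variance explained and F-statistic of one variant (vectorised).

    Raises ``ValueError`` if R^2 >= 1 (malformed input: such a beta cannot
    come from a standardised trait).
    """
    eaf = np.asarray(eaf, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = np.asarray(n, dtype=float)
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    if np.any(r2 >= 1.0):
        raise ValueError("R^2 >= 1: beta is not on a standardized-trait scale")
    f = r2 * (n - 2.0) / (1.0 - r2)
    if r2.ndim == 0:
        return float(r2), float(f)
    return r2, f


def add_strength(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a sumstats frame with R2 and F columns appended."""
    r2, f = compute_strength(df["EAF"].to_numpy(), df["BETA"].to_numpy(),
                             df["N"].to_numpy())
    out = df.copy()
    out["R2"] = r2
    out["F"] = f
    return out


def variant_strength(v: VariantAssociation) -> tuple[float, float]:
    return compute_strength(v.eaf, v.beta, v.n)


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix | None,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> pd.DataFrame:
    """Greedy LD clumping of a sumstats frame.

    Sort ascending by p-value (ties broken by chromosome, position, SNP id);
    accept the best remaining SNP, discard every candidate on the same
    chromosome within ``window_kb`` whose r^2 with an accepted SNP is
    >= ``r2_max``; repeat.  SNPs absent from the LD matrix are treated as
    unlinked and logged.
    """
    if candidates.empty:
        return candidates.copy()
    order = candidates.sort_values(
        ["P", "CHR", "POS", "SNP"], kind="mergesort"
    ).reset_index(drop=True)
    if ld is not None:
        missing = [s for s in order["SNP"] if s not in ld]
        if missing:
            logger.warning(
                "ld_clump: %d SNPs absent from LD matrix treated as unlinked "
                "(first: %s)", len(missing), missing[0],
            )
    accepted: list[int] = []
    window_bp = window_kb * 1000
    for i in range(len(order)):
        snp_i = order.at[i, "SNP"]
        chr_i = order.at[i, "CHR"]
        pos_i = order.at[i, "POS"]
        dominated = False
        for j in accepted:
            if order.at[j, "CHR"] != chr_i:
                continue
            if abs(int(order.at[j, "POS"]) - int(pos_i)) > window_bp:
                continue
            snp_j = order.at[j, "SNP"]
            if ld is not None and snp_i in ld and snp_j in ld:
                if ld.r2(snp_i, snp_j) >= r2_max:
                    dominated = True
                    break
        if not dominated:
            accepted.append(i)
    return order.loc[accepted].reset_index(drop=True)


def select_cis_instruments(
    sumstats: pd.DataFrame,
    gene: GeneAnnotation,
    ld: LDMatrix | None,
    p_threshold: float = 5e-8,
    cis_kb: int = 1000,
    mhc: tuple = MHC_REGION,
    f_min: float = 10.0,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    standardized: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Select cis-pQTL instruments for one protein.

    Filters, in order: genome-wide significance, cis window (closed interval
    of ``cis_kb`` kb around the TSS on the gene's chromosome), MHC
    exclusion (closed interval, variant position), LD clumping, F-statistic.
    Returns the retained frame (with R2/F columns) and per-filter attrition
    counts.  Refuses F-filtering when betas are not flagged as
    standardised-scale.
    """
    if gene is None:
        raise ValueError("missing gene annotation")
    if not standardized:
        raise ValueError(
            "F-statistic filtering requires betas on a standardized-trait "
            "scale; set standardized=True only when this holds"
        )
    attrition: dict[str, int] = {"input": len(sumstats)}

    df = sumstats.loc[sumstats["P"] < p_threshold]
    attrition["significant"] = len(df)

    cis_bp = cis_kb * 1000
    in_cis = (df["CHR"].astype(str) == gene.chrom) & (
        (df["POS"] - gene.tss).abs() <= cis_bp
    )
    df = df.loc[in_cis]
    attrition["cis"] = len(df)

    mhc_chrom, mhc_lo, mhc_hi = mhc
    in_mhc = (df["CHR"].astype(str) == str(mhc_chrom)) & (
        (df["POS"] >= mhc_lo) & (df["POS"] <= mhc_hi)
    )
    df = df.loc[~in_mhc]
    attrition["non_mhc"] = len(df)

    df = ld_clump(df, ld, r2_max=r2_max, window_kb=window_kb)
    attrition["clumped"] = len(df)

    df = add_strength(df)
    df = df.loc[df["F"] > f_min].reset_index(drop=True)
    attrition["strong"] = len(df)
    return df, attrition


def select_genomewide_instruments(
    sumstats: pd.DataFrame,
    ld: LDMatrix | None,
    p_threshold: float = 5e-8,
    f_min: float = 10.0,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> pd.DataFrame:
    """Instrument selection without the cis restriction (reverse MR and
    risk-factor exposures): significance, clumping, F only."""
    df = sumstats.loc[sumstats["P"] < p_threshold]
    df = ld_clump(df, ld, r2_max=r2_max, window_kb=window_kb)
    df = add_strength(df)
    return df.loc[df["F"] > f_min].reset_index(drop=True)
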