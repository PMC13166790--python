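"""Reading, validation and allele harmonisation of GWAS summary statistics.

The in-memory container for a set of per-SNP marginal association results is
a pandas DataFrame with the canonical columns

    SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N

(effect allele EA, other allele OA, effect-allele frequency EAF, per-allele
effect BETA with standard error SE, two-sided p-value P, sample size N).
``VariantAssociation`` is the validated single-record view of one row.

Harmonisation aligns an outcome set onto the exposure's effect alleles, the
prerequisite of any two-sample MR analysis: swapped allele labels flip the
sign of the outcome effect, palindromic (A/T, C/G) variants with ambiguous
strand are resolved by allele frequency or dropped near EAF 0.5, and
incompatible allele pairs are removed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_ALLELE_RE = re.compile(r"^[ACGT]+$")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = [
    "SNP", "CHR", "POS", "beta_gx", "se_gx", "beta_gy", "se_gy",
    "eaf", "eaf_gy", "n_gx", "n_gy", "flipped", "palindromic",
]


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's marginal GWAS result for one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if not _ALLELE_RE.match(self.effect_allele or ""):
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if not _ALLELE_RE.match(self.other_allele or ""):
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele identical")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"eaf {self.eaf} outside (0,1)")
        if not self.se > 0.0:
            raise ValueError(f"se {self.se} not positive")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"pvalue {self.pvalue} outside (0,1]")
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} < 1")
        if self.n < 2:
            raise ValueError(f"n {self.n} < 2")


@dataclass
class TraitMeta:
    """Trait-level metadata carried alongside a summary-statistics table."""

    trait_id: str
    n_total: int
    trait_type: str = "quantitative"
    n_cases: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.n_cases is not None and self.n_cases > self.n_total:
            raise ValueError("n_cases exceeds n_total")


@dataclass
class LDMatrix:
    """Signed pairwise allelic correlations for an ordered set of SNPs."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match snp_ids")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValueError("|r| exceeds 1")
        if np.any(np.abs(np.diag(self.r) - 1.0) > 1e-8):
            raise ValueError("LD diagonal not 1")
        if np.any(np.abs(self.r - self.r.T) > 1e-8):
            raise ValueError("LD matrix not symmetric")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != k:
            raise ValueError("duplicate SNP ids in LD matrix")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r_of(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r_of(a, b) ** 2

    def subset(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating the record invariants; count each reason."""
    rejections: dict[str, int] = {}
    ea = df["EA"].astype(str).str.upper()
    oa = df["OA"].astype(str).str.upper()
    checks = {
        "bad_allele": ~(ea.str.match(_ALLELE_RE) & oa.str.match(_ALLELE_RE)),
        "identical_alleles": ea == oa,
        "eaf_out_of_range": ~((df["EAF"] > 0) & (df["EAF"] < 1)),
        "nonpositive_se": ~(df["SE"] > 0),
        "pvalue_out_of_range": ~((df["P"] > 0) & (df["P"] <= 1)),
        "pos_below_one": df["POS"] < 1,
        "n_below_two": df["N"] < 2,
        "missing_value": df[CANONICAL_COLUMNS].isna().any(axis=1),
    }
    bad = pd.Series(False, index=df.index)
    for reason, mask in checks.items():
        mask = mask.fillna(True)
        new = mask & ~bad
        if new.any():
            rejections[reason] = int(new.sum())
        bad |= mask
    out = df.loc[~bad].copy()
    out["EA"] = ea.loc[~bad]
    out["OA"] = oa.loc[~bad]
    out["CHR"] = out["CHR"].astype(str)
    out["POS"] = out["POS"].astype(int)
    out["N"] = out["N"].astype(int)
    return out, rejections


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a delimited summary-statistics file.

    ``column_map`` maps file column names onto canonical names, e.g.
    ``{"A1": "EA"}``.  Rows violating the record invariants are dropped and
    counted in the returned rejection log.

    Raises ``ValueError`` if the file is empty or a required column is
    missing (the error names the column).
    """
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty summary-statistics file: {path}") from None
    if df.empty:
        raise ValueError(f"no data rows in summary-statistics file: {path}")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    df = df[CANONICAL_COLUMNS]
    out, rejections = _validate_frame(df)
    if rejections:
        logger.info("read_sumstats(%s): rejected %s", path, rejections)
    return out.reset_index(drop=True), rejections


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a canonical-column summary-statistics table as TSV."""
    df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LDMatrix:
    """Read a square TSV LD matrix with SNP ids on first row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError("LD matrix is not square")
    if list(df.index) != list(df.columns):
        raise ValueError("LD matrix row/column ids disagree")
    return LDMatrix([str(s) for s in df.index], df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def records_to_frame(records: Sequence[VariantAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "POS": [r.pos for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "P": [r.pvalue for r in records],
            "N": [r.n for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[VariantAssociation]:
    return [
        VariantAssociation(
            snp_id=row.SNP, chrom=str(row.CHR), pos=int(row.POS),
            effect_allele=row.EA, other_allele=row.OA, eaf=float(row.EAF),
            beta=float(row.BETA), se=float(row.SE), pvalue=float(row.P),
            n=int(row.N),
        )
        for row in df.itertuples(index=False)
    ]


@dataclass
class HarmonizedPair:
    """Allele-aligned exposure/outcome effect pair for one SNP.

    The exposure's effect allele is the reference orientation; ``flipped``
    records whether the outcome effect had to be sign-flipped.
    """

    snp_id: str
    beta_gx: float
    se_gx: float
    beta_gy: float
    se_gy: float
    eaf: float
    n_gx: int
    n_gy: int
    flipped: bool = False
    palindromic_dropped: bool = False


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    # indels (multi-base alleles) are never treated as palindromic
    single = (ea.str.len() == 1) & (oa.str.len() == 1)
    comp = ea.map(_COMPLEMENT)
    return single & (comp == oa)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_window: float = 0.08,
) -> pd.DataFrame:
    """Align outcome effects onto the exposure's effect alleles.

    Returns a DataFrame with ``HARMONIZED_COLUMNS``.  SNPs absent from
    either side are dropped; swapped allele labels negate the outcome beta
    and complement its EAF; palindromic SNPs are resolved by frequency
    concordance, or dropped when either trait's EAF lies within
    ``palindrome_eaf_window`` of 0.5; incompatible allele pairs are dropped.

    Raises ``ValueError`` on duplicate SNP ids within either input.
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        dup = df["SNP"][df["SNP"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate SNP id in {name}: {dup.iloc[0]!r}")

    m = exposure.merge(outcome, on="SNP", suffixes=("_x", "_y"), how="inner")
    if m.empty:
        return pd.DataFrame(columns=HARMONIZED_COLUMNS)

    direct = (m["EA_x"] == m["EA_y"]) & (m["OA_x"] == m["OA_y"])
    swapped = (m["EA_x"] == m["OA_y"]) & (m["OA_x"] == m["EA_y"])
    palin = _is_palindromic(m["EA_x"], m["OA_x"]) & _is_palindromic(
        m["EA_y"], m["OA_y"]
    )

    keep = direct | swapped
    n_incompatible = int((~keep).sum())
    if n_incompatible:
        logger.info("harmonize: dropped %d allele-incompatible SNPs", n_incompatible)
    m = m.loc[keep].copy()
    direct, swapped, palin = direct[keep], swapped[keep], palin[keep]

    # Non-palindromic: orientation follows the allele labels.
    flipped = swapped & ~palin

    # Palindromic: labels are strand-ambiguous; orient by frequency
    # concordance, but drop when either frequency is too close to 0.5.
    ambiguous = palin & (
        ((m["EAF_x"] - 0.5).abs() < palindrome_eaf_window)
        | ((m["EAF_y"] - 0.5).abs() < palindrome_eaf_window)
    )
    n_palin_dropped = int(ambiguous.sum())
    discordant = palin & ~ambiguous & (
        np.sign(m["EAF_x"] - 0.5) != np.sign(m["EAF_y"] - 0.5)
    )
    flipped = flipped | discordant

    m = m.loc[~ambiguous]
    flipped = flipped[~ambiguous].to_numpy(dtype=bool)
    palin = palin[~ambiguous].to_numpy(dtype=bool)
    if n_palin_dropped:
        logger.info(
            "harmonize: dropped %d palindromic SNPs with EAF near 0.5",
            n_palin_dropped,
        )

    beta_gy = np.where(flipped, -m["BETA_y"], m["BETA_y"])
    eaf_gy = np.where(flipped, 1.0 - m["EAF_y"], m["EAF_y"])
    out = pd.DataFrame(
        {
            "SNP": m["SNP"].to_numpy(),
            "CHR": m["CHR_x"].astype(str).to_numpy(),
            "POS": m["POS_x"].to_numpy(dtype=int),
            "beta_gx": m["BETA_x"].to_numpy(dtype=float),
            "se_gx": m["SE_x"].to_numpy(dtype=float),
            "beta_gy": beta_gy.astype(float),
            "se_gy": m["SE_y"].to_numpy(dtype=float),
            "eaf": m["EAF_x"].to_numpy(dtype=float),
            "eaf_gy": eaf_gy.astype(float),
            "n_gx": m["N_x"].to_numpy(dtype=int),
            "n_gy": m["N_y"].to_numpy(dtype=int),
            "flipped": flipped,
            "palindromic": palin,
        }
    )
    return out.reset_index(drop=True)
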