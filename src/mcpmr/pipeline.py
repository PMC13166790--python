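"""Orchestration of the full proteome-wide MR workflow.

Stages, in order: discovery MR of every protein against the outcome
(cis-pQTL instruments, Wald ratio or IVW, BH-FDR), replication in a second
pQTL set (nominal p < 0.05 with consistent direction), reverse MR and
Steiger directionality, SMR/HEIDI, colocalization, evidence tiering,
mediation screen (risk factor -> protein -> outcome), and phenome-wide MR
of the identified proteins.  Every threshold lives in :class:`RunConfig`
and is echoed into the run log; reruns with the same config and seed are
byte-identical.

Tier rules: a protein with no replication evidence is tier 3; a replicated
protein that fails any validation (SMR, HEIDI, colocalization, reverse MR,
Steiger) is tier 2; a replicated protein passing all of them is tier 1.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coloc import coloc as run_coloc, coloc_report_row
from . import estimators as est
from .instruments import (
    GeneAnnotation,
    read_gene_annotation,
    select_cis_instruments,
    select_genomewide_instruments,
)
from .mediation import mediate
from .simulate import PhewasOutcome, Study
from .smr import smr_heidi
from .sumstats import (
    LDMatrix,
    TraitMeta,
    harmonize,
    read_ld_matrix,
    read_sumstats,
    write_ld_matrix,
    write_sumstats,
)

logger = logging.getLogger(__name__)

REPORT_NAMES = (
    "discovery", "replication", "reverse", "smr_heidi", "coloc",
    "tiers", "mediation", "phewas",
)

TIER_FLAGS = ("replicated", "smr_pass", "heidi_pass", "coloc_pass",
              "reverse_null", "steiger_pass")


@dataclass
class RunConfig:
    """All thresholds of the workflow.  ``from_dict``/``from_yaml`` require
    every field to be present, so a run can always be reproduced from its
    config file alone."""

    seed: int
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    cis_kb: int = 1000
    mhc_chrom: str = "6"
    mhc_start: int = 26_000_000
    mhc_end: int = 34_000_000
    f_min: float = 10.0
    fdr_alpha: float = 0.05
    ivw_model: str = "random"
    second_order_se: bool = False
    replication_alpha: float = 0.05
    reverse_alpha: float = 0.05
    steiger_alpha: float = 0.05
    heterogeneity_alpha: float = 0.05
    pleiotropy_alpha: float = 0.05
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    smr_p_top: float = 5e-8
    smr_alpha: float = 0.05
    heidi_r2_min: float = 0.05
    heidi_r2_max: float = 0.9
    heidi_max_snps: int = 20
    heidi_p_expo_max: float = 1.57e-3
    heidi_pass_threshold: float = 0.01
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_window_kb: int = 500
    coloc_prior_sd_quant: float = 0.15
    coloc_prior_sd_binary: float = 0.2
    pph4_strong: float = 0.8
    coloc_pass_threshold: float = 0.6
    mediation_fdr_alpha: float = 0.05
    sobel_alpha: float = 0.05
    phewas_min_cases: int = 500
    palindrome_eaf_window: float = 0.08

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        missing = sorted(names - set(d))
        if missing:
            raise ValueError(f"config missing required field(s): {missing}")
        unknown = sorted(set(d) - names)
        if unknown:
            raise ValueError(f"config has unknown field(s): {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def log_lines(self) -> list[str]:
        return [f"{k} = {v}" for k, v in
                sorted(dataclasses.asdict(self).items())]


@dataclass
class TierAssignment:
    protein_id: str
    tier: int
    flags: dict = field(default_factory=dict)


def classify_tier(protein_id: str, flags: dict) -> TierAssignment:
    """Deterministic tier from the evidence flags.

    ``replicated`` may be None ("unavailable"); an unavailable or failed
    replication is tier 3.  A validation flag that is None (test not
    performable, e.g. HEIDI with too few LD SNPs) does not count as a
    failure.  Raises ``ValueError`` for a replicated protein with no SMR
    result (pipeline bug).
    """
    replicated = flags.get("replicated")
    if not replicated:
        return TierAssignment(protein_id, 3, dict(flags))
    if flags.get("smr_pass") is None:
        raise ValueError(f"{protein_id}: replicated but SMR result missing")
    validations = [flags.get(k) for k in
                   ("smr_pass", "heidi_pass", "coloc_pass",
                    "reverse_null", "steiger_pass")]
    any_failed = any(v is not None and not bool(v) for v in validations)
    if any_failed:
        return TierAssignment(protein_id, 2, dict(flags))
    return TierAssignment(protein_id, 1, dict(flags))


def _mr_estimate(pairs: pd.DataFrame, config: RunConfig,
                 exposure_id: str, outcome_id: str) -> est.MREstimate:
    if len(pairs) == 1:
        return est.wald_ratio(pairs.iloc[0], exposure_id, outcome_id,
                              config.second_order_se)
    return est.ivw(pairs, config.ivw_model, exposure_id, outcome_id,
                   config.second_order_se)


def _select_protein_instruments(sumstats, gene, ld, config: RunConfig):
    instr, attrition = select_cis_instruments(
        sumstats, gene, ld,
        p_threshold=config.p_threshold, cis_kb=config.cis_kb,
        mhc=(config.mhc_chrom, config.mhc_start, config.mhc_end),
        f_min=config.f_min, r2_max=config.clump_r2,
        window_kb=config.clump_window_kb,
    )
    return instr, attrition


def run_discovery(
    proteins: dict,
    genes: dict,
    outcome: pd.DataFrame,
    ld: LDMatrix,
    config: RunConfig,
    outcome_id: str = "outcome",
) -> tuple[pd.DataFrame, dict]:
    """Proteome-wide MR of every protein on the outcome.

    Returns the per-protein report (estimate, diagnostics, q-value,
    significance at FDR < ``fdr_alpha``) and the dict of harmonized
    instrument sets for downstream stages.  Proteins with no surviving
    instrument are reported as untestable, not as null.
    """
    if outcome is None or len(outcome) == 0:
        raise ValueError("outcome summary statistics missing")
    rows = []
    pairs_by_protein: dict[str, pd.DataFrame] = {}
    for i, pid in enumerate(sorted(proteins)):
        gene = genes.get(pid)
        if gene is None:
            raise ValueError(f"missing gene annotation for {pid}")
        instr, attrition = _select_protein_instruments(
            proteins[pid], gene, ld, config)
        row = {"protein": pid, "n_instruments": len(instr),
               "status": "tested"}
        if len(instr) == 0:
            row.update(status="untestable", method=None, beta=np.nan,
                       se=np.nan, pvalue=np.nan)
            rows.append(row)
            continue
        pairs = harmonize(instr, outcome, config.palindrome_eaf_window)
        if len(pairs) == 0:
            row.update(status="untestable", method=None, beta=np.nan,
                       se=np.nan, pvalue=np.nan)
            rows.append(row)
            continue
        pairs_by_protein[pid] = pairs
        e = _mr_estimate(pairs, config, pid, outcome_id)
        row.update(
            n_instruments=len(pairs), method=e.method, beta=e.beta, se=e.se,
            ci_low=e.ci_low, ci_high=e.ci_high, pvalue=e.pvalue,
            odds_ratio=e.odds_ratio,
        )
        if len(pairs) >= 2:
            q, qp = est.cochran_q(pairs, config.second_order_se)
            row.update(q_stat=q, q_pvalue=qp)
        if len(pairs) >= 3:
            eg = est.egger(pairs, pid, outcome_id)
            row.update(egger_intercept=eg.intercept,
                       egger_intercept_pvalue=eg.intercept_pvalue)
        if len(pairs) >= 4:
            pr = est.presso(pairs, config.presso_n_sim,
                            seed=config.seed + 7919 * (i + 1),
                            outlier_alpha=config.presso_alpha)
            row.update(presso_global_pvalue=pr.global_pvalue,
                       presso_outliers=";".join(map(str, pr.outlier_ids)))
        rows.append(row)
    report = pd.DataFrame(rows)
    tested = report["status"] == "tested"
    report["qvalue"] = np.nan
    if tested.any():
        report.loc[tested, "qvalue"] = est.bh_fdr(
            report.loc[tested, "pvalue"].to_numpy())
    report["significant"] = report["qvalue"] < config.fdr_alpha
    return report, pairs_by_protein


def run_replication(
    replication: dict,
    genes: dict,
    outcome: pd.DataFrame,
    ld: LDMatrix,
    discovery: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Replication MR: re-estimate each protein with the replication pQTL
    set; replicated = nominal p < ``replication_alpha`` with direction
    consistent with discovery."""
    disc_beta = dict(zip(discovery["protein"], discovery["beta"]))
    rows = []
    for pid in sorted(replication):
        gene = genes.get(pid)
        if gene is None:
            continue
        instr, _ = _select_protein_instruments(
            replication[pid], gene, ld, config)
        if len(instr) == 0:
            rows.append({"protein": pid, "status": "untestable",
                         "replicated": None})
            continue
        pairs = harmonize(instr, outcome, config.palindrome_eaf_window)
        if len(pairs) == 0:
            rows.append({"protein": pid, "status": "untestable",
                         "replicated": None})
            continue
        e = _mr_estimate(pairs, config, pid, "outcome")
        consistent = (pid in disc_beta
                      and np.sign(e.beta) == np.sign(disc_beta[pid]))
        rows.append({
            "protein": pid, "status": "tested", "n_instruments": len(pairs),
            "beta": e.beta, "se": e.se, "pvalue": e.pvalue,
            "direction_consistent": bool(consistent),
            "replicated": bool(e.pvalue < config.replication_alpha
                               and consistent),
        })
    return pd.DataFrame(rows)


def run_reverse(
    outcome: pd.DataFrame,
    proteins: dict,
    forward_pairs: dict,
    ld: LDMatrix,
    config: RunConfig,
) -> pd.DataFrame:
    """Reverse MR (outcome as exposure) plus Steiger directionality of the
    forward instruments, for each protein in ``forward_pairs``."""
    out_instr = select_genomewide_instruments(
        outcome, ld, p_threshold=config.p_threshold, f_min=config.f_min,
        r2_max=config.clump_r2, window_kb=config.clump_window_kb,
    )
    rows = []
    for pid in sorted(forward_pairs):
        row: dict = {"protein": pid}
        if len(out_instr) == 0:
            row.update(status="untestable", reverse_null=None)
        else:
            pairs = harmonize(out_instr, proteins[pid],
                              config.palindrome_eaf_window)
            if len(pairs) == 0:
                row.update(status="untestable", reverse_null=None)
            else:
                e = _mr_estimate(pairs, config, "outcome", pid)
                row.update(status="tested", n_instruments=len(pairs),
                           reverse_beta=e.beta, reverse_pvalue=e.pvalue,
                           reverse_null=bool(e.pvalue >= config.reverse_alpha))
        sp, correct = est.steiger(forward_pairs[pid])
        row.update(steiger_pvalue=sp,
                   steiger_correct_direction=bool(correct),
                   steiger_pass=bool(correct and sp < config.steiger_alpha))
        rows.append(row)
    return pd.DataFrame(rows)


def _locus_frames(protein_df, outcome_df, gene: GeneAnnotation,
                  pairs: pd.DataFrame, config: RunConfig):
    """Protein and outcome sumstats restricted to the coloc window around
    the lead cis-pQTL."""
    lead = pairs.loc[(pairs["beta_gx"] / pairs["se_gx"]).abs().idxmax()]
    half = config.coloc_window_kb * 1000
    sel_p = (protein_df["CHR"].astype(str) == gene.chrom) & (
        (protein_df["POS"] - int(lead.POS)).abs() <= half)
    sel_o = (outcome_df["CHR"].astype(str) == gene.chrom) & (
        (outcome_df["POS"] - int(lead.POS)).abs() <= half)
    return protein_df.loc[sel_p], outcome_df.loc[sel_o]


def run_smr_coloc(
    proteins: dict,
    genes: dict,
    outcome: pd.DataFrame,
    ld: LDMatrix,
    forward_pairs: dict,
    config: RunConfig,
    outcome_meta: TraitMeta | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SMR/HEIDI and colocalization at each significant protein's locus."""
    prior_sd2 = (config.coloc_prior_sd_binary
                 if outcome_meta is not None
                 and outcome_meta.trait_type == "binary"
                 else config.coloc_prior_sd_quant)
    smr_rows, coloc_rows = [], []
    for pid in sorted(forward_pairs):
        gene = genes[pid]
        locus_p, locus_o = _locus_frames(
            proteins[pid], outcome, gene, forward_pairs[pid], config)
        locus_pairs = harmonize(locus_p, locus_o,
                                config.palindrome_eaf_window)
        try:
            res = smr_heidi(
                locus_pairs, ld, probe_id=pid,
                p_top_threshold=config.smr_p_top,
                r2_min=config.heidi_r2_min, r2_max=config.heidi_r2_max,
                max_snps=config.heidi_max_snps,
                p_expo_max=config.heidi_p_expo_max,
            )
            smr_rows.append({
                "probe": pid, "top_snp": res.top_snp, "b_smr": res.b_smr,
                "se_smr": res.se_smr, "p_smr": res.p_smr,
                "heidi_p": res.heidi_p if res.heidi_p is not None else "NA",
                "n_heidi_snps": res.n_heidi_snps,
                "smr_pass": bool(res.p_smr < config.smr_alpha),
                "heidi_pass": (bool(res.heidi_p >= config.heidi_pass_threshold)
                               if res.heidi_p is not None else None),
            })
        except ValueError:
            smr_rows.append({"probe": pid, "top_snp": None, "b_smr": np.nan,
                             "se_smr": np.nan, "p_smr": np.nan,
                             "heidi_p": "NA", "n_heidi_snps": 0,
                             "smr_pass": None, "heidi_pass": None})
        cres = run_coloc(
            locus_p, locus_o, config.coloc_p1, config.coloc_p2,
            config.coloc_p12, config.coloc_prior_sd_quant, prior_sd2,
            locus_id=pid,
        )
        crow = coloc_report_row(cres, config.pph4_strong)
        crow["coloc_pass"] = bool(cres.pph4 >= config.coloc_pass_threshold)
        coloc_rows.append(crow)
    return pd.DataFrame(smr_rows), pd.DataFrame(coloc_rows)


def run_phewas(
    instruments: pd.DataFrame,
    outcomes: list,
    config: RunConfig,
    protein_id: str = "protein",
) -> pd.DataFrame:
    """Phenome-wide MR of one protein's fixed instrument set.

    ``outcomes`` is a list of ``PhewasOutcome`` (sumstats, TraitMeta,
    category).  Binary outcomes with n_cases <= ``phewas_min_cases`` are
    excluded before testing (strictly more than the minimum is required);
    FDR is computed across the retained outcomes.
    """
    rows = []
    for oc in outcomes:
        if oc.meta.n_cases is not None and oc.meta.n_cases <= config.phewas_min_cases:
            rows.append({"protein": protein_id, "outcome": oc.meta.trait_id,
                         "category": oc.category, "status": "excluded",
                         "n_cases": oc.meta.n_cases})
            continue
        pairs = harmonize(instruments, oc.sumstats,
                          config.palindrome_eaf_window)
        if len(pairs) == 0:
            rows.append({"protein": protein_id, "outcome": oc.meta.trait_id,
                         "category": oc.category, "status": "untestable"})
            continue
        e = _mr_estimate(pairs, config, protein_id, oc.meta.trait_id)
        rows.append({
            "protein": protein_id, "outcome": oc.meta.trait_id,
            "category": oc.category, "status": "tested",
            "n_cases": oc.meta.n_cases, "n_instruments": len(pairs),
            "beta": e.beta, "se": e.se, "pvalue": e.pvalue,
            "odds_ratio": e.odds_ratio,
        })
    report = pd.DataFrame(rows)
    tested = report["status"] == "tested"
    report["qvalue"] = np.nan
    if tested.any():
        report.loc[tested, "qvalue"] = est.bh_fdr(
            report.loc[tested, "pvalue"].to_numpy())
    report["significant"] = report["qvalue"] < config.fdr_alpha
    return report


def run_mediation_screen(
    riskfactors: dict,
    proteins: dict,
    protein_estimates: dict,
    outcome: pd.DataFrame,
    ld: LDMatrix,
    config: RunConfig,
) -> pd.DataFrame:
    """Two-step mediation screen: risk factor -> protein -> outcome.

    beta1 (risk factor on protein) and c' (risk factor on outcome) are
    IVW-estimated from genome-wide significant risk-factor instruments;
    beta2 comes from the discovery estimates.  Each leg is FDR-screened at
    ``mediation_fdr_alpha``; pathways passing all legs get the delta-method
    decomposition and reliability gate (Sobel p, direction agreement, no
    pleiotropy in the total effect).
    """
    rf_instr = {
        rid: select_genomewide_instruments(
            riskfactors[rid], ld, p_threshold=config.p_threshold,
            f_min=config.f_min, r2_max=config.clump_r2,
            window_kb=config.clump_window_kb)
        for rid in sorted(riskfactors)
    }
    # c' leg per risk factor, with its pleiotropy diagnostic
    totals: dict[str, tuple] = {}
    for rid, instr in rf_instr.items():
        if len(instr) == 0:
            continue
        pairs = harmonize(instr, outcome, config.palindrome_eaf_window)
        if len(pairs) == 0:
            continue
        e = _mr_estimate(pairs, config, rid, "outcome")
        pleio_p = 1.0
        if len(pairs) >= 3:
            pleio_p = est.egger(pairs, rid, "outcome").intercept_pvalue
        totals[rid] = (e, pleio_p)
    total_q = dict(zip(
        totals, est.bh_fdr([e.pvalue for e, _ in totals.values()])
    )) if totals else {}

    # beta1 leg across all risk factor x protein pairs
    step1: dict[tuple, est.MREstimate] = {}
    for rid, instr in rf_instr.items():
        if rid not in totals or len(instr) == 0:
            continue
        for pid in sorted(protein_estimates):
            pairs = harmonize(instr, proteins[pid],
                              config.palindrome_eaf_window)
            if len(pairs) == 0:
                continue
            step1[(rid, pid)] = _mr_estimate(pairs, config, rid, pid)
    step1_q = dict(zip(
        step1, est.bh_fdr([e.pvalue for e in step1.values()])
    )) if step1 else {}

    rows = []
    for (rid, pid), e1 in step1.items():
        e2 = protein_estimates[pid]
        etot, pleio_p = totals[rid]
        legs_pass = (
            step1_q[(rid, pid)] < config.mediation_fdr_alpha
            and total_q[rid] < config.mediation_fdr_alpha
        )
        row = {
            "risk_factor": rid, "mediator": pid,
            "beta1": e1.beta, "se1": e1.se, "beta1_q": step1_q[(rid, pid)],
            "beta2": e2.beta, "se2": e2.se,
            "c_prime": etot.beta, "se_c": etot.se, "c_prime_q": total_q[rid],
            "total_pleiotropy_p": pleio_p, "legs_pass_fdr": bool(legs_pass),
        }
        if legs_pass and etot.beta != 0.0:
            m = mediate(e1, e2, etot, total_pleiotropy_p=pleio_p,
                        sobel_alpha=config.sobel_alpha,
                        pleiotropy_alpha=config.pleiotropy_alpha)
            row.update(
                mediated=m.mediated, se_mediated=m.se_mediated,
                sobel_p=m.sobel_p,
                proportion_pct=100 * m.proportion,
                prop_ci_low_pct=100 * m.prop_ci_low,
                prop_ci_high_pct=100 * m.prop_ci_high,
                reliable=m.reliable,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def assign_tiers(
    significant: list,
    replication_report: pd.DataFrame,
    reverse_report: pd.DataFrame,
    smr_report: pd.DataFrame,
    coloc_report: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Combine stage flags into tier assignments for significant proteins."""

    def lookup(df, key_col, key, col):
        if df is None or len(df) == 0 or key_col not in df or col not in df:
            return None
        sub = df.loc[df[key_col] == key, col]
        if len(sub) == 0:
            return None
        v = sub.iloc[0]
        return None if pd.isna(v) else v

    rows = []
    for pid in sorted(significant):
        flags = {
            "replicated": lookup(replication_report, "protein", pid,
                                 "replicated"),
            "smr_pass": lookup(smr_report, "probe", pid, "smr_pass"),
            "heidi_pass": lookup(smr_report, "probe", pid, "heidi_pass"),
            "coloc_pass": lookup(coloc_report, "locus_id", pid, "coloc_pass"),
            "reverse_null": lookup(reverse_report, "protein", pid,
                                   "reverse_null"),
            "steiger_pass": lookup(reverse_report, "protein", pid,
                                   "steiger_pass"),
        }
        t = classify_tier(pid, flags)
        rows.append({"protein": pid, "tier": t.tier, **t.flags})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study IO and end-to-end run
# ---------------------------------------------------------------------------

def _check_not_truth(path) -> None:
    if "truth" in Path(path).parts:
        raise ValueError(f"refusing to read ground-truth path {path}")


def write_study(study: Study, out_dir) -> None:
    """Write a simulated study as the TSV/JSON directory layout
    ``load_study`` reads; ground truth goes under ``truth/``."""
    out = Path(out_dir)
    for sub in ("proteins", "replication", "riskfactors", "phewas", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for pid, df in study.proteins.items():
        write_sumstats(df, out / "proteins" / f"{pid}.tsv")
    for pid, df in study.replication.items():
        write_sumstats(df, out / "replication" / f"{pid}.tsv")
    for rid, df in study.riskfactors.items():
        write_sumstats(df, out / "riskfactors" / f"{rid}.tsv")
    write_sumstats(study.outcome, out / "outcome.tsv")
    write_ld_matrix(study.ld, out / "ld.tsv")
    pd.DataFrame(
        {"gene_id": list(study.genes),
         "chrom": [g.chrom for g in study.genes.values()],
         "tss": [g.tss for g in study.genes.values()]}
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    phemeta = []
    for oc in study.phewas:
        write_sumstats(oc.sumstats, out / "phewas" / f"{oc.meta.trait_id}.tsv")
        phemeta.append({
            "trait_id": oc.meta.trait_id, "trait_type": oc.meta.trait_type,
            "n_total": oc.meta.n_total, "n_cases": oc.meta.n_cases,
            "category": oc.category,
        })
    (out / "phewas" / "meta.json").write_text(json.dumps(phemeta, indent=1))
    (out / "meta.json").write_text(json.dumps(
        {"outcome": {"trait_id": study.outcome_meta.trait_id,
                     "trait_type": study.outcome_meta.trait_type,
                     "n_total": study.outcome_meta.n_total}}, indent=1))
    (out / "truth" / "truth.json").write_text(json.dumps(study.truth, indent=1))


def load_study(study_dir) -> Study:
    """Load a study directory (as written by ``write_study``).  The
    ``truth/`` subdirectory is never read into the analysis inputs."""
    root = Path(study_dir)

    def read_dir(sub):
        d = {}
        for p in sorted((root / sub).glob("*.tsv")):
            _check_not_truth(p)
            d[p.stem], _ = read_sumstats(p)
        return d

    proteins = read_dir("proteins")
    replication = read_dir("replication") if (root / "replication").exists() else {}
    riskfactors = read_dir("riskfactors") if (root / "riskfactors").exists() else {}
    outcome, _ = read_sumstats(root / "outcome.tsv")
    ld = read_ld_matrix(root / "ld.tsv")
    genes = read_gene_annotation(root / "genes.tsv")
    meta = json.loads((root / "meta.json").read_text())
    om = meta.get("outcome", {})
    outcome_meta = TraitMeta(
        trait_id=om.get("trait_id", "outcome"),
        n_total=om.get("n_total", int(outcome["N"].median())),
        trait_type=om.get("trait_type", "quantitative"),
    )
    phewas = []
    pmeta_path = root / "phewas" / "meta.json"
    if pmeta_path.exists():
        for entry in json.loads(pmeta_path.read_text()):
            df, _ = read_sumstats(root / "phewas" / f"{entry['trait_id']}.tsv")
            phewas.append(PhewasOutcome(
                df,
                TraitMeta(entry["trait_id"], entry["n_total"],
                          entry["trait_type"], entry["n_cases"]),
                entry.get("category", ""),
            ))
    return Study(proteins=proteins, genes=genes, outcome=outcome,
                 outcome_meta=outcome_meta, ld=ld, replication=replication,
                 riskfactors=riskfactors, phewas=phewas, truth={})


def run_all(study: Study, config: RunConfig, out_dir=None) -> dict:
    """Execute the full workflow on a study; optionally write all TSV
    reports plus a run log echoing every threshold and the seed.

    Returns the dict of report DataFrames keyed by ``REPORT_NAMES``.
    Reruns with identical study, config and seed produce byte-identical
    report files.
    """
    discovery, pairs = run_discovery(
        study.proteins, study.genes, study.outcome, study.ld, config,
        outcome_id=study.outcome_meta.trait_id)
    significant = sorted(
        discovery.loc[discovery["significant"] == True, "protein"])  # noqa: E712
    sig_pairs = {pid: pairs[pid] for pid in significant if pid in pairs}

    replication = run_replication(
        {pid: df for pid, df in study.replication.items()
         if pid in significant},
        study.genes, study.outcome, study.ld, discovery, config)
    reverse = run_reverse(study.outcome, study.proteins, sig_pairs,
                          study.ld, config)
    smr_report, coloc_report = run_smr_coloc(
        study.proteins, study.genes, study.outcome, study.ld, sig_pairs,
        config, study.outcome_meta)
    tiers = assign_tiers(significant, replication, reverse, smr_report,
                         coloc_report, config)

    protein_estimates = {
        pid: _mr_estimate(sig_pairs[pid], config, pid,
                          study.outcome_meta.trait_id)
        for pid in sig_pairs
    }
    mediation_report = run_mediation_screen(
        study.riskfactors, study.proteins, protein_estimates,
        study.outcome, study.ld, config)

    phewas_frames = []
    for pid in significant:
        if pid not in sig_pairs or not study.phewas:
            continue
        instr_ids = set(sig_pairs[pid]["SNP"])
        instr = study.proteins[pid].loc[
            study.proteins[pid]["SNP"].isin(instr_ids)]
        phewas_frames.append(
            run_phewas(instr, study.phewas, config, protein_id=pid))
    phewas_report = (pd.concat(phewas_frames, ignore_index=True)
                     if phewas_frames else pd.DataFrame())

    reports = {
        "discovery": discovery, "replication": replication,
        "reverse": reverse, "smr_heidi": smr_report, "coloc": coloc_report,
        "tiers": tiers, "mediation": mediation_report,
        "phewas": phewas_report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in REPORT_NAMES:
            reports[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)
        log_lines = ["run configuration:"] + config.log_lines()
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        if study.truth:
            _truth_comparison(reports, study.truth).to_csv(
                out / "truth_comparison.tsv", sep="\t", index=False)
    return reports


def _truth_comparison(reports: dict, truth: dict) -> pd.DataFrame:
    """Side-by-side of planted truth and pipeline calls."""
    disc = reports["discovery"]
    rows = []
    for pid, theta in sorted(truth.get("theta", {}).items()):
        sub = disc.loc[disc["protein"] == pid]
        called = bool(sub["significant"].iloc[0]) if len(sub) else None
        est_beta = float(sub["beta"].iloc[0]) if len(sub) else np.nan
        tier_df = reports["tiers"]
        tier_row = tier_df.loc[tier_df["protein"] == pid, "tier"] \
            if len(tier_df) else []
        rows.append({
            "protein": pid, "true_effect": theta,
            "estimated_beta": est_beta, "called_significant": called,
            "tier": int(tier_row.iloc[0]) if len(tier_row) else None,
        })
    return pd.DataFrame(rows)


def run_all_from_paths(study_dir, config: RunConfig, out_dir) -> dict:
    _check_not_truth(study_dir)
    study = load_study(study_dir)
    return run_all(study, config, out_dir)
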