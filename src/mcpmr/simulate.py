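"""Synthetic GWAS summary statistics with known ground truth.

Emulates the statistical structure of the study's inputs — marginal
per-SNP linear-regression summary statistics over LD blocks for protein
exposures (an Olink-style plasma-proteome GWAS), a quantitative pain-site
count outcome (0-7 sites), and modifiable risk factors — so every pipeline
stage can be exercised end to end with the truth on file.

Two generation routes are provided:

* a genotype-level route (`simulate_genotypes` + `simulate_trait_gwas`):
  per LD block, latent AR(1) Gaussian vectors are thresholded into 0/1/2
  dosages at Hardy-Weinberg frequencies, traits are built as linear
  genetic values plus Gaussian noise, and marginal simple-regression
  summary statistics are computed per SNP on standardized phenotypes (so
  R^2 = 2*EAF*(1-EAF)*beta^2 holds);

* a summary-level route (`simulate_iv_summary`, `simulate_locus_sumstats`):
  marginal effect estimates are drawn directly from their sampling
  distribution — independent normals around the true marginal effects for
  unlinked instruments, the standard multivariate-normal z-score model
  z ~ N(R z_true, R) over an LD block — which is what the
  repetition-heavy calibration checks use.

Everything is deterministic under an explicit seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import GeneAnnotation
from .sumstats import LDMatrix, TraitMeta, write_ld_matrix, write_sumstats

P_FLOOR = 1e-300  # keep p-values inside (0, 1]

SCENARIOS = ("H0", "H1", "H2", "H3", "H4", "mediation_chain", "null_mr", "effect_mr")


@dataclass
class SimulationConfig:
    """Layout and effect sizes of one simulated dataset."""

    seed: int
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    n_riskfactor: int = 50_000
    n_blocks: int = 20
    block_size: int = 50
    rho: float = 0.8
    maf_range: tuple = (0.05, 0.45)
    causal_scenario: str = "effect_mr"
    true_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high < 0.5")
        if self.causal_scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.causal_scenario!r}")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")


@dataclass
class TruthRecord:
    """Ground truth of one simulated scenario."""

    scenario: str
    causal_snp_ids: dict = field(default_factory=dict)
    true_causal_effect: float | None = None
    true_beta1: float | None = None
    true_beta2: float | None = None
    true_c_prime: float | None = None
    per_snp_effects: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class Genotypes:
    """A dosage panel with SNP metadata."""

    dosages: np.ndarray  # (n, m) float32 in {0,1,2}
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)


def ar1_corr(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _block_latent(rng, n: int, m: int, rho: float) -> np.ndarray:
    x = rng.standard_normal((n, m))
    if rho != 0.0:
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            x[:, j] = rho * x[:, j - 1] + scale * x[:, j]
    return x


def simulate_genotypes(
    config: SimulationConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    chrom_labels: list[str] | None = None,
    pos_start: int = 1_000_000,
    pos_step: int = 2_000,
    snp_prefix: str = "rs",
    mafs: np.ndarray | None = None,
) -> tuple[Genotypes, LDMatrix]:
    """Simulate a diploid dosage panel over AR(1) LD blocks.

    Per block, two haplotype-level latent AR(1) Gaussian vectors are
    thresholded at the normal quantile of each SNP's MAF and summed, giving
    Hardy-Weinberg 0/1/2 dosages with geometrically decaying LD.  Returns
    the panel and the empirical LD correlation matrix.  MAFs may be passed
    in to share allele frequencies between cohort panels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = n or config.n_exposure
    nb, bs = config.n_blocks, config.block_size
    m = nb * bs
    if mafs is None:
        mafs = rng.uniform(*config.maf_range, size=m)
    thresholds = stats.norm.ppf(mafs)
    dos = np.empty((n, m), dtype=np.float32)
    for b in range(nb):
        sl = slice(b * bs, (b + 1) * bs)
        h1 = _block_latent(rng, n, bs, config.rho) < thresholds[sl]
        h2 = _block_latent(rng, n, bs, config.rho) < thresholds[sl]
        dos[:, sl] = h1.astype(np.float32) + h2.astype(np.float32)
    if chrom_labels is None:
        chrom_labels = [str(b + 1) for b in range(nb)]
    chrom = np.repeat(np.asarray(chrom_labels, dtype=object), bs)
    pos = np.tile(pos_start + pos_step * np.arange(bs), nb)
    snp_ids = [f"{snp_prefix}{j:05d}" for j in range(m)]

    r = np.eye(m)
    for b in range(nb):
        sl = slice(b * bs, (b + 1) * bs)
        block = dos[:, sl]
        sd = block.std(axis=0)
        ok = sd > 0
        rb = np.eye(bs)
        if ok.any():
            c = np.corrcoef(block[:, ok], rowvar=False)
            rb[np.ix_(ok, ok)] = np.atleast_2d(c)
        r[sl, sl.start:sl.stop] = rb
    np.fill_diagonal(r, 1.0)
    geno = Genotypes(dos, snp_ids, chrom, pos, np.asarray(mafs))
    return geno, LDMatrix(snp_ids, np.clip(r, -1.0, 1.0))


def effect_for_variance(ve: float, maf: float) -> float:
    """Per-allele effect explaining variance fraction ``ve`` at ``maf`` on a
    unit-variance trait."""
    return float(np.sqrt(ve / (2.0 * maf * (1.0 - maf))))


def simulate_trait_gwas(
    geno: Genotypes,
    effects: np.ndarray,
    rng: np.random.Generator,
    trait_id: str = "trait",
    noise_var: float | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Marginal per-SNP simple-regression summary statistics for a
    quantitative trait built from ``effects`` on the panel.

    The phenotype is standardized (mean 0, variance 1) before regression so
    the R^2 = 2*EAF*(1-EAF)*beta^2 identity is valid for the emitted betas.
    """
    effects = np.asarray(effects, dtype=float)
    g = geno.dosages
    n = geno.n
    gv = g @ effects.astype(np.float32) if effects.any() else np.zeros(n, dtype=np.float32)
    gv = gv.astype(float)
    if noise_var is None:
        noise_var = max(1.0 - float(np.var(gv)), 0.05)
    if noise_var <= 0:
        raise ValueError("heritability >= 1: non-positive noise variance")
    y = gv + rng.normal(0.0, np.sqrt(noise_var), size=n)
    if standardize:
        y = (y - y.mean()) / y.std()
    return _marginal_regression(geno, y, trait_id)


def simulate_binary_trait_gwas(
    geno: Genotypes,
    effects: np.ndarray,
    rng: np.random.Generator,
    trait_id: str = "trait",
    intercept: float = -3.0,
) -> tuple[pd.DataFrame, TraitMeta]:
    """Binary (case/control) trait via a logistic liability; summary
    statistics by linear regression on the 0/1 phenotype (common biobank
    practice for large cohorts)."""
    effects = np.asarray(effects, dtype=float)
    eta = intercept + (geno.dosages @ effects.astype(np.float32)).astype(float)
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    meta = TraitMeta(trait_id=trait_id, n_total=geno.n,
                     trait_type="binary", n_cases=int(y.sum()))
    return _marginal_regression(geno, y, trait_id), meta


def _marginal_regression(geno: Genotypes, y: np.ndarray, trait_id: str) -> pd.DataFrame:
    g = geno.dosages
    n = geno.n
    gm = g.mean(axis=0, dtype=np.float64)
    sxx = np.einsum("ij,ij->j", g, g, dtype=np.float64) - n * gm**2
    ym = y.mean()
    syy = float(np.sum((y - ym) ** 2))
    sxy = (y - ym) @ g
    sxx = np.maximum(sxx, 1e-12)
    beta = sxy / sxx
    resid_var = np.maximum(syy - beta**2 * sxx, 0.0) / (n - 2)
    se = np.sqrt(np.maximum(resid_var, 1e-30) / sxx)
    tval = beta / se
    p = np.maximum(2.0 * stats.t.sf(np.abs(tval), n - 2), P_FLOOR)
    eaf = np.clip(gm / 2.0, 1e-6, 1 - 1e-6)
    return pd.DataFrame(
        {
            "SNP": geno.snp_ids,
            "CHR": geno.chrom,
            "POS": geno.pos,
            "EA": "A",
            "OA": "G",
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
        }
    )


# ---------------------------------------------------------------------------
# scenario generation (genotype-level)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedScenario:
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    riskfactor: pd.DataFrame | None
    ld: LDMatrix
    truth: TruthRecord
    genes: list[GeneAnnotation]


def _effects_vector(m: int, idx_to_effect: dict[int, float]) -> np.ndarray:
    e = np.zeros(m)
    for i, v in idx_to_effect.items():
        e[i] = v
    return e


def simulate_scenario(config: SimulationConfig) -> SimulatedScenario:
    """Simulate exposure/outcome (and risk factor) GWAS under a named
    causal scenario; see :class:`SimulationConfig` and the module docstring.

    Scenarios H0-H4 are single-locus colocalization layouts; ``null_mr`` /
    ``effect_mr`` plant one causal exposure SNP per block with causal
    effect 0 / ``theta`` on the outcome; ``mediation_chain`` builds a
    risk-factor -> mediator-protein -> outcome chain with effects
    (beta1, beta2) plus a direct effect, so c' = beta1*beta2 + direct.
    """
    te = config.true_effects
    rng = np.random.default_rng(config.seed)
    scen = config.causal_scenario
    m = config.n_blocks * config.block_size
    mafs = rng.uniform(*config.maf_range, size=m)

    def panel(n, salt):
        geno, ld = simulate_genotypes(
            config, n=n, rng=np.random.default_rng((config.seed, salt)),
            mafs=mafs,
        )
        return geno, ld

    ve = te.get("var_explained", 0.01)
    theta = te.get("theta", 0.15)

    if scen in ("H0", "H1", "H2", "H3", "H4"):
        geno_x, ld = panel(config.n_exposure, 1)
        geno_y, _ = panel(config.n_outcome, 2)
        c1 = te.get("causal_index", config.block_size // 2)
        c2 = te.get("causal_index_2", min(c1 + te.get("h3_separation", 3),
                                          config.block_size - 1))
        ex_eff: dict[int, float] = {}
        out_eff: dict[int, float] = {}
        truth = TruthRecord(scenario=scen)
        if scen in ("H1", "H3", "H4"):
            ex_eff[c1] = effect_for_variance(ve, mafs[c1])
            truth.causal_snp_ids["exposure"] = [geno_x.snp_ids[c1]]
        if scen == "H2":
            out_eff[c1] = effect_for_variance(ve, mafs[c1])
            truth.causal_snp_ids["outcome"] = [geno_y.snp_ids[c1]]
        if scen == "H3":
            out_eff[c2] = effect_for_variance(ve, mafs[c2])
            truth.causal_snp_ids["outcome"] = [geno_y.snp_ids[c2]]
        if scen == "H4":
            out_eff[c1] = theta * ex_eff[c1]
            truth.causal_snp_ids["outcome"] = [geno_y.snp_ids[c1]]
            truth.true_causal_effect = theta
        exposure = simulate_trait_gwas(
            geno_x, _effects_vector(m, ex_eff), rng, "exposure")
        outcome = simulate_trait_gwas(
            geno_y, _effects_vector(m, out_eff), rng, "outcome")
        truth.per_snp_effects = {
            "exposure": {geno_x.snp_ids[i]: v for i, v in ex_eff.items()},
            "outcome": {geno_y.snp_ids[i]: v for i, v in out_eff.items()},
        }
        genes = [GeneAnnotation("GENE1", "1", 1_000_000 +
                                (config.block_size // 2) * 2_000)]
        return SimulatedScenario(exposure, outcome, None, ld, truth, genes)

    if scen in ("null_mr", "effect_mr"):
        theta = theta if scen == "effect_mr" else 0.0
        geno_x, ld = panel(config.n_exposure, 1)
        geno_y, _ = panel(config.n_outcome, 2)
        centers = [b * config.block_size + config.block_size // 2
                   for b in range(config.n_blocks)]
        ex_eff = {c: effect_for_variance(ve, mafs[c]) for c in centers}
        out_eff = {c: theta * v for c, v in ex_eff.items()}
        exposure = simulate_trait_gwas(
            geno_x, _effects_vector(m, ex_eff), rng, "exposure")
        outcome = simulate_trait_gwas(
            geno_y, _effects_vector(m, out_eff), rng, "outcome")
        truth = TruthRecord(
            scenario=scen,
            causal_snp_ids={"exposure": [geno_x.snp_ids[c] for c in centers]},
            true_causal_effect=theta,
            per_snp_effects={
                "exposure": {geno_x.snp_ids[c]: v for c, v in ex_eff.items()},
                "outcome": {geno_y.snp_ids[c]: v for c, v in out_eff.items()},
            },
        )
        genes = [
            GeneAnnotation(f"GENE{b+1}", str(b + 1),
                           1_000_000 + (config.block_size // 2) * 2_000)
            for b in range(config.n_blocks)
        ]
        return SimulatedScenario(exposure, outcome, None, ld, truth, genes)

    # mediation_chain: first half of blocks instrument the risk factor,
    # second half the mediator protein
    beta1 = te.get("beta1", 0.2)
    beta2 = te.get("beta2", 0.3)
    direct = te.get("direct", 0.14)
    half = max(config.n_blocks // 2, 1)
    r_centers = [b * config.block_size + config.block_size // 2
                 for b in range(half)]
    m_centers = [b * config.block_size + config.block_size // 2
                 for b in range(half, config.n_blocks)]
    a_eff = {c: effect_for_variance(ve, mafs[c]) for c in r_centers}
    b_eff = {c: effect_for_variance(ve, mafs[c]) for c in m_centers}

    geno_r, ld = panel(config.n_riskfactor, 1)
    geno_m, _ = panel(config.n_exposure, 2)
    geno_y, _ = panel(config.n_outcome, 3)

    a_vec = _effects_vector(m, a_eff)
    b_vec = _effects_vector(m, b_eff)
    med_vec = beta1 * a_vec + b_vec                 # mediator marginal
    out_vec = beta2 * med_vec + direct * a_vec      # outcome marginal

    riskfactor = simulate_trait_gwas(geno_r, a_vec, rng, "riskfactor")
    exposure = simulate_trait_gwas(geno_m, med_vec, rng, "mediator")
    outcome = simulate_trait_gwas(geno_y, out_vec, rng, "outcome")
    truth = TruthRecord(
        scenario=scen,
        causal_snp_ids={
            "riskfactor": [geno_r.snp_ids[c] for c in r_centers],
            "mediator": [geno_m.snp_ids[c] for c in m_centers],
        },
        true_beta1=beta1, true_beta2=beta2,
        true_c_prime=beta1 * beta2 + direct,
        per_snp_effects={
            "riskfactor": {geno_r.snp_ids[c]: v for c, v in a_eff.items()},
            "mediator": {geno_m.snp_ids[c]: float(med_vec[c])
                         for c in r_centers + m_centers},
        },
    )
    genes = [
        GeneAnnotation(f"GENE{b+1}", str(b + 1),
                       1_000_000 + (config.block_size // 2) * 2_000)
        for b in range(config.n_blocks)
    ]
    return SimulatedScenario(exposure, outcome, riskfactor, ld, truth, genes)


def write_scenario(sim: SimulatedScenario, out_dir) -> None:
    """Write a simulated scenario as TSV/JSON: exposure.tsv, outcome.tsv,
    optional riskfactor.tsv, ld.tsv, truth/truth.json, meta.json.

    Truth goes in its own subdirectory so analysis inputs and ground truth
    stay separate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sumstats(sim.exposure, out / "exposure.tsv")
    write_sumstats(sim.outcome, out / "outcome.tsv")
    if sim.riskfactor is not None:
        write_sumstats(sim.riskfactor, out / "riskfactor.tsv")
    write_ld_matrix(sim.ld, out / "ld.tsv")
    genes = pd.DataFrame(
        {"gene_id": [g.gene_id for g in sim.genes],
         "chrom": [g.chrom for g in sim.genes],
         "tss": [g.tss for g in sim.genes]}
    )
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    (out / "truth").mkdir(exist_ok=True)
    (out / "truth" / "truth.json").write_text(sim.truth.to_json())
    (out / "meta.json").write_text(json.dumps({"scenario": sim.truth.scenario}))


# ---------------------------------------------------------------------------
# summary-level fast paths
# ---------------------------------------------------------------------------

def marginal_se(maf, n) -> np.ndarray:
    """Standard error of the marginal per-allele estimate on a
    unit-variance trait: 1/sqrt(2*maf*(1-maf)*n)."""
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * np.asarray(n, dtype=float))


def simulate_iv_summary(
    rng: np.random.Generator,
    k: int = 10,
    n_gx: int = 50_000,
    n_gy: int = 50_000,
    maf: float = 0.3,
    var_explained: float = 0.01,
    theta: float = 0.0,
    pleiotropy: np.ndarray | float = 0.0,
    outlier_idx: int | None = None,
    outlier_shift_se: float = 0.0,
) -> pd.DataFrame:
    """Draw a harmonized instrument set directly from the sampling
    distribution of marginal estimates at ``k`` unlinked SNPs.

    Exposure effects explain ``var_explained`` (scalar, or one value per
    SNP); the outcome effect of
    each SNP is ``theta`` times its exposure effect plus any per-SNP
    ``pleiotropy`` term; ``outlier_idx`` displaces one outcome estimate by
    ``outlier_shift_se`` outcome standard errors.
    """
    maf_arr = np.full(k, maf, dtype=float)
    ve = np.broadcast_to(np.asarray(var_explained, dtype=float), (k,))
    b = np.array([effect_for_variance(v, f) for v, f in zip(ve, maf_arr)])
    se_gx = marginal_se(maf_arr, n_gx)
    se_gy = marginal_se(maf_arr, n_gy)
    alpha = np.broadcast_to(np.asarray(pleiotropy, dtype=float), (k,)).copy()
    mean_gy = theta * b + alpha
    if outlier_idx is not None:
        mean_gy[outlier_idx] += outlier_shift_se * se_gy[outlier_idx]
    return pd.DataFrame(
        {
            "SNP": [f"iv{j:03d}" for j in range(k)],
            "beta_gx": rng.normal(b, se_gx),
            "se_gx": se_gx,
            "beta_gy": rng.normal(mean_gy, se_gy),
            "se_gy": se_gy,
            "eaf": maf_arr,
            "eaf_gy": maf_arr,
            "n_gx": n_gx,
            "n_gy": n_gy,
        }
    )


def simulate_locus_sumstats(
    rng: np.random.Generator,
    r: np.ndarray,
    z_causal_1: float,
    z_causal_2: float,
    causal_idx_1: int,
    causal_idx_2: int | None = None,
    n1: int = 50_000,
    n2: int = 50_000,
    maf: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw two traits' locus summary statistics from the standard MVN
    z-score model z ~ N(R z_true, R) over LD matrix ``r``.

    Trait 1's causal variant is ``causal_idx_1`` with non-centrality
    ``z_causal_1``; trait 2 shares it when ``causal_idx_2`` is None (the
    shared-variant hypothesis) and has its own otherwise.
    Returns canonical sumstats frames for both traits.
    """
    m = r.shape[0]
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    if causal_idx_2 is None:
        causal_idx_2 = causal_idx_1
    mu1 = r[:, causal_idx_1] * z_causal_1
    mu2 = r[:, causal_idx_2] * z_causal_2
    z1 = mu1 + chol @ rng.standard_normal(m)
    z2 = mu2 + chol @ rng.standard_normal(m)
    maf_arr = np.full(m, maf)
    se1 = marginal_se(maf_arr, n1)
    se2 = marginal_se(maf_arr, n2)
    ids = [f"rs{j:05d}" for j in range(m)]

    def frame(z, se, n):
        return pd.DataFrame(
            {
                "SNP": ids, "CHR": "1",
                "POS": 1_000_000 + 2_000 * np.arange(m),
                "EA": "A", "OA": "G", "EAF": maf_arr,
                "BETA": z * se, "SE": se,
                "P": np.maximum(2 * stats.norm.sf(np.abs(z)), P_FLOOR),
                "N": n,
            }
        )

    return frame(z1, se1, n1), frame(z2, se2, n2)


# ---------------------------------------------------------------------------
# full-study generation for the end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PhewasOutcome:
    sumstats: pd.DataFrame
    meta: TraitMeta
    category: str


@dataclass
class Study:
    """A complete simulated study: discovery and replication pQTL sets, the
    pain outcome, risk factors, phenome-wide outcomes, LD and truth."""

    proteins: dict
    genes: dict
    outcome: pd.DataFrame
    outcome_meta: TraitMeta
    ld: LDMatrix
    replication: dict
    riskfactors: dict
    phewas: list
    truth: dict


def simulate_study(
    seed: int,
    n_proteins: int = 12,
    n_causal: int = 4,
    n_riskfactors: int = 3,
    blocks_per_gene: int = 4,
    block_size: int = 8,
    n_exposure: int = 20_000,
    n_outcome: int = 50_000,
    n_replication: int = 5_000,
    n_riskfactor_cohort: int = 20_000,
    rho: float = 0.8,
    ve_per_snp: float = 0.015,
    theta: float = 0.2,
    beta1: float = 0.25,
    direct: float = 0.05,
    maf_range: tuple = (0.1, 0.4),
) -> Study:
    """Simulate the full study layout with known ground truth.

    Each protein (and each risk factor, and the outcome's own polygenic
    background) occupies ``blocks_per_gene`` independent AR(1) LD blocks on
    its own chromosome, with one causal variant per block — so clumping
    leaves several independent cis-pQTL instruments per protein, as in the
    real proteome.  The first ``n_causal`` proteins causally raise the
    outcome by ``theta`` per standardised protein unit.  Risk factor R1
    affects the first protein (the mediator) with effect ``beta1`` and the
    outcome directly with ``direct``, so its total effect is
    c' = beta1*theta + direct.  Replication pQTLs (a smaller independent
    cohort) exist only for a subset of proteins, emulating incomplete
    replication coverage.  Phenome-wide outcomes include nulls, one planted
    protein effect, and a rare binary trait excluded by the >500-cases rule.
    """
    protein_ids = [f"P{i+1:02d}" for i in range(n_proteins)]
    rf_ids = [f"R{i+1}" for i in range(n_riskfactors)]
    entities = protein_ids + rf_ids + ["_OUTCOME_BG_"]
    bpg, bs = blocks_per_gene, block_size
    n_blocks = len(entities) * bpg
    m = n_blocks * bs
    cfg = SimulationConfig(
        seed=seed, n_blocks=n_blocks, block_size=bs, rho=rho,
        maf_range=maf_range,
    )
    root = np.random.default_rng(seed)
    mafs = root.uniform(*maf_range, size=m)

    # chromosome per entity; positions run contiguously across the
    # entity's blocks so the whole gene region sits inside one cis window
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    for i, _ in enumerate(entities):
        lo = i * bpg * bs
        chrom[lo:lo + bpg * bs] = str(i + 1)
        pos[lo:lo + bpg * bs] = 1_000_000 + 2_000 * np.arange(bpg * bs)

    def panel(n, salt):
        geno, ld = simulate_genotypes(
            cfg, n=n, rng=np.random.default_rng((seed, salt)), mafs=mafs)
        geno.chrom = chrom
        geno.pos = pos
        return geno, ld

    geno_x, ld = panel(n_exposure, 1)
    geno_y, _ = panel(n_outcome, 2)
    geno_rep, _ = panel(n_replication, 3)
    geno_rf, _ = panel(n_riskfactor_cohort, 4)
    rng = np.random.default_rng((seed, 5))

    def causal_indices(entity_idx):
        base = entity_idx * bpg * bs
        return [base + b * bs + bs // 2 for b in range(bpg)]

    def eff_map(entity_idx):
        return {j: effect_for_variance(ve_per_snp, mafs[j])
                for j in causal_indices(entity_idx)}

    prot_eff = {pid: eff_map(i) for i, pid in enumerate(protein_ids)}
    rf_eff = {rid: eff_map(n_proteins + i) for i, rid in enumerate(rf_ids)}
    out_bg_eff = eff_map(n_proteins + n_riskfactors)

    thetas = {pid: (theta if i < n_causal else 0.0)
              for i, pid in enumerate(protein_ids)}
    mediator = protein_ids[0]
    r1 = rf_ids[0]

    prot_vec = {pid: _effects_vector(m, eff) for pid, eff in prot_eff.items()}
    rf_vec = {rid: _effects_vector(m, eff) for rid, eff in rf_eff.items()}
    # the mediator protein also carries the risk factor's genetics
    prot_vec[mediator] = prot_vec[mediator] + beta1 * rf_vec[r1]
    out_vec = sum(thetas[pid] * prot_vec[pid] for pid in protein_ids)
    out_vec = out_vec + direct * rf_vec[r1] + _effects_vector(m, out_bg_eff)

    proteins = {pid: simulate_trait_gwas(geno_x, prot_vec[pid], rng, pid)
                for pid in protein_ids}
    outcome = simulate_trait_gwas(geno_y, out_vec, rng, "MCP")
    riskfactors = {rid: simulate_trait_gwas(geno_rf, rf_vec[rid], rng, rid)
                   for rid in rf_ids}

    # replication covers two causal proteins and two nulls
    rep_ids = [protein_ids[0], protein_ids[1],
               protein_ids[n_causal], protein_ids[n_causal + 1]]
    replication = {pid: simulate_trait_gwas(geno_rep, prot_vec[pid], rng, pid)
                   for pid in rep_ids}

    genes = {
        pid: GeneAnnotation(
            pid, str(i + 1), 1_000_000 + 2_000 * (bpg * bs // 2))
        for i, pid in enumerate(protein_ids)
    }

    # phenome-wide outcomes on the outcome cohort
    phewas: list[PhewasOutcome] = []
    planted = 0.3 * prot_vec[mediator]
    df = simulate_trait_gwas(geno_y, planted, rng, "PW_planted")
    phewas.append(PhewasOutcome(
        df, TraitMeta("PW_planted", n_outcome), "planted"))
    for j in range(4):
        df = simulate_trait_gwas(geno_y, np.zeros(m), rng, f"PW_null{j+1}")
        phewas.append(PhewasOutcome(
            df, TraitMeta(f"PW_null{j+1}", n_outcome), "null"))
    df, meta = simulate_binary_trait_gwas(
        geno_y, np.zeros(m), rng, "PW_binary_common", intercept=-3.0)
    phewas.append(PhewasOutcome(df, meta, "binary_null"))
    df, meta = simulate_binary_trait_gwas(
        geno_y, np.zeros(m), rng, "PW_binary_rare", intercept=-5.2)
    phewas.append(PhewasOutcome(df, meta, "binary_rare"))

    truth = {
        "theta": thetas,
        "causal_proteins": [p for p in protein_ids if thetas[p] != 0.0],
        "replication_proteins": rep_ids,
        "mediator": mediator,
        "mediation": {
            "risk_factor": r1, "mediator": mediator,
            "beta1": beta1, "beta2": thetas[mediator],
            "direct": direct,
            "c_prime": beta1 * thetas[mediator] + direct,
            "proportion": beta1 * thetas[mediator]
            / (beta1 * thetas[mediator] + direct),
        },
        "phewas_planted": {"trait": "PW_planted", "protein": mediator,
                           "effect": 0.3},
        "causal_snps": {pid: [geno_x.snp_ids[j] for j in eff]
                        for pid, eff in prot_eff.items()},
    }
    return Study(
        proteins=proteins, genes=genes, outcome=outcome,
        outcome_meta=TraitMeta("MCP", n_outcome), ld=ld,
        replication=replication, riskfactors=riskfactors,
        phewas=phewas, truth=truth,
    )
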