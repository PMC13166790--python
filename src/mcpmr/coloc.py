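"""Bayesian colocalization of two association signals at a locus.

Under the single-causal-variant-per-trait assumption, the evidence at a
locus of m shared variants decomposes over five hypotheses:

* H0 - no association with either trait,
* H1/H2 - association with trait 1 / trait 2 only,
* H3 - both traits associated, distinct causal variants,
* H4 - both traits associated, one shared causal variant.

Per-variant evidence is the Wakefield approximate Bayes factor computed
from the marginal (beta, se): with z = beta/se and shrinkage
r = W/(W + se^2) for effect-prior variance W,

    log ABF = 0.5 * [log(1 - r) + r * z^2].

Hypothesis sums are accumulated in log space (log-sum-exp); H3 is computed
stably as the full cross-product minus the shared-variant diagonal, never
by naive subtraction of probabilities.  Posteriors are proportional to
{1, p1*S1, p2*S2, p1*p2*S3, p12*S4} with per-variant prior probabilities
p1, p2 (single-trait causality) and p12 (shared causality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    locus_id: str
    n_variants: int
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    priors: tuple
    lead_shared_snp: str

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


def log_abf(beta, se, prior_sd: float = PRIOR_SD_QUANTITATIVE) -> np.ndarray:
    """Wakefield log approximate Bayes factor for marginal estimates."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * (np.log1p(-r) + r * z**2)


def coloc(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
    prior_sd1: float = PRIOR_SD_QUANTITATIVE,
    prior_sd2: float = PRIOR_SD_QUANTITATIVE,
    locus_id: str = "locus",
) -> ColocResult:
    """Colocalize two traits' summary statistics over their shared variants.

    ``trait1`` and ``trait2`` are canonical sumstats frames (``SNP``,
    ``BETA``, ``SE``); variants are intersected on SNP id.  Raises
    ``ValueError`` when the intersection is empty.
    """
    m = trait1[["SNP", "BETA", "SE"]].merge(
        trait2[["SNP", "BETA", "SE"]], on="SNP", suffixes=("_1", "_2")
    )
    if m.empty:
        raise ValueError("traits share no variants at this locus")

    l1 = log_abf(m["BETA_1"], m["SE_1"], prior_sd1)
    l2 = log_abf(m["BETA_2"], m["SE_2"], prior_sd2)

    ls1 = logsumexp(l1)                    # sum_j ABF1_j
    ls2 = logsumexp(l2)                    # sum_j ABF2_j
    ls4 = logsumexp(l1 + l2)               # sum_j ABF1_j*ABF2_j (shared)
    # H3: sum_{j != k} ABF1_j * ABF2_k = full cross product minus diagonal
    if len(m) > 1:
        full = ls1 + ls2
        with np.errstate(divide="ignore"):
            ls3 = full + np.log1p(-min(np.exp(ls4 - full), 1.0))
    else:
        ls3 = -np.inf

    logpost = np.array(
        [
            0.0,
            np.log(p1) + ls1,
            np.log(p2) + ls2,
            np.log(p1) + np.log(p2) + ls3 if np.isfinite(ls3) else -np.inf,
            np.log(p12) + ls4,
        ]
    )
    post = np.exp(logpost - logsumexp(logpost))
    post /= post.sum()

    lead = m["SNP"].iloc[int(np.argmax(l1 + l2))]
    return ColocResult(
        locus_id=locus_id, n_variants=len(m),
        pph0=float(post[0]), pph1=float(post[1]), pph2=float(post[2]),
        pph3=float(post[3]), pph4=float(post[4]),
        priors=(p1, p2, p12), lead_shared_snp=str(lead),
    )


def coloc_report_row(res: ColocResult, pph4_strong: float = 0.8) -> dict:
    """Flat dict for the TSV report, mirroring PPH0-4 plus PPH3+PPH4."""
    return {
        "locus_id": res.locus_id,
        "n_variants": res.n_variants,
        "PPH0": res.pph0, "PPH1": res.pph1, "PPH2": res.pph2,
        "PPH3": res.pph3, "PPH4": res.pph4,
        "PPH3_plus_PPH4": res.pph3 + res.pph4,
        "pph4_strong": res.pph4 > pph4_strong,
        "lead_shared_snp": res.lead_shared_snp,
    }
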