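"""Two-step mediation MR: risk factor -> protein mediator -> outcome.

Given three MR estimates on compatible scales —

* beta1: causal effect of the risk factor on the mediator protein,
* beta2: causal effect of the mediator on the outcome,
* c': total causal effect of the risk factor on the outcome —

the mediated (indirect) effect is beta1*beta2 with the Sobel standard
error sqrt(beta2^2 se1^2 + beta1^2 se2^2), and the proportion mediated is
beta1*beta2/c'.  The proportion's 95% CI uses a first-order delta method
over (beta1, beta2, c') treated as independent (two-sample designs with
non-overlapping instruments); a variant holding c' fixed is available.

A mediation pathway is flagged ``reliable`` only when the Sobel test is
significant, the mediated effect's sign agrees with the total effect, and
the total-effect analysis shows no directional pleiotropy — pathways whose
total effect fails the pleiotropy test are excluded regardless of the
Sobel p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import Z975, MREstimate


@dataclass
class MediationResult:
    """beta1/beta2/c' decomposition with Sobel p and proportion mediated."""

    risk_factor_id: str
    mediator_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    c_prime: float
    se_c: float
    mediated: float
    se_mediated: float
    sobel_p: float
    proportion: float
    prop_ci_low: float
    prop_ci_high: float
    reliable: bool

    @property
    def proportion_pct(self) -> str:
        """Percentage formatting, e.g. '20.49% [15.90%-25.07%]'."""
        return (
            f"{100 * self.proportion:.2f}% "
            f"[{100 * self.prop_ci_low:.2f}%-{100 * self.prop_ci_high:.2f}%]"
        )


def mediate(
    step1: MREstimate,
    step2: MREstimate,
    total: MREstimate,
    total_pleiotropy_p: float = 1.0,
    sobel_alpha: float = 0.05,
    pleiotropy_alpha: float = 0.05,
    c_prime_fixed: bool = False,
) -> MediationResult:
    """Combine the three MR legs into a mediation decomposition.

    ``total_pleiotropy_p`` is the pleiotropy (Egger intercept) p-value of
    the total-effect analysis; values below ``pleiotropy_alpha`` make the
    pathway unreliable.  ``c_prime_fixed=True`` drops the c' variance term
    from the proportion CI.

    Raises ``ValueError`` when c' = 0 (proportion undefined).
    """
    b1, s1 = step1.beta, step1.se
    b2, s2 = step2.beta, step2.se
    c, sc = total.beta, total.se
    if c == 0.0:
        raise ValueError("total effect c' = 0: proportion mediated undefined")

    mediated = b1 * b2
    se_med = float(np.sqrt(b2**2 * s1**2 + b1**2 * s2**2))
    if se_med == 0.0:
        sobel_p = 1.0 if mediated == 0.0 else 0.0
    else:
        sobel_p = float(2.0 * stats.norm.sf(abs(mediated) / se_med))

    proportion = mediated / c
    # first-order delta variance of b1*b2/c; algebraically equals
    # prop^2 * (s1^2/b1^2 + s2^2/b2^2 + sc^2/c^2) when b1, b2 != 0 but
    # stays defined at zero effects
    var_prop = (b2**2 * s1**2 + b1**2 * s2**2) / c**2
    if not c_prime_fixed:
        var_prop += mediated**2 * sc**2 / c**4
    sd_prop = float(np.sqrt(var_prop))

    reliable = (
        sobel_p < sobel_alpha
        and np.sign(mediated) == np.sign(c)
        and total_pleiotropy_p >= pleiotropy_alpha
    )
    return MediationResult(
        risk_factor_id=step1.exposure_id,
        mediator_id=step2.exposure_id,
        beta1=b1, se1=s1, beta2=b2, se2=s2,
        c_prime=c, se_c=sc,
        mediated=mediated, se_mediated=se_med, sobel_p=sobel_p,
        proportion=proportion,
        prop_ci_low=proportion - Z975 * sd_prop,
        prop_ci_high=proportion + Z975 * sd_prop,
        reliable=bool(reliable),
    )
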