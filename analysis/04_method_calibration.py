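"""Calibration and power of the individual tests, summary-level.

Fast repetition-heavy checks on the estimators themselves (no genotype
panels): type-I error of IVW and the Egger intercept, HEIDI size under a
shared causal variant, IVW effect recovery, PRESSO outlier detection and
Steiger orientation.  Writes results/method_calibration.tsv.

Run from the repository root:  python analysis/04_method_calibration.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mcpmr.estimators import egger, ivw, presso, steiger
from mcpmr.simulate import ar1_corr, simulate_iv_summary, simulate_locus_sumstats
from mcpmr.smr import heidi_test
from mcpmr.sumstats import LDMatrix, harmonize

SEED = 20240919
OUT = Path("results/method_calibration.tsv")


def main():
    rng = np.random.default_rng(SEED)
    rows = []

    reps = 2000
    rej = sum(ivw(simulate_iv_summary(rng, k=10, theta=0.0),
                  "random").pvalue < 0.05 for _ in range(reps))
    rows.append(("ivw_null_type1_error", rej / reps, reps, "nominal 0.05"))

    rej = sum(egger(simulate_iv_summary(rng, k=10, theta=0.1))
              .intercept_pvalue < 0.05 for _ in range(reps))
    rows.append(("egger_intercept_null_size", rej / reps, reps,
                 "nominal 0.05"))

    m = 40
    r = ar1_corr(m, 0.85)
    ldm = LDMatrix([f"rs{j:05d}" for j in range(m)], r)
    reps_h, rej = 1000, 0
    for _ in range(reps_h):
        t1, t2 = simulate_locus_sumstats(rng, r, 30.0, 8.0, m // 2)
        pairs = harmonize(t1, t2)
        top = pairs.loc[(pairs.beta_gx / pairs.se_gx).abs().idxmax(), "SNP"]
        p, _ = heidi_test(pairs, ldm, top)
        rej += p is not None and p < 0.05
    rows.append(("heidi_null_size", rej / reps_h, reps_h, "nominal 0.05"))

    est = [ivw(simulate_iv_summary(rng, k=10, theta=0.15), "random").beta
           for _ in range(500)]
    rows.append(("ivw_median_estimate", float(np.median(est)), 500,
                 "truth 0.15"))

    found = 0
    for rep in range(100):
        pairs = simulate_iv_summary(rng, k=20, theta=0.1, outlier_idx=7,
                                    outlier_shift_se=10.0)
        found += "iv007" in presso(pairs, n_sim=500,
                                   seed=SEED + rep).outlier_ids
    rows.append(("presso_outlier_detection_rate", found / 100, 100,
                 "10 se displacement"))

    fwd = sum(steiger(simulate_iv_summary(rng, k=10, theta=0.15))[1]
              for _ in range(200))
    rows.append(("steiger_forward_correct_rate", fwd / 200, 200,
                 "forward-causal"))

    table = pd.DataFrame(rows, columns=["check", "value", "n", "reference"])
    OUT.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT, sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
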