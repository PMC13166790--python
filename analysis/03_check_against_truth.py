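"""Compare the pipeline's calls with the generator's ground truth.

Reads the reports from 02 and the truth file the pipeline itself never
sees, and tabulates discovery sensitivity/specificity, tier assignments
versus the planted replication design, and recovery of the planted
mediation chain.  Writes results/truth_check.tsv.

Run after 02_run_pipeline.py:  python analysis/03_check_against_truth.py
"""

import json
from pathlib import Path

import pandas as pd

STUDY_DIR = Path("scratch/study")
REPORT_DIR = Path("results/pipeline")
OUT = Path("results/truth_check.tsv")


def main():
    truth = json.loads((STUDY_DIR / "truth" / "truth.json").read_text())
    disc = pd.read_csv(REPORT_DIR / "discovery.tsv", sep="\t")
    tiers = pd.read_csv(REPORT_DIR / "tiers.tsv", sep="\t")
    med = pd.read_csv(REPORT_DIR / "mediation.tsv", sep="\t")

    causal = set(truth["causal_proteins"])
    replicated = set(truth["replication_proteins"])
    called = set(disc.loc[disc["significant"] == True, "protein"])  # noqa: E712

    rows = []
    for pid in sorted(disc["protein"]):
        t = tiers.loc[tiers["protein"] == pid, "tier"]
        rows.append({
            "protein": pid,
            "true_effect": truth["theta"][pid],
            "called_significant": pid in called,
            "replication_available": pid in replicated,
            "tier": int(t.iloc[0]) if len(t) else None,
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT, sep="\t", index=False)

    tp = len(called & causal)
    fp = len(called - causal)
    print(f"discovery: {tp}/{len(causal)} causal proteins recovered, "
          f"{fp} false positives among {len(disc) - len(causal)} nulls")

    chain = truth["mediation"]
    hit = med.loc[(med["risk_factor"] == chain["risk_factor"])
                  & (med["mediator"] == chain["mediator"])]
    if len(hit) and bool(hit["legs_pass_fdr"].iloc[0]):
        est = hit["proportion_pct"].iloc[0]
        print(f"mediation chain recovered: proportion {est:.1f}% "
              f"(truth {100 * chain['proportion']:.1f}%)")
    else:
        print("mediation chain NOT recovered at FDR thresholds")
    print(f"per-protein table in {OUT}")


if __name__ == "__main__":
    main()
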