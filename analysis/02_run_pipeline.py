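"""Run the full proteome-wide MR workflow on the simulated study.

Discovery MR across all proteins, replication, reverse MR + Steiger,
SMR/HEIDI, colocalization, tier assignment, the mediation screen and
phenome-wide MR — all thresholds at the study defaults (genome-wide
p < 5e-8 instruments, clump r^2 < 0.001 in 10 Mb, cis 1 Mb, MHC excluded,
F > 10, FDR 0.05, coloc priors 1e-4/1e-4/1e-5).  Reports land in
results/pipeline/.

Run after 01_simulate_study.py:  python analysis/02_run_pipeline.py
"""

from pathlib import Path

from mcpmr.pipeline import RunConfig, load_study, run_all

STUDY_DIR = Path("scratch/study")
OUT_DIR = Path("results/pipeline")
SEED = 20240918


def main():
    study = load_study(STUDY_DIR)
    cfg = RunConfig(seed=SEED)
    reports = run_all(study, cfg, OUT_DIR)

    disc = reports["discovery"]
    sig = disc.loc[disc["significant"] == True]  # noqa: E712
    print(f"discovery: {len(sig)}/{len(disc)} proteins significant "
          f"after FDR (q < 0.05): {', '.join(sig['protein'])}")
    print(reports["tiers"][["protein", "tier", "replicated", "smr_pass",
                            "heidi_pass", "coloc_pass"]]
          .to_string(index=False))
    med = reports["mediation"]
    passed = med.loc[med["legs_pass_fdr"] == True]  # noqa: E712
    for _, row in passed.iterrows():
        rel = row.get("reliable", False)
        print(f"mediation {row.risk_factor} -> {row.mediator} -> MCP: "
              f"proportion {row.proportion_pct:.1f}% "
              f"[{row.prop_ci_low_pct:.1f}%, {row.prop_ci_high_pct:.1f}%], "
              f"Sobel p = {row.sobel_p:.2e}, reliable = {bool(rel)}")
    print(f"reports in {OUT_DIR}/")


if __name__ == "__main__":
    main()
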