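"""Generate the synthetic study inputs.

Builds a full proteome-MR study with known ground truth — 12 plasma
proteins (4 causal for the pain outcome), a Finngen-style smaller
replication cohort covering a subset of proteins, 3 modifiable risk
factors with one planted risk-factor -> protein -> outcome chain, and a
small phenome of extra outcomes — and writes it as a TSV directory under
scratch/study/ (inputs are bulky and regenerable, so they stay out of
results/).

Run from the repository root:  python analysis/01_simulate_study.py
"""

from pathlib import Path

from mcpmr.pipeline import write_study
from mcpmr.simulate import simulate_study

SEED = 20240917
STUDY_DIR = Path("scratch/study")


def main():
    study = simulate_study(seed=SEED)
    write_study(study, STUDY_DIR)
    n_snps = len(study.outcome)
    print(f"study written to {STUDY_DIR}/")
    print(f"  proteins: {len(study.proteins)} "
          f"(causal: {', '.join(study.truth['causal_proteins'])})")
    print(f"  replication cohort covers: "
          f"{', '.join(study.truth['replication_proteins'])}")
    print(f"  risk factors: {len(study.riskfactors)}; planted chain "
          f"{study.truth['mediation']['risk_factor']} -> "
          f"{study.truth['mediation']['mediator']} -> MCP "
          f"(true proportion mediated "
          f"{100 * study.truth['mediation']['proportion']:.1f}%)")
    print(f"  phenome outcomes: {len(study.phewas)}; variants: {n_snps}")


if __name__ == "__main__":
    main()
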