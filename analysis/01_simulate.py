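#!/usr/bin/env python
"""Generate the default synthetic study and record its ground truth.

Writes the planted-effect truth table and a study summary to results/, plus
a small fully materialised demo study (FASTA + annotations + scores + truth)
under results/data_demo/ for eyeballing the file formats. Downstream
analysis scripts regenerate the full default study in memory from the same
seed, so nothing bulky needs to live on disk.
"""

from pathlib import Path

import pandas as pd

from satmut import CategoryPlan, GeneratorConfig, simulate_study, write_study

RESULTS = Path(__file__).resolve().parents[1] / "results"
STUDY_SEED = 2026

DEMO_PLANS = {
    "functional": CategoryPlan(0.05, (1, 3)),
    "ptm": CategoryPlan(0.05, (1, 1)),
    "secondary_structure": CategoryPlan(0.30, (3, 8)),
    "domain": CategoryPlan(0.35, (10, 20)),
    "ppi": CategoryPlan(0.06, (2, 6)),
    "topology": CategoryPlan(0.45, (5, 15)),
}


def main() -> None:
    study = simulate_study(GeneratorConfig(seed=STUDY_SEED))
    RESULTS.mkdir(exist_ok=True)
    study.truth.to_csv(RESULTS / "planted_truth.tsv", sep="\t", index=False)

    summary = pd.DataFrame(
        [
            {
                "n_proteins": len(study.proteome),
                "total_residues": study.proteome.total_residues,
                "n_annotations": len(study.annotations),
                "n_variants": len(study.scan),
                "seed": STUDY_SEED,
            }
        ]
    )
    summary.to_csv(RESULTS / "study_summary.tsv", sep="\t", index=False)

    demo = simulate_study(
        GeneratorConfig(
            n_proteins=2, length_range=(40, 40), category_plans=DEMO_PLANS, seed=STUDY_SEED
        )
    )
    write_study(demo, RESULTS / "data_demo")

    print(f"default study: {summary.iloc[0].to_dict()}")
    print(f"planted truth -> {RESULTS / 'planted_truth.tsv'}")
    print(f"demo files -> {RESULTS / 'data_demo'} ({len(demo.scan)} scored variants)")


if __name__ == "__main__":
    main()
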