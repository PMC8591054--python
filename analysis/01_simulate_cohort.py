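"""Generate the study cohort: 300 tumors with three latent immune phenotypes.

Writes the full fixture set (expression, clinical incl. immunophenoscore,
MAF, ground truth) under results/cohort/.  Every later analysis step reads
these files, never this script's memory.
"""

from pathlib import Path

import pandas as pd

import iciscore as ic

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = ic.simulate_cohort(ic.SimulationConfig(seed=SEED))
    ic.write_expression(cohort.expression, OUT / "expression.tsv")
    ic.write_clinical(cohort.clinical, OUT / "clinical.tsv")
    cohort.maf.table.to_csv(OUT / "mutations.maf", sep="\t", index=False)
    cohort.true_fractions.to_csv(OUT / "true_fractions.tsv", sep="\t",
                                 index_label="sample_id")
    truth = pd.DataFrame({"phenotype": cohort.true_phenotype,
                          "latent_score": cohort.true_latent_score,
                          "response": cohort.response},
                         index=pd.Index(cohort.sample_ids, name="sample_id"))
    truth.to_csv(OUT / "truth.tsv", sep="\t")
    n_events = int(cohort.clinical.os_event.sum())
    print(f"cohort: {len(cohort.sample_ids)} samples, "
          f"{cohort.expression.shape[0]} genes, {len(cohort.maf)} variants, "
          f"{n_events} deaths -> {OUT}")


if __name__ == "__main__":
    main()
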