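"""Generate the synthetic study-like family cohort.

Writes subject and variant tables plus the generator's carrier ledger to
results/cohort/.  The cohort emulates the study design: 43 families,
~116 subjects at a 86:30 case:control balance, a pediatric-fracture
subphenotype among cases, enriched genes at the published odds ratios,
and a null background gene layer.
"""

import sys
from pathlib import Path

from famburden.io import write_cohort
from famburden.simulate import (
    SimulationConfig,
    generate_cohort_with_ledger,
    study_like_gene_specs,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(genes=study_like_gene_specs(), seed=SEED)
    cohort, ledger = generate_cohort_with_ledger(config)
    write_cohort(cohort, OUT / "subjects.tsv", OUT / "variants.tsv")
    with open(OUT / "carrier_ledger.tsv", "w") as fh:
        fh.write("gene\tcase_carriers\tcontrol_carriers\n")
        for gene in sorted(ledger.case_carriers):
            fh.write(f"{gene}\t{ledger.case_carriers[gene]}"
                     f"\t{ledger.control_carriers[gene]}\n")
    print(f"cohort: {len(cohort.subjects)} subjects in "
          f"{len(cohort.families())} families "
          f"({cohort.n_cases} cases / {cohort.n_controls} controls), "
          f"{len(cohort.calls)} variant calls")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
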