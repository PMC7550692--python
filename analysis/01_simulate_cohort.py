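"""Simulate the synthetic PDAC cohort and summarise driver-mutation frequencies.

Generates a 762-patient cohort at the default marginal mutation
frequencies (KRAS 90.43%, TP53 69.13%, SMAD4 23.21%, CDKN2A 20.66%) with
the TP53 co-occurrence link, builds per-patient driver profiles, and
writes the mutation/clinical/profile tables plus a frequency summary.
"""

import json
from pathlib import Path

from pdacdriver import CohortParams, build_profiles, frequency_summary, generate_cohort
from pdacdriver.io import write_tsv
from pdacdriver.mutation_profiles import filter_exonic

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    params = CohortParams(seed=20260926)
    mutations, clinical = generate_cohort(params)
    profiles = build_profiles(filter_exonic(mutations), clinical)
    write_tsv(mutations, OUT / "mutations.tsv")
    write_tsv(clinical, OUT / "clinical.tsv")
    write_tsv(profiles, OUT / "profiles.tsv")

    summary = frequency_summary(profiles)
    with open(OUT / "frequency_summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")

    print(f"cohort: {summary['n_patients']} patients, {len(mutations)} mutation rows")
    for gene, stats in summary["genes"].items():
        print(f"  {gene:7s} {stats['percent']:5.2f}%  ({stats['n_mutant']}/{stats['n_total']})")
    print(
        f"  multi-mutant (>=2 drivers): {summary['multi_mutant']['percent']:.2f}%, "
        f"of whom {summary['kras_among_multi']['percent']:.2f}% carry KRAS"
    )


if __name__ == "__main__":
    main()
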