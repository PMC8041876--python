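"""Deduce KIR-binding HLA ligand epitopes for the simulated cohort.

Reads results/cohort.tsv, assigns C1/C2/Bw4/A3-A11 epitope flags from
the HLA allele names against the packaged reference, and summarises
carriage and typing completeness.  Writes results/ligand_profiles.tsv.
"""

import csv
from pathlib import Path

from kirhla.cohort_io import read_cohort
from kirhla.hla_ligands import assign_epitopes

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    subjects = read_cohort(BASE / "cohort.tsv")
    for s in subjects:
        if s.hla is not None:
            s.ligands = assign_epitopes(s.hla.all_alleles)

    with open(BASE / "ligand_profiles.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject_id", "C1", "C2", "Bw4", "A3A11",
                    "C_typed", "B_typed", "A_typed"])
        for s in subjects:
            lig = s.ligands
            w.writerow([
                s.subject_id,
                *(int(getattr(lig, f)) if lig else "" for f in
                  ("c1_pos", "c2_pos", "bw4_pos", "a3a11_pos")),
                *(int(getattr(lig, f)) if lig else 0 for f in
                  ("c_typed", "b_typed", "a_typed")),
            ])

    for flag, typed, label in (
        ("c1_pos", "c_typed", "C1"), ("c2_pos", "c_typed", "C2"),
        ("bw4_pos", "b_typed", "Bw4"), ("a3a11_pos", "a_typed", "A3/A11"),
    ):
        typed_subjects = [s for s in subjects if s.ligands and getattr(s.ligands, typed)]
        pos = sum(getattr(s.ligands, flag) for s in typed_subjects)
        print(f"{label:7s} carriers: {pos}/{len(typed_subjects)} typed "
              f"({100 * pos / len(typed_subjects):.1f}%)")


if __name__ == "__main__":
    main()
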