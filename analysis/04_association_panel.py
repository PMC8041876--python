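"""Run the full carrier-frequency association panel on the cohort.

Reads results/cohort.tsv, derives ligand profiles, and tests every
marker family (16 KIR genes, AA/Bx, C4/T4, the 12 KIR+ligand
combinations) in each case stratum against controls with the two-tailed
Fisher exact test and Woolf 95% CIs.  Writes results/associations.tsv
and prints the markers significant at p < 0.05 for the pooled contrast.
"""

from pathlib import Path

from kirhla.assoc_stats import run_association_panel
from kirhla.cohort_io import read_cohort, write_association_table
from kirhla.hla_ligands import assign_epitopes
from kirhla.markers import build_markers

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    subjects = read_cohort(BASE / "cohort.tsv")
    for s in subjects:
        if s.hla is not None:
            s.ligands = assign_epitopes(s.hla.all_alleles)

    markers = build_markers(["genes", "haplogroups", "linkage", "combos"])
    results = run_association_panel(subjects, markers)
    write_association_table(results, BASE / "associations.tsv")
    print(f"{len(results)} marker x contrast results -> {BASE / 'associations.tsv'}")

    print("\nall cases vs controls, p < 0.05:")
    for r in results:
        if r.stratum == "all" and r.p_two_sided < 0.05:
            print(f"  {r.marker:30s} {r.freq_case:5.1f}% vs {r.freq_control:5.1f}%  "
                  f"p={r.p_two_sided:.4g}  OR {r.or_point:.2f} "
                  f"({r.ci_low:.2f}-{r.ci_high:.2f})")


if __name__ == "__main__":
    main()
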