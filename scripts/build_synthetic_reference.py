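"""Regenerate the packaged synthetic HLA exon-2 reference.

The packaged mini-reference (``src/kirhla/data/``) pairs real HLA class I
allele names and their real, textbook epitope assignments with *synthetic*
exon-2 nucleotide backbones — only the epitope-determining codons matter
to the pipeline, so everything else is deterministic constructed filler.
Each 270-bp sequence translates in frame to alpha-1 domain
residues 1-90 with:

* residue 76 (Val for HLA-C and for the C1-bearing B*46:01/B*73:01,
  Glu otherwise),
* residue 80 (Asn for C1, Lys for C2 HLA-C allotypes),
* the residue 77-83 Bw4/Bw6 motif for HLA-B and Bw4-bearing HLA-A,
* allele-unique barcode codons so every sequence is distinguishable.

Deterministic (fixed seed); run from the repository root:

    python scripts/build_synthetic_reference.py
"""

from __future__ import annotations

import random
from pathlib import Path

from Bio.Seq import Seq

OUT = Path(__file__).resolve().parents[1] / "src" / "kirhla" / "data"

# one sense codon per amino acid (no stops)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACA", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}
SENSE_CODONS = [
    c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if str(Seq(c).translate()) != "*"
]

# allele -> (c_epitope, b_epitope, a_epitope); epitopes are the real ones
ALLELES: dict[str, tuple[str, str, str]] = {}

for fam in ("01:01", "02:01", "26:01", "29:02", "30:01", "31:01",
            "33:01", "36:01", "68:01", "69:01"):
    ALLELES[f"A*{fam}"] = ("none", "none", "none")
for fam in ("03:01", "11:01"):
    ALLELES[f"A*{fam}"] = ("none", "none", "A3/A11")
for fam in ("23:01", "24:02", "25:01", "32:01"):
    ALLELES[f"A*{fam}"] = ("none", "Bw4", "none")

BW4_80T = ("13:02", "27:05", "37:01", "44:02", "44:03", "47:01")
BW4_80I = ("38:01", "49:01", "51:01", "52:01", "53:01", "57:01", "58:01")
BW6 = ("07:02", "08:01", "14:02", "15:01", "18:01", "35:01", "39:01",
       "40:01", "41:01", "50:01", "55:01", "56:01")
for fam in BW4_80T + BW4_80I:
    ALLELES[f"B*{fam}"] = ("none", "Bw4", "none")
for fam in BW6:
    ALLELES[f"B*{fam}"] = ("none", "Bw6", "none")
# Bw6 molecules carrying the C1 epitope (Val76 + Asn80)
ALLELES["B*46:01"] = ("C1", "Bw6", "none")
ALLELES["B*73:01"] = ("C1", "Bw6", "none")

C1 = ("01:02", "03:03", "03:04", "07:01", "07:02", "08:01", "08:02",
      "12:02", "12:03", "14:02", "16:01")
C2 = ("02:02", "04:01", "05:01", "06:02", "15:02", "17:01")
for fam in C1:
    ALLELES[f"C*{fam}"] = ("C1", "none", "none")
for fam in C2:
    ALLELES[f"C*{fam}"] = ("C2", "none", "none")

NEUTRAL_77_83 = "QDTELVE"  # not a Bw4 or Bw6 motif
BARCODE_CODONS = (9, 10, 11, 12, 44, 45, 60, 61)  # 0-based codon indices


def motif_for(allele: str, b_epi: str) -> str | None:
    locus, rest = allele.split("*")
    fam = rest.split(":")[0]
    if b_epi == "Bw6":
        return "SLRNLRG"
    if b_epi == "Bw4":
        if locus == "B" and rest in BW4_80I:
            return "NLRIALR"
        if locus == "A":
            return "NLRIALR"
        return "NLRTALR"
    if locus == "A":
        return NEUTRAL_77_83
    return None  # HLA-C: backbone motif, only codon 80 is set


def build() -> tuple[dict[str, str], list[str]]:
    rng = random.Random(20210412)
    backbones = {
        locus: [rng.choice(SENSE_CODONS) for _ in range(90)]
        for locus in ("A", "B", "C")
    }
    # keep backbone 77-83 neutral so untouched positions never fake a motif
    for locus in ("A", "B", "C"):
        for i, aa in enumerate(NEUTRAL_77_83):
            backbones[locus][76 + i] = CODON[aa]

    seqs: dict[str, str] = {}
    rows: list[str] = []
    for allele in sorted(ALLELES):
        c_epi, b_epi, a_epi = ALLELES[allele]
        locus = allele[0]
        codons = list(backbones[locus])
        codons[75] = CODON["V" if c_epi in ("C1",) or locus == "C" else "E"]
        motif = motif_for(allele, b_epi)
        if motif:
            for i, aa in enumerate(motif):
                codons[76 + i] = CODON[aa]
        if locus == "C":
            codons[79] = CODON["N" if c_epi == "C1" else "K"]
        for pos in BARCODE_CODONS:
            codons[pos] = rng.choice(SENSE_CODONS)
        seq = "".join(codons)
        assert len(seq) == 270 and "*" not in str(Seq(seq).translate())
        seqs[allele] = seq
        amplicon = "C" if allele == "B*73:01" else locus
        rows.append("\t".join([allele, locus, amplicon, c_epi, b_epi, a_epi]))

    assert len(set(seqs.values())) == len(seqs), "sequences must be unique"
    return seqs, rows


def main() -> None:
    seqs, rows = build()
    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "hla_exon2_synthetic.fasta", "w") as fh:
        for allele, seq in seqs.items():
            fh.write(f">{allele} synthetic exon-2 (epitope codons real)\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(OUT / "hla_epitopes.tsv", "w") as fh:
        fh.write("allele\tlocus\tamplicon_group\tc_epitope\tb_epitope\ta_epitope\n")
        fh.write("\n".join(rows) + "\n")
    print(f"wrote {len(seqs)} alleles to {OUT}")


if __name__ == "__main__":
    main()
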