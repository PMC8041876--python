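"""KIR-binding HLA class I ligand epitope assignment.

Four epitopes on HLA class I molecules serve as ligands for inhibitory
and activating KIR:

* **C1** (HLA-C with Asn at mature-protein position 80; also B*46:01 and
  B*73:01, which carry the C1 epitope through Val76+Asn80) — ligand of
  KIR2DL2/2DL3 (and weakly 2DS2).
* **C2** (HLA-C with Lys at position 80) — ligand of KIR2DL1 and 2DS1.
* **Bw4** (HLA-B, and some HLA-A, with an Arg83-type motif at residues
  77–83) — ligand of KIR3DL1/3DS1.  Bw6 molecules (Asn80/Gly83 motif)
  are not KIR ligands.
* **A3/A11** (HLA-A*03 and A*11) — ligand of KIR3DL2.

Epitopes are deduced from 2-field allele names against a packaged
reference, or from exon-2 sequence fragments matched against the
packaged exon-2 library (emulating direct sequencing of the exon that
encodes the ligand-determining residues).  The packaged reference is a
deterministic *synthetic* construction: allele names and their epitope
assignments are real, while the exon-2 backbones outside the
epitope-determining codons are constructed filler (see ``data/``).

One amplification quirk is modelled: the HLA-B PCR does not amplify
B*73:01 (reverse-primer site mutations), while the HLA-C amplification
does.  Locus-B sequence calls therefore never return B*73:01, but
locus-C calls may.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Epitope-determining protein motifs (mature-protein numbering)
# ---------------------------------------------------------------------------

#: Residue 77-83 motifs that carry the Bw4 epitope (Arg83; Ile/Thr 80).
BW4_MOTIFS: frozenset[str] = frozenset({"NLRIALR", "NLRTALR", "NLRTLLR", "DLRTLLR"})
#: Residue 77-83 motif of Bw6 molecules (Asn80, Gly83).
BW6_MOTIFS: frozenset[str] = frozenset({"SLRNLRG"})

#: HLA-A families carrying the A3/A11 epitope.
A3A11_FAMILIES: frozenset[str] = frozenset({"03", "11"})
#: HLA-A families carrying the Bw4 epitope.
HLA_A_BW4_FAMILIES: frozenset[str] = frozenset({"23", "24", "25", "32"})


def c_epitope_from_protein(protein: str) -> Optional[str]:
    """C1/C2 from the alpha-1 domain sequence (residues 1-90).

    C1 requires Val76 + Asn80 (satisfied by C1 HLA-C allotypes and by
    B*46:01/B*73:01); C2 is Lys80.  Returns ``"C1"``, ``"C2"`` or None.
    """
    if len(protein) < 83:
        raise ValueError("need at least 83 residues of the alpha-1 domain")
    if protein[79] == "K":
        return "C2"
    if protein[79] == "N" and protein[75] == "V":
        return "C1"
    return None


def b_epitope_from_protein(protein: str) -> Optional[str]:
    """Bw4/Bw6 from the residue 77-83 motif; None when neither."""
    motif = protein[76:83]
    if motif in BW4_MOTIFS:
        return "Bw4"
    if motif in BW6_MOTIFS:
        return "Bw6"
    return None


# ---------------------------------------------------------------------------
# Allele names
# ---------------------------------------------------------------------------

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?([ABC])\*(\d{2,})((?::\d{2,})+)$", re.IGNORECASE
)


@dataclass(frozen=True)
class AlleleName:
    """A 2-field molecular HLA class I allele name, e.g. ``C*04:01``."""

    locus: str
    family: str
    protein: str

    @property
    def name(self) -> str:
        return f"{self.locus}*{self.family}:{self.protein}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def parse_allele(text: str) -> AlleleName:
    """Parse and normalise an HLA allele name to 2-field resolution.

    Accepts an optional ``HLA-`` prefix and any letter case; fields
    beyond the protein field are truncated (logged).  Serologic names
    (``Cw4``, ``B27``) are rejected: the sequencing-based method yields
    molecular names only.
    """
    if not text or not text.strip():
        raise ValueError("empty allele name")
    token = text.strip()
    m = _ALLELE_RE.match(token)
    if not m:
        raise ValueError(f"unparseable HLA allele name: {token!r}")
    locus = m.group(1).upper()
    family = m.group(2)
    fields = m.group(3).lstrip(":").split(":")
    if len(fields) > 1:
        logger.info("truncating %r to 2-field resolution", token)
    return AlleleName(locus=locus, family=family, protein=fields[0])


# ---------------------------------------------------------------------------
# Ligand profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LigandProfile:
    """Per-subject KIR-ligand epitope carriage with typing availability.

    ``*_typed`` records whether the corresponding HLA locus was typed at
    all; combination denominators exclude subjects untyped at a locus
    the combination references.
    """

    c1_pos: bool = False
    c2_pos: bool = False
    bw4_pos: bool = False
    a3a11_pos: bool = False
    c_typed: bool = False
    b_typed: bool = False
    a_typed: bool = False


@dataclass(frozen=True)
class LigandOptions:
    """Tunable epitope-assignment policy.

    include_hla_a_bw4:
        Count Bw4-bearing HLA-A allotypes (A*23/24/25/32) toward Bw4
        positivity.  Off by default: sequencing-based ligand studies
        commonly score Bw4 on HLA-B only.
    unknown_allele_policy:
        ``"error"`` (default) or ``"unknown"``: skip the allele, keep
        the locus typed flag, and log a warning.
    """

    include_hla_a_bw4: bool = False
    unknown_allele_policy: str = "error"


# ---------------------------------------------------------------------------
# Packaged reference
# ---------------------------------------------------------------------------


@dataclass
class EpitopeReference:
    """Allele -> epitope table plus exon-2 sequence library.

    ``amplicon_group`` maps each allele to the locus-specific PCR that
    amplifies it (B*73:01 sits in the C group, not the B group).
    """

    epitopes: dict[str, dict[str, Optional[str]]]
    sequences: dict[str, str]
    amplicon_group: dict[str, str] = field(default_factory=dict)

    def alleles(self, locus: Optional[str] = None) -> list[str]:
        names = sorted(self.epitopes)
        if locus is None:
            return names
        return [a for a in names if a.startswith(f"{locus}*")]

    def amplified_by(self, locus: str) -> list[str]:
        """Alleles amplified by the locus-specific PCR."""
        return sorted(
            a for a, grp in self.amplicon_group.items() if grp == locus
        )


def load_reference(
    fasta_path=None, sidecar_path=None
) -> EpitopeReference:
    """Load the exon-2 FASTA + epitope sidecar (defaults to packaged)."""
    if fasta_path is None or sidecar_path is None:
        data = resources.files("kirhla") / "data"
        fasta_path = fasta_path or str(data / "hla_exon2_synthetic.fasta")
        sidecar_path = sidecar_path or str(data / "hla_epitopes.tsv")

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()

    epitopes: dict[str, dict[str, Optional[str]]] = {}
    amplicon: dict[str, str] = {}
    with open(sidecar_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            allele = row["allele"]
            epitopes[allele] = {
                "c_epitope": row["c_epitope"] or None,
                "b_epitope": row["b_epitope"] or None,
                "a_epitope": row["a_epitope"] or None,
            }
            for k in epitopes[allele]:
                if epitopes[allele][k] == "none":
                    epitopes[allele][k] = None
            amplicon[allele] = row["amplicon_group"]
    missing = set(epitopes) ^ set(sequences)
    if missing:
        raise ValueError(f"reference FASTA/sidecar mismatch: {sorted(missing)}")
    return EpitopeReference(epitopes, sequences, amplicon)


_REFERENCE: Optional[EpitopeReference] = None


def default_reference() -> EpitopeReference:
    global _REFERENCE
    if _REFERENCE is None:
        _REFERENCE = load_reference()
    return _REFERENCE


# ---------------------------------------------------------------------------
# Epitope assignment
# ---------------------------------------------------------------------------


def assign_epitopes(
    alleles: Iterable[AlleleName | str],
    reference: Optional[EpitopeReference] = None,
    options: LigandOptions = LigandOptions(),
) -> LigandProfile:
    """Deduce the KIR-ligand profile from assigned HLA alleles.

    Order-invariant and idempotent: each allele contributes its epitope
    flags by reference lookup, and a locus is ``typed`` when at least
    one allele of that locus is supplied.
    """
    reference = reference or default_reference()
    parsed = [a if isinstance(a, AlleleName) else parse_allele(a) for a in alleles]

    prof = LigandProfile()
    typed = {"A": False, "B": False, "C": False}
    for al in parsed:
        typed[al.locus] = True
        info = reference.epitopes.get(al.name)
        if info is None:
            if options.unknown_allele_policy == "unknown":
                logger.warning("allele %s not in reference; treated as unknown", al.name)
                continue
            raise KeyError(f"allele {al.name} not in packaged reference")
        if info["c_epitope"] == "C1":
            prof = replace(prof, c1_pos=True)
        elif info["c_epitope"] == "C2":
            prof = replace(prof, c2_pos=True)
        if info["b_epitope"] == "Bw4":
            if al.locus == "B" or options.include_hla_a_bw4:
                prof = replace(prof, bw4_pos=True)
        if info["a_epitope"] == "A3/A11":
            prof = replace(prof, a3a11_pos=True)
    return replace(
        prof, a_typed=typed["A"], b_typed=typed["B"], c_typed=typed["C"]
    )


# ---------------------------------------------------------------------------
# Exon-2 sequence matching
# ---------------------------------------------------------------------------

_IUPAC_CLASS = {
    code.upper(): "[" + "".join(sorted(bases)) + "]" if len(bases) > 1 else bases
    for code, bases in ambiguous_dna_values.items()
}


def _iupac_regex(read: str) -> re.Pattern:
    try:
        body = "".join(_IUPAC_CLASS[b] for b in read.upper())
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from exc
    return re.compile(body)


def _consistent(read: str, candidates: Sequence[str], reference: EpitopeReference) -> set[str]:
    rx = _iupac_regex(read)
    return {a for a in candidates if rx.search(reference.sequences[a])}


def call_alleles_from_exon2(
    read_fwd: str,
    read_rev: str,
    locus: str,
    reference: Optional[EpitopeReference] = None,
) -> list[AlleleName]:
    """Match bidirectional exon-2 reads against the packaged library.

    The reverse read is reverse-complemented, then each read is matched
    (IUPAC-ambiguity-aware exact substring) against the exon-2 sequences
    of every allele amplified by the locus-specific PCR.  All consistent
    alleles are returned.  Locus-B calls never return B*73:01; locus-C
    calls may, mirroring the amplification behaviour.

    Raises ``ValueError`` when the two reads each match reference
    alleles but no allele is consistent with both (discordant reads).
    """
    if locus not in ("A", "B", "C"):
        raise ValueError(f"locus must be A, B or C, got {locus!r}")
    reference = reference or default_reference()
    candidates = reference.amplified_by(locus)

    fwd_set = _consistent(read_fwd, candidates, reference)
    rev_set = _consistent(str(Seq(read_rev).reverse_complement()), candidates, reference)

    if fwd_set and rev_set and not (fwd_set & rev_set):
        raise ValueError(
            "forward and reverse reads match disjoint allele sets "
            f"({sorted(fwd_set)} vs {sorted(rev_set)})"
        )
    hits = fwd_set & rev_set
    if not hits:
        logger.warning("no %s-locus reference allele consistent with both reads", locus)
        return []
    return [parse_allele(a) for a in sorted(hits)]
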