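"""Per-subject KIR-receptor + HLA-ligand combination flags.

Each combination is a conjunction of KIR gene presence (``+``) or
absence (``-``) with ligand-epitope positivity, e.g. ``2DL1+C2+2DS1-``:
2DL1 present, the C2 epitope carried, and the activating counterpart
2DS1 absent.  Flags are tri-state: ``True`` / ``False`` / ``None``
(not evaluable).  A flag is not evaluable exactly when an HLA locus it
references is untyped — KIR genes are always typed — so per-combination
denominators vary with HLA typing completeness, as in the source data
where the control denominator is 256 for C-epitope rows, 233 for Bw4
rows and 125 for the A3/A11 row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .hla_ligands import LigandProfile
from .kir_classify import KIRProfile


@dataclass(frozen=True)
class ComboDef:
    """One KIR+ligand combination: gene requirements and ligand epitopes."""

    name: str
    kir_present: tuple[str, ...]
    kir_absent: tuple[str, ...]
    ligands: tuple[str, ...]  # epitope flags required positive

    #: HLA locus consulted per epitope (evaluability rule).
    _EPITOPE_LOCUS = {"C1": "C", "C2": "C", "Bw4": "B", "A3/A11": "A"}

    def referenced_loci(self) -> set[str]:
        return {self._EPITOPE_LOCUS[e] for e in self.ligands}


COMBOS: tuple[ComboDef, ...] = (
    ComboDef("2DL1+C2+", ("2DL1",), (), ("C2",)),
    ComboDef("2DL2+2DL3+C1+", ("2DL2", "2DL3"), (), ("C1",)),
    ComboDef("3DL1+Bw4+", ("3DL1",), (), ("Bw4",)),
    ComboDef("3DL2+A3/A11+", ("3DL2",), (), ("A3/A11",)),
    ComboDef("2DS1+C2+", ("2DS1",), (), ("C2",)),
    ComboDef("3DS1+Bw4+", ("3DS1",), (), ("Bw4",)),
    ComboDef("2DL1+C2+2DS1+", ("2DL1", "2DS1"), (), ("C2",)),
    ComboDef("2DL1+C2+2DS1-", ("2DL1",), ("2DS1",), ("C2",)),
    ComboDef("3DL1+Bw4+3DS1+", ("3DL1", "3DS1"), (), ("Bw4",)),
    ComboDef("3DL1+Bw4+3DS1-", ("3DL1",), ("3DS1",), ("Bw4",)),
    ComboDef(
        "2DL1+C2+3DL1+Bw4+2DS1+3DS1+",
        ("2DL1", "3DL1", "2DS1", "3DS1"), (), ("C2", "Bw4"),
    ),
    ComboDef(
        "2DL1+C2+3DL1+Bw4+2DS1-3DS1-",
        ("2DL1", "3DL1"), ("2DS1", "3DS1"), ("C2", "Bw4"),
    ),
)

COMBO_NAMES: tuple[str, ...] = tuple(c.name for c in COMBOS)

_LIGAND_FLAG = {
    "C1": "c1_pos",
    "C2": "c2_pos",
    "Bw4": "bw4_pos",
    "A3/A11": "a3a11_pos",
}
_LOCUS_TYPED = {"A": "a_typed", "B": "b_typed", "C": "c_typed"}


def derive_combos(
    kir: KIRProfile,
    ligands: Optional[LigandProfile],
    c1_pair_mode: str = "both",
) -> dict[str, Optional[bool]]:
    """Evaluate every tabulated KIR+ligand combination for one subject.

    ``c1_pair_mode`` controls the ``2DL2+2DL3+C1+`` row, whose label is
    ambiguous: ``"both"`` (default, literal reading) requires both genes
    present; ``"either"`` treats the pair as the C1-receptor group
    (2DL2 and/or 2DL3).
    """
    if c1_pair_mode not in ("both", "either"):
        raise ValueError(f"c1_pair_mode must be 'both' or 'either', got {c1_pair_mode!r}")

    out: dict[str, Optional[bool]] = {}
    for combo in COMBOS:
        loci = combo.referenced_loci()
        if ligands is None or any(
            not getattr(ligands, _LOCUS_TYPED[l]) for l in loci
        ):
            out[combo.name] = None
            continue
        if combo.name == "2DL2+2DL3+C1+" and c1_pair_mode == "either":
            genes_ok = kir.has("2DL2") or kir.has("2DL3")
        else:
            genes_ok = all(kir.has(g) for g in combo.kir_present)
        value = (
            genes_ok
            and not any(kir.has(g) for g in combo.kir_absent)
            and all(getattr(ligands, _LIGAND_FLAG[e]) for e in combo.ligands)
        )
        out[combo.name] = value
    return out
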