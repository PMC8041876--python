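"""Marker predicates for the association panel.

A marker is a named tri-state predicate over subjects: ``True`` /
``False`` for carriage, ``None`` when not evaluable (a referenced HLA
locus untyped).  KIR-only markers are always evaluable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from . import combos as combos_mod
from .combos import derive_combos
from .kir_classify import (
    KIR_LOCI,
    GenotypeRecord,
    classify_haplogroup,
    detect_linkage_groups,
)


@dataclass(frozen=True)
class Marker:
    name: str
    fn: Callable


def gene_markers(loci: Sequence[str] = KIR_LOCI) -> list[Marker]:
    return [
        Marker(locus, lambda s, _l=locus: s.kir.has(_l)) for locus in loci
    ]


def haplogroup_markers() -> list[Marker]:
    return [
        Marker("AA", lambda s: classify_haplogroup(s.kir) == "AA"),
        Marker("Bx", lambda s: classify_haplogroup(s.kir) == "Bx"),
    ]


def linkage_markers() -> list[Marker]:
    return [
        Marker("C4", lambda s: detect_linkage_groups(s.kir)["has_C4"]),
        Marker("T4", lambda s: detect_linkage_groups(s.kir)["has_T4"]),
    ]


def genotype_markers(catalog: Sequence[GenotypeRecord]) -> list[Marker]:
    return [
        Marker(
            f"genotype {rec.genotype_id}",
            lambda s, _p=rec.pattern: s.kir.pattern == _p,
        )
        for rec in catalog
    ]


def _ligand_flag(s, flag: str, typed: str) -> Optional[bool]:
    if s.ligands is None or not getattr(s.ligands, typed):
        return None
    return getattr(s.ligands, flag)


def ligand_markers() -> list[Marker]:
    defs = [
        ("C1", "c1_pos", "c_typed"),
        ("C2", "c2_pos", "c_typed"),
        ("Bw4", "bw4_pos", "b_typed"),
        ("A3/A11", "a3a11_pos", "a_typed"),
    ]
    return [
        Marker(name, lambda s, _f=flag, _t=typed: _ligand_flag(s, _f, _t))
        for name, flag, typed in defs
    ]


def combo_markers(c1_pair_mode: str = "both") -> list[Marker]:
    def make(name: str) -> Callable:
        def fn(s, _n=name):
            return derive_combos(s.kir, s.ligands, c1_pair_mode=c1_pair_mode)[_n]

        return fn

    return [Marker(name, make(name)) for name in combos_mod.COMBO_NAMES]


FAMILIES = ("genes", "haplogroups", "linkage", "ligands", "combos", "genotypes")


def build_markers(
    families: Sequence[str],
    catalog: Optional[Sequence[GenotypeRecord]] = None,
    c1_pair_mode: str = "both",
) -> list[Marker]:
    """Resolve marker-family names to Marker lists.

    ``genotypes`` requires a genotype catalog (from
    ``kir_classify.build_catalog``).
    """
    out: list[Marker] = []
    for fam in families:
        if fam == "genes":
            out += gene_markers()
        elif fam == "haplogroups":
            out += haplogroup_markers()
        elif fam == "linkage":
            out += linkage_markers()
        elif fam == "ligands":
            out += ligand_markers()
        elif fam == "combos":
            out += combo_markers(c1_pair_mode)
        elif fam == "genotypes":
            if catalog is None:
                raise ValueError("genotype markers need a catalog")
            out += genotype_markers(catalog)
        else:
            raise ValueError(f"unknown marker family {fam!r}; expected {FAMILIES}")
    return out
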