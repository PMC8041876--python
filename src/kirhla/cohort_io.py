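"""Cohort tables, configuration, and result rendering.

On-disk cohort schema (delimited text, header row)::

    subject_id  stratum  KIR3DL3 ... KIR3DL2  A_1 A_2 B_1 B_2 C_1 C_2

KIR columns hold 0/1 (blank is illegal); HLA columns hold 2-field allele
names and may be blank (untyped locus).  Framework-gene columns may be
omitted entirely, in which case the gene is imputed present (framework
genes are carried by all haplotypes) and a warning is logged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

from .hla_ligands import AlleleName, LigandProfile, parse_allele
from .kir_classify import (
    CASE_STRATA,
    FRAMEWORK_LOCI,
    KIR_LOCI,
    STRATA,
    UNKNOWN_STAGE,
    KIRProfile,
)

if TYPE_CHECKING:  # pragma: no cover
    from .assoc_stats import AssociationResult

logger = logging.getLogger(__name__)

KIR_COLUMNS = tuple(f"KIR{locus}" for locus in KIR_LOCI)
HLA_COLUMNS = ("A_1", "A_2", "B_1", "B_2", "C_1", "C_2")
#: `case` marks a case of unknown stage: counted in "all cases" only.
VALID_STRATA = (*STRATA, UNKNOWN_STAGE)


@dataclass
class HLATyping:
    """Up to two 2-field allele names per locus; absent locus = untyped."""

    alleles: dict[str, tuple[AlleleName, ...]] = field(default_factory=dict)

    def locus(self, locus: str) -> tuple[AlleleName, ...]:
        return self.alleles.get(locus, ())

    @property
    def all_alleles(self) -> list[AlleleName]:
        return [a for locus in sorted(self.alleles) for a in self.alleles[locus]]


@dataclass
class Subject:
    subject_id: str
    stratum: str
    kir: KIRProfile
    hla: Optional[HLATyping] = None
    ligands: Optional[LigandProfile] = None

    @property
    def is_case(self) -> bool:
        return self.stratum in CASE_STRATA


def _sniff_delimiter(path: Path, override: Optional[str]) -> str:
    if override:
        return override
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cohort(path, schema_config: Optional[Mapping] = None) -> list[Subject]:
    """Read a subject table into ``Subject`` records.

    ``schema_config`` may carry ``{"delimiter": ...}`` to override the
    extension-based delimiter choice.
    """
    path = Path(path)
    cfg = dict(schema_config or {})
    delim = _sniff_delimiter(path, cfg.get("delimiter"))

    subjects: list[Subject] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing_kir = [c for c in KIR_COLUMNS if c not in header]
        non_framework_missing = [
            c for c in missing_kir if c.removeprefix("KIR") not in FRAMEWORK_LOCI
        ]
        if non_framework_missing:
            raise ValueError(
                f"missing non-framework KIR columns: {non_framework_missing}"
            )
        if missing_kir:
            logger.warning(
                "framework columns %s absent; imputing present", missing_kir
            )
        for i, row in enumerate(reader, start=2):
            sid = (row.get("subject_id") or "").strip()
            if not sid:
                raise ValueError(f"row {i}: missing subject_id")
            if sid in seen:
                raise ValueError(f"duplicate subject_id {sid!r}")
            seen.add(sid)

            stratum = (row.get("stratum") or "").strip()
            if stratum not in VALID_STRATA:
                raise ValueError(
                    f"row {i} (subject {sid}): unknown stratum {stratum!r}; "
                    f"expected one of {VALID_STRATA}"
                )

            present = set()
            for col in KIR_COLUMNS:
                locus = col.removeprefix("KIR")
                if col in missing_kir:
                    present.add(locus)  # imputed framework gene
                    continue
                cell = (row.get(col) or "").strip()
                if cell not in ("0", "1"):
                    raise ValueError(
                        f"row {i} (subject {sid}): KIR cell {col}={cell!r} "
                        "must be 0 or 1"
                    )
                if cell == "1":
                    present.add(locus)
            kir = KIRProfile(frozenset(present))
            if kir.atypical:
                logger.warning("subject %s: atypical profile (framework gene absent)", sid)

            typing: dict[str, tuple[AlleleName, ...]] = {}
            for locus in ("A", "B", "C"):
                names = []
                for col in (f"{locus}_1", f"{locus}_2"):
                    cell = (row.get(col) or "").strip()
                    if cell:
                        names.append(parse_allele(cell))
                if names:
                    typing[locus] = tuple(names)
            hla = HLATyping(typing) if typing else None

            subjects.append(Subject(sid, stratum, kir, hla))
    return subjects


def write_cohort(subjects: Sequence[Subject], path, delimiter: str = "\t") -> None:
    """Write subjects in the canonical cohort schema (round-trips read_cohort)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["subject_id", "stratum", *KIR_COLUMNS, *HLA_COLUMNS])
        for s in subjects:
            hla_cells = []
            for locus in ("A", "B", "C"):
                alleles = s.hla.locus(locus) if s.hla else ()
                hla_cells += [
                    alleles[0].name if len(alleles) > 0 else "",
                    alleles[1].name if len(alleles) > 1 else "",
                ]
            w.writerow(
                [s.subject_id, s.stratum]
                + ["1" if l in s.kir.present else "0" for l in KIR_LOCI]
                + hla_cells
            )


# ---------------------------------------------------------------------------
# Result rendering
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (matches the published table rendering)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def write_association_table(results: Sequence["AssociationResult"], path) -> None:
    """Emit association results as a TSV in the published-table layout.

    Percentages are rendered to 1 decimal and OR/CI to 2 decimals,
    half-away-from-zero.
    """
    if not results:
        raise ValueError("no association results to write")
    cols = [
        "marker", "stratum", "pctF_case", "Npos_case", "n_case",
        "pctF_control", "Npos_control", "n_control", "p", "OR",
        "CI_low", "CI_high", "zero_cell_corrected",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(cols)
        for r in results:
            w.writerow([
                r.marker, r.stratum,
                f"{round_half_away(r.freq_case, 1):.1f}", r.table.a, r.table.n1,
                f"{round_half_away(r.freq_control, 1):.1f}", r.table.c, r.table.n0,
                f"{r.p_two_sided:.6g}",
                f"{round_half_away(r.or_point, 2):.2f}",
                f"{round_half_away(r.ci_low, 2):.2f}",
                f"{round_half_away(r.ci_high, 2):.2f}",
                int(r.zero_cell_corrected),
            ])


def load_config(path) -> dict:
    """Load the YAML run configuration (sections io, ligands, stats, simulate)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for section in ("io", "ligands", "stats", "simulate"):
        cfg.setdefault(section, {})
    return cfg
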