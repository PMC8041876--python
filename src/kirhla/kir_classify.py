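"""KIR gene-content classification.

The KIR locus (chromosome 19q13.4) shows presence/absence variation of
individual genes between haplotypes.  Two broad haplotype groups are
recognised: group A, with a fixed gene content of nine loci (the four
framework genes plus 2DL3-2DL1-2DP1 centromerically and 3DL1-2DS4
telomerically), and group B, carrying one or more of seven B-specific
genes (2DL2, 2DL5, 2DS1, 2DS2, 2DS3, 2DS5, 3DS1).  A diploid gene-content
genotype is *AA* when both haplotypes are group A — equivalently, when
only the nine A-genotype loci are present — and *Bx* otherwise.

Two tightly linked B-haplotype gene clusters are scored as units: the
centromeric *C4* group (2DS2-2DL2-2DS3-2DL5B) and the telomeric *T4*
group (3DS1-2DL5A-2DS5-2DS1).  Gene-content typing does not resolve
2DL5A from 2DL5B, so both group tests use the collapsed 2DL5 flag; this
is an approximation inherent to presence/absence typing resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: Canonical locus order used for 16-bit genotype patterns and file columns.
KIR_LOCI: tuple[str, ...] = (
    "3DL3", "2DS2", "2DL2", "2DL3", "2DP1", "2DL1", "3DP1", "2DL4",
    "3DL1", "3DS1", "2DL5", "2DS3", "2DS5", "2DS1", "2DS4", "3DL2",
)

#: Framework loci, carried by essentially all haplotypes.
FRAMEWORK_LOCI: frozenset[str] = frozenset({"3DL3", "3DP1", "2DL4", "3DL2"})

#: The nine loci that define the A genotype.
A_GENOTYPE_LOCI: frozenset[str] = frozenset(
    {"3DL3", "2DL3", "2DL1", "2DP1", "3DP1", "2DL4", "3DL1", "2DS4", "3DL2"}
)

#: The seven B-haplotype-specific loci.
B_SPECIFIC_LOCI: frozenset[str] = frozenset(
    {"2DL2", "2DL5", "2DS1", "2DS2", "2DS3", "2DS5", "3DS1"}
)

C4_LOCI: frozenset[str] = frozenset({"2DS2", "2DL2", "2DS3", "2DL5"})
T4_LOCI: frozenset[str] = frozenset({"3DS1", "2DL5", "2DS5", "2DS1"})


@dataclass(frozen=True)
class KIRProfile:
    """Presence/absence of the 16 KIR loci for one subject.

    Profiles missing a framework gene are accepted but flagged
    ``atypical`` rather than rejected: with real typing such profiles
    are resolved by re-typing, which an in-silico pipeline cannot do.
    """

    present: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.present - set(KIR_LOCI)
        if unknown:
            raise ValueError(f"unknown KIR loci: {sorted(unknown)}")

    @classmethod
    def from_flags(cls, flags: Mapping[str, bool]) -> "KIRProfile":
        return cls(frozenset(locus for locus, on in flags.items() if on))

    @classmethod
    def from_pattern(cls, pattern: str) -> "KIRProfile":
        """Build from a 16-character 0/1 string in canonical locus order."""
        if len(pattern) != len(KIR_LOCI) or set(pattern) - {"0", "1"}:
            raise ValueError(f"bad pattern {pattern!r}")
        return cls(frozenset(l for l, c in zip(KIR_LOCI, pattern) if c == "1"))

    def has(self, locus: str) -> bool:
        if locus not in KIR_LOCI:
            raise KeyError(locus)
        return locus in self.present

    @property
    def pattern(self) -> str:
        """16-character 0/1 string in canonical locus order."""
        return "".join("1" if l in self.present else "0" for l in KIR_LOCI)

    @property
    def atypical(self) -> bool:
        """True when a framework gene is missing."""
        return not FRAMEWORK_LOCI <= self.present


#: Canonical AA gene-content pattern (the nine A-genotype loci only).
AA_CANONICAL = KIRProfile(A_GENOTYPE_LOCI)


def classify_haplogroup(profile: KIRProfile) -> str:
    """Classify a gene-content profile as ``"AA"`` or ``"Bx"``.

    AA requires all nine A-genotype loci present and every B-specific
    locus absent; any profile carrying a B-specific gene is Bx.
    """
    if A_GENOTYPE_LOCI <= profile.present and not (
        B_SPECIFIC_LOCI & profile.present
    ):
        return "AA"
    return "Bx"


def detect_linkage_groups(profile: KIRProfile) -> dict[str, bool]:
    """Score the centromeric C4 and telomeric T4 linked gene clusters.

    Both tests use the collapsed 2DL5 presence flag in place of the
    unresolved 2DL5B (C4) / 2DL5A (T4) subtypes.
    """
    return {
        "has_C4": C4_LOCI <= profile.present,
        "has_T4": T4_LOCI <= profile.present,
    }


STRATA = ("control", "early", "advanced")
#: Extra stored label for cases of unknown stage; counted in "all" only.
UNKNOWN_STAGE = "case"
CASE_STRATA = ("early", "advanced", UNKNOWN_STAGE)


@dataclass
class GenotypeRecord:
    """One distinct 16-gene presence/absence pattern with cohort counts."""

    genotype_id: str
    pattern: str
    counts: dict[str, int] = field(default_factory=dict)
    freqs: dict[str, float] = field(default_factory=dict)

    @property
    def profile(self) -> KIRProfile:
        return KIRProfile.from_pattern(self.pattern)


def _stratum_groups(subjects: Sequence) -> dict[str, list]:
    groups: dict[str, list] = {s: [] for s in (*STRATA, "all")}
    for s in subjects:
        if s.stratum == "control":
            groups["control"].append(s)
        else:
            groups["all"].append(s)
            if s.stratum in ("early", "advanced"):
                groups[s.stratum].append(s)
    return groups


def build_catalog(
    subjects: Sequence,
    id_map: Optional[Mapping[str, str]] = None,
) -> list[GenotypeRecord]:
    """Catalogue the distinct KIR gene-content genotypes of a cohort.

    One record per distinct 16-bit pattern, with carrier counts and
    frequencies (%F = 100 N+/n) per stratum plus the pooled case group
    ``all``.  Patterns listed in ``id_map`` keep their mapped identifier;
    the rest are labelled G1, G2, ... in descending order of total
    count, ties broken by ascending big-endian value of the pattern.

    Parameters
    ----------
    subjects:
        Cohort members (``cohort_io.Subject``-like, needing ``.kir`` and
        ``.stratum``).
    id_map:
        Optional mapping of 16-character pattern -> genotype identifier.
    """
    if not subjects:
        raise ValueError("build_catalog requires at least one subject")
    if id_map is not None:
        if len(set(id_map)) != len(list(id_map)):
            raise ValueError("id_map contains duplicate patterns")
        for pat in id_map:
            KIRProfile.from_pattern(pat)  # validates

    groups = _stratum_groups(subjects)
    sizes = {k: len(v) for k, v in groups.items()}

    by_pattern: dict[str, dict[str, int]] = {}
    for name, members in groups.items():
        for subj in members:
            pat = subj.kir.pattern
            by_pattern.setdefault(pat, {k: 0 for k in groups})[name] += 1

    # total over non-overlapping strata only (all = early+advanced+unknown)
    def total(counts: dict[str, int]) -> int:
        return counts["control"] + counts["all"]

    ordered = sorted(
        by_pattern.items(), key=lambda kv: (-total(kv[1]), int(kv[0], 2))
    )

    records: list[GenotypeRecord] = []
    next_systematic = 1
    for pattern, counts in ordered:
        if id_map is not None and pattern in id_map:
            gid = id_map[pattern]
        else:
            gid = f"G{next_systematic}"
            next_systematic += 1
        freqs = {
            k: (100.0 * c / sizes[k]) if sizes[k] else float("nan")
            for k, c in counts.items()
        }
        records.append(GenotypeRecord(gid, pattern, counts, freqs))
    return records


def catalog_to_frame(records: Iterable[GenotypeRecord]) -> pd.DataFrame:
    """Flatten a genotype catalog into a table (one row per genotype)."""
    rows = []
    for rec in records:
        row: dict = {"genotype_id": rec.genotype_id, "pattern": rec.pattern}
        for k in ("control", "all", "early", "advanced"):
            row[f"N_{k}"] = rec.counts.get(k, 0)
            row[f"pctF_{k}"] = rec.freqs.get(k, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
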