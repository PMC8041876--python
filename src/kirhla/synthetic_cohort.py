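"""Synthetic case-control cohorts with KIR haplotype-pool structure.

Subjects are diploid: a KIR gene-content profile is the union of two
haplotypes drawn from a pool of (gene set, frequency) pairs, so linked
gene clusters (C4, T4) co-occur within profiles exactly as they do on
real haplotypes.  HLA ligand epitopes are drawn per chromosome
(Bernoulli per locus) and collapsed to carriage flags; per-locus
missingness emulates incomplete HLA typing.

Case arms can be *enriched* for named markers at specified target odds
ratios.  Enrichment exponentially tilts the exact joint distribution
over (diploid KIR pattern, ligand state) atoms; the tilt weights are
solved jointly so that every marker attains its target OR against the
control arm in expectation, even when markers overlap (e.g. T4 carriers
are a subset of Bx).  Sampling is categorical over the tilted atoms, so
within-profile linkage is preserved by construction.

The default pool (one A haplotype + seven B variants) is illustrative:
its frequencies echo the control-arm margins of the study population
this package models (AA about 28%, C4 about 33%, T4 about 22%), not an
inference from data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import root

from .assoc_stats import ContingencyTable
from .cohort_io import HLATyping, Subject
from .hla_ligands import LigandProfile, parse_allele
from .kir_classify import (
    A_GENOTYPE_LOCI,
    B_SPECIFIC_LOCI,
    FRAMEWORK_LOCI,
    KIRProfile,
    classify_haplogroup,
    detect_linkage_groups,
)

# ---------------------------------------------------------------------------
# Haplotype pool
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplotypePool:
    """Named KIR haplotypes (gene sets) with population frequencies."""

    haplotypes: tuple[tuple[str, frozenset, float], ...]

    def __post_init__(self) -> None:
        total = 0.0
        for name, genes, freq in self.haplotypes:
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"haplotype {name}: frequency {freq} outside [0,1]")
            if not FRAMEWORK_LOCI <= genes:
                raise ValueError(f"haplotype {name}: framework genes missing")
            is_a = genes == A_GENOTYPE_LOCI
            if not is_a and not (genes & B_SPECIFIC_LOCI):
                raise ValueError(
                    f"haplotype {name}: non-canonical-A haplotype without "
                    "any B-specific gene"
                )
            total += freq
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, _, f in self.haplotypes])

    def gene_frequency(self, locus: str) -> float:
        """Pool-summed frequency of haplotypes carrying ``locus``."""
        return sum(f for _, genes, f in self.haplotypes if locus in genes)


_FW = frozenset(FRAMEWORK_LOCI)
_CEN_A = frozenset({"2DL3", "2DP1", "2DL1"})
_TEL_A = frozenset({"3DL1", "2DS4"})
_CEN_B4 = frozenset({"2DS2", "2DL2", "2DS3", "2DL5"})  # full C4 motif
_TEL_B4 = frozenset({"3DS1", "2DL5", "2DS5", "2DS1"})  # full T4 motif

#: Illustrative default: 1 A haplotype + 7 B variants.  Frequencies give
#: control margins of AA ~28.1%, C4 carriage ~33.6%, T4 ~21.3%.
DEFAULT_POOL = HaplotypePool((
    ("A", A_GENOTYPE_LOCI, 0.53),
    ("B-cenB4-telA", _FW | _CEN_B4 | frozenset({"2DP1", "2DL1"}) | _TEL_A, 0.10),
    ("B-cenB4-telB4", _FW | _CEN_B4 | frozenset({"2DP1", "2DL1"}) | _TEL_B4, 0.085),
    ("B-cenA-telB4", _FW | _CEN_A | _TEL_B4, 0.03),
    ("B-cenB2-telA", _FW | frozenset({"2DS2", "2DL2", "2DL5", "2DP1", "2DL1"}) | _TEL_A, 0.125),
    ("B-cenA-telB2", _FW | _CEN_A | frozenset({"3DS1", "2DL5", "2DS1"}), 0.075),
    ("B-cenB1-telA", _FW | frozenset({"2DS2", "2DL2", "2DP1", "2DL1"}) | _TEL_A, 0.045),
    ("B-cenA-telB3", _FW | _CEN_A | frozenset({"3DS1", "2DL5", "2DS5"}), 0.01),
))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LigandFreqs:
    """Per-chromosome epitope probabilities and per-locus missingness.

    Defaults are chosen so control-arm carrier rates echo the study's
    control margins: C2 carriage ~75%, Bw4 ~64%, A3/A11 ~40%, and HLA
    typing completeness of ~92% (C), ~84% (B), ~45% (A).
    """

    p_c1: float = 0.5
    p_c2: float = 0.5
    p_bw4: float = 0.4
    p_a3a11: float = 0.225
    miss_a: float = 0.55
    miss_b: float = 0.16
    miss_c: float = 0.08

    def __post_init__(self) -> None:
        for name in ("p_c1", "p_c2", "p_bw4", "p_a3a11", "miss_a", "miss_b", "miss_c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.p_c1 + self.p_c2 > 1.0 + 1e-12:
            raise ValueError("p_c1 + p_c2 exceeds 1")


#: Enrichment predicates evaluate (KIRProfile, LigandProfile) -> bool.
EnrichmentPredicate = Callable[[KIRProfile, LigandProfile], bool]


def enrichment_predicate(name: str) -> EnrichmentPredicate:
    """Resolve a marker name to an enrichment predicate.

    Supported: ``AA``/``Bx``, ``C4``/``T4``, any single KIR locus, the
    ligand epitopes ``C1``/``C2``/``Bw4``/``A3/A11``.
    """
    if name in ("AA", "Bx"):
        return lambda kir, lig, _n=name: classify_haplogroup(kir) == _n
    if name in ("C4", "T4"):
        return lambda kir, lig, _n=name: detect_linkage_groups(kir)[f"has_{_n}"]
    if name in ("C1", "C2", "Bw4", "A3/A11"):
        attr = {"C1": "c1_pos", "C2": "c2_pos", "Bw4": "bw4_pos", "A3/A11": "a3a11_pos"}[name]
        return lambda kir, lig, _a=attr: getattr(lig, _a)
    # single KIR gene
    return lambda kir, lig, _n=name: kir.has(_n)


@dataclass
class CohortSimParams:
    """Full specification of a simulated case-control cohort."""

    n_control: int = 278
    n_early: int = 70
    n_advanced: int = 44
    n_unknown_stage: int = 48
    pool: HaplotypePool = field(default_factory=lambda: DEFAULT_POOL)
    ligands: LigandFreqs = field(default_factory=LigandFreqs)
    #: (marker name or predicate, target odds ratio) applied to case arms.
    enrichment: tuple = ()
    seed: int = 0
    #: "ligand" draws epitope flags directly; "allele" draws allele names
    #: from the packaged reference so the ligand caller can be exercised.
    hla_mode: str = "ligand"

    def __post_init__(self) -> None:
        for n in (self.n_control, self.n_early, self.n_advanced, self.n_unknown_stage):
            if n < 0:
                raise ValueError("stratum sizes must be >= 0")
        if self.hla_mode not in ("ligand", "allele"):
            raise ValueError(f"hla_mode {self.hla_mode!r}")


# ---------------------------------------------------------------------------
# Exact atom distribution and tilting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Atom:
    kir: KIRProfile
    ligands: LigandProfile  # all typed flags True; missingness applied later
    prob: float


def _kir_pattern_distribution(pool: HaplotypePool) -> dict[frozenset, float]:
    """Exact diploid gene-content distribution from haplotype pairs."""
    out: dict[frozenset, float] = {}
    haps = pool.haplotypes
    for (ni, gi, fi), (nj, gj, fj) in itertools.combinations_with_replacement(haps, 2):
        p = fi * fj if ni == nj else 2 * fi * fj
        if p == 0.0:
            continue
        union = frozenset(gi | gj)
        out[union] = out.get(union, 0.0) + p
    return out


def _ligand_state_distribution(lf: LigandFreqs) -> list[tuple[LigandProfile, float]]:
    """Exact distribution of diploid epitope-carriage flags."""
    p0 = 1.0 - lf.p_c1 - lf.p_c2
    c_states = {
        (False, False): p0 * p0,
        (True, False): lf.p_c1 ** 2 + 2 * lf.p_c1 * p0,
        (False, True): lf.p_c2 ** 2 + 2 * lf.p_c2 * p0,
        (True, True): 2 * lf.p_c1 * lf.p_c2,
    }
    b_states = {True: 1 - (1 - lf.p_bw4) ** 2, False: (1 - lf.p_bw4) ** 2}
    a_states = {True: 1 - (1 - lf.p_a3a11) ** 2, False: (1 - lf.p_a3a11) ** 2}

    states = []
    for (c1, c2), pc in c_states.items():
        if pc == 0.0:
            continue
        for bw4, pb in b_states.items():
            for a3, pa in a_states.items():
                prof = LigandProfile(
                    c1_pos=c1, c2_pos=c2, bw4_pos=bw4, a3a11_pos=a3,
                    c_typed=True, b_typed=True, a_typed=True,
                )
                states.append((prof, pc * pb * pa))
    return states


def _atoms(params: CohortSimParams) -> list[_Atom]:
    kir_dist = _kir_pattern_distribution(params.pool)
    lig_dist = _ligand_state_distribution(params.ligands)
    return [
        _Atom(KIRProfile(genes), lig, pk * pl)
        for genes, pk in kir_dist.items()
        for lig, pl in lig_dist
    ]


def _resolve_enrichment(
    enrichment,
) -> list[tuple[str, EnrichmentPredicate, float]]:
    resolved = []
    for marker, target_or in enrichment:
        if callable(marker):
            resolved.append((getattr(marker, "__name__", "custom"), marker, float(target_or)))
        else:
            resolved.append((str(marker), enrichment_predicate(marker), float(target_or)))
    return resolved


def case_tilt(
    atoms: Sequence[_Atom], enrichment
) -> np.ndarray:
    """Tilted case-arm atom probabilities hitting every target OR.

    Solves exp-tilt weights w_m jointly: Q_i proportional to
    P_i * prod_m w_m^[marker m positive on atom i], such that the tilted
    marginal carrier probability of each marker equals the probability
    whose odds are OR_m times the control-arm odds.
    """
    probs = np.array([a.prob for a in atoms])
    probs = probs / probs.sum()
    resolved = _resolve_enrichment(enrichment)
    if not resolved:
        return probs

    M = np.array(
        [[1.0 if pred(a.kir, a.ligands) else 0.0 for a in atoms] for _, pred, _ in resolved]
    )
    q0 = M @ probs
    targets = np.empty(len(resolved))
    for m, (name, _, target_or) in enumerate(resolved):
        if q0[m] <= 0.0 or q0[m] >= 1.0:
            if target_or != 1.0:
                raise ValueError(
                    f"enrichment target OR {target_or} for {name!r} unreachable: "
                    f"control carrier probability is {q0[m]:.3g}"
                )
            targets[m] = q0[m]
        else:
            odds = target_or * q0[m] / (1.0 - q0[m])
            targets[m] = odds / (1.0 + odds)

    def tilted(logw: np.ndarray) -> np.ndarray:
        w = np.exp(M.T @ logw)  # per-atom product of weights
        q = probs * w
        q /= q.sum()
        return q

    def residual(logw: np.ndarray) -> np.ndarray:
        return M @ tilted(logw) - targets

    x0 = np.array([
        math.log(t * (1 - q) / (q * (1 - t))) if 0 < q < 1 else 0.0
        for q, t in zip(q0, targets)
    ])
    sol = root(residual, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(residual(sol.x))) > 1e-8:
        raise RuntimeError(f"tilt solve failed: {sol.message}")
    return tilted(sol.x)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _apply_missingness(
    lig: LigandProfile, rng: np.random.Generator, lf: LigandFreqs
) -> LigandProfile:
    u = rng.random(3)
    c_typed = u[0] >= lf.miss_c
    b_typed = u[1] >= lf.miss_b
    a_typed = u[2] >= lf.miss_a
    return LigandProfile(
        c1_pos=lig.c1_pos and c_typed,
        c2_pos=lig.c2_pos and c_typed,
        bw4_pos=lig.bw4_pos and b_typed,
        a3a11_pos=lig.a3a11_pos and a_typed,
        c_typed=c_typed, b_typed=b_typed, a_typed=a_typed,
    )


def _alleles_for_state(
    lig: LigandProfile, rng: np.random.Generator, lf: LigandFreqs, reference
) -> HLATyping:
    """Draw allele names from the packaged reference consistent with flags.

    C1-carrying HLA-B allotypes (B*46:01, B*73:01) are excluded from the
    draw so that allele-mode ligand profiles reproduce the sampled flags
    exactly.
    """
    by = {
        "C1": [a for a in reference.alleles("C") if reference.epitopes[a]["c_epitope"] == "C1"],
        "C2": [a for a in reference.alleles("C") if reference.epitopes[a]["c_epitope"] == "C2"],
        "Bw4": [a for a in reference.alleles("B") if reference.epitopes[a]["b_epitope"] == "Bw4"],
        "Bw6": [
            a for a in reference.alleles("B")
            if reference.epitopes[a]["b_epitope"] == "Bw6"
            and reference.epitopes[a]["c_epitope"] is None
        ],
        "A3/A11": [a for a in reference.alleles("A") if reference.epitopes[a]["a_epitope"] == "A3/A11"],
        "A-other": [a for a in reference.alleles("A") if reference.epitopes[a]["a_epitope"] is None],
    }

    def pick(group: str) -> str:
        alleles = by[group]
        return alleles[rng.integers(len(alleles))]

    def pair(flag_pair: tuple[str, ...], p_first: float) -> list[str]:
        # chromosome states conditional on at-least-one when flag is set
        first, other = flag_pair
        s1 = first if rng.random() < p_first else other
        s2 = first if rng.random() < p_first else other
        if s1 != first and s2 != first:
            s1 = first  # condition on carriage
        return [pick(s1), pick(s2)]

    typing: dict[str, tuple] = {}
    if lig.c_typed:
        if lig.c1_pos and lig.c2_pos:
            names = [pick("C1"), pick("C2")]
        elif lig.c1_pos:
            names = [pick("C1"), pick("C1")]
        else:
            names = [pick("C2"), pick("C2")]
        typing["C"] = tuple(parse_allele(n) for n in names)
    if lig.b_typed:
        if lig.bw4_pos:
            names = pair(("Bw4", "Bw6"), lf.p_bw4)
        else:
            names = [pick("Bw6"), pick("Bw6")]
        typing["B"] = tuple(parse_allele(n) for n in names)
    if lig.a_typed:
        if lig.a3a11_pos:
            names = pair(("A3/A11", "A-other"), lf.p_a3a11)
        else:
            names = [pick("A-other"), pick("A-other")]
        typing["A"] = tuple(parse_allele(n) for n in names)
    return HLATyping(typing)


def simulate_cohort(params: CohortSimParams) -> list[Subject]:
    """Draw a reproducible synthetic cohort.

    Control subjects follow the pool's diploid distribution exactly;
    case strata (early, advanced, unknown-stage) follow the tilted
    distribution implied by ``params.enrichment``.  With
    ``hla_mode="allele"`` subjects carry HLA allele names (ligands left
    for the epitope-assignment stage); with ``"ligand"`` the epitope
    flags are set directly.
    """
    rng = np.random.default_rng(params.seed)
    atoms = _atoms(params)
    p_control = np.array([a.prob for a in atoms])
    p_control = p_control / p_control.sum()
    p_case = case_tilt(atoms, params.enrichment)

    reference = None
    if params.hla_mode == "allele":
        from .hla_ligands import default_reference

        reference = default_reference()

    subjects: list[Subject] = []
    plan = [
        ("control", params.n_control, p_control, "ctl"),
        ("early", params.n_early, p_case, "ear"),
        ("advanced", params.n_advanced, p_case, "adv"),
        ("case", params.n_unknown_stage, p_case, "cas"),
    ]
    for stratum, n, dist, prefix in plan:
        if n == 0:
            continue
        idx = rng.choice(len(atoms), size=n, p=dist)
        for k, i in enumerate(idx, start=1):
            atom = atoms[i]
            lig = _apply_missingness(atom.ligands, rng, params.ligands)
            if params.hla_mode == "allele":
                hla = _alleles_for_state(lig, rng, params.ligands, reference)
                subj = Subject(f"{prefix}{k:05d}", stratum, atom.kir, hla=hla)
            else:
                subj = Subject(f"{prefix}{k:05d}", stratum, atom.kir, ligands=lig)
            subjects.append(subj)
    return subjects


def expected_carrier_probability(
    params: CohortSimParams, marker: str | EnrichmentPredicate, arm: str = "control"
) -> float:
    """Closed-form carrier probability of a marker under the pool (or tilt)."""
    atoms = _atoms(params)
    probs = np.array([a.prob for a in atoms])
    probs = probs / probs.sum()
    if arm == "case":
        probs = case_tilt(atoms, params.enrichment)
    pred = marker if callable(marker) else enrichment_predicate(marker)
    return float(sum(p for a, p in zip(atoms, probs) if pred(a.kir, a.ligands)))


# ---------------------------------------------------------------------------
# Published contingency fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureTable:
    """A 2x2 carrier table assembled from published counts.

    ``printed_or``/``printed_ci``/``printed_p`` hold the values printed
    alongside those counts *only when they reproduce from the counts*
    (Woolf z=1.96, point-probability Fisher) at printed precision;
    published statistics that are internally inconsistent with their own
    counts are carried as ``None`` and documented in the methods note.
    """

    marker: str
    stratum: str
    a: int
    b: int
    c: int
    d: int
    printed_or: Optional[float] = None
    printed_ci: Optional[tuple[float, float]] = None
    printed_p: Optional[float] = None

    @property
    def table(self) -> ContingencyTable:
        return ContingencyTable(self.a, self.b, self.c, self.d)


def _t1(marker, npos_ctl, npos_all, npos_adv, all_stats=None, adv_stats=None):
    """Expand a published gene-table row into per-contrast fixtures."""
    rows = []
    for stratum, npos_case, n_case, stats in (
        ("all", npos_all, 162, all_stats),
        ("advanced", npos_adv, 44, adv_stats),
    ):
        kw = {}
        if stats:
            kw = dict(zip(("printed_or", "printed_ci", "printed_p"), stats))
        rows.append(
            FixtureTable(
                marker, stratum, npos_case, n_case - npos_case,
                npos_ctl, 278 - npos_ctl, **kw
            )
        )
    return rows


def fixture_tables() -> list[FixtureTable]:
    """The published 2x2 carrier tables (genotype, gene, and combination).

    Counts come from the published frequency tables (controls n=278,
    all cases n=162, advanced n=44; combination rows carry their own
    denominators reflecting HLA typing completeness).
    """
    t: list[FixtureTable] = []
    # --- genotype / linkage-group / gene rows ---------------------------
    # advanced-contrast p's printed as 0.003 trace to a Wald test, not
    # Fisher on the counts (which gives 0.0014); carried as None.
    t += _t1("AA", 78, 27, 3,
             (0.51, (0.31, 0.84), 0.007), (0.19, (0.06, 0.62), None))
    t += _t1("Bx", 200, 135, 41,
             (1.95, (1.19, 3.18), 0.007), (5.33, (1.60, 17.72), None))
    t += _t1("C4", 93, 58, 12)
    t += _t1("T4", 60, 60, 20,
             (2.14, (1.39, 3.28), 0.0005), (3.03, (1.57, 5.85), 0.001))
    t += _t1("2DL1", 272, 157, 42)
    t += _t1("2DL3", 252, 120, 31,
             (0.29, (0.17, 0.50), None), (None, (0.11, None), None))
    t += _t1("3DL1", 266, 146, 39, (0.41, (0.19, 0.89), None))
    t += _t1("2DS4", 267, 148, 40, (0.44, (0.19, 0.98), None))
    t += _t1("2DL2", 166, 113, 32, (1.56, (1.03, None), None))
    t += _t1("2DL5", 163, 111, 31, (1.54, (1.02, None), None))
    # 3DS1 advanced: published OR 2.88 does not follow from its own
    # counts (26/44 vs 95/278 give 2.78); probable erratum, no goldens.
    t += _t1("3DS1", 95, 75, 26, (1.66, None, None))
    t += _t1("2DS1", 101, 90, 31,
             (2.19, (1.48, 3.25), None), (4.18, (2.09, 8.35), 0.0001))
    t += _t1("2DS2", 152, 85, 19)
    t += _t1("2DS3", 109, 66, 14)
    t += _t1("2DS5", 71, 70, 23,
             (2.22, (1.47, 3.35), 0.0001), (3.19, (1.67, 6.12), 0.0005))
    t += _t1("2DL4", 278, 162, 44)
    t += _t1("3DL2", 278, 162, 44)
    t += _t1("3DL3", 278, 162, 44)
    t += _t1("2DP1", 271, 143, 38,
             (0.19, (0.08, 0.47), None), (0.16, (0.05, 0.51), None))
    t += _t1("3DP1", 278, 162, 44)
    # --- individual genotypes (results text) ----------------------------
    t.append(FixtureTable("genotype #1", "all", 8, 154, 34, 244,
                          0.37, (0.17, 0.83), None))
    t.append(FixtureTable("genotype #1", "advanced", 0, 44, 34, 244,
                          0.08, (0.005, 1.32), None))
    t.append(FixtureTable("genotype #42", "all", 7, 155, 2, 276,
                          6.23, (1.28, 30.4), None))
    t.append(FixtureTable("genotype #42", "advanced", 4, 40, 2, 276,
                          13.8, (2.45, 77.8), None))
    # --- KIR + ligand combinations (printed counts; the published ORs for
    # these rows trace to the printed percentages, not the counts, so no
    # goldens are attached) ----------------------------------------------
    combo_rows = [
        ("2DL1+C2+", (192, 256), (93, 135), (31, 38)),
        ("2DL2+2DL3+C1+", (92, 256), (50, 140), (15, 38)),
        ("3DL1+Bw4+", (143, 233), (62, 116), (20, 32)),
        ("3DL2+A3/A11+", (50, 125), (39, 92), (7, 22)),
        ("2DS1+C2+", (73, 256), (53, 135), (22, 38)),
        ("3DS1+Bw4+", (46, 233), (37, 116), (12, 32)),
        ("2DL1+C2+2DS1+", (72, 256), (51, 135), (22, 38)),
        ("2DL1+C2+2DS1-", (120, 256), (42, 135), (9, 38)),
        ("3DL1+Bw4+3DS1+", (41, 233), (30, 116), (12, 32)),
        ("3DL1+Bw4+3DS1-", (102, 233), (32, 116), (8, 32)),
        ("2DL1+C2+3DL1+Bw4+2DS1+3DS1+", (30, 233), (19, 116), (8, 32)),
        ("2DL1+C2+3DL1+Bw4+2DS1-3DS1-", (66, 233), (19, 116), (5, 32)),
    ]
    for marker, (c_pos, c_n), (all_pos, all_n), (adv_pos, adv_n) in combo_rows:
        t.append(FixtureTable(marker, "all", all_pos, all_n - all_pos,
                              c_pos, c_n - c_pos))
        t.append(FixtureTable(marker, "advanced", adv_pos, adv_n - adv_pos,
                              c_pos, c_n - c_pos))
    return t
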