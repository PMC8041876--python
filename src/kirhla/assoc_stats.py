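"""Carrier-frequency case-control association statistics.

For each marker (gene, genotype, linkage group, ligand, or KIR+ligand
combination) and each case stratum, a 2x2 carrier table is formed over
the subjects evaluable for that marker, and three quantities are
reported, following standard immunogenetic case-control practice:

* the two-tailed Fisher exact probability, by the point-probability
  rule: the sum of hypergeometric probabilities of all tables with the
  observed margins that are no more probable than the observed table;
* the odds ratio OR = ad/bc;
* its 95% confidence interval by the Woolf logit method,
  exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)), with the
  Haldane-Anscombe +0.5 correction applied to every cell when any cell
  is zero (the correction flag is carried on the result).

No multiple-testing adjustment is applied by default; an optional
Bonferroni-adjusted column can be annotated for reuse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom, norm

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_io import Subject

#: Relative log-probability slack when comparing table probabilities for
#: the two-sided rule; absorbs floating-point error on exact ties.
_TIE_EPS = 1e-7

#: z quantile used for 95% CIs.  1.96 (not the fuller-precision normal
#: quantile) matches the convention of the published tables.
Z_DEFAULT = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: cases (a carriers, b non) vs controls (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n0(self) -> int:
        return self.c + self.d

    def swapped_arms(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass
class AssociationResult:
    marker: str
    stratum: str
    freq_case: float
    freq_control: float
    p_two_sided: float
    or_point: float
    ci_low: float
    ci_high: float
    zero_cell_corrected: bool
    table: ContingencyTable
    p_bonferroni: Optional[float] = None


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-tailed Fisher exact p by the point-probability rule.

    Conditioning on both margins, the carrier count among cases follows
    a hypergeometric distribution; p is the total probability of all
    outcomes whose point probability does not exceed that of the
    observed table.  Computed in log space for numerical stability.
    """
    M = t.a + t.b + t.c + t.d
    K = t.a + t.c  # carriers overall
    N = t.n1       # cases drawn
    if M == 0:
        raise ValueError("empty table")
    kmin = max(0, N - (M - K))
    kmax = min(N, K)
    ks = np.arange(kmin, kmax + 1)
    logp = hypergeom.logpmf(ks, M, K, N)
    log_obs = hypergeom.logpmf(t.a, M, K, N)
    mask = logp <= log_obs + _TIE_EPS
    p = float(np.exp(logp[mask]).sum())
    return min(p, 1.0)


def odds_ratio_ci(
    t: ContingencyTable,
    alpha: float = 0.05,
    z: Optional[float] = Z_DEFAULT,
) -> dict:
    """Odds ratio with Woolf (logit) confidence interval.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to all
    four cells) for both the point estimate and the interval.  Two zero
    cells on a diagonal leave the OR undefined and raise ``ValueError``.
    ``z`` defaults to 1.96; pass ``z=None`` to use the exact normal
    quantile for ``alpha``.
    """
    if (t.a == 0 and t.d == 0) or (t.b == 0 and t.c == 0):
        raise ValueError("odds ratio undefined: zero cells on a diagonal")
    if z is None:
        z = float(norm.ppf(1 - alpha / 2))

    corrected = 0 in (t.a, t.b, t.c, t.d)
    shift = 0.5 if corrected else 0.0
    a, b, c, d = (t.a + shift, t.b + shift, t.c + shift, t.d + shift)

    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_point)
    return {
        "or_point": or_point,
        "ci_low": math.exp(log_or - z * se),
        "ci_high": math.exp(log_or + z * se),
        "zero_cell_corrected": corrected,
    }


# ---------------------------------------------------------------------------
# Cohort-level panel
# ---------------------------------------------------------------------------

Predicate = Callable[["Subject"], Optional[bool]]

CONTRASTS = ("all", "early", "advanced")


def _in_stratum(subject: "Subject", stratum: str) -> bool:
    if stratum == "all":
        return subject.is_case
    if stratum == "control":
        return subject.stratum == "control"
    return subject.stratum == stratum


def carrier_frequency(
    subjects: Sequence["Subject"], predicate: Predicate, stratum: str
) -> dict:
    """Carrier percentage over evaluable subjects of one stratum.

    ``stratum`` is ``control``, ``early``, ``advanced`` or ``all``
    (every case, including unknown stage).  Subjects on whom the marker
    is not evaluable (untyped HLA locus) are excluded from ``n``.
    """
    flags = [predicate(s) for s in subjects if _in_stratum(s, stratum)]
    evaluable = [f for f in flags if f is not None]
    n = len(evaluable)
    if n == 0:
        raise ValueError(f"empty denominator for stratum {stratum!r}")
    n_pos = sum(evaluable)
    return {"pct": 100.0 * n_pos / n, "n_pos": n_pos, "n": n}


def contingency_from_subjects(
    subjects: Sequence["Subject"], predicate: Predicate, case_stratum: str
) -> ContingencyTable:
    case = carrier_frequency(subjects, predicate, case_stratum)
    ctrl = carrier_frequency(subjects, predicate, "control")
    return ContingencyTable(
        case["n_pos"], case["n"] - case["n_pos"],
        ctrl["n_pos"], ctrl["n"] - ctrl["n_pos"],
    )


def run_association_panel(
    subjects: Sequence["Subject"],
    markers: Iterable,
    contrasts: Sequence[str] = CONTRASTS,
    alpha: float = 0.05,
    z: Optional[float] = Z_DEFAULT,
    bonferroni: bool = False,
) -> list[AssociationResult]:
    """One association result per marker x (case stratum vs controls).

    ``markers`` are ``markers.Marker`` objects (name + tri-state
    predicate).  Unadjusted p-values are reported; with ``bonferroni``
    an adjusted value (p x number of tests, capped at 1) is annotated.
    """
    markers = list(markers)
    bad = [m for m in contrasts if m not in CONTRASTS]
    if bad:
        raise ValueError(f"unknown contrasts: {bad}")

    results: list[AssociationResult] = []
    for marker in markers:
        for contrast in contrasts:
            t = contingency_from_subjects(subjects, marker.fn, contrast)
            orci = odds_ratio_ci(t, alpha=alpha, z=z)
            results.append(
                AssociationResult(
                    marker=marker.name,
                    stratum=contrast,
                    freq_case=100.0 * t.a / t.n1,
                    freq_control=100.0 * t.c / t.n0,
                    p_two_sided=fisher_exact_two_sided(t),
                    table=t,
                    **orci,
                )
            )
    if bonferroni:
        m = len(results)
        for r in results:
            r.p_bonferroni = min(1.0, r.p_two_sided * m)
    return results
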