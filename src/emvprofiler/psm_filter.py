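"""Target-decoy PSM filtering.

The false-positive rate of a composite forward+reverse database search is
estimated as

    FPR = 2 * N_rev / (N_rev + N_fwd)

where N_rev and N_fwd count retained reverse- and forward-database matches.
The filter cascade gates on ion score (strict), parent and fragment mass
tolerance (strict), missed cleavages (inclusive) and peptide probability
(inclusive); the ion-score threshold is then optimized to maximize the
number of retained forward peptides subject to an FPR ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import PSMRecord


@dataclass(frozen=True)
class FilterThresholds:
    """Gate settings of the filter cascade.

    ``min_ion_score`` is a strict lower bound (score must exceed it);
    ``min_probability`` is inclusive; mass tolerances are strict upper
    bounds on the absolute error.
    """

    min_ion_score: float = 40.0
    max_parent_error_da: float = 0.1
    max_fragment_error_da: float = 0.2
    max_missed_cleavages: int = 1
    min_probability: float = 0.90
    fpr_max: float = 0.005

    def __post_init__(self) -> None:
        if self.max_parent_error_da <= 0 or self.max_fragment_error_da <= 0:
            raise ValueError("mass tolerances must be positive")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not 0.0 <= self.min_probability <= 1.0:
            raise ValueError("min_probability must be in [0, 1]")
        if not 0.0 < self.fpr_max <= 1.0:
            raise ValueError("fpr_max must be in (0, 1]")


@dataclass
class FilterResult:
    """Outcome of one filter application.

    PSM-level counts (``n_fwd``, ``n_rev``, ``fpr``) are canonical;
    peptide-level counts (distinct (peptide, charge) pairs) are reported
    alongside because threshold optimization maximizes peptides.
    """

    retained: list[PSMRecord]
    n_fwd: int
    n_rev: int
    fpr: float
    thresholds_used: FilterThresholds
    n_fwd_peptides: int = 0
    n_rev_peptides: int = 0
    fpr_peptide: float = 0.0
    constraint_met: bool = True

    def summary(self) -> dict:
        t = self.thresholds_used
        return {
            "n_retained": len(self.retained),
            "n_fwd": self.n_fwd,
            "n_rev": self.n_rev,
            "fpr": self.fpr,
            "n_fwd_peptides": self.n_fwd_peptides,
            "n_rev_peptides": self.n_rev_peptides,
            "fpr_peptide": self.fpr_peptide,
            "constraint_met": self.constraint_met,
            "thresholds": {
                "min_ion_score": t.min_ion_score,
                "max_parent_error_da": t.max_parent_error_da,
                "max_fragment_error_da": t.max_fragment_error_da,
                "max_missed_cleavages": t.max_missed_cleavages,
                "min_probability": t.min_probability,
                "fpr_max": t.fpr_max,
            },
        }


def compute_fpr(n_rev: int, n_fwd: int) -> float:
    """Target-decoy false-positive rate 2*n_rev/(n_rev+n_fwd), capped at 1."""
    if n_rev < 0 or n_fwd < 0:
        raise ValueError("counts must be non-negative")
    if n_rev + n_fwd == 0:
        raise ValueError("no retained peptides: FPR undefined")
    return min(1.0, 2.0 * n_rev / (n_rev + n_fwd))


def _passes(psm: PSMRecord, t: FilterThresholds) -> bool:
    return (psm.ion_score > t.min_ion_score
            and abs(psm.parent_error_da) < t.max_parent_error_da
            and psm.fragment_error_da < t.max_fragment_error_da
            and psm.missed_cleavages <= t.max_missed_cleavages
            and psm.probability >= t.min_probability)


def _peptide_counts(retained: Iterable[PSMRecord]) -> tuple[int, int]:
    fwd, rev = set(), set()
    for p in retained:
        (rev if p.is_decoy else fwd).add((p.peptide, p.charge))
    return len(fwd), len(rev)


def apply_filters(psms: Sequence[PSMRecord],
                  thresholds: FilterThresholds | None = None) -> FilterResult:
    """Apply the full gate cascade and compute the FPR of the retained set.

    An empty retained set is reported with FPR 0 by convention (no decoy
    evidence of false positives, but also nothing identified).
    """
    if not psms:
        raise ValueError("empty PSM input")
    t = thresholds or FilterThresholds()
    retained = [p for p in psms if _passes(p, t)]
    n_rev = sum(1 for p in retained if p.is_decoy)
    n_fwd = len(retained) - n_rev
    fpr = compute_fpr(n_rev, n_fwd) if retained else 0.0
    n_fwd_pep, n_rev_pep = _peptide_counts(retained)
    fpr_pep = (compute_fpr(n_rev_pep, n_fwd_pep)
               if (n_fwd_pep + n_rev_pep) else 0.0)
    return FilterResult(
        retained=retained, n_fwd=n_fwd, n_rev=n_rev, fpr=fpr,
        thresholds_used=t, n_fwd_peptides=n_fwd_pep,
        n_rev_peptides=n_rev_pep, fpr_peptide=fpr_pep,
        constraint_met=fpr <= t.fpr_max,
    )


def optimize_thresholds(psms: Sequence[PSMRecord],
                        fpr_max: float = 0.005,
                        grid: Sequence[float] = tuple(range(10, 85, 5)),
                        base: FilterThresholds | None = None) -> FilterResult:
    """Search the ion-score grid for the threshold that maximizes retained
    forward peptides subject to FPR <= fpr_max.

    Only the ion-score gate is searched; the secondary gates stay at their
    defaults (or ``base``). Ties are broken toward lower achieved FPR, then
    the higher (more conservative) score threshold. If no grid point meets
    the ceiling, the minimum-FPR point is returned with ``constraint_met``
    False.
    """
    if not psms:
        raise ValueError("empty PSM input")
    if not grid:
        raise ValueError("empty score-threshold grid")
    base = base or FilterThresholds()

    results: list[FilterResult] = []
    for score in grid:
        t = FilterThresholds(
            min_ion_score=float(score),
            max_parent_error_da=base.max_parent_error_da,
            max_fragment_error_da=base.max_fragment_error_da,
            max_missed_cleavages=base.max_missed_cleavages,
            min_probability=base.min_probability,
            fpr_max=fpr_max,
        )
        results.append(apply_filters(psms, t))

    feasible = [r for r in results if r.fpr <= fpr_max]
    if feasible:
        best = max(feasible, key=lambda r: (
            r.n_fwd_peptides, -r.fpr, r.thresholds_used.min_ion_score))
        best.constraint_met = True
        return best
    best = min(results, key=lambda r: (r.fpr, -r.thresholds_used.min_ion_score))
    best.constraint_met = False
    return best
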