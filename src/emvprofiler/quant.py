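"""MS1 signal-fraction quantification and small-sample group comparison.

The MS signal of a protein group is the sum of intensities of ions whose
assigned peptide maps to at least one group member; the total MS signal
sums every ion in the run, including unassigned features, so a group's
signal fraction is its share of everything the instrument saw.

Shared peptides count fully toward every matching group (no razor
splitting), so fractions of overlapping groups can sum above 1; reports
flag when this occurs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

from .io_formats import IonFeature, ProteinEntry


@dataclass
class SignalReport:
    group_id: str
    group_signal: float
    total_signal: float
    fraction: float

    def __post_init__(self) -> None:
        if self.total_signal <= 0:
            raise ValueError("total_signal must be positive")


def group_signal(ions: Sequence[IonFeature],
                 peptide_to_proteins: Mapping[str, set[str]],
                 group: set[str]) -> float:
    """Sum of intensities of ions assigned to any protein in ``group``.

    Each ion counts at most once per group, however many group members its
    peptide maps to. An assigned peptide missing from the mapping is an
    error (it would silently leak signal otherwise).
    """
    total = 0.0
    for ion in ions:
        if ion.peptide is None:
            continue
        if ion.peptide not in peptide_to_proteins:
            raise KeyError(
                f"assigned peptide '{ion.peptide}' absent from peptide-to-"
                "protein mapping")
        if peptide_to_proteins[ion.peptide] & group:
            total += ion.intensity
    return total


def total_signal(ions: Sequence[IonFeature],
                 include_unassigned: bool = True) -> float:
    """Total MS signal of the run (by default: every ion, assigned or not)."""
    return sum(i.intensity for i in ions
               if include_unassigned or i.peptide is not None)


def signal_fraction(ions: Sequence[IonFeature],
                    peptide_to_proteins: Mapping[str, set[str]],
                    group: set[str],
                    group_id: str = "group",
                    include_unassigned: bool = True) -> SignalReport:
    """Fraction of total MS signal attributable to ``group``."""
    tot = total_signal(ions, include_unassigned)
    if tot <= 0:
        raise ValueError("total MS signal is zero")
    g = group_signal(ions, peptide_to_proteins, group)
    return SignalReport(group_id=group_id, group_signal=g,
                        total_signal=tot, fraction=g / tot)


def fold_enrichment(report_a: SignalReport, report_b: SignalReport) -> float:
    """Per-protein fold-enrichment of a group between two runs.

    Computed on the odds scale, (f_a/(1-f_a)) / (f_b/(1-f_b)): the ratio of
    group to non-group signal in each run. A uniform k-fold scaling of
    every group member's intensities in run *a* moves this statistic by
    exactly k, which the plain fraction ratio does not once the group's
    share is no longer small. The plain ratio f_a/f_b is reported by the
    pipeline alongside.
    """
    fa, fb = report_a.fraction, report_b.fraction
    if fb <= 0 or fa >= 1 or fb >= 1:
        raise ValueError("fold enrichment undefined for fractions 0 or 1")
    return (fa / (1 - fa)) / (fb / (1 - fb))


def group_by_family(proteins: Iterable[ProteinEntry]) -> dict[str, set[str]]:
    """Partition accessions by family symbol (e.g. ACTB/ACTG1 -> 'ACT')."""
    out: dict[str, set[str]] = {}
    for p in proteins:
        out.setdefault(p.family_symbol, set()).add(p.accession)
    return out


def _midranks(values: Sequence[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def _u_statistic(ranks: Sequence[float], a_idx: Iterable[int], n: int) -> float:
    rank_sum = sum(ranks[i] for i in a_idx)
    return rank_sum - n * (n + 1) / 2


def mann_whitney_exact(a: Sequence[float],
                       b: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by complete enumeration.

    Enumerates all C(n+m, n) assignments of the pooled observations to the
    two groups, with midranks for ties; the two-sided p-value is the
    fraction of assignments whose U deviates from the null mean nm/2 at
    least as far as the observed U. Restricted to n+m <= 12, the regime
    where exact enumeration is the only meaningful option (e.g. triplicate
    versus triplicate comparisons).
    """
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    n, m = len(a), len(b)
    if n + m > 12:
        raise ValueError(
            "combined sample size > 12: use a normal-approximation test")
    pooled = list(a) + list(b)
    ranks = _midranks(pooled)
    u_obs = _u_statistic(ranks, range(n), n)
    mean_u = n * m / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = comb(n + m, n)
    extreme = 0
    eps = 1e-12
    for a_idx in itertools.combinations(range(n + m), n):
        u = _u_statistic(ranks, a_idx, n)
        if abs(u - mean_u) >= dev_obs - eps:
            extreme += 1
    return u_obs, extreme / total
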