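"""Catalog overlap and permutation over-representation analysis.

Identified protein lists are compared against marker catalogs and membrane
proteomes by exact set overlap (2- or 3-way Venn regions), and flat
category annotations are tested for over-representation against random
same-size lists drawn from a reference proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ProteinEntry


def normalize_id(identifier: str) -> str:
    """Canonical identifier form: uppercase, isoform suffix ("-n") stripped."""
    return identifier.upper().split("-")[0]


def normalize_ids(identifiers: Iterable[str]) -> set[str]:
    return {normalize_id(i) for i in identifiers}


@dataclass
class VennCounts:
    """Exact region counts of a 2- or 3-set overlap.

    ``regions`` is keyed by the sorted "|"-joined membership signature,
    e.g. ``"A"``, ``"A|B"``, ``"A|B|C"``.
    """

    set_names: tuple[str, ...]
    regions: dict[str, int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


@dataclass
class OverrepResult:
    category: str
    observed: int
    null_counts: list[int]
    p_empirical: float
    B: int


def venn(sets: Mapping[str, set[str]]) -> VennCounts:
    """Region counts for 2 or 3 named sets by membership signature."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn supports exactly 2 or 3 sets")
    names = tuple(sets)
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    # every non-empty membership signature, including empty regions
    import itertools
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            regions["|".join(combo)] = 0
    for element in universe:
        signature = "|".join(n for n in names if element in sets[n])
        regions[signature] += 1
    return VennCounts(set_names=names, regions=regions)


def marker_overlap(identified: set[str],
                   marker_families: Mapping[str, str]
                   ) -> tuple[int, int, set[str]]:
    """How many marker families have at least one identified member.

    ``marker_families`` maps a marker accession to its family symbol.
    Returns (families found, families total, found family symbols).
    """
    families = set(marker_families.values())
    found = {fam for acc, fam in marker_families.items() if acc in identified}
    return len(found), len(families), found


def overrep_test(list_proteins: set[str],
                 reference: Sequence[ProteinEntry],
                 category: str,
                 B: int = 100,
                 seed: int = 0) -> OverrepResult:
    """Permutation over-representation of one category tag.

    Draws B random accession lists of size |list_proteins| without
    replacement from the reference proteome, counts category members in
    each, and reports the add-one empirical p-value
    (1 + #{null >= observed}) / (B + 1), whose floor is 1/(B+1); with the
    default B=100 no p below ~0.0099 is reportable.
    """
    n = len(list_proteins)
    if n > len(reference):
        raise ValueError("query list larger than the reference proteome")
    cat_members = {p.accession for p in reference if category in p.categories}
    if not cat_members:
        raise ValueError(f"category '{category}' absent from reference")
    observed = len(list_proteins & cat_members)

    rng = np.random.default_rng(seed)
    accessions = np.array([p.accession for p in reference])
    in_cat = np.array([a in cat_members for a in accessions])
    null_counts = [int(in_cat[rng.choice(len(accessions), size=n,
                                         replace=False)].sum())
                   for _ in range(B)]
    p = (1 + sum(c >= observed for c in null_counts)) / (B + 1)
    return OverrepResult(category=category, observed=observed,
                         null_counts=null_counts, p_empirical=p, B=B)
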