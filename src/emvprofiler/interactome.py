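"""In-silico cell-cell interactomics.

Counts potential surface protein-protein interactions between the surface
proteome of extracellular microvesicles and a target cell's surface
proteome, against a user-supplied PPI edge list. An interaction is a
distinct unordered protein pair with one side on each surface; a pair
supported by multiple database records counts once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import ProteinEntry


@dataclass
class InteractionSummary:
    n_emv_partnered: int
    n_target_partnered: int
    n_interactions: int
    edges: list[tuple[str, str]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_emv_partnered": self.n_emv_partnered,
            "n_target_partnered": self.n_target_partnered,
            "n_interactions": self.n_interactions,
        }


def count_interactions(emv_surface: set[str],
                       target_surface: set[str],
                       ppi_edges: Iterable[frozenset[str] | tuple[str, str]]
                       ) -> InteractionSummary:
    """Cross-surface interactions implied by a PPI edge list.

    Both orientations of each unordered edge are checked; a self-edge of a
    protein present on both surfaces counts as one interaction partnering
    that protein on each side. Empty inputs yield an all-zero summary.
    """
    pairs: set[tuple[str, str]] = set()
    for edge in ppi_edges:
        nodes = tuple(edge) if not isinstance(edge, frozenset) else tuple(edge)
        if len(nodes) == 1:
            x = y = nodes[0]
        else:
            x, y = nodes[0], nodes[1]
        for a, b in ((x, y), (y, x)):
            if a in emv_surface and b in target_surface:
                pairs.add((a, b))
    # unordered pair counted once even if both orientations qualify
    seen: set[frozenset[str]] = set()
    edges: list[tuple[str, str]] = []
    for a, b in sorted(pairs):
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        edges.append((a, b))
    return InteractionSummary(
        n_emv_partnered=len({a for a, _ in edges}),
        n_target_partnered=len({b for _, b in edges}),
        n_interactions=len(edges),
        edges=edges,
    )


def surface_filter(proteins: Iterable[ProteinEntry],
                   annotated: set[str] | None = None) -> set[str]:
    """Accessions flagged as cell-surface proteins.

    Surface/intracellular annotation is an input, not inferred; when
    ``annotated`` (the set of accessions whose flag is trusted) is given,
    any protein outside it is an error.
    """
    proteins = list(proteins)
    if annotated is not None:
        missing = sorted({p.accession for p in proteins
                          if p.accession not in annotated})
        if missing:
            raise ValueError(
                "proteins without surface annotation: " + ", ".join(missing))
    return {p.accession for p in proteins if p.is_surface}
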