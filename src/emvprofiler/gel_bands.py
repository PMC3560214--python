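"""Gel-band molecular-weight concordance analysis.

Proteins identified in an SDS-PAGE band are compared against the band's
observed MW range (from the marker lane): a theoretical MW above the upper
bound indicates a degraded/truncated product running faster than the intact
protein; below the lower bound suggests post-translational modification
retarding migration. Per band, the analysis reports the share of MS signal
carried by each class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence


class MWClass(str, Enum):
    DEGRADED = "degraded"
    CONCORDANT = "concordant"
    MODIFIED = "modified"


@dataclass
class GelBand:
    """One excised gel band with its member protein signals."""

    index: int
    mw_lower_kda: float
    mw_upper_kda: float
    #: (accession, theoretical_mw_kda, ms_signal)
    members: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.mw_lower_kda < self.mw_upper_kda:
            raise ValueError("require 0 < mw_lower_kda < mw_upper_kda")


@dataclass
class BandReport:
    index: int
    n_proteins: int
    mean_theoretical_mw_kda: float
    sd_theoretical_mw_kda: float
    pct_signal_degraded: float
    pct_signal_modified: float
    pct_signal_concordant: float
    stats_defined: bool = True


def classify_protein(theoretical_mw_kda: float, band: GelBand) -> MWClass:
    """Classify a protein against a band's observed MW window.

    Strictly above the window -> degraded/truncated; strictly below ->
    potentially modified; a MW exactly on a bound is concordant.
    """
    if theoretical_mw_kda <= 0:
        raise ValueError("theoretical MW must be positive")
    if theoretical_mw_kda > band.mw_upper_kda:
        return MWClass.DEGRADED
    if theoretical_mw_kda < band.mw_lower_kda:
        return MWClass.MODIFIED
    return MWClass.CONCORDANT


def band_summary(band: GelBand) -> BandReport:
    """Mean/SD of member theoretical MWs and signal-share percentages.

    SD is the sample standard deviation (n-1). An empty band yields a
    report with ``n_proteins`` 0 and NaN statistics, flagged via
    ``stats_defined``.
    """
    n = len(band.members)
    if n == 0:
        return BandReport(band.index, 0, math.nan, math.nan,
                          math.nan, math.nan, math.nan, stats_defined=False)
    mws = [m[1] for m in band.members]
    mean = sum(mws) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in mws) / (n - 1)) if n > 1 else 0.0
    totals = {c: 0.0 for c in MWClass}
    for _, mw, signal in band.members:
        totals[classify_protein(mw, band)] += signal
    grand = sum(totals.values())
    if grand <= 0:
        return BandReport(band.index, n, mean, sd,
                          math.nan, math.nan, math.nan, stats_defined=False)
    pct_deg = 100.0 * totals[MWClass.DEGRADED] / grand
    pct_mod = 100.0 * totals[MWClass.MODIFIED] / grand
    # concordant closes the partition exactly: (deg + mod) + con == 100.0
    pct_con = 100.0 - (pct_deg + pct_mod)
    return BandReport(band.index, n, mean, sd, pct_deg, pct_mod, pct_con)


def overall_degraded_pct(bands: Sequence[GelBand]) -> float:
    """Signal-weighted percentage of degraded signal across all bands."""
    deg = tot = 0.0
    for band in bands:
        for _, mw, signal in band.members:
            tot += signal
            if classify_protein(mw, band) is MWClass.DEGRADED:
                deg += signal
    if tot <= 0:
        raise ValueError("no signal in any band")
    return 100.0 * deg / tot


def assemble_bands(assignments: Sequence[tuple[str, int, float]],
                   mw_table: Mapping[str, float],
                   bounds: Mapping[int, tuple[float, float]]) -> list[GelBand]:
    """Join a band-assignment table with MW annotations and band bounds.

    A protein identified in two bands contributes its per-band signal to
    each separately. Accessions without a theoretical MW (e.g. sequences
    containing X) are skipped.
    """
    bands = {idx: GelBand(idx, lo, hi) for idx, (lo, hi) in bounds.items()}
    for acc, idx, signal in assignments:
        if idx not in bands:
            raise KeyError(f"band index {idx} has no MW bounds")
        if acc not in mw_table:
            continue
        bands[idx].members.append((acc, mw_table[acc], signal))
    # bands ordered by decreasing MW (band 1 = top of the gel)
    return [bands[i] for i in sorted(bands)]


def infer_band_bounds(marker_lane: Sequence[tuple[float, float]],
                      band_edges: Sequence[float]
                      ) -> list[tuple[float, float]]:
    """Map band-edge migration positions to MW bounds via the marker lane.

    SDS-PAGE migration is modelled as linear in log10(MW): marker
    (position, MW) pairs define a piecewise-linear log10(MW)-vs-position
    curve, and each consecutive pair of band edges becomes one
    (mw_lower, mw_upper) interval. Edges beyond the outermost markers are
    clamped to the nearest marker's MW and a warning is logged.
    """
    import logging

    import numpy as np

    log = logging.getLogger(__name__)
    if len(marker_lane) < 2:
        raise ValueError("need at least 2 marker-lane points")
    positions = [p for p, _ in marker_lane]
    diffs = [b - a for a, b in zip(positions, positions[1:])]
    if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
        raise ValueError("marker positions must be strictly monotone")
    markers = sorted(marker_lane)
    xs = np.array([p for p, _ in markers])
    ys = np.log10([m for _, m in markers])
    edges = np.asarray(band_edges, dtype=float)
    if np.any(edges < xs[0]) or np.any(edges > xs[-1]):
        log.warning("band edges outside marker range are clamped")
    mws = 10.0 ** np.interp(edges, xs, ys)
    bounds = []
    for a, b in zip(mws, mws[1:]):
        lo, hi = sorted((a, b))
        bounds.append((float(lo), float(hi)))
    return bounds
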