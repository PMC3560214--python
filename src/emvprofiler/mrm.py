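"""Targeted SRM/MRM detection and relative quantification.

Extracts signature-fragment signal from transition traces within an m/z
tolerance window, calls peptide presence from the number of matched
fragments, and normalizes raw transition signal to the median of untreated
control samples. The pinned default target is the FC5 signature peptide
(precursor m/z 844.92).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ._constants import (
    DEFAULT_MRM_TOLERANCE_DA,
    FC5_FRAGMENT_MZS,
    FC5_PEPTIDE,
    FC5_PRECURSOR_MZ,
)
from .io_formats import TransitionSet


def fc5_transitions(tolerance_da: float = DEFAULT_MRM_TOLERANCE_DA
                    ) -> TransitionSet:
    """The FC5-specific transition set monitored in SRM mode."""
    return TransitionSet(precursor_mz=FC5_PRECURSOR_MZ, peptide=FC5_PEPTIDE,
                         fragment_mzs=list(FC5_FRAGMENT_MZS),
                         tolerance_da=tolerance_da)


@dataclass
class TransitionSignal:
    fragment_mz: float
    matched_intensity: float
    n_trace_points_matched: int

    def __post_init__(self) -> None:
        if (self.matched_intensity == 0) != (self.n_trace_points_matched == 0):
            raise ValueError(
                "matched_intensity must be 0 exactly when no points matched")


@dataclass
class RelativeLevel:
    sample_id: str
    raw_signal: float
    relative_to_median_control: float


def extract_transition_signal(
        trace: Sequence[tuple[float, float]],
        transitions: TransitionSet,
        rt_range: tuple[float, float] | None = None,
        trace_rts: Sequence[float] | None = None,
) -> tuple[list[TransitionSignal], float]:
    """Per-fragment matched intensity within +/- tolerance, and the total.

    Every trace point within the tolerance window of a fragment m/z is
    summed (no peak-shape fitting). Retention-time gating is optional and
    off by default: pass ``rt_range`` together with per-point ``trace_rts``
    to restrict matching to a time window.
    """
    if not transitions.fragment_mzs:
        raise ValueError("empty transition list")
    tol = transitions.tolerance_da
    if rt_range is not None:
        if trace_rts is None or len(trace_rts) != len(trace):
            raise ValueError("rt_range requires per-point trace_rts")
        lo, hi = rt_range
        trace = [p for p, rt in zip(trace, trace_rts) if lo <= rt <= hi]
    signals: list[TransitionSignal] = []
    total = 0.0
    for frag in transitions.fragment_mzs:
        matched = [inten for mz, inten in trace if abs(mz - frag) <= tol]
        # points of zero intensity carry no evidence of a match
        nonzero = [x for x in matched if x > 0]
        s = float(sum(nonzero))
        signals.append(TransitionSignal(fragment_mz=frag, matched_intensity=s,
                                        n_trace_points_matched=len(nonzero)))
        total += s
    return signals, total


def detect_peptide(signals: Sequence[TransitionSignal],
                   min_fragments_matched: int = 3) -> bool:
    """Presence call: at least this many fragments carry matched signal."""
    if min_fragments_matched < 1:
        raise ValueError("min_fragments_matched must be >= 1")
    n = sum(1 for s in signals if s.matched_intensity > 0)
    return n >= min_fragments_matched


def _lower_median(values: Sequence[float]) -> float:
    """Median that is always an observed value (lower of the middle pair
    for even counts), so the normalization anchor exists in the data."""
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def relative_level(samples: Mapping[str, float],
                   control_ids: Sequence[str]) -> list[RelativeLevel]:
    """Raw signals normalized to the median untreated-control signal."""
    controls = [samples[c] for c in control_ids if c in samples]
    if not controls:
        raise ValueError("no control samples present")
    anchor = _lower_median(controls)
    if anchor <= 0:
        raise ValueError("control median signal is zero")
    return [RelativeLevel(sample_id=sid, raw_signal=raw,
                          relative_to_median_control=raw / anchor)
            for sid, raw in samples.items()]
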