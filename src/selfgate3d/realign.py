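"""Projection realignment: respiratory binning and cardiac phase assignment.

Each projection is stamped with the respiratory amplitude and cardiac phase
at its acquisition time (the timestamp of its middle partition line, since
all partitions of a projection are acquired back-to-back).  Projections are
segmented into six equal-width respiratory-amplitude bins and only the most
populated bin is kept.  Cardiac cycles are delimited peak-to-peak on the
gating waveform; the number of cardiac phases equals the rounded mean number
of projections per R-R interval, cycles more than 30 % longer or shorter
than that mean are discarded (arrhythmia rejection), and within each kept
cycle a projection at cycle fraction f maps to phase floor(f * n_phases).
The quiescent (near end-diastolic) phase is the last one before the next
waveform peak.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import GatingFailureError
from .selfgating import GatingSignals

N_RESP_BINS = 6
CYCLE_REJECT_FRACTION = 0.3
UNASSIGNED = -1


@dataclass
class BinAssignment:
    """Respiratory bin and cardiac phase label for every projection."""

    resp_bin: np.ndarray  # (n_projections,) int in [0, n_bins)
    bin_counts: np.ndarray  # (n_bins,)
    selected_resp_bin: int
    n_cardiac_phases: int
    cardiac_phase: np.ndarray  # (n_projections,) int, UNASSIGNED outside
    cycle_id: np.ndarray  # (n_projections,) int, UNASSIGNED outside cycles
    discarded_cycles: np.ndarray  # indices of rejected R-R cycles
    kept: np.ndarray  # (n_projections,) bool: in selected bin, kept cycle
    quiescent_phase: int
    n_bins: int = N_RESP_BINS
    counts: dict = field(default_factory=dict)

    @property
    def n_projections(self) -> int:
        return self.resp_bin.shape[0]

    def projections_for_phase(self, phase: int) -> np.ndarray:
        return np.nonzero(self.kept & (self.cardiac_phase == phase))[0]

    def to_csv(self) -> str:
        """Assignment table: projection, resp bin, cycle, phase, kept flag."""
        buf = io.StringIO()
        buf.write("projection,resp_bin,cycle_id,cardiac_phase,kept\n")
        for p in range(self.n_projections):
            buf.write(
                f"{p},{self.resp_bin[p]},{self.cycle_id[p]},"
                f"{self.cardiac_phase[p]},{int(self.kept[p])}\n"
            )
        return buf.getvalue()


def assign_resp_bins(
    resp_trace: np.ndarray, n_bins: int = N_RESP_BINS
) -> tuple[np.ndarray, int, np.ndarray]:
    """Equal-width amplitude binning of the respiratory trace.

    Bin edges partition the robust amplitude range (2nd-98th percentile;
    values outside are clipped into the end bins).  Returns (bin index per
    projection, selected bin = the most populated, counts).  Ties break
    toward the lower-amplitude bin, nearest end-expiration.
    """
    trace = np.asarray(resp_trace, dtype=float)
    lo, hi = np.percentile(trace, [2.0, 98.0])
    if hi - lo <= 0:
        bins = np.zeros(trace.shape[0], dtype=int)
        counts = np.bincount(bins, minlength=n_bins)
        return bins, 0, counts
    clipped = np.clip(trace, lo, hi)
    bins = np.minimum(
        ((clipped - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1
    )
    counts = np.bincount(bins, minlength=n_bins)
    selected = int(np.argmax(counts))  # first max = lowest amplitude on ties
    return bins, selected, counts


def assign_cardiac_phases(
    cardiac_peaks: np.ndarray,
    in_bin: np.ndarray,
    n_projections: int | None = None,
    reject_fraction: float = CYCLE_REJECT_FRACTION,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Label projections with cardiac phases; reject arrhythmic cycles.

    ``cardiac_peaks`` are projection indices of the gating-waveform peaks
    (one gating sample per projection); ``in_bin`` is a boolean mask of
    projections in the selected respiratory bin.  The mean cycle length is
    computed once over all cycles before rejection.

    Returns (cardiac_phase, cycle_id, discarded_cycles, n_phases); phase
    and cycle are UNASSIGNED outside the peak-to-peak span or outside the
    selected bin.
    """
    peaks = np.asarray(cardiac_peaks, dtype=int)
    if peaks.size < 2:
        raise GatingFailureError("need at least two cardiac peaks to form cycles")
    in_bin = np.asarray(in_bin, dtype=bool)
    n_proj = in_bin.shape[0] if n_projections is None else int(n_projections)

    lengths = np.diff(peaks).astype(float)
    mean_len = float(np.mean(lengths))
    n_phases = int(round(mean_len))
    if n_phases < 1:
        raise GatingFailureError(
            f"mean R-R interval {mean_len:.2f} projections yields no cardiac phase"
        )
    lo, hi = (1.0 - reject_fraction) * mean_len, (1.0 + reject_fraction) * mean_len
    discarded = np.nonzero((lengths < lo) | (lengths > hi))[0]
    bad = np.zeros(lengths.size, dtype=bool)
    bad[discarded] = True

    phase = np.full(n_proj, UNASSIGNED, dtype=int)
    cycle = np.full(n_proj, UNASSIGNED, dtype=int)
    proj = np.arange(n_proj)
    idx = np.searchsorted(peaks, proj, side="right") - 1
    in_cycle = (idx >= 0) & (idx < lengths.size)
    sel = in_cycle & in_bin
    ci = idx[sel]
    frac = (proj[sel] - peaks[ci]) / lengths[ci]
    ph = np.minimum((frac * n_phases).astype(int), n_phases - 1)
    phase[sel] = np.where(bad[ci], UNASSIGNED, ph)
    cycle[sel] = ci
    # cycle id is bookkept for all projections inside the peak span
    cycle[in_cycle] = idx[in_cycle]
    return phase, cycle, discarded, n_phases


def pick_quiescent_phase(n_cardiac_phases: int) -> int:
    """Phase right before the next waveform peak (near end-diastole)."""
    if n_cardiac_phases < 1:
        raise GatingFailureError("no cardiac phases defined")
    return n_cardiac_phases - 1


def realign(
    gating: GatingSignals,
    n_bins: int = N_RESP_BINS,
    reject_fraction: float = CYCLE_REJECT_FRACTION,
) -> BinAssignment:
    """Full realignment from extracted gating signals."""
    resp = gating.resp_trace[:, gating.resp_coil]
    bins, selected, counts = assign_resp_bins(resp, n_bins=n_bins)
    in_bin = bins == selected
    phase, cycle, discarded, n_phases = assign_cardiac_phases(
        gating.cardiac_peaks, in_bin, reject_fraction=reject_fraction
    )
    kept = in_bin & (phase != UNASSIGNED)
    n_proj = bins.shape[0]
    accounting = {
        "n_projections": int(n_proj),
        "in_selected_bin": int(in_bin.sum()),
        "phase_assigned": int(kept.sum()),
        "in_discarded_cycles": int((in_bin & (cycle != UNASSIGNED) & ~kept).sum()),
        "outside_cycles": int((in_bin & (cycle == UNASSIGNED)).sum()),
        "n_cycles": int(gating.cardiac_peaks.size - 1),
        "n_discarded_cycles": int(discarded.size),
    }
    return BinAssignment(
        resp_bin=bins,
        bin_counts=counts,
        selected_resp_bin=selected,
        n_cardiac_phases=n_phases,
        cardiac_phase=phase,
        cycle_id=cycle,
        discarded_cycles=discarded,
        kept=kept,
        quiescent_phase=pick_quiescent_phase(n_phases),
        n_bins=n_bins,
        counts=accounting,
    )
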