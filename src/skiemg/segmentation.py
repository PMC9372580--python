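"""Turn-cycle segmentation from the trunk accelerometer resultant.

A turn switch is the instant separating two consecutive turns, taken at a
local minimum of the low-pass-filtered resultant acceleration (the skier is
unweighted while changing edges, so AccR dips between turns). A *cycle* is a
right turn followed by a left turn; with right-leg instrumentation the right
turn is the inside-leg (IL) half and the left turn the outside-leg (OL)
half. Cycles are time-normalized to a 200-point grid (100 points per leg)
and the edge-change phases (0-10%, 40-60%, 90-100% of the cycle) are masked
out of EMG averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ConfigurationError, RunMarker
from .preprocess import ACCR_CUTOFF_HZ
from scipy import signal as _signal

log = logging.getLogger(__name__)

GRID_N = 200  # points per normalized cycle (100 per leg)
EDGE_PHASES_PCT = ((0.0, 10.0), (40.0, 60.0), (90.0, 100.0))


class SegmentationError(RuntimeError):
    pass


def compute_accr(acc_x: np.ndarray, acc_y: np.ndarray, acc_z: np.ndarray) -> np.ndarray:
    """Resultant acceleration AccR = sqrt(x^2 + y^2 + z^2), elementwise (g)."""
    x, y, z = (np.asarray(a, dtype=float) for a in (acc_x, acc_y, acc_z))
    if not (len(x) == len(y) == len(z)):
        raise ConfigurationError(f"axis length mismatch: {len(x)}, {len(y)}, {len(z)}")
    return np.sqrt(x * x + y * y + z * z)


def detect_turn_switches(
    accr_filtered: np.ndarray,
    rate_hz: float,
    discipline: str,
    t0_s: float = 0.0,
) -> np.ndarray:
    """Ordered turn-switch times at local minima of the filtered AccR.

    A minimum-separation guard of ``0.5 / f_cutoff(discipline)`` seconds
    suppresses noise-induced double minima. Times are reported relative to
    the session clock via ``t0_s`` (time of the first sample passed in).
    """
    if discipline not in ACCR_CUTOFF_HZ:
        raise ConfigurationError(f"unknown discipline {discipline!r}")
    accr = np.asarray(accr_filtered, dtype=float)
    min_sep_s = 0.5 / ACCR_CUTOFF_HZ[discipline]
    distance = max(1, int(round(min_sep_s * rate_hz)))
    idx, _props = _signal.find_peaks(-accr, distance=distance)
    if len(idx) < 3:
        raise SegmentationError(f"no switches: only {len(idx)} AccR minima found (need >= 3 for a cycle)")
    return t0_s + idx / rate_hz


@dataclass
class TurnCycle:
    """One double turn: a right (IL) plus a left (OL) turn."""

    cycle_index: int
    run_index: int
    start_s: float
    mid_s: float
    end_s: float
    excluded: bool = False  # first/last cycle of a run
    grid: dict[str, np.ndarray] = field(default_factory=dict)  # 200-pt traces

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def leg_bounds(self, leg: str) -> tuple[float, float]:
        return (self.start_s, self.mid_s) if leg == "IL" else (self.mid_s, self.end_s)

    def retained_bounds(self, leg: str) -> tuple[float, float]:
        """Leg interval with edge-change phases removed, on the native time base.

        Cycle phases 10-40% map onto the IL turn, 60-90% onto the OL turn.
        """
        c = self.duration_s
        if leg == "IL":
            return (self.start_s + 0.10 * c, self.start_s + 0.40 * c)
        return (self.start_s + 0.60 * c, self.start_s + 0.90 * c)


def infer_first_turn(lateral_filtered: np.ndarray, rate_hz: float, first_two_switches) -> str:
    """Polarity of a run's opening turn from the lateral trunk acceleration.

    Convention: positive lateral acceleration during right turns (config the
    sign at the hardware level if mounted mirrored). The mean lateral signal
    over the first inter-switch interval decides the side.
    """
    a, b = first_two_switches
    seg = lateral_filtered[int(a * rate_hz) : int(b * rate_hz)]
    if seg.size == 0:
        return "right"
    return "right" if float(seg.mean()) > 0 else "left"


def build_cycles(
    switch_times: np.ndarray,
    run_markers: list[RunMarker],
    first_turn: str = "right",
    first_turn_per_run: dict[int, str] | None = None,
    boundary_tol_s: float = 0.25,
) -> list[TurnCycle]:
    """Pair consecutive (right, left) turns into cycles, per run.

    The first switch of a run opens a turn on the side given by
    ``first_turn`` (polarity is not derivable from AccR alone; see
    :func:`infer_first_turn` for the lateral-axis rule), overridable per run
    via ``first_turn_per_run``. If the run starts mid-left-turn the leading
    unpaired turn is dropped, as is an unpaired trailing turn. The first and
    last cycles of each run are flagged ``excluded`` and skipped by the
    metrics layer. Cycles never cross run boundaries; ``boundary_tol_s``
    absorbs small detection offsets at the run edges.
    """
    if first_turn not in ("right", "left"):
        raise ConfigurationError(f"first_turn must be 'right' or 'left', got {first_turn!r}")
    switch_times = np.asarray(switch_times, dtype=float)
    cycles: list[TurnCycle] = []
    counter = 0
    for marker in run_markers:
        s = switch_times[(switch_times >= marker.start_s - boundary_tol_s) & (switch_times <= marker.end_s + boundary_tol_s)]
        if len(s) < 4:
            log.warning("run %d: only %d switches inside run, no cycles built", marker.run_index, len(s))
            continue
        side = (first_turn_per_run or {}).get(marker.run_index, first_turn)
        start = 0 if side == "right" else 1
        run_cycles: list[TurnCycle] = []
        for k in range(start, len(s) - 2, 2):
            run_cycles.append(TurnCycle(counter, marker.run_index, float(s[k]), float(s[k + 1]), float(s[k + 2])))
            counter += 1
        if run_cycles:
            run_cycles[0].excluded = True
            run_cycles[-1].excluded = True
        cycles.extend(run_cycles)
    return cycles


def time_normalize(
    cycle: TurnCycle,
    samples: np.ndarray,
    rate_hz: float,
    t0_s: float = 0.0,
    points_per_leg: int = GRID_N // 2,
) -> np.ndarray:
    """Resample a channel onto the cycle's normalized grid.

    Each leg half is linearly interpolated onto its own ``points_per_leg``
    grid spanning its native duration, so unequal halves each occupy exactly
    half the cycle grid; endpoint values are preserved.
    """
    if cycle.mid_s <= cycle.start_s or cycle.end_s <= cycle.mid_s:
        raise ConfigurationError("cycle has an empty half")
    samples = np.asarray(samples, dtype=float)
    times = t0_s + np.arange(len(samples)) / rate_hz
    halves = []
    for a, b in ((cycle.start_s, cycle.mid_s), (cycle.mid_s, cycle.end_s)):
        grid_t = np.linspace(a, b, points_per_leg)
        halves.append(np.interp(grid_t, times, samples))
    return np.concatenate(halves)


def edge_phase_mask(n: int = GRID_N) -> np.ndarray:
    """Boolean mask over the cycle grid, True where a point is retained.

    Excluded (edge-change) phases are [0,10)%, [40,60)% and [90,100]% of the
    cycle; interior boundaries are half-open so no point is counted twice.
    Exactly 60% of the points are retained (120 of 200 at the default size).
    """
    pct = np.arange(n) * (100.0 / n)
    excluded = (pct < 10.0) | ((pct >= 40.0) & (pct < 60.0)) | (pct >= 90.0)
    return ~excluded


def write_cycle_intervals(cycles: list[TurnCycle], path) -> None:
    """Export cycle boundaries as a BED-like tab-separated audit file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("run_index\tstart_s\tend_s\tcycle_index\texcluded\n")
        for c in cycles:
            fh.write(f"{c.run_index}\t{c.start_s:.6f}\t{c.end_s:.6f}\t{c.cycle_index}\t{int(c.excluded)}\n")
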