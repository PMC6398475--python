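"""Growth-phase segmentation of microtubule length traces.

A length-versus-time trace is split into linear phases by recursive
bisection: fit a least-squares line; if the mean perpendicular distance of
the points from the line exceeds 20 nm, split at the point of greatest
distance and recurse on both halves (the split point is shared between
them).  Terminal segments become growth phases; phases are kept for
analysis when they last at least 10 s and grow at 10-30 nm/s, and within a
kept phase only timepoints whose end fit passed the 50-200 nm sigma gate
are used.

"Perpendicular distance" mixes seconds and nanometres; here it is the
vertical residual |length - fit| in nm (equivalently, the geometric
point-to-line distance with the time axis compressed until the line is
flat).  This keeps the 20 nm threshold commensurate with the nm-scale
noise of the length trace; dividing by sqrt(1 + m^2) with m in nm/s would
shrink every distance ~20-fold at typical growth speeds and no trace would
ever split.  A ``time_scale_nm_per_s`` argument restores the geometric
definition in (t * scale, length) coordinates for comparison.
"""

from __future__ import annotations

import numpy as np

from .containers import GrowthPhase, LengthTrace, TipFit

MAX_PERP_NM = 20.0
MIN_DURATION_S = 10.0
VELOCITY_RANGE_NM_S = (10.0, 30.0)
MIN_POINTS = 3


def _fit_line(t: np.ndarray, y: np.ndarray,
              time_scale_nm_per_s: float | None) -> tuple[float, float, np.ndarray]:
    m, b = np.polyfit(t, y, 1)
    resid = np.abs(y - (m * t + b))
    if time_scale_nm_per_s is None:
        perp = resid
    else:
        m_scaled = m / time_scale_nm_per_s
        perp = resid / np.sqrt(1.0 + m_scaled * m_scaled)
    return float(m), float(b), perp


def segment_phases(trace: LengthTrace,
                   max_perp_nm: float = MAX_PERP_NM,
                   min_duration_s: float = MIN_DURATION_S,
                   velocity_range_nm_s: tuple[float, float] = VELOCITY_RANGE_NM_S,
                   min_points: int = MIN_POINTS,
                   time_scale_nm_per_s: float | None = None) -> list[GrowthPhase]:
    """Recursive segment-line fitting of a length trace into linear phases."""
    t, y = trace.time_s, trace.length_nm
    if t.size < min_points:
        raise ValueError(f"trace has {t.size} points; need >= {min_points}")

    phases: list[GrowthPhase] = []

    def recurse(i: int, j: int) -> None:  # inclusive indices
        if j - i + 1 < min_points:
            return  # too small: discarded, not recursed
        tt, yy = t[i:j + 1], y[i:j + 1]
        m, _b, perp = _fit_line(tt, yy, time_scale_nm_per_s)
        if perp.mean() > max_perp_nm:
            k = i + int(np.argmax(perp))  # earliest max wins on ties
            k = min(max(k, i + 1), j - 1)  # a split must shrink both sides
            recurse(i, k)
            recurse(k, j)  # split point shared between segments
            return
        duration = float(tt[-1] - tt[0])
        eps = 1e-9  # float tolerance at the gate boundaries
        kept = bool(duration >= min_duration_s - eps
                    and velocity_range_nm_s[0] - eps <= m
                    <= velocity_range_nm_s[1] + eps)
        phases.append(GrowthPhase(
            start_s=float(tt[0]), end_s=float(tt[-1]), velocity_nm_s=m,
            mean_perp_dist_nm=float(perp.mean()), kept=kept,
            start_index=i, end_index=j))

    recurse(0, t.size - 1)
    phases.sort(key=lambda p: p.start_s)
    return phases


def filter_timepoints(phase: GrowthPhase, tips: list[TipFit],
                      times_s: np.ndarray | None = None,
                      sigma_gate_nm: tuple[float, float] = (50.0, 200.0),
                      ) -> list[int]:
    """Indices of timepoints inside a kept phase whose end fit is accepted
    and has sigma within the gate."""
    if not phase.kept:
        raise ValueError("timepoint filtering applies to kept phases only")
    if times_s is None:
        times_s = np.arange(len(tips), dtype=float)
    keep = []
    for i, tip in enumerate(tips):
        if not (phase.start_s <= times_s[i] <= phase.end_s):
            continue
        if not tip.accepted:
            continue
        if not (sigma_gate_nm[0] <= tip.sigma_nm <= sigma_gate_nm[1]):
            continue
        keep.append(i)
    return keep
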