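"""Kymograph comet-shape analysis and tip-relative averaging.

Kymograph convention: rows are time, columns position along the
microtubule with the seed at low column index, so the growing tip sits at
the high-column edge of the comet and the EB tail decays towards low
columns.  Comet profiles are reported on a tip-relative axis with positive
positions behind the tip (into the lattice).

The tip trajectory on a kymograph cropped to one linear growth phase is
detected as a straight line through the per-row positions of the first
pixel (scanning from the tip-proximal side) reaching 90% of the row
maximum, refined within a +/-5 pixel confidence band and rejected when the
residual error exceeds one pixel (81 nm).  Profiles are cubic-interpolated
10-fold to 8.1 nm/pixel, aligned on the reference line, averaged over the
growth phase, background-subtracted (region ahead of the tip) and
max-normalised.  Profiles from different microtubules are superaveraged on
their first half-maximal point.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit

from .containers import (CometProfile, GrowthPhase, Kymograph, PeakDistance,
                         TipFit, TipLine)
from . import fits as _fits

UPSAMPLE = 10
BACKGROUND_AHEAD_PX = 15  # raw pixels ahead of the tip line


# --------------------------------------------------------------------------
# tip line

def _first_from_tip(row: np.ndarray, threshold: float,
                    lo: int = 0, hi: int | None = None) -> int | None:
    """First column >= threshold scanning from the tip-proximal (high) side
    within [lo, hi)."""
    hi = len(row) if hi is None else hi
    idx = np.flatnonzero(row[lo:hi] >= threshold)
    return None if idx.size == 0 else lo + int(idx[-1])


def detect_tip_line(kymo: Kymograph, threshold_frac: float = 0.9,
                    band_px: int = 5, residual_gate_px: float = 1.0,
                    threshold_ref: str = "row") -> TipLine:
    """Two-pass linear fit to the comet tip trajectory.

    ``threshold_ref="row"`` (default) takes 90% of each row's maximum;
    ``"global"`` uses the kymograph-wide maximum instead.
    """
    data = kymo.data
    n_rows = data.shape[0]
    if n_rows < 5:
        raise ValueError("kymograph must have at least 5 time rows")
    gmax = data.max()

    def row_tip(i: int, lo: int = 0, hi: int | None = None) -> int | None:
        seg = data[i, lo:hi if hi is not None else data.shape[1]]
        if seg.size == 0:
            return None
        ref = seg.max() if threshold_ref == "row" else gmax
        return _first_from_tip(data[i], threshold_frac * ref, lo=lo, hi=hi)

    rows, tips = [], []
    for i in range(n_rows):
        t = row_tip(i)
        if t is not None:
            rows.append(i)
            tips.append(t)
    if len(rows) < 5:
        raise ValueError("fewer than 5 rows with detectable tip")
    slope, intercept = np.polyfit(rows, tips, 1)

    # second pass restricted to the +/- band confidence interval
    rows2, tips2 = [], []
    for i in range(n_rows):
        centre = intercept + slope * i
        lo = max(int(math.floor(centre - band_px)), 0)
        hi = min(int(math.ceil(centre + band_px)) + 1, data.shape[1])
        t = row_tip(i, lo=lo, hi=hi)
        if t is not None:
            rows2.append(i)
            tips2.append(t)
    slope, intercept = np.polyfit(rows2, tips2, 1)
    resid = np.asarray(tips2) - (intercept + slope * np.asarray(rows2))
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return TipLine(float(slope), float(intercept), rms,
                   accepted=rms <= residual_gate_px)


# --------------------------------------------------------------------------
# alignment and averaging

def _upsample_row(row: np.ndarray, factor: int) -> np.ndarray:
    p = np.arange(row.size, dtype=float)
    fine = np.arange((row.size - 1) * factor + 1) / factor
    return CubicSpline(p, row)(fine)


def align_and_average_comet(kymo: Kymograph, line: TipLine,
                            upsample: int = UPSAMPLE,
                            background_ahead_px: float = BACKGROUND_AHEAD_PX,
                            ) -> CometProfile:
    """Align rows on the tip reference line, average, subtract the pre-tip
    background and normalise to peak 1."""
    data = kymo.data
    n_rows, n_cols = data.shape
    fine_nm = kymo.pixel_nm / upsample
    fine_len = (n_cols - 1) * upsample + 1

    refs, rows = [], []
    for i in range(n_rows):
        ref = int(round(line.position_px(i) * upsample))
        if 0 <= ref <= fine_len - 1:
            refs.append(ref)
            rows.append(i)
    if not rows:
        raise ValueError("reference line lies outside the kymograph")
    # tip-relative index r = ref - i_fine (positive behind the tip);
    # keep the range covered by every row
    r_lo = max(r - (fine_len - 1) for r in refs)
    r_hi = min(refs)
    rel = np.arange(r_lo, r_hi + 1)
    acc = np.zeros(rel.size)
    for i, ref in zip(rows, refs):
        fine = _upsample_row(data[i], upsample)
        acc += fine[ref - rel]
    mean = acc / len(rows)
    position_nm = rel * fine_nm

    ahead = position_nm <= -background_ahead_px * kymo.pixel_nm
    if not ahead.any():
        raise ValueError("background region ahead of the tip is empty")
    mean = mean - mean[ahead].mean()
    peak = mean.max()
    if peak <= 0:
        raise ValueError("profile has no positive signal after background "
                         "subtraction")
    return CometProfile(position_nm, mean / peak, n=len(rows))


def _first_half_max_index(profile: CometProfile) -> int | None:
    """Index of the first half-maximal point scanning from the tip side
    (from ahead of the tip towards the lattice)."""
    y = profile.intensity
    idx = np.flatnonzero(y >= 0.5 * y.max())
    return int(idx[0]) if idx.size else None


def superaverage(profiles: list[CometProfile]) -> CometProfile:
    """Average profiles from different microtubules after registering each
    at its first half-maximal point (placed at position 0)."""
    if not profiles:
        raise ValueError("need at least one profile")
    spacing = profiles[0].spacing_nm
    usable, halves = [], []
    for k, p in enumerate(profiles):
        if abs(p.spacing_nm - spacing) > 1e-6:
            raise ValueError("profiles must share one sampling grid")
        h = _first_half_max_index(p)
        if h is None:
            warnings.warn(f"profile {k} never reaches half-maximum; excluded")
            continue
        usable.append(p)
        halves.append(h)
    if not usable:
        raise ValueError("no profile reaches half-maximum")
    lo = max(-h for h in halves)
    hi = min(p.intensity.size - 1 - h for p, h in zip(usable, halves))
    rel = np.arange(lo, hi + 1)
    acc = np.zeros(rel.size)
    for p, h in zip(usable, halves):
        acc += p.intensity[h + rel]
    return CometProfile(rel * spacing, acc / len(usable),
                        n=sum(p.n for p in usable))


# --------------------------------------------------------------------------
# comet area

def comet_area(profile: CometProfile, split_frac: float = 0.85,
               tail_floor_frac: float = 0.02) -> dict:
    """Area under the comet: direct integration up to the post-peak
    ``split_frac`` crossing, plus the analytic area ``A * lambda`` of an
    exponential fitted to the decay beyond it."""
    x, y = profile.position_nm, profile.intensity
    peak = int(np.argmax(y))  # first maximum: ties break towards the tip
    ymax = y[peak]
    level = split_frac * ymax
    below = np.flatnonzero(y[peak:] < level)
    if below.size == 0:
        raise ValueError("no post-peak crossing of the split level")
    k = peak + int(below[0])
    # linear interpolation of the crossing position
    x_split = x[k - 1] + (x[k] - x[k - 1]) * (y[k - 1] - level) / (y[k - 1] - y[k])
    head = x <= x[k - 1]
    area_head = np.trapezoid(y[head], x[head])
    area_head += 0.5 * (y[k - 1] + level) * (x_split - x[k - 1])

    tail = (x >= x_split) & (y >= tail_floor_frac * ymax)
    xt, yt = x[tail], y[tail]
    if xt.size < 3:
        raise ValueError("comet tail too short for an exponential fit")
    lam0 = max(-(xt[-1] - xt[0]) / math.log(max(yt[-1], 1e-9) / yt[0]), 1.0) \
        if yt[-1] < yt[0] else (xt[-1] - xt[0])
    popt, _ = curve_fit(lambda xx, a, lam: a * np.exp(-(xx - x_split) / lam),
                        xt, yt, p0=(level, lam0), maxfev=2000)
    amp, lam = popt
    return {
        "area_nm": float(area_head + amp * lam),
        "decay_nm": float(lam),
        "split_position_nm": float(x_split),
        "tail_amplitude": float(amp),
    }


# --------------------------------------------------------------------------
# dual colour

def _time_interp2(kymo: Kymograph) -> Kymograph:
    """Linear 2-fold temporal interpolation (rows 2T-1, half the interval)."""
    d = kymo.data
    out = np.empty((2 * d.shape[0] - 1, d.shape[1]))
    out[0::2] = d
    out[1::2] = 0.5 * (d[:-1] + d[1:])
    return Kymograph(out, pixel_nm=kymo.pixel_nm,
                     line_interval_s=kymo.line_interval_s / 2.0,
                     channel=kymo.channel)


def dual_colour_peak_distance(kymo_a: Kymograph, kymo_b: Kymograph,
                              trim: bool = True,
                              ) -> tuple[PeakDistance, CometProfile, CometProfile]:
    """Peak distance between two sequentially imaged channels.

    Channel A is the reference (tip line detected on A and applied to B).
    Both kymographs are interpolated 2-fold in time; the first row of A and
    the last row of B are removed to cancel the half-frame acquisition
    offset (``trim=False`` skips the correction, exposing the bias it
    removes).  Positive distance: channel B peaks farther behind the tip.
    """
    if kymo_a.data.shape != kymo_b.data.shape:
        raise ValueError("channel kymographs must have identical shape")
    a2, b2 = _time_interp2(kymo_a), _time_interp2(kymo_b)
    if trim:
        a2 = Kymograph(a2.data[1:], a2.pixel_nm, a2.line_interval_s, a2.channel)
        b2 = Kymograph(b2.data[:-1], b2.pixel_nm, b2.line_interval_s, b2.channel)
    line = detect_tip_line(a2)
    prof_a = align_and_average_comet(a2, line)
    prof_b = align_and_average_comet(b2, line)
    pos_a = prof_a.position_nm[int(np.argmax(prof_a.intensity))]
    pos_b = prof_b.position_nm[int(np.argmax(prof_b.intensity))]
    speed = line.slope_px_per_row * kymo_a.pixel_nm / a2.line_interval_s
    return (PeakDistance(float(pos_b - pos_a), float(speed)), prof_a, prof_b)


def superaveraged_peak_distance(profiles_a: list[CometProfile],
                                profiles_b: list[CometProfile]) -> float:
    """Peak distance between the superaveraged curves of two channels.

    The registration shift of each profile pair comes from channel A (the
    reference) and is applied to both channels, so inter-channel offsets
    survive the averaging.
    """
    if len(profiles_a) != len(profiles_b):
        raise ValueError("channel profile lists must pair up")
    shifted_b = []
    for pa, pb in zip(profiles_a, profiles_b):
        h = _first_half_max_index(pa)
        if h is None:
            warnings.warn("reference profile never reaches half-maximum; "
                          "pair excluded")
            continue
        # express channel B on channel A's registered axis
        shift = pa.position_nm[h]
        shifted_b.append(CometProfile(pb.position_nm - shift, pb.intensity,
                                      n=pb.n))
    sa = superaverage(profiles_a)

    # average the already-registered B profiles on their common grid
    if not shifted_b:
        raise ValueError("no usable profile pairs")
    lo = max(p.position_nm.min() for p in shifted_b)
    hi = min(p.position_nm.max() for p in shifted_b)
    grid = np.arange(0.0, hi - lo + 1e-9, shifted_b[0].spacing_nm) + lo
    acc = np.zeros(grid.size)
    for p in shifted_b:
        acc += np.interp(grid, p.position_nm, p.intensity)
    pa_peak = sa.position_nm[int(np.argmax(sa.intensity))]
    pb_peak = grid[int(np.argmax(acc))]
    return float(pb_peak - pa_peak)


# --------------------------------------------------------------------------
# tip-relative EB averaging (two-channel image-stack analysis)

def tip_relative_average(tips: list[TipFit], phase: GrowthPhase,
                         eb_intensity: np.ndarray, pixel_nm: float,
                         times_s: np.ndarray | None = None,
                         delay_s: float = 0.5,
                         grid_step_nm: float = 8.0,
                         grid_span_nm: tuple[float, float] = (-1500.0, 2000.0),
                         indices: list[int] | None = None,
                         ) -> tuple[CometProfile, np.ndarray]:
    """Average EB intensity relative to the fitted microtubule end.

    Per accepted timepoint the EB axial profile (``eb_intensity[frame,
    col]``, columns at ``(c+0.5)*pixel_nm`` with the tip at high position)
    is sampled every ``grid_step_nm`` around the reference ``mu - delay_s *
    v_growth`` (the half-frame sequential-imaging correction) and averaged.
    Additionally a Gaussian is fitted to each timepoint's EB peak; the
    returned array holds the per-timepoint peak-to-tip distances (nm,
    positive behind the tip).
    """
    from .phases import filter_timepoints

    if times_s is None:
        times_s = np.arange(len(tips), dtype=float)
    if indices is None:
        indices = filter_timepoints(phase, tips, times_s=times_s)
    if not indices:
        raise ValueError("no accepted timepoints in the phase")
    x = (np.arange(eb_intensity.shape[1]) + 0.5) * pixel_nm
    r = np.arange(grid_span_nm[0], grid_span_nm[1] + grid_step_nm / 2,
                  grid_step_nm)
    acc = np.zeros(r.size)
    distances = []
    for i in indices:
        ref = tips[i].mu_nm - delay_s * phase.velocity_nm_s
        spline = CubicSpline(x, eb_intensity[i])
        row = spline(np.clip(ref - r, x[0], x[-1]))
        acc += row
        # per-timepoint Gaussian peak fit in a window around the maximum
        win = (r > -500.0) & (r < 1000.0)
        rw, yw = r[win], row[win]
        centre0 = rw[int(np.argmax(yw))]
        sel = np.abs(rw - centre0) <= 400.0
        try:
            peak = _fits.fit_gaussian_peak(rw[sel], yw[sel])
            distances.append(peak.centre)
        except ValueError:
            continue
    mean = acc / len(indices)
    ahead = r <= grid_span_nm[0] + 0.2 * (grid_span_nm[1] - grid_span_nm[0])
    mean = mean - mean[ahead].mean()
    peak_val = mean.max()
    if peak_val <= 0:
        raise ValueError("averaged EB profile has no signal")
    return CometProfile(r, mean / peak_val, n=len(indices)), np.asarray(distances)


# --------------------------------------------------------------------------
# cell line-scan averaging

def align_cell_linescans(scans: list[dict[str, np.ndarray]],
                         mode: str = "fixed", pixel_nm: float = 81.0,
                         reference_channels: tuple[str, ...] = ("EB1", "EB3"),
                         live_reference: str = "EB3",
                         ) -> dict[str, CometProfile]:
    """Align and average multi-channel line scans across microtubules.

    ``mode="fixed"``: the alignment reference of each scan is the pixel
    closest to the midpoint between the first half-maximal points of the
    two ``reference_channels``.  ``mode="live"``: the first half-maximal
    point of ``live_reference`` alone.  All channels of a scan are shifted
    jointly; scans whose reference channel(s) never reach half-maximum are
    excluded with a warning.  Averaged channels are max-normalised.
    """
    def half_idx(y: np.ndarray) -> int | None:
        y = np.asarray(y, dtype=float)
        rng = y.max() - y.min()
        if rng <= 0:
            return None
        idx = np.flatnonzero((y - y.min()) >= 0.5 * rng)
        return int(idx[0]) if idx.size else None

    refs, usable = [], []
    for k, scan in enumerate(scans):
        if mode == "fixed":
            hs = [half_idx(scan[ch]) for ch in reference_channels]
            if any(h is None for h in hs):
                warnings.warn(f"scan {k}: reference channel never reaches "
                              "half-maximum; excluded")
                continue
            ref = int(round(sum(hs) / len(hs)))
        elif mode == "live":
            h = half_idx(scan[live_reference])
            if h is None:
                warnings.warn(f"scan {k}: reference channel never reaches "
                              "half-maximum; excluded")
                continue
            ref = h
        else:
            raise ValueError(f"unknown mode {mode!r}")
        refs.append(ref)
        usable.append(scan)
    if not usable:
        raise ValueError("no usable scans")

    channels = usable[0].keys()
    lo = max(-r for r in refs)
    hi = min(len(next(iter(s.values()))) - 1 - r for s, r in zip(usable, refs))
    rel = np.arange(lo, hi + 1)
    out = {}
    for ch in channels:
        acc = np.zeros(rel.size)
        for scan, r in zip(usable, refs):
            acc += np.asarray(scan[ch], dtype=float)[r + rel]
        mean = acc / len(usable)
        out[ch] = CometProfile(rel * pixel_nm, mean / mean.max(), n=len(usable))
    return out
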