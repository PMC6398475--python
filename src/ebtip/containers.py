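"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* distances are in nanometres, times in seconds, intensities in arbitrary
  (camera) units;
* image stacks are ``(frames, rows, cols)`` arrays; kymographs are
  ``(time rows, position cols)`` arrays;
* along a kymograph the microtubule seed sits at low column index and the
  growing plus end at high index, so the EB comet tail decays towards low
  columns;
* comet profiles use a tip-relative axis where *positive* positions point
  from the tip into the lattice (behind the tip) and negative positions lie
  ahead of the tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A fluorescence movie: ``data[frame, row, col]`` plus calibration.

    ``ground_truth`` is filled by the synthetic generator with the true end
    positions of the microtubule per frame (nm, image coordinates) and the
    backbone row; it is ``None`` for experimental data.
    """

    data: np.ndarray
    pixel_nm: float
    frame_interval_s: float = 1.0
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageStack.data must be (frames, rows, cols)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageStack.data must be finite")
        if np.any(self.data < 0):
            raise ValueError("ImageStack.data must be nonnegative")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class Kymograph:
    """Time (rows) x position (cols) intensity matrix for one channel."""

    data: np.ndarray
    pixel_nm: float = 81.0
    line_interval_s: float = 1.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Kymograph.data must be 2-D (time x position)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Kymograph intensities must be finite")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


@dataclass
class CometProfile:
    """Averaged, background-subtracted, max-normalised comet intensity.

    ``position_nm`` increases from ahead of the tip (negative) into the
    lattice (positive), uniformly spaced.
    """

    position_nm: np.ndarray
    intensity: np.ndarray
    n: int = 1

    def __post_init__(self) -> None:
        self.position_nm = np.asarray(self.position_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position_nm.shape != self.intensity.shape:
            raise ValueError("position and intensity must have equal shape")

    @property
    def spacing_nm(self) -> float:
        return float(np.diff(self.position_nm).mean())


@dataclass
class FrapTrace:
    """A FRAP trace normalised to 1 at the last pre-bleach frame and 0 at
    the first post-bleach frame.  ``time_s`` is measured from the first
    post-bleach frame (pre-bleach times are negative)."""

    time_s: np.ndarray
    intensity: np.ndarray
    n_pre: int
    tau_true_s: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal shape")

    @property
    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        sel = slice(self.n_pre, None)
        return self.time_s[sel], self.intensity[sel]


@dataclass
class TipFit:
    """Result of a Gauss-error-function fit to a microtubule end.

    ``mu_nm`` is the end position along the backbone, ``sigma_nm`` the edge
    width (PSF plus end taper).  ``accepted`` applies the 50-200 nm sigma
    gate; a failed fit is returned with ``accepted=False`` and a ``reason``
    rather than raising.
    """

    frame: int | None
    mu_nm: float
    sigma_nm: float
    amplitude: float
    baseline: float
    residual: float
    accepted: bool
    reason: str | None = None


@dataclass
class LengthTrace:
    """Microtubule length versus time, derived from per-frame end fits."""

    time_s: np.ndarray
    length_nm: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.length_nm = np.asarray(self.length_nm, dtype=float)
        if self.time_s.shape != self.length_nm.shape:
            raise ValueError("time and length must have equal shape")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class GrowthPhase:
    """One linear growth phase from recursive segment-line fitting."""

    start_s: float
    end_s: float
    velocity_nm_s: float
    mean_perp_dist_nm: float
    kept: bool
    start_index: int = 0
    end_index: int = 0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TipLine:
    """Linear fit to the comet tip trajectory on a kymograph."""

    slope_px_per_row: float
    intercept_px: float
    residual_px: float
    accepted: bool

    def position_px(self, row: np.ndarray | float) -> np.ndarray | float:
        return self.intercept_px + self.slope_px_per_row * np.asarray(row, dtype=float)


@dataclass
class PeakDistance:
    """Distance between channel peaks for one growth phase.

    Positive distance means channel B peaks farther from the tip (deeper
    into the lattice) than channel A.
    """

    distance_nm: float
    growth_speed_nm_s: float
    phase_id: int = 0


@dataclass
class BackboneFit:
    """Per-column Gaussian ridge centres and the line/cubic model through them."""

    columns: np.ndarray
    centres_px: np.ndarray
    model: str  # "line" | "cubic"
    coefficients: np.ndarray
    residual_rms_px: float

    def centre_at(self, col: np.ndarray | float) -> np.ndarray | float:
        return np.polyval(self.coefficients, col)
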