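"""Synthetic-data generation with known ground truth.

This module produces every input the analysis pipeline consumes:

* image stacks of a single growing/shrinking microtubule rendered with
  stochastic fluorophore labelling, a Gaussian point-spread function and
  additive background noise at a target signal-to-noise ratio (SNR);
* single- and multi-channel EB-comet kymographs with known peak offsets;
* FRAP recovery traces.

The image model follows the standard simulation strategy for benchmarking
end-detection algorithms: tubulin dimers occupy an 8 nm axial lattice on 13
protofilaments, a fraction of dimers carries dye (binomial labelling with a
mean dye:dimer ratio realised per labelled dimer as a Poisson draw), images
are rendered on a 1 nm grid, blurred with a Gaussian PSF (sigma 130 nm by
default) and downsampled to the camera pixel size (81 nm by default).
Background noise is Gaussian i.i.d. with its standard deviation set so that
the measured SNR -- (mean backbone - mean background) / sd(background) --
matches the requested target; user-acquired noise frames can be tiled in
instead via ``noise_frames``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import erf

from .containers import FrapTrace, ImageStack, Kymograph


@dataclass
class SimImageConfig:
    """Parameters of the synthetic microtubule movie.

    The default length trajectory ramps from ``length_min_nm`` to
    ``length_max_nm`` and back at ``step_nm_per_frame`` per frame
    (2 um -> 4 um -> 2 um at 50 nm/frame over 81 frames).
    """

    length_min_nm: float = 2000.0
    length_max_nm: float = 4000.0
    step_nm_per_frame: float = 50.0
    n_frames: int = 81
    pixel_nm: float = 81.0
    psf_sigma_nm: float = 130.0
    labeled_fraction: float = 0.18
    dyes_per_dimer: float = 1.5
    target_snr: float = 6.0
    protofilaments: int = 13
    dimer_rise_nm: float = 8.0
    seed: int | None = None
    # rendering geometry
    n_rows: int = 25
    margin_nm: float = 600.0
    background_mean: float = 50.0
    frame_interval_s: float = 1.0
    # deterministic limit: expected dye counts instead of sampling, no noise
    noise_free: bool = False
    # "poisson": per-layer dye count ~ Poisson(protofilaments * labelled
    # fraction * dyes/dimer); "binomial-poisson": binomial dimer labelling,
    # then a Poisson number of dyes per labelled dimer (higher variance)
    labelling_model: str = "poisson"

    def validate(self) -> None:
        if not (0.0 < self.labeled_fraction <= 1.0):
            raise ValueError("labeled_fraction must be in (0, 1]")
        if self.target_snr <= 0:
            raise ValueError("target_snr must be positive")
        if self.length_min_nm >= self.length_max_nm:
            raise ValueError("length_min_nm must be below length_max_nm")
        for name in ("length_min_nm", "length_max_nm", "step_nm_per_frame",
                     "pixel_nm", "psf_sigma_nm", "dimer_rise_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_rows < 21:
            raise ValueError("n_rows must be >= 21 to allow straightening")
        if self.labelling_model not in ("poisson", "binomial-poisson"):
            raise ValueError(f"unknown labelling_model {self.labelling_model!r}")


def triangular_lengths(cfg: SimImageConfig) -> np.ndarray:
    """True microtubule length per frame: grow to max, shrink back, repeat."""
    n_up = int(round((cfg.length_max_nm - cfg.length_min_nm) / cfg.step_nm_per_frame))
    f = np.arange(cfg.n_frames)
    phase = f % (2 * n_up) if n_up > 0 else np.zeros_like(f)
    up = np.minimum(phase, 2 * n_up - phase) if n_up > 0 else phase
    return cfg.length_min_nm + cfg.step_nm_per_frame * up


def _transverse_weights(n_rows: int, row0: int, pixel_nm: float,
                        sigma_nm: float) -> np.ndarray:
    """Fraction of a 2-D Gaussian PSF captured by each pixel row for a line
    source on the centre of row ``row0`` (exact pixel integral via erf)."""
    y0 = (row0 + 0.5) * pixel_nm
    edges = np.arange(n_rows + 1) * pixel_nm
    z = (edges - y0) / (sigma_nm * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


def simulate_microtubule_stack(cfg: SimImageConfig) -> ImageStack:
    """Render a synthetic movie of one horizontal microtubule.

    Returns an :class:`ImageStack` whose ``ground_truth`` carries the true
    end positions per frame (nm, measured along the column axis with the
    origin at the left image edge) and the backbone row.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    lengths = triangular_lengths(cfg)
    n_cols = int(math.ceil((cfg.length_max_nm + 2 * cfg.margin_nm) / cfg.pixel_nm))
    width_nm = n_cols * cfg.pixel_nm
    if cfg.length_max_nm + 2 * cfg.margin_nm > width_nm + 1e-9:
        raise ValueError("image too small to contain the microtubule")
    px = int(round(cfg.pixel_nm))
    if abs(px - cfg.pixel_nm) > 1e-9:
        raise ValueError("pixel_nm must be an integer number of nm")

    row0 = cfg.n_rows // 2
    w_t = _transverse_weights(cfg.n_rows, row0, cfg.pixel_nm, cfg.psf_sigma_nm)

    # 1 nm axial PSF kernel, unit sum (photon conserving)
    half = int(5 * cfg.psf_sigma_nm)
    xk = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (xk / cfg.psf_sigma_nm) ** 2)
    kernel /= kernel.sum()

    start_nm = cfg.margin_nm
    nbins = int(round(width_nm))
    frames = np.empty((cfg.n_frames, cfg.n_rows, n_cols))
    mean_per_layer = cfg.protofilaments * cfg.labeled_fraction * cfg.dyes_per_dimer

    for f, length in enumerate(lengths):
        n_layers = int(length // cfg.dimer_rise_nm)
        centres = start_nm + cfg.dimer_rise_nm * (np.arange(n_layers) + 0.5)
        if cfg.noise_free:
            counts = np.full(n_layers, mean_per_layer)
        elif cfg.labelling_model == "poisson":
            counts = rng.poisson(mean_per_layer, size=n_layers).astype(float)
        else:
            labelled = rng.binomial(cfg.protofilaments, cfg.labeled_fraction,
                                    size=n_layers)
            counts = rng.poisson(cfg.dyes_per_dimer * labelled).astype(float)
        axial = np.zeros(nbins)
        np.add.at(axial, np.clip(centres.astype(int), 0, nbins - 1), counts)
        axial = fftconvolve(axial, kernel, mode="same")
        cols = axial.reshape(n_cols, px).sum(axis=1)
        np.clip(cols, 0.0, None, out=cols)  # fft round-off
        frames[f] = w_t[:, None] * cols[None, :]

    if not cfg.noise_free:
        # expected backbone-pixel signal far from the ends
        s0 = (cfg.pixel_nm / cfg.dimer_rise_nm) * mean_per_layer * w_t[row0]
        sd = s0 / cfg.target_snr
        frames += rng.normal(cfg.background_mean, sd, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)

    gt = {
        "start_nm": np.full(cfg.n_frames, start_nm),
        "end_nm": start_nm + lengths,
        "length_nm": lengths,
        "row": row0,
        "config": asdict(cfg),
    }
    return ImageStack(frames, pixel_nm=cfg.pixel_nm,
                      frame_interval_s=cfg.frame_interval_s, ground_truth=gt)


def default_snr_masks(stack: ImageStack,
                      inset_nm: float = 300.0,
                      clearance_rows: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Backbone / background masks for :func:`estimate_snr` from ground truth.

    Backbone: the backbone row restricted to columns covered by the
    microtubule in every frame (inset by ``inset_nm`` from the ends).
    Background: all rows at least ``clearance_rows`` away from the backbone.
    """
    if stack.ground_truth is None:
        raise ValueError("stack has no ground truth")
    gt = stack.ground_truth
    n_rows, n_cols = stack.data.shape[1:]
    x = (np.arange(n_cols) + 0.5) * stack.pixel_nm
    lo = np.max(gt["start_nm"]) + inset_nm
    hi = np.min(gt["end_nm"]) - inset_nm
    backbone = np.zeros((n_rows, n_cols), dtype=bool)
    backbone[gt["row"], (x >= lo) & (x <= hi)] = True
    rows = np.arange(n_rows)
    background = np.zeros_like(backbone)
    background[np.abs(rows - gt["row"]) >= clearance_rows, :] = True
    return backbone, background


def estimate_snr(stack: ImageStack, backbone_mask: np.ndarray,
                 background_mask: np.ndarray) -> float:
    """SNR = (mean backbone - mean background) / sd(background)."""
    backbone_mask = np.asarray(backbone_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not backbone_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if np.any(backbone_mask & background_mask):
        raise ValueError("masks must be disjoint")
    bb = stack.data[:, backbone_mask]
    bg = stack.data[:, background_mask]
    sd = float(bg.std())
    if sd == 0.0:
        raise ValueError("degenerate background: zero variance")
    return float((bb.mean() - bg.mean()) / sd)


@dataclass
class SimKymoConfig:
    """Parameters of a synthetic comet kymograph.

    ``channel_offsets_nm`` gives, per channel, how far *behind* the tip that
    channel's comet peak sits (positive = deeper into the lattice).
    ``channel_delay_s`` staggers acquisition: channel ``i`` samples the scene
    at ``t + i * channel_delay_s`` (sequential two-colour imaging).
    """

    comet_shape: str = "exponential"  # or "convolved-pair-profile"
    amplitude: float = 1.0
    decay_nm: float = 300.0
    growth_speed_nm_s: float = 20.0
    duration_s: float = 60.0
    line_interval_s: float = 1.0
    pixel_nm: float = 81.0
    channel_offsets_nm: tuple[float, ...] = (0.0,)
    channel_delay_s: float = 0.0
    noise_sd: float = 0.0
    start_position_nm: float = 2000.0
    field_nm: float | None = None
    seed: int | None = None

    def validate(self) -> None:
        if self.decay_nm <= 0:
            raise ValueError("decay_nm must be positive")
        if self.growth_speed_nm_s < 0:
            raise ValueError("growth_speed_nm_s must be >= 0")
        if not np.all(np.isfinite(self.channel_offsets_nm)):
            raise ValueError("channel offsets must be finite")
        if self.comet_shape not in ("exponential", "convolved-pair-profile"):
            raise ValueError(f"unknown comet_shape {self.comet_shape!r}")
        if self.line_interval_s <= 0 or self.duration_s <= 0:
            raise ValueError("duration and line interval must be positive")


def _comet_template(cfg: SimKymoConfig):
    """Return f(r): intensity at distance r behind the tip (r >= 0 in the
    tail, r < 0 ahead of the tip)."""
    if cfg.comet_shape == "exponential":
        def f(r: np.ndarray) -> np.ndarray:
            out = np.where(r >= 0.0, np.exp(-np.maximum(r, 0.0) / cfg.decay_nm), 0.0)
            return cfg.amplitude * out
        return f
    # comet shaped like a PSF-convolved nucleotide-pair profile (GTP/Pi pair)
    from . import nucsim

    params = nucsim.KineticParams(growth_speed_nm_s=max(cfg.growth_speed_nm_s, 1.0))
    profile = nucsim.solve_nucleotide_odes(params)
    pairs = nucsim.pair_distributions(profile, params.protofilaments)
    conv = nucsim.convolve_with_psf(pairs, params.psf_sigma_nm)
    pos, curve = conv["TP"]

    def f(r: np.ndarray) -> np.ndarray:
        return cfg.amplitude * np.interp(r, pos, curve, left=0.0, right=0.0)
    return f


def simulate_kymograph(cfg: SimKymoConfig) -> list[Kymograph]:
    """One kymograph per channel, with the comet peak of channel ``i`` at
    ``start + v * (t + i*delay) - offset_i``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_rows = max(int(round(cfg.duration_s / cfg.line_interval_s)), 2)
    field_nm = cfg.field_nm
    if field_nm is None:
        field_nm = (cfg.start_position_nm
                    + cfg.growth_speed_nm_s * cfg.duration_s + 2500.0)
    n_cols = int(math.ceil(field_nm / cfg.pixel_nm))
    if 5 * cfg.decay_nm > n_cols * cfg.pixel_nm:
        raise ValueError("comet wider than the field")
    x = (np.arange(n_cols) + 0.5) * cfg.pixel_nm
    template = _comet_template(cfg)

    kymos = []
    for ch, offset in enumerate(cfg.channel_offsets_nm):
        data = np.empty((n_rows, n_cols))
        for i in range(n_rows):
            t = i * cfg.line_interval_s + ch * cfg.channel_delay_s
            x0 = cfg.start_position_nm + cfg.growth_speed_nm_s * t - offset
            data[i] = template(x0 - x)
        if cfg.noise_sd > 0:
            data = data + rng.normal(0.0, cfg.noise_sd, size=data.shape)
        kymos.append(Kymograph(data, pixel_nm=cfg.pixel_nm,
                               line_interval_s=cfg.line_interval_s,
                               channel=str(ch)))
    return kymos


def simulate_frap_trace(tau_s: float, n_pre: int = 5, n_post: int = 40,
                        noise_sd: float = 0.0, seed: int | None = None,
                        dt_s: float = 0.3, plateau: float = 1.0) -> FrapTrace:
    """FRAP trace: plateau*(1 - exp(-t/tau)) recovery plus noise, then
    normalised to 1 at the last pre-bleach point and 0 at the first
    post-bleach point."""
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if n_pre < 2 or n_post < 2:
        raise ValueError("need at least 2 pre- and post-bleach points")
    rng = np.random.default_rng(seed)
    t_pre = (np.arange(n_pre) - n_pre) * dt_s
    t_post = np.arange(n_post) * dt_s
    raw = np.concatenate([
        np.ones(n_pre),
        plateau * (1.0 - np.exp(-t_post / tau_s)),
    ])
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    # the normalisation rule: last pre-bleach -> 1, first post-bleach -> 0
    lo, hi = raw[n_pre], raw[n_pre - 1]
    if hi == lo:
        raise ValueError("degenerate trace: pre-bleach equals post-bleach")
    norm = (raw - lo) / (hi - lo)
    return FrapTrace(np.concatenate([t_pre, t_post]), norm, n_pre=n_pre,
                     tau_true_s=tau_s)
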