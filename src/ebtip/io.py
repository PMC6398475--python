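"""File formats, run configuration and pipeline orchestration.

Image stacks travel as multi-page 16-bit TIFF with a JSON sidecar
(``<stem>.json``) carrying pixel size, frame interval and, for synthetic
stacks, the ground truth.  Kymographs are TIFF or CSV matrices (rows =
time).  Tables are comma-separated UTF-8 with a header row, '.' decimal,
positions in nm and times in s.  All randomness derives from one root seed;
output filenames embed the config hash and seed so reruns are reproducible
and traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict

from . import mtend, phases, simgen
from .containers import ImageStack, Kymograph, LengthTrace

log = logging.getLogger("ebtip")


# --------------------------------------------------------------------------
# stacks

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page uint16 TIFF plus a JSON sidecar with
    calibration and ground truth."""
    path = Path(path)
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta: dict = {"pixel_nm": stack.pixel_nm,
                  "frame_interval_s": stack.frame_interval_s}
    if stack.ground_truth is not None:
        meta["ground_truth"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in stack.ground_truth.items()
        }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path, pixel_nm: float | None = None,
               frame_interval_s: float | None = None) -> ImageStack:
    """Read a (multi-page) TIFF stack; calibration comes from the JSON
    sidecar or must be supplied explicitly."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    ground_truth = None
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        pixel_nm = pixel_nm or meta.get("pixel_nm")
        frame_interval_s = frame_interval_s or meta.get("frame_interval_s")
        gt = meta.get("ground_truth")
        if gt is not None:
            ground_truth = {k: (np.asarray(v) if isinstance(v, list) else v)
                            for k, v in gt.items()}
    if pixel_nm is None:
        raise ValueError(f"{path}: no pixel size; supply pixel_nm "
                         "(CLI: --pixel-nm) or a JSON sidecar")
    return ImageStack(np.asarray(data, dtype=float), pixel_nm=pixel_nm,
                      frame_interval_s=frame_interval_s or 1.0,
                      ground_truth=ground_truth)


# --------------------------------------------------------------------------
# kymographs

def write_kymograph(kymo: Kymograph, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, kymo.data.astype(np.float32))
    else:
        np.savetxt(path, kymo.data, delimiter=",")
    return path


def read_kymograph(path: str | Path, pixel_nm: float = 81.0,
                   line_interval_s: float = 1.0, channel: str = "") -> Kymograph:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.loadtxt(path, delimiter=",")
    return Kymograph(np.asarray(data, dtype=float), pixel_nm=pixel_nm,
                     line_interval_s=line_interval_s, channel=channel)


# --------------------------------------------------------------------------
# run configuration and pipeline

class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    stages: list[str] = []
    simulate_images: dict = {}
    benchmark: dict = {}

    def config_hash(self) -> str:
        payload = self.model_dump_json(exclude={"out_dir", "log_level"})
        return hashlib.sha1(payload.encode()).hexdigest()[:8]


_KNOWN_STAGES = ("simulate_images", "detect_ends", "segment_phases",
                 "benchmark")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write tables plus a
    machine-readable summary.  Identical config+seed give identical
    outputs."""
    import warnings as _w

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    tag = f"{config.config_hash()}_s{config.seed}"
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stages": list(config.stages), "outputs": {}}
    if not config.stages:
        _w.warn("empty stage list: nothing to do")
        return summary

    stack: ImageStack | None = None
    tips_table: pd.DataFrame | None = None
    root = np.random.SeedSequence(config.seed)
    substreams = {name: int(child.generate_state(1)[0] % (2 ** 31))
                  for name, child in zip(_KNOWN_STAGES, root.spawn(len(_KNOWN_STAGES)))}

    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            if stage == "simulate_images":
                cfg = simgen.SimImageConfig(**config.simulate_images,
                                            seed=substreams[stage])
                stack = simgen.simulate_microtubule_stack(cfg)
                p = out_dir / f"stack_{tag}.tif"
                write_stack(stack, p)
                summary["outputs"]["stack"] = str(p)
            elif stage == "detect_ends":
                if stack is None:
                    raise ValueError("no stack available (run simulate_images"
                                     " first or load one)")
                tips_table = mtend.measure_lengths(stack)
                p = out_dir / f"tips_{tag}.csv"
                tips_table.to_csv(p, index=False)
                summary["outputs"]["tips"] = str(p)
            elif stage == "segment_phases":
                if tips_table is None:
                    raise ValueError("no tip table available")
                ok = tips_table[tips_table["ok"]]
                trace = LengthTrace(ok["frame"].to_numpy(dtype=float),
                                    ok["length_nm"].to_numpy())
                found = phases.segment_phases(trace)
                p = out_dir / f"phases_{tag}.csv"
                pd.DataFrame([vars(ph) for ph in found]).to_csv(p, index=False)
                summary["outputs"]["phases"] = str(p)
                summary["n_phases_kept"] = sum(ph.kept for ph in found)
            elif stage == "benchmark":
                params = dict(config.benchmark)
                n_stacks = int(params.pop("n_stacks", 10))
                snr_range = params.pop("snr_range", (6.0, 11.0))
                report = run_benchmark(n_stacks=n_stacks, snr_range=snr_range,
                                       seed=substreams[stage], **params)
                p = out_dir / f"benchmark_{tag}.csv"
                report.pop("table").to_csv(p, index=False)
                summary["outputs"]["benchmark"] = str(p)
                summary["benchmark"] = report
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out_dir / f"summary_{tag}.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_benchmark(n_stacks: int = 10, snr_range: tuple[float, float] = (6.0, 11.0),
                  labeled_fraction: float = 0.18, seed: int = 0,
                  **cfg_kwargs) -> dict:
    """Length-accuracy benchmark: generate ``n_stacks`` synthetic stacks
    with SNR spread evenly over ``snr_range``, fit both ends per frame and
    report the signed-error statistics."""
    snrs = np.linspace(snr_range[0], snr_range[1], n_stacks)
    ss = np.random.SeedSequence(seed)
    stacks = []
    for snr, child in zip(snrs, ss.spawn(n_stacks)):
        cfg = simgen.SimImageConfig(labeled_fraction=labeled_fraction,
                                    target_snr=float(snr),
                                    seed=int(child.generate_state(1)[0] % (2 ** 31)),
                                    **cfg_kwargs)
        stacks.append(simgen.simulate_microtubule_stack(cfg))
    return mtend.benchmark_length_accuracy(stacks)
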