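"""Stack I/O, run configuration and the end-to-end pipeline orchestrator."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .frames import FrameStack
from .pipeline import (
    discard_aberrant,
    filter_blurred,
    flatten_background,
    project,
    register,
    shuffle_decorrelate,
    unshuffle,
)
from .synthetic import MotionModel, generate_network, render_movie

__all__ = ["read_stack", "write_stack", "RunConfig", "run_pipeline"]


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page grayscale TIFF into a FrameStack.

    RGB pages are converted to luminance with a warning; pages of mixed bit
    depth are rejected; an unreadable page raises an error naming its
    index.
    """
    path = Path(path)
    pages = []
    with tifffile.TiffFile(path) as tif:
        for k, page in enumerate(tif.pages):
            try:
                arr = page.asarray()
            except Exception as exc:  # corrupt page
                raise IOError(f"cannot read page {k} of {path}: {exc}") from exc
            if arr.ndim == 3:
                warnings.warn(
                    f"page {k} is RGB; converting to luminance", stacklevel=2
                )
                arr = (arr @ np.array([0.2126, 0.7152, 0.0722])).astype(arr.dtype)
            pages.append(arr)
    if not pages:
        raise IOError(f"{path} holds no image pages")
    dtypes = {p.dtype for p in pages}
    if len(dtypes) > 1:
        raise IOError(f"{path} mixes bit depths {sorted(map(str, dtypes))}")
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise IOError(f"{path} mixes page shapes {sorted(shapes)}")
    return FrameStack(frames=np.stack(pages))


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a FrameStack as a multi-page TIFF (bit-exact round trip).

    Float stacks are stored as 16-bit scaled to [0, 1] full range only if
    requested elsewhere; here the dtype is preserved as-is, so a write ->
    read round trip is identical.
    """
    tifffile.imwrite(Path(path), stack.frames, photometric="minisblack")


def quantize_16bit(image: np.ndarray) -> np.ndarray:
    """Scale a float image to the full uint16 range (for stable checksums
    and viewable output)."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint16)
    return np.round((img - lo) / (hi - lo) * 65535).astype(np.uint16)


def _checksum(image: np.ndarray) -> str:
    return hashlib.sha256(quantize_16bit(image).tobytes()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Fully serialisable parameters of one pipeline run."""

    input_path: str | None = None
    synthetic: dict | None = None  # network/motion config for a generated movie
    n_frames: int = 300
    seed: int = 0
    shuffle: bool = True
    roi: tuple[int, int, int, int] | None = None
    keep_fraction: float = 0.5
    blur_criterion: str = "roi_gray"
    aberrant_min_correlation: float = 0.1
    registration_model: str = "translation"
    registration_mode: str = "sequential"
    background_radius: float = 0.0  # 0 disables background flattening
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if cfg.roi is not None:
            cfg.roi = tuple(cfg.roi)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if data["roi"] is not None:
            data["roi"] = list(data["roi"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _auto_roi(stack: FrameStack, size: int = 24) -> tuple[int, int, int, int]:
    """Pick an ROI centred on the darkest smoothed spot of a provisional
    minima image — a stand-in for the operator clicking a crisp dark
    feature."""
    from scipy import ndimage

    prov = stack.frames.astype(float).min(axis=0)
    sm = ndimage.uniform_filter(prov, size)
    H, W = prov.shape
    border = size
    inner = sm[border:H - border, border:W - border]
    iy, ix = np.unravel_index(np.argmin(inner), inner.shape)
    cy, cx = iy + border, ix + border
    half = size // 2
    return (int(cx - half), int(cy - half), size, size)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full processing chain and return a result manifest.

    Stage order: shuffle -> blur filter -> aberrant filter -> register ->
    unshuffle -> project (minima and average) -> optional background
    flattening.  The manifest records per-stage frame counts, the estimated
    transforms and projection checksums; with ``out_dir`` set, projections
    (16-bit TIFF), the per-frame log (CSV) and the manifest (JSON) are
    written there.
    """
    manifest: dict = {"stages": {}, "config": asdict(config)}

    if config.input_path is not None:
        stack = read_stack(config.input_path)
        gt = None
    elif config.synthetic is not None:
        net = generate_network(config.synthetic["network"])
        motion = MotionModel(**{**config.synthetic.get("motion", {}),
                                "seed": config.seed})
        render_kwargs = config.synthetic.get("render", {})
        stack, gt = render_movie(net, motion, n_frames=config.n_frames,
                                 **render_kwargs)
    else:
        raise ValueError("config needs input_path or a synthetic movie definition")
    manifest["stages"]["input"] = {"n_frames": len(stack)}

    perm = None
    if config.shuffle:
        try:
            stack, perm = shuffle_decorrelate(stack)
        except ValueError as exc:
            raise RuntimeError(f"stage shuffle failed: {exc}") from exc
    manifest["stages"]["shuffle"] = {
        "enabled": config.shuffle, "n_frames": len(stack),
    }

    roi = config.roi
    if roi is None and config.blur_criterion == "roi_gray":
        roi = _auto_roi(stack)
    try:
        stack = filter_blurred(stack, roi=roi, keep_fraction=config.keep_fraction,
                               criterion=config.blur_criterion)
    except ValueError as exc:
        raise RuntimeError(f"stage blur-filter failed: {exc}") from exc
    manifest["stages"]["blur_filter"] = {
        "n_frames": len(stack), "roi": list(roi) if roi else None,
    }

    stack = discard_aberrant(stack, reference_slot=0,
                             min_correlation=config.aberrant_min_correlation)
    manifest["stages"]["aberrant_filter"] = {"n_frames": len(stack)}

    stack, reg = register(stack, reference_slot=0,
                          model=config.registration_model,
                          mode=config.registration_mode)
    manifest["stages"]["register"] = {
        "n_frames": len(stack),
        "max_shift_px": float(np.abs(reg.shifts).max()),
    }
    acq_order = np.argsort(stack.frame_indices, kind="stable")

    stack = unshuffle(stack, perm)
    manifest["stages"]["unshuffle"] = {"n_frames": len(stack)}

    minima = project(stack, "minima")
    average = project(stack, "average")
    if config.background_radius > 0:
        minima = flatten_background(minima, config.background_radius)
        average = flatten_background(average, config.background_radius)
    manifest["projections"] = {
        "minima_checksum": _checksum(minima.image),
        "average_checksum": _checksum(average.image),
    }
    manifest["frame_log"] = {
        "kept_acquisition_indices": stack.frame_indices.tolist(),
        "shifts": reg.shifts[acq_order].tolist(),
        "scores": reg.scores[acq_order].tolist(),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "minima.tif", quantize_16bit(minima.image))
        tifffile.imwrite(out / "average.tif", quantize_16bit(average.image))
        pd.DataFrame({
            "acquisition_index": stack.frame_indices,
            "dy": reg.shifts[acq_order, 0],
            "dx": reg.shifts[acq_order, 1],
            "score": reg.scores[acq_order],
        }).to_csv(out / "frame_log.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    manifest["_results"] = {"minima": minima, "average": average,
                            "stack": stack, "registration": reg,
                            "ground_truth": gt}
    return manifest
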