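"""Shared fixtures: seeded synthetic benchmarks used across the suite.

Everything is generated at test time; the heavy movies are session-scoped
so rendering and pipeline runs happen once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import spearmanr
from skimage.filters import threshold_otsu

import camtrace as ct
from camtrace.pipeline import (
    discard_aberrant,
    filter_blurred,
    project,
    register,
    shuffle_decorrelate,
    unshuffle,
)

BENCHMARK_SEED = 5
BENCHMARK_N_FRAMES = 300
#: ROI around the junction of the benchmark Y network (a dark crisp feature)
BENCHMARK_ROI = (60, 110, 60, 60)


def make_benchmark_network() -> ct.VesselNetwork:
    """Y-shaped network: cylindrical parent, fully flattened distal branch,
    and a thinner side branch — mixed orientations so rigid registration is
    well-posed."""
    cfg = {
        "shape": (220, 260),
        "segments": [
            {"points": [(30, 160), (110, 110)], "radius_px": 9,
             "flattening": 0.0, "speed_px_per_frame": 2.5},
            {"points": [(110, 110), (225, 80)], "radius_px": 8,
             "flattening": 1.0, "speed_px_per_frame": 2.5},
            {"points": [(110, 110), (150, 190)], "radius_px": 6,
             "flattening": 0.0, "speed_px_per_frame": 2.0},
        ],
    }
    return ct.generate_network(cfg)


@pytest.fixture(scope="session")
def benchmark_network():
    return make_benchmark_network()


@pytest.fixture(scope="session")
def benchmark_movie(benchmark_network):
    """300-frame movie with heartbeat jitter (<= 6 px), slow drift, 50%
    blurred frames and rare aberrant frames."""
    motion = ct.MotionModel(jitter_amplitude_px=6.0, seed=BENCHMARK_SEED)
    stack, gt = ct.render_movie(benchmark_network, motion,
                                n_frames=BENCHMARK_N_FRAMES)
    return stack, gt


def run_full_pipeline(stack, gt, shuffle: bool) -> dict:
    """Shuffle -> blur filter -> aberrant filter -> register -> unshuffle ->
    project, scored against ground truth (in scene coordinates)."""
    s = stack
    perm = None
    if shuffle:
        s, perm = shuffle_decorrelate(s)
    filtered = filter_blurred(s, roi=BENCHMARK_ROI, keep_fraction=0.5)
    blur_agreement = float((~gt.blur_flags[filtered.frame_indices]).mean())
    cleaned = discard_aberrant(filtered, reference_slot=0)
    registered, reg = register(cleaned, reference_slot=0, model="translation",
                               mode="sequential")
    # registration error vs ground truth (transforms are relative to slot 0)
    rel = gt.shifts[cleaned.frame_indices] - gt.shifts[cleaned.frame_indices[0]]
    shift_err = np.hypot(reg.shifts[:, 0] + rel[:, 1],
                         reg.shifts[:, 1] + rel[:, 0])
    ordered = unshuffle(registered, perm)
    minima = project(ordered, "minima")
    average = project(ordered, "average")
    # the registered stack lives in the reference frame's coordinates;
    # map projections back to scene coordinates via the known jitter of
    # the reference acquisition
    dx0, dy0 = gt.shifts[cleaned.frame_indices[0]]
    minima_scene = ndimage.shift(minima.image, (-dy0, -dx0), order=1,
                                 mode="nearest")
    average_scene = ndimage.shift(average.image, (-dy0, -dx0), order=1,
                                  mode="nearest")
    mask = gt.vessel_mask
    pred = minima_scene < threshold_otsu(minima_scene)
    dice = 2.0 * (pred & mask).sum() / (pred.sum() + mask.sum())
    od_avg = -np.log(np.clip(average_scene / gt.static_background, 1e-6, None))
    flux_spearman = float(spearmanr(od_avg[mask], gt.mean_flux[mask]).statistic)
    return {
        "n_kept": len(filtered),
        "blur_agreement": blur_agreement,
        "shift_errors": shift_err,
        "dice": float(dice),
        "flux_spearman": flux_spearman,
        "minima_scene": minima_scene,
        "stack": ordered,
        "registration": reg,
    }


@pytest.fixture(scope="session")
def pipeline_shuffled(benchmark_movie):
    stack, gt = benchmark_movie
    return run_full_pipeline(stack, gt, shuffle=True)


@pytest.fixture(scope="session")
def pipeline_unshuffled(benchmark_movie):
    stack, gt = benchmark_movie
    return run_full_pipeline(stack, gt, shuffle=False)


def render_saturated_vessel(flattening: float, n_frames: int = 400,
                            radius_px: float = 12.0):
    """Single straight vessel in the saturated-absorption regime (the lumen
    repeatedly packed with cells), motion-free: the minima projection then
    approaches OD proportional to the chord thickness."""
    cfg = {"shape": (120, 260), "segments": [
        {"points": [(25, 60), (235, 60)], "radius_px": radius_px,
         "flattening": flattening, "speed_px_per_frame": 2.5},
    ]}
    net = ct.generate_network(cfg)
    motion = ct.MotionModel(jitter_amplitude_px=0.0, drift_px_per_frame=(0, 0),
                            blur_fraction=0.0, aberrant_frame_rate=0.0, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # density deliberately saturating
        stack, gt = ct.render_movie(net, motion, n_frames=n_frames,
                                    tracer_density=2400.0)
    return net, project(stack, "minima"), gt


@pytest.fixture(scope="session")
def saturated_cylinder():
    return render_saturated_vessel(flattening=0.0)


@pytest.fixture(scope="session")
def saturated_flattened():
    return render_saturated_vessel(flattening=1.0)
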