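"""Core containers for time-lapse stack processing.

A movie is a ``FrameStack``: an ordered T x H x W grayscale array whose
slots remember the *acquisition index* of the frame they hold, so that
frames can be shuffled, filtered and later restored to acquisition order
without losing track of what was discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["FrameStack", "ShufflePermutation", "RegistrationResult", "ProjectionImage"]


@dataclass
class FrameStack:
    """An ordered stack of same-shape grayscale frames.

    Parameters
    ----------
    frames : (T, H, W) ndarray
        Grayscale frames, any numeric dtype (floats in [0, 1] for synthetic
        movies, integers for camera data).
    frame_indices : (T,) ndarray of int, optional
        Acquisition index of the frame in each slot; defaults to 0..T-1.
        Always a subset of the original acquisition indices, in the order
        the slots currently hold them.
    fps : float, optional
        Acquisition frame rate.
    pixel_size_um : float, optional
        Physical pixel pitch, if known.
    valid_masks : (T, H, W) bool ndarray, optional
        Per-frame validity (False where resampling pulled in out-of-frame
        pixels); projections exclude invalid pixels.
    """

    frames: np.ndarray
    frame_indices: np.ndarray | None = None
    fps: float | None = None
    pixel_size_um: float | None = None
    valid_masks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.frames))
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
            if len(self.frame_indices) != len(self.frames):
                raise ValueError("frame_indices length must match frame count")
        if self.valid_masks is not None and self.valid_masks.shape != self.frames.shape:
            raise ValueError("valid_masks must match frames shape")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def take(self, slots) -> "FrameStack":
        """New stack holding the given slots, in the given order."""
        slots = np.asarray(slots, dtype=np.int64)
        return replace(
            self,
            frames=self.frames[slots],
            frame_indices=self.frame_indices[slots],
            valid_masks=None if self.valid_masks is None else self.valid_masks[slots],
        )

    def copy(self) -> "FrameStack":
        return replace(
            self,
            frames=self.frames.copy(),
            frame_indices=self.frame_indices.copy(),
            valid_masks=None if self.valid_masks is None else self.valid_masks.copy(),
        )


@dataclass
class ShufflePermutation:
    """Bijection between output slots and input slots of the shuffle.

    ``forward[k]`` is the input slot whose frame ends up in output slot
    ``k``; ``inverse`` undoes it (``inverse[forward[k]] = k``).
    """

    forward: np.ndarray

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=np.int64)
        n = len(self.forward)
        if sorted(self.forward.tolist()) != list(range(n)):
            raise ValueError("forward map must be a permutation of 0..N-1")

    @property
    def inverse(self) -> np.ndarray:
        inv = np.empty_like(self.forward)
        inv[self.forward] = np.arange(len(self.forward))
        return inv

    def __len__(self) -> int:
        return len(self.forward)


@dataclass
class RegistrationResult:
    """Estimated per-slot rigid transforms mapping each frame onto the
    reference frame's coordinates.

    ``shifts[t] = (dy, dx)`` is the translation applied to frame t (pixels);
    ``rotations[t]`` the rotation about the image centre (radians, 0 for the
    translation model); ``scores[t]`` an alignment quality in [0, 1]
    (low scores flag featureless or poorly matched frames).
    """

    shifts: np.ndarray
    rotations: np.ndarray
    scores: np.ndarray
    reference_slot: int = 0

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class ProjectionImage:
    """Z-projection of a registered stack.

    ``mode='minima'`` keeps the darkest value ever seen at each pixel (the
    vessel lumens, for dark tracers on a bright field); ``mode='average'``
    the mean (the qualitative flux map).  ``n_frames`` counts contributing
    frames per pixel.
    """

    image: np.ndarray
    mode: str
    n_frames: np.ndarray | int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("minima", "average"):
            raise ValueError(f"unknown projection mode {self.mode!r}")
        self.image = np.asarray(self.image, dtype=float)
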