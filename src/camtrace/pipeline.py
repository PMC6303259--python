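"""The core stack-processing algorithm.

Order of operations for a raw tracer movie:

1. ``shuffle_decorrelate`` — permute the frames so that temporally adjacent
   slots hold frames acquired ~half the movie apart.  Registration
   algorithms try to cancel *all* apparent motion; on an unshuffled movie
   the coherent displacement of the erythrocytes biases every pairwise
   alignment in the flow direction and the errors accumulate into a drift.
   Shuffling decorrelates the tracer pattern between neighbouring slots so
   the bias averages out.
2. ``filter_blurred`` — rank frames by the gray level of a dark crisp
   feature (defocus diffuses light, so the feature pales) and keep the
   sharpest half.
3. ``discard_aberrant`` — drop frames too dissimilar from a chosen
   reference (spurious saturated frames from the camera electronics).
4. ``register`` — rigid alignment by subpixel phase correlation,
   sequentially (each frame to its predecessor, accumulated) or to a fixed
   reference.
5. ``unshuffle`` — restore acquisition order (the registered movie then
   plays as a smooth flow).
6. ``project`` — pixelwise minima (the lumens) or average (the flux map),
   optionally followed by ``flatten_background``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .frames import FrameStack, ProjectionImage, RegistrationResult, ShufflePermutation

__all__ = [
    "shuffle_decorrelate",
    "filter_blurred",
    "discard_aberrant",
    "register",
    "unshuffle",
    "project",
    "flatten_background",
]


def make_shuffle_permutation(n: int) -> ShufflePermutation:
    """Interleave the two halves of the stack: 0, h, 1, h+1, ... (h = ceil(N/2)).

    Any two adjacent output slots then hold frames acquired at least
    ``floor(N/2) - 1`` frames apart — each "next plate" is replaced by a
    plate from the far half of the stack.
    """
    if n < 4:
        raise ValueError(f"need at least 4 frames to shuffle, got {n}")
    h = (n + 1) // 2
    first = np.arange(h)
    second = np.arange(h, n)
    forward = np.empty(n, dtype=np.int64)
    forward[0::2] = first
    forward[1::2] = second
    return ShufflePermutation(forward=forward)


def shuffle_decorrelate(stack: FrameStack) -> tuple[FrameStack, ShufflePermutation]:
    """Reorder frames to decorrelate tracer motion between adjacent slots."""
    perm = make_shuffle_permutation(len(stack))
    return stack.take(perm.forward), perm


def _roi_slices(roi, shape):
    x, y, w, h = (int(v) for v in roi)
    H, W = shape
    if w <= 0 or h <= 0:
        raise ValueError(f"ROI has zero area: {roi}")
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError(f"ROI {roi} extends outside the {H}x{W} frame")
    return slice(y, y + h), slice(x, x + w)


def filter_blurred(
    stack: FrameStack,
    roi: tuple[int, int, int, int] | None = None,
    keep_fraction: float = 0.5,
    criterion: str = "roi_gray",
) -> FrameStack:
    """Keep the sharpest ``ceil(keep_fraction * N)`` frames, in order.

    Parameters
    ----------
    roi : (x, y, w, h)
        Rectangle around a dark, crisp feature.  With ``criterion
        'roi_gray'`` frames are ranked by the gray level of the feature —
        the mean of the darkest 1% of ROI pixels: defocus diffuses the
        feature's darkness away, so a *lower* value marks a sharper frame.
        (A low quantile rather than the plain ROI mean keeps the measure
        valid while rigid jitter moves the feature around inside the ROI.)
    criterion : {'roi_gray', 'gradient'}
        'gradient' ranks by gradient energy (Tenengrad) instead — an
        operator-free alternative for unattended time-lapse runs; the ROI
        is then optional (whole frame if omitted).

    Relative frame order is preserved; ties keep the earlier slot.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    n = len(stack)
    if criterion == "roi_gray":
        if roi is None:
            raise ValueError("criterion 'roi_gray' requires an ROI around a dark feature")
        sy, sx = _roi_slices(roi, stack.frame_shape)
        # sharper = darker feature = lower gray level of the darkest pixels
        sub = stack.frames[:, sy, sx].reshape(len(stack), -1).astype(float)
        k = max(1, sub.shape[1] // 100)
        badness = np.sort(sub, axis=1)[:, :k].mean(axis=1)
    elif criterion == "gradient":
        if roi is not None:
            sy, sx = _roi_slices(roi, stack.frame_shape)
            sub = stack.frames[:, sy, sx].astype(float)
        else:
            sub = stack.frames.astype(float)
        gx = np.diff(sub, axis=2)
        gy = np.diff(sub, axis=1)
        badness = -(
            (gx**2).mean(axis=(1, 2)) + (gy**2).mean(axis=(1, 2))
        )
    else:
        raise ValueError(f"unknown sharpness criterion {criterion!r}")
    n_keep = int(np.ceil(keep_fraction * n))
    order = np.argsort(badness, kind="stable")[:n_keep]
    return stack.take(np.sort(order))


def discard_aberrant(
    stack: FrameStack,
    reference_slot: int = 0,
    min_correlation: float = 0.1,
) -> FrameStack:
    """Drop frames whose normalized cross-correlation with the reference
    frame falls below ``min_correlation``; the reference is always kept.

    ``min_correlation = -1`` accepts everything.
    """
    n = len(stack)
    if not 0 <= reference_slot < n:
        raise ValueError(f"reference slot {reference_slot} outside stack of {n}")
    ref = stack.frames[reference_slot].astype(float)
    ref = ref - ref.mean()
    ref_norm = np.sqrt((ref**2).sum())
    keep = []
    for t in range(n):
        if t == reference_slot:
            keep.append(t)
            continue
        f = stack.frames[t].astype(float)
        f = f - f.mean()
        denom = ref_norm * np.sqrt((f**2).sum())
        ncc = float((ref * f).sum() / denom) if denom > 0 else 0.0
        if ncc >= min_correlation:
            keep.append(t)
    if len(keep) == 1:
        warnings.warn(
            "aberrant-frame threshold removed every frame but the reference",
            stacklevel=2,
        )
    return stack.take(np.array(sorted(keep)))


def _phase_shift(a: np.ndarray, b: np.ndarray, upsample: int) -> tuple[np.ndarray, float]:
    """Subpixel (dy, dx) moving b onto a, plus a quality score in [0, 1]."""
    if a.std() == 0 or b.std() == 0:
        return np.zeros(2), 0.0
    shift, error, _ = phase_cross_correlation(a, b, upsample_factor=upsample,
                                              normalization=None)
    return shift, float(np.clip(1.0 - error, 0.0, 1.0))


def _lk_shift(template: np.ndarray, frame: np.ndarray, weight: np.ndarray,
              cval: float, iters: int = 3, max_step: float = 2.0) -> np.ndarray:
    """Weighted Lucas-Kanade estimate of the residual (dy, dx) shift that
    aligns ``frame`` onto ``template`` (both already coarsely aligned).

    Solves the linearised brightness-constancy normal equations with the
    given per-pixel weights; the weights let transient content (passing
    tracers) be excluded so only the static scene drives the estimate.
    """
    gy, gx = np.gradient(template)
    e = np.zeros(2)
    cur = frame
    for _ in range(iters):
        r = cur - template
        a11 = (weight * gy * gy).sum()
        a12 = (weight * gy * gx).sum()
        a22 = (weight * gx * gx).sum()
        b1 = -(weight * r * gy).sum()
        b2 = -(weight * r * gx).sum()
        det = a11 * a22 - a12 * a12
        if det <= 0:
            return -e * 0.0
        de = np.array([(a22 * b1 - a12 * b2) / det, (a11 * b2 - a12 * b1) / det])
        e += de
        if np.hypot(*e) > max_step:
            return np.zeros(2)
        cur = ndimage.shift(frame, -e, order=1, mode="constant", cval=cval)
        if np.hypot(*de) < 0.005:
            break
    return -e


def _rotate(img: np.ndarray, angle_rad: float) -> np.ndarray:
    if angle_rad == 0.0:
        return img
    return ndimage.rotate(img, np.degrees(angle_rad), reshape=False,
                          order=1, mode="nearest")


def _estimate_rotation(a, b, upsample, angles=None):
    """Coarse search + refinement of the rotation aligning b to a."""
    if angles is None:
        angles = np.radians(np.arange(-3.0, 3.01, 1.0))
    best = (None, -np.inf, 0.0)
    for ang in angles:
        shift, score = _phase_shift(a, _rotate(b, ang), upsample=4)
        if score > best[1]:
            best = (ang, score, shift)
    ang = best[0]
    fine = ang + np.radians(np.array([-0.5, -0.25, 0.25, 0.5]))
    for f in fine:
        shift, score = _phase_shift(a, _rotate(b, f), upsample=4)
        if score > best[1]:
            best = (f, score, shift)
    return best[0]


def register(
    stack: FrameStack,
    reference_slot: int = 0,
    model: str = "translation",
    mode: str = "sequential",
    upsample: int = 20,
    refine_passes: int = 1,
) -> tuple[FrameStack, RegistrationResult]:
    """Rigidly align all frames into the reference frame's coordinates.

    Parameters
    ----------
    model : {'translation', 'rigid'}
        'rigid' adds a small-angle rotation search on top of the subpixel
        phase-correlation translation estimate.
    mode : {'sequential', 'reference'}
        'sequential' registers each frame to its predecessor and accumulates
        the transforms (robust to slow appearance changes, but sensitive to
        coherent tracer flow — which is what the decorrelation shuffle is
        for); 'reference' registers every frame directly to the reference.
    refine_passes : int
        After the first alignment, each frame is re-registered this many
        times against the pixelwise *median* of the aligned stack (the
        median template suppresses the moving tracers, leaving the static
        scene), and the original frame is resampled once with the combined
        shift.  Refinement sharpens a roughly aligned stack to subpixel
        precision but cannot rescue a drifted one.

    Frames are resampled bilinearly; pixels pulled in from outside the
    frame are filled with the background median and marked invalid so the
    projections can exclude them.  Featureless (zero-variance) frames get
    an identity transform with a zero score.
    """
    n = len(stack)
    if n == 0:
        raise ValueError("empty stack")
    if not 0 <= reference_slot < n:
        raise ValueError(f"reference slot {reference_slot} outside stack of {n}")
    if model not in ("translation", "rigid"):
        raise ValueError(f"unknown registration model {model!r}")
    if mode not in ("sequential", "reference"):
        raise ValueError(f"unknown registration mode {mode!r}")

    frames = stack.frames.astype(float)
    shifts = np.zeros((n, 2))
    rots = np.zeros(n)
    scores = np.ones(n)

    if n > 1 and mode == "sequential":
        # pairwise transforms between consecutive slots, then accumulate
        pair_shift = np.zeros((n, 2))
        pair_rot = np.zeros(n)
        for t in range(1, n):
            a, b = frames[t - 1], frames[t]
            if model == "rigid":
                pair_rot[t] = _estimate_rotation(a, b, upsample)
                b = _rotate(b, pair_rot[t])
            pair_shift[t], scores[t] = _phase_shift(a, b, upsample)
        shifts = np.cumsum(pair_shift, axis=0)
        rots = np.cumsum(pair_rot)
        shifts -= shifts[reference_slot]
        rots -= rots[reference_slot]
    elif n > 1:
        ref = frames[reference_slot]
        for t in range(n):
            if t == reference_slot:
                continue
            b = frames[t]
            if model == "rigid":
                rots[t] = _estimate_rotation(ref, b, upsample)
                b = _rotate(b, rots[t])
            shifts[t], scores[t] = _phase_shift(ref, b, upsample)

    bg = float(np.median(frames))
    ones = np.ones(stack.frame_shape)

    def resample(all_shifts, all_rots):
        out = np.empty_like(frames)
        valid = np.empty(frames.shape, dtype=bool)
        for t in range(n):
            img = _rotate(frames[t], all_rots[t])
            out[t] = ndimage.shift(img, all_shifts[t], order=1,
                                   mode="constant", cval=bg)
            v = ndimage.shift(_rotate(ones, all_rots[t]), all_shifts[t],
                              order=1, mode="constant", cval=0.0)
            valid[t] = v > 0.999
        return out, valid

    out, valid = resample(shifts, rots)
    for _ in range(refine_passes if n > 2 else 0):
        template = np.median(out, axis=0)
        mad = float(np.median(np.abs(out - template)))
        moved = False
        for t in range(n):
            d, sc = _phase_shift(template, out[t], upsample)
            scores[t] = max(scores[t], sc)
            # subpixel polish: masked Lucas-Kanade against the template,
            # excluding transient (tracer) pixels and invalid borders
            frame_d = ndimage.shift(out[t], d, order=1, mode="constant", cval=bg) \
                if np.any(np.abs(d) > 1e-6) else out[t]
            w = valid[t] & (np.abs(frame_d - template) < 4.0 * mad + 1e-9)
            d = d + _lk_shift(template, frame_d, w.astype(float), bg)
            if np.any(np.abs(d) > 1e-3):
                moved = True
            shifts[t] += d
        shifts -= shifts[reference_slot]
        out, valid = resample(shifts, rots)
        if not moved:
            break
    result = RegistrationResult(shifts=shifts, rotations=rots, scores=scores,
                                reference_slot=reference_slot)
    registered = FrameStack(
        frames=out,
        frame_indices=stack.frame_indices.copy(),
        fps=stack.fps,
        pixel_size_um=stack.pixel_size_um,
        valid_masks=valid,
    )
    return registered, result


def unshuffle(stack: FrameStack, perm: ShufflePermutation | None = None) -> FrameStack:
    """Restore acquisition order (frames discarded meanwhile are skipped).

    The stack's own acquisition bookkeeping (``frame_indices``) defines the
    order; ``perm`` is accepted for symmetry and validated against it.
    """
    if perm is not None:
        if stack.frame_indices.max(initial=-1) >= len(perm):
            raise ValueError("permutation does not cover the stack's acquisition indices")
    order = np.argsort(stack.frame_indices, kind="stable")
    return stack.take(order)


def project(stack: FrameStack, mode: str = "minima") -> ProjectionImage:
    """Pixelwise minima (lumens) or average (flux) over the stack.

    Invalid pixels (marked by registration) are excluded; a pixel with no
    valid contribution falls back to the all-frame value.
    """
    if len(stack) == 0:
        raise ValueError("cannot project an empty stack")
    frames = stack.frames.astype(float)
    if stack.valid_masks is None:
        counts = np.full(stack.frame_shape, len(stack))
        img = frames.min(axis=0) if mode == "minima" else frames.mean(axis=0)
        return ProjectionImage(image=img, mode=mode, n_frames=counts)
    v = stack.valid_masks
    counts = v.sum(axis=0)
    if mode == "minima":
        img = np.where(v, frames, np.inf).min(axis=0)
        fallback = frames.min(axis=0)
    elif mode == "average":
        with np.errstate(invalid="ignore", divide="ignore"):
            img = np.where(v, frames, 0.0).sum(axis=0) / counts
        fallback = frames.mean(axis=0)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    img = np.where(counts > 0, img, fallback)
    return ProjectionImage(image=img, mode=mode, n_frames=counts)


def flatten_background(
    image: ProjectionImage | np.ndarray,
    radius: float = 40.0,
    vessel_width_hint: float | None = None,
) -> ProjectionImage:
    """Remove slowly varying illumination from a projection.

    The background is estimated by grayscale closing with a disc of the
    given radius (which erases dark features narrower than the disc) and
    subtracted; vessels must be narrower than ``radius`` or they are
    erased along with the illumination.
    """
    if vessel_width_hint is not None and radius <= vessel_width_hint:
        warnings.warn(
            f"background radius {radius} <= vessel width {vessel_width_hint}: "
            "vessels will be flattened away",
            stacklevel=2,
        )
    proj = image if isinstance(image, ProjectionImage) else None
    img = np.asarray(image.image if proj is not None else image, dtype=float)
    r = int(round(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    footprint = (xx**2 + yy**2) <= r**2
    bg = ndimage.grey_closing(img, footprint=footprint, mode="nearest")
    out = img - bg
    return ProjectionImage(
        image=out,
        mode=proj.mode if proj is not None else "minima",
        n_frames=proj.n_frames if proj is not None else 0,
    )
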