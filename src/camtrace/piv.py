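"""Block-matching particle-image velocimetry on registered stacks.

Ensemble PIV: for each interrogation window the mean-subtracted
cross-correlation planes of all consecutive frame pairs are accumulated,
the displacement is the correlation peak with parabolic subpixel
refinement, and the quality is the peak-to-second-peak ratio.  Suited to
quasi-steady flows such as tracer movies after registration and
unshuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FrameStack

__all__ = ["VelocityField", "piv_pass", "median_filter_vectors", "plot_vectors"]


@dataclass
class VelocityField:
    """Displacement vectors on a grid of interrogation-window centres.

    ``u, v`` in px/frame (x and y components); convert to um/s by
    ``u * pixel_size_um * fps``.  ``quality`` is the correlation
    peak-to-second-peak ratio; ``valid`` flags vectors that survived
    outlier filtering (all True after ``piv_pass``).
    """

    x: np.ndarray  # (ny, nx) window-centre x coords
    y: np.ndarray
    u: np.ndarray  # px/frame
    v: np.ndarray
    quality: np.ndarray
    valid: np.ndarray
    window_px: int = 0
    frame_step: int = 1


def _parabolic_peak(plane: np.ndarray, py: int, px: int) -> tuple[float, float]:
    """3-point parabolic refinement of an integer peak location."""
    dy = dx = 0.0
    if 0 < py < plane.shape[0] - 1:
        c, l, r = plane[py, px], plane[py - 1, px], plane[py + 1, px]
        denom = l - 2 * c + r
        if denom != 0:
            dy = 0.5 * (l - r) / denom
    if 0 < px < plane.shape[1] - 1:
        c, l, r = plane[py, px], plane[py, px - 1], plane[py, px + 1]
        denom = l - 2 * c + r
        if denom != 0:
            dx = 0.5 * (l - r) / denom
    return dy, dx


def piv_pass(
    stack: FrameStack,
    window_px: int = 32,
    overlap: float = 0.5,
    frame_step: int = 1,
    search_px: int | None = None,
) -> VelocityField:
    """Single-pass ensemble PIV over all frame pairs ``(t, t + frame_step)``.

    Parameters
    ----------
    window_px : int
        Interrogation window size (>= 8 px, must fit in the frame).
    overlap : float
        Window overlap fraction in [0, 1).
    search_px : int
        Maximum displacement searched (default window_px // 2 - 1).

    Returns px/frame displacements: positive u means motion toward +x
    between a frame and its successor.
    """
    if window_px < 8:
        raise ValueError("interrogation window must be at least 8 px")
    H, W = stack.frame_shape
    if window_px > min(H, W):
        raise ValueError(f"window {window_px} px larger than image {H}x{W}")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if frame_step < 1:
        raise ValueError("frame_step must be >= 1")
    if len(stack) < frame_step + 1:
        raise ValueError("not enough frames for the requested frame_step")
    if search_px is None:
        search_px = window_px // 2 - 1
    search_px = min(search_px, window_px - 1)

    stride = max(int(round(window_px * (1.0 - overlap))), 1)
    x0s = np.arange(0, W - window_px + 1, stride)
    y0s = np.arange(0, H - window_px + 1, stride)
    frames = stack.frames.astype(float)

    nfft = 2 * window_px
    # batch all windows of one frame into a single FFT call
    def windows(img):
        w = np.empty((len(y0s) * len(x0s), window_px, window_px))
        k = 0
        for y0 in y0s:
            for x0 in x0s:
                w[k] = img[y0:y0 + window_px, x0:x0 + window_px]
                k += 1
        w -= w.mean(axis=(1, 2), keepdims=True)
        return w

    acc = np.zeros((len(y0s) * len(x0s), nfft, nfft))
    for t in range(len(stack) - frame_step):
        a = windows(frames[t])
        b = windows(frames[t + frame_step])
        fa = np.fft.rfft2(a, s=(nfft, nfft))
        fb = np.fft.rfft2(b, s=(nfft, nfft))
        acc += np.fft.irfft2(fb * np.conj(fa), s=(nfft, nfft))

    # correlation plane: displacement d appears at index d (mod nfft)
    acc = np.fft.fftshift(acc, axes=(1, 2))
    centre = nfft // 2
    # undo the triangular overlap weighting of finite windows (otherwise
    # peaks are biased toward zero displacement)
    d1 = np.abs(np.arange(nfft) - centre)
    ovl = np.maximum(window_px - d1[:, None], 1) * np.maximum(window_px - d1[None, :], 1)
    acc = acc / ovl
    lo, hi = centre - search_px, centre + search_px + 1
    u = np.empty(len(acc))
    v = np.empty(len(acc))
    q = np.empty(len(acc))
    for k, plane in enumerate(acc):
        sub = plane[lo:hi, lo:hi]
        py, px = np.unravel_index(np.argmax(sub), sub.shape)
        dy, dx = _parabolic_peak(sub, py, px)
        v[k] = py - search_px + dy
        u[k] = px - search_px + dx
        peak = sub[py, px]
        masked = sub.copy()
        masked[max(0, py - 1):py + 2, max(0, px - 1):px + 2] = -np.inf
        second = masked.max()
        q[k] = peak / second if np.isfinite(second) and second > 0 else np.inf

    shape = (len(y0s), len(x0s))
    X, Y = np.meshgrid(x0s + window_px / 2.0, y0s + window_px / 2.0)
    return VelocityField(
        x=X, y=Y,
        u=(u / frame_step).reshape(shape),
        v=(v / frame_step).reshape(shape),
        quality=q.reshape(shape),
        valid=np.ones(shape, dtype=bool),
        window_px=window_px, frame_step=frame_step,
    )


def median_filter_vectors(field: VelocityField, threshold: float = 3.0) -> VelocityField:
    """Flag vectors deviating from their 3x3 neighbourhood median by more
    than ``threshold`` MADs (per component); flagged vectors keep their
    values but ``valid`` is set False."""
    if field.u.size == 0:
        raise ValueError("empty velocity field")
    ny, nx = field.u.shape
    valid = field.valid.copy()
    for comp in (field.u, field.v):
        med = np.empty_like(comp)
        mad = np.empty_like(comp)
        for i in range(ny):
            for j in range(nx):
                sl = comp[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
                med[i, j] = np.median(sl)
                mad[i, j] = np.median(np.abs(sl - med[i, j]))
        dev = np.abs(comp - med)
        floor = 0.1  # px/frame, keeps uniform fields from flagging on noise
        valid &= dev <= threshold * np.maximum(mad, floor)
    return VelocityField(x=field.x, y=field.y, u=field.u, v=field.v,
                         quality=field.quality, valid=valid,
                         window_px=field.window_px, frame_step=field.frame_step)


def plot_vectors(field: VelocityField, background: np.ndarray | None = None,
                 path: str | None = None, scale: float | None = None):
    """Quiver overlay of the valid vectors, optionally on a background
    image (e.g. the average projection); saved to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    if background is not None:
        ax.imshow(background, cmap="gray")
    else:
        ax.invert_yaxis()
    v = field.valid
    ax.quiver(field.x[v], field.y[v], field.u[v], field.v[v],
              angles="xy", color="tab:red", scale=scale, width=0.004)
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
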