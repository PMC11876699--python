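"""Rigid drift estimation and correction by frame-to-frame cross-correlation.

Stage drift in time-lapse acquisitions is estimated on a single channel by
locating the peak of the cross-correlation between successive frames and
refined to subpixel precision by quadratic interpolation of the peak and
its neighbours; the cumulative track (relative to frame 0) is then applied,
negated, to all channels.  Frames are mean-subtracted and edge-tapered with
a Hann window before correlation to suppress wraparound artefacts of the
FFT-based correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["DriftTrack", "estimate_drift", "correct_drift"]


@dataclass
class DriftTrack:
    """Cumulative per-frame displacement (dx, dy) in pixels.

    The displacement of the reference frame (index 0) is (0, 0).  ``dx``
    is along the last image axis, ``dy`` along the first.
    """

    shifts: np.ndarray  # (n_frames, 2) -> columns (dx, dy)
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must have shape (n_frames, 2)")
        if not np.allclose(self.shifts[self.reference_frame], 0.0):
            raise ValueError("displacement of the reference frame must be (0, 0)")

    def __len__(self) -> int:
        return self.shifts.shape[0]

    def per_frame(self) -> np.ndarray:
        """Frame-to-frame increments (first row is zero)."""
        return np.diff(self.shifts, axis=0, prepend=self.shifts[:1])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"frame": np.arange(len(self)), "dx": self.shifts[:, 0], "dy": self.shifts[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DriftTrack":
        df = pd.read_csv(path)
        return cls(shifts=df[["dx", "dy"]].to_numpy())


def _hann2d(shape: tuple) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _quadratic_peak_offset(c: np.ndarray, peak: tuple) -> np.ndarray:
    """Subpixel offset of a correlation peak from a 3-point parabola per axis."""
    py, px = peak
    out = np.zeros(2)
    for axis, p in ((0, py), (1, px)):
        if p == 0 or p == c.shape[axis] - 1:
            continue
        idx = [slice(None)] * 2
        idx[axis] = slice(p - 1, p + 2)
        other = [py, px]
        other[axis] = slice(p - 1, p + 2)
        tri = c[tuple(other)]
        denom = tri[0] - 2.0 * tri[1] + tri[2]
        if denom != 0:
            out[axis] = 0.5 * (tri[0] - tri[2]) / denom
    return out


def _correlation(a: np.ndarray, b: np.ndarray, window: np.ndarray) -> np.ndarray:
    a = (a - a.mean()) * window
    b = (b - b.mean()) * window
    corr = np.fft.irfft2(np.conj(np.fft.rfft2(a)) * np.fft.rfft2(b), s=a.shape)
    return np.fft.fftshift(corr)


def _pair_shift(ref: np.ndarray, moving: np.ndarray, window: np.ndarray,
                max_shift: float | None) -> np.ndarray:
    """Shift (dy, dx) such that ``moving`` ~= ``ref`` translated by it.

    Two stages: the integer shift from the tapered FFT cross-correlation
    peak, then quadratic interpolation of the correlation of the
    integer-aligned pair.  Refining after alignment keeps the peak
    symmetric under the taper, so integer drifts are recovered exactly.
    """
    for name, frame in (("reference", ref), ("moving", moving)):
        if np.ptp(frame) == 0:
            raise ValueError(
                f"{name} frame has zero variance; shift is undefined on flat frames"
            )
    corr = _correlation(ref, moving, window)
    center = np.array([s // 2 for s in corr.shape])
    if max_shift is not None:
        mask = np.ones_like(corr, dtype=bool)
        m = int(np.ceil(max_shift))
        ylo, yhi = center[0] - m, center[0] + m + 1
        xlo, xhi = center[1] - m, center[1] + m + 1
        mask[max(ylo, 0):yhi, max(xlo, 0):xhi] = False
        corr = np.where(mask, -np.inf, corr)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    integer = np.asarray(peak, dtype=int) - center

    aligned = np.roll(moving, shift=tuple(-integer), axis=(0, 1))
    corr2 = _correlation(ref, aligned, window)
    peak2 = np.unravel_index(np.argmax(corr2), corr2.shape)
    if np.any(np.abs(np.asarray(peak2) - center) > 1):
        peak2 = tuple(center)  # refinement stays local to the aligned peak
    offset = np.asarray(peak2, dtype=float) - center + _quadratic_peak_offset(corr2, peak2)
    return integer + offset


def estimate_drift(
    movie,
    channel: str | None = None,
    max_shift: float | None = None,
    reference_frame: int = 0,
    presmooth_sigma: float = 1.0,
) -> DriftTrack:
    """Estimate cumulative rigid drift from successive-frame correlations.

    ``movie`` is a (frames, y, x) array or a dict of channel label to such
    an array, in which case ``channel`` selects the one to measure on.
    ``max_shift`` caps the per-frame search radius (pixels).
    ``presmooth_sigma`` lightly low-passes the frames before correlation;
    detection noise otherwise random-walks into the cumulative track.
    """
    if isinstance(movie, dict):
        if channel is None or channel not in movie:
            raise ValueError(f"channel {channel!r} not present in movie")
        frames = np.asarray(movie[channel], dtype=float)
    else:
        frames = np.asarray(movie, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("movie must have >= 2 frames of identical shape")
    if presmooth_sigma > 0:
        frames = ndimage.gaussian_filter1d(
            ndimage.gaussian_filter1d(frames, presmooth_sigma, axis=1),
            presmooth_sigma,
            axis=2,
        )
    window = _hann2d(frames.shape[1:])
    increments = np.zeros((frames.shape[0], 2))
    for i in range(1, frames.shape[0]):
        dy, dx = _pair_shift(frames[i - 1], frames[i], window, max_shift)
        increments[i] = (dx, dy)
    cumulative = np.cumsum(increments, axis=0)
    cumulative -= cumulative[reference_frame]
    return DriftTrack(shifts=cumulative, reference_frame=reference_frame)


def correct_drift(movie, track: DriftTrack, fill: float | None = None):
    """Undo the drift in ``track`` on every channel of ``movie``.

    Each frame is translated by the negated cumulative shift with bilinear
    interpolation; uncovered edges are filled with the frame's median (a
    robust background estimate) unless ``fill`` is given.  The track length
    must match the frame count.
    """
    def _correct(frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames, dtype=float)
        if frames.shape[0] != len(track):
            raise ValueError(
                f"track length {len(track)} does not match frame count {frames.shape[0]}"
            )
        out = np.empty_like(frames)
        for i, frame in enumerate(frames):
            dx, dy = track.shifts[i]
            cval = float(np.median(frame)) if fill is None else fill
            if dx == 0 and dy == 0:
                out[i] = frame
            else:
                out[i] = ndimage.shift(frame, (-dy, -dx), order=1, mode="constant", cval=cval)
        return out

    if isinstance(movie, dict):
        return {label: _correct(frames) for label, frames in movie.items()}
    return _correct(movie)
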