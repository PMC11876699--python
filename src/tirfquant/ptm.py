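"""Per-microtubule linescan quantification of antibody (PTM) signal.

The polyglutamylation assay snapshots two channels per field of view
(FOV): a seed channel (stabilized, labelled microtubule seeds) and an
antibody channel reporting the PTM of interest along the polymerized
lattice.  Quantification follows the scheme:

* a 2-pixel-wide linescan along each traced microtubule, averaged
  perpendicular to the local tangent;
* background subtraction using the linescan edges beyond the microtubule
  ends (the trace must extend past both ends into empty background);
* the per-microtubule background-subtracted means are averaged over the
  FOV and normalized against the FOV-average seed-channel intensity,
  measured the same way on the seed segments:

      normalized = 100 * mean_MT(antibody) / mean_seed(seed channel).

The factor 100 is a reporting convention that places typical values on a
convenient 1-100 scale; every comparison between conditions is a ratio, so
the constant is neutral.  Microtubules whose linescan edges are not
signal-free are excluded from the FOV average and enumerated with reasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import FOVImage

__all__ = [
    "LinescanProfile",
    "MTMeasurement",
    "FOVQuantification",
    "linescan_profile",
    "subtract_background",
    "fov_normalized_intensity",
    "per_seed_total_signal",
    "extend_polyline",
]


@dataclass
class LinescanProfile:
    """Sampled intensities along a polyline, averaged across its width."""

    polyline: np.ndarray  # (n_vertices, 2) of (x, y) pixel coordinates
    width: int
    step_px: float
    distances_px: np.ndarray  # arclength of each sample
    samples: dict  # channel label -> (n_samples,) mean intensity


@dataclass
class MTMeasurement:
    """Background-subtracted mean intensity of one microtubule."""

    value: float
    background: float
    span: tuple  # (first, last) sample indices of the on-microtubule region
    excluded: bool = False
    reason: str = ""


@dataclass
class FOVQuantification:
    """FOV-level summary of the normalized antibody intensity."""

    normalized: float
    mean_mt: float
    mean_seed: float
    mt_values: np.ndarray
    per_mt_normalized: np.ndarray
    seed_values: np.ndarray
    n_microtubules: int
    n_seeds: int
    excluded: list = field(default_factory=list)  # (index, reason) pairs

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def extend_polyline(polyline: np.ndarray, pad_px: float) -> np.ndarray:
    """Extend a polyline beyond both end vertices along the end tangents."""
    p = np.asarray(polyline, dtype=float)
    if p.shape[0] < 2:
        raise ValueError("polyline needs at least 2 vertices")
    u0 = p[0] - p[1]
    u0 = u0 / np.hypot(*u0)
    u1 = p[-1] - p[-2]
    u1 = u1 / np.hypot(*u1)
    return np.vstack([p[0] + pad_px * u0, p, p[-1] + pad_px * u1])


def _resample(polyline: np.ndarray, step_px: float):
    """Equally spaced samples along the polyline with unit tangents."""
    p = np.asarray(polyline, dtype=float)
    seg = np.diff(p, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ValueError("polyline has coincident consecutive vertices")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    dists = np.arange(0.0, total + 0.5 * step_px, step_px)
    dists = np.clip(dists, 0.0, total)
    idx = np.clip(np.searchsorted(cum, dists, side="right") - 1, 0, len(seg) - 1)
    frac = (dists - cum[idx]) / seg_len[idx]
    points = p[idx] + frac[:, None] * seg[idx]
    tangents = seg[idx] / seg_len[idx, None]
    return dists, points, tangents


def linescan_profile(
    image,
    polyline,
    width: int = 2,
    step_px: float = 0.5,
    prefiltered: bool = False,
) -> LinescanProfile:
    """Sample channels along a polyline, averaging over ``width`` pixels
    perpendicular to the local tangent.

    Perpendicular offsets are ``j - (width - 1) / 2`` pixels, so a width-2
    scan averages two lines 1 px apart straddling the polyline.  Sampling
    is cubic-spline interpolation.  ``image`` is a :class:`FOVImage` or a
    dict of 2-D channel arrays.  A polyline vertex outside the image is
    rejected with its index.  ``prefiltered=True`` declares that the
    channel arrays are already cubic-spline coefficient images
    (``scipy.ndimage.spline_filter``), which avoids refiltering when many
    linescans sample the same field.
    """
    channels = image.channels if isinstance(image, FOVImage) else dict(image)
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    shape = next(iter(channels.values())).shape
    p = np.asarray(polyline, dtype=float)
    for i, (x, y) in enumerate(p):
        if not (0 <= x <= shape[1] - 1 and 0 <= y <= shape[0] - 1):
            raise ValueError(f"polyline vertex {i} at ({x:.1f}, {y:.1f}) exits the image")

    dists, points, tangents = _resample(p, step_px)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    offsets = np.arange(width) - (width - 1) / 2.0
    # (width, n_samples, 2) sample coordinates
    coords = points[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    yx = np.stack([coords[..., 1], coords[..., 0]])  # map_coordinates axis order

    samples = {}
    for label, img in channels.items():
        vals = ndimage.map_coordinates(
            np.asarray(img, dtype=float),
            yx.reshape(2, -1),
            order=3,
            mode="nearest",
            prefilter=not prefiltered,
        ).reshape(width, -1)
        samples[label] = vals.mean(axis=0)
    return LinescanProfile(
        polyline=p, width=width, step_px=step_px, distances_px=dists, samples=samples
    )


def subtract_background(
    profile: LinescanProfile,
    channel: str,
    edge_len: int = 5,
    span: tuple | None = None,
    margin_samples: int = 6,
) -> MTMeasurement:
    """Per-microtubule mean minus the linescan-edge background.

    The background is the mean of the outermost ``edge_len`` samples at
    both ends of the linescan, which must lie beyond the microtubule.  The
    on-microtubule span is either given (sample indices) or located as the
    half-maximum extent of the background-subtracted profile, shrunk by
    ``margin_samples`` on each side to stay clear of the PSF roll-off at
    the ends.  A profile whose edges are not signal-free (edge mean above
    the on-span mean) is flagged excluded, not silently averaged.
    """
    vals = profile.samples[channel]
    n = vals.size
    if n < 2 * edge_len + 3:
        raise ValueError("linescan too short for the requested edge length")
    lead, trail = vals[:edge_len], vals[-edge_len:]
    bg = float(np.mean(np.concatenate([lead, trail])))
    # the quieter edge estimates the detection noise; a contaminated edge
    # inflates its own spread and must not mask itself
    noise_sd = float(min(np.std(lead), np.std(trail)))
    net = vals - bg
    if span is None:
        peak = net.max()
        if peak <= 0:
            return MTMeasurement(
                value=0.0, background=bg, span=(0, 0), excluded=True,
                reason="no signal above background on the linescan",
            )
        above = np.nonzero(net >= 0.5 * peak)[0]
        i0, i1 = int(above[0]) + margin_samples, int(above[-1]) - margin_samples
        if i1 <= i0:
            mid = int(np.mean(above))
            i0, i1 = mid, mid + 1
    else:
        i0, i1 = int(span[0]), int(span[1])
        if not (0 <= i0 < i1 <= n):
            raise ValueError(f"span {span} outside the profile of {n} samples")
    value = float(np.mean(net[i0:i1]))
    # edges clearly brighter than the on-MT span -> contaminated background
    sem = noise_sd * np.sqrt(1.0 / max(i1 - i0, 1) + 1.0 / (2.0 * edge_len))
    if value < -4.0 * sem - 1e-12:
        return MTMeasurement(
            value=value, background=bg, span=(i0, i1), excluded=True,
            reason="linescan edges brighter than the microtubule span",
        )
    return MTMeasurement(value=value, background=bg, span=(i0, i1))


def fov_normalized_intensity(
    fov: FOVImage,
    traces,
    seed_traces,
    antibody_channel: str = "antibody",
    seed_channel: str = "seed",
    width: int = 2,
    edge_len: int = 5,
    trace_pad_px: float = 10.0,
    seed_pad_px: float = 10.0,
    step_px: float = 0.5,
    margin_samples: int = 6,
) -> FOVQuantification:
    """FOV-averaged, seed-normalized antibody intensity.

    ``traces`` and ``seed_traces`` are lists of polylines (px coordinates)
    spanning exactly the microtubules and the seed segments.  Traces are
    extended by ``trace_pad_px`` beyond both ends so the linescan edges
    sample empty background, and the on-structure span is derived from the
    known padding (shrunk by ``margin_samples`` to stay clear of the PSF
    roll-off at the ends).  The FOV average runs over per-microtubule
    values first, then conditions average over FOV means, so the FOV is
    the statistical unit throughout.
    """
    if len(traces) < 1 or len(seed_traces) < 1:
        raise ValueError("need at least one microtubule trace and one seed per FOV")

    filtered = {
        label: ndimage.spline_filter(np.asarray(img, dtype=float), order=3, mode="nearest")
        for label, img in fov.channels.items()
    }

    def _measure(poly, pad, channel):
        prof = linescan_profile(
            filtered, extend_polyline(poly, pad), width=width, step_px=step_px,
            prefiltered=True,
        )
        n = prof.samples[channel].size
        pad_samples = int(round(pad / step_px))
        i0 = pad_samples + margin_samples
        i1 = n - pad_samples - margin_samples
        if i1 <= i0:
            i0, i1 = n // 2, n // 2 + 1
        return subtract_background(prof, channel, edge_len=edge_len, span=(i0, i1))

    mt_values, excluded = [], []
    for i, poly in enumerate(traces):
        m = _measure(poly, trace_pad_px, antibody_channel)
        if m.excluded:
            excluded.append((i, m.reason))
        else:
            mt_values.append(m.value)
    if not mt_values:
        raise ValueError("every microtubule in the FOV was excluded")

    seed_values = []
    for poly in seed_traces:
        m = _measure(poly, seed_pad_px, seed_channel)
        if not m.excluded:
            seed_values.append(m.value)
    if not seed_values:
        raise ValueError("no usable seed measurement in the FOV")

    mt_values = np.asarray(mt_values)
    seed_values = np.asarray(seed_values)
    mean_seed = float(seed_values.mean())
    if mean_seed <= 1e-6:  # counts; anything below is numerically zero
        raise ValueError("FOV seed-channel mean is not positive; cannot normalize")
    mean_mt = float(mt_values.mean())
    return FOVQuantification(
        normalized=100.0 * mean_mt / mean_seed,
        mean_mt=mean_mt,
        mean_seed=mean_seed,
        mt_values=mt_values,
        per_mt_normalized=100.0 * mt_values / mean_seed,
        seed_values=seed_values,
        n_microtubules=int(mt_values.size),
        n_seeds=int(seed_values.size),
        excluded=excluded,
    )


def per_seed_total_signal(
    fov: FOVImage,
    seed_count: int,
    background_region: tuple | None,
    channel: str = "antibody",
) -> float:
    """Total background-subtracted channel signal divided by the seed count.

    The background estimate is the mean of a user-supplied signal-free
    region (a ``(row_slice, col_slice)`` pair) times the total pixel
    count.  There is no default region: pass one explicitly.
    """
    if seed_count < 1:
        raise ValueError(f"seed_count must be >= 1, got {seed_count}")
    if background_region is None:
        raise ValueError(
            "no signal-free region given; supply background_region=(row_slice, col_slice)"
        )
    img = np.asarray(fov.channels[channel], dtype=float)
    region = img[background_region]
    if region.size == 0:
        raise ValueError("background region is empty")
    total = img.sum() - float(region.mean()) * img.size
    return float(total / seed_count)
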