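"""Synthetic-data generator with known ground truth for every assay.

This module emulates the quantified in-vitro experiments end to end:

* **Dynamics**: straight microtubules elongate from stabilized seeds at a
  constant mean speed per end (fast plus end, slow minus end); the time
  from growth onset to catastrophe is gamma distributed; after catastrophe
  the extension collapses back to the seed (instantaneously by default)
  and regrows after a short delay.
* **Kymographs**: space-time renderings of a single microtubule with a
  Gaussian point-spread function, constant background and detection noise.
* **Fields of view**: multichannel snapshots of many microtubules (bright
  seed segments plus an antibody channel proportional to a per-microtubule
  ground-truth density), used to validate the polyglutamylation linescan
  pipeline.
* **Drift**: rigid per-frame translation of a movie (fixture for the
  registration module).
* **Titrations**: two-fold dilution series following the quadratic 1:1
  depletion isotherm with additive Gaussian noise.

Everything is deterministic given an integer seed; a single
`numpy.random.Generator` per call, seed recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .binding import Titration, fraction_bound
from .images import FOVImage, ImagingParams, Kymograph

__all__ = [
    "DynamicsParams",
    "EventTable",
    "MicrotubuleSpec",
    "FOVLayout",
    "TitrationDesign",
    "DEFAULT_LIFETIME_SCALE_S",
    "scale_for_median",
    "simulate_dynamics",
    "render_kymograph",
    "render_fov_image",
    "make_fov_layout",
    "expected_linescan_mean",
    "density_for_linescan_mean",
    "apply_drift",
    "simulate_titration",
]


def scale_for_median(median_s: float, shape: float) -> float:
    """Gamma scale whose distribution has the requested median at a given shape."""
    if median_s <= 0 or shape <= 0:
        raise ValueError("median and shape must be > 0")
    return float(median_s / special.gammaincinv(shape, 0.5))


#: scale of the default lifetime law: shape 3 with median equal to the
#: buffer-control lifetime estimate (202.61 s)
DEFAULT_LIFETIME_SCALE_S = scale_for_median(202.61, 3.0)


@dataclass(frozen=True)
class DynamicsParams:
    """Ground-truth dynamic-instability parameters.

    Speeds are in µm/min.  Defaults are the buffer-control condition of the
    plus/minus-end growth assays: mean plus-end speed 1.002 µm/min,
    minus-end 0.348 µm/min, per-event speed CV 0.16 (matching the observed
    event-to-event dispersion), and a gamma lifetime law of shape 3 whose
    median equals the control lifetime estimate.  ``shrink_speed_um_min=None``
    means instantaneous collapse to the seed after catastrophe.
    """

    v_plus_um_min: float = 1.002
    v_minus_um_min: float = 0.348
    shrink_speed_um_min: float | None = None
    lifetime_shape: float = 3.0
    lifetime_scale_s: float = DEFAULT_LIFETIME_SCALE_S
    regrow_delay_s: float = 10.0
    speed_cv: float = 0.16

    def __post_init__(self) -> None:
        for name in ("v_plus_um_min", "v_minus_um_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.shrink_speed_um_min is not None and not self.shrink_speed_um_min > 0:
            raise ValueError(
                f"shrink_speed_um_min must be > 0 or None, got {self.shrink_speed_um_min}"
            )
        if not self.lifetime_shape > 0:
            raise ValueError(f"lifetime_shape must be > 0, got {self.lifetime_shape}")
        if not self.lifetime_scale_s > 0:
            raise ValueError(f"lifetime_scale_s must be > 0, got {self.lifetime_scale_s}")
        if self.regrow_delay_s < 0:
            raise ValueError(f"regrow_delay_s must be >= 0, got {self.regrow_delay_s}")
        if self.speed_cv < 0:
            raise ValueError(f"speed_cv must be >= 0, got {self.speed_cv}")

    def speed(self, end: str) -> float:
        return self.v_plus_um_min if end == "plus" else self.v_minus_um_min

    @classmethod
    def control(cls) -> "DynamicsParams":
        return cls()

    @classmethod
    def elongator(cls) -> "DynamicsParams":
        """Reconstituted Elp123 + 2x Elp456 condition (plus 1.380,
        minus 0.472 µm/min)."""
        return cls(v_plus_um_min=1.380, v_minus_um_min=0.472)


@dataclass
class EventTable:
    """Per-microtubule growth events with generator metadata.

    ``events`` columns: mt_id, end ('plus'/'minus'), onset_time_s,
    catastrophe_time_s (NaN when censored), censored (bool),
    speed_um_min.  A censored event is one still growing at movie end.
    """

    events: pd.DataFrame
    duration_s: float
    seed_length_um: float
    params: DynamicsParams
    rng_seed: int

    COLUMNS = ("mt_id", "end", "onset_time_s", "catastrophe_time_s", "censored", "speed_um_min")

    def for_mt(self, mt_id: int) -> pd.DataFrame:
        sub = self.events[self.events["mt_id"] == mt_id]
        if sub.empty:
            raise KeyError(f"mt_id {mt_id} not found in event table")
        return sub

    def mt_ids(self) -> np.ndarray:
        return self.events["mt_id"].unique()

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


def simulate_dynamics(
    params: DynamicsParams,
    n_seeds: int,
    duration_s: float,
    rng_seed: int,
    seed_length_um: float = 3.0,
) -> EventTable:
    """Draw alternating growth events for both ends of ``n_seeds`` seeds.

    Per end: growth starts at t=0, the lifetime is a gamma(shape, scale)
    draw, the event speed is the configured mean for that end perturbed by
    the per-event CV (clipped at 10% of the mean to stay positive), and
    after catastrophe (plus optional shrink time) the end pauses for
    ``regrow_delay_s`` before nucleating the next event.  Events still
    growing at ``duration_s`` are flagged censored.  Deterministic given
    ``rng_seed``.
    """
    if not duration_s > 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be >= 1, got {n_seeds}")
    if not seed_length_um > 0:
        raise ValueError(f"seed_length_um must be > 0, got {seed_length_um}")

    rng = np.random.default_rng(rng_seed)
    rows = []
    for mt_id in range(n_seeds):
        for end in ("plus", "minus"):
            v_mean = params.speed(end)
            t = 0.0
            while t < duration_s:
                onset = t
                lifetime = rng.gamma(params.lifetime_shape, params.lifetime_scale_s)
                speed = v_mean * (1.0 + params.speed_cv * rng.standard_normal())
                speed = max(speed, 0.1 * v_mean)
                cat = onset + lifetime
                if cat >= duration_s:
                    rows.append((mt_id, end, onset, np.nan, True, speed))
                    break
                rows.append((mt_id, end, onset, cat, False, speed))
                t = cat
                if params.shrink_speed_um_min is not None:
                    length_um = speed * lifetime / 60.0
                    t += 60.0 * length_um / params.shrink_speed_um_min
                t += params.regrow_delay_s

    df = pd.DataFrame(rows, columns=list(EventTable.COLUMNS))
    return EventTable(
        events=df,
        duration_s=float(duration_s),
        seed_length_um=float(seed_length_um),
        params=params,
        rng_seed=int(rng_seed),
    )


def _tip_extension_um(sub: pd.DataFrame, params: DynamicsParams, times_s: np.ndarray,
                      duration_s: float) -> np.ndarray:
    """Extension beyond the seed edge (µm) at each frame for one end."""
    ext = np.zeros_like(times_s)
    for row in sub.itertuples(index=False):
        v_um_s = row.speed_um_min / 60.0
        cat = duration_s if row.censored else row.catastrophe_time_s
        growing = (times_s >= row.onset_time_s) & (times_s < cat)
        ext[growing] = v_um_s * (times_s[growing] - row.onset_time_s)
        if not row.censored and params.shrink_speed_um_min is not None:
            len_cat = v_um_s * (cat - row.onset_time_s)
            shrink_um_s = params.shrink_speed_um_min / 60.0
            t_end = cat + len_cat / shrink_um_s
            shrinking = (times_s >= cat) & (times_s < t_end)
            ext[shrinking] = len_cat - shrink_um_s * (times_s[shrinking] - cat)
    return np.clip(ext, 0.0, None)


def _coverage(left_um: np.ndarray, right_um: np.ndarray, n_px: int,
              pixel_size_um: float) -> np.ndarray:
    """Fractional pixel coverage of the interval [left, right] per frame.

    Pixel ``i`` spans ``[(i - 0.5) * ps, (i + 0.5) * ps)``.
    """
    edges_l = (np.arange(n_px) - 0.5) * pixel_size_um
    edges_r = edges_l + pixel_size_um
    lo = np.maximum(left_um[:, None], edges_l[None, :])
    hi = np.minimum(right_um[:, None], edges_r[None, :])
    return np.clip((hi - lo) / pixel_size_um, 0.0, 1.0)


def render_kymograph(
    events: EventTable,
    imaging: ImagingParams,
    mt_id: int,
    margin_um: float = 2.0,
    rng_seed: int = 0,
) -> Kymograph:
    """Render the space-time image of one microtubule from its events.

    The seed sits at a fixed interval on the spatial axis; the tubulin
    channel covers the contiguous polymer (minus tip to plus tip, seed
    included), the seed channel only the seed segment.  Pixel-integrated
    occupancy is convolved with a 1-D Gaussian PSF, scaled by the channel
    gain, offset by the background and corrupted by the noise model.  The
    per-frame ground-truth tip positions are returned in ``truth``.
    """
    sub = events.for_mt(mt_id)
    ps = imaging.pixel_size_um
    dt = imaging.frame_interval_s
    times = np.arange(int(round(events.duration_s / dt))) * dt

    ext_plus = _tip_extension_um(sub[sub["end"] == "plus"], events.params, times,
                                 events.duration_s)
    ext_minus = _tip_extension_um(sub[sub["end"] == "minus"], events.params, times,
                                  events.duration_s)

    s0 = margin_um + ext_minus.max()
    s1 = s0 + events.seed_length_um
    width_um = s1 + ext_plus.max() + margin_um
    n_px = int(np.ceil(width_um / ps)) + 1

    minus_tip = s0 - ext_minus
    plus_tip = s1 + ext_plus

    rng = np.random.default_rng(rng_seed)
    channels = {}
    for label, (left, right) in (
        ("seed", (np.full_like(times, s0), np.full_like(times, s1))),
        ("tubulin", (minus_tip, plus_tip)),
    ):
        cov = _coverage(left, right, n_px, ps)
        if imaging.psf_sigma_px > 0:
            cov = ndimage.gaussian_filter1d(cov, imaging.psf_sigma_px, axis=1)
        img = imaging.background + imaging.channel_gains.get(label, 0.0) * cov
        channels[label] = imaging.noise.apply(img, rng)

    return Kymograph(
        channels=channels,
        pixel_size_um=ps,
        frame_interval_s=dt,
        seed_extent_px=(s0 / ps, s1 / ps),
        mt_id=int(mt_id),
        truth={
            "plus_tip_um": plus_tip,
            "minus_tip_um": minus_tip,
            "seed_extent_um": (s0, s1),
            "events": sub.reset_index(drop=True),
            "rng_seed": int(rng_seed),
        },
    )


# --------------------------------------------------------------------------
# Fields of view


@dataclass(frozen=True)
class MicrotubuleSpec:
    """Geometry and ground-truth densities of one microtubule in a FOV.

    ``anchor_px`` is the seed center (x, y) in pixel coordinates; lengths
    are in µm; densities are counts per µm of polymer before PSF and
    channel gain.
    """

    anchor_px: tuple
    angle_rad: float
    seed_length_um: float
    plus_length_um: float
    minus_length_um: float
    antibody_density: float
    seed_density: float

    def __post_init__(self) -> None:
        if self.antibody_density < 0 or self.seed_density < 0:
            raise ValueError("densities must be >= 0")
        if min(self.seed_length_um, self.plus_length_um, self.minus_length_um) < 0:
            raise ValueError("lengths must be >= 0")

    def _endpoints_px(self, pixel_size_um: float):
        u = np.array([np.cos(self.angle_rad), np.sin(self.angle_rad)])
        a = np.asarray(self.anchor_px, dtype=float)
        half_seed = 0.5 * self.seed_length_um / pixel_size_um
        seed0 = a - half_seed * u
        seed1 = a + half_seed * u
        mt0 = seed0 - (self.minus_length_um / pixel_size_um) * u
        mt1 = seed1 + (self.plus_length_um / pixel_size_um) * u
        return mt0, mt1, seed0, seed1


@dataclass
class FOVLayout:
    """Image shape plus the microtubules it contains."""

    shape: tuple  # (ny, nx)
    mts: list

    def __post_init__(self) -> None:
        ny, nx = self.shape
        for i, mt in enumerate(self.mts):
            x, y = mt.anchor_px
            if not (0 <= x < nx and 0 <= y < ny):
                raise ValueError(f"seed anchor of microtubule {i} lies outside the image")


def _add_gaussian_segment(img: np.ndarray, p0, p1, amplitude: float, sigma: float) -> None:
    """Add the exact image of a uniform line segment under a Gaussian PSF.

    ``amplitude`` is counts per pixel of segment length; the rendered value
    at a point is amplitude * N(d_perp; sigma) * cap-factor, the analytic
    integral of a 2-D Gaussian along the segment.  Operates in place on a
    bounding box padded by 5 sigma.
    """
    if amplitude == 0:
        return
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = np.hypot(*(p1 - p0))
    if length == 0:
        return
    u = (p1 - p0) / length
    pad = 5.0 * sigma + 1.0
    ny, nx = img.shape
    x_lo = int(max(0, np.floor(min(p0[0], p1[0]) - pad)))
    x_hi = int(min(nx, np.ceil(max(p0[0], p1[0]) + pad) + 1))
    y_lo = int(max(0, np.floor(min(p0[1], p1[1]) - pad)))
    y_hi = int(min(ny, np.ceil(max(p0[1], p1[1]) + pad) + 1))
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    xs = np.arange(x_lo, x_hi)
    ys = np.arange(y_lo, y_hi)
    xx, yy = np.meshgrid(xs, ys)
    dx = xx - p0[0]
    dy = yy - p0[1]
    t = dx * u[0] + dy * u[1]
    d = dx * -u[1] + dy * u[0]
    s2 = sigma * np.sqrt(2.0)
    profile = (
        amplitude
        / (np.sqrt(2.0 * np.pi) * sigma)
        * np.exp(-0.5 * (d / sigma) ** 2)
        * 0.5
        * (special.erf((length - t) / s2) - special.erf(-t / s2))
    )
    img[y_lo:y_hi, x_lo:x_hi] += profile


def expected_linescan_mean(density: float, imaging: ImagingParams, channel: str,
                           width: int = 2) -> float:
    """Expected background-subtracted linescan value on an isolated straight
    microtubule of the given density, for a width-``width`` axial linescan.

    The linescan averages samples at perpendicular offsets
    ``j - (width - 1) / 2`` (pixels); each sample sees the Gaussian ridge
    amplitude at that offset.
    """
    lam = density * imaging.pixel_size_um * imaging.channel_gains.get(channel, 0.0)
    sigma = imaging.psf_sigma_px
    if sigma == 0:
        raise ValueError("expected_linescan_mean requires psf_sigma_px > 0")
    offsets = np.arange(width) - (width - 1) / 2.0
    return float(
        lam / (np.sqrt(2.0 * np.pi) * sigma)
        * np.mean(np.exp(-0.5 * (offsets / sigma) ** 2))
    )


def density_for_linescan_mean(target: float, imaging: ImagingParams, channel: str,
                              width: int = 2) -> float:
    """Inverse of :func:`expected_linescan_mean`: density giving a target value."""
    unit = expected_linescan_mean(1.0, imaging, channel, width=width)
    return float(target / unit)


def make_fov_layout(
    n_mts: int,
    imaging: ImagingParams,
    rng: np.random.Generator,
    antibody_density_mean: float,
    seed_density: float,
    shape: tuple = (540, 540),
    density_cv: float = 0.3,
    seed_density_cv: float = 0.06,
    max_angle_deg: float = 3.0,
) -> FOVLayout:
    """Place ``n_mts`` non-crossing microtubules on a jittered grid.

    Grid placement with small random orientations emulates a flow-aligned
    field while guaranteeing that linescans and their background edges are
    uncontaminated by neighbours.  Per-microtubule antibody densities are
    gamma-distributed around the calibrated mean (CV ``density_cv``); seed
    densities are nearly constant, matching the homogeneity of seed
    brightness across fields.
    """
    ny, nx = shape
    n_cols = 3
    n_rows = int(np.ceil(n_mts / n_cols))
    border = 18.0  # px; keeps traces plus their background pads inside
    cell_w = (nx - 2 * border) / n_cols
    cell_h = (ny - 2 * border) / n_rows
    mts = []
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)][:n_mts]
    for r, c in cells:
        seed_len = rng.uniform(2.0, 4.0)
        plus_len = rng.uniform(3.0, 6.0)
        minus_len = rng.uniform(1.0, 3.0)
        cx = border + (c + 0.5) * cell_w + rng.uniform(-8.0, 8.0)
        cy = border + (r + 0.5) * cell_h + rng.uniform(-2.0, 2.0)
        angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
        # half-extents of the full polymer around the seed center, px
        ext_plus = (0.5 * seed_len + plus_len) / imaging.pixel_size_um
        ext_minus = (0.5 * seed_len + minus_len) / imaging.pixel_size_um
        ux, uy = abs(np.cos(angle)), abs(np.sin(angle))
        ext_x = max(ext_plus, ext_minus) * ux
        ext_y = max(ext_plus, ext_minus) * uy
        cx = float(np.clip(cx, border + ext_x, nx - 1 - border - ext_x))
        cy = float(np.clip(cy, border + ext_y, ny - 1 - border - ext_y))
        dens_ab = rng.gamma(1.0 / density_cv**2, antibody_density_mean * density_cv**2) \
            if density_cv > 0 else antibody_density_mean
        dens_seed = seed_density * (1.0 + seed_density_cv * rng.standard_normal())
        mts.append(
            MicrotubuleSpec(
                anchor_px=(cx, cy),
                angle_rad=angle,
                seed_length_um=seed_len,
                plus_length_um=plus_len,
                minus_length_um=minus_len,
                antibody_density=float(dens_ab),
                seed_density=float(max(dens_seed, 0.0)),
            )
        )
    return FOVLayout(shape=shape, mts=mts)


def _segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2-D segments."""
    from itertools import product

    def point_seg(p, q0, q1):
        v = q1 - q0
        vv = v @ v
        t = 0.0 if vv == 0 else np.clip((p - q0) @ v / vv, 0.0, 1.0)
        return np.hypot(*(p - (q0 + t * v)))

    return min(
        point_seg(p, q0, q1)
        for p, (q0, q1) in product((a0, a1, b0, b1), ((a0, a1), (b0, b1)))
        if not (p is q0 or p is q1)
    )


def render_fov_image(layout: FOVLayout, imaging: ImagingParams, rng_seed: int = 0) -> FOVImage:
    """Render seed and antibody channels of a FOV with ground truth.

    The antibody channel carries each microtubule's ground-truth density
    along its whole polyline; the seed channel only the seed segment.
    Rendering uses the analytic Gaussian line integral (exact pixel sums).
    Microtubule pairs closer than 4 PSF sigma anywhere are flagged as
    overlapping in the returned ground truth.
    """
    rng = np.random.default_rng(rng_seed)
    ny, nx = layout.shape
    ps = imaging.pixel_size_um
    sigma = imaging.psf_sigma_px
    seed_img = np.zeros((ny, nx))
    ab_img = np.zeros((ny, nx))
    mt_polylines, seed_polylines = [], []
    for mt in layout.mts:
        mt0, mt1, seed0, seed1 = mt._endpoints_px(ps)
        lam_ab = mt.antibody_density * ps * imaging.channel_gains.get("antibody", 0.0)
        lam_seed = mt.seed_density * ps * imaging.channel_gains.get("seed", 0.0)
        _add_gaussian_segment(ab_img, mt0, mt1, lam_ab, sigma)
        _add_gaussian_segment(seed_img, seed0, seed1, lam_seed, sigma)
        mt_polylines.append(np.array([mt0, mt1]))
        seed_polylines.append(np.array([seed0, seed1]))

    overlapping = [False] * len(layout.mts)
    for i in range(len(layout.mts)):
        for j in range(i + 1, len(layout.mts)):
            d = _segment_distance(*mt_polylines[i], *mt_polylines[j])
            if d < 4.0 * sigma:
                overlapping[i] = overlapping[j] = True

    channels = {}
    for label, img in (("seed", seed_img), ("antibody", ab_img)):
        channels[label] = imaging.noise.apply(img + imaging.background, rng)

    return FOVImage(
        channels=channels,
        pixel_size_um=ps,
        truth={
            "mt_polylines": mt_polylines,
            "seed_polylines": seed_polylines,
            "antibody_densities": np.array([m.antibody_density for m in layout.mts]),
            "seed_densities": np.array([m.seed_density for m in layout.mts]),
            "overlapping": overlapping,
            "layout": layout,
            "rng_seed": int(rng_seed),
        },
    )


# --------------------------------------------------------------------------
# Drift and titrations


def apply_drift(movie: np.ndarray, drift_track: np.ndarray, fill: float | None = None) -> np.ndarray:
    """Translate each frame by its cumulative drift (dx, dy) in pixels.

    Subpixel shifts use bilinear interpolation; uncovered edges are filled
    with ``fill`` (default: the frame's median, a background estimate).
    Drifts at least as large as the frame are rejected.
    """
    movie = np.asarray(movie, dtype=float)
    track = np.asarray(drift_track, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be a (frames, y, x) array")
    if track.shape != (movie.shape[0], 2):
        raise ValueError("drift_track must have shape (n_frames, 2)")
    ny, nx = movie.shape[1:]
    if np.any(np.abs(track[:, 0]) >= nx) or np.any(np.abs(track[:, 1]) >= ny):
        raise ValueError("drift exceeds the image size")
    out = np.empty_like(movie)
    for i, frame in enumerate(movie):
        dx, dy = track[i]
        cval = float(np.median(frame)) if fill is None else fill
        if dx == 0 and dy == 0:
            out[i] = frame
        else:
            out[i] = ndimage.shift(frame, (dy, dx), order=1, mode="constant", cval=cval)
    return out


@dataclass(frozen=True)
class TitrationDesign:
    """Design of a two-fold dilution binding series.

    ``labeled_total`` is the constant concentration of the labelled
    species (default 50 nM); the titrant starts at ``top_concentration``
    and is diluted by ``dilution_factor`` for ``n_points`` steps.
    ``noise_sd`` is additive Gaussian noise on the response (a.u.).
    """

    kd: float
    top_concentration: float
    n_points: int = 24
    dilution_factor: float = 2.0
    labeled_total: float = 50e-9
    signal_free: float = 0.2
    signal_bound: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")
        if not self.top_concentration > 0:
            raise ValueError(f"top_concentration must be > 0, got {self.top_concentration}")
        if self.n_points < 6:
            raise ValueError(f"n_points must be >= 6, got {self.n_points}")
        if not self.dilution_factor > 1:
            raise ValueError(f"dilution_factor must be > 1, got {self.dilution_factor}")
        if not self.labeled_total > 0:
            raise ValueError(f"labeled_total must be > 0, got {self.labeled_total}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def concentrations(self) -> np.ndarray:
        return self.top_concentration / self.dilution_factor ** np.arange(self.n_points)


def simulate_titration(design: TitrationDesign, rng_seed: int = 0) -> Titration:
    """Responses of a dilution series under the quadratic depletion model."""
    rng = np.random.default_rng(rng_seed)
    conc = design.concentrations()
    frac = fraction_bound(design.labeled_total, conc, design.kd, of="R")
    resp = design.signal_free + (design.signal_bound - design.signal_free) * frac
    if design.noise_sd > 0:
        resp = resp + rng.normal(0.0, design.noise_sd, size=resp.shape)
    return Titration(titrant_total=conc, response=resp, labeled_total=design.labeled_total)
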