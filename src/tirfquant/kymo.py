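"""Kymograph tip tracking, growth-event segmentation and dynamics measures.

A kymograph is a space-time image of one microtubule; the seed occupies a
fixed interval and the two ends grow away from it on either side.  The
analysis chain is:

1. :func:`extract_tip_trajectory` — per frame and per side, the tip is the
   farthest half-maximum crossing of the (smoothed) intensity profile
   beyond the seed, linearly interpolated to subpixel.  Frames with no
   signal beyond the seed sit at the seed edge.
2. :func:`segment_growth_events` — a growth event starts when the tip
   first exceeds the seed edge by an onset threshold (back-dated to when
   it left the seed) and ends at a catastrophe: a single-frame regression
   larger than a drop threshold or a return below the seed edge.  Events
   still growing at the last frame are censored.
3. :func:`estimate_growth_speed` — ordinary least-squares slope of tip
   position versus time over the event, in µm/min.  Fitting the whole
   event averages over transient growth irregularities.
4. :func:`extract_lifetimes` — lifetimes (onset to last frame before
   catastrophe) of uncensored events; censored events are excluded from
   lifetime statistics but always counted so the bias stays visible.
5. :func:`assign_polarity` — the faster side of a seed is the plus end.

Coordinates: 0-based pixels, positions at pixel centers, time at frame
start; speeds in µm/min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import Kymograph

__all__ = [
    "TipTrajectory",
    "GrowthEvent",
    "extract_tip_trajectory",
    "segment_growth_events",
    "estimate_growth_speed",
    "extract_lifetimes",
    "assign_polarity",
    "analyze_kymograph",
]

logger = logging.getLogger(__name__)

#: frames closer than this to the seed edge are flagged low-quality: there
#: the tip profile merges with the seed edge response and half-maximum
#: localization is biased
NEAR_SEED_PX = 3.0

#: tips within this band of the seed edge count as "at the seed" for
#: event segmentation (onset back-walk and collapse detection)
RESET_PX = 0.75


@dataclass
class TipTrajectory:
    """Per-frame tip position of one side of a seed.

    ``positions_um`` are absolute positions along the kymograph axis;
    ``quality`` is False where the tip is indistinguishable from the seed
    edge (no signal, or within the merge zone) or pinned at the image
    border.  ``outward(i)`` grows positive as the microtubule elongates,
    regardless of side.
    """

    side: str  # 'left' or 'right'
    times_s: np.ndarray
    positions_um: np.ndarray
    quality: np.ndarray
    seed_edge_um: float
    pixel_size_um: float
    frame_interval_s: float

    def __len__(self) -> int:
        return self.times_s.size

    def outward_um(self) -> np.ndarray:
        """Extension beyond the seed edge, positive outward."""
        rel = self.positions_um - self.seed_edge_um
        return rel if self.side == "right" else -rel


@dataclass
class GrowthEvent:
    """One growth episode of one microtubule end."""

    side: str
    onset_frame: int
    last_frame: int
    onset_time_s: float
    catastrophe_time_s: float | None
    censored: bool
    lifetime_s: float | None
    speed_um_min: float | None = None
    fit_residual_um: float | None = None
    n_frames_fit: int = 0
    end_label: str | None = None


def _side_trajectory(
    profile: np.ndarray,
    col_positions_px: np.ndarray,
    seed_edge_px: float,
    side: str,
    pixel_size_um: float,
    frame_interval_s: float,
    smooth_sigma: float,
    min_snr: float,
    edge_cols: int,
    plateau: float,
) -> TipTrajectory:
    """Half-maximum tip localization on one side, vectorized over frames.

    ``profile`` columns are ordered seed -> image border (i.e. already
    mirrored for the left side); ``col_positions_px`` maps columns to
    absolute pixel coordinates.  ``plateau`` is the global on-polymer
    intensity level of the channel: because the linear density of the
    polymer is uniform, a single plateau serves every frame, including
    frames where the extension is too short to show a plateau of its own.
    """
    smoothed = (
        ndimage.gaussian_filter1d(profile, smooth_sigma, axis=1)
        if smooth_sigma > 0
        else profile.astype(float)
    )
    edge = smoothed[:, -edge_cols:]
    bg = float(np.median(edge))
    noise = 1.4826 * float(np.median(np.abs(edge - bg)))

    present = np.full(profile.shape[0], (plateau - bg) > max(min_snr * noise, 1e-9))
    half = bg + 0.5 * (plateau - bg)

    above = smoothed >= half
    any_above = above.any(axis=1)
    last = profile.shape[1] - 1 - np.argmax(above[:, ::-1], axis=1)
    at_border = last >= profile.shape[1] - 1

    nxt = np.minimum(last + 1, profile.shape[1] - 1)
    v0 = smoothed[np.arange(len(last)), last]
    v1 = smoothed[np.arange(len(last)), nxt]
    denom = v0 - v1
    frac = np.where(denom > 0, (v0 - half) / np.where(denom > 0, denom, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    tip_px = col_positions_px[last] + frac * (
        col_positions_px[nxt] - col_positions_px[last]
    )

    sign = 1.0 if side == "right" else -1.0
    rel = sign * (tip_px - seed_edge_px)
    ok = present & any_above & ~at_border
    rel = np.where(ok, np.clip(rel, 0.0, None), 0.0)

    positions = (seed_edge_px + sign * rel) * pixel_size_um
    quality = ok & (rel >= NEAR_SEED_PX)
    times = np.arange(profile.shape[0]) * frame_interval_s
    return TipTrajectory(
        side=side,
        times_s=times,
        positions_um=positions,
        quality=quality,
        seed_edge_um=seed_edge_px * pixel_size_um,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    )


def extract_tip_trajectory(
    kymo: Kymograph,
    seed_extent_px: tuple | None = None,
    channel: str = "tubulin",
    smooth_sigma: float = 1.0,
    min_snr: float = 4.0,
    edge_cols: int = 5,
) -> dict:
    """Locate the tip on both sides of the seed for every frame.

    Returns ``{'left': TipTrajectory, 'right': TipTrajectory}``.  The seed
    extent defaults to the one recorded on the kymograph.  Background and
    noise are estimated from the outermost ``edge_cols`` columns of each
    side, so results are invariant to a constant intensity offset.
    """
    if seed_extent_px is None:
        seed_extent_px = kymo.seed_extent_px
    a, b = float(seed_extent_px[0]), float(seed_extent_px[1])
    img = np.asarray(kymo.channels[channel], dtype=float)
    n_px = img.shape[1]
    if not (0 <= a < b <= n_px - 1):
        raise ValueError(
            f"seed extent ({a:.1f}, {b:.1f}) outside image of width {n_px}"
        )

    smoothed_all = (
        ndimage.gaussian_filter1d(img, smooth_sigma, axis=1) if smooth_sigma > 0 else img
    )
    # global plateau: median of pixels in the upper half of the intensity
    # range (the on-polymer level; the seed region guarantees such pixels)
    lo = float(np.median(smoothed_all))
    hi = float(smoothed_all.max())
    on = smoothed_all >= lo + 0.5 * (hi - lo)
    plateau = float(np.median(smoothed_all[on])) if on.any() else hi

    cb = int(np.ceil(b))
    right = _side_trajectory(
        img[:, cb:],
        np.arange(cb, n_px, dtype=float),
        b,
        "right",
        kymo.pixel_size_um,
        kymo.frame_interval_s,
        smooth_sigma,
        min_snr,
        edge_cols,
        plateau,
    )
    ca = int(np.floor(a))
    left = _side_trajectory(
        img[:, ca::-1],
        np.arange(ca, -1, -1, dtype=float),
        a,
        "left",
        kymo.pixel_size_um,
        kymo.frame_interval_s,
        smooth_sigma,
        min_snr,
        edge_cols,
        plateau,
    )
    return {"left": left, "right": right}


def segment_growth_events(
    traj: TipTrajectory,
    onset_threshold_px: float = 3.0,
    catastrophe_drop_px: float = 3.0,
    reset_px: float = RESET_PX,
) -> list:
    """Split a tip trajectory into growth events.

    A candidate event is armed when the outward extension first exceeds
    ``onset_threshold_px``; its onset is back-dated to the last frame at
    which the tip was still within ``reset_px`` of the seed edge.  A
    catastrophe is a regression by more than ``catastrophe_drop_px`` within
    one frame interval, or a fall back below the seed edge; the event ends
    at the last frame before it.  An event still growing at the final
    frame is censored.
    """
    rel = traj.outward_um()
    ps = traj.pixel_size_um
    thr_on = onset_threshold_px * ps
    drop = catastrophe_drop_px * ps
    reset = reset_px * ps
    dt = traj.frame_interval_s

    events: list[GrowthEvent] = []
    state = "idle"  # idle -> growing; back to idle after catastrophe + reset
    onset = 0
    n = len(traj)
    for t in range(n):
        if state == "idle":
            if rel[t] > thr_on:
                onset = t
                for t0 in range(t, -1, -1):
                    if rel[t0] <= reset:
                        onset = t0
                        break
                    onset = t0
                state = "growing"
        elif state == "growing":
            fell_back = rel[t] <= reset
            regressed = (rel[t] - rel[t - 1]) < -drop
            if fell_back or regressed:
                last = t - 1
                events.append(
                    GrowthEvent(
                        side=traj.side,
                        onset_frame=onset,
                        last_frame=last,
                        onset_time_s=onset * dt,
                        catastrophe_time_s=last * dt,
                        censored=False,
                        lifetime_s=(last - onset) * dt,
                    )
                )
                state = "waiting" if not fell_back else "idle"
        elif state == "waiting":
            if rel[t] <= reset:
                state = "idle"
    if state == "growing":
        events.append(
            GrowthEvent(
                side=traj.side,
                onset_frame=onset,
                last_frame=n - 1,
                onset_time_s=onset * dt,
                catastrophe_time_s=None,
                censored=True,
                lifetime_s=None,
            )
        )
    elif state == "idle" and n >= 3:
        # a nucleation just before movie end may not have reached the full
        # onset threshold yet; accept a sustained half-threshold tail as a
        # censored event so late events are not silently dropped
        tail = rel[-3:]
        if tail.min() > reset and tail.max() >= 0.5 * thr_on:
            onset = n - 1
            for t0 in range(n - 1, -1, -1):
                if rel[t0] <= reset:
                    onset = t0
                    break
                onset = t0
            events.append(
                GrowthEvent(
                    side=traj.side,
                    onset_frame=onset,
                    last_frame=n - 1,
                    onset_time_s=onset * dt,
                    catastrophe_time_s=None,
                    censored=True,
                    lifetime_s=None,
                )
            )
    return events


def estimate_growth_speed(event: GrowthEvent, traj: TipTrajectory) -> float | None:
    """OLS slope of tip extension versus time over the event, in µm/min.

    Only good-quality frames (beyond the seed-merge zone) enter the fit;
    an event with fewer than 3 such frames is dropped (speed None) with a
    logged warning.  The RMS fit residual is stored on the event for
    auditing irregular growth.
    """
    sl = slice(event.onset_frame, event.last_frame + 1)
    rel = traj.outward_um()[sl]
    good = traj.quality[sl]
    t_all = traj.times_s[sl] / 60.0
    near = NEAR_SEED_PX * traj.pixel_size_um

    def _drop(n: int):
        logger.warning(
            "event on side %s at frame %d dropped: only %d usable frames",
            traj.side, event.onset_frame, n,
        )
        event.speed_um_min = None
        event.n_frames_fit = int(n)
        return None

    if np.count_nonzero(good) < 3:
        return _drop(int(np.count_nonzero(good)))
    # pass 1: frames flagged good (measured position beyond the seed-merge
    # zone).  Selecting on the *measured* position truncates the noise
    # asymmetrically near the cut, so pass 2 reselects frames by their
    # *predicted* position from the pass-1 line, which is independent of
    # each frame's own noise, and refits.
    slope, intercept = np.polyfit(t_all[good], rel[good], 1)
    predicted = slope * t_all + intercept
    use = predicted >= near
    if np.count_nonzero(use) < 3:
        use = good
    if np.count_nonzero(use) < 3:
        return _drop(int(np.count_nonzero(use)))
    slope, intercept = np.polyfit(t_all[use], rel[use], 1)
    resid = rel[use] - (slope * t_all[use] + intercept)
    event.speed_um_min = float(slope)
    event.fit_residual_um = float(np.sqrt(np.mean(resid**2)))
    event.n_frames_fit = int(np.count_nonzero(use))
    if slope > 0:
        # refine the onset to where the fitted line leaves the seed edge:
        # threshold crossing alone would date the onset late by
        # (threshold / speed), a bias of order 5-15 s per event.  The
        # back-dating window scales with the time the tip needs to clear
        # the reset band at the fitted speed.
        dt_s = traj.frame_interval_s
        t0_s = event.onset_frame * dt_s
        reset_um = RESET_PX * traj.pixel_size_um
        lo = t0_s - 60.0 * reset_um / slope - 2 * dt_s
        crossing_s = 60.0 * (-intercept / slope)
        event.onset_time_s = float(np.clip(crossing_s, lo, t0_s + 5 * dt_s))
        if not event.censored and event.catastrophe_time_s is not None:
            event.lifetime_s = float(event.catastrophe_time_s - event.onset_time_s)
    return event.speed_um_min


def extract_lifetimes(events) -> tuple:
    """Lifetimes (s) of uncensored events plus the censored count.

    Censored events never enter lifetime statistics; their count is
    reported alongside so the exclusion is visible.
    """
    lifetimes = np.array(
        [e.lifetime_s for e in events if not e.censored], dtype=float
    )
    censored = sum(1 for e in events if e.censored)
    return lifetimes, censored


def assign_polarity(events_by_side: dict) -> tuple:
    """Label the faster side of a seed 'plus' and the slower 'minus'.

    Ties break toward the side with more events, then lexicographically;
    tied assignments are flagged ambiguous.  A seed with events on a
    single side gets 'unknown' labels rather than a guess.  Returns
    ``(labels, ambiguous)`` with ``labels`` mapping side -> end label.
    """
    sides = sorted(events_by_side)
    speeds = {}
    for side in sides:
        vals = [e.speed_um_min for e in events_by_side[side] if e.speed_um_min is not None]
        speeds[side] = float(np.mean(vals)) if vals else None

    active = [s for s in sides if speeds[s] is not None]
    if len(active) < 2:
        return {s: "unknown" for s in sides}, False

    a, b = active[0], active[1]
    ambiguous = False
    if speeds[a] > speeds[b]:
        plus = a
    elif speeds[b] > speeds[a]:
        plus = b
    else:
        na, nb = len(events_by_side[a]), len(events_by_side[b])
        plus = a if na > nb else b if nb > na else min(a, b)
        ambiguous = True
    labels = {s: "unknown" for s in sides}
    labels[plus] = "plus"
    labels[b if plus == a else a] = "minus"
    for side, label in labels.items():
        for e in events_by_side[side]:
            e.end_label = label
    return labels, ambiguous


def analyze_kymograph(
    kymo: Kymograph,
    seed_extent_px: tuple | None = None,
    channel: str = "tubulin",
    **segment_kwargs,
) -> dict:
    """Full chain on one kymograph: tracking, segmentation, speeds, polarity.

    Returns a dict with ``trajectories`` (per side), ``events`` (flat list
    with end labels), ``labels`` and ``ambiguous``.
    """
    trajectories = extract_tip_trajectory(kymo, seed_extent_px, channel=channel)
    events_by_side = {}
    for side, traj in trajectories.items():
        events = segment_growth_events(traj, **segment_kwargs)
        for e in events:
            estimate_growth_speed(e, traj)
        events_by_side[side] = events
    labels, ambiguous = assign_polarity(events_by_side)
    flat = [e for side in sorted(events_by_side) for e in events_by_side[side]]
    return {
        "trajectories": trajectories,
        "events": flat,
        "events_by_side": events_by_side,
        "labels": labels,
        "ambiguous": ambiguous,
    }
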