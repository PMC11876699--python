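"""End-to-end recovery experiments on synthetic data.

Each function generates data at known ground truth with the synthetic
module, runs the corresponding measurement pipeline, and returns the
recovered quantities together with the truth — the package's own
validation harness.  All randomness derives from a single integer seed per
call.
"""

from __future__ import annotations

import numpy as np

from . import kymo as kymo_mod
from .binding import fit_kd
from .images import ImagingParams
from .lifetime import GammaLifetimeFit, analyze_lifetimes
from .synthetic import (
    DynamicsParams,
    TitrationDesign,
    density_for_linescan_mean,
    make_fov_layout,
    render_fov_image,
    render_kymograph,
    scale_for_median,
    simulate_dynamics,
    simulate_titration,
)

__all__ = [
    "recover_growth_speeds",
    "recover_lifetime_statistic",
    "recover_kd",
    "recover_normalized_intensity",
]

_SEED_MOD = 2**31 - 1


def _derive_seeds(base_seed: int, n: int, stream: int) -> np.ndarray:
    """Independent child seeds for sub-simulations, all below 2**31."""
    rng = np.random.default_rng([int(base_seed) % _SEED_MOD, stream])
    return rng.integers(0, _SEED_MOD, size=n)


def recover_growth_speeds(
    params: DynamicsParams,
    n_seeds: int,
    duration_s: float,
    rng_seed: int,
    imaging: ImagingParams | None = None,
) -> dict:
    """Simulate, render and re-measure growth speeds and lifetimes.

    Runs the full chain (event simulation -> kymograph rendering -> tip
    tracking -> segmentation -> OLS speeds -> polarity assignment) on
    ``n_seeds`` microtubules and pools the per-event measurements by the
    *measured* end label.  Returns measured speeds/lifetimes per end, the
    censored counts, and the true-vs-detected event counts per seed.
    """
    imaging = imaging or ImagingParams()
    events = simulate_dynamics(params, n_seeds, duration_s, rng_seed)
    render_seeds = _derive_seeds(rng_seed, n_seeds, stream=1)

    speeds = {"plus": [], "minus": [], "unknown": []}
    lifetimes = {"plus": [], "minus": [], "unknown": []}
    censored = {"plus": 0, "minus": 0, "unknown": 0}
    count_pairs = []  # (true events, detected events) per seed
    n_ambiguous = 0
    for i, mt_id in enumerate(events.mt_ids()):
        k = render_kymograph(events, imaging, mt_id, rng_seed=int(render_seeds[i]))
        res = kymo_mod.analyze_kymograph(k)
        n_ambiguous += int(res["ambiguous"])
        for e in res["events"]:
            label = e.end_label or "unknown"
            if e.speed_um_min is not None:
                speeds[label].append(e.speed_um_min)
            if e.censored:
                censored[label] += 1
            elif e.lifetime_s is not None:
                lifetimes[label].append(e.lifetime_s)
        n_true = len(events.for_mt(mt_id))
        count_pairs.append((n_true, len(res["events"])))

    return {
        "speeds": {k: np.asarray(v) for k, v in speeds.items()},
        "lifetimes": {k: np.asarray(v) for k, v in lifetimes.items()},
        "censored": censored,
        "count_pairs": np.asarray(count_pairs),
        "n_ambiguous": n_ambiguous,
        "params": params,
    }


def recover_lifetime_statistic(
    median_s: float,
    n_events: int,
    rng_seed: int,
    shape: float = 3.0,
    n_bootstrap: int = 10_000,
) -> GammaLifetimeFit:
    """Draw lifetimes from a gamma law with the given median and run the
    full statistic chain (MLE -> gamma median -> bootstrap IQR error)."""
    scale = scale_for_median(median_s, shape)
    rng = np.random.default_rng([int(rng_seed) % _SEED_MOD, 2])
    lifetimes = rng.gamma(shape, scale, size=n_events)
    boot_seed = int(_derive_seeds(rng_seed, 1, stream=3)[0])
    return analyze_lifetimes(lifetimes, n_bootstrap=n_bootstrap, rng_seed=boot_seed)


def recover_kd(
    kd: float,
    top_concentration: float,
    n_points: int,
    n_replicates: int,
    rng_seed: int,
    labeled_total: float = 50e-9,
    noise_fraction: float = 0.05,
    signal_free: float = 0.2,
    signal_bound: float = 1.0,
) -> dict:
    """Fit Kd from noisy two-fold dilution series, replicated over seeds.

    ``noise_fraction`` scales the additive noise to the response dynamic
    range.  Returns the per-replicate fitted Kds (valid fits only) and
    their median.
    """
    design = TitrationDesign(
        kd=kd,
        top_concentration=top_concentration,
        n_points=n_points,
        labeled_total=labeled_total,
        signal_free=signal_free,
        signal_bound=signal_bound,
        noise_sd=noise_fraction * abs(signal_bound - signal_free),
    )
    seeds = _derive_seeds(rng_seed, n_replicates, stream=4)
    kds, n_invalid = [], 0
    for s in seeds:
        fit = fit_kd(simulate_titration(design, rng_seed=int(s)))
        if fit.valid:
            kds.append(fit.kd)
        else:
            n_invalid += 1
    kds = np.asarray(kds)
    return {
        "kds": kds,
        "median_kd": float(np.median(kds)) if kds.size else np.nan,
        "n_invalid": n_invalid,
        "design": design,
    }


def recover_normalized_intensity(
    target_normalized: float,
    n_fov: int,
    n_mts_per_fov: int,
    rng_seed: int,
    imaging: ImagingParams | None = None,
    seed_linescan_target: float = 175.0,
) -> dict:
    """Render FOVs calibrated to a target normalized intensity and re-measure.

    Seed densities are calibrated so the expected seed linescan value is
    ``seed_linescan_target`` counts; mean antibody densities so the
    ground-truth normalized statistic (100 x antibody mean / seed mean)
    equals ``target_normalized``.  Returns per-FOV pipeline values and
    their mean.
    """
    imaging = imaging or ImagingParams()
    dens_seed = density_for_linescan_mean(seed_linescan_target, imaging, "seed")
    dens_ab = density_for_linescan_mean(
        seed_linescan_target * target_normalized / 100.0, imaging, "antibody"
    )
    layout_seeds = _derive_seeds(rng_seed, n_fov, stream=5)
    render_seeds = _derive_seeds(rng_seed, n_fov, stream=6)
    from .ptm import fov_normalized_intensity

    fov_values, n_mts, n_excluded = [], 0, 0
    for i in range(n_fov):
        rng = np.random.default_rng(int(layout_seeds[i]))
        layout = make_fov_layout(
            n_mts_per_fov, imaging, rng,
            antibody_density_mean=dens_ab, seed_density=dens_seed,
        )
        fov = render_fov_image(layout, imaging, rng_seed=int(render_seeds[i]))
        q = fov_normalized_intensity(
            fov, fov.truth["mt_polylines"], fov.truth["seed_polylines"]
        )
        fov_values.append(q.normalized)
        n_mts += q.n_microtubules
        n_excluded += q.n_excluded

    fov_values = np.asarray(fov_values)
    return {
        "fov_values": fov_values,
        "mean_normalized": float(fov_values.mean()),
        "n_microtubules": n_mts,
        "n_excluded": n_excluded,
        "target": target_normalized,
    }
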