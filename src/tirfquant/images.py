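"""Image containers and acquisition parameters shared across modules.

Conventions: pixels are 0-based with positions reported at pixel centers,
so the physical coordinate of pixel index ``i`` is ``i * pixel_size_um``.
Kymographs are (time, position) arrays with rows ordered by frame and time
measured at frame start.  Multichannel images are dictionaries of 2-D
arrays keyed by channel label ('seed', 'tubulin', 'antibody', ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseModel", "ImagingParams", "Kymograph", "FOVImage"]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian (``sd`` counts) or Poisson (``gain`` counts per
    photon) detection noise; ``kind='none'`` disables noise."""

    kind: str = "gaussian"
    sd: float = 6.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson", "none"):
            raise ValueError(f"noise kind must be gaussian/poisson/none, got {self.kind!r}")
        if self.sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.sd}")
        if self.gain <= 0:
            raise ValueError(f"noise gain must be > 0, got {self.gain}")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or (self.kind == "gaussian" and self.sd == 0):
            return image
        if self.kind == "gaussian":
            return image + rng.normal(0.0, self.sd, size=image.shape)
        return rng.poisson(np.clip(image, 0, None) / self.gain) * self.gain


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition model for the synthetic TIRF rig.

    Defaults (0.107 µm/px, 2 s/frame, sigma 1.3 px PSF) are plausible for a
    100x objective on an sCMOS camera; all overridable.  ``channel_gains``
    are counts deposited per unit linear density, per channel label.
    """

    pixel_size_um: float = 0.107
    frame_interval_s: float = 2.0
    psf_sigma_px: float = 1.3
    background: float = 100.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    channel_gains: dict = field(
        default_factory=lambda: {"seed": 80.0, "tubulin": 80.0, "antibody": 1.0}
    )

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise ValueError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")
        if self.psf_sigma_px < 0:
            raise ValueError(f"psf_sigma_px must be >= 0, got {self.psf_sigma_px}")
        if any(g < 0 for g in self.channel_gains.values()):
            raise ValueError("channel_gains must all be >= 0")


@dataclass
class Kymograph:
    """Space-time image of one microtubule: rows are frames, columns are
    position along the axis (pixel centers)."""

    channels: dict  # label -> (n_frames, n_px) float array
    pixel_size_um: float
    frame_interval_s: float
    seed_extent_px: tuple  # (left_edge, right_edge) in pixel coordinates
    mt_id: int | None = None
    truth: dict | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def n_px(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class FOVImage:
    """Multichannel snapshot of a field of view plus generator ground truth."""

    channels: dict  # label -> (ny, nx) float array
    pixel_size_um: float
    truth: dict | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape
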