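"""Synthetic brain-like 4D dynamic study with known lesion ground truth.

Builds a small dynamic volume from the phantom curve physics: background
air, a normally perfused compartment, a penumbra-like ring (long Tmax,
moderate CBF), a core-like centre (very low CBF, very long Tmax), an
arterial voxel cluster carrying the arterial curve, and Gaussian noise.
The exact truth masks are returned for end-to-end assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lesion import DynamicVolume
from .phantom import (
    GroundTruthParams,
    make_arterial_tdc,
    make_gamma_variate_irf,
    simulate_tissue_tdc,
)

__all__ = ["RegionSpec", "SynthConfig", "make_synthetic_study"]


@dataclass(frozen=True)
class RegionSpec:
    """Perfusion ground truth of one tissue compartment (cbv, mtt, t0)."""

    cbv: float
    mtt: float
    t0: float

    def params(self) -> GroundTruthParams:
        return GroundTruthParams.from_cbv_mtt(self.cbv, self.mtt, self.t0)


@dataclass
class SynthConfig:
    shape: tuple = (64, 64, 4)
    spacing: tuple = (2.0, 2.0, 5.0)  # mm
    n_t: int = 30
    dt_s: float = 2.0
    sigma_hu: float = 1.0
    brain_radius: float = 28.0  # voxels, in-plane
    brain_center: tuple = (32.0, 32.0)
    lesion_center: tuple = (22.0, 32.0)
    core_radius: float = 8.0
    penumbra_radius: float = 16.0
    # CBF 50, Tmax 2 s
    normal: RegionSpec = field(default_factory=lambda: RegionSpec(10.0 / 3.0, 4.0, 0.0))
    # CBF 15, Tmax 7 s
    penumbra: RegionSpec = field(default_factory=lambda: RegionSpec(2.0, 8.0, 3.0))
    # CBF 3, Tmax 14 s
    core: RegionSpec = field(default_factory=lambda: RegionSpec(0.8, 16.0, 6.0))
    aif_corner: tuple = (44, 44)
    aif_size: int = 2
    aif_kwargs: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return (self.n_t - 1) * self.dt_s


def _disk_mask(shape2d, center, radius) -> np.ndarray:
    xx, yy = np.ogrid[: shape2d[0], : shape2d[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def make_synthetic_study(
    config: SynthConfig | None = None, seed: int = 0
) -> tuple[DynamicVolume, dict]:
    """Build the synthetic study; returns (volume, ground truth).

    The truth dict carries boolean masks (``core``, ``penumbra``,
    ``hypoperfusion``, ``normal``, ``brain``, ``aif``), the per-region
    parameters, and the truth volumes in ml. Bit-reproducible for a
    fixed seed.
    """
    cfg = config or SynthConfig()
    nx, ny, nz = cfg.shape
    if cfg.penumbra_radius + max(
        abs(cfg.lesion_center[0] - cfg.brain_center[0]),
        abs(cfg.lesion_center[1] - cfg.brain_center[1]),
    ) > cfg.brain_radius:
        raise ValueError("lesion extends beyond the brain disk")
    if cfg.brain_radius >= min(nx, ny) / 2:
        raise ValueError("brain disk exceeds the volume bounds")

    times = np.arange(cfg.n_t) * cfg.dt_s
    duration = cfg.duration_s
    aif = make_arterial_tdc(duration, 0.5, **cfg.aif_kwargs)

    def region_curve(spec: RegionSpec) -> np.ndarray:
        irf = make_gamma_variate_irf(spec.params())
        return simulate_tissue_tdc(aif, irf, dt_out=cfg.dt_s,
                                   duration_s=duration).v

    curves = {
        "normal": region_curve(cfg.normal),
        "penumbra": region_curve(cfg.penumbra),
        "core": region_curve(cfg.core),
    }

    brain2d = _disk_mask((nx, ny), cfg.brain_center, cfg.brain_radius)
    hypo2d = _disk_mask((nx, ny), cfg.lesion_center, cfg.penumbra_radius) & brain2d
    core2d = _disk_mask((nx, ny), cfg.lesion_center, cfg.core_radius) & brain2d
    pen2d = hypo2d & ~core2d

    aif2d = np.zeros((nx, ny), dtype=bool)
    ax, ay = cfg.aif_corner
    aif2d[ax : ax + cfg.aif_size, ay : ay + cfg.aif_size] = True

    def stack(m2d):
        return np.repeat(m2d[:, :, None], nz, axis=2)

    brain = stack(brain2d & ~aif2d)
    core = stack(core2d)
    penumbra = stack(pen2d)
    hypo = stack(hypo2d)
    normal = brain & ~hypo
    aif_mask = stack(aif2d)

    data = np.zeros((nx, ny, nz, cfg.n_t))
    data[normal] = curves["normal"]
    data[penumbra] = curves["penumbra"]
    data[core] = curves["core"]
    data[aif_mask] = aif.interp(times)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noisy = brain | aif_mask
    data[noisy] += rng.normal(0.0, cfg.sigma_hu, size=(int(noisy.sum()), cfg.n_t))

    voxel_ml = float(np.prod(cfg.spacing)) / 1000.0
    truth = {
        "masks": {
            "brain": brain,
            "core": core,
            "penumbra": penumbra,
            "hypoperfusion": hypo,
            "normal": normal,
            "aif": aif_mask,
        },
        "params": {
            "normal": cfg.normal.params(),
            "penumbra": cfg.penumbra.params(),
            "core": cfg.core.params(),
        },
        "volumes_ml": {
            "core": float(core.sum()) * voxel_ml,
            "penumbra": float(penumbra.sum()) * voxel_ml,
            "hypoperfusion": float(hypo.sum()) * voxel_ml,
        },
        "voxel_ml": voxel_ml,
    }
    vol = DynamicVolume(
        data=data,
        spacing=cfg.spacing,
        times=times,
        brain_mask=brain,
        aif_voxel=(ax, ay, 0),
    )
    return vol, truth
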