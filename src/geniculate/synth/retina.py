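"""Two-channel flat-mount retina phantom.

Renders a ChAT channel containing two bright, smooth, possibly undulating
band surfaces and an RGC channel containing branched dendrite polylines
whose depths track the true band surfaces at the centers of their target
strata, exactly as a real arbor follows the curved inner plexiform layer.
The generator returns its own ground truth (band surfaces, per-cell
masks and strata) so downstream flattening and typing can be asserted
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..flatten import stratum_center

__all__ = ["PhantomCell", "RetinaPhantomConfig", "gen_retina_stack"]


@dataclass(frozen=True)
class PhantomCell:
    soma_xy: tuple[float, float]           # (row, col), pixels
    target_strata: tuple[int, ...]
    asymmetric: bool = False
    cofasciculating: bool = False
    n_branches: int = 8
    arbor_radius_px: float = 18.0

    def __post_init__(self) -> None:
        if not self.target_strata:
            raise ValueError("cell needs at least one target stratum")
        if any(not 1 <= k <= 10 for k in self.target_strata):
            raise ValueError("target strata must lie in 1..10")


@dataclass(frozen=True)
class RetinaPhantomConfig:
    xy_size: int = 64
    z_size: int = 48
    band_sep: float = 10.0        # mean ChAT-band separation, planes
    curvature_amp: float = 0.0    # max band undulation, planes
    cells: tuple[PhantomCell, ...] = ()
    noise_sd: float = 0.0
    band_sigma_planes: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xy_size < 4 or self.z_size < 8:
            raise ValueError("stack too small")
        if self.band_sep <= 0:
            raise ValueError("band_sep must be positive")
        if self.noise_sd < 0 or self.curvature_amp < 0:
            raise ValueError("noise_sd and curvature_amp must be >= 0")
        # strata 1..10 span relative depths [-0.625, 1.875] around the bands
        z_lo = self.z_size * 0.5 - 0.75 * self.band_sep - 0.625 * self.band_sep
        z_hi = self.z_size * 0.5 - 0.75 * self.band_sep + 1.875 * self.band_sep
        if z_lo - self.curvature_amp < 1 or z_hi + self.curvature_amp > self.z_size - 2:
            raise ValueError(
                "band separation/curvature exceed the z extent needed for strata 1..10"
            )


def gen_retina_stack(
    cfg: RetinaPhantomConfig,
) -> tuple[np.ndarray, dict, dict]:
    """Render the phantom.

    Returns ``(stack, surfaces_truth, cells_truth)`` where ``stack`` has
    shape (2, z, y, x) with channel 0 = ChAT and channel 1 = RGC,
    ``surfaces_truth`` holds ``off_z``/``on_z`` (y, x) arrays, and
    ``cells_truth`` maps cell index to ``{"mask", "soma_xy", "strata",
    "voxels"}`` with ``voxels`` the rendered (z, y, x) sample points.
    """
    rng = np.random.default_rng(cfg.seed)
    n, nz = cfg.xy_size, cfg.z_size
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")

    z0 = nz * 0.5 - 0.75 * cfg.band_sep
    if cfg.curvature_amp > 0:
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        undulation = cfg.curvature_amp * np.sin(2 * np.pi * xx / n + ph1) * np.cos(
            2 * np.pi * yy / n + ph2
        )
    else:
        undulation = np.zeros((n, n))
    off_z = z0 + undulation
    on_z = off_z + cfg.band_sep

    stack = np.zeros((2, nz, n, n))
    zaxis = np.arange(nz)[:, None, None]
    for surf in (off_z, on_z):
        stack[0] += np.exp(-0.5 * ((zaxis - surf[None]) / cfg.band_sigma_planes) ** 2)

    cells_truth: dict[int, dict] = {}
    for ci, cell in enumerate(cfg.cells):
        mask = np.zeros((n, n), dtype=bool)
        voxels: list[tuple[float, int, int]] = []
        n_br = cell.n_branches
        if cell.asymmetric:
            # strongly one-sided arbor: branches confined to a 90° sector
            sector = rng.uniform(0, 2 * np.pi)
            angles = sector + rng.uniform(0, np.pi / 2, n_br)
        else:
            angles = np.arange(n_br) * 2 * np.pi / n_br + rng.uniform(0, 2 * np.pi)
        strata_cycle = [cell.target_strata[i % len(cell.target_strata)] for i in range(n_br)]
        for ang, k in zip(angles, strata_cycle):
            rel = stratum_center(k)
            steps = int(cell.arbor_radius_px)
            direction = ang
            y, x = cell.soma_xy
            for _ in range(steps):
                direction += rng.normal(0, 0.15)  # gentle meander
                y += np.sin(direction)
                x += np.cos(direction)
                iy, ix = int(round(y)), int(round(x))
                if not (0 <= iy < n and 0 <= ix < n):
                    break
                zc = off_z[iy, ix] + rel * (on_z[iy, ix] - off_z[iy, ix])
                z_lo = max(int(np.floor(zc - 1.5)), 0)
                z_hi = min(int(np.ceil(zc + 1.5)), nz - 1)
                zs = np.arange(z_lo, z_hi + 1)
                stack[1, zs, iy, ix] += np.exp(-0.5 * ((zs - zc) / 0.6) ** 2)
                mask[iy, ix] = True
                voxels.append((zc, iy, ix))
        cells_truth[ci] = {
            "mask": mask,
            "soma_xy": cell.soma_xy,
            "strata": tuple(cell.target_strata),
            "voxels": np.array(voxels) if voxels else np.empty((0, 3)),
        }

    if cfg.noise_sd > 0:
        stack += rng.normal(0, cfg.noise_sd, stack.shape)
    surfaces_truth = {"off_z": off_z, "on_z": on_z, "seed": cfg.seed}
    return stack, surfaces_truth, cells_truth
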