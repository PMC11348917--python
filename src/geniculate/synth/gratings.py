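"""Synthetic drifting-grating calcium-imaging sessions.

Each simulated cell has a ground-truth tuning kind — DS (von Mises in
direction), OS (von Mises doubled in angle), SbC (tonic activity dipping
during stimuli) or broad (direction-independent) — and optional dendritic
compartments that share the soma's tuning scaled by a per-compartment
attenuation factor.  Stimulus-locked responses are convolved with a
single-exponential indicator kernel (default 1.5 s decay, approximating a
slow calcium indicator) and summed into movie frames over spatial
footprints, plus i.i.d. Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..protocol import StimulusProtocol

__all__ = ["TuningSpec", "GratingSimConfig", "gen_grating_session"]


@dataclass(frozen=True)
class TuningSpec:
    kind: str                    # DS | OS | SbC | broad | DS_neg | OS_neg
    preferred_deg: float = 0.0
    concentration: float = 4.0   # von Mises κ
    amplitude: float = 1.0
    sbc_fraction: float = 1.0    # fraction of tonic rate suppressed during stimuli

    def __post_init__(self) -> None:
        if self.kind not in ("DS", "OS", "SbC", "broad", "DS_neg", "OS_neg"):
            raise ValueError(f"unknown tuning kind {self.kind!r}")
        if not 0 <= self.preferred_deg < 360:
            raise ValueError("preferred angle must lie in [0, 360)")
        if self.amplitude < 0 or self.concentration < 0:
            raise ValueError("amplitude and concentration must be >= 0")
        if not 0 <= self.sbc_fraction <= 1:
            raise ValueError("sbc_fraction must lie in [0, 1]")

    @property
    def tonic(self) -> bool:
        """Kinds whose signature is suppression need tonic baseline activity."""
        return self.kind in ("SbC", "DS_neg", "OS_neg")

    def response(self, direction_deg: float) -> float:
        """Stimulus-period drive (relative to baseline) for one direction."""
        th = np.deg2rad(direction_deg - self.preferred_deg)
        vm_dir = float(np.exp(self.concentration * (np.cos(th) - 1)))
        vm_ori = float(np.exp(self.concentration * (np.cos(2 * th) - 1)))
        if self.kind == "DS":
            return self.amplitude * vm_dir
        if self.kind == "OS":
            return self.amplitude * vm_ori
        if self.kind == "broad":
            return self.amplitude
        if self.kind == "DS_neg":
            return -self.amplitude * vm_dir  # direction-tuned dip below tonic level
        if self.kind == "OS_neg":
            return -self.amplitude * vm_ori
        return -self.amplitude * self.sbc_fraction  # SbC: dip below tonic baseline


@dataclass(frozen=True)
class GratingSimConfig:
    tuning_specs: tuple[TuningSpec, ...]
    protocol: StimulusProtocol = StimulusProtocol()
    frame_rate: float = 5.0
    fov_px: int = 48
    um_per_px: float = 2.0
    dendrites_per_cell: int = 0
    dendrite_attenuation: tuple[float, ...] = ()
    noise_sd: float = 0.05
    indicator_decay_s: float = 1.5
    soma_radius_px: float = 2.5
    sbc_baseline: float = 1.0   # tonic fluorescence of SbC cells above rest
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dendrites_per_cell and len(self.dendrite_attenuation) != self.dendrites_per_cell:
            raise ValueError("need one attenuation per dendrite compartment")
        if any(not 0 < a <= 1 for a in self.dendrite_attenuation):
            raise ValueError("attenuation must lie in (0, 1]")


def _indicator_kernel(decay_s: float, frame_rate: float) -> np.ndarray:
    n = max(int(round(5 * decay_s * frame_rate)), 1)
    k = np.exp(-np.arange(n) / (decay_s * frame_rate))
    return k / k.sum()


def gen_grating_session(
    cfg: GratingSimConfig,
) -> tuple[np.ndarray, list[dict], list[dict]]:
    """Simulate one session.

    Returns ``(movie, roi_truth, tuning_truth)``: the movie (t, y, x);
    per-cell footprint masks for soma and dendrite compartments; and the
    ground-truth tuning including attenuation and the per-stimulus ideal
    drive table.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    prot = cfg.protocol
    n_frames = int(np.ceil(prot.total_duration_s * cfg.frame_rate)) + 1
    fov = cfg.fov_px
    movie = np.zeros((n_frames, fov, fov))
    kernel = _indicator_kernel(cfg.indicator_decay_s, cfg.frame_rate)
    sched = prot.schedule()

    n_cells = len(cfg.tuning_specs)
    centers = _spread_centers(n_cells, fov, rng)
    roi_truth: list[dict] = []
    tuning_truth: list[dict] = []
    yy, xx = np.meshgrid(np.arange(fov), np.arange(fov), indexing="ij")

    for ci, spec in enumerate(cfg.tuning_specs):
        cy, cx = centers[ci]
        # rate trace: tonic baseline (SbC) plus stimulus-locked boxcars
        rate = np.zeros(n_frames)
        if spec.tonic:
            rate += cfg.sbc_baseline
        for _, r in sched.iterrows():
            on = int(round(r["onset_s"] * cfg.frame_rate))
            off = int(round(r["offset_s"] * cfg.frame_rate))
            rate[on:off] += spec.response(float(r["direction"]))
        fluo = np.convolve(rate, kernel)[:n_frames]

        soma = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.soma_radius_px**2
        movie += soma[None] * fluo[:, None, None]
        compartments = [{"mask": soma, "kind": "soma", "attenuation": 1.0,
                         "centroid": (cy, cx)}]

        base_angle = rng.uniform(0, 2 * np.pi)
        for di in range(cfg.dendrites_per_cell):
            att = cfg.dendrite_attenuation[di]
            ang = base_angle + di * 2 * np.pi / max(cfg.dendrites_per_cell, 1)
            mask = _dendrite_polyline(cy, cx, ang, cfg.soma_radius_px, fov, rng)
            if not mask.any():
                continue
            movie += mask[None] * (att * fluo)[:, None, None]
            ys, xs = np.nonzero(mask)
            compartments.append(
                {"mask": mask, "kind": "dendrite", "attenuation": att,
                 "centroid": (float(ys.mean()), float(xs.mean()))}
            )
        roi_truth.append({"cell": ci, "compartments": compartments})
        drive = {
            (float(r["speed"]), float(r["direction"])): spec.response(float(r["direction"]))
            for _, r in sched.drop_duplicates(["speed", "direction"]).iterrows()
        }
        tuning_truth.append(
            {"cell": ci, "kind": spec.kind, "preferred_deg": spec.preferred_deg,
             "amplitude": spec.amplitude, "drive": drive, "seed": cfg.seed}
        )

    if cfg.noise_sd > 0:
        movie += rng.normal(0, cfg.noise_sd, movie.shape)
    return movie, roi_truth, tuning_truth


def _spread_centers(n: int, fov: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Cell centers on a jittered grid, keeping footprints apart."""
    per_side = int(np.ceil(np.sqrt(n)))
    pitch = fov / (per_side + 1)
    centers = []
    for i in range(n):
        gy, gx = divmod(i, per_side)
        cy = (gy + 1) * pitch + rng.uniform(-1, 1)
        cx = (gx + 1) * pitch + rng.uniform(-1, 1)
        centers.append((int(np.clip(cy, 3, fov - 4)), int(np.clip(cx, 3, fov - 4))))
    return centers


def _dendrite_polyline(
    cy: float, cx: float, angle: float, start_r: float, fov: int, rng: np.random.Generator,
    length_px: int = 10,
) -> np.ndarray:
    mask = np.zeros((fov, fov), dtype=bool)
    y = cy + (start_r + 1.5) * np.sin(angle)
    x = cx + (start_r + 1.5) * np.cos(angle)
    d = angle
    for _ in range(length_px):
        d += rng.normal(0, 0.1)
        y += np.sin(d)
        x += np.cos(d)
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < fov and 0 <= ix < fov):
            break
        mask[iy, ix] = True
    return mask
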