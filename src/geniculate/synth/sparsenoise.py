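"""Synthetic sparse-noise sessions for receptive-field mapping.

Flashes 8°-squares at pseudo-random grid positions (one permutation of
all positions per trial) and synthesizes per-cell fluorescence traces: a
flash falling inside a cell's Gaussian receptive field evokes a transient
during the flash (ON), after flash offset (OFF), or both, scaled by the
spatial RF profile at the flash position, plus i.i.d. Gaussian noise.

The transient is a raised-cosine bump starting 50 ms after the driving
event and fully decayed before the next baseline window — a fast-
indicator idealization that keeps ON responses confined to the flash
period and OFF responses to the gap, so the generated ground truth maps
cleanly onto the ON/OFF analysis windows.  The slow tail of real calcium
indicators (which bleeds ON responses into the OFF window) is deliberately
not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RFTruth", "SparseNoiseSimConfig", "gen_sparse_noise_session"]


@dataclass(frozen=True)
class RFTruth:
    center_deg: tuple[float, float]  # (azimuth, elevation)
    sd_deg: float
    polarity: str                    # ON | OFF | ON-OFF
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.polarity not in ("ON", "OFF", "ON-OFF"):
            raise ValueError("polarity must be ON, OFF or ON-OFF")
        if self.sd_deg <= 0 or self.amplitude < 0:
            raise ValueError("sd_deg must be > 0 and amplitude >= 0")


@dataclass(frozen=True)
class SparseNoiseSimConfig:
    rf_truth: tuple[RFTruth, ...]
    grid_rows: int = 10
    grid_cols: int = 14
    screen_extent_deg: tuple[float, float] = (116.0, 86.0)  # (width, height)
    flash_s: float = 0.6
    gap_s: float = 0.6
    n_trials: int = 5
    frame_rate: float = 30.0
    noise_sd: float = 0.05
    transient_onset_s: float = 0.05
    transient_dur_s: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.flash_s <= 0 or self.gap_s <= 0 or self.frame_rate <= 0:
            raise ValueError("flash_s, gap_s and frame_rate must be positive")
        if not 1 <= self.n_trials:
            raise ValueError("n_trials must be >= 1")
        w, h = self.screen_extent_deg
        for rf in self.rf_truth:
            az, el = rf.center_deg
            if not (0 <= az <= w and 0 <= el <= h):
                raise ValueError(f"RF center {rf.center_deg} outside screen extent")

    @property
    def pixel_deg(self) -> tuple[float, float]:
        return (
            self.screen_extent_deg[0] / self.grid_cols,
            self.screen_extent_deg[1] / self.grid_rows,
        )


def gen_sparse_noise_session(
    cfg: SparseNoiseSimConfig,
) -> tuple[np.ndarray, pd.DataFrame, tuple[RFTruth, ...]]:
    """Simulate one session.

    Returns ``(traces, schedule, rf_truth)``: traces (n_cells, n_samples)
    at ``cfg.frame_rate``; a schedule table with columns ``row``, ``col``,
    ``trial``, ``onset_s``, ``offset_s`` (one pseudo-random permutation of
    all grid positions per trial); and the ground truth passed through.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pos = cfg.grid_rows * cfg.grid_cols
    period = cfg.flash_s + cfg.gap_s
    rows = []
    t = cfg.gap_s
    for trial in range(cfg.n_trials):
        order = rng.permutation(n_pos)
        for pos in order:
            r, c = divmod(int(pos), cfg.grid_cols)
            rows.append(
                {"row": r, "col": c, "trial": trial, "onset_s": t, "offset_s": t + cfg.flash_s}
            )
            t += period
    schedule = pd.DataFrame(rows)
    total_s = t + cfg.gap_s
    n_samp = int(np.ceil(total_s * cfg.frame_rate)) + 1
    times = np.arange(n_samp) / cfg.frame_rate

    px_w, px_h = cfg.pixel_deg
    traces = np.zeros((len(cfg.rf_truth), n_samp))
    n_k = max(int(round(cfg.transient_dur_s * cfg.frame_rate)), 2)
    kernel = np.hanning(n_k + 2)[1:-1]  # raised-cosine bump, zero at both ends
    lag = int(round(cfg.transient_onset_s * cfg.frame_rate))

    for ci, rf in enumerate(cfg.rf_truth):
        drive_on = np.zeros(n_samp)
        drive_off = np.zeros(n_samp)
        for _, ev in schedule.iterrows():
            az = (ev["col"] + 0.5) * px_w
            el = (ev["row"] + 0.5) * px_h
            g = rf.amplitude * np.exp(
                -((az - rf.center_deg[0]) ** 2 + (el - rf.center_deg[1]) ** 2)
                / (2 * rf.sd_deg**2)
            )
            if g < 1e-4:
                continue
            i_on = int(round(ev["onset_s"] * cfg.frame_rate))
            i_off = int(round(ev["offset_s"] * cfg.frame_rate))
            if rf.polarity in ("ON", "ON-OFF"):
                drive_on[min(i_on + lag, n_samp - 1)] += g
            if rf.polarity in ("OFF", "ON-OFF"):
                drive_off[min(i_off + lag, n_samp - 1)] += g
        tr = np.convolve(drive_on + drive_off, kernel)[:n_samp]
        if cfg.noise_sd > 0:
            tr = tr + rng.normal(0, cfg.noise_sd, n_samp)
        traces[ci] = tr

    _ = times  # samples are implicitly at frame_rate; kept for clarity
    return traces, schedule, cfg.rf_truth
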