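"""Grating stimulus protocol: geometry, timing and trial schedule.

The standard protocol shows white-black gratings moving in 8 directions
(45° spacing) at 3 speeds on the retina.  The grating has a 40° spatial
period (1200 μm at 30 μm/°) and each presentation lasts 4 cycles, so
duration, speed and temporal frequency are locked together:

    temporal_freq = speed / spatial_period
    duration      = n_cycles / temporal_freq

giving 12 / 4 / 2 s at 400 / 1200 / 2400 μm/s (0.33 / 1 / 2 Hz).
Stimulus angles on the screen are corrected for the 20° tilt between the
mouse eye's main axis and the screen's horizontal axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StimulusProtocol", "UM_PER_DEGREE"]

UM_PER_DEGREE = 30.0  # μm on the retina per degree of visual angle


@dataclass(frozen=True)
class StimulusProtocol:
    directions: tuple[float, ...] = tuple(float(d) for d in range(0, 360, 45))
    speeds_um_s: tuple[float, ...] = (400.0, 1200.0, 2400.0)
    spatial_period_um: float = 1200.0
    n_cycles: float = 4.0
    interstim_s: float = 4.0
    n_trials: int = 4
    eye_axis_offset_deg: float = 20.0
    shuffle_order: bool = True
    order_seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_period_um <= 0 or self.n_cycles <= 0:
            raise ValueError("spatial_period_um and n_cycles must be positive")
        if any(s <= 0 for s in self.speeds_um_s):
            raise ValueError("speeds must be positive")
        if self.interstim_s < 0 or self.n_trials < 1:
            raise ValueError("interstim_s must be >= 0 and n_trials >= 1")
        angles = np.asarray(self.directions)
        if ((angles < 0) | (angles >= 360)).any():
            raise ValueError("directions must lie in [0, 360)")

    @property
    def n_stimuli(self) -> int:
        return len(self.directions) * len(self.speeds_um_s)

    def temporal_freq(self, speed: float) -> float:
        return speed / self.spatial_period_um

    def stim_duration(self, speed: float) -> float:
        return self.n_cycles / self.temporal_freq(speed)

    @property
    def stim_durations_s(self) -> tuple[float, ...]:
        return tuple(self.stim_duration(s) for s in self.speeds_um_s)

    def schedule(self) -> pd.DataFrame:
        """Onset/offset table, one row per presentation.

        Presentations run trial-by-trial over all speed × direction
        combinations.  With ``shuffle_order`` (default) the 24 stimuli are
        presented in a fresh pseudo-random order each trial, deterministic
        under ``order_seed``; otherwise sequentially (speeds slow to fast,
        directions in listed order).  Columns: ``trial``, ``speed``,
        ``direction``, ``onset_s``, ``offset_s``.
        """
        combos = [
            (speed, direction)
            for speed in self.speeds_um_s
            for direction in self.directions
        ]
        rng = np.random.default_rng(self.order_seed)
        rows = []
        t = self.interstim_s
        for trial in range(self.n_trials):
            order = rng.permutation(len(combos)) if self.shuffle_order else range(len(combos))
            for k in order:
                speed, direction = combos[k]
                dur = self.stim_duration(speed)
                rows.append(
                    {
                        "trial": trial,
                        "speed": speed,
                        "direction": direction,
                        "onset_s": t,
                        "offset_s": t + dur,
                    }
                )
                t += dur + self.interstim_s
        return pd.DataFrame(rows)

    @property
    def total_duration_s(self) -> float:
        per_trial = sum(
            (self.stim_duration(s) + self.interstim_s) * len(self.directions)
            for s in self.speeds_um_s
        )
        return self.interstim_s + per_trial * self.n_trials
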