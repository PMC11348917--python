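"""Sparse-noise receptive-field mapping with shuffle significance.

White squares (8° on average) are flashed for 0.6 s at pseudo-random grid
positions on a black background covering 116° × 86° of visual space, with
0.6 s gaps.  Per grid position, trial responses are aligned at flash
onset, interpolated to 33 Hz, averaged and smoothed with a 150 ms running
mean.  The ON amplitude is the signed extremum (max or min, whichever is
larger in magnitude) during the flash after subtracting the 200–75 ms
pre-onset baseline; the OFF amplitude the analogous extremum between
flashes against the 200–75 ms pre-offset baseline; ±75 ms around on- and
offset are excluded to avoid filtering artifacts.

Significance uses a trial-shuffle control: the map statistic is the
maximum Pearson correlation of the map with itself shifted by one pixel
in any of the 8 directions (horizontal, vertical, oblique); position
labels are permuted within trials (10⁴ shuffles by default), the full
map pipeline is recomputed on each permutation, and the p-value is the
add-one-smoothed fraction of shuffled statistics at least as large.

A significant map is smoothed by a 3×3 running average; the receptive
field is the 8-connected region above half the filtered maximum that
contains the maximum, its area the region's pixel count times the pixel
area, its position the intensity-weighted center of mass.  For cells
significant in both polarities, region and center are computed on the sum
of both filtered maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RFMapPair",
    "ReceptiveField",
    "RetinotopicConfig",
    "event_aligned_maps",
    "map_shift_correlation",
    "shuffle_significance",
    "rf_from_map",
    "retinotopic_map",
]

ALIGN_RATE_HZ = 33.0
SMOOTH_S = 0.150
BASELINE_WINDOW_S = (0.200, 0.075)  # before onset / offset
EDGE_EXCLUDE_S = 0.075
PIXEL_DEG = 8.0
PRE_S = 0.25  # aligned window starts this long before flash onset


@dataclass
class RFMapPair:
    """ON/OFF amplitude maps on the stimulus grid, with shuffle p-values.

    ``segments`` keeps the aligned, interpolated, smoothed single-trial
    traces (n_positions, n_trials, n_samples) so the shuffle control can
    re-run the identical map pipeline on permuted position labels.
    """

    on_map: np.ndarray   # (rows, cols)
    off_map: np.ndarray
    p_on: float = 1.0
    p_off: float = 1.0
    n_trials: int = 0
    segments: np.ndarray | None = field(default=None, repr=False)
    t_rel: np.ndarray | None = field(default=None, repr=False)
    flash_s: float = 0.6
    gap_s: float = 0.6


@dataclass
class ReceptiveField:
    significant: bool
    polarity: str              # ON | OFF | ON-OFF | none
    region: np.ndarray | None  # boolean mask on the grid
    area_deg2: float
    center_deg: tuple[float, float] | None  # (azimuth, elevation)


@dataclass(frozen=True)
class RetinotopicConfig:
    mask_um: float = 300.0
    sigma_um: float = 75.0

    def __post_init__(self) -> None:
        if self.sigma_um <= 0 or self.mask_um <= 0:
            raise ValueError("sigma_um and mask_um must be positive")


def _amplitudes(
    avg: np.ndarray, t_rel: np.ndarray, flash_s: float, gap_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """ON/OFF signed-extremum amplitudes from averaged traces (..., n_samp)."""
    on_base = (t_rel >= -BASELINE_WINDOW_S[0]) & (t_rel <= -BASELINE_WINDOW_S[1])
    on_win = (t_rel >= EDGE_EXCLUDE_S) & (t_rel <= flash_s - EDGE_EXCLUDE_S)
    off_base = (t_rel >= flash_s - BASELINE_WINDOW_S[0]) & (t_rel <= flash_s - BASELINE_WINDOW_S[1])
    off_win = (t_rel >= flash_s + EDGE_EXCLUDE_S) & (t_rel <= flash_s + gap_s - EDGE_EXCLUDE_S)

    def extremum(win_mask: np.ndarray, base_mask: np.ndarray) -> np.ndarray:
        base = avg[..., base_mask].mean(axis=-1) if base_mask.any() else 0.0
        w = avg[..., win_mask] - np.asarray(base)[..., None]
        hi, lo = w.max(axis=-1), w.min(axis=-1)
        return np.where(np.abs(hi) >= np.abs(lo), hi, lo)

    return extremum(on_win, on_base), extremum(off_win, off_base)


def event_aligned_maps(
    trace: np.ndarray,
    schedule: pd.DataFrame,
    grid_shape: tuple[int, int],
    frame_rate: float,
) -> RFMapPair:
    """Per-position ON/OFF response amplitudes from one cell's trace.

    ``schedule`` needs columns ``row``, ``col``, ``trial``, ``onset_s``,
    ``offset_s``.  Flash and gap durations are taken from the schedule's
    medians.  Raises when any grid position has zero trials.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    trace = np.asarray(trace, dtype=float)
    rows, cols = grid_shape
    n_pos = rows * cols
    sched = schedule.sort_values("onset_s").reset_index(drop=True)
    flash_s = float(np.median(sched["offset_s"] - sched["onset_s"]))
    gap_s = float(np.median(np.diff(sched["onset_s"]))) - flash_s
    smooth = max(int(round(SMOOTH_S * ALIGN_RATE_HZ)), 1)
    t_rel = np.arange(-PRE_S, flash_s + gap_s, 1.0 / ALIGN_RATE_HZ)
    src_t = np.arange(len(trace)) / frame_rate

    per_pos: dict[int, list[np.ndarray]] = {i: [] for i in range(n_pos)}
    for _, r in sched.iterrows():
        pos = int(r["row"]) * cols + int(r["col"])
        seg = np.interp(t_rel + float(r["onset_s"]), src_t, trace)
        seg = ndimage.uniform_filter1d(seg, size=smooth, mode="nearest")
        per_pos[pos].append(seg)
    n_trials = min(len(v) for v in per_pos.values())
    if n_trials == 0:
        empty = [i for i, v in per_pos.items() if not v]
        raise ValueError(f"grid positions with zero trials: {empty[:10]}")
    segments = np.array([per_pos[i][:n_trials] for i in range(n_pos)])
    on_amp, off_amp = _amplitudes(segments.mean(axis=1), t_rel, flash_s, gap_s)
    return RFMapPair(
        on_map=on_amp.reshape(rows, cols),
        off_map=off_amp.reshape(rows, cols),
        n_trials=n_trials,
        segments=segments,
        t_rel=t_rel,
        flash_s=flash_s,
        gap_s=gap_s,
    )


def map_shift_correlation(map2d: np.ndarray) -> float:
    """Maximum Pearson correlation of a map with its 8 one-pixel shifts.

    Correlations are computed on the overlapping sub-grid with both copies
    mean-centered; a constant map has statistic 0.
    """
    m = np.asarray(map2d, dtype=float)
    best = 0.0
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            a = m[max(dy, 0) : m.shape[0] + min(dy, 0), max(dx, 0) : m.shape[1] + min(dx, 0)]
            b = m[max(-dy, 0) : m.shape[0] + min(-dy, 0), max(-dx, 0) : m.shape[1] + min(-dx, 0)]
            av, bv = a.ravel() - a.mean(), b.ravel() - b.mean()
            denom = np.sqrt((av**2).sum() * (bv**2).sum())
            if denom > 0:
                best = max(best, float((av * bv).sum() / denom))
    return best


def shuffle_significance(
    maps: RFMapPair,
    n_shuffles: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Trial-shuffle p-values for the ON and OFF maps.

    Position labels of the aligned single-trial traces are permuted
    independently within each trial; the trial average, amplitude
    extraction and shift-correlation statistic are recomputed per shuffle.
    Returns ``(p_on, p_off)``.
    """
    if maps.segments is None or maps.t_rel is None:
        raise ValueError("maps must carry aligned single-trial segments")
    if maps.n_trials < 2:
        raise ValueError("shuffle control needs >= 2 trials")
    rng = np.random.default_rng(seed)
    segs = maps.segments  # (n_pos, n_tr, n_samp)
    n_pos, n_tr, n_samp = segs.shape
    shape = maps.on_map.shape
    obs_on = map_shift_correlation(maps.on_map)
    obs_off = map_shift_correlation(maps.off_map)
    count_on = count_off = 0
    batch = max(1, int(2e7 / (n_pos * n_tr * n_samp)))
    done = 0
    segs_t = np.ascontiguousarray(segs.transpose(1, 0, 2))  # (n_tr, n_pos, n_samp)
    while done < n_shuffles:
        b = min(batch, n_shuffles - done)
        perm = np.argsort(rng.random((b, n_tr, n_pos)), axis=-1)
        shuffled = segs_t[np.arange(n_tr)[None, :, None], perm]  # (b, tr, pos, samp)
        avg = shuffled.mean(axis=1)  # (b, n_pos, n_samp)
        on_amp, off_amp = _amplitudes(avg, maps.t_rel, maps.flash_s, maps.gap_s)
        for k in range(b):
            if map_shift_correlation(on_amp[k].reshape(shape)) >= obs_on:
                count_on += 1
            if map_shift_correlation(off_amp[k].reshape(shape)) >= obs_off:
                count_off += 1
        done += b
    return (
        float((1 + count_on) / (1 + n_shuffles)),
        float((1 + count_off) / (1 + n_shuffles)),
    )


def rf_from_map(
    maps: RFMapPair,
    pixel_deg: float = PIXEL_DEG,
    grid_origin_deg: tuple[float, float] = (0.0, 0.0),
    alpha: float = 0.05,
) -> ReceptiveField:
    """Receptive-field region, area and center from significant maps.

    The map (or, for ON-OFF cells, the sum of both filtered maps) is
    smoothed by a 3×3 running average with shrink-at-border normalization;
    the field is the 8-connected above-half-max region containing the
    maximum.  ``center_deg`` is (azimuth, elevation) with columns mapping
    to azimuth via ``grid_origin_deg + pixel_deg * index``.
    """
    sig_on = maps.p_on < alpha
    sig_off = maps.p_off < alpha
    if not (sig_on or sig_off):
        return ReceptiveField(False, "none", None, 0.0, None)
    filt_on = _box3(maps.on_map)
    filt_off = _box3(maps.off_map)
    if sig_on and sig_off:
        polarity, m = "ON-OFF", filt_on + filt_off
    elif sig_on:
        polarity, m = "ON", filt_on
    else:
        polarity, m = "OFF", filt_off
    peak = np.unravel_index(np.argmax(m), m.shape)
    half = m[peak] / 2.0
    above = m > half
    lab, _ = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    region = lab == lab[peak]
    area = float(region.sum()) * pixel_deg**2
    ys, xs = np.nonzero(region)
    w = m[region]
    az = grid_origin_deg[0] + pixel_deg * float(np.average(xs, weights=w))
    el = grid_origin_deg[1] + pixel_deg * float(np.average(ys, weights=w))
    return ReceptiveField(True, polarity, region, area, (az, el))


def _box3(m: np.ndarray) -> np.ndarray:
    """3×3 mean filter averaging only in-grid pixels (no padding bias)."""
    num = ndimage.uniform_filter(m, size=3, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones_like(m), size=3, mode="constant", cval=0.0)
    return num / den


def retinotopic_map(
    positions_um: np.ndarray,
    values: np.ndarray,
    grid_y_um: np.ndarray,
    grid_x_um: np.ndarray,
    cfg: RetinotopicConfig = RetinotopicConfig(),
) -> np.ndarray:
    """Gaussian-weighted interpolation of per-cell values over tissue space.

    Each cell contributes a 2D Gaussian weight (σ = 75 μm, truncated to a
    300 × 300 μm mask) centered at its position; the map holds the
    weighted mean of ``values`` at each coordinate and NaN where no cell
    contributes.
    """
    pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
    vals = np.asarray(values, dtype=float)
    if len(pos) == 0 or len(vals) == 0:
        raise ValueError("no significant cells to interpolate")
    gy, gx = np.meshgrid(np.asarray(grid_y_um), np.asarray(grid_x_um), indexing="ij")
    num = np.zeros_like(gy, dtype=float)
    den = np.zeros_like(gy, dtype=float)
    half = cfg.mask_um / 2.0
    for (py, px), v in zip(pos, vals):
        dy, dx = gy - py, gx - px
        w = np.exp(-(dy**2 + dx**2) / (2 * cfg.sigma_um**2))
        w[(np.abs(dy) > half) | (np.abs(dx) > half)] = 0.0
        num += w * v
        den += w
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out
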