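"""Calcium-imaging tuning analysis for drifting-grating sessions.

The stages mirror a standard two-photon workflow: movie preprocessing
(bidirectional line-phase and rigid motion correction, 500-ms moving
average), ROI detection seeded on a local-correlation image, per-stimulus
response extraction with pre-onset baselining, circular-variance
direction/orientation selectivity with trial-permutation significance,
suppressed-by-contrast classification, and a fixed category hierarchy
(DS > OS > DS_neg > OS_neg > SbC > broad) that assigns each cell a unique
label.

Selectivity indices are the resultant lengths of the tuning vector built
from positive (P) or negative (N) response amplitudes over the 8 stimulus
directions θ_i (negative amplitudes set to zero first):

    DSI = |Σ A_i e^{iθ_i}| / Σ A_i        OSI = |Σ A_i e^{i2θ_i}| / Σ A_i

with the preferred direction (orientation) the complex phase (half-phase)
of the population vector, corrected for the 20° tilt between the eye's
main axis and the screen horizontal.  An index is forced to zero when the
corresponding response SNR is ≤ 2.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .protocol import StimulusProtocol

__all__ = [
    "Roi",
    "ResponseMatrix",
    "SpeedIndices",
    "TuningResult",
    "preprocess_movie",
    "local_correlation_image",
    "segment_rois",
    "roi_trace",
    "extract_responses",
    "selectivity_indices",
    "permutation_significance",
    "classify_sbc",
    "categorize",
    "analyze_tuning",
    "match_rois",
]

SNR_GATE = 2.5
DSI_THRESHOLD = 0.3
BROAD_THRESHOLD = 0.15
ALPHA = 0.05


@dataclass
class Roi:
    """One segmented region with its local-background pixel set."""

    pixels: np.ndarray            # (n, 2) array of (row, col)
    centroid: tuple[float, float]  # (row, col), pixels
    kind: str = "unassigned"      # soma | dendrite | unassigned
    background_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.pixels) < 1:
            raise ValueError("ROI must contain at least one pixel")
        if self.background_pixels is not None and len(self.background_pixels):
            a = {tuple(p) for p in np.asarray(self.pixels)}
            b = {tuple(p) for p in np.asarray(self.background_pixels)}
            if a & b:
                raise ValueError("background pixels overlap the ROI")


@dataclass
class ResponseMatrix:
    """Per-stimulus response amplitudes for one ROI.

    ``P``/``N``/``mean_resp``/``baselines`` are (n_speeds, n_directions)
    arrays; ``segments[speed]`` keeps the per-trial baseline-subtracted
    stimulus-period traces (n_directions, n_trials, n_samples) needed for
    permutation tests.
    """

    speeds: tuple[float, ...]
    directions: tuple[float, ...]
    P: np.ndarray
    N: np.ndarray
    mean_resp: np.ndarray
    baselines: np.ndarray
    F0: float
    baseline_sd: float
    frame_rate: float
    filter_samples: int
    segments: dict[float, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def snr(self) -> float:
        peak = max(np.abs(self.P).max(), np.abs(self.N).max())
        return _safe_ratio(peak, self.baseline_sd)

    def snr_pos(self, speed: float | None = None) -> float:
        P = self.P if speed is None else self.P[self.speeds.index(speed)]
        return _safe_ratio(np.clip(P, 0, None).max(), self.baseline_sd)

    def snr_neg(self, speed: float | None = None) -> float:
        N = self.N if speed is None else self.N[self.speeds.index(speed)]
        return _safe_ratio(np.clip(N, 0, None).max(), self.baseline_sd)


def _safe_ratio(num: float, den: float) -> float:
    if den == 0:
        return float("inf") if num > 0 else 0.0
    return float(num / den)


@dataclass
class SpeedIndices:
    """Selectivity indices at one grating speed."""

    speed: float
    dsi: float
    osi: float
    dsi_neg: float
    osi_neg: float
    preferred_direction: float   # deg, eye-axis corrected; NaN when undefined
    preferred_orientation: float  # deg in [0, 180)


@dataclass
class TuningResult:
    dsi: float
    osi: float
    dsi_neg: float
    osi_neg: float
    p_ds: float
    p_os: float
    p_ds_neg: float
    p_os_neg: float
    preferred_direction: float
    preferred_orientation: float
    sbc: bool
    pct_suppressed: float
    category: str
    best_speed_pos: float
    best_speed_neg: float
    per_speed: list[SpeedIndices] = field(default_factory=list)


# ---------------------------------------------------------------------------
# movie preprocessing and segmentation
# ---------------------------------------------------------------------------

def preprocess_movie(
    movie: np.ndarray,
    frame_rate: float,
    correct_bidirectional: bool = True,
    motion_correct: bool = True,
    filter_ms: float = 500.0,
    max_shift: int = 10,
) -> np.ndarray:
    """Line-phase correction, rigid registration and temporal smoothing.

    The bidirectional line-phase offset is estimated once from the
    time-average image (cross-correlation of even against odd lines) and
    removed by shifting odd lines.  Rigid motion is estimated per frame
    against the median image by the correlation peak.  Finally a centered
    moving average of ``filter_ms`` is applied along time.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if movie.ndim != 3:
        raise ValueError("movie must be 3D (t, y, x)")
    out = np.asarray(movie, dtype=float).copy()

    if correct_bidirectional and out.shape[1] >= 2:
        mean_img = out.mean(axis=0)
        offset = _line_phase_offset(mean_img, max_shift)
        if offset != 0:
            out[:, 1::2, :] = np.roll(out[:, 1::2, :], -offset, axis=-1)

    if motion_correct and out.shape[0] >= 2:
        ref = np.median(out, axis=0)
        for t in range(out.shape[0]):
            dy, dx = _register_translation(ref, out[t], max_shift)
            if dy or dx:
                out[t] = np.roll(np.roll(out[t], dy, axis=0), dx, axis=1)

    size = max(int(round(filter_ms / 1000.0 * frame_rate)), 1)
    if size > 1:
        out = ndimage.uniform_filter1d(out, size=size, axis=0, mode="nearest")
    return out


def _line_phase_offset(img: np.ndarray, max_shift: int) -> int:
    even, odd = img[0::2], img[1::2]
    n = min(len(even), len(odd))
    a = even[:n].mean(axis=0) - even[:n].mean()
    b = odd[:n].mean(axis=0) - odd[:n].mean()
    if np.allclose(a, 0) or np.allclose(b, 0):
        return 0
    vals = {s: float(np.dot(a, np.roll(b, -s))) for s in range(-max_shift, max_shift + 1)}
    best = max(vals, key=vals.get)
    # only correct when the offset clearly beats zero shift (structureless
    # images would otherwise pick an arbitrary spurious offset)
    if vals[best] <= vals[0] * 1.02:
        return 0
    return best


def _register_translation(ref: np.ndarray, img: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (dy, dx) shift maximizing correlation of ``img`` to ``ref``."""
    f = np.fft.rfft2(ref) * np.conj(np.fft.rfft2(img))
    cc = np.fft.irfft2(f, s=ref.shape)
    cy, cx = np.unravel_index(np.argmax(_mask_shifts(cc, max_shift)), cc.shape)
    dy = cy if cy <= ref.shape[0] // 2 else cy - ref.shape[0]
    dx = cx if cx <= ref.shape[1] // 2 else cx - ref.shape[1]
    return int(dy), int(dx)


def _mask_shifts(cc: np.ndarray, max_shift: int) -> np.ndarray:
    out = np.full_like(cc, -np.inf)
    m = min(max_shift, min(cc.shape) // 2)
    out[: m + 1, : m + 1] = cc[: m + 1, : m + 1]
    out[: m + 1, -m:] = cc[: m + 1, -m:]
    out[-m:, : m + 1] = cc[-m:, : m + 1]
    out[-m:, -m:] = cc[-m:, -m:]
    return out


def local_correlation_image(movie: np.ndarray) -> np.ndarray:
    """Mean Pearson correlation of each pixel's time series with its 8 neighbors.

    Constant pixels contribute zero correlation.  A single-frame movie has
    no defined correlation and raises.
    """
    if movie.ndim != 3:
        raise ValueError("movie must be 3D (t, y, x)")
    if movie.shape[0] < 2:
        raise ValueError("local correlation undefined for a single-frame movie")
    x = np.asarray(movie, dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, x / sd, 0.0)
    h, w = z.shape[1:]
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            ys = slice(max(dy, 0), h + min(dy, 0))
            xs = slice(max(dx, 0), w + min(dx, 0))
            ys2 = slice(max(-dy, 0), h + min(-dy, 0))
            xs2 = slice(max(-dx, 0), w + min(-dx, 0))
            r = (z[:, ys, xs] * z[:, ys2, xs2]).mean(axis=0)
            acc[ys, xs] += r
            cnt[ys, xs] += 1
    return acc / cnt


def segment_rois(
    movie: np.ndarray,
    corr_image: np.ndarray,
    um_per_px: float = 1.0,
    seed_floor: float = 0.3,
    f_seed: float = 0.5,
    bg_margin: float = 0.1,
    bg_radius_um: float = 15.0,
    n_bg_pixels: int = 5,
    max_pixels: int = 400,
) -> list[Roi]:
    """Correlation-seeded region growing.

    Seeds are local maxima of the correlation image above ``seed_floor``.
    A region grows 8-connected while the pixel correlation exceeds
    ``max(f_seed * seed_value, background_level + bg_margin)``, where the
    background level is the mean correlation of the ``n_bg_pixels`` darkest
    pixels (by mean intensity) within ``bg_radius_um`` of the seed.
    """
    mean_img = np.asarray(movie, dtype=float).mean(axis=0)
    h, w = corr_image.shape
    claimed = np.zeros((h, w), dtype=bool)
    seeds = _local_maxima(corr_image, seed_floor)
    rois: list[Roi] = []
    radius_px = bg_radius_um / um_per_px
    for sy, sx in seeds:
        if claimed[sy, sx]:
            continue
        bg_pix = _darkest_within(mean_img, (sy, sx), radius_px, n_bg_pixels, exclude=None)
        bg_level = float(corr_image[bg_pix[:, 0], bg_pix[:, 1]].mean()) if len(bg_pix) else 0.0
        thr = max(f_seed * corr_image[sy, sx], bg_level + bg_margin)
        region = _grow(corr_image, (sy, sx), thr, claimed, max_pixels)
        if len(region) == 0:
            continue
        claimed[region[:, 0], region[:, 1]] = True
        centroid = (float(region[:, 0].mean()), float(region[:, 1].mean()))
        bg = _darkest_within(mean_img, centroid, radius_px, n_bg_pixels, exclude=region)
        rois.append(Roi(region, centroid, background_pixels=bg))
    return rois


def _local_maxima(img: np.ndarray, floor: float) -> list[tuple[int, int]]:
    mx = ndimage.maximum_filter(img, size=3, mode="nearest")
    ys, xs = np.nonzero((img == mx) & (img > floor))
    order = np.argsort(img[ys, xs])[::-1]
    return [(int(ys[i]), int(xs[i])) for i in order]


def _darkest_within(
    mean_img: np.ndarray,
    center: tuple[float, float],
    radius_px: float,
    n: int,
    exclude: np.ndarray | None,
) -> np.ndarray:
    h, w = mean_img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    within = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
    if exclude is not None and len(exclude):
        within[exclude[:, 0], exclude[:, 1]] = False
    ys, xs = np.nonzero(within)
    if len(ys) == 0:
        return np.empty((0, 2), dtype=int)
    order = np.argsort(mean_img[ys, xs])[:n]
    return np.stack([ys[order], xs[order]], axis=1)


def _grow(
    img: np.ndarray, seed: tuple[int, int], thr: float, claimed: np.ndarray, max_pixels: int
) -> np.ndarray:
    h, w = img.shape
    if img[seed] < thr or claimed[seed]:
        return np.empty((0, 2), dtype=int)
    stack = [seed]
    seen = {seed}
    region = []
    while stack and len(region) < max_pixels:
        y, x = stack.pop()
        region.append((y, x))
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if (ny, nx) in seen or not (0 <= ny < h and 0 <= nx < w):
                    continue
                if not claimed[ny, nx] and img[ny, nx] >= thr:
                    seen.add((ny, nx))
                    stack.append((ny, nx))
    return np.array(region, dtype=int)


def roi_trace(movie: np.ndarray, roi: Roi, subtract_background: bool = True) -> np.ndarray:
    """Mean ROI time series with local-background subtraction."""
    tr = movie[:, roi.pixels[:, 0], roi.pixels[:, 1]].mean(axis=1)
    if subtract_background and roi.background_pixels is not None and len(roi.background_pixels):
        bg = movie[:, roi.background_pixels[:, 0], roi.background_pixels[:, 1]].mean(axis=1)
        tr = tr - bg
    return tr


# ---------------------------------------------------------------------------
# response extraction and selectivity
# ---------------------------------------------------------------------------

def extract_responses(
    trace: np.ndarray,
    protocol: StimulusProtocol,
    frame_rate: float,
    filter_ms: float = 500.0,
    baseline_window: tuple[float, float] = (1.75, 0.25),
) -> ResponseMatrix:
    """Baselined per-stimulus responses from one ROI trace.

    Per stimulus: each trial's pre-onset baseline (median over the
    ``baseline_window`` seconds before onset) is subtracted, the pointwise
    median across trials is taken over the stimulation period, smoothed
    with the ``filter_ms`` moving average; P is its maximum, N the negated
    minimum and ``mean_resp`` its average.  F0 is the smallest of the 24
    per-stimulus average baselines.  The SNR denominator is the SD of the
    trial-median baseline-window samples pooled over stimuli.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    trace = np.asarray(trace, dtype=float)
    sched = protocol.schedule()
    end_needed = sched["offset_s"].max()
    if len(trace) < int(end_needed * frame_rate):
        raise ValueError("trace shorter than the stimulus schedule")
    fsize = max(int(round(filter_ms / 1000.0 * frame_rate)), 1)

    speeds = tuple(protocol.speeds_um_s)
    dirs = tuple(protocol.directions)
    n_sp, n_dir = len(speeds), len(dirs)
    P = np.zeros((n_sp, n_dir))
    N = np.zeros((n_sp, n_dir))
    mean_resp = np.zeros((n_sp, n_dir))
    baselines = np.zeros((n_sp, n_dir))
    segments: dict[float, np.ndarray] = {}
    base_samples = []

    for i, speed in enumerate(speeds):
        n_samp = max(int(round(protocol.stim_duration(speed) * frame_rate)), 1)
        segs = None
        for j, direction in enumerate(dirs):
            rows = sched[(sched["speed"] == speed) & (sched["direction"] == direction)]
            if rows.empty:
                raise ValueError(f"missing stimulus: speed={speed}, direction={direction}")
            trial_segs, trial_bases, trial_base_segs = [], [], []
            for _, r in rows.iterrows():
                on = int(round(r["onset_s"] * frame_rate))
                b0 = max(int(round((r["onset_s"] - baseline_window[0]) * frame_rate)), 0)
                b1 = max(int(round((r["onset_s"] - baseline_window[1]) * frame_rate)), b0 + 1)
                base = float(np.median(trace[b0:b1]))
                trial_bases.append(base)
                trial_base_segs.append(trace[b0:b1] - base)
                seg = trace[on : on + n_samp]
                if len(seg) < n_samp:
                    seg = np.pad(seg, (0, n_samp - len(seg)), mode="edge")
                trial_segs.append(seg - base)
            arr = np.asarray(trial_segs)
            if segs is None:
                segs = np.zeros((n_dir, arr.shape[0], n_samp))
            segs[j] = arr
            med = np.median(arr, axis=0)
            med = ndimage.uniform_filter1d(med, size=fsize, mode="nearest") if fsize > 1 else med
            P[i, j] = max(med.max(), 0.0)   # negative values set to zero:
            N[i, j] = max(-med.min(), 0.0)  # amplitudes feed the index formula
            mean_resp[i, j] = med.mean()
            baselines[i, j] = float(np.mean(trial_bases))
            bmed = np.median(np.asarray(trial_base_segs), axis=0)
            if fsize > 1:
                bmed = ndimage.uniform_filter1d(bmed, size=fsize, mode="nearest")
            base_samples.append(bmed)
        segments[speed] = segs

    baseline_sd = float(np.concatenate(base_samples).std(ddof=0))
    return ResponseMatrix(
        speeds=speeds,
        directions=dirs,
        P=P,
        N=N,
        mean_resp=mean_resp,
        baselines=baselines,
        F0=float(baselines.min()),
        baseline_sd=baseline_sd,
        frame_rate=frame_rate,
        filter_samples=fsize,
        segments=segments,
    )


def _resultant(amps: np.ndarray, directions: np.ndarray, mult: int) -> tuple[float, float]:
    """(index, phase deg) of the circular-variance population vector."""
    amps = np.clip(np.asarray(amps, dtype=float), 0.0, None)
    total = amps.sum()
    if total == 0:
        return 0.0, float("nan")
    vec = np.sum(amps * np.exp(1j * mult * np.deg2rad(directions)))
    r = float(np.abs(vec) / total)
    if r < 1e-12:  # exact cancellation up to floating-point residue
        return 0.0, float("nan")
    return r, float(np.rad2deg(np.angle(vec)))


def selectivity_indices(
    resp: ResponseMatrix,
    speed: float,
    snr_gate: float = SNR_GATE,
    eye_axis_offset_deg: float = 20.0,
    correction_sign: int = -1,
) -> SpeedIndices:
    """Circular-variance DSI/OSI (positive and negative) at one speed.

    Preferred angles are rotated by the eye-axis correction
    (``correction_sign * eye_axis_offset_deg``, default screen→retina by
    subtracting 20°).  Indices are zeroed when the respective SNR ≤ gate.
    """
    i = resp.speeds.index(speed)
    dirs = np.asarray(resp.directions)
    dsi, ang_d = _resultant(resp.P[i], dirs, 1)
    osi, ang_o = _resultant(resp.P[i], dirs, 2)
    dsi_n, _ = _resultant(resp.N[i], dirs, 1)
    osi_n, _ = _resultant(resp.N[i], dirs, 2)
    if resp.snr_pos(speed) <= snr_gate:
        dsi, osi = 0.0, 0.0
    if resp.snr_neg(speed) <= snr_gate:
        dsi_n, osi_n = 0.0, 0.0
    corr = correction_sign * eye_axis_offset_deg
    pref_dir = (ang_d + corr) % 360 if np.isfinite(ang_d) else float("nan")
    pref_ori = ((ang_o / 2.0) + corr) % 180 if np.isfinite(ang_o) else float("nan")
    return SpeedIndices(speed, dsi, osi, dsi_n, osi_n, pref_dir, pref_ori)


def permutation_significance(
    segments: np.ndarray,
    directions: np.ndarray,
    index: str = "DSI",
    sign: str = "pos",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    filter_samples: int = 1,
    batch: int = 200,
) -> float:
    """Trial-permutation p-value for one selectivity index at one speed.

    Whole trials are reassigned at random across direction labels (within
    the speed); the index is recomputed from the permuted trial-median
    responses.  Returns ``(1 + #{permuted ≥ observed}) / (1 + n_perm)``.
    """
    segs = np.asarray(segments, dtype=float)
    n_dir, n_trial, n_samp = segs.shape
    if n_trial < 2:
        raise ValueError("permutation test needs >= 2 trials per stimulus")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    mult = {"DSI": 1, "OSI": 2}[index]
    observed = _index_from_segments(segs[None], directions, mult, sign, filter_samples)[0]
    flat = segs.reshape(n_dir * n_trial, n_samp)
    count = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm = np.argsort(rng.random((b, n_dir * n_trial)), axis=1)
        permuted = flat[perm].reshape(b, n_dir, n_trial, n_samp)
        vals = _index_from_segments(permuted, directions, mult, sign, filter_samples)
        count += int(np.sum(vals >= observed))
        done += b
    return float((1 + count) / (1 + n_perm))


def _index_from_segments(
    segs: np.ndarray, directions: np.ndarray, mult: int, sign: str, filter_samples: int
) -> np.ndarray:
    med = np.median(segs, axis=-2)
    if filter_samples > 1:
        med = ndimage.uniform_filter1d(med, size=filter_samples, axis=-1, mode="nearest")
    amps = med.max(axis=-1) if sign == "pos" else -med.min(axis=-1)
    amps = np.clip(amps, 0.0, None)
    vec = np.abs(np.sum(amps * np.exp(1j * mult * np.deg2rad(directions)), axis=-1))
    tot = amps.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, vec / tot, 0.0)


def classify_sbc(resp: ResponseMatrix) -> tuple[bool, float]:
    """Suppressed-by-contrast rule over all 24 stimuli.

    A stimulus counts as suppressed when its average response falls below
    baseline; the cell is SbC when strictly more than half of the 24
    average responses are suppressed.
    """
    means = resp.mean_resp.ravel()
    pct = float((means < 0).mean())
    return pct > 0.5, pct


def _best_speed(resp: ResponseMatrix, sign: str) -> float:
    amps = resp.P if sign == "pos" else resp.N
    order = np.argsort(resp.speeds)  # tie-break toward the slowest speed
    best, best_val = resp.speeds[order[0]], -np.inf
    for i in order:
        val = float(np.clip(amps[i], 0, None).max())
        if val > best_val:
            best, best_val = resp.speeds[i], val
    return best


def analyze_tuning(
    resp: ResponseMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    snr_gate: float = SNR_GATE,
    eye_axis_offset_deg: float = 20.0,
    alpha: float = ALPHA,
) -> TuningResult:
    """Full per-cell tuning analysis: indices, p-values, SbC, category.

    Speed-independent positive indices come from the speed evoking the
    maximum positive response, negative indices from the speed evoking the
    maximum negative response (ties toward the slowest speed).
    """
    rng = np.random.default_rng(seed)
    dirs = np.asarray(resp.directions)
    per_speed = [
        selectivity_indices(resp, s, snr_gate, eye_axis_offset_deg) for s in resp.speeds
    ]
    sp_pos = _best_speed(resp, "pos")
    sp_neg = _best_speed(resp, "neg")
    idx_pos = per_speed[resp.speeds.index(sp_pos)]
    idx_neg = per_speed[resp.speeds.index(sp_neg)]

    def pval(speed: float, index: str, sign: str, gated_value: float) -> float:
        if gated_value == 0.0:
            return 1.0
        return permutation_significance(
            resp.segments[speed], dirs, index, sign, n_perm, rng, resp.filter_samples
        )

    p_ds = pval(sp_pos, "DSI", "pos", idx_pos.dsi)
    p_os = pval(sp_pos, "OSI", "pos", idx_pos.osi)
    p_ds_neg = pval(sp_neg, "DSI", "neg", idx_neg.dsi_neg)
    p_os_neg = pval(sp_neg, "OSI", "neg", idx_neg.osi_neg)

    sbc, pct = classify_sbc(resp)
    category = categorize(
        idx_pos.dsi, idx_pos.osi, idx_neg.dsi_neg, idx_neg.osi_neg,
        p_ds, p_os, p_ds_neg, p_os_neg, sbc, alpha=alpha,
    )
    return TuningResult(
        dsi=idx_pos.dsi,
        osi=idx_pos.osi,
        dsi_neg=idx_neg.dsi_neg,
        osi_neg=idx_neg.osi_neg,
        p_ds=p_ds,
        p_os=p_os,
        p_ds_neg=p_ds_neg,
        p_os_neg=p_os_neg,
        preferred_direction=idx_pos.preferred_direction,
        preferred_orientation=idx_pos.preferred_orientation,
        sbc=sbc,
        pct_suppressed=pct,
        category=category,
        best_speed_pos=sp_pos,
        best_speed_neg=sp_neg,
        per_speed=per_speed,
    )


def categorize(
    dsi: float,
    osi: float,
    dsi_neg: float,
    osi_neg: float,
    p_ds: float,
    p_os: float,
    p_ds_neg: float,
    p_os_neg: float,
    sbc: bool,
    dsi_threshold: float = DSI_THRESHOLD,
    broad_threshold: float = BROAD_THRESHOLD,
    alpha: float = ALPHA,
) -> str:
    """Unique category by the fixed hierarchy DS > OS > DS_neg > OS_neg > SbC > broad."""
    if dsi > dsi_threshold and p_ds < alpha:
        return "DS"
    if osi > dsi_threshold and p_os < alpha:
        return "OS"
    if dsi_neg > dsi_threshold and p_ds_neg < alpha:
        return "DS_neg"
    if osi_neg > dsi_threshold and p_os_neg < alpha:
        return "OS_neg"
    if sbc:
        return "SbC"
    if dsi < broad_threshold and osi < broad_threshold:
        return "broad"
    return "none"


# ---------------------------------------------------------------------------
# cross-session ROI matching
# ---------------------------------------------------------------------------

def match_rois(
    sessions: list[dict],
    max_dist_px: float = 3.0,
    max_shift: int = 20,
    selection: str = "best_snr",
) -> list[list[tuple[int, int]]]:
    """Match ROIs of the same imaging region across sessions.

    Each session is a dict with ``image`` (reference 2D image), ``rois``
    (list of :class:`Roi`) and optionally ``snr`` (per-ROI).  Sessions are
    rigidly aligned to the first by the correlation peak; ROIs whose
    aligned centroids fall within ``max_dist_px`` are grouped.  Returns
    groups of ``(session_index, roi_index)``; with ``selection="best_snr"``
    each group is ordered so its first member has the highest SNR.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions to match")
    ref = np.asarray(sessions[0]["image"], dtype=float)
    cents: list[list[tuple[float, float]]] = []
    for s in sessions:
        img = np.asarray(s["image"], dtype=float)
        if img.shape != ref.shape:
            raise ValueError("session images must share a shape")
        dy, dx = _register_translation(ref, img, max_shift)
        cents.append([(r.centroid[0] + dy, r.centroid[1] + dx) for r in s["rois"]])
    if all(len(c) == 0 for c in cents[1:]) and len(cents[0]) == 0:
        raise ValueError("no ROIs in any session")

    groups: list[list[tuple[int, int]]] = [[(0, i)] for i in range(len(cents[0]))]
    for si in range(1, len(sessions)):
        for ri, c in enumerate(cents[si]):
            best_g, best_d = None, max_dist_px
            for g in groups:
                g0_sess, g0_roi = g[0]
                ref_c = cents[g0_sess][g0_roi]
                d = float(np.hypot(ref_c[0] - c[0], ref_c[1] - c[1]))
                if d <= best_d and all(s != si for s, _ in g):
                    best_g, best_d = g, d
            if best_g is not None:
                best_g.append((si, ri))
            else:
                groups.append([(si, ri)])
    matched = [g for g in groups if len(g) > 1]
    if selection == "best_snr":
        for g in matched:
            g.sort(
                key=lambda sr: -float(sessions[sr[0]].get("snr", [0] * 10**6)[sr[1]])
                if len(sessions[sr[0]].get("snr", [])) > sr[1]
                else 0.0
            )
    return matched
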