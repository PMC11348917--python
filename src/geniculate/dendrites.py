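"""Dendrite-versus-soma feature correspondence.

Dendritic compartments imaged in the same plane as their soma are
compared through the 16-dimensional response vector (8 positive + 8
negative amplitudes at the cell's maximum-response speed): Pearson
correlation against the soma, distance-binned summaries, circular
differences of preferred angles, and a mono-exponential decay fit

    y = Δ · exp(−x / λ) + y₀

of selectivity against Euclidean soma distance (a lower bound on dendritic
path length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .tuning import ResponseMatrix, SNR_GATE, _best_speed

__all__ = [
    "CompartmentRecord",
    "ExpFitResult",
    "response_vector_16",
    "soma_dendrite_correlation",
    "binned_stats",
    "exp_decay_fit",
    "angular_difference",
]


@dataclass
class CompartmentRecord:
    """One ROI (soma or dendritic compartment) of a cell."""

    soma_id: str
    compartment_id: str
    distance_um: float          # Euclidean distance to the soma ROI center
    response_vector: np.ndarray  # 16 = 8 positive + 8 negative amplitudes
    snr: float

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise ValueError("distance must be >= 0")
        if len(self.response_vector) != 16:
            raise ValueError("response vector must have 16 entries")


@dataclass
class ExpFitResult:
    delta: float
    lam_um: float
    y0: float
    rss: float
    identifiable: bool  # False when the decay amplitude is ~0 (flat data)


def response_vector_16(resp: ResponseMatrix, speed: float | None = None) -> np.ndarray:
    """8 positive + 8 negative amplitudes at the selected speed.

    Default speed is the one evoking the maximum response, positive or
    negative, over the cell's 24 stimuli.
    """
    if speed is None:
        sp_pos = _best_speed(resp, "pos")
        sp_neg = _best_speed(resp, "neg")
        i_pos, i_neg = resp.speeds.index(sp_pos), resp.speeds.index(sp_neg)
        speed = sp_pos if resp.P[i_pos].max() >= resp.N[i_neg].max() else sp_neg
    i = resp.speeds.index(speed)
    return np.concatenate([resp.P[i], resp.N[i]])


def soma_dendrite_correlation(
    records: list[CompartmentRecord], snr_gate: float = SNR_GATE
) -> pd.DataFrame:
    """Pearson r of each compartment's 16-vector with its soma's.

    The soma is the record at distance 0.  Compartments failing the SNR
    gate are dropped; constant vectors yield NaN with ``flagged=True``.
    """
    somata = [r for r in records if r.distance_um == 0]
    if len(somata) != 1:
        raise ValueError("records must contain exactly one soma (distance 0)")
    soma = somata[0]
    if soma.snr <= snr_gate:
        raise ValueError("soma fails the SNR gate")
    rows = []
    for r in records:
        if r is soma or r.snr <= snr_gate:
            continue
        a, b = np.asarray(soma.response_vector), np.asarray(r.response_vector)
        if np.std(a) == 0 or np.std(b) == 0:
            rows.append((r.compartment_id, r.distance_um, np.nan, True))
        else:
            rows.append((r.compartment_id, r.distance_um, pearsonr(a, b)[0], False))
    return pd.DataFrame(rows, columns=["compartment_id", "distance_um", "r", "flagged"])


def binned_stats(
    values: np.ndarray, distances: np.ndarray, bin_um: float = 50.0
) -> pd.DataFrame:
    """Mean ± SD of ``values`` in distance bins with edges at 0, 50, 100, … μm.

    Empty bins are reported with NaN mean/SD and n = 0.
    """
    values = np.asarray(values, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if len(values) != len(distances):
        raise ValueError("values and distances must have equal length")
    n_bins = int(np.floor(distances.max() / bin_um)) + 1 if len(distances) else 0
    rows = []
    for i in range(n_bins):
        lo, hi = i * bin_um, (i + 1) * bin_um
        m = (distances >= lo) & (distances < hi)
        v = values[m]
        rows.append(
            {
                "bin_lo_um": lo,
                "bin_hi_um": hi,
                "n": int(m.sum()),
                "mean": float(v.mean()) if len(v) else np.nan,
                "sd": float(v.std(ddof=0)) if len(v) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def exp_decay_fit(
    x: np.ndarray,
    y: np.ndarray,
    n_starts: int = 8,
    flat_delta_frac: float = 0.05,
) -> ExpFitResult:
    """Least-squares mono-exponential fit ``y = Δ·exp(−x/λ) + y₀``.

    λ is constrained positive; ``n_starts`` initializations spread over
    the observed distance range guard against local minima.  Flat data
    (fitted |Δ| below ``flat_delta_frac`` of the y-range, or a y-range of
    zero) are flagged unidentifiable in λ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    span = x.max() - x.min()
    if span <= 0:
        raise ValueError("x values must have positive spread")
    yr = y.max() - y.min()
    if yr == 0:
        return ExpFitResult(0.0, float("inf"), float(y[0]), 0.0, False)

    def model(xv, delta, lam, y0):
        return delta * np.exp(-xv / lam) + y0

    best = None
    lam_grid = np.geomspace(max(span / 20, 1e-6), span * 4, n_starts)
    for lam0 in lam_grid:
        try:
            popt, _ = curve_fit(
                model,
                x,
                y,
                p0=[yr * np.sign(y[np.argmin(x)] - y[np.argmax(x)]) or yr, lam0, y.min()],
                bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10_000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError(
            f"exponential fit failed to converge from {n_starts} starts "
            f"(n={len(x)}, x span {span:.3g})"
        )
    (delta, lam, y0), rss = best
    identifiable = abs(delta) >= flat_delta_frac * yr
    return ExpFitResult(float(delta), float(lam), float(y0), rss, identifiable)


def angular_difference(a: float, b: float, mode: str = "direction") -> float:
    """Circular absolute angle difference in degrees.

    ``direction`` works modulo 360 (result in [0, 180]); ``orientation``
    modulo 180 (result in [0, 90]).
    """
    period = {"direction": 360.0, "orientation": 180.0}[mode]
    d = abs((float(a) - float(b)) % period)
    return min(d, period - d)
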