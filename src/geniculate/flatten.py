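"""ChAT-band-referenced flattening and stratification typing of flat-mount stacks.

The two ChAT bands (starburst-amacrine plexus layers) serve as depth
landmarks in the inner plexiform layer.  After detecting both band
surfaces, each image column is remapped to *relative depth*, with the OFF
band at 0 and the ON band at 1, resampled at increments of 0.025.  Ten
strata tile the relative-depth axis at intervals of 0.25 with strata 3
and 7 centered on the OFF and ON bands, i.e. stratum k spans
0.25·(k−3) ± 0.125 for k = 1..10.

RGC dendrites are then summarized as a per-stratum signal profile, and a
rule set calls the morphological type (12, 12_asym, 37, 7, 4, 89, 189)
together with its functional tags (sustained/transient, ON/OFF/ON-OFF,
DS, JAM-B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "DEPTH_STEP",
    "DEPTH_RANGE",
    "N_STRATA",
    "ChatBandSurfaces",
    "FlattenedStack",
    "StratificationProfile",
    "RGCTypeCall",
    "CANONICAL_TAGS",
    "stratum_center",
    "stratum_of_depth",
    "detect_band_probability",
    "extract_band_surfaces",
    "flatten_stack",
    "stratum_colored_projection",
    "stratification_profile",
    "classify_rgc",
]

DEPTH_STEP = 0.025
DEPTH_RANGE = (-0.625, 1.875)  # exactly tiles strata 1..10
N_STRATA = 10


def stratum_center(k: int) -> float:
    """Relative-depth center of stratum k (stratum 3 → 0, stratum 7 → 1)."""
    if not 1 <= k <= N_STRATA:
        raise ValueError("stratum index must lie in 1..10")
    return 0.25 * (k - 3)


def stratum_of_depth(rel_depth: np.ndarray | float) -> np.ndarray | int:
    """Stratum index (1..10) containing a relative depth; clipped at the ends."""
    r = np.asarray(rel_depth, dtype=float)
    k = np.floor((r - (stratum_center(1) - 0.125)) / 0.25).astype(int) + 1
    k = np.clip(k, 1, N_STRATA)
    return int(k) if np.isscalar(rel_depth) else k


@dataclass
class ChatBandSurfaces:
    """Single-valued z-coordinate maps of the two ChAT bands over xy."""

    off_z: np.ndarray  # (y, x); stratum-3 band
    on_z: np.ndarray   # (y, x); stratum-7 band

    def __post_init__(self) -> None:
        if self.off_z.shape != self.on_z.shape:
            raise ValueError("band surfaces must share a shape")
        d = self.on_z - self.off_z
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("band surfaces cross or touch")


@dataclass
class FlattenedStack:
    """Intensity resampled on the relative-depth grid (depth, y, x)."""

    data: np.ndarray
    depths: np.ndarray  # relative-depth sample positions, step 0.025

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.depths):
            raise ValueError("depth axis mismatch")
        steps = np.diff(self.depths)
        if not np.allclose(steps, DEPTH_STEP, atol=1e-9):
            raise ValueError("relative-depth sampling step must be 0.025")


@dataclass
class StratificationProfile:
    """Per-stratum dendritic signal fractions and derived flags for one cell."""

    fractions: np.ndarray  # length 10, sums to 1
    cofasciculation_3: bool
    cofasciculation_7: bool
    asymmetry_index: float

    def __post_init__(self) -> None:
        if len(self.fractions) != N_STRATA:
            raise ValueError("need 10 per-stratum fractions")
        if abs(float(np.sum(self.fractions)) - 1.0) > 1e-6:
            raise ValueError("stratum fractions must sum to 1")


@dataclass
class RGCTypeCall:
    type_label: str  # 12 | 12_asym | 37 | 7 | 4 | 89 | 189 | other
    kinetics: str    # sustained | transient
    polarity: str    # ON | OFF | ON-OFF
    is_ds: bool
    is_jamb: bool


# canonical functional tags of the seven called types, by the stratum rules
from .specialization import TypeTags  # noqa: E402

CANONICAL_TAGS: dict[str, TypeTags] = {
    "12": TypeTags("sustained", "OFF"),
    "12_asym": TypeTags("sustained", "OFF", is_jamb=True),
    "37": TypeTags("transient", "ON-OFF", is_ds=True),
    "7": TypeTags("transient", "ON", is_ds=True),
    "4": TypeTags("transient", "OFF"),
    "89": TypeTags("sustained", "ON"),
    "189": TypeTags("sustained", "ON-OFF"),
}


def detect_band_probability(
    stack: np.ndarray,
    detector: Callable[[np.ndarray], np.ndarray] | None = None,
    band_sigma_planes: float = 1.5,
    xy_sigma_px: float = 2.0,
) -> np.ndarray:
    """Per-voxel ChAT-band membership probability in [0, 1].

    The default classical detector matched-filters the z-profile of each
    column with a Gaussian band-width kernel after light xy smoothing, then
    min-max normalizes to [0, 1].  Any callable mapping a 3D stack to a
    probability stack of the same shape (e.g. a trained network) can be
    substituted via ``detector``.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("ChAT stack must be 3D (z, y, x)")
    if detector is not None:
        prob = np.asarray(detector(stack), dtype=float)
        if prob.shape != stack.shape:
            raise ValueError("detector must preserve the stack shape")
        return np.clip(prob, 0.0, 1.0)
    smoothed = ndimage.gaussian_filter(stack, sigma=(0, xy_sigma_px, xy_sigma_px))
    resp = ndimage.gaussian_filter1d(smoothed, sigma=band_sigma_planes, axis=0)
    lo, hi = resp.min(), resp.max()
    if hi == lo:
        return np.zeros_like(resp)
    return (resp - lo) / (hi - lo)


def extract_band_surfaces(
    prob: np.ndarray,
    min_separation_planes: int = 3,
    smooth_px: int = 5,
    peak_floor: float = 0.2,
    max_ambiguous_frac: float = 0.2,
) -> ChatBandSurfaces:
    """Two smooth single-valued band surfaces from a probability stack.

    Per xy column the two strongest z-peaks at least
    ``min_separation_planes`` apart are taken; columns where fewer than two
    peaks rise above ``peak_floor`` are marked ambiguous and filled from
    neighbors, but the extraction fails if more than
    ``max_ambiguous_frac`` of columns are ambiguous.  Surfaces are
    smoothed by a running median over xy and the OFF band is the surface
    with smaller z (flip the stack beforehand for the opposite acquisition
    direction).
    """
    prob = np.asarray(prob, dtype=float)
    if prob.ndim != 3:
        raise ValueError("probability stack must be 3D (z, y, x)")
    nz, ny, nx = prob.shape
    z1 = np.full((ny, nx), np.nan)
    z2 = np.full((ny, nx), np.nan)
    for y in range(ny):
        for x in range(nx):
            col = prob[:, y, x]
            peaks, props = signal.find_peaks(
                col, height=peak_floor, distance=min_separation_planes
            )
            if len(peaks) < 2:
                continue
            top = peaks[np.argsort(props["peak_heights"])[::-1][:2]]
            z1[y, x], z2[y, x] = sorted(top)
    ambiguous = np.isnan(z1)
    frac = float(ambiguous.mean())
    if frac > max_ambiguous_frac:
        ys, xs = np.nonzero(ambiguous)
        raise ValueError(
            f"fewer than two band ridges in {frac:.0%} of columns "
            f"(first ambiguous columns: {list(zip(ys[:5].tolist(), xs[:5].tolist()))})"
        )
    if ambiguous.any():
        z1 = _fill_nan_nearest(z1)
        z2 = _fill_nan_nearest(z2)
    if smooth_px > 1:
        z1 = ndimage.median_filter(z1, size=smooth_px, mode="nearest")
        z2 = ndimage.median_filter(z2, size=smooth_px, mode="nearest")
    if not (z2 > z1).all():
        raise ValueError("candidate band surfaces cross after smoothing")
    return ChatBandSurfaces(off_z=z1, on_z=z2)


def _fill_nan_nearest(a: np.ndarray) -> np.ndarray:
    mask = np.isnan(a)
    if not mask.any():
        return a
    idx = ndimage.distance_transform_edt(mask, return_distances=False, return_indices=True)
    return a[tuple(idx)]


def flatten_stack(
    stack: np.ndarray,
    surfaces: ChatBandSurfaces,
    depth_range: tuple[float, float] = DEPTH_RANGE,
    step: float = DEPTH_STEP,
) -> FlattenedStack:
    """Resample a stack into band-relative depth coordinates.

    Each column is mapped linearly so the OFF band sits at relative depth
    0 and the ON band at 1, with linear extrapolation beyond the bands,
    and interpolated at ``step`` increments over ``depth_range`` (default
    covers strata 1–10).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (z, y, x)")
    if surfaces.off_z.shape != stack.shape[1:]:
        raise ValueError("surfaces must be defined over the stack's xy grid")
    gap = surfaces.on_z - surfaces.off_z
    if np.any(gap == 0):
        raise ValueError("off_z equals on_z somewhere; flattening undefined")
    n = int(round((depth_range[1] - depth_range[0]) / step)) + 1
    depths = depth_range[0] + step * np.arange(n)
    ny, nx = stack.shape[1:]
    zc = surfaces.off_z[None, :, :] + depths[:, None, None] * gap[None, :, :]
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    coords = np.stack(
        [zc, np.broadcast_to(yy, zc.shape), np.broadcast_to(xx, zc.shape)]
    )
    data = ndimage.map_coordinates(stack, coords, order=1, mode="constant", cval=0.0)
    return FlattenedStack(data=data, depths=depths)


def stratum_colored_projection(
    flattened: FlattenedStack, intensity_threshold: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-colored maximum projection.

    Returns ``(labels, max_intensity)`` where each xy pixel is labeled with
    the stratum (1..10) of its brightest relative-depth sample; pixels at
    or below ``intensity_threshold`` are labeled 0 (background).
    """
    data = flattened.data
    arg = data.argmax(axis=0)
    mx = data.max(axis=0)
    labels = stratum_of_depth(flattened.depths[arg])
    labels = np.where(mx > intensity_threshold, labels, 0)
    return labels, mx


def stratification_profile(
    flattened: FlattenedStack,
    cell_mask: np.ndarray,
    chat_flattened: FlattenedStack | None = None,
    soma_xy: tuple[float, float] | None = None,
    band_fraction_threshold: float = 0.25,
    chat_overlap_threshold: float = 0.5,
    chat_intensity_frac: float = 0.25,
) -> StratificationProfile:
    """Per-stratum signal fractions, cofasciculation flags and asymmetry.

    ``cell_mask`` is a 2D xy mask of one cell's dendrites.  Cofasciculation
    with band k (3 or 7) requires at least ``band_fraction_threshold`` of
    the cell's signal within ±0.125 of the band center *and* — when a
    flattened ChAT channel is supplied — that at least
    ``chat_overlap_threshold`` of that in-band signal lies on columns with
    above-threshold ChAT intensity.  The asymmetry index is the distance
    from soma to the dendritic center of mass, normalized by arbor radius.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != flattened.data.shape[1:]:
        raise ValueError("cell_mask must match the stack's xy grid")
    if not mask.any():
        raise ValueError("empty cell mask")
    sub = flattened.data[:, mask]  # (depth, n_pixels)
    sub = np.clip(sub, 0.0, None)
    total = sub.sum()
    if total == 0:
        raise ValueError("cell mask contains no signal")
    strata = stratum_of_depth(flattened.depths)
    fractions = np.array([sub[strata == k].sum() / total for k in range(1, N_STRATA + 1)])

    cofasc = {}
    for k in (3, 7):
        in_band = np.abs(flattened.depths - stratum_center(k)) <= 0.125
        band_frac = float(sub[in_band].sum() / total)
        has_band = band_frac >= band_fraction_threshold
        if has_band and chat_flattened is not None:
            chat_band = np.clip(chat_flattened.data[in_band], 0.0, None).sum(axis=0)
            thr = chat_intensity_frac * chat_band.max()  # plexus covers the field; cut above noise floor
            band_signal = sub[in_band].sum(axis=0)  # per masked pixel
            on_chat = chat_band[mask] > thr
            denom = band_signal.sum()
            overlap = float(band_signal[on_chat].sum() / denom) if denom > 0 else 0.0
            has_band = overlap >= chat_overlap_threshold
        cofasc[k] = has_band

    asym = 0.0
    if soma_xy is not None:
        weights = sub.sum(axis=0)
        ys, xs = np.nonzero(mask)
        com_y = float(np.average(ys, weights=weights))
        com_x = float(np.average(xs, weights=weights))
        dists = np.hypot(ys - soma_xy[0], xs - soma_xy[1])
        radius = float(np.quantile(dists, 0.95))
        if radius > 0:
            asym = float(np.hypot(com_y - soma_xy[0], com_x - soma_xy[1]) / radius)
    return StratificationProfile(fractions, cofasc[3], cofasc[7], asym)


def classify_rgc(
    profile: StratificationProfile,
    dominant_threshold: float = 0.10,
    minor_branch_threshold: float = 0.15,
    asymmetry_threshold: float = 0.3,
) -> RGCTypeCall:
    """Rule-based type call from a stratification profile.

    Rule order: 37 (co-fasciculating with both bands), 7 (ON band with
    only minor stratum-3 branches), 12_asym (strata 1–2 with JAM-B-like
    asymmetry), 12, 189 (strata 1–2 plus 8–10), 89, 4, other.  The
    *dominant set* holds every stratum with at least ``dominant_threshold``
    of the cell's signal.  Deterministic and total: anything unmatched
    falls through to ``other``.
    """
    f = profile.fractions
    dom = {k for k in range(1, N_STRATA + 1) if f[k - 1] >= dominant_threshold}
    inner = set(range(3, 8))          # strata 3..7 → transient
    outer = {1, 2, 8, 9, 10}          # → sustained
    frac = lambda ks: float(sum(f[k - 1] for k in ks))

    if profile.cofasciculation_3 and profile.cofasciculation_7:
        label = "37"
    elif profile.cofasciculation_7 and f[2] < minor_branch_threshold:
        label = "7"
    elif dom and dom <= {1, 2} and profile.asymmetry_index > asymmetry_threshold:
        label = "12_asym"
    elif dom and dom <= {1, 2}:
        label = "12"
    elif dom & {1, 2} and dom & {8, 9, 10}:
        label = "189"
    elif dom and dom <= {8, 9, 10}:
        label = "89"
    elif dom == {4}:
        label = "4"
    else:
        label = "other"

    if dom and dom <= inner:
        kinetics = "transient"
    elif dom and dom <= outer:
        kinetics = "sustained"
    else:
        kinetics = "transient" if frac(inner) >= frac(outer) else "sustained"
    if dom and dom <= set(range(6, 11)):
        polarity = "ON"
    elif dom and dom <= set(range(1, 5)):
        polarity = "OFF"
    else:
        polarity = "ON-OFF"
    return RGCTypeCall(
        type_label=label,
        kinetics=kinetics,
        polarity=polarity,
        is_ds=label in ("37", "7"),
        is_jamb=label == "12_asym",
    )
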