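"""Specialization statistics for presynaptic RGC-type clusters.

A rabies tracing from one postsynaptic dLGN neuron yields a *cluster* of
presynaptic retinal ganglion cells, each assigned a morphological type
label and an eye of origin.  The central question is whether a cluster is
*specialized* — drawn from fewer types than expected if presynaptic
partners were sampled at random from a reference type distribution.

The null model is an occupancy problem: draw ``n`` cells i.i.d. from the
reference distribution and count distinct type labels.  The Monte-Carlo
mean and SD of that count give the specialization Z score

    z = (observed distinct types − expected) / SD.

``z < −2`` flags a cluster as specialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PresynapticCluster",
    "ReferenceConfig",
    "OccupancyNull",
    "SpecializationResult",
    "PreferenceIndices",
    "TypeTags",
    "reference_distribution",
    "occupancy_null",
    "occupancy_moments",
    "specialization_z",
    "specialization_boundary",
    "pooling_experiment",
    "dominance",
    "preference_indices",
    "binocular_randomness_test",
]

ECCENTRICITY_MAX = 115.0  # degrees, optic nerve (0) to far periphery


@dataclass
class PresynapticCluster:
    """Traced presynaptic RGCs for one postsynaptic cell.

    ``cells`` holds one row per traced RGC with columns ``cell_id``,
    ``eye`` (``contra``/``ipsi``) and ``type_label``; an optional
    ``eccentricity_deg`` column must lie within [0, 115].
    """

    postsynaptic_id: str
    cells: pd.DataFrame
    label_set: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        required = {"cell_id", "eye", "type_label"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cluster table missing columns: {sorted(missing)}")
        bad_eye = set(self.cells["eye"].unique()) - {"contra", "ipsi"}
        if bad_eye:
            raise ValueError(f"eye labels must be contra/ipsi, got {sorted(bad_eye)}")
        if self.label_set is not None:
            unknown = set(self.cells["type_label"]) - set(self.label_set)
            if unknown:
                raise ValueError(f"type labels outside declared set: {sorted(unknown)}")
        if "eccentricity_deg" in self.cells.columns:
            ecc = self.cells["eccentricity_deg"].dropna()
            if ((ecc < 0) | (ecc > ECCENTRICITY_MAX)).any():
                raise ValueError("eccentricity_deg outside [0, 115]")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def observed_types(self) -> int:
        return int(self.cells["type_label"].nunique())

    def type_counts(self) -> pd.Series:
        return self.cells["type_label"].value_counts()

    def by_eye(self, eye: str) -> "PresynapticCluster":
        sub = self.cells[self.cells["eye"] == eye].reset_index(drop=True)
        return PresynapticCluster(f"{self.postsynaptic_id}:{eye}", sub, self.label_set)


@dataclass(frozen=True)
class ReferenceConfig:
    """Weighted mixture of the TCN- and interneuron-presynaptic type distributions.

    The reference distribution is proportional to
    ``p_tcn * w_tcn * n_tcn + p_in * w_in * n_in`` where ``n_tcn`` / ``n_in``
    are the mean numbers of presynaptic RGCs per thalamocortical neuron /
    interneuron and the weights reflect the relative prevalence of the two
    postsynaptic classes.
    """

    p_tcn: Mapping[str, float]
    p_in: Mapping[str, float]
    w_tcn: float = 0.8
    w_in: float = 0.2
    n_tcn: float = 20.0
    n_in: float = 96.0

    def __post_init__(self) -> None:
        for name, val in (("w_tcn", self.w_tcn), ("w_in", self.w_in),
                          ("n_tcn", self.n_tcn), ("n_in", self.n_in)):
            if val < 0 or (name.startswith("n") and val <= 0):
                raise ValueError(f"{name} must be positive, got {val}")
        for name, dist in (("p_tcn", self.p_tcn), ("p_in", self.p_in)):
            _validate_distribution(dist, name)


@dataclass
class OccupancyNull:
    """Monte-Carlo null distribution of the distinct-type count."""

    n_cells: int
    expected_types: float
    sd_types: float
    n_reps: int
    n_types: int
    samples: np.ndarray | None = field(default=None, repr=False)


@dataclass
class SpecializationResult:
    observed_types: int
    z_score: float
    null: OccupancyNull


@dataclass
class PreferenceIndices:
    """Functional composition indices of one cluster (or per-eye sub-cluster)."""

    st_index: float        # (#sustained − #transient) / (#sustained + #transient)
    onoff_index: float     # (#ON·1 + #OFF·0 + #ON-OFF·0.5) / total
    ds_ratio: float        # DS RGCs / all classified, JAM-B included
    ds_ratio_no_jamb: float
    dominance: float


@dataclass(frozen=True)
class TypeTags:
    """Functional tags attached to an RGC type label."""

    kinetics: str          # "sustained" | "transient"
    polarity: str          # "ON" | "OFF" | "ON-OFF"
    is_ds: bool = False
    is_jamb: bool = False


def _validate_distribution(dist: Mapping[str, float], name: str = "distribution") -> None:
    probs = np.asarray(list(dist.values()), dtype=float)
    if len(probs) == 0:
        raise ValueError(f"{name} is empty")
    if (probs < 0).any():
        raise ValueError(f"{name} has negative probabilities")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {probs.sum():.12g})")


def reference_distribution(cfg: ReferenceConfig) -> dict[str, float]:
    """Weighted-average reference type distribution.

    Raises if the two component distributions are not defined over the same
    label set.
    """
    labels_tcn, labels_in = set(cfg.p_tcn), set(cfg.p_in)
    if labels_tcn != labels_in:
        raise ValueError(
            "p_tcn and p_in must share one label set; "
            f"difference: {sorted(labels_tcn ^ labels_in)}"
        )
    labels = sorted(labels_tcn)
    raw = np.array(
        [cfg.p_tcn[t] * cfg.w_tcn * cfg.n_tcn + cfg.p_in[t] * cfg.w_in * cfg.n_in
         for t in labels]
    )
    out = raw / raw.sum()
    return dict(zip(labels, out))


def occupancy_moments(probs: Sequence[float], n_cells: int) -> tuple[float, float]:
    """Closed-form mean and SD of the distinct-type count.

    For ``n`` i.i.d. draws from type probabilities ``p_t``, with
    ``q_t = (1 − p_t)^n`` the probability type ``t`` is missed,

        E[K]   = Σ_t (1 − q_t)
        Var[K] = Σ_t q_t(1 − q_t) + Σ_{t≠u} [(1 − p_t − p_u)^n − q_t q_u]
    """
    p = np.asarray(probs, dtype=float)
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    q = (1.0 - p) ** n_cells
    mean = float(np.sum(1.0 - q))
    pair = (1.0 - p[:, None] - p[None, :]) ** n_cells - q[:, None] * q[None, :]
    np.fill_diagonal(pair, 0.0)
    var = float(np.sum(q * (1.0 - q)) + pair.sum())
    return mean, float(np.sqrt(max(var, 0.0)))


def occupancy_null(
    dist: Mapping[str, float] | Sequence[float],
    n_cells: int,
    n_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
    keep_samples: bool = False,
) -> OccupancyNull:
    """Monte-Carlo null of the distinct-type count among ``n_cells`` draws.

    ``dist`` may be a label→probability mapping or a bare probability
    vector.  The per-replicate type multiplicities are multinomial, which
    is distributionally identical to counting distinct labels among
    ``n_cells`` independent draws.
    """
    if isinstance(dist, Mapping):
        probs = np.asarray(list(dist.values()), dtype=float)
    else:
        probs = np.asarray(dist, dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be nonnegative and sum to 1")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        counts = np.zeros(n_reps, dtype=np.int64)
    else:
        draws = rng.multinomial(n_cells, probs, size=n_reps)
        counts = (draws > 0).sum(axis=1)
    return OccupancyNull(
        n_cells=int(n_cells),
        expected_types=float(counts.mean()),
        sd_types=float(counts.std(ddof=0)),
        n_reps=int(n_reps),
        n_types=len(probs),
        samples=counts if keep_samples else None,
    )


def specialization_z(
    cluster: PresynapticCluster | int, null: OccupancyNull
) -> SpecializationResult:
    """Specialization Z score of a cluster against its occupancy null.

    ``cluster`` may be a :class:`PresynapticCluster` or directly the
    observed distinct-type count.  The null must have been built for the
    cluster's classified-cell count.
    """
    observed = cluster if isinstance(cluster, (int, np.integer)) else cluster.observed_types
    if null.sd_types == 0:
        raise ValueError("degenerate null: SD of distinct-type count is zero")
    z = (observed - null.expected_types) / null.sd_types
    return SpecializationResult(int(observed), float(z), null)


def specialization_boundary(null: OccupancyNull, z_threshold: float = -2.0) -> int:
    """Smallest distinct-type count *not* flagged as specialized.

    A cluster is flagged specialized when its Z score falls below
    ``z_threshold``; the boundary is the smallest integer count ``k`` with
    ``(k − expected)/SD ≥ z_threshold``.
    """
    if null.sd_types == 0:
        raise ValueError("degenerate null: SD of distinct-type count is zero")
    k = int(np.ceil(z_threshold * null.sd_types + null.expected_types))
    # guard against floating-point edge: adjust to the exact defining inequality
    while (k - null.expected_types) / null.sd_types < z_threshold:
        k += 1
    while k > 0 and (k - 1 - null.expected_types) / null.sd_types >= z_threshold:
        k -= 1
    return k


def pooling_experiment(
    n_types: int,
    n_cells: int,
    observed_subset: Sequence[int],
    pooling_map: Mapping[int, int] | None = None,
    n_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
    observed_convention: str = "subset_size",
) -> SpecializationResult:
    """Specialization of a fully-specialized subset under optional type pooling.

    Models a cell whose presynaptic pool covers exactly ``observed_subset``
    of ``n_types`` equally frequent types.  With ``pooling_map`` (a
    surjection original→pooled label), both the observed subset and the
    null label set are pooled before computing the Z score.

    ``observed_convention``:

    - ``"subset_size"`` (default): the observed count is the number of
      distinct pooled labels covering the subset — the convention that a
      large cluster realizes its full specialized repertoire.
    - ``"sampled"``: the observed count is instead the mean distinct pooled
      label count among ``n_cells`` draws restricted to the subset.
    """
    labels = list(range(1, n_types + 1))
    subset = list(observed_subset)
    if not subset:
        raise ValueError("observed_subset is empty")
    if not set(subset) <= set(labels):
        raise ValueError("observed_subset not within the label set")
    if pooling_map is None:
        pooling_map = {t: t for t in labels}
    if not set(labels) <= set(pooling_map):
        raise ValueError("pooling_map must cover every original label")

    pooled_labels = sorted(set(pooling_map[t] for t in labels))
    # pooling k-to-1 of a uniform distribution stays uniform over pooled labels
    pooled_sizes = pd.Series([pooling_map[t] for t in labels]).value_counts()
    probs = (pooled_sizes.loc[pooled_labels] / n_types).to_numpy()

    rng = np.random.default_rng(seed)
    null = occupancy_null(probs, n_cells, n_reps=n_reps, seed=rng)

    if observed_convention == "subset_size":
        observed = len(set(pooling_map[t] for t in subset))
    elif observed_convention == "sampled":
        sub_probs = np.full(len(subset), 1.0 / len(subset))
        draws = rng.multinomial(n_cells, sub_probs, size=n_reps)
        pooled_of_subset = np.array([pooling_map[t] for t in subset])
        uniq = np.unique(pooled_of_subset)
        present = np.zeros((n_reps, len(uniq)), dtype=bool)
        for j, u in enumerate(uniq):
            present[:, j] = draws[:, pooled_of_subset == u].sum(axis=1) > 0
        observed = int(round(present.sum(axis=1).mean()))
    else:
        raise ValueError(f"unknown observed_convention {observed_convention!r}")
    return specialization_z(observed, null)


def dominance(cluster: PresynapticCluster | Mapping[str, int] | pd.Series) -> float:
    """Relative abundance of the most prevalent type (modal count / total)."""
    if isinstance(cluster, PresynapticCluster):
        counts = cluster.type_counts()
    else:
        counts = pd.Series(dict(cluster), dtype=float)
    total = counts.sum()
    if total == 0 or len(counts) == 0:
        raise ValueError("dominance undefined for an empty cluster")
    return float(counts.max() / total)


def preference_indices(
    cluster: PresynapticCluster, tag_map: Mapping[str, TypeTags]
) -> PreferenceIndices:
    """Sustained/transient, ON/OFF and DS composition of a cluster.

    ``st_index`` runs from −1 (all transient) to +1 (all sustained);
    ``onoff_index`` from 0 (all OFF) to 1 (all ON), ON-OFF counting 0.5.
    ``ds_ratio`` is the fraction of DS types among all classified cells and
    is reported both including and excluding JAM-B-like (asymmetric
    strata-1/2) cells.
    """
    labels = cluster.cells["type_label"]
    unknown = set(labels) - set(tag_map)
    if unknown:
        raise ValueError(f"type labels without tags: {sorted(unknown)}")
    tags = labels.map(tag_map)
    n = len(tags)
    if n == 0:
        raise ValueError("empty cluster")
    n_sus = sum(t.kinetics == "sustained" for t in tags)
    n_tra = sum(t.kinetics == "transient" for t in tags)
    st = (n_sus - n_tra) / (n_sus + n_tra) if (n_sus + n_tra) else float("nan")
    pol_score = {"ON": 1.0, "OFF": 0.0, "ON-OFF": 0.5}
    onoff = sum(pol_score[t.polarity] for t in tags) / n
    n_ds = sum(t.is_ds or t.is_jamb for t in tags)
    n_ds_no_jamb = sum(t.is_ds and not t.is_jamb for t in tags)
    return PreferenceIndices(
        st_index=float(st),
        onoff_index=float(onoff),
        ds_ratio=n_ds / n,
        ds_ratio_no_jamb=n_ds_no_jamb / n,
        dominance=dominance(cluster),
    )


def binocular_randomness_test(
    eye_counts: Sequence[tuple[int, int]],
    p_contra: float = 0.87,
    n_reps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo test of binomial eye-of-origin mixing.

    ``eye_counts`` holds ``(n_contra, n_ipsi)`` per postsynaptic cell.  The
    test statistic is the summed absolute contra−ipsi difference; its null
    distribution is simulated by drawing each cell's contralateral count
    from Binomial(total, ``p_contra``) at matched totals.  Returns the
    Monte-Carlo p-value ``(1 + #{sim ≥ obs}) / (1 + n_reps)``.
    """
    counts = np.asarray(eye_counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty input")
    if counts.ndim != 2 or counts.shape[1] != 2 or (counts < 0).any():
        raise ValueError("eye_counts must be nonnegative (n_contra, n_ipsi) pairs")
    if not 0 < p_contra < 1:
        # degenerate binomials are deterministic; handle exactly
        if p_contra in (0.0, 1.0):
            totals = counts.sum(axis=1)
            contra_exp = totals if p_contra == 1.0 else np.zeros_like(totals)
            obs = np.abs(counts[:, 0] - counts[:, 1]).sum()
            sim = np.abs(2 * contra_exp - totals).sum()
            return 1.0 if sim >= obs else 1.0 / (1 + n_reps)
        raise ValueError("p_contra must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    observed = int(np.abs(counts[:, 0] - counts[:, 1]).sum())
    sim_contra = rng.binomial(totals[None, :], p_contra, size=(n_reps, len(totals)))
    sim_stat = np.abs(2 * sim_contra - totals[None, :]).sum(axis=1)
    return float((1 + np.sum(sim_stat >= observed)) / (1 + n_reps))
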