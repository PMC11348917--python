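"""Simulated presynaptic RGC clusters.

Draws a cluster of traced cells from a configurable type distribution,
optionally restricted to a subset of allowed types (a specialized
cluster), with eye of origin drawn Bernoulli(p_contra).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ..specialization import PresynapticCluster, _validate_distribution

__all__ = ["ClusterSimConfig", "gen_clusters"]


@dataclass(frozen=True)
class ClusterSimConfig:
    """Ground-truth description of one simulated cluster.

    ``type_probs`` maps each type label to its draw probability; ``subset``
    restricts draws to the listed types (probabilities renormalized within
    the subset).  ``p_contra`` is the probability a traced cell originates
    from the contralateral eye; the empirical average across tracings
    is 0.87.
    """

    type_probs: dict[str, float]
    n_cells: int
    subset: tuple[str, ...] | None = None
    p_contra: float = 0.87
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_distribution(self.type_probs, "type_probs")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.p_contra <= 1.0:
            raise ValueError("p_contra must lie in [0, 1]")
        if self.subset is not None:
            if len(self.subset) == 0:
                raise ValueError("subset must not be empty")
            unknown = set(self.subset) - set(self.type_probs)
            if unknown:
                raise ValueError(f"subset labels not in type_probs: {sorted(unknown)}")

    @staticmethod
    def uniform(n_types: int, n_cells: int, **kwargs) -> "ClusterSimConfig":
        labels = [f"t{i:02d}" for i in range(1, n_types + 1)]
        return ClusterSimConfig(
            type_probs={t: 1.0 / n_types for t in labels}, n_cells=n_cells, **kwargs
        )


def gen_clusters(
    cfg: ClusterSimConfig, postsynaptic_id: str = "sim"
) -> PresynapticCluster:
    """Draw one cluster under the configured type distribution.

    Deterministic under ``cfg.seed``; the resulting table carries one row
    per cell with ``cell_id``, ``eye`` and ``type_label`` columns.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = list(cfg.type_probs)
    probs = np.array([cfg.type_probs[t] for t in labels])
    if cfg.subset is not None:
        keep = np.array([t in set(cfg.subset) for t in labels])
        probs = probs * keep
        if probs.sum() == 0:
            raise ValueError("subset has zero total probability")
        probs = probs / probs.sum()
    idx = rng.choice(len(labels), size=cfg.n_cells, p=probs)
    eyes = np.where(rng.random(cfg.n_cells) < cfg.p_contra, "contra", "ipsi")
    table = pd.DataFrame(
        {
            "cell_id": [f"{postsynaptic_id}_c{i:04d}" for i in range(cfg.n_cells)],
            "eye": eyes,
            "type_label": [labels[i] for i in idx],
        }
    )
    return PresynapticCluster(postsynaptic_id, table, label_set=tuple(labels))
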