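"""Reference-network labelling of LEiDA states.

Each state centroid (a signed N-vector over ROIs) is compared with the seven
canonical Yeo resting-state networks by Pearson correlation against each
network's binary ROI-membership column.  Significance uses a Bonferroni-style
threshold alpha = 0.01 / k over the k states; a state with no significant
network is flagged as a global-coherence candidate (all phases aligned, no
subnetwork detaching from the global mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .leida import StateRepertoire

__all__ = [
    "YEO7_NETWORKS",
    "ReferenceNetworks",
    "StateLabel",
    "load_membership",
    "yeo7_reference",
    "alpha_for_k",
    "label_states",
]

YEO7_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)


@dataclass(frozen=True)
class ReferenceNetworks:
    """N x 7 binary ROI-by-network membership with ROI and network names."""

    membership: np.ndarray
    network_names: tuple[str, ...]
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        object.__setattr__(self, "membership", m.astype(float))
        if m.ndim != 2 or m.shape[1] != len(self.network_names):
            raise ValueError("membership must be N x len(network_names)")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("membership entries must be binary")
        empty = np.nonzero(m.sum(axis=0) == 0)[0]
        if empty.size:
            raise ValueError(f"network {self.network_names[empty[0]]!r} has no ROIs")


@dataclass(frozen=True)
class StateLabel:
    """Spatial-correlation profile of one state against the reference networks."""

    state_index: int
    r: np.ndarray
    p: np.ndarray
    significant: tuple[str, ...]
    alpha: float
    network_names: tuple[str, ...]

    @property
    def is_global_candidate(self) -> bool:
        return not self.significant

    @property
    def best_network(self) -> str:
        return self.network_names[int(np.argmax(self.r))]


def load_membership(path) -> ReferenceNetworks:
    """Read a delimited roi_name,network table into :class:`ReferenceNetworks`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    unknown = set(df["network"]) - set(YEO7_NETWORKS)
    if unknown:
        raise ValueError(f"unknown network labels {sorted(unknown)}; expected {YEO7_NETWORKS}")
    membership = np.stack(
        [(df["network"] == net).to_numpy(dtype=float) for net in YEO7_NETWORKS], axis=1
    )
    return ReferenceNetworks(
        membership=membership,
        network_names=YEO7_NETWORKS,
        roi_names=tuple(df["roi_name"]),
    )


def yeo7_reference() -> ReferenceNetworks:
    """The packaged heuristic 105-ROI Yeo-7 membership fixture."""
    ref = resources.files("musicstates.data").joinpath("yeo7_membership.tsv")
    with resources.as_file(ref) as path:
        return load_membership(path)


def alpha_for_k(k: int) -> float:
    """Per-comparison significance threshold 0.01 / k for a k-state repertoire."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 0.01 / k


def label_states(repertoire: StateRepertoire, ref: ReferenceNetworks) -> list[StateLabel]:
    """Correlate every state centroid with every reference network.

    Uses the full signed centroid against each binary membership column
    (two-sided Pearson p); the significant set collects networks with
    p < 0.01/k.  1-based state indices match :class:`StateSequence` labels.
    """
    centroids = np.asarray(repertoire.centroids, dtype=float)
    if centroids.shape[1] != ref.membership.shape[0]:
        raise ValueError(
            f"centroid length {centroids.shape[1]} does not match "
            f"{ref.membership.shape[0]} reference ROIs"
        )
    alpha = alpha_for_k(repertoire.k)
    labels = []
    for s, centroid in enumerate(centroids, start=1):
        if np.ptp(centroid) == 0:
            raise ValueError(f"state {s}: zero-variance centroid cannot be correlated")
        r = np.empty(len(ref.network_names))
        p = np.empty(len(ref.network_names))
        for j in range(len(ref.network_names)):
            r[j], p[j] = stats.pearsonr(centroid, ref.membership[:, j])
        significant = tuple(
            name for name, pj in zip(ref.network_names, p) if pj < alpha
        )
        labels.append(
            StateLabel(
                state_index=s,
                r=r,
                p=p,
                significant=significant,
                alpha=alpha,
                network_names=ref.network_names,
            )
        )
    return labels
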