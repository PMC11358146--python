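"""Leading-eigenvector dynamics analysis (LEiDA) of ROI BOLD timeseries.

The pipeline: each ROI signal is demeaned and Hilbert-transformed to an
analytic signal whose angle is the instantaneous BOLD phase theta(t).  At each
volume the dynamic phase-locking matrix dPL(t)_ij = cos(theta_i - theta_j)
captures pairwise phase alignment; its unit leading eigenvector V1(t) (sign
convention: majority of elements negative, so the globally synchronised mode is
all-negative) is a low-dimensional snapshot of the instantaneous connectivity
pattern.  Eigenvectors pooled over subjects are k-means clustered for k in a
candidate range, the Dunn index selects k, and each state is summarised by its
probability of occurrence, mean lifetime and switching probabilities.

Because dPL(t) = C C^T with C = [cos theta, sin theta] (N x 2), the matrix has
rank <= 2 and its leading eigenpair follows exactly from the 2 x 2 Gram matrix
C^T C; :func:`leading_eigenvector_series` uses this closed form while the
generic :func:`leading_eigenvector` runs a dense symmetric eigensolver on any
symmetric matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal
from sklearn.cluster import KMeans

from .schedule import ConditionLabels

__all__ = [
    "RoiTimeseries",
    "PhaseSeries",
    "LeadingEigSeries",
    "StateRepertoire",
    "StateSequence",
    "StateMetrics",
    "DegenerateEigenvectorWarning",
    "compute_phases",
    "phase_locking_matrix",
    "leading_eigenvector",
    "leading_eigenvector_series",
    "pool_and_cluster",
    "dunn_index",
    "state_metrics",
    "condition_metrics",
]

logger = logging.getLogger(__name__)


class DegenerateEigenvectorWarning(UserWarning):
    """Top eigenvalue (near-)degenerate; the reported eigenvector is a tie-break."""


@dataclass(frozen=True)
class RoiTimeseries:
    """T x N BOLD matrix (volumes x regions) for one subject."""

    subject_id: str
    data: np.ndarray
    tr_s: float
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] < 8 or data.shape[1] < 2:
            raise ValueError(
                f"{self.subject_id}: need a T x N matrix with T >= 8, N >= 2, got {data.shape}"
            )
        if np.isnan(data).any():
            raise ValueError(f"{self.subject_id}: timeseries contains missing values")
        if self.roi_names and len(self.roi_names) != data.shape[1]:
            raise ValueError(f"{self.subject_id}: roi_names do not match N={data.shape[1]}")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_rois(self) -> int:
        return int(self.data.shape[1])


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous BOLD phases, T x N, each entry in (-pi, pi]."""

    subject_id: str
    theta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if theta.min() <= -np.pi or theta.max() > np.pi:
            raise ValueError("phases must lie in (-pi, pi]")


@dataclass(frozen=True)
class LeadingEigSeries:
    """Per-volume unit leading eigenvectors of dPL(t) and their eigenvalues."""

    subject_id: str
    v1: np.ndarray
    eigval: np.ndarray

    @property
    def n_volumes(self) -> int:
        return int(self.v1.shape[0])


@dataclass(frozen=True)
class StateRepertoire:
    """Selected k, centroids and the Dunn score of every candidate k."""

    k: int
    centroids: np.ndarray
    dunn_by_k: dict[int, float]
    kmeans_seed: int
    n_restarts: int

    def __post_init__(self) -> None:
        if self.k not in self.dunn_by_k:
            raise ValueError("selected k is outside the searched range")
        best = max(self.dunn_by_k.values())
        if self.dunn_by_k[self.k] < best - 1e-12:
            raise ValueError("selected k does not maximise the Dunn score")


@dataclass(frozen=True)
class StateSequence:
    """Per-volume state assignments (1-based labels in 1..k) for one subject."""

    subject_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=int)
        object.__setattr__(self, "states", states)
        if states.ndim != 1 or states.size == 0:
            raise ValueError("states must be a nonempty 1-D integer sequence")


@dataclass(frozen=True)
class StateMetrics:
    """Occurrence probability, mean lifetime (TRs) and switching matrix.

    ``lifetime_trs[s]`` and ``switching[s, :]`` are NaN ("flagged undefined")
    for states that never occur / never emit a transition.
    """

    subject_id: str
    occurrence: np.ndarray
    lifetime_trs: np.ndarray
    switching: np.ndarray

    @property
    def k(self) -> int:
        return int(self.occurrence.size)


def compute_phases(ts: RoiTimeseries) -> PhaseSeries:
    """Demean each ROI and extract the analytic-signal phase (Hilbert transform)."""
    data = ts.data
    dead = np.nonzero(np.ptp(data, axis=0) == 0)[0]
    if dead.size:
        name = ts.roi_names[dead[0]] if ts.roi_names else f"column {dead[0]}"
        raise ValueError(f"{ts.subject_id}: constant (zero-variance) ROI {name}")
    analytic = scipy.signal.hilbert(data - data.mean(axis=0), axis=0)
    theta = np.angle(analytic)
    theta[theta == -np.pi] = np.pi  # fold the branch cut into (-pi, pi]
    return PhaseSeries(subject_id=ts.subject_id, theta=theta)


def phase_locking_matrix(theta_t: np.ndarray) -> np.ndarray:
    """dPL for one volume: entry (i, j) = cos(theta_i - theta_j)."""
    theta_t = np.asarray(theta_t, dtype=float)
    if theta_t.ndim != 1 or theta_t.size < 2:
        raise ValueError("expected N >= 2 phases for a single timepoint")
    c, s = np.cos(theta_t), np.sin(theta_t)
    return np.outer(c, c) + np.outer(s, s)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Majority-negative sign convention with deterministic tie-breaks."""
    neg = int((v < 0).sum())
    pos = int((v > 0).sum())
    if neg > pos:
        return v
    if pos > neg:
        return -v
    total = v.sum()
    if total > 0:
        return -v
    if total < 0:
        return v
    nz = np.nonzero(v)[0]
    if nz.size and v[nz[0]] > 0:
        return -v
    return v


def leading_eigenvector(m: np.ndarray, degeneracy_tol: float = 1e-9) -> tuple[np.ndarray, float]:
    """Unit leading eigenvector and largest eigenvalue of a symmetric matrix.

    The eigenvector is sign-normalised so that the majority of its elements are
    negative (ties: flip so the element sum is <= 0; a zero sum forces the
    first nonzero element negative).  A top eigenvalue with multiplicity > 1
    within ``degeneracy_tol`` (relative) emits
    :class:`DegenerateEigenvectorWarning`; the deterministic eigensolver output
    is still returned.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    n = m.shape[0]
    lo = max(n - 2, 0)
    w, v = scipy.linalg.eigh(m, subset_by_index=[lo, n - 1])
    top = float(w[-1])
    if n > 1 and abs(top - w[-2]) <= degeneracy_tol * max(1.0, abs(top)):
        warnings.warn(
            f"top eigenvalue {top:.6g} is degenerate (gap {top - w[-2]:.2e}); "
            "eigenvector chosen by deterministic solver tie-break",
            DegenerateEigenvectorWarning,
            stacklevel=2,
        )
    v1 = _fix_sign(v[:, -1] / np.linalg.norm(v[:, -1]))
    return v1, top


def leading_eigenvector_series(
    phases: PhaseSeries, degeneracy_tol: float = 1e-9
) -> LeadingEigSeries:
    """Leading eigenpair of dPL(t) at every volume via the rank-2 closed form."""
    theta = phases.theta
    c, s = np.cos(theta), np.sin(theta)  # T x N each; dPL(t) = [c s][c s]^T
    a = np.einsum("tn,tn->t", c, c)
    b = np.einsum("tn,tn->t", c, s)
    d = np.einsum("tn,tn->t", s, s)
    half_gap = np.sqrt(((a - d) / 2.0) ** 2 + b**2)
    lam = (a + d) / 2.0 + half_gap
    degen = 2.0 * half_gap <= degeneracy_tol * np.maximum(1.0, np.abs(lam))
    if degen.any():
        warnings.warn(
            f"{phases.subject_id}: degenerate leading eigenvalue at "
            f"{int(degen.sum())} volume(s); deterministic tie-break applied",
            DegenerateEigenvectorWarning,
            stacklevel=2,
        )
    # top eigenvector of the 2x2 Gram matrix [[a, b], [b, d]]
    u0 = np.where(np.abs(b) > 1e-300, b, np.where(a >= d, 1.0, 0.0))
    u1 = np.where(np.abs(b) > 1e-300, lam - a, np.where(a >= d, 0.0, 1.0))
    v = c * u0[:, None] + s * u1[:, None]
    norms = np.linalg.norm(v, axis=1)
    norms[norms == 0] = 1.0
    v /= norms[:, None]
    v = np.vstack([_fix_sign(row) for row in v])
    return LeadingEigSeries(subject_id=phases.subject_id, v1=v, eigval=lam)


def dunn_index(points: np.ndarray, labels: np.ndarray, chunk: int = 1024) -> float:
    """Point-based Dunn validity index of a partition.

    Minimum pairwise inter-cluster Euclidean distance divided by the maximum
    intra-cluster diameter.  Returns ``inf`` (with a logged flag) when every
    cluster has zero diameter.  Pairwise distances are accumulated in row
    chunks so pools of several thousand eigenvectors fit in memory.
    """
    x = np.asarray(points, dtype=float)
    codes, counts = np.unique(np.asarray(labels), return_counts=True)
    k = codes.size
    if k < 2:
        raise ValueError("Dunn index needs at least 2 nonempty clusters")
    code_of = {c: i for i, c in enumerate(codes)}
    lab = np.array([code_of[c] for c in np.asarray(labels).ravel()])
    n = x.shape[0]
    sq = np.einsum("ij,ij->i", x, x)
    min_inter = np.full((k, k), np.inf)
    max_intra = np.zeros(k)
    col_masks = [lab == j for j in range(k)]
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        d2 = sq[i0:i1, None] + sq[None, :] - 2.0 * (x[i0:i1] @ x.T)
        np.maximum(d2, 0.0, out=d2)
        rows = lab[i0:i1]
        for j in range(k):
            dj = d2[:, col_masks[j]]
            np.minimum.at(min_inter[:, j], rows, dj.min(axis=1))
            same = rows == j
            if same.any():
                np.maximum.at(max_intra, rows[same], dj[same].max(axis=1))
    diameter = float(np.sqrt(max_intra.max()))
    off = ~np.eye(k, dtype=bool)
    separation = float(np.sqrt(min_inter[off].min()))
    if diameter == 0.0:
        logger.warning("all clusters have zero diameter; Dunn index flagged infinite")
        return np.inf
    return separation / diameter


def pool_and_cluster(
    eigs: list[LeadingEigSeries],
    k_min: int = 5,
    k_max: int = 10,
    seed: int = 0,
    n_restarts: int = 50,
) -> tuple[StateRepertoire, list[StateSequence]]:
    """Pool all subjects' eigenvectors, k-means cluster for each candidate k,
    and keep the k with the highest Dunn index.

    k-means is Euclidean with ``n_restarts`` random initialisations per k
    (best within-cluster sum of squares kept) and a per-k seed derived from
    ``seed``, so repeated calls are bit-identical.  Assignments are split back
    per subject in input order; state labels are 1-based.
    """
    if k_min > k_max or k_min < 2:
        raise ValueError("need 2 <= k_min <= k_max")
    x = np.vstack([e.v1 for e in eigs])
    if x.shape[0] < k_max:
        raise ValueError(f"only {x.shape[0]} eigenvectors pooled; need >= k_max={k_max}")
    ss = np.random.SeedSequence(seed)
    fits: dict[int, KMeans] = {}
    dunn_by_k: dict[int, float] = {}
    for k, child in zip(range(k_min, k_max + 1), ss.spawn(k_max - k_min + 1)):
        km = KMeans(
            n_clusters=k,
            n_init=n_restarts,
            random_state=int(child.generate_state(1)[0]) % (2**31),
            max_iter=300,
        ).fit(x)
        sizes = np.bincount(km.labels_, minlength=k)
        if (sizes == 0).any():
            raise RuntimeError(f"k-means produced an empty cluster at k={k}")
        fits[k] = km
        dunn_by_k[k] = dunn_index(x, km.labels_)
        logger.info("k=%d: Dunn %.4f, inertia %.4f", k, dunn_by_k[k], km.inertia_)
    # highest Dunn wins; ties break toward the smaller (more parsimonious) k
    best_k = min(dunn_by_k, key=lambda k: (-dunn_by_k[k], k))
    km = fits[best_k]
    repertoire = StateRepertoire(
        k=best_k,
        centroids=km.cluster_centers_.copy(),
        dunn_by_k=dunn_by_k,
        kmeans_seed=seed,
        n_restarts=n_restarts,
    )
    sequences = []
    offset = 0
    for e in eigs:
        t = e.n_volumes
        sequences.append(
            StateSequence(subject_id=e.subject_id, states=km.labels_[offset : offset + t] + 1)
        )
        offset += t
    return repertoire, sequences


def _run_lengths(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state, length) of each maximal consecutive run."""
    change = np.nonzero(np.diff(arr) != 0)[0] + 1
    bounds = np.concatenate([[0], change, [arr.size]])
    return arr[bounds[:-1]], np.diff(bounds)


def state_metrics(seq: StateSequence | np.ndarray, k: int, subject_id: str | None = None) -> StateMetrics:
    """The three per-state summaries of a state sequence.

    occurrence(s) = count(s)/T; lifetime(s) = mean length (in TRs) of maximal
    consecutive runs of s; switching(i, j) = transitions i->j between
    consecutive volumes over all transitions out of i (self-transitions count,
    so rows are stochastic).
    """
    if isinstance(seq, StateSequence):
        states, sid = seq.states, seq.subject_id
    else:
        states, sid = np.asarray(seq, dtype=int), subject_id or ""
    if states.min() < 1 or states.max() > k:
        raise ValueError(f"state labels must lie in 1..{k}")
    t = states.size
    occurrence = np.bincount(states - 1, minlength=k) / t
    run_states, run_lens = _run_lengths(states)
    lifetime = np.full(k, np.nan)
    for s in range(k):
        mine = run_states == s + 1
        if mine.any():
            lifetime[s] = run_lens[mine].mean()
    switching = np.full((k, k), np.nan)
    if t > 1:
        counts = np.zeros((k, k))
        np.add.at(counts, (states[:-1] - 1, states[1:] - 1), 1.0)
        out = counts.sum(axis=1)
        rows = out > 0
        switching[rows] = counts[rows] / out[rows, None]
    return StateMetrics(subject_id=sid, occurrence=occurrence, lifetime_trs=lifetime, switching=switching)


def condition_metrics(
    seq: StateSequence, labels: ConditionLabels, condition: str, k: int
) -> StateMetrics:
    """State metrics restricted to the volumes of one song condition.

    Metrics are computed per song (runs truncated at song boundaries) and then
    averaged across all songs of the condition, matching a per-song-type
    analysis.  ``condition`` may be a base valence or a derived
    ``neutral_following_*`` category.
    """
    mask = labels.mask(condition)
    if not mask.any():
        raise ValueError(f"condition {condition!r} has no volumes")
    if labels.n_volumes != seq.states.size:
        raise ValueError("state sequence and condition labels are not aligned")
    per_song = []
    for ev in np.unique(labels.event_index[mask]):
        vols = mask & (labels.event_index == ev)
        per_song.append(state_metrics(seq.states[vols], k, subject_id=seq.subject_id))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN song rows
        occurrence = np.mean([m.occurrence for m in per_song], axis=0)
        lifetime = np.nanmean([m.lifetime_trs for m in per_song], axis=0)
        switching = np.nanmean([m.switching for m in per_song], axis=0)
    return StateMetrics(
        subject_id=seq.subject_id,
        occurrence=occurrence,
        lifetime_trs=lifetime,
        switching=switching,
    )
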