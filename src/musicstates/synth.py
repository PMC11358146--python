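"""Synthetic music-listening cohorts with planted, recoverable structure.

The generator emulates exactly the statistical structure the analysis assumes,
so every pipeline stage has an analytic ground truth:

* **Brain states** — each subject follows a Markov chain over ``planted_k``
  phase-locking states (dwell = 2 TRs + shifted geometric).  At every volume
  all ROIs share a common carrier phase except the active state's community,
  which is anti-phase (shifted by pi); smooth per-ROI phase noise is added and
  the BOLD value is the cosine of the phase, with the pi shift realised as a
  signed envelope whose raised-cosine crossing falls between volumes so the
  sampled signal stays band-limited across switches.  In the noiseless limit
  the leading eigenvector of dPL(t) at every volume is exactly the +/-1
  pattern of the active community, which makes the planted state sequence the
  oracle for clustering and state metrics.
* **Attentional-state tilt** — a per-subject loading biases transitions into a
  designated dorsal-attention-like state, creating between-subject variance in
  its occupancy.
* **Behaviour** — a planted mediation chain: standardized anhedonia
  (MASQ-AD-like, 14..70) loads on the z-scored attentional-state occupancy
  with coefficient ``a_true``; the rating-trace amplitude shrinks with
  standardized anhedonia through ``b_true`` (negative = emotional blunting).
  Residual standard deviations are sqrt(1 - coef^2) on both paths so the
  planted standardized coefficients are exact.  Ratings follow the packaged
  13-piece schedule (+amplitude during happy pieces, -amplitude during sad,
  ~0 during neutral and silence) with Gaussian noise, clipped to [-6, 6].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .leida import RoiTimeseries, StateSequence
from .networks import YEO7_NETWORKS, yeo7_reference
from .schedule import (
    ConditionLabels,
    RatingTrace,
    StimulusSchedule,
    SubjectMeta,
    label_timepoints,
    table1_schedule,
    write_schedule,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "default_centroids",
    "gen_state_timeseries",
    "gen_behaviour",
    "generate_cohort",
    "write_cohort",
    "load_truth",
]

logger = logging.getLogger(__name__)

# anhedonic-depression score location/scale used to map the standardized
# latent onto the 14..70 questionnaire range (cohort mean ~34, SD ~9)
MASQ_MU = 34.0
MASQ_SD = 9.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the canonical cohort scale: 31 subjects, 105 ROIs, 250
    volumes at TR 2 s, a repertoire of 8 planted states (one global-coherence
    mode plus the 7 Yeo network communities), mean dwell of 10 TRs, 0.3 rad
    phase noise, a 0.1 Hz carrier (upper edge of the BOLD band, so each state
    epoch spans about two carrier cycles and instantaneous phase is
    well-defined), and the planted standardized mediation paths a=0.54,
    b=-0.62.
    """

    n_subjects: int = 31
    n_rois: int = 105
    n_volumes: int = 250
    tr_s: float = 2.0
    planted_k: int = 8
    planted_centroids: np.ndarray | None = None
    dwell_mean_trs: float = 10.0
    phase_noise_sd: float = 0.3
    masq_range: tuple[int, int] = (14, 70)
    a_true: float = 0.54
    b_true: float = -0.62
    rating_noise_sd: float = 0.5
    base_amplitude: float = 3.0
    amp_scale: float = 0.35
    dan_bias_scale: float = 1.0
    carrier_freq_hz: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_k < 2:
            raise ValueError("planted_k must be >= 2")
        if self.dwell_mean_trs < 1:
            raise ValueError("dwell_mean_trs must be >= 1")
        lo, hi = self.masq_range
        if not (14 <= lo < hi <= 70):
            raise ValueError("masq_range must lie within [14, 70]")
        if self.n_subjects < 2 or self.n_volumes < 8 or self.n_rois < 2:
            raise ValueError("cohort too small to generate")


@dataclass(frozen=True)
class SyntheticCohort:
    timeseries: list[RoiTimeseries]
    ratings: list[RatingTrace]
    meta: list[SubjectMeta]
    truth: dict
    schedule: StimulusSchedule
    labels: ConditionLabels
    roi_networks: tuple[str, ...]


def _subject_id(i: int) -> str:
    return f"sub-{i + 1:02d}"


def default_centroids(n_rois: int, planted_k: int) -> tuple[np.ndarray, np.ndarray, int, list[str]]:
    """Planted centroid patterns, communities, DAN-like state and ROI networks.

    State 1 is the global-coherence mode (empty community).  At the canonical
    scale (105 ROIs, k=8) the communities are the 7 Yeo networks of the
    packaged membership fixture; otherwise they are disjoint contiguous ROI
    blocks assigned Yeo network names cyclically.  Returns (k x N signed unit
    patterns, k x N boolean communities, 1-based DAN-like state index,
    per-ROI network names).
    """
    communities = np.zeros((planted_k, n_rois), dtype=bool)
    if n_rois == 105 and planted_k == 8:
        ref = yeo7_reference()
        roi_networks = []
        for j, net in enumerate(YEO7_NETWORKS):
            communities[j + 1] = ref.membership[:, j] == 1
        for i in range(n_rois):
            roi_networks.append(YEO7_NETWORKS[int(np.argmax(ref.membership[i]))])
        dan_state = 2 + YEO7_NETWORKS.index("dorsal_attention")
    else:
        block = max(2, n_rois // (planted_k + 1))
        # background ROIs cycle through all 7 names so every network is
        # nonempty in the emitted membership table (when N permits)
        roi_networks = [YEO7_NETWORKS[i % len(YEO7_NETWORKS)] for i in range(n_rois)]
        for j in range(1, planted_k):
            sl = slice((j - 1) * block, j * block)
            communities[j, sl] = True
            net = YEO7_NETWORKS[(j - 1) % len(YEO7_NETWORKS)]
            for i in range(*sl.indices(n_rois)):
                roi_networks[i] = net
        if communities[1:].sum(axis=1).min() < 2:
            raise ValueError("too many planted states for this ROI count")
        dan_candidates = [
            j + 1
            for j in range(1, planted_k)
            if YEO7_NETWORKS[(j - 1) % len(YEO7_NETWORKS)] == "dorsal_attention"
        ]
        dan_state = dan_candidates[0] if dan_candidates else 2
    patterns = np.where(communities, 1.0, -1.0) / np.sqrt(n_rois)
    return patterns, communities, dan_state, roi_networks


def _roi_names(n_rois: int) -> tuple[str, ...]:
    if n_rois == 105:
        return yeo7_reference().roi_names
    return tuple(f"ROI_{i + 1:03d}" for i in range(n_rois))


def gen_state_timeseries(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[RoiTimeseries], list[StateSequence], np.ndarray, dict]:
    """Markov-switching phase-coupled BOLD for every subject.

    Returns (timeseries, planted state sequences, n_subjects x k planted
    occupancies, extras) where ``extras`` holds the planted centroids,
    communities and the DAN-like state index.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    k, n, t = cfg.planted_k, cfg.n_rois, cfg.n_volumes
    if cfg.planted_centroids is not None:
        patterns = np.asarray(cfg.planted_centroids, dtype=float)
        communities = patterns > 0
        dan_state = 2 if k >= 2 else 1
        roi_networks = ["default_mode"] * n
    else:
        patterns, communities, dan_state, roi_networks = default_centroids(n, k)
    roi_names = _roi_names(n)
    # integer carrier cycles per acquisition keep the series circularly
    # continuous, so the FFT-based analytic signal has no boundary transient
    cycles = max(1, round(cfg.carrier_freq_hz * cfg.tr_s * t))
    omega = 2.0 * np.pi * cycles / t
    # dwell = 2 + shifted geometric (mean dwell_mean_trs); states shorter than
    # 2 volumes have no observable instantaneous phase at the TR resolution
    p_new_run = 1.0 / max(cfg.dwell_mean_trs - 1.0, 1.0)

    timeseries, sequences = [], []
    occupancies = np.zeros((cfg.n_subjects, k))
    for s in range(cfg.n_subjects):
        loading = rng.normal()
        weights = np.ones(k)
        weights[dan_state - 1] = np.exp(cfg.dan_bias_scale * loading)
        runs: list[tuple[int, int]] = []
        cur = int(rng.choice(k, p=weights / weights.sum()))
        total = 0
        while total < t:
            length = 1 + int(rng.geometric(p_new_run))
            runs.append((cur, length))
            total += length
            w = weights.copy()
            w[cur] = 0.0
            cur = int(rng.choice(k, p=w / w.sum()))
        states = np.concatenate([np.full(l, st) for st, l in runs])[:t]
        # close the cycle (last run state = first) so the periodic extension
        # the Hilbert transform assumes has no spurious switch at the wrap
        switches = np.nonzero(np.diff(states) != 0)[0]
        if switches.size and states[-1] != states[0]:
            states[switches[-1] + 1 :] = states[0]
        carrier = omega * np.arange(t) + rng.uniform(0, 2 * np.pi)
        # smooth (AR(1)) per-ROI phase jitter with marginal sd phase_noise_sd:
        # BOLD phase fluctuations are slow relative to the TR
        rho = 0.8
        eps = rng.normal(size=(t, n))
        for v in range(1, t):
            eps[v] = rho * eps[v - 1] + np.sqrt(1.0 - rho**2) * eps[v]
        theta = carrier[:, None] + cfg.phase_noise_sd * eps
        # anti-phase flip as a signed envelope with a raised-cosine crossing
        # between volumes: the sampled signal stays band-limited, the sign at
        # every sample still matches the active state's community, and the
        # analytic phase does not smear across switches
        sgn = np.where(communities[states], -1.0, 1.0)
        padded = np.vstack([sgn[-1:], sgn, sgn[:1]])
        env = 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]
        sid = _subject_id(s)
        timeseries.append(
            RoiTimeseries(
                subject_id=sid, data=env * np.cos(theta), tr_s=cfg.tr_s, roi_names=roi_names
            )
        )
        sequences.append(StateSequence(subject_id=sid, states=states + 1))
        occupancies[s] = np.bincount(states, minlength=k) / t
    extras = {
        "patterns": patterns,
        "communities": communities,
        "dan_state": dan_state,
        "roi_networks": roi_networks,
    }
    return timeseries, sequences, occupancies, extras


def gen_behaviour(
    cfg: GeneratorConfig,
    dan_occupancy: np.ndarray,
    rng: np.random.Generator | None = None,
    labels: ConditionLabels | None = None,
) -> tuple[list[SubjectMeta], list[RatingTrace], dict]:
    """Planted-mediation questionnaire scores and rating traces.

    ``dan_occupancy`` (one value per subject, in [0, 1]) is the IV; the
    standardized anhedonia latent is a_true * z(occupancy) +
    sqrt(1 - a_true^2) * noise, mapped onto the questionnaire range; the
    per-subject rating amplitude is base * (1 + amp_scale * (b_true *
    z(masq) + sqrt(1 - b_true^2) * noise)), clipped at zero (logged) so
    b_true < 0 plants emotional blunting.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    occ = np.asarray(dan_occupancy, dtype=float)
    if occ.min() < 0 or occ.max() > 1:
        raise ValueError("occupancies must lie in [0, 1]")
    n_sub = occ.size
    if labels is None:
        labels = label_timepoints(table1_schedule(), cfg.tr_s, cfg.n_volumes)
    sd = occ.std()
    z_occ = (occ - occ.mean()) / sd if sd > 0 else np.zeros(n_sub)
    latent = cfg.a_true * z_occ + np.sqrt(max(0.0, 1.0 - cfg.a_true**2)) * rng.normal(size=n_sub)
    lo, hi = cfg.masq_range
    masq = np.clip(np.rint(MASQ_MU + MASQ_SD * latent), lo, hi).astype(int)
    msd = masq.std()
    z_masq = (masq - masq.mean()) / msd if msd > 0 else np.zeros(n_sub)
    amp_dev = cfg.b_true * z_masq + np.sqrt(max(0.0, 1.0 - cfg.b_true**2)) * rng.normal(size=n_sub)
    amp = cfg.base_amplitude * (1.0 + cfg.amp_scale * amp_dev)
    clipped = amp < 0
    if clipped.any():
        logger.warning("amplitude clipped at 0 for %d subject(s)", int(clipped.sum()))
        amp = np.maximum(amp, 0.0)

    target = np.zeros(labels.n_volumes)
    target[labels.mask("happy")] = 1.0
    target[labels.mask("sad")] = -1.0

    meta, traces = [], []
    ages = np.clip(np.rint(rng.normal(22.6, 4.0, size=n_sub)), 18, 30).astype(int)
    genders = rng.choice(["F", "M"], size=n_sub)
    music = rng.integers(1, 6, size=n_sub)
    for s in range(n_sub):
        sid = _subject_id(s)
        meta.append(
            SubjectMeta(
                subject_id=sid,
                masq_ad=int(masq[s]),
                age=float(ages[s]),
                gender=str(genders[s]),
                music_background=int(music[s]),
            )
        )
        values = amp[s] * target + rng.normal(0.0, cfg.rating_noise_sd, size=target.size)
        traces.append(
            RatingTrace(
                subject_id=sid,
                values=np.clip(values, -6.0, 6.0),
                dt_s=cfg.tr_s,
                t0_s=cfg.tr_s / 2.0,  # sampled at volume midpoints
            )
        )
    truth = {
        "a_true": cfg.a_true,
        "b_true": cfg.b_true,
        "ab_true": cfg.a_true * cfg.b_true,
        "masq": masq.tolist(),
        "amplitude": amp.tolist(),
        "dan_occupancy": occ.tolist(),
    }
    return meta, traces, truth


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Full deterministic cohort: timeseries, ratings, metadata and truth."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_states, rng_behaviour = (np.random.default_rng(c) for c in ss.spawn(2))
    timeseries, sequences, occupancies, extras = gen_state_timeseries(cfg, rng_states)
    schedule = table1_schedule()
    labels = label_timepoints(schedule, cfg.tr_s, cfg.n_volumes)
    dan_occ = occupancies[:, extras["dan_state"] - 1]
    meta, traces, behaviour_truth = gen_behaviour(cfg, dan_occ, rng_behaviour, labels)
    truth = {
        "seed": cfg.seed,
        "planted_k": cfg.planted_k,
        "dan_state": extras["dan_state"],
        "dwell_mean_trs": cfg.dwell_mean_trs,
        "state_sequences": {seq.subject_id: seq.states.tolist() for seq in sequences},
        "occupancies": {
            _subject_id(s): occupancies[s].tolist() for s in range(cfg.n_subjects)
        },
        "communities": extras["communities"].astype(int).tolist(),
        **behaviour_truth,
    }
    return SyntheticCohort(
        timeseries=timeseries,
        ratings=traces,
        meta=meta,
        truth=truth,
        schedule=schedule,
        labels=labels,
        roi_networks=tuple(extras["roi_networks"]),
    )


def write_cohort(cohort: SyntheticCohort, directory) -> Path:
    """Serialise a cohort into the file layout the pipeline consumes.

    Layout: ``schedule.tsv``, ``metadata.tsv``, ``membership.tsv``,
    ``timeseries/<subject>.tsv`` (volumes x ROIs with ROI-name header),
    ``ratings/<subject>.tsv`` (time_s, rating) and ``truth.json``.  Numeric
    formatting is fixed so equal seeds give byte-identical files.
    """
    directory = Path(directory)
    (directory / "timeseries").mkdir(parents=True, exist_ok=True)
    (directory / "ratings").mkdir(parents=True, exist_ok=True)
    write_schedule(cohort.schedule, directory / "schedule.tsv")
    pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "masq_ad": m.masq_ad,
                "age": m.age,
                "gender": m.gender,
                "music_background": m.music_background,
            }
            for m in cohort.meta
        ]
    ).to_csv(directory / "metadata.tsv", sep="\t", index=False, float_format="%.10g")
    ts0 = cohort.timeseries[0]
    pd.DataFrame({"roi_name": list(ts0.roi_names), "network": list(cohort.roi_networks)}).to_csv(
        directory / "membership.tsv", sep="\t", index=False
    )
    for ts in cohort.timeseries:
        pd.DataFrame(ts.data, columns=list(ts.roi_names)).to_csv(
            directory / "timeseries" / f"{ts.subject_id}.tsv",
            sep="\t",
            index=False,
            float_format="%.8g",
        )
    for trace in cohort.ratings:
        t = trace.t0_s + np.arange(trace.n_samples) * trace.dt_s
        pd.DataFrame({"time_s": t, "rating": trace.values}).to_csv(
            directory / "ratings" / f"{trace.subject_id}.tsv",
            sep="\t",
            index=False,
            float_format="%.8g",
        )
    with open(directory / "truth.json", "w") as f:
        json.dump(cohort.truth, f, indent=1, sort_keys=True)
    return directory


def load_truth(directory) -> dict:
    with open(Path(directory) / "truth.json") as f:
        return json.load(f)
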