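"""End-to-end orchestration: files in, tidy tables + JSON report out.

``run_full`` executes the whole analysis on a cohort directory: ROI
timeseries -> phases -> leading eigenvectors -> pooled clustering with Dunn
model selection -> network labelling -> emotion metrics -> covariate-controlled
correlations with FDR -> bootstrap mediation -> per-song-type metrics and the
median-split summary.  Every random stage draws its seed from the single
config seed through ``numpy.random.SeedSequence`` spawn keys, so a config
reproduces a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .emotion import EmotionMetrics, emotion_metrics
from .leida import (
    LeadingEigSeries,
    RoiTimeseries,
    compute_phases,
    condition_metrics,
    leading_eigenvector_series,
    pool_and_cluster,
    state_metrics,
)
from .networks import load_membership
from .schedule import (
    RatingTrace,
    SubjectMeta,
    label_timepoints,
    load_schedule,
    resample_ratings,
)
from .stats import fdr_bh, mediate, median_split, partial_pearson
from .synth import GeneratorConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "RunReport", "run_full", "run_generate"]

logger = logging.getLogger(__name__)

SONG_TYPE_CONDITIONS = (
    "happy",
    "sad",
    "neutral",
    "neutral_following_sad",
    "neutral_following_happy",
)


@dataclass
class RunConfig:
    """All inputs, parameters and flags of one pipeline run."""

    timeseries_dir: str
    ratings_dir: str
    metadata_file: str
    schedule_file: str
    membership_file: str
    out_dir: str
    tr_s: float = 2.0
    dummy_offset_s: float = 0.0
    k_min: int = 5
    k_max: int = 10
    n_restarts: int = 50
    seed: int = 0
    n_boot: int = 5000
    ci_level: float = 0.95
    fdr_q: float = 0.05
    bandpass: tuple[float, float] | None = None
    binarize_centroids: bool = False
    covariates_in_mediation: bool = False
    exclude_silence: bool = False

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise ValueError("k_min must not exceed k_max")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls(**raw)

    @classmethod
    def from_data_dir(cls, data_dir, out_dir, **kwargs) -> "RunConfig":
        """Convenience constructor for the ``write_cohort`` directory layout."""
        d = Path(data_dir)
        return cls(
            timeseries_dir=str(d / "timeseries"),
            ratings_dir=str(d / "ratings"),
            metadata_file=str(d / "metadata.tsv"),
            schedule_file=str(d / "schedule.tsv"),
            membership_file=str(d / "membership.tsv"),
            out_dir=str(out_dir),
            **kwargs,
        )


@dataclass
class RunReport:
    """In-memory bundle of everything a run computed."""

    config: RunConfig
    selected_k: int
    dunn_by_k: dict[int, float]
    state_labels: pd.DataFrame
    cohort: pd.DataFrame
    correlations: pd.DataFrame
    mediation: dict
    condition_occurrence: pd.DataFrame
    condition_correlations: pd.DataFrame
    median_split_summary: pd.DataFrame
    manifest: dict


def _read_subjects(config: RunConfig):
    meta_df = pd.read_csv(config.metadata_file, sep="\t")
    subjects = list(meta_df["subject_id"])
    meta = {
        row["subject_id"]: SubjectMeta(
            subject_id=row["subject_id"],
            masq_ad=int(row["masq_ad"]),
            age=float(row["age"]),
            gender=str(row["gender"]),
            music_background=int(row["music_background"]),
        )
        for _, row in meta_df.iterrows()
    }
    timeseries, ratings = {}, {}
    for sid in subjects:
        ts_path = Path(config.timeseries_dir) / f"{sid}.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(f"missing timeseries file for subject {sid}: {ts_path}")
        df = pd.read_csv(ts_path, sep="\t")
        timeseries[sid] = RoiTimeseries(
            subject_id=sid,
            data=df.to_numpy(dtype=float),
            tr_s=config.tr_s,
            roi_names=tuple(df.columns),
        )
        r_path = Path(config.ratings_dir) / f"{sid}.tsv"
        if not r_path.exists():
            raise FileNotFoundError(f"missing ratings file for subject {sid}: {r_path}")
        rdf = pd.read_csv(r_path, sep="\t")
        t = rdf["time_s"].to_numpy(dtype=float)
        dt = float(np.diff(t).mean()) if t.size > 1 else config.tr_s
        if t.size > 2 and np.ptp(np.diff(t)) > 1e-6:
            raise ValueError(f"ratings for subject {sid} are not on a uniform grid")
        ratings[sid] = RatingTrace(
            subject_id=sid, values=rdf["rating"].to_numpy(dtype=float), dt_s=dt, t0_s=float(t[0])
        )
    shapes = {sid: ts.data.shape for sid, ts in timeseries.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"inconsistent timeseries dimensions across subjects: {shapes}")
    return subjects, meta, timeseries, ratings


def _encode_gender(values: pd.Series) -> np.ndarray:
    cats = sorted(values.unique())
    if len(cats) > 2:
        raise ValueError(f"expected a binary gender column, got {cats}")
    return (values == cats[-1]).to_numpy(dtype=float)


def _corr_family(cohort: pd.DataFrame, pairs, covs, fdr_q):
    """Partial correlations for one FDR family."""
    rows = []
    for x_name, y_name in pairs:
        res = partial_pearson(
            cohort[x_name],
            cohort[y_name],
            covariates=covs,
            x_name=x_name,
            y_name=y_name,
            covariate_names=("age", "gender", "music_background"),
        )
        rows.append(res)
    reject, p_adj = fdr_bh([r.p for r in rows], q=fdr_q)
    return [
        dataclasses.replace(r, p_fdr=float(pa)) for r, pa in zip(rows, p_adj)
    ], reject


def run_full(config: RunConfig) -> RunReport:
    """Execute the complete analysis and write its report bundle to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("musicstates")
    root.addHandler(log_handler)
    try:
        return _run_full(config, out)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run_full(config: RunConfig, out: Path) -> RunReport:
    schedule = load_schedule(config.schedule_file)
    ref = load_membership(config.membership_file)
    subjects, meta, timeseries, ratings = _read_subjects(config)
    n_volumes = timeseries[subjects[0]].n_volumes
    labels = label_timepoints(schedule, config.tr_s, n_volumes, config.dummy_offset_s)
    logger.info("cohort: %d subjects, %d volumes, %d ROIs", len(subjects),
                n_volumes, timeseries[subjects[0]].n_rois)

    # --- LEiDA ---------------------------------------------------------
    eigs: list[LeadingEigSeries] = []
    for sid in subjects:
        ts = timeseries[sid]
        if config.bandpass is not None:
            from scipy.signal import butter, filtfilt

            lo, hi = config.bandpass
            nyq = 0.5 / config.tr_s
            bb, ba = butter(2, [lo / nyq, hi / nyq], btype="band")
            ts = RoiTimeseries(
                subject_id=sid,
                data=filtfilt(bb, ba, ts.data, axis=0),
                tr_s=ts.tr_s,
                roi_names=ts.roi_names,
            )
        eigs.append(leading_eigenvector_series(compute_phases(ts)))
    leida_seed = int(np.random.SeedSequence(config.seed, spawn_key=(1,)).generate_state(1)[0] % (2**31))
    repertoire, sequences = pool_and_cluster(
        eigs, config.k_min, config.k_max, seed=leida_seed, n_restarts=config.n_restarts
    )
    k = repertoire.k
    logger.info("selected k=%d (Dunn %s)", k, repertoire.dunn_by_k)
    metrics = {seq.subject_id: state_metrics(seq, k) for seq in sequences}

    centroids = repertoire.centroids
    if config.binarize_centroids:
        centroids = np.where(centroids > 0, 1.0, 0.0)
        repertoire = dataclasses.replace(repertoire, centroids=centroids)
    from .networks import label_states  # local import to avoid cycle at module load

    state_labels = label_states(repertoire, ref)

    # --- behaviour -----------------------------------------------------
    emetrics: dict[str, EmotionMetrics] = {}
    for sid in subjects:
        per_tr = resample_ratings(ratings[sid], labels)
        emetrics[sid] = emotion_metrics(sid, per_tr, labels, exclude_silence=config.exclude_silence)

    cohort = pd.DataFrame(
        {
            "subject_id": subjects,
            "masq_ad": [meta[s].masq_ad for s in subjects],
            "age": [meta[s].age for s in subjects],
            "gender": [meta[s].gender for s in subjects],
            "music_background": [meta[s].music_background for s in subjects],
            "std": [emetrics[s].std for s in subjects],
            "rmssd": [emetrics[s].rmssd for s in subjects],
            "mean_happy": [emetrics[s].mean_by_condition.get("happy", np.nan) for s in subjects],
            "mean_sad": [emetrics[s].mean_by_condition.get("sad", np.nan) for s in subjects],
            "mean_neutral": [
                emetrics[s].mean_by_condition.get("neutral", np.nan) for s in subjects
            ],
        }
    )
    for s in range(1, k + 1):
        cohort[f"occ_state{s}"] = [metrics[sid].occurrence[s - 1] for sid in subjects]
        cohort[f"lt_state{s}"] = [metrics[sid].lifetime_trs[s - 1] for sid in subjects]

    covs = np.column_stack(
        [
            cohort["age"].to_numpy(dtype=float),
            _encode_gender(cohort["gender"]),
            cohort["music_background"].to_numpy(dtype=float),
        ]
    )

    # --- correlations (one FDR family per metric) ----------------------
    corr_rows = []
    families = {
        "masq_emotion": [("masq_ad", "std"), ("masq_ad", "rmssd")],
        "masq_occurrence": [("masq_ad", f"occ_state{s}") for s in range(1, k + 1)],
        "masq_lifetime": [("masq_ad", f"lt_state{s}") for s in range(1, k + 1)],
        "std_occurrence": [("std", f"occ_state{s}") for s in range(1, k + 1)],
        "rmssd_occurrence": [("rmssd", f"occ_state{s}") for s in range(1, k + 1)],
    }
    family_results = {}
    for fam, pairs in families.items():
        results, reject = _corr_family(cohort, pairs, covs, config.fdr_q)
        family_results[fam] = results
        for res, rej in zip(results, reject):
            corr_rows.append(
                {
                    "family": fam,
                    "x": res.x_name,
                    "y": res.y_name,
                    "n": res.n,
                    "r": res.r,
                    "p": res.p,
                    "p_fdr": res.p_fdr,
                    "significant_fdr": bool(rej),
                }
            )
    correlations = pd.DataFrame(corr_rows)

    # --- mediation: occupancy of the most MASQ-associated state --------
    occ_family = family_results["masq_occurrence"]
    best = min(occ_family, key=lambda r: r.p)
    iv_state = int(best.y_name.removeprefix("occ_state"))
    logger.info("mediation IV: %s (r=%.3f, p=%.4g)", best.y_name, best.r, best.p)
    med_seed = int(np.random.SeedSequence(config.seed, spawn_key=(2,)).generate_state(1)[0] % (2**31))
    iv = cohort[best.y_name].to_numpy(dtype=float)
    m = cohort["masq_ad"].to_numpy(dtype=float)
    dv = cohort["std"].to_numpy(dtype=float)
    if config.covariates_in_mediation:
        design = np.column_stack([np.ones(len(cohort)), covs])
        proj = lambda v: v - design @ np.linalg.lstsq(design, v, rcond=None)[0]
        iv, m, dv = proj(iv), proj(m), proj(dv)
    med = mediate(iv, m, dv, n_boot=config.n_boot, ci_level=config.ci_level, seed=med_seed)
    mediation = {
        "iv": best.y_name,
        "iv_state": iv_state,
        "mediator": "masq_ad",
        "dv": "std",
        **{f: getattr(med, f) for f in (
            "a", "b", "ab", "c_prime", "c_total", "p_a", "p_b", "p_c_prime",
            "p_c_total", "n", "n_boot", "ci_level", "full_mediation")},
        "ci_ab": list(med.ci_ab),
        "seed": med_seed,
    }

    # --- per-song-type metrics for the mediation state ------------------
    cond_rows = []
    for seq in sequences:
        for cond in SONG_TYPE_CONDITIONS:
            cm = condition_metrics(seq, labels, cond, k)
            cond_rows.append(
                {
                    "subject_id": seq.subject_id,
                    "condition": cond,
                    "occurrence": cm.occurrence[iv_state - 1],
                    "lifetime_trs": cm.lifetime_trs[iv_state - 1],
                }
            )
    condition_occurrence = pd.DataFrame(cond_rows)
    cc_rows = []
    pvals = []
    for cond in SONG_TYPE_CONDITIONS:
        occ_c = (
            condition_occurrence.query("condition == @cond")
            .set_index("subject_id")
            .loc[subjects, "occurrence"]
            .to_numpy(dtype=float)
        )
        res = partial_pearson(
            cohort["masq_ad"], occ_c, covariates=covs,
            x_name="masq_ad", y_name=f"occ_state{iv_state}_{cond}",
            covariate_names=("age", "gender", "music_background"),
        )
        cc_rows.append({"condition": cond, "n": res.n, "r": res.r, "p": res.p})
        pvals.append(res.p)
    _, p_adj = fdr_bh(pvals, q=config.fdr_q)
    condition_correlations = pd.DataFrame(cc_rows).assign(p_fdr=p_adj)

    # --- median split ----------------------------------------------------
    groups = median_split(cohort["masq_ad"])
    cohort["masq_group"] = groups
    split_rows = []
    for grp in ("low", "high"):
        sel = [s for s, g in zip(subjects, groups) if g == grp]
        for cond in ("sad", "neutral_following_sad"):
            vals = (
                condition_occurrence.query("condition == @cond")
                .set_index("subject_id")
                .loc[sel, "occurrence"]
                .to_numpy(dtype=float)
            )
            split_rows.append(
                {
                    "group": grp,
                    "n": len(sel),
                    "condition": cond,
                    "mean_occurrence": float(vals.mean()),
                    "sd_occurrence": float(vals.std(ddof=1)) if len(sel) > 1 else np.nan,
                }
            )
    median_split_summary = pd.DataFrame(split_rows)

    # --- serialise -------------------------------------------------------
    labels_df = pd.DataFrame(
        [
            {
                "state": lab.state_index,
                **{f"r_{n}": lab.r[j] for j, n in enumerate(lab.network_names)},
                **{f"p_{n}": lab.p[j] for j, n in enumerate(lab.network_names)},
                "significant": ",".join(lab.significant),
                "global_candidate": lab.is_global_candidate,
                "alpha": lab.alpha,
            }
            for lab in state_labels
        ]
    )
    manifest = {
        "package_version": __version__,
        "config": {
            f.name: getattr(config, f.name)
            if not isinstance(getattr(config, f.name), tuple)
            else list(getattr(config, f.name))
            for f in dataclasses.fields(config)
        },
        "selected_k": k,
        "dunn_by_k": {str(kk): v for kk, v in repertoire.dunn_by_k.items()},
        "n_subjects": len(subjects),
        "n_volumes": n_volumes,
        "n_rois": timeseries[subjects[0]].n_rois,
        "stage_seeds": {"kmeans": leida_seed, "bootstrap": med_seed},
    }

    fmt = dict(sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(repertoire.centroids, columns=list(ref.roi_names) or None).to_csv(
        out / "repertoire.tsv", **fmt
    )
    pd.DataFrame(
        {seq.subject_id: seq.states for seq in sequences}
    ).to_csv(out / "state_sequences.tsv", **fmt)
    long_rows = []
    for sid in subjects:
        sm = metrics[sid]
        for s in range(1, k + 1):
            long_rows.append(
                {
                    "subject_id": sid,
                    "state": s,
                    "occurrence": sm.occurrence[s - 1],
                    "lifetime_trs": sm.lifetime_trs[s - 1],
                    "lifetime_s": sm.lifetime_trs[s - 1] * config.tr_s,
                }
            )
    pd.DataFrame(long_rows).to_csv(out / "state_metrics.tsv", **fmt)
    cohort.to_csv(out / "cohort.tsv", **fmt)
    labels_df.to_csv(out / "state_labels.tsv", **fmt)
    correlations.to_csv(out / "correlations.tsv", **fmt)
    condition_occurrence.to_csv(out / "condition_occurrence.tsv", **fmt)
    condition_correlations.to_csv(out / "condition_correlations.tsv", **fmt)
    median_split_summary.to_csv(out / "median_split.tsv", **fmt)
    with open(out / "mediation.json", "w") as f:
        json.dump(mediation, f, indent=1, sort_keys=True)
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True, default=str)

    return RunReport(
        config=config,
        selected_k=k,
        dunn_by_k=repertoire.dunn_by_k,
        state_labels=labels_df,
        cohort=cohort,
        correlations=correlations,
        mediation=mediation,
        condition_occurrence=condition_occurrence,
        condition_correlations=condition_correlations,
        median_split_summary=median_split_summary,
        manifest=manifest,
    )


def run_generate(
    cfg: GeneratorConfig, out_dir, k_min: int = 5, k_max: int = 10
) -> Path:
    """Generate a synthetic cohort on disk (config passthrough to synth)."""
    if not k_min <= cfg.planted_k <= k_max:
        warnings.warn(
            f"planted_k={cfg.planted_k} lies outside the model-selection range "
            f"[{k_min}, {k_max}]; Dunn selection cannot recover the truth",
            UserWarning,
            stacklevel=2,
        )
    cohort = generate_cohort(cfg)
    return write_cohort(cohort, out_dir)
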