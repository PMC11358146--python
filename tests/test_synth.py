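import json

import numpy as np
import pytest

from musicstates import (
    GeneratorConfig,
    compute_phases,
    compute_std,
    gen_behaviour,
    generate_cohort,
    label_timepoints,
    leading_eigenvector_series,
    load_truth,
    mediate,
    phase_locking_matrix,
    pool_and_cluster,
    table1_schedule,
    write_cohort,
)

from conftest import matched_accuracy


class TestStateTimeseries:
    def test_noiseless_eigenvector_positive_set_is_the_community(self):
        cfg = GeneratorConfig(
            n_subjects=2, n_rois=40, n_volumes=120, planted_k=4, phase_noise_sd=0.0, seed=3
        )
        cohort = generate_cohort(cfg)
        communities = np.array(cohort.truth["communities"], dtype=bool)
        ts = cohort.timeseries[0]
        seq = np.array(cohort.truth["state_sequences"][ts.subject_id]) - 1
        eigs = leading_eigenvector_series(compute_phases(ts))
        matches = [
            set(np.nonzero(eigs.v1[t] > 0)[0]) == set(np.nonzero(communities[seq[t]])[0])
            for t in range(ts.n_volumes)
        ]
        assert np.mean(matches) == pytest.approx(1.0)

    def test_noiseless_dpl_has_two_phase_communities(self):
        cfg = GeneratorConfig(
            n_subjects=2, n_rois=24, n_volumes=80, planted_k=3, phase_noise_sd=0.0, seed=4
        )
        cohort = generate_cohort(cfg)
        communities = np.array(cohort.truth["communities"], dtype=bool)
        seq = np.array(cohort.truth["state_sequences"]["sub-01"]) - 1
        # construction-level phases: carrier plus pi on the active community
        t = 30
        theta = np.where(communities[seq[t]], np.pi, 0.0)
        m = phase_locking_matrix(theta)
        inside = communities[seq[t]]
        if inside.any():
            assert np.allclose(m[np.ix_(inside, inside)], 1.0)
            assert np.allclose(m[np.ix_(inside, ~inside)], -1.0)
        assert np.allclose(m[np.ix_(~inside, ~inside)], 1.0)

    def test_mean_dwell_matches_configuration(self):
        cfg = GeneratorConfig(
            n_subjects=8, n_rois=12, n_volumes=1000, planted_k=4, dwell_mean_trs=5.0, seed=5
        )
        cohort = generate_cohort(cfg)
        lengths = []
        for seq in cohort.truth["state_sequences"].values():
            arr = np.asarray(seq)
            bounds = np.concatenate([[0], np.nonzero(np.diff(arr) != 0)[0] + 1, [arr.size]])
            lengths.extend(np.diff(bounds))
        assert np.mean(lengths) == pytest.approx(5.0, abs=1.0)

    def test_moderate_noise_recovery(self):
        cfg = GeneratorConfig(
            n_subjects=6, n_rois=40, n_volumes=150, planted_k=5, phase_noise_sd=0.3, seed=6
        )
        cohort = generate_cohort(cfg)
        eigs = [leading_eigenvector_series(compute_phases(ts)) for ts in cohort.timeseries]
        rep, seqs = pool_and_cluster(eigs, 4, 8, seed=0, n_restarts=8)
        assert rep.k == 5
        accs = [
            matched_accuracy(
                np.array(cohort.truth["state_sequences"][s.subject_id]), s.states, 5, rep.k
            )
            for s in seqs
        ]
        assert np.mean(accs) >= 0.9

    def test_dan_occupancy_varies_across_subjects(self, tiny_cohort):
        _, cohort = tiny_cohort
        occ = np.array(cohort.truth["dan_occupancy"])
        assert occ.std() > 0.01
        assert occ.min() >= 0 and occ.max() <= 1


class TestBehaviour:
    @staticmethod
    def _labels(cfg):
        return label_timepoints(table1_schedule(), cfg.tr_s, cfg.n_volumes)

    def test_no_blunting_effect_when_b_zero(self):
        cfg = GeneratorConfig(b_true=0.0, seed=7)
        rng = np.random.default_rng(0)
        labels = self._labels(cfg)
        rs = []
        for _ in range(40):
            occ = rng.beta(2, 12, size=31)
            meta, traces, _ = gen_behaviour(cfg, occ, rng, labels)
            masq = np.array([m.masq_ad for m in meta])
            stds = np.array([compute_std(t.values) for t in traces])
            rs.append(np.corrcoef(masq, stds)[0, 1])
        assert abs(np.mean(rs)) < 0.08

    def test_planted_mediation_chain_recovered(self):
        """At the cohort size n=31, the mean indirect effect over replicates
        matches the planted a*b."""
        cfg = GeneratorConfig(seed=8)
        rng = np.random.default_rng(1)
        labels = self._labels(cfg)
        abs_ = []
        for rep in range(200):
            occ = rng.beta(2, 12, size=31)
            meta, traces, _ = gen_behaviour(cfg, occ, rng, labels)
            masq = np.array([m.masq_ad for m in meta])
            stds = np.array([compute_std(t.values) for t in traces])
            abs_.append(mediate(occ, masq, stds, n_boot=1000, seed=rep).ab)
        assert np.mean(abs_) == pytest.approx(0.54 * -0.62, abs=0.07)

    def test_noiseless_std_matches_schedule_closed_form(self):
        cfg = GeneratorConfig(rating_noise_sd=0.0, amp_scale=0.0, seed=9)
        labels = self._labels(cfg)
        _, traces, _ = gen_behaviour(cfg, np.linspace(0.1, 0.4, 31), labels=labels)
        n = labels.n_volumes
        nh = int(labels.mask("happy").sum())
        ns = int(labels.mask("sad").sum())
        amp = cfg.base_amplitude
        mu = amp * (nh - ns) / n
        var = (nh * (amp - mu) ** 2 + ns * (-amp - mu) ** 2 + (n - nh - ns) * mu**2) / n
        for trace in traces:
            assert compute_std(trace.values) == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_masq_scores_respect_range(self):
        cfg = GeneratorConfig(seed=10)
        meta, _, _ = gen_behaviour(cfg, np.linspace(0, 1, 31), labels=self._labels(cfg))
        scores = [m.masq_ad for m in meta]
        assert min(scores) >= 14 and max(scores) <= 70


class TestSerialization:
    def test_same_seed_writes_byte_identical_cohorts(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=3, n_rois=16, n_volumes=60, planted_k=3, seed=11)
        d1 = write_cohort(generate_cohort(cfg), tmp_path / "a")
        d2 = write_cohort(generate_cohort(cfg), tmp_path / "b")
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_truth_manifest_round_trips(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=3, n_rois=16, n_volumes=60, planted_k=3, seed=12)
        cohort = generate_cohort(cfg)
        write_cohort(cohort, tmp_path)
        reread = load_truth(tmp_path)
        assert reread == json.loads(json.dumps(cohort.truth))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            GeneratorConfig(planted_k=1)
        with pytest.raises(ValueError):
            GeneratorConfig(masq_range=(10, 70))
        with pytest.raises(ValueError):
            GeneratorConfig(dwell_mean_trs=0.5)
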