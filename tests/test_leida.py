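import numpy as np
import pytest
import scipy.linalg

from musicstates import (
    DegenerateEigenvectorWarning,
    RoiTimeseries,
    StateSequence,
    compute_phases,
    condition_metrics,
    dunn_index,
    label_timepoints,
    leading_eigenvector,
    leading_eigenvector_series,
    phase_locking_matrix,
    pool_and_cluster,
    state_metrics,
)
from musicstates.leida import PhaseSeries, _fix_sign



def _wrap(x):
    return np.angle(np.exp(1j * x))


class TestComputePhases:
    def test_pure_tone_phase_slope(self):
        t = np.arange(200)
        tr, f = 2.0, 0.05  # 20 full cycles over the series
        data = np.column_stack([np.cos(2 * np.pi * f * tr * t), np.sin(2 * np.pi * f * tr * t)])
        phases = compute_phases(RoiTimeseries("s", data, tr))
        core = slice(20, 180)  # exclude 10% edge volumes
        slopes = _wrap(np.diff(phases.theta[core, 0]))
        assert np.allclose(slopes, 2 * np.pi * f * tr, atol=0.05)

    def test_quarter_cycle_phase_offset(self):
        t = np.arange(200)
        w = 2 * np.pi * 0.05 * 2.0
        data = np.column_stack([np.cos(w * t), np.cos(w * t + np.pi / 2)])
        theta = compute_phases(RoiTimeseries("s", data, 2.0)).theta
        core = slice(20, 180)
        offsets = _wrap(theta[core, 1] - theta[core, 0] - np.pi / 2)
        assert np.abs(offsets).max() < 0.05

    def test_sign_flip_shifts_phase_by_pi(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(64, 3))
        flipped = data.copy()
        flipped[:, 1] *= -1
        a = compute_phases(RoiTimeseries("s", data, 2.0)).theta
        b = compute_phases(RoiTimeseries("s", flipped, 2.0)).theta
        assert np.allclose(np.abs(_wrap(b[:, 1] - a[:, 1])), np.pi, atol=1e-9)
        assert np.allclose(b[:, 0], a[:, 0])

    def test_constant_roi_is_rejected_by_name(self):
        data = np.random.default_rng(1).normal(size=(32, 2))
        data[:, 1] = 4.2
        with pytest.raises(ValueError, match="roiB"):
            compute_phases(RoiTimeseries("s", data, 2.0, roi_names=("roiA", "roiB")))

    def test_phases_in_half_open_interval(self, tiny_cohort):
        _, cohort = tiny_cohort
        theta = compute_phases(cohort.timeseries[0]).theta
        assert theta.min() > -np.pi and theta.max() <= np.pi


class TestPhaseLockingMatrix:
    @pytest.mark.parametrize(
        "theta, off_diag",
        [(np.zeros(4), 1.0), (np.array([0.0, np.pi]), -1.0), (np.array([0.0, np.pi / 2]), 0.0)],
    )
    def test_closed_forms(self, theta, off_diag):
        m = phase_locking_matrix(theta)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        assert m[0, 1] == pytest.approx(off_diag, abs=1e-12)

    def test_entries_bounded(self):
        theta = np.random.default_rng(2).uniform(-np.pi, np.pi, 20)
        m = phase_locking_matrix(theta)
        assert m.min() >= -1 - 1e-12 and m.max() <= 1 + 1e-12


class TestLeadingEigenvector:
    def test_rank_one_all_ones(self):
        v, lam = leading_eigenvector(np.ones((5, 5)))
        assert lam == pytest.approx(5.0)
        np.testing.assert_allclose(v, np.full(5, -1 / np.sqrt(5)))

    def test_identity_is_flagged_degenerate(self):
        with pytest.warns(DegenerateEigenvectorWarning):
            leading_eigenvector(np.eye(4))

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = rng.integers(3, 30)
            a = rng.normal(size=(n, n))
            m = (a + a.T) / 2
            v, lam = leading_eigenvector(m)
            w, vecs = scipy.linalg.eigh(m)
            assert lam == pytest.approx(w[-1], rel=1e-12, abs=1e-12)
            assert abs(v @ vecs[:, -1]) > 1 - 1e-10

    def test_sign_convention_tie_breaks(self):
        # majority negative wins outright
        assert (_fix_sign(np.array([0.9, -0.3, -0.3])) < 0).sum() == 2
        # equal counts: flip so the sum is <= 0
        v = _fix_sign(np.array([0.8, -0.2]))
        assert v.sum() <= 0
        # zero sum: first nonzero element forced negative
        v = _fix_sign(np.array([0.5, -0.5]))
        assert v[0] < 0

    def test_series_closed_form_agrees_with_dense_route(self, tiny_cohort):
        _, cohort = tiny_cohort
        phases = compute_phases(cohort.timeseries[0])
        series = leading_eigenvector_series(phases)
        for t in range(0, phases.theta.shape[0], 17):
            v, lam = leading_eigenvector(phase_locking_matrix(phases.theta[t]))
            assert lam == pytest.approx(series.eigval[t], rel=1e-9)
            np.testing.assert_allclose(series.v1[t], v, atol=1e-8)

    def test_eigval_reconstruction_bound(self, tiny_cohort):
        """eigval/N lies in (0, 1]; it reaches 1 exactly for equal phases."""
        _, cohort = tiny_cohort
        series = leading_eigenvector_series(compute_phases(cohort.timeseries[0]))
        n = cohort.timeseries[0].n_rois
        assert (series.eigval > 0).all() and (series.eigval <= n + 1e-9).all()
        # all-equal phases give the rank-one global mode with eigval exactly N
        flat = PhaseSeries("s", np.full((12, 8), 0.5))
        flat_series = leading_eigenvector_series(flat)
        assert np.allclose(flat_series.eigval, 8.0)
        assert (flat_series.v1 < 0).all()


class TestDunnIndex:
    def test_two_tight_distant_clusters(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        assert dunn_index(pts, [0, 0, 1, 1]) == pytest.approx(99.0)

    def test_separated_beats_overlapping(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, (100, 2)), rng.normal(0, 1, (100, 2))
        labels = np.repeat([0, 1], 100)
        overlapping = dunn_index(np.vstack([a, b + 0.5]), labels)
        separated = dunn_index(np.vstack([a, b + 20.0]), labels)
        assert separated > overlapping

    def test_zero_diameter_flags_infinite(self):
        pts = np.array([[0.0, 0.0]] * 3 + [[5.0, 5.0]] * 3)
        assert dunn_index(pts, [0, 0, 0, 1, 1, 1]) == np.inf

    def test_chunked_equals_unchunked(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(300, 4))
        labels = rng.integers(0, 4, 300)
        assert dunn_index(pts, labels, chunk=37) == pytest.approx(
            dunn_index(pts, labels, chunk=1024), rel=1e-12
        )


class TestPoolAndCluster:
    @staticmethod
    def _cloud_eigs(rng, centroids, n_each, spread, subject="s1"):
        from musicstates import LeadingEigSeries

        rows = []
        for c in centroids:
            pts = c + rng.normal(0, spread, size=(n_each, c.size))
            rows.append(pts / np.linalg.norm(pts, axis=1, keepdims=True))
        rows = np.vstack(rows)
        rng.shuffle(rows)
        return LeadingEigSeries(subject, rows, np.ones(len(rows)))

    def test_recovers_planted_orthogonal_centroids(self):
        rng = np.random.default_rng(6)
        centroids = -np.eye(20)[:6]
        eigs = [self._cloud_eigs(rng, centroids, 40, 0.02, f"s{i}") for i in range(3)]
        rep, seqs = pool_and_cluster(eigs, k_min=5, k_max=10, seed=0, n_restarts=10)
        assert rep.k == 6
        # every centroid matches one planted pattern almost exactly
        sims = np.abs(rep.centroids @ centroids.T)
        assert (sims.max(axis=1) > 0.99).all()

    def test_duplicated_input_keeps_centroids_and_doubles_sizes(self):
        rng = np.random.default_rng(7)
        centroids = -np.eye(12)[:3]
        eigs = [self._cloud_eigs(rng, centroids, 30, 0.02)]
        rep1, seqs1 = pool_and_cluster(eigs, 2, 4, seed=3, n_restarts=10)
        rep2, seqs2 = pool_and_cluster(eigs * 2, 2, 4, seed=3, n_restarts=10)
        assert rep1.k == rep2.k
        order1 = np.lexsort(rep1.centroids.T)
        order2 = np.lexsort(rep2.centroids.T)
        np.testing.assert_allclose(
            rep1.centroids[order1], rep2.centroids[order2], atol=1e-8
        )
        sizes1 = np.bincount(np.concatenate([s.states for s in seqs1]))
        sizes2 = np.bincount(np.concatenate([s.states for s in seqs2]))
        assert sorted(sizes2[1:]) == sorted(2 * sizes1[1:])

    def test_fixed_seed_is_bit_identical(self, tiny_eigs):
        rep1, seqs1 = pool_and_cluster(tiny_eigs, 4, 6, seed=11, n_restarts=4)
        rep2, seqs2 = pool_and_cluster(tiny_eigs, 4, 6, seed=11, n_restarts=4)
        assert rep1.k == rep2.k
        assert np.array_equal(rep1.centroids, rep2.centroids)
        for a, b in zip(seqs1, seqs2):
            assert np.array_equal(a.states, b.states)

    def test_too_few_eigenvectors_rejected(self, tiny_eigs):
        from musicstates import LeadingEigSeries

        short = LeadingEigSeries("s", tiny_eigs[0].v1[:4], tiny_eigs[0].eigval[:4])
        with pytest.raises(ValueError, match="k_max"):
            pool_and_cluster([short], 5, 10, seed=0)


class TestStateMetrics:
    def test_worked_example(self):
        m = state_metrics(np.array([1, 1, 2, 2, 2, 1]), k=2)
        np.testing.assert_allclose(m.occurrence, [0.5, 0.5])
        np.testing.assert_allclose(m.lifetime_trs, [1.5, 3.0])

    def test_constant_sequence(self):
        m = state_metrics(np.array([3, 3, 3, 3]), k=3)
        assert m.occurrence[2] == 1.0
        assert m.lifetime_trs[2] == 4.0
        assert m.switching[2, 2] == 1.0
        assert np.isnan(m.lifetime_trs[0]) and np.isnan(m.switching[0]).all()

    def test_alternating_sequence_switching(self):
        m = state_metrics(np.array([1, 2, 1, 2]), k=2)
        np.testing.assert_allclose(m.switching, [[0, 1], [1, 0]])

    def test_run_count_identity_random_sequences(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            seq = rng.integers(1, k + 1, size=int(rng.integers(2, 200)))
            m = state_metrics(seq, k)
            assert m.occurrence.sum() == pytest.approx(1.0, abs=1e-9)
            runs = 1 + int((np.diff(seq) != 0).sum())
            occurring = ~np.isnan(m.lifetime_trs)
            est = (m.occurrence[occurring] * seq.size / m.lifetime_trs[occurring]).sum()
            assert est == pytest.approx(runs, abs=1e-9)


class TestConditionMetrics:
    def test_state_filling_happy_volumes(self, schedule):
        labels = label_timepoints(schedule, 2.0, 250)
        states = np.where(labels.mask("happy"), 2, 1)
        seq = StateSequence("s1", states)
        m = condition_metrics(seq, labels, "happy", k=2)
        assert m.occurrence[1] == pytest.approx(1.0)
        m_neutral = condition_metrics(seq, labels, "neutral", k=2)
        assert m_neutral.occurrence[0] == pytest.approx(1.0)

    def test_condition_restricted_matches_global_for_uniform_states(self, schedule):
        labels = label_timepoints(schedule, 2.0, 250)
        rng = np.random.default_rng(9)
        occs = []
        for _ in range(40):
            seq = StateSequence("s1", rng.integers(1, 4, 250))
            occs.append(condition_metrics(seq, labels, "happy", k=3).occurrence)
        got = np.mean(occs, axis=0)
        np.testing.assert_allclose(got, [1 / 3] * 3, atol=0.03)

    def test_planted_elevation_during_neutral_following_sad(self, schedule):
        labels = label_timepoints(schedule, 2.0, 250)
        rng = np.random.default_rng(10)
        base = rng.integers(2, 4, 250)
        states = np.where(labels.mask("neutral_following_sad"), 1, base)
        m = condition_metrics(StateSequence("s1", states), labels, "neutral_following_sad", k=3)
        assert m.occurrence[0] == pytest.approx(1.0)
        m_other = condition_metrics(StateSequence("s1", states), labels, "neutral_following_happy", k=3)
        assert m_other.occurrence[0] < 0.2

    def test_runs_truncated_at_song_boundaries(self, schedule):
        labels = label_timepoints(schedule, 2.0, 250)
        seq = StateSequence("s1", np.ones(250, dtype=int))
        m = condition_metrics(seq, labels, "sad", k=1)
        # each sad piece is one maximal run; the mean lifetime is the mean
        # sad-piece length in volumes, not the whole-task run length
        sad_events = [ev for ev in np.unique(labels.event_index[labels.mask("sad")])]
        lengths = [(labels.event_index == ev).sum() for ev in sad_events]
        assert m.lifetime_trs[0] == pytest.approx(np.mean(lengths))

    def test_absent_condition_errors(self, schedule):
        labels = label_timepoints(schedule, 2.0, 10)
        with pytest.raises(ValueError, match="happy"):
            condition_metrics(StateSequence("s1", np.ones(10, dtype=int)), labels, "happy", k=1)
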