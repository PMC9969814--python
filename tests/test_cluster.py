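"""DTW and k-medoids contracts, including the brute-force path oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import scgvar
from scgvar import cross_tabulate_phase, dtw_distance, k_medoids_dtw
from scgvar.cluster import dtw_distance_matrix
from scgvar.segment import BeatEvent, BeatSet

from _oracle import dtw_bruteforce
from conftest import label_agreement


def beatset_from_waveforms(waves, rr=None, fs=1000.0):
    """Wrap raw waveforms as an already-normalized BeatSet."""
    beats = []
    t = 0.5
    for i, w in enumerate(waves):
        w = np.asarray(w, dtype=float)
        rr_i = rr[i] if rr is not None else 1.0
        beats.append(
            BeatEvent(
                index=i,
                r_time=t,
                start_sample=int((t - 0.1) * fs),
                end_sample=int((t - 0.1) * fs) + len(w),
                samples=w / np.max(np.abs(w)),
                rr_s=rr_i,
                hr_bpm=60.0 / rr_i,
                normalized=True,
                raw_samples=w,
            )
        )
        t += rr_i
    return BeatSet(fs=fs, beats=beats)


class TestDTW:
    def test_identity_distance_is_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=rng.integers(2, 50))
            assert dtw_distance(x, x) == 0.0

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0, 1, 0], [0, 1, 1, 0], 0.0),
            ([0, 0, 0], [1, 1, 1], 3.0),
            ([1.0], [3.0], 2.0),
        ],
    )
    def test_small_cases_match_path_enumeration(self, x, y, expected):
        assert dtw_bruteforce(x, y) == pytest.approx(expected)
        assert dtw_distance(np.array(x, float), np.array(y, float)) == pytest.approx(
            expected
        )

    @given(
        hst.lists(hst.floats(-5, 5), min_size=1, max_size=6),
        hst.lists(hst.floats(-5, 5), min_size=1, max_size=6),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_oracle_on_random_short_pairs(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        assert dtw_distance(x, y) == pytest.approx(dtw_bruteforce(x, y), abs=1e-9)

    @given(
        hst.lists(hst.floats(-10, 10), min_size=1, max_size=30),
        hst.lists(hst.floats(-10, 10), min_size=1, max_size=30),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_nonnegativity(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        d = dtw_distance(x, y)
        assert d >= 0
        assert d == pytest.approx(dtw_distance(y, x), abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance(np.array([]), np.ones(3))

    def test_sakoe_chiba_band_upper_bounds_unconstrained(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(size=50)
        free = dtw_distance(x, y)
        banded = dtw_distance(x, y, window=5)
        assert banded >= free - 1e-12

    def test_distance_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        waves = [rng.normal(size=rng.integers(20, 30)) for _ in range(6)]
        D = dtw_distance_matrix(waves)
        np.testing.assert_allclose(D, D.T)
        assert np.all(np.diag(D) == 0)


class TestKMedoids:
    def test_identical_beats_converge_immediately(self):
        waves = [np.array([0.0, 1.0, 0.5, -0.2])] * 8
        bs = beatset_from_waveforms(waves)
        cr = k_medoids_dtw(bs, seed=0)
        assert cr.converged
        assert cr.iterations == 1
        assert cr.objective_trace[-1] == 0.0

    def test_two_template_instance_recovers_templates_exactly(self):
        """Two distinct shapes repeated 10x: medoids are the templates and
        the objective is zero."""
        a = np.array([0.0, 1.0, 0.0, -0.5, 0.0])
        b = np.array([0.0, -1.0, 0.3, 1.0, 0.0])
        waves = [a, b] * 10
        rr = [0.9 if i % 2 == 0 else 1.0 for i in range(20)]
        bs = beatset_from_waveforms(waves, rr=rr)
        cr = k_medoids_dtw(bs, seed=3)
        assert cr.objective_trace[-1] == 0.0
        assert cr.n1 == cr.n2 == 10
        # groups are exactly the two templates (cluster 1 = shorter RR here)
        assert {tuple(cr.C1), tuple(cr.C2)} == {
            tuple(a / np.max(np.abs(a))), tuple(b / np.max(np.abs(b)))
        }

    def test_planted_regimes_recovered(self, planted_beats, planted_clustering):
        agree = label_agreement(planted_clustering.labels, planted_beats["labels"])
        assert agree >= 0.95

    def test_objective_non_increasing(self, planted_clustering):
        trace = planted_clustering.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_seed_reproducibility(self, planted_beats):
        a = k_medoids_dtw(planted_beats["beats"], seed=5)
        b = k_medoids_dtw(planted_beats["beats"], seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.medoid_indices == b.medoid_indices

    def test_cluster_one_has_higher_heart_rate(self, planted_beats,
                                               planted_clustering):
        bs = planted_beats["beats"]
        hr = bs.hr
        labels = planted_clustering.labels
        assert hr[labels == 1].mean() > hr[labels == 2].mean()

    def test_order_permutation_invariance(self):
        """Same initial medoid beats => same partition, regardless of the
        order beats are listed in."""
        rng = np.random.default_rng(7)
        waves = [rng.normal(size=30) + (5.0 if i % 2 else 0.0) for i in range(12)]
        rr = list(np.linspace(0.8, 1.2, 12))
        bs = beatset_from_waveforms(waves, rr=rr)
        cr = k_medoids_dtw(bs, seed=1, init="farthest")
        perm = rng.permutation(12)
        bs_p = beatset_from_waveforms([waves[i] for i in perm],
                                      rr=[rr[i] for i in perm])
        cr_p = k_medoids_dtw(bs_p, seed=1, init="farthest")
        # compare partitions through the permutation
        np.testing.assert_array_equal(cr_p.labels, cr.labels[perm])

    def test_too_few_beats_rejected(self):
        bs = beatset_from_waveforms([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            k_medoids_dtw(bs, seed=0)

    def test_unnormalized_beats_rejected(self):
        fs = 1000.0
        scg = np.random.default_rng(0).normal(size=4000)
        bs = scgvar.segment_beats(scg, fs, np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="normalized"):
            k_medoids_dtw(bs, seed=0)


class TestPhaseCrossTab:
    def test_planted_coupling_scores_high(self, planted_beats,
                                          planted_clustering):
        table, score = cross_tabulate_phase(
            planted_clustering, planted_beats["phases"]
        )
        assert table.to_numpy().sum() == len(planted_beats["beats"])
        assert table.shape == (2, 4)
        assert score >= 0.80
        # cluster 1 concentrates in the inspiratory phases
        c1 = table.loc[1]
        assert c1["LLV-INS"] + c1["HLV-INS"] >= 0.8 * c1.sum()

    def test_no_modulation_scores_near_chance(self):
        """With no morphology modulation and no respiration-coupled beat
        length (rsa_depth=0) or wander, clusters split on noise only."""
        cfg = scgvar.GeneratorConfig(
            duration_s=40, seed=17, cluster_mod_depth=0.0, noise_sd=0.3,
            rsa_depth=0.0, baseline_wander_amp=0.0,
        )
        record, gt = scgvar.generate_recording(cfg)
        bs = scgvar.segment_beats(
            record.channels["scg_dv"], record.fs, gt.r_times
        )
        nbs = scgvar.normalize_beats(bs)
        cr = k_medoids_dtw(nbs, seed=2)
        _, score = cross_tabulate_phase(cr, gt.resp_phase[: len(nbs)])
        assert score < 0.75

    def test_single_phase_degenerates_to_one_column(self):
        waves = [np.array([0.0, 1.0, 0.0]), np.array([0.0, -1.0, 0.0])] * 3
        bs = beatset_from_waveforms(waves)
        cr = k_medoids_dtw(bs, seed=0)
        table, _ = cross_tabulate_phase(cr, ["LLV-INS"] * 6)
        assert table["LLV-INS"].sum() == 6
        assert table.drop(columns="LLV-INS").to_numpy().sum() == 0

    def test_length_mismatch_rejected(self, planted_clustering):
        with pytest.raises(ValueError):
            cross_tabulate_phase(planted_clustering, ["LLV-INS"])
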