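"""Feature extraction: cluster distances, spectra, timing, heart rate."""

import numpy as np
import pytest

import scgvar
from scgvar import (
    GeneratorConfig,
    band_energy_ratios,
    compute_cti,
    detect_ao_ac,
    generate_recording,
    heart_rate_by_cluster,
    inter_cluster_distance,
    intra_cluster_distance,
)
from scgvar.cluster import dtw_distance, k_medoids_dtw

from test_cluster import beatset_from_waveforms


def direct_distance_sums(cr, bs, crossed):
    """Independent direct summation of the cluster-distance definitions."""
    waves = bs.waveforms(raw=True)
    C1 = waves[cr.medoid_index_1]
    C2 = waves[cr.medoid_index_2]
    idx1 = [i for i, lab in enumerate(cr.labels) if lab == 1]
    idx2 = [i for i, lab in enumerate(cr.labels) if lab == 2]
    if crossed:
        total = sum(dtw_distance(C2, waves[i]) for i in idx1)
        total += sum(dtw_distance(C1, waves[i]) for i in idx2)
    else:
        total = sum(dtw_distance(C1, waves[i]) for i in idx1)
        total += sum(dtw_distance(C2, waves[i]) for i in idx2)
    return total / (len(idx1) + len(idx2))


class TestClusterDistances:
    def test_two_singletons_intra_zero_inter_is_pair_distance(self):
        a = np.array([0.0, 2.0, 0.0, 1.0])
        b = np.array([0.0, -1.0, 3.0, 0.0])
        bs = beatset_from_waveforms([a, b], rr=[0.9, 1.0])
        cr = k_medoids_dtw(bs, seed=0)
        assert intra_cluster_distance(cr, bs) == 0.0
        assert inter_cluster_distance(cr, bs) == pytest.approx(
            dtw_distance(a, b)
        )

    def test_identical_beats_give_zero_distances(self):
        waves = [np.array([0.0, 1.0, -0.5])] * 6
        bs = beatset_from_waveforms(waves)
        cr = k_medoids_dtw(bs, seed=1)
        assert intra_cluster_distance(cr, bs) == 0.0
        assert inter_cluster_distance(cr, bs) == 0.0

    def test_matches_independent_direct_summation(
        self, planted_beats, planted_clustering
    ):
        bs = planted_beats["beats"]
        cr = planted_clustering
        assert intra_cluster_distance(cr, bs) == pytest.approx(
            direct_distance_sums(cr, bs, crossed=False), rel=1e-12
        )
        assert inter_cluster_distance(cr, bs) == pytest.approx(
            direct_distance_sums(cr, bs, crossed=True), rel=1e-12
        )

    def test_planted_regimes_have_intra_below_inter(
        self, planted_beats, planted_clustering
    ):
        bs = planted_beats["beats"]
        assert intra_cluster_distance(planted_clustering, bs) < \
            inter_cluster_distance(planted_clustering, bs)

    def test_separation_grows_with_modulation_depth(self):
        gaps = []
        for depth in (0.2, 0.6):
            cfg = GeneratorConfig(
                duration_s=30, seed=37, cluster_mod_depth=depth, noise_sd=0.05,
            )
            record, gt = generate_recording(cfg)
            bs = scgvar.segment_beats(
                record.channels["scg_dv"], record.fs, gt.r_times
            )
            nbs = scgvar.normalize_beats(bs)
            cr = k_medoids_dtw(nbs, seed=0)
            gaps.append(
                inter_cluster_distance(cr, nbs) - intra_cluster_distance(cr, nbs)
            )
        assert gaps[1] > gaps[0] > 0


class TestSpectralRatios:
    def _tone_pair(self, freq, fs=1000.0, duration=1.0):
        t = np.arange(0, duration, 1 / fs)
        w = np.sin(2 * np.pi * freq * t)
        return (w, w.copy())

    def test_pure_15hz_tone_lands_in_second_band(self):
        """A pure in-band tone concentrates in its band; the rectangular
        window's leakage sidelobes keep ~2% outside it."""
        dist = band_energy_ratios(self._tone_pair(15.0), 1000.0)
        assert dist.ratios[dist.band_labels.index("11-20")] >= 0.95
        assert np.argmax(dist.ratios) == dist.band_labels.index("11-20")

    def test_pure_35hz_tone_lands_in_fourth_band(self):
        dist = band_energy_ratios(self._tone_pair(35.0), 1000.0)
        assert np.argmax(dist.ratios) == dist.band_labels.index("31-40")

    def test_ratios_sum_to_one_and_are_scale_invariant(self):
        rng = np.random.default_rng(5)
        w1, w2 = rng.normal(size=800), rng.normal(size=900)
        dist = band_energy_ratios((w1, w2), 1000.0)
        assert float(np.sum(dist.ratios)) == pytest.approx(1.0, abs=1e-6)
        scaled = band_energy_ratios((w1 * 37.0, w2 * 0.01), 1000.0)
        np.testing.assert_allclose(scaled.ratios, dist.ratios, atol=1e-12)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            band_energy_ratios(self._tone_pair(15.0, fs=80.0), 80.0)


class TestTimingIntervals:
    def test_cti_arithmetic(self):
        pep, lvep, ratio = compute_cti(0.0, 0.070, 0.370)
        assert pep == pytest.approx(70.0)
        assert lvep == pytest.approx(300.0)
        assert ratio == pytest.approx(70 / 300)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            compute_cti(0.07, 0.07, 0.370)

    def test_planted_ao_ac_recovered_on_medoid(self, clean_recording):
        record, gt = clean_recording
        fs = record.fs
        bs = scgvar.segment_beats(record.channels["scg_dv"], fs, gt.r_times)
        beat = bs.beats[2]
        ao, ac = detect_ao_ac(beat.samples, fs)
        start_t = beat.r_time - 0.1
        assert abs((start_t + ao) - gt.ao_times[2]) <= 0.005
        assert abs((start_t + ac) - gt.ac_times[2]) <= 0.010

    def test_missing_ac_packet_is_flagged(self):
        cfg = GeneratorConfig(
            duration_s=15, seed=41, ac_amp=0.0, noise_sd=0.0,
            baseline_wander_amp=0.0, cluster_mod_depth=0.0, ecg_noise_sd=0.0,
        )
        record, gt = generate_recording(cfg)
        bs = scgvar.segment_beats(record.channels["scg_dv"], record.fs, gt.r_times)
        ao, ac = detect_ao_ac(bs.beats[1].samples, record.fs)
        assert np.isfinite(ao)
        assert np.isnan(ac)

    def test_tie_takes_earlier_peak(self):
        fs = 1000.0
        w = np.zeros(800)
        w[150] = 1.0   # 50 ms after R
        w[180] = 1.0   # equal-height later peak
        ao, _ = detect_ao_ac(w, fs)
        assert ao == pytest.approx(0.150)

    def test_pep_lvep_grid_recovery_through_fiducials(self):
        """Planted PEP/LVEP over a physiologic grid recovered within 5 ms."""
        for pep, lvep in [(60, 320), (70, 300), (80, 280), (90, 260)]:
            cfg = GeneratorConfig(
                duration_s=15, seed=43 + pep, pep_ms=pep, lvep_ms=lvep,
                jitter_sd_ms=0.0, noise_sd=0.05,
            )
            record, gt = generate_recording(cfg)
            bs = scgvar.segment_beats(
                record.channels["scg_dv"], record.fs, gt.r_times
            )
            b = bs.beats[3]
            ao, ac = detect_ao_ac(b.samples, record.fs)
            q_rel = gt.q_times[3] - (b.r_time - 0.1)
            got_pep, got_lvep, _ = compute_cti(q_rel, ao, ac)
            assert abs(got_pep - pep) <= 5.0
            assert abs(got_lvep - lvep) <= 5.0


class TestHeartRate:
    def test_constant_rr_means_and_zero_se(self):
        waves = [np.array([0.0, 1.0, 0.0])] * 6
        bs = beatset_from_waveforms(waves, rr=[1.0] * 6)
        hr = heart_rate_by_cluster(bs, np.array([1, 1, 1, 2, 2, 2]))
        assert hr[1] == (pytest.approx(60.0), pytest.approx(0.0))
        assert hr[2] == (pytest.approx(60.0), pytest.approx(0.0))

    def test_cluster_means_reflect_rr(self):
        waves = [np.array([0.0, 1.0, 0.0])] * 4
        bs = beatset_from_waveforms(waves, rr=[0.9, 0.9, 1.0, 1.0])
        hr = heart_rate_by_cluster(bs, np.array([1, 1, 2, 2]))
        assert hr[1][0] == pytest.approx(60 / 0.9)
        assert hr[2][0] == pytest.approx(60.0)

    def test_rsa_coupling_makes_cluster_one_faster(
        self, planted_beats, planted_clustering
    ):
        hr = heart_rate_by_cluster(
            planted_beats["beats"], planted_clustering.labels
        )
        assert hr[1][0] > hr[2][0]

    def test_label_mismatch_rejected(self):
        waves = [np.array([0.0, 1.0, 0.0])] * 3
        bs = beatset_from_waveforms(waves)
        with pytest.raises(ValueError):
            heart_rate_by_cluster(bs, np.array([1, 2]))
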