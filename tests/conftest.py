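"""Shared fixtures: small ground-truthed synthetic recordings.

Recordings are module-scoped where processing is expensive (clustering is
quadratic in beats), so several tests can share one generated cohort.
"""

import numpy as np
import pytest

import scgvar
from scgvar import segment as seg


@pytest.fixture(scope="session")
def clean_cfg():
    """No noise, no wander, no regime modulation: every beat identical."""
    return scgvar.GeneratorConfig(
        duration_s=20.0,
        cluster_mod_depth=0.0,
        noise_sd=0.0,
        baseline_wander_amp=0.0,
        ecg_noise_sd=0.0,
        jitter_sd_ms=0.0,
        rsa_depth=0.0,
        hr_mean=60.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_cfg):
    return scgvar.generate_recording(clean_cfg)


@pytest.fixture(scope="session")
def planted_cfg():
    """Strong two-regime morphology, low noise: separable clusters."""
    return scgvar.GeneratorConfig(
        duration_s=40.0,
        cluster_mod_depth=0.5,
        noise_sd=0.05,
        baseline_wander_amp=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_recording(planted_cfg):
    return scgvar.generate_recording(planted_cfg)


@pytest.fixture(scope="session")
def planted_beats(planted_recording):
    """Conditioned, segmented, normalized beats plus aligned ground truth."""
    record, gt = planted_recording
    cond = scgvar.preprocess_record(record)
    r_times = seg.detect_r_peaks(cond.channels["ecg"], cond.fs)
    q_times, _ = seg.detect_q_points(cond.channels["ecg"], cond.fs, r_times)
    bs = seg.segment_beats(cond.channels["scg_dv"], cond.fs, r_times)
    nbs = seg.normalize_beats(bs)
    n = len(nbs)
    return {
        "beats": nbs,
        "q_times": q_times[:n],
        "labels": gt.planted_label[:n],
        "phases": gt.resp_phase[:n],
        "gt": gt,
        "fs": cond.fs,
    }


@pytest.fixture(scope="session")
def planted_clustering(planted_beats):
    cr = scgvar.k_medoids_dtw(planted_beats["beats"], seed=0)
    return cr


def label_agreement(labels: np.ndarray, planted: np.ndarray) -> float:
    """Best agreement over the two cluster-label permutations."""
    labels = np.asarray(labels)
    planted = np.asarray(planted)
    direct = np.mean(labels == planted)
    flipped = np.mean(labels == (3 - planted))
    return float(max(direct, flipped))
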