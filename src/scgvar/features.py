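"""SCG feature families computed from a clustered beat set.

Four families, per recording:

* morphological variability — mean DTW of beats to their own cluster's
  medoid (intra) and to the opposite medoid (inter), in milli-g;
* spectral distribution — energy in five bands (nominally 0.5-10, 11-20,
  21-30, 31-40, 41-50 Hz) relative to the total in 0.5-50 Hz, averaged
  over the two cluster medoids;
* cardiac timing intervals — PEP (ECG Q point to the AO peak of SCG1) and
  LVEP (AO peak to the AC peak of SCG2), per medoid and averaged;
* heart rate per cluster (mean and standard error of 60/RR).

Clustering operates on unit-peak beats, but morphological distances are
reported on the raw milli-g waveforms (against the medoids' raw
waveforms) so the variability carries physical units; a flag restores
normalized-scale output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .cluster import ClusterResult, dtw_distance
from .segment import BeatSet

#: nominal band labels (Hz) and the contiguous half-open edges that
#: implement them; the last band closes at 50 Hz so the bins tile the
#: 0.5-50 Hz reference exactly
BAND_LABELS = ("0.5-10", "11-20", "21-30", "31-40", "41-50")
BAND_EDGES = (0.5, 10.5, 20.5, 30.5, 40.5, 50.0)


@dataclass
class VariabilityResult:
    intra: float   # milli-g
    inter: float   # milli-g

    def __post_init__(self) -> None:
        if self.intra < 0 or self.inter < 0:
            raise ValueError("distances must be nonnegative")


@dataclass
class SpectralDistribution:
    band_labels: tuple[str, ...]
    band_edges: tuple[float, ...]
    ratios: np.ndarray            # one per band, sums to 1
    reference_band: tuple[float, float] = (0.5, 50.0)

    def __post_init__(self) -> None:
        if np.any(self.ratios < 0) or np.any(self.ratios > 1):
            raise ValueError("band ratios must lie in [0, 1]")
        if abs(float(np.sum(self.ratios)) - 1.0) > 1e-6:
            raise ValueError("band ratios must sum to 1")


@dataclass
class CTIResult:
    """Cardiac timing intervals for the two medoids and their average.

    Times are in ms relative to beat start (beats start 0.1 s before R).
    """

    pep_ms: tuple[float, float]
    lvep_ms: tuple[float, float]
    pep_ms_avg: float
    lvep_ms_avg: float
    pep_lvep_ratio: float
    q_time_ms: tuple[float, float]
    ao_time_ms: tuple[float, float]
    ac_time_ms: tuple[float, float]


def _member_distances(
    cr: ClusterResult, bs: BeatSet, crossed: bool, raw: bool
) -> float:
    waves = bs.waveforms(raw=raw)
    m1 = waves[cr.medoid_index_1]
    m2 = waves[cr.medoid_index_2]
    if crossed:
        ref = {1: m2, 2: m1}
    else:
        ref = {1: m1, 2: m2}
    total = 0.0
    for lab, w in zip(cr.labels, waves):
        total += dtw_distance(ref[int(lab)], w)
    return total / len(cr.labels)


def intra_cluster_distance(
    cr: ClusterResult, bs: BeatSet, raw: bool = True
) -> float:
    """Mean DTW of each beat to its own cluster's medoid.

    ``(1/(n1+n2)) * [sum_i dtw(C1, X_i1) + sum_i dtw(C2, X_i2)]``, on raw
    milli-g waveforms by default.
    """
    if cr.n1 == 0 or cr.n2 == 0:
        raise ValueError("both clusters must be non-empty")
    return _member_distances(cr, bs, crossed=False, raw=raw)


def inter_cluster_distance(
    cr: ClusterResult, bs: BeatSet, raw: bool = True
) -> float:
    """Mean DTW of each beat to the *opposite* cluster's medoid.

    ``(1/(n1+n2)) * [sum_i dtw(C2, X_i1) + sum_i dtw(C1, X_i2)]``.
    """
    if cr.n1 == 0 or cr.n2 == 0:
        raise ValueError("both clusters must be non-empty")
    return _member_distances(cr, bs, crossed=True, raw=raw)


def morphological_variability(cr: ClusterResult, bs: BeatSet) -> VariabilityResult:
    return VariabilityResult(
        intra=intra_cluster_distance(cr, bs),
        inter=inter_cluster_distance(cr, bs),
    )


# ----------------------------------------------------------- spectral

def _band_energy(x: np.ndarray, fs: float) -> np.ndarray:
    nfft = int(2 ** np.ceil(np.log2(max(4 * len(x), 8))))
    freqs, pxx = sps.periodogram(x, fs=fs, window="boxcar", nfft=nfft)
    out = np.empty(len(BAND_EDGES) - 1)
    for k in range(len(out)):
        lo, hi = BAND_EDGES[k], BAND_EDGES[k + 1]
        mask = (freqs >= lo) & (freqs < hi) if k < len(out) - 1 else (
            (freqs >= lo) & (freqs <= hi)
        )
        out[k] = pxx[mask].sum()
    return out


def band_energy_ratios(
    medoids: tuple[np.ndarray, np.ndarray], fs: float
) -> SpectralDistribution:
    """Per-band spectral energy relative to 0.5-50 Hz, medoid-averaged.

    Each medoid's rectangular-window periodogram (zero-padded to the next
    power of two >= 4x length) is binned into the five bands and divided
    by its total in the reference band; the two distributions are then
    averaged. Ratios are amplitude-scale invariant by construction.
    """
    if fs < 100:
        raise ValueError("bands up to 50 Hz are undefined below fs = 100 Hz")
    dists = []
    for w in medoids:
        e = _band_energy(np.asarray(w, dtype=float), fs)
        total = e.sum()
        if total <= 0:
            raise ValueError("medoid has no energy in the 0.5-50 Hz band")
        dists.append(e / total)
    ratios = np.mean(dists, axis=0)
    return SpectralDistribution(
        band_labels=BAND_LABELS, band_edges=BAND_EDGES, ratios=ratios
    )


# ----------------------------------------------------- timing intervals

def detect_ao_ac(
    medoid: np.ndarray,
    fs: float,
    pre_s: float = 0.1,
    ao_window_s: tuple[float, float] = (0.0, 0.200),
    ac_window_s: tuple[float, float] = (0.250, 0.450),
    min_rel_prominence: float = 0.01,
) -> tuple[float, float]:
    """AO and AC peak times (s, relative to beat start) on a medoid beat.

    The beat is assumed to start ``pre_s`` before its R peak. AO is the
    tallest local maximum in (R, R+200 ms], AC the tallest in
    (R+250 ms, R+450 ms]; windows are configurable and chosen to bracket
    physiologic systole at resting heart rate. Candidate peaks must have
    prominence of at least ``min_rel_prominence`` times the beat's peak
    amplitude, so numerical ripple does not pass for a wave complex. Ties
    take the earlier peak; a window with no qualifying local maximum
    yields NaN for that fiducial.
    """
    medoid = np.asarray(medoid, dtype=float)
    r_idx = int(round(pre_s * fs))
    prom = min_rel_prominence * float(np.max(np.abs(medoid)))

    def tallest(win_lo_s: float, win_hi_s: float) -> float:
        lo = r_idx + int(round(win_lo_s * fs)) + 1
        hi = min(r_idx + int(round(win_hi_s * fs)) + 1, len(medoid))
        if hi - lo < 3:
            return float("nan")
        seg = medoid[lo:hi]
        peaks, _ = sps.find_peaks(seg, prominence=prom)
        if len(peaks) == 0:
            return float("nan")
        best = peaks[np.argmax(seg[peaks])]   # argmax -> earliest on ties
        return (lo + best) / fs

    ao = tallest(*ao_window_s)
    ac = tallest(*ac_window_s)
    return ao, ac


def compute_cti(
    q_time: float, ao_time: float, ac_time: float
) -> tuple[float, float, float]:
    """PEP, LVEP (ms) and their ratio from one beat's fiducials (s)."""
    if not q_time < ao_time < ac_time:
        raise ValueError(
            f"fiducial ordering violated: q={q_time}, ao={ao_time}, ac={ac_time}"
        )
    pep = (ao_time - q_time) * 1000.0
    lvep = (ac_time - ao_time) * 1000.0
    return pep, lvep, pep / lvep


def medoid_cti(
    cr: ClusterResult,
    bs: BeatSet,
    q_times: np.ndarray,
    fs: float,
    pre_s: float = 0.1,
    ao_window_s: tuple[float, float] = (0.0, 0.200),
    ac_window_s: tuple[float, float] = (0.250, 0.450),
) -> CTIResult:
    """CTIs for both cluster medoids plus their average.

    ``q_times`` are absolute Q times (s) aligned with the beats of ``bs``;
    each medoid's Q is converted to beat-relative time before the PEP is
    formed with the detected AO.
    """
    peps, lveps, qs, aos, acs = [], [], [], [], []
    waves = bs.waveforms(raw=True)
    for m_idx in cr.medoid_indices:
        beat = bs.beats[m_idx]
        q_rel = q_times[m_idx] - (beat.r_time - pre_s)
        if not np.isfinite(q_rel):
            raise ValueError(f"medoid beat {m_idx} has no valid Q point")
        ao, ac = detect_ao_ac(waves[m_idx], fs, pre_s, ao_window_s, ac_window_s)
        if not (np.isfinite(ao) and np.isfinite(ac)):
            raise ValueError(f"medoid beat {m_idx}: AO/AC peak not found")
        pep, lvep, _ = compute_cti(q_rel, ao, ac)
        peps.append(pep)
        lveps.append(lvep)
        qs.append(q_rel * 1000.0)
        aos.append(ao * 1000.0)
        acs.append(ac * 1000.0)
    pep_avg = float(np.mean(peps))
    lvep_avg = float(np.mean(lveps))
    return CTIResult(
        pep_ms=(peps[0], peps[1]),
        lvep_ms=(lveps[0], lveps[1]),
        pep_ms_avg=pep_avg,
        lvep_ms_avg=lvep_avg,
        pep_lvep_ratio=pep_avg / lvep_avg,
        q_time_ms=(qs[0], qs[1]),
        ao_time_ms=(aos[0], aos[1]),
        ac_time_ms=(acs[0], acs[1]),
    )


# ------------------------------------------------------------ heart rate

def heart_rate_by_cluster(
    bs: BeatSet, labels: np.ndarray
) -> dict[int, tuple[float, float]]:
    """Per-cluster mean heart rate and standard error (bpm)."""
    labels = np.asarray(labels)
    if len(labels) != len(bs):
        raise ValueError("labels must align with beats")
    hr = bs.hr
    out: dict[int, tuple[float, float]] = {}
    for j in (1, 2):
        vals = hr[labels == j]
        if len(vals) == 0:
            out[j] = (float("nan"), float("nan"))
        elif len(vals) == 1:
            out[j] = (float(vals[0]), 0.0)
        else:
            out[j] = (
                float(np.mean(vals)),
                float(np.std(vals, ddof=1) / np.sqrt(len(vals))),
            )
    return out
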