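"""ECG R-peak detection (Pan-Tompkins) and R-gated SCG segmentation.

Beats are cut so that each SCG event starts 0.1 s before its R peak and
ends 0.1 s before the next R peak; the last R peak therefore anchors no
beat. Windows are half-open in 0-based sample indices, so consecutive
beats tile the record with no gap or overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger("scgvar")

# Pan-Tompkins constants (seconds unless noted)
PT_BANDPASS = (5.0, 15.0)
PT_INTEGRATION_WINDOW = 0.150
PT_REFRACTORY = 0.200
PT_TWAVE_WINDOW = 0.360   # slope comparison window for T-wave rejection
PT_SEARCHBACK_FACTOR = 1.66


@dataclass
class BeatEvent:
    """One R-gated SCG segment."""

    index: int
    r_time: float
    start_sample: int
    end_sample: int          # half-open [start, end)
    samples: np.ndarray      # milli-g; unit-peak if ``normalized``
    rr_s: float
    hr_bpm: float
    normalized: bool = False
    raw_samples: np.ndarray | None = None   # original milli-g amplitudes

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ValueError("end_sample must exceed start_sample")
        if len(self.samples) != self.end_sample - self.start_sample:
            raise ValueError("samples length must equal end - start")

    @property
    def raw(self) -> np.ndarray:
        return self.raw_samples if self.raw_samples is not None else self.samples


@dataclass
class BeatSet:
    """Ordered, non-overlapping beats from one recording."""

    fs: float
    beats: list[BeatEvent]
    posture: str = "supine"
    session: int = 1
    subject_id: str = "S00"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = [b.r_time for b in self.beats]
        if any(b > a for a, b in zip(r[1:], r[:-1])):
            raise ValueError("beats must be ordered by r_time")

    def __len__(self) -> int:
        return len(self.beats)

    def __iter__(self):
        return iter(self.beats)

    @property
    def rr(self) -> np.ndarray:
        return np.array([b.rr_s for b in self.beats])

    @property
    def hr(self) -> np.ndarray:
        return np.array([b.hr_bpm for b in self.beats])

    def waveforms(self, raw: bool = False) -> list[np.ndarray]:
        return [b.raw if raw else b.samples for b in self.beats]


# ------------------------------------------------------- R-peak detection

def _pt_preprocess(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass, derivative, squaring, moving-window integration."""
    sos = signal.butter(2, PT_BANDPASS, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, ecg)
    deriv = np.gradient(filt) * fs
    squared = deriv**2
    win = max(1, int(round(PT_INTEGRATION_WINDOW * fs)))
    return np.convolve(squared, np.ones(win) / win, mode="same")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak times via the Pan-Tompkins stages with adaptive thresholds.

    Candidate peaks of the moving-window-integrated slope energy are
    screened against dual adaptive thresholds (signal/noise running
    estimates, refractory 200 ms); a search-back pass at half threshold
    fills gaps longer than 1.66x the running RR average. Peak positions are
    refined to the local ECG maximum. A flat or empty record yields an
    empty array rather than an error.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 200:
        raise ValueError("fs must be at least 200 Hz for QRS detection")
    if len(ecg) < int(2 * fs):
        raise ValueError("need at least 2 s of ECG")
    if np.ptp(ecg) == 0:
        return np.array([])

    mwi = _pt_preprocess(ecg, fs)
    refractory = int(round(PT_REFRACTORY * fs))
    peaks, _ = signal.find_peaks(mwi, distance=refractory)
    if len(peaks) == 0:
        return np.array([])

    # threshold bootstrap from the first two seconds
    head = mwi[: int(2 * fs)]
    spki = 0.6 * head.max()
    npki = 0.5 * head.mean()

    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for p in peaks:
        if mwi[p] > threshold():
            accepted.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(accepted) >= 2:
                rr_history.append((accepted[-1] - accepted[-2]) / fs)
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki

    # search-back: revisit long gaps at half threshold
    if rr_history:
        rr_avg = float(np.mean(rr_history[-8:]))
        limit = PT_SEARCHBACK_FACTOR * rr_avg * fs
        filled: list[int] = []
        prev = None
        for p in accepted:
            if prev is not None and p - prev > limit:
                seg = [
                    c for c in peaks
                    if prev + refractory < c < p - refractory
                    and mwi[c] > 0.5 * threshold()
                ]
                if seg:
                    filled.append(max(seg, key=lambda c: mwi[c]))
            filled.append(p)
            prev = p
        accepted = sorted(filled)

    # refine each fiducial to the nearby raw-ECG maximum
    half = int(round(0.075 * fs))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refractory:
            if ecg[p] > ecg[out[-1]]:
                out[-1] = int(p)
        else:
            out.append(int(p))
    return np.asarray(out) / fs


def detect_q_points(
    ecg: np.ndarray,
    fs: float,
    r_times: np.ndarray,
    window_s: float = 0.050,
) -> tuple[np.ndarray, np.ndarray]:
    """Q as the ECG minimum in [R - window, R) for each R peak.

    Returns ``(q_times, flags)``; a beat is flagged when its window is
    empty (R too close to record start) — its Q is NaN — or when the argmin
    sits on the window's left edge (degenerate monotone window; the edge
    value is still reported).
    """
    ecg = np.asarray(ecg, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    q_times = np.full(len(r_times), np.nan)
    flags = np.zeros(len(r_times), dtype=bool)
    w = int(round(window_s * fs))
    for i, rt in enumerate(r_times):
        r_idx = int(round(rt * fs))
        lo = r_idx - w
        if lo < 0:
            flags[i] = True
            logger.warning("beat %d: Q window precedes record start", i)
            continue
        win = ecg[lo:r_idx]
        if len(win) == 0:
            flags[i] = True
            continue
        k = int(np.argmin(win))
        q_times[i] = (lo + k) / fs
        if k == 0:
            flags[i] = True
    return q_times, flags


# ---------------------------------------------------------- segmentation

def segment_beats(
    scg: np.ndarray,
    fs: float,
    r_times: np.ndarray,
    pre_s: float = 0.1,
    posture: str = "supine",
    session: int = 1,
    subject_id: str = "S00",
) -> BeatSet:
    """Cut the SCG into beats spanning [R_i - pre, R_{i+1} - pre).

    The last R peak yields no beat (no following R to close the window); a
    first R earlier than ``pre_s`` into the record is dropped with a log
    message.
    """
    scg = np.asarray(scg, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) < 2:
        raise ValueError("need at least two R peaks to segment")
    dropped = 0
    if r_times[0] < pre_s:
        logger.info("first beat dropped: R at %.3f s precedes the %.1f s margin",
                    float(r_times[0]), pre_s)
        r_times = r_times[1:]
        dropped = 1
    beats: list[BeatEvent] = []
    for i in range(len(r_times) - 1):
        start = int(round((r_times[i] - pre_s) * fs))
        end = int(round((r_times[i + 1] - pre_s) * fs))
        rr = r_times[i + 1] - r_times[i]
        beats.append(
            BeatEvent(
                index=i,
                r_time=float(r_times[i]),
                start_sample=start,
                end_sample=min(end, len(scg)),
                samples=scg[start:end].copy(),
                rr_s=float(rr),
                hr_bpm=60.0 / float(rr),
            )
        )
    return BeatSet(
        fs=fs, beats=beats, posture=posture, session=session,
        subject_id=subject_id, meta={"dropped_first": dropped},
    )


def normalize_beats(bs: BeatSet) -> BeatSet:
    """Scale every beat to unit peak (|sample|max = 1), keeping the raw
    milli-g waveform alongside for distance reporting."""
    out: list[BeatEvent] = []
    for b in bs.beats:
        peak = float(np.max(np.abs(b.raw)))
        if peak == 0:
            raise ValueError(f"beat {b.index} is identically zero; cannot normalize")
        out.append(
            BeatEvent(
                index=b.index,
                r_time=b.r_time,
                start_sample=b.start_sample,
                end_sample=b.end_sample,
                samples=b.raw / peak,
                rr_s=b.rr_s,
                hr_bpm=b.hr_bpm,
                normalized=True,
                raw_samples=b.raw,
            )
        )
    return BeatSet(
        fs=bs.fs, beats=out, posture=bs.posture, session=bs.session,
        subject_id=bs.subject_id, meta=dict(bs.meta),
    )
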