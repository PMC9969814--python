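"""Synthetic ECG + SCG + respiration generator with known ground truth.

The generator emulates the structure of a resting dorsoventral SCG
recording gated by a simultaneous ECG:

* RR intervals follow respiratory sinus arrhythmia (RSA):
  ``RR_i = (60/hr_mean) * (1 + rsa_depth * sin(2*pi*f_resp*t_i))``.
* The ECG contributes, per beat, a narrow positive R deflection and a small
  negative Q deflection 30 ms earlier (P and T waves are deliberately
  absent — only Q and R are used downstream).
* The SCG contributes, per beat, two Gaussian-windowed cosine packets: the
  AO complex (aortic opening, ~20 Hz carrier) centred ``pep_ms`` after Q and
  the smaller AC complex (aortic closure, ~30 Hz carrier) centred
  ``lvep_ms`` after AO. Cosine carriers put the packet maximum exactly at
  the planted fiducial time.
* Beat morphology is modulated by a two-regime function of respiratory
  phase: inspiration beats (regime 1) keep the baseline shape, expiration
  beats (regime 2) get rebalanced AO/AC amplitudes plus an extra
  mid-systolic packet, with the contrast scaled by ``cluster_mod_depth``.
  This plants a known two-cluster structure for the clustering stage.
* Baseline wander at the respiratory rate and white Gaussian noise are
  added; lung volume is a raised cosine and flow its analytic derivative.

Lung volume is phased so that inspiration (flow > 0) coincides with the
shorter-RR half of the RSA cycle: heart rate is higher during inspiration,
as in real recordings, so the inspiration cluster is the faster one.

Everything random is drawn from one ``numpy`` generator seeded from
``GeneratorConfig.seed``; identical configs produce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .preprocess import SignalRecord

RESP_PHASES = ("LLV-INS", "HLV-INS", "HLV-EXP", "LLV-EXP")

#: per-posture (pep_ms, lvep_ms, hr_mean) presets for a healthy resting adult
POSTURE_PRESETS: dict[str, dict[str, float]] = {
    "supine": {"pep_ms": 70.0, "lvep_ms": 300.0, "hr_mean": 62.0},
    "tilt45": {"pep_ms": 74.0, "lvep_ms": 286.9, "hr_mean": 65.0},
    "sitting": {"pep_ms": 80.6, "lvep_ms": 272.0, "hr_mean": 67.0},
}


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic recording.

    Units: times in the names (s/ms), rates in Hz or per-minute as named,
    SCG amplitudes in milli-g, ECG amplitudes in mV.
    """

    duration_s: float = 60.0
    fs: float = 1000.0
    hr_mean: float = 62.0           # beats/min
    rsa_depth: float = 0.08         # fraction of RR modulated by respiration
    resp_rate: float = 15.0         # breaths/min
    pep_ms: float = 70.0            # Q -> AO
    lvep_ms: float = 300.0          # AO -> AC
    cluster_mod_depth: float = 0.3  # regime-2 morphology contrast
    noise_sd: float = 0.2           # milli-g, additive white noise on SCG
    baseline_wander_amp: float = 1.0  # milli-g, at resp_rate
    seed: int = 0
    # secondary shape parameters
    qr_ms: float = 30.0             # Q precedes R by this much
    jitter_sd_ms: float = 2.0       # per-beat Gaussian jitter on PEP/LVEP
    ao_amp: float = 3.0             # milli-g
    ac_amp: float = 1.5             # milli-g
    ecg_noise_sd: float = 0.02      # mV
    tidal_volume_l: float = 0.5

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs < 200:
            raise ValueError("fs must be at least 200 Hz")
        if not 0 <= self.rsa_depth < 1:
            raise ValueError("rsa_depth must lie in [0, 1) (RR must stay positive)")
        min_rr_ms = 60000.0 / self.hr_mean * (1.0 - self.rsa_depth)
        if not 0 < self.pep_ms < self.pep_ms + self.lvep_ms < min_rr_ms:
            raise ValueError(
                f"need 0 < pep < pep+lvep < min RR ({min_rr_ms:.0f} ms); "
                f"got pep={self.pep_ms}, lvep={self.lvep_ms}"
            )

    @classmethod
    def for_posture(cls, posture: str, **overrides) -> "GeneratorConfig":
        """Config with per-posture PEP/LVEP/heart-rate presets applied."""
        params = dict(POSTURE_PRESETS[posture])
        params.update(overrides)
        return cls(**params)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Planted per-beat fiducials, labels and respiratory state."""

    r_times: np.ndarray      # s
    q_times: np.ndarray      # s
    ao_times: np.ndarray     # s
    ac_times: np.ndarray     # s
    planted_label: np.ndarray  # {1, 2} per beat
    resp_phase: list[str]      # 4-way phase label per beat
    lung_volume: np.ndarray | None = None
    flow: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.r_times)
        for name in ("q_times", "ao_times", "ac_times", "planted_label"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch ({n} beats)")
        if len(self.resp_phase) != n:
            raise ValueError("resp_phase length mismatch")
        if n and not (
            np.all(self.q_times < self.r_times)
            and np.all(self.r_times < self.ao_times)
            and np.all(self.ao_times < self.ac_times)
        ):
            raise ValueError("fiducial ordering q < r < ao < ac violated")

    @property
    def n_beats(self) -> int:
        return len(self.r_times)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "r_times": self.r_times.tolist(),
            "q_times": self.q_times.tolist(),
            "ao_times": self.ao_times.tolist(),
            "ac_times": self.ac_times.tolist(),
            "planted_label": [int(v) for v in self.planted_label],
            "resp_phase": list(self.resp_phase),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            r_times=np.asarray(d["r_times"], dtype=float),
            q_times=np.asarray(d["q_times"], dtype=float),
            ao_times=np.asarray(d["ao_times"], dtype=float),
            ac_times=np.asarray(d["ac_times"], dtype=float),
            planted_label=np.asarray(d["planted_label"], dtype=int),
            resp_phase=list(d["resp_phase"]),
        )


# ------------------------------------------------------------- RR series

def generate_rr_series(cfg: GeneratorConfig, t0: float = 0.0) -> np.ndarray:
    """RSA-modulated RR intervals whose cumulative sum fits in the record.

    RR_i is evaluated at the onset time t_i of beat i (first onset ``t0``),
    so the instantaneous rate tracks the respiratory phase at each beat.
    """
    base = 60.0 / cfg.hr_mean
    omega = 2.0 * np.pi * cfg.resp_rate / 60.0
    rr: list[float] = []
    t = t0
    while True:
        r = base * (1.0 + cfg.rsa_depth * np.sin(omega * t))
        if t + r > cfg.duration_s:
            break
        rr.append(r)
        t += r
    return np.asarray(rr)


# --------------------------------------------------------- respiration

def _lung_volume(t: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    # raised cosine: starts at end-inspiration (full), inspiration on sin<0
    omega = 2.0 * np.pi * cfg.resp_rate / 60.0
    return cfg.tidal_volume_l * 0.5 * (1.0 + np.cos(omega * t))


def _flow(t: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    omega = 2.0 * np.pi * cfg.resp_rate / 60.0
    return -cfg.tidal_volume_l * 0.5 * omega * np.sin(omega * t)


def classify_resp_phase(
    lung_volume: np.ndarray,
    flow: np.ndarray,
    fs: float,
    at_time: float | np.ndarray,
) -> str | list[str]:
    """4-way respiratory phase at a query time.

    INS iff flow > 0 (flow exactly 0 ties to EXP); HLV iff volume exceeds
    the mid-range, i.e. the mean of the sequence's min and max.
    """
    lung_volume = np.asarray(lung_volume, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if len(lung_volume) != len(flow):
        raise ValueError("volume and flow must share one sample grid")
    mid = 0.5 * (lung_volume.min() + lung_volume.max())
    scalar = np.isscalar(at_time)
    times = np.atleast_1d(np.asarray(at_time, dtype=float))
    idx = np.clip(np.round(times * fs).astype(int), 0, len(flow) - 1)
    labels = [
        ("HLV" if lung_volume[i] > mid else "LLV")
        + "-"
        + ("INS" if flow[i] > 0 else "EXP")
        for i in idx
    ]
    return labels[0] if scalar else labels


# ------------------------------------------------------------ recording

def _gauss_packet(
    t: np.ndarray, center: float, carrier_hz: float, width_s: float, amp: float
) -> np.ndarray:
    env = np.exp(-0.5 * ((t - center) / width_s) ** 2)
    return amp * env * np.cos(2.0 * np.pi * carrier_hz * (t - center))


def generate_recording(
    cfg: GeneratorConfig,
    subject_id: str = "S00",
    posture: str = "supine",
    session: int = 1,
) -> tuple[SignalRecord, GroundTruth]:
    """Build one synthetic recording and its fully populated ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    # beat grid: first R late enough for the pre-R beat margin and Q window
    r0 = 0.5
    rr = generate_rr_series(cfg, t0=r0)
    if len(rr) < 2:
        raise ValueError("recording too short for at least two beats")
    r_times = r0 + np.concatenate([[0.0], np.cumsum(rr[:-1])])

    volume = _lung_volume(t, cfg)
    flow = _flow(t, cfg)
    omega = 2.0 * np.pi * cfg.resp_rate / 60.0

    q_times = r_times - cfg.qr_ms / 1000.0
    jit = rng.normal(0.0, cfg.jitter_sd_ms / 1000.0, size=(2, len(r_times)))
    ao_times = q_times + cfg.pep_ms / 1000.0 + jit[0]
    ac_times = ao_times + cfg.lvep_ms / 1000.0 + jit[1]

    # regime 1 = inspiration (sin of respiratory phase < 0 at the R time)
    sin_phase = np.sin(omega * r_times)
    planted_label = np.where(sin_phase < 0, 1, 2).astype(int)
    resp_phase = classify_resp_phase(volume, flow, cfg.fs, r_times)

    ecg = np.zeros(n)
    scg = np.zeros(n)
    mod = cfg.cluster_mod_depth
    for i in range(len(r_times)):
        ecg += _gauss_packet(t, r_times[i], 0.0, 0.006, 1.0)
        ecg += _gauss_packet(t, q_times[i], 0.0, 0.004, -0.2)
        if planted_label[i] == 1:
            ao_amp, ac_amp, extra_amp = cfg.ao_amp, cfg.ac_amp, 0.0
        else:
            ao_amp = cfg.ao_amp * (1.0 - 0.5 * mod)
            ac_amp = cfg.ac_amp * (1.0 + mod)
            extra_amp = 0.6 * mod * cfg.ao_amp
        scg += _gauss_packet(t, ao_times[i], 20.0, 0.015, ao_amp)
        scg += _gauss_packet(t, ac_times[i], 30.0, 0.012, ac_amp)
        if extra_amp:
            scg += _gauss_packet(t, ao_times[i] + 0.080, 25.0, 0.012, extra_amp)

    scg += cfg.baseline_wander_amp * np.sin(omega * t)
    if cfg.noise_sd > 0:
        scg += rng.normal(0.0, cfg.noise_sd, size=n)
    if cfg.ecg_noise_sd > 0:
        ecg += rng.normal(0.0, cfg.ecg_noise_sd, size=n)

    record = SignalRecord(
        fs=cfg.fs,
        channels={"ecg": ecg, "scg_dv": scg, "lung_volume": volume, "flow": flow},
        subject_id=subject_id,
        posture=posture,
        session=session,
        meta={"seed": int(cfg.seed), "synthetic": True},
    )
    gt = GroundTruth(
        r_times=r_times,
        q_times=q_times,
        ao_times=ao_times,
        ac_times=ac_times,
        planted_label=planted_label,
        resp_phase=resp_phase,
        lung_volume=volume,
        flow=flow,
    )
    return record, gt
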