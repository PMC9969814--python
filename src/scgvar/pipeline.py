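"""End-to-end orchestration: cohorts, per-record runs, comparison tables.

A run is described by a :class:`RunManifest` — a list of records (paths to
CSV recordings, or generator configs for synthetic cohorts) plus the
pipeline parameters. Each record flows through conditioning, R/Q
detection, segmentation, normalization, K=2 DTW clustering and feature
extraction, yielding one feature row; rows assemble into a tidy table on
which postural (paired t + Cohen's d) and longitudinal (one-way ANOVA)
comparisons are computed.

Every record gets its own derived seed, ``crc32("subject|posture|session")``
mixed with the global seed, so noise is independent across records yet the
whole run is reproducible from one integer.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as clu
from . import features as feat
from . import preprocess as pre
from . import segment as seg
from . import stats as st
from .synth import GeneratorConfig, POSTURE_PRESETS, generate_recording

logger = logging.getLogger("scgvar")

POSTURE_PAIRS = (("supine", "tilt45"), ("tilt45", "sitting"), ("supine", "sitting"))

FEATURE_COLUMNS = (
    "intra", "inter",
    "ratio_0.5-10", "ratio_11-20", "ratio_21-30", "ratio_31-40", "ratio_41-50",
    "pep_ms", "lvep_ms", "pep_lvep_ratio",
    "hr_c1", "hr_c2", "hr_mean",
)


@dataclass
class PipelineParams:
    """Every numeric decision of the per-record pipeline in one place."""

    bp_low: float = 0.5
    bp_high: float = 50.0
    bp_order: int = 4
    bp_stop_atten_db: float = 40.0
    ma_order: int = 5
    fs_target: float = 1000.0
    pre_s: float = 0.1
    q_window_s: float = 0.050
    edge_guard_s: float = 2.0   # drop beats overlapping filter edge transients
    K: int = 2
    max_iter: int = 100
    cluster_init: str = "random"
    dtw_window: int | None = None


@dataclass
class RecordSpec:
    subject_id: str
    posture: str
    session: int
    path: str | None = None                  # CSV on disk, or ...
    config: GeneratorConfig | None = None    # ... generated on the fly

    def __post_init__(self) -> None:
        if (self.path is None) == (self.config is None):
            raise ValueError("exactly one of path/config must be set")


@dataclass
class RunManifest:
    records: list[RecordSpec]
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "seed": int(self.seed),
            "out_dir": self.out_dir,
            "params": asdict(self.params),
            "records": [
                {
                    "subject_id": r.subject_id,
                    "posture": r.posture,
                    "session": int(r.session),
                    "path": r.path,
                    "config": asdict(r.config) if r.config else None,
                }
                for r in self.records
            ],
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        d = yaml.safe_load(Path(path).read_text())
        records = [
            RecordSpec(
                subject_id=r["subject_id"],
                posture=r["posture"],
                session=int(r["session"]),
                path=r.get("path"),
                config=GeneratorConfig(**r["config"]) if r.get("config") else None,
            )
            for r in d["records"]
        ]
        return cls(
            records=records,
            params=PipelineParams(**d.get("params", {})),
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir"),
        )


def record_seed(global_seed: int, subject: str, posture: str, session: int) -> int:
    """Stable per-record seed below 2^31."""
    tag = zlib.crc32(f"{subject}|{posture}|{session}".encode())
    return int((global_seed * 1_000_003 + tag) % (2**31 - 1))


# -------------------------------------------------------------- cohorts

def make_cohort(
    n_subjects: int = 19,
    postures: tuple[str, ...] = ("supine", "tilt45", "sitting"),
    sessions: tuple[int, ...] = (1,),
    seed: int = 0,
    duration_s: float = 60.0,
    subject_sd: dict[str, float] | None = None,
    **config_overrides,
) -> RunManifest:
    """Manifest for a synthetic cohort with between-subject variation.

    Each subject carries Gaussian offsets on PEP, LVEP and resting heart
    rate (SDs roughly matching between-subject spread in healthy resting
    adults) that persist across postures and sessions, so paired postural
    comparisons see a consistent within-subject effect. Posture enters
    through the PEP/LVEP/HR presets.
    """
    sd = {"pep_ms": 9.0, "lvep_ms": 17.0, "hr_mean": 5.0}
    if subject_sd:
        sd.update(subject_sd)
    rng = np.random.default_rng(seed)
    offsets = {
        f"S{i:02d}": {k: rng.normal(0.0, v) for k, v in sd.items()}
        for i in range(1, n_subjects + 1)
    }
    records = []
    for subj, off in offsets.items():
        for posture in postures:
            for session in sessions:
                preset = POSTURE_PRESETS[posture]
                cfg = GeneratorConfig(
                    duration_s=duration_s,
                    pep_ms=preset["pep_ms"] + off["pep_ms"],
                    lvep_ms=preset["lvep_ms"] + off["lvep_ms"],
                    hr_mean=preset["hr_mean"] + off["hr_mean"],
                    seed=record_seed(seed, subj, posture, session),
                    **config_overrides,
                )
                records.append(
                    RecordSpec(subject_id=subj, posture=posture,
                               session=session, config=cfg)
                )
    return RunManifest(records=records, seed=seed)


def simulate_cohort(manifest: RunManifest, out_dir: str | Path) -> list[Path]:
    """Materialize a synthetic manifest: CSV + ground-truth JSON per record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in manifest.records:
        if r.config is None:
            raise ValueError("simulate_cohort needs generator configs")
        record, gt = generate_recording(
            r.config, subject_id=r.subject_id, posture=r.posture, session=r.session
        )
        stem = f"{r.subject_id}_{r.posture}_s{r.session}"
        csv_path = out_dir / f"{stem}.csv"
        record.to_csv(csv_path)
        gt.to_json(out_dir / f"{stem}.truth.json")
        r.config.to_yaml(out_dir / f"{stem}.config.yaml")
        paths.append(csv_path)
    return paths


# ------------------------------------------------------------ per record

def process_record(
    record: pre.SignalRecord,
    params: PipelineParams | None = None,
    cluster_seed: int = 0,
) -> dict:
    """Run one recording through the full chain; returns a feature row."""
    p = params or PipelineParams()
    conditioned = pre.preprocess_record(
        record, p.bp_low, p.bp_high, p.bp_order, p.bp_stop_atten_db,
        p.ma_order, p.fs_target,
    )
    fs = conditioned.fs
    ecg = conditioned.channels["ecg"]
    scg = conditioned.channels["scg_dv"]

    r_times = seg.detect_r_peaks(ecg, fs)
    if len(r_times) < max(p.K + 1, 3):
        raise ValueError(f"only {len(r_times)} R peaks detected")
    q_times, q_flags = seg.detect_q_points(ecg, fs, r_times, p.q_window_s)

    bs = seg.segment_beats(
        scg, fs, r_times, p.pre_s,
        posture=record.posture, session=record.session,
        subject_id=record.subject_id,
    )
    if bs.meta.get("dropped_first"):
        r_times = r_times[1:]
        q_times, q_flags = q_times[1:], q_flags[1:]
    q_times, q_flags = q_times[: len(bs)], q_flags[: len(bs)]  # last R has no beat

    # the zero-phase band-pass rings near the record boundaries; beats
    # overlapping that zone would register as spurious morphology
    guard = int(round(p.edge_guard_s * fs))
    keep = [
        k for k, b in enumerate(bs.beats)
        if b.start_sample >= guard and b.end_sample <= len(scg) - guard
    ]
    if len(keep) < len(bs):
        logger.info("%d edge beats dropped (guard %.1f s)",
                    len(bs) - len(keep), p.edge_guard_s)
    kept_beats = []
    for new_idx, k in enumerate(keep):
        b = bs.beats[k]
        b.index = new_idx
        kept_beats.append(b)
    bs = seg.BeatSet(fs=fs, beats=kept_beats, posture=bs.posture,
                     session=bs.session, subject_id=bs.subject_id,
                     meta=dict(bs.meta))
    q_times, q_flags = q_times[keep], q_flags[keep]
    if len(bs) < max(p.K + 1, 3):
        raise ValueError(f"only {len(bs)} beats remain after edge guard")

    nbs = seg.normalize_beats(bs)
    cr = clu.k_medoids_dtw(
        nbs, K=p.K, max_iter=p.max_iter, seed=cluster_seed,
        init=p.cluster_init, window=p.dtw_window,
    )
    var = feat.morphological_variability(cr, nbs)
    spec = feat.band_energy_ratios(
        (nbs.waveforms(raw=True)[cr.medoid_index_1],
         nbs.waveforms(raw=True)[cr.medoid_index_2]),
        fs,
    )
    cti = feat.medoid_cti(cr, nbs, q_times, fs, p.pre_s)
    hr = feat.heart_rate_by_cluster(nbs, cr.labels)

    row = {
        "subject": record.subject_id,
        "posture": record.posture,
        "session": int(record.session),
        "n_beats": len(bs),
        "n_flagged_q": int(np.sum(q_flags)),
        "intra": var.intra,
        "inter": var.inter,
        "pep_ms": cti.pep_ms_avg,
        "lvep_ms": cti.lvep_ms_avg,
        "pep_lvep_ratio": cti.pep_lvep_ratio,
        "hr_c1": hr[1][0],
        "hr_c2": hr[2][0],
        "hr_mean": float(np.mean(bs.hr)),
        "cluster_iterations": cr.iterations,
        "cluster_converged": cr.converged,
    }
    for lab, val in zip(spec.band_labels, spec.ratios):
        row[f"ratio_{lab}"] = float(val)
    logger.info(
        "%s/%s/s%d: %d beats, clusters %d/%d, intra %.3f inter %.3f",
        record.subject_id, record.posture, record.session,
        len(bs), cr.n1, cr.n2, var.intra, var.inter,
    )
    return row


def run_pipeline(manifest: RunManifest) -> pd.DataFrame:
    """Process every record in the manifest into one tidy feature table.

    A record that fails at any stage is logged and skipped; the run
    continues for the remaining records.
    """
    rows = []
    for r in manifest.records:
        try:
            if r.path is not None:
                record = pre.SignalRecord.from_csv(r.path)
            else:
                record, _ = generate_recording(
                    r.config, subject_id=r.subject_id,
                    posture=r.posture, session=r.session,
                )
            cseed = record_seed(manifest.seed, r.subject_id, r.posture, r.session)
            rows.append(process_record(record, manifest.params, cluster_seed=cseed))
        except Exception:
            logger.exception(
                "record %s/%s/s%d failed; continuing",
                r.subject_id, r.posture, r.session,
            )
    df = pd.DataFrame(rows)
    if manifest.out_dir:
        out = Path(manifest.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "features.csv", index=False)
    return df


# ----------------------------------------------------------- comparisons

def compare_postures(
    df: pd.DataFrame, features: tuple[str, ...] = FEATURE_COLUMNS
) -> pd.DataFrame:
    """Pairwise paired t + Cohen's d between postures for each feature.

    Values are averaged over sessions per (subject, posture) first; a
    subject missing either posture of a pair is excluded from that pair.
    """
    present = [f for f in features if f in df.columns]
    by_subject = df.groupby(["subject", "posture"])[list(present)].mean()
    rows = []
    postures = [p for p in ("supine", "tilt45", "sitting")
                if p in df["posture"].unique()]
    if len(postures) < 2:
        logger.warning("fewer than two postures present; empty comparison table")
        return pd.DataFrame(
            columns=["feature", "pair", "n", "t", "p_value", "cohens_d", "effect"]
        )
    for pa, pb in combinations(postures, 2):
        a = by_subject.xs(pa, level="posture")
        b = by_subject.xs(pb, level="posture")
        common = a.index.intersection(b.index)
        if len(common) < len(a.index.union(b.index)):
            logger.info("pair %s-%s: unpaired subjects excluded", pa, pb)
        for featname in present:
            x = a.loc[common, featname].to_numpy()
            y = b.loc[common, featname].to_numpy()
            res = st.paired_t(x - y)
            d, _ = st.cohens_d_from_samples(x, y)
            rows.append({
                "feature": featname,
                "pair": f"{pa}-{pb}",
                "n": len(common),
                "t": res.statistic,
                "p_value": res.p_value,
                "cohens_d": d,
                "effect": st.classify_effect(d),
            })
    return pd.DataFrame(rows)


def compare_sessions(
    df: pd.DataFrame, features: tuple[str, ...] = FEATURE_COLUMNS
) -> pd.DataFrame:
    """One-way ANOVA across sessions, per posture and feature."""
    present = [f for f in features if f in df.columns]
    rows = []
    for posture, sub in df.groupby("posture"):
        sessions = sorted(sub["session"].unique())
        if len(sessions) < 2:
            logger.warning("posture %s has < 2 sessions; skipped", posture)
            continue
        for featname in present:
            groups = [
                sub.loc[sub["session"] == s, featname].to_numpy()
                for s in sessions
            ]
            res = st.one_way_anova(groups)
            rows.append({
                "posture": posture,
                "feature": featname,
                "n_sessions": len(sessions),
                "F": res.statistic,
                "p_value": res.p_value,
                "df_between": res.df[0],
                "df_within": res.df[1],
            })
    return pd.DataFrame(rows)


def posture_agreement(
    df: pd.DataFrame, feature: str, posture_a: str, posture_b: str
) -> st.BlandAltman:
    """Bland-Altman agreement of one feature between two postures."""
    by_subject = df.groupby(["subject", "posture"])[[feature]].mean()
    a = by_subject.xs(posture_a, level="posture")[feature]
    b = by_subject.xs(posture_b, level="posture")[feature]
    common = a.index.intersection(b.index)
    return st.bland_altman(a.loc[common].to_numpy(), b.loc[common].to_numpy())
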