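"""Session I/O, configuration and the end-to-end pipeline.

Sessions are stored as plain tab-separated UTF-8 tables with a header
row: an EEG table (time + one column per 10/20 channel, microvolts), a
BIDS-events-like epoch table, and a kinematics table (per-arm 3D
velocity and position).  EDF recordings can be read when ``mne`` is
available; all writing uses the delimited tables, which are lossless at
microvolt scale and diff-friendly.  Coordinates are 0-based and epochs
half-open, as noted in each table's header comment.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, fbcsp, feedback, mtp, synthgen
from .paradigm import (
    KinematicsSeries,
    ParadigmSchedule,
    TargetLayout,
    build_offline_schedule,
    build_online_schedule,
)
from .preprocess import EEGRecording

_HEADER_NOTE = "# 0-based sample indices; epochs cover half-open [onset, onset+duration)"


@dataclass
class SessionBundle:
    """Paths of one stored session."""

    eeg: Path
    events: Path
    kinematics: Path | None = None

    @classmethod
    def in_dir(cls, directory) -> "SessionBundle":
        d = Path(directory)
        eeg = d / "eeg.tsv"
        if not eeg.exists() and (d / "eeg.edf").exists():
            eeg = d / "eeg.edf"
        kin = d / "kinematics.tsv"
        return cls(eeg=eeg, events=d / "events.tsv",
                   kinematics=kin if kin.exists() else None)


def write_eeg(path, rec: EEGRecording) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sfreq_hz={rec.sfreq}\treference={rec.reference}\n")
        fh.write(_HEADER_NOTE + "\n")
        df = pd.DataFrame(rec.data.T, columns=rec.ch_names)
        df.insert(0, "time_s", rec.times)
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_eeg(path) -> EEGRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split("\t"))
        df = pd.read_csv(fh, sep="\t", comment="#")
    ch_names = [c for c in df.columns if c != "time_s"]
    return EEGRecording(
        data=df[ch_names].to_numpy().T,
        sfreq=float(meta["sfreq_hz"]),
        ch_names=ch_names,
        reference=meta.get("reference", "unknown").strip(),
    )


def _read_edf(path) -> EEGRecording:
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
    )


def write_events(path, schedule: ParadigmSchedule) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mode={schedule.mode}\n")
        fh.write(_HEADER_NOTE + "\n")
        schedule.to_frame().to_csv(fh, sep="\t", index=False)


def read_events(path) -> ParadigmSchedule:
    with open(path) as fh:
        header = fh.readline()
        mode = header.lstrip("# ").strip().split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", comment="#")
    _validate_events(df)
    return ParadigmSchedule.from_frame(df, mode=mode)


def _validate_events(df: pd.DataFrame) -> None:
    ends = df["onset_s"] + df["duration_s"]
    onsets = df["onset_s"]
    order = np.argsort(onsets.to_numpy())
    bad_rows = []
    for a, b in zip(order[:-1], order[1:]):
        if onsets.iloc[b] < ends.iloc[a] - 1e-9:
            bad_rows.append((int(a), int(b)))
    if bad_rows:
        raise ValueError(f"overlapping epochs in event table rows {bad_rows}")


def write_kinematics(path, kin: KinematicsSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={kin.sample_rate}\n")
        fh.write(_HEADER_NOTE + "\n")
        kin.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_kinematics(path) -> KinematicsSeries:
    with open(path) as fh:
        header = fh.readline()
        rate = float(header.lstrip("# ").strip().split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", comment="#")
    return KinematicsSeries.from_frame(df, sample_rate=rate)


def write_session(directory, rec, schedule, kin=None) -> SessionBundle:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_eeg(d / "eeg.tsv", rec)
    write_events(d / "events.tsv", schedule)
    if kin is not None:
        write_kinematics(d / "kinematics.tsv", kin)
    return SessionBundle.in_dir(d)


def read_session(bundle: SessionBundle):
    """Load a stored session into aligned in-memory objects."""
    for p in (bundle.eeg, bundle.events):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    rec = read_eeg(bundle.eeg)
    schedule = read_events(bundle.events)
    if bundle.kinematics is None or not Path(bundle.kinematics).exists():
        if schedule.mode == "offline":
            raise FileNotFoundError(
                "offline session lacks a kinematics table; generate the "
                "session with the synthgen module (`mtpbci simulate`)"
            )
        kin = None
    else:
        kin = read_kinematics(bundle.kinematics)
        if abs(kin.sample_rate - rec.sfreq) > 1e-6:
            raise ValueError(
                f"kinematics rate {kin.sample_rate} does not match EEG "
                f"rate {rec.sfreq}"
            )
    return rec, schedule, kin


# ---------------------------------------------------------------------------
# configuration and pipeline


DEFAULT_CONFIG = {
    "sample_rate": 120.0,
    "n_runs": 6,
    "noise": {},
    "encoding": {},
    "window_step_samples": 6,  # calibration feature step for the search
    "lag_spacings": [0.1],
    "lag_counts": [1, 2],
    "min_channels": 6,
    "max_channels": 12,
    "fbcsp_plan": {
        "n_pairs_grid": [1, 2],
        "n_levels_grid": [4, 8],
        "k_grid": [4, 8],
        "gamma_grid": [0.1, 0.5],
    },
    "n_perm": 200,
}


def load_config(path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    return cfg


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, outdir, seed: int, log=print) -> Path:
    """Simulate -> preprocess -> select -> train -> closed loop ->
    evaluate -> FBCSP, writing per-stage artifacts and a manifest.

    Every random draw derives from ``seed``; the manifest records the
    seed, the per-stage parameters and artifact hashes so a rerun with
    the same seed reproduces identical deterministic outputs.
    """
    if seed is None:
        raise ValueError("a seed is required; refusing silent nondeterminism")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "stages": {}}

    def stage(name):
        t0 = time.time()
        log(f"[{name}] start")
        return t0

    def done(name, t0, **info):
        manifest["stages"][name] = {"wall_s": round(time.time() - t0, 2), **info}
        log(f"[{name}] done in {manifest['stages'][name]['wall_s']}s")

    rng = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(4)]

    layout = TargetLayout.default()
    fs = config["sample_rate"]

    t0 = stage("simulate")
    sched = build_offline_schedule(layout, n_runs=config["n_runs"], seed=seeds[0])
    rec, kin = synthgen.synthesize_mtp_session(
        sched, layout,
        synthgen.EncodingSpec.default(**config.get("encoding", {})),
        synthgen.NoiseSpec(**config.get("noise", {})),
        seed=seeds[0], sfreq=fs,
    )
    bundle = write_session(out / "session", rec, sched, kin)
    done("simulate", t0, eeg_sha=_sha(Path(bundle.eeg)))

    t0 = stage("preprocess")
    ds = mtp.prepare_dataset(
        rec, sched, kin, layout,
        window_step_samples=config["window_step_samples"],
    )
    done("preprocess", t0, n_channels=len(ds.bp.ch_names))

    t0 = stage("select-architecture")
    arches = {}
    for arm in ("left", "right"):
        res = mtp.recursive_selection(
            ds, arm,
            lag_spacings=tuple(config["lag_spacings"]),
            lag_counts=tuple(config["lag_counts"]),
            min_channels=config["min_channels"],
            max_channels=config["max_channels"],
            log=log,
        )
        arches[arm] = res
    (out / "architecture.json").write_text(
        json.dumps(
            {
                arm: {
                    "channels": a.selected_channels,
                    "lag_spacing": a.selected_lag_spacing,
                    "n_lags": a.selected_n_lags,
                    "cv_error": a.selected_error,
                    "elimination_order": a.elimination_order,
                }
                for arm, a in arches.items()
            },
            indent=1,
        )
    )
    done("select-architecture", t0)

    t0 = stage("train")
    models = {}
    for arm, a in arches.items():
        m = mtp.fit_architecture(
            ds, arm, a.selected_channels, a.selected_lag_spacing, a.selected_n_lags
        )
        (out / f"model_{arm}.json").write_text(m.to_json())
        models[arm] = m
    done("train", t0)

    t0 = stage("simulate-online")
    online_sched = build_online_schedule(layout, n_runs=config["n_runs"], seed=seeds[1])
    decoder = feedback.NoisyOracleDecoder(noise_std=1.0, seed=seeds[1])
    log_assisted = feedback.simulate_online_session(
        online_sched, layout, decoder, mode="assisted", seed=seeds[1]
    )
    log_assisted.to_table(out / "online_assisted.tsv")
    log_direct = feedback.simulate_online_session(
        online_sched, layout, decoder, mode="direct", seed=seeds[1]
    )
    log_direct.to_table(out / "online_direct.tsv")
    done("simulate-online", t0)

    t0 = stage("evaluate")
    rep = mtp.crossvalidate(
        ds,
        arches["left"].selected_lag_spacing,
        arches["left"].selected_n_lags,
        channels=arches["left"].selected_channels,
        arms=("left",),
    )
    trials = rep.trials("left")
    fwd = [t for t in trials if t.direction == "forward"]
    landmarks = evaluate.target_landmarks(layout, "left")
    perm = evaluate.permutation_null(
        [t.pred_coords for t in fwd],
        [t.target for t in fwd],
        landmarks,
        n_perm=config["n_perm"],
        seed=seeds[2],
    )
    evaluate.export_da_table(out / "da_offline_left.tsv", perm)
    done(
        "evaluate", t0,
        peak_da=round(perm.observed.peak, 1),
        null_peak=round(float(perm.null_curves.mean(axis=0).max()), 1),
    )

    t0 = stage("fbcsp")
    class_rec, class_trials = synthgen.synthesize_class_session(
        sched, seed=seeds[3], sfreq=fs
    )
    tds = fbcsp.build_trial_dataset(class_rec, class_trials)
    plan = fbcsp.NestedCVPlan.single_session(
        **{k: tuple(v) for k, v in config["fbcsp_plan"].items()}
    )
    res = fbcsp.nested_cv(tds, plan)
    pd.DataFrame(
        {"offset_s": res.offsets, "mean_da_percent": res.mean_da}
    ).to_csv(out / "fbcsp_da.tsv", sep="\t", index=False)
    done("fbcsp", t0, peak_da=round(res.peak, 1))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
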