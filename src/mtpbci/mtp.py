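"""Trajectory decoding: lag-embedded multiple linear regression.

The decoder estimates each arm's 3D velocity from standardized,
lag-embedded band-power features with one ordinary-least-squares model
per arm and axis (six independent regressions).  Model architecture --
the channel subset, the lag spacing and the lag count -- is chosen by a
recursive channel-elimination search under 6-fold leave-one-run-out
cross-validation, scored by the trial-wise trajectory reconstruction
error:

* predicted and target velocities are normalized sample-wise to unit
  length,
* converted to relative coordinates by the running mean of the
  normalized velocities within each movement trial (first sample is the
  trial's zero reference),
* and the reconstruction error ``eps_t`` is the mean 3D distance between
  the two coordinate series over the trial.

Channels are scored from the fitted weights, ``R_jnf = sum_k sum_i
b_ijnfk^2 / (L + 1)``, averaged over test folds and bands; the
lowest-scoring channel is dropped each round.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .paradigm import (
    ARMS,
    KinematicsSeries,
    MOVEMENT_KINDS,
    ParadigmSchedule,
    TargetLayout,
)
from .preprocess import (
    BandPowerSeries,
    EEGRecording,
    MTP_BANDS,
    bandpower_features,
    car_filter,
    qc_channels,
)

#: lag-parameter grid examined by the architecture search
DEFAULT_LAG_SPACINGS = (0.05, 0.1, 0.2)
DEFAULT_LAG_COUNTS = (1, 2, 4, 8)


# ---------------------------------------------------------------------------
# small kinematics helpers


@dataclass
class VelocitySeries:
    """A single-arm velocity estimate stream."""

    times: np.ndarray  # (T,)
    velocity: np.ndarray  # (T, 3)


def normalize_velocity(v: np.ndarray, eps: float = 1e-9) -> tuple[np.ndarray, bool]:
    """Scale a 3D vector to unit length.

    Near-zero vectors are returned as the zero vector with a degenerate
    flag instead of raising; downstream metrics treat them as "no
    direction".
    """
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    scale = max(np.max(np.abs(v)), 1.0)
    if n <= eps * scale:
        return np.zeros(3), True
    return v / n, False


def normalize_rows(V: np.ndarray, eps: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise unit normalization of an (m, 3) array; flags zero rows."""
    V = np.asarray(V, float)
    norms = np.linalg.norm(V, axis=1)
    scale = max(np.max(np.abs(V), initial=0.0), 1.0)
    degenerate = norms <= eps * scale
    out = np.zeros_like(V)
    ok = ~degenerate
    out[ok] = V[ok] / norms[ok, None]
    return out, degenerate


def smooth_prediction(velocity: np.ndarray, width: int = 9) -> np.ndarray:
    """Centered moving average per axis; edges use shrunken windows.

    The default 9-sample window corresponds to 200 ms at the 40 Hz
    prediction rate and removes sample-to-sample jitter.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    if width == 1:
        return np.asarray(velocity, float).copy()
    V = np.atleast_2d(np.asarray(velocity, float))
    kernel = np.ones(width)
    counts = np.convolve(np.ones(V.shape[0]), kernel, mode="same")
    out = np.stack(
        [np.convolve(V[:, i], kernel, mode="same") / counts for i in range(V.shape[1])],
        axis=1,
    )
    return out


def relative_coordinates(
    velocities: np.ndarray,
    normalized: bool = True,
    mode: str = "running_mean",
    dt: float | None = None,
) -> np.ndarray:
    """Trial velocities -> relative coordinates.

    ``running_mean`` (the selection metric): coordinate at sample m is
    the mean of the (unit-normalized) velocities over samples 1..m, with
    the trial start as the zero reference.  Under this scheme a perfect
    straight reach sits exactly at its target's unit direction vector.
    ``cumsum``: plain integration (cumulative sum x dt) for display
    only, never for model selection.
    """
    V = np.asarray(velocities, float)
    if V.ndim != 2 or V.shape[1] != 3:
        raise ValueError("expected an (m, 3) velocity array")
    if V.shape[0] == 0:
        raise ValueError("empty trial")
    if normalized:
        V, _ = normalize_rows(V)
    if mode == "running_mean":
        m = np.arange(1, V.shape[0] + 1)[:, None]
        return np.cumsum(V, axis=0) / m
    if mode == "cumsum":
        if dt is None:
            raise ValueError("cumsum mode requires dt")
        return np.cumsum(V, axis=0) * dt
    raise ValueError(f"unknown mode {mode!r}")


def reconstruction_error(target: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean 3D Euclidean distance between two coordinate series."""
    a = np.asarray(target, float)
    b = np.asarray(reconstructed, float)
    if a.shape != b.shape:
        raise ValueError("coordinate series have different shapes")
    return float(np.mean(np.linalg.norm(a - b, axis=-1)))


# ---------------------------------------------------------------------------
# model


@dataclass
class MTPModel:
    """Per-arm linear velocity decoder (intercept + lag-embedded weights)."""

    arm: str
    intercept: np.ndarray  # (3,)
    weights: np.ndarray  # (3, n_features)
    col_band: np.ndarray
    col_channel: np.ndarray
    col_lag: np.ndarray
    ch_names: list[str]
    bands: tuple
    lag_spacing: float
    n_lags: int
    sigma: np.ndarray | None  # (n_bands, n_channels) training-fold sigma
    feature_step: float  # s between feature samples
    residual_std: np.ndarray | None = None

    def to_json(self) -> str:
        doc = {
            "arm": self.arm,
            "intercept": self.intercept.tolist(),
            "weights": self.weights.tolist(),
            "col_band": self.col_band.tolist(),
            "col_channel": self.col_channel.tolist(),
            "col_lag": self.col_lag.tolist(),
            "ch_names": self.ch_names,
            "bands": [list(b) for b in self.bands],
            "lag_spacing": self.lag_spacing,
            "n_lags": self.n_lags,
            "sigma": None if self.sigma is None else self.sigma.tolist(),
            "feature_step": self.feature_step,
            "residual_std": None
            if self.residual_std is None
            else self.residual_std.tolist(),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "MTPModel":
        d = json.loads(text)
        return cls(
            arm=d["arm"],
            intercept=np.array(d["intercept"]),
            weights=np.array(d["weights"]),
            col_band=np.array(d["col_band"]),
            col_channel=np.array(d["col_channel"]),
            col_lag=np.array(d["col_lag"]),
            ch_names=d["ch_names"],
            bands=tuple(tuple(b) for b in d["bands"]),
            lag_spacing=d["lag_spacing"],
            n_lags=d["n_lags"],
            sigma=None if d["sigma"] is None else np.array(d["sigma"]),
            feature_step=d["feature_step"],
            residual_std=None
            if d["residual_std"] is None
            else np.array(d["residual_std"]),
        )


def _ols(X: np.ndarray, Y: np.ndarray, ridge: float = 1e-8):
    """Least squares with intercept; minimum-norm on rank deficiency.

    Solved by orthogonal decomposition (LAPACK gelsd).  If the solution
    is non-finite (pathological conditioning) a small ridge on the
    normal matrix is used instead.
    """
    A = np.column_stack([np.ones(X.shape[0]), X])
    coef, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    if not np.all(np.isfinite(coef)):
        G = A.T @ A
        G[np.diag_indices_from(G)] += ridge * np.trace(G) / G.shape[0]
        coef = np.linalg.solve(G, A.T @ Y)
    return coef[0], coef[1:].T  # intercept (3,), weights (3, F)


def train_mlr(features, kin: KinematicsSeries, arm: str) -> MTPModel:
    """Fit the velocity decoder for one arm by ordinary least squares.

    ``features`` is a :class:`~mtpbci.preprocess.LaggedFeatures`; the
    kinematic targets are matched to the feature timestamps by nearest
    sample.  Three independent regressions (one per axis) share the
    design matrix.
    """
    idx = np.clip(
        np.round(features.times * kin.sample_rate).astype(int),
        0,
        len(kin.times) - 1,
    )
    Y = kin.velocity[arm][idx]
    intercept, weights = _ols(features.X, Y)
    resid = Y - (features.X @ weights.T + intercept)
    return MTPModel(
        arm=arm,
        intercept=intercept,
        weights=weights,
        col_band=features.col_band,
        col_channel=features.col_channel,
        col_lag=features.col_lag,
        ch_names=list(features.ch_names),
        bands=features.bands,
        lag_spacing=features.lag_spacing,
        n_lags=features.n_lags,
        sigma=features.sigma,
        feature_step=features.times[1] - features.times[0]
        if len(features.times) > 1
        else 0.0,
        residual_std=resid.std(axis=0),
    )


def predict_velocity(
    model: MTPModel, features, output_step: float = 0.025
) -> VelocitySeries:
    """Apply the decoder; emit estimates every ``output_step`` seconds.

    Features must have been standardized with the model's training
    sigma.
    """
    if (
        model.sigma is not None
        and features.sigma is not None
        and not np.allclose(model.sigma, features.sigma)
    ):
        raise ValueError("features were standardized with a different sigma")
    V = features.X @ model.weights.T + model.intercept
    step = features.times[1] - features.times[0] if len(features.times) > 1 else output_step
    k = max(1, int(round(output_step / step)))
    return VelocitySeries(times=features.times[::k], velocity=V[::k])


# ---------------------------------------------------------------------------
# channel scoring


@dataclass
class ChannelScoreTable:
    """Regression-weight channel scores, per band and band-averaged."""

    ch_names: list[str]
    scores_per_band: np.ndarray  # (n_bands, n_channels)
    scores: np.ndarray  # (n_channels,) band-averaged
    ranking: list[str]  # best first


def score_channels(models: list[MTPModel]) -> ChannelScoreTable:
    """Score channels from squared regression weights.

    Per model, band and channel: ``sum_k sum_i b^2 / (L + 1)``; scores
    are averaged over the supplied (per-fold) models and over bands, and
    channels are ranked by the averaged score.  Negating weights leaves
    scores unchanged.
    """
    ref = models[0]
    n_bands = len(ref.bands)
    n_ch = len(ref.ch_names)
    acc = np.zeros((n_bands, n_ch))
    for m in models:
        if m.ch_names != ref.ch_names or m.n_lags != ref.n_lags:
            raise ValueError("models do not share an architecture")
        w2 = (m.weights**2).sum(axis=0)  # sum over axes i, per column
        per_bn = np.zeros((n_bands, n_ch))
        np.add.at(per_bn, (m.col_band, m.col_channel), w2)
        acc += per_bn / (m.n_lags + 1)
    scores_per_band = acc / len(models)
    scores = scores_per_band.mean(axis=0)
    order = np.argsort(-scores, kind="stable")
    return ChannelScoreTable(
        ch_names=list(ref.ch_names),
        scores_per_band=scores_per_band,
        scores=scores,
        ranking=[ref.ch_names[i] for i in order],
    )


def _drop_lowest(table: ChannelScoreTable) -> str:
    """Channel to eliminate: lowest score; ties drop the higher index."""
    lo = table.scores.min()
    candidates = [i for i, s in enumerate(table.scores) if s == lo]
    return table.ch_names[max(candidates)]


# ---------------------------------------------------------------------------
# dataset container and cross-validation


@dataclass
class MTPDataset:
    """Offline calibration dataset: band power + kinematics + schedule."""

    bp: BandPowerSeries
    kin: KinematicsSeries
    schedule: ParadigmSchedule
    layout: TargetLayout


def prepare_dataset(
    rec: EEGRecording,
    schedule: ParadigmSchedule,
    kin: KinematicsSeries,
    layout: TargetLayout,
    bands=MTP_BANDS,
    window_width: float = 0.25,
    window_step_samples: int = 1,
    qc: bool = True,
    car: bool = True,
) -> MTPDataset:
    """QC, re-reference and band-power the raw recording."""
    if qc:
        rec, _ = qc_channels(rec)
    if car:
        rec = car_filter(rec)
    bp = bandpower_features(rec, bands, window_width, window_step_samples)
    return MTPDataset(bp=bp, kin=kin, schedule=schedule, layout=layout)


@dataclass
class TrialResult:
    """One movement trial of a test fold."""

    run: int
    block: int
    arm: str
    target: str
    direction: str  # 'forward' | 'backward'
    times: np.ndarray
    pred_coords: np.ndarray  # (m, 3) relative coordinates
    target_coords: np.ndarray
    pred_velocity: np.ndarray  # (m, 3) smoothed 40 Hz estimates
    error: float  # eps_t


@dataclass
class FoldResult:
    run: int
    models: dict[str, MTPModel]
    trials: list[TrialResult]

    @property
    def mean_error(self) -> float:
        return float(np.mean([t.error for t in self.trials]))


@dataclass
class CVReport:
    """Leave-one-run-out cross-validation report."""

    folds: list[FoldResult]
    lag_spacing: float
    n_lags: int
    channels: list[str]

    @property
    def mean_error(self) -> float:
        return float(np.mean([f.mean_error for f in self.folds]))

    def arm_mean_error(self, arm: str) -> float:
        errs = [t.error for f in self.folds for t in f.trials if t.arm == arm]
        return float(np.mean(errs))

    def trials(self, arm: str | None = None) -> list[TrialResult]:
        out = [t for f in self.folds for t in f.trials]
        if arm is not None:
            out = [t for t in out if t.arm == arm]
        return out


def _interval_labels(times: np.ndarray, schedule: ParadigmSchedule):
    """Per feature-time run id and sub-block id (0 where unlabeled)."""
    run_of = np.zeros(len(times), dtype=int)
    sb_of = np.zeros(len(times), dtype=int)
    for e in schedule.epochs:
        if e.sub_block is None:
            continue
        i0 = np.searchsorted(times, e.onset - 1e-9, side="left")
        i1 = np.searchsorted(times, e.end - 1e-9, side="left")
        run_of[i0:i1] = e.run
        sb_of[i0:i1] = e.sub_block
    return run_of, sb_of


def _gather_design(values: np.ndarray, rows: np.ndarray, lag_step: int, n_lags: int):
    """Design matrix for selected feature rows only (memory-friendly).

    Column order matches :func:`mtpbci.preprocess.lag_embed`: (band,
    channel) major, lag minor.
    """
    b, n, t = values.shape
    offsets = np.arange(n_lags + 1) * lag_step
    idx = rows[:, None] - offsets[None, :]  # (R, L+1)
    flat = values.reshape(b * n, t)
    gathered = flat[:, idx]  # (B*N, R, L+1)
    X = gathered.transpose(1, 0, 2).reshape(len(rows), b * n * (n_lags + 1))
    bn = np.arange(b * n)
    col_band = np.repeat(bn // n, n_lags + 1)
    col_channel = np.repeat(bn % n, n_lags + 1)
    col_lag = np.tile(np.arange(n_lags + 1), b * n)
    return X, col_band, col_channel, col_lag


class _Lagged:
    """Lightweight LaggedFeatures stand-in for pre-gathered rows."""

    def __init__(self, X, times, cb, cc, cl, bands, ch_names, lag_spacing, n_lags, sigma):
        self.X = X
        self.times = times
        self.col_band = cb
        self.col_channel = cc
        self.col_lag = cl
        self.bands = bands
        self.ch_names = ch_names
        self.lag_spacing = lag_spacing
        self.n_lags = n_lags
        self.sigma = sigma


def crossvalidate(
    ds: MTPDataset,
    lag_spacing: float,
    n_lags: int,
    channels: list[str] | None = None,
    arms=ARMS,
    sub_block: int = 2,
    output_step: float = 0.025,
    smooth_width: int = 9,
    require_six_runs: bool = True,
) -> CVReport:
    """Leave-one-run-out cross-validation of the velocity decoder.

    Folds are the offline runs; training and testing use the second
    sub-block of each block (the cycles without displayed movement), so
    held-out data never enters training -- including the per-feature
    standardization sigma, which is recomputed from the training runs of
    every fold.  Each test fold contributes one forward and one backward
    movement trial per block.
    """
    runs = ds.schedule.run_ids()
    if require_six_runs and len(runs) != 6:
        raise ValueError(
            f"expected 6 offline runs, got {len(runs)}; "
            "pass require_six_runs=False to override"
        )
    bp = ds.bp if channels is None else ds.bp.pick(channels)
    values = bp.values
    step_s = bp.window_step
    lag_step = max(1, int(round(lag_spacing / step_s)))
    if n_lags > 0 and abs(lag_step * step_s - lag_spacing) > 1e-9:
        raise ValueError("lag spacing is not a multiple of the feature step")

    run_of, sb_of = _interval_labels(bp.times, ds.schedule)
    history_ok = np.arange(values.shape[2]) >= n_lags * lag_step
    usable = (sb_of == sub_block) & history_ok
    rows = np.where(usable)[0]
    if len(rows) == 0:
        raise ValueError("no usable feature rows for the requested sub-block")
    X_raw, cb, cc, cl = _gather_design(values, rows, lag_step, n_lags)
    row_times = bp.times[rows]
    row_run = run_of[rows]
    k_out = max(1, int(round(output_step / step_s)))

    kin_idx = np.clip(
        np.round(row_times * ds.kin.sample_rate).astype(int),
        0,
        len(ds.kin.times) - 1,
    )

    folds = []
    for r in runs:
        train = row_run != r
        test = ~train
        sigma = values[:, :, (sb_of == sub_block) & (run_of != r)].std(axis=2)
        if np.any(sigma <= 0):
            raise ValueError("zero-variance feature in training fold")
        inv = 1.0 / sigma.reshape(-1)[cb * values.shape[1] + cc]
        models: dict[str, MTPModel] = {}
        preds: dict[str, np.ndarray] = {}
        for arm in arms:
            Y = ds.kin.velocity[arm][kin_idx]
            a, W = _ols(X_raw[train] * inv, Y[train])
            models[arm] = MTPModel(
                arm=arm,
                intercept=a,
                weights=W,
                col_band=cb,
                col_channel=cc,
                col_lag=cl,
                ch_names=list(bp.ch_names),
                bands=bp.bands,
                lag_spacing=lag_spacing,
                n_lags=n_lags,
                sigma=sigma,
                feature_step=step_s,
            )
            preds[arm] = (X_raw[test] * inv) @ W.T + a
        test_times = row_times[test]
        trials = _extract_trials(
            ds, r, sub_block, arms, preds, test_times, k_out, smooth_width
        )
        folds.append(FoldResult(run=r, models=models, trials=trials))
    return CVReport(
        folds=folds,
        lag_spacing=lag_spacing,
        n_lags=n_lags,
        channels=list(bp.ch_names),
    )


def _extract_trials(
    ds, run, sub_block, arms, preds, test_times, k_out, smooth_width
) -> list[TrialResult]:
    """Cut a fold's predictions into per-trial 40 Hz trajectories."""
    trials: list[TrialResult] = []
    for block, arm, target in ds.schedule.blocks(run):
        if arm not in arms or arm not in preds:
            continue
        cycle = [
            e
            for e in ds.schedule.epochs
            if e.run == run and e.block == block and e.sub_block == sub_block
        ]
        if not cycle:
            continue
        c_on = min(e.onset for e in cycle)
        c_end = max(e.end for e in cycle)
        in_cycle = (test_times >= c_on - 1e-9) & (test_times < c_end - 1e-9)
        idx = np.where(in_cycle)[0][::k_out]
        if len(idx) == 0:
            continue
        v_pred = smooth_prediction(preds[arm][idx], smooth_width)
        t_cycle = test_times[idx]
        kin_i = np.clip(
            np.round(t_cycle * ds.kin.sample_rate).astype(int),
            0,
            len(ds.kin.times) - 1,
        )
        v_true = ds.kin.velocity[arm][kin_i]
        for e in cycle:
            if e.kind not in MOVEMENT_KINDS:
                continue
            sel = (t_cycle >= e.onset - 1e-9) & (t_cycle < e.end - 1e-9)
            if not np.any(sel):
                continue
            pc = relative_coordinates(v_pred[sel])
            tc = relative_coordinates(v_true[sel])
            trials.append(
                TrialResult(
                    run=run,
                    block=block,
                    arm=arm,
                    target=target,
                    direction="forward" if e.kind == "home_to_target" else "backward",
                    times=t_cycle[sel],
                    pred_coords=pc,
                    target_coords=tc,
                    pred_velocity=v_pred[sel],
                    error=reconstruction_error(tc, pc),
                )
            )
    return trials


# ---------------------------------------------------------------------------
# recursive architecture search


@dataclass
class EliminationRecord:
    """One round of the recursive search at a fixed channel-set size."""

    channels: list[str]
    cell_errors: dict[tuple[float, int], float]
    best_cell: tuple[float, int]
    best_error: float
    scores: np.ndarray
    dropped: str | None


@dataclass
class ArchitectureSearchResult:
    arm: str
    records: list[EliminationRecord]
    selected_channels: list[str]
    selected_lag_spacing: float
    selected_n_lags: int
    selected_error: float
    elimination_order: list[str]  # first dropped first


def recursive_selection(
    ds: MTPDataset,
    arm: str,
    lag_spacings=DEFAULT_LAG_SPACINGS,
    lag_counts=DEFAULT_LAG_COUNTS,
    min_channels: int = 6,
    max_channels: int = 12,
    sub_block: int = 2,
    log=None,
    **cv_kwargs,
) -> ArchitectureSearchResult:
    """Recursive channel elimination with a lag-parameter grid.

    Starting from all channels: every (lag spacing, lag count) grid cell
    is cross-validated, the best cell's per-fold models score the
    channels, and the lowest-scoring channel is dropped; the loop
    repeats down to ``min_channels``.  The selected architecture is the
    (channel set, spacing, count) with the lowest mean reconstruction
    error among sets of size ``min_channels..max_channels``.
    """
    channels = list(ds.bp.ch_names)
    if len(channels) < min_channels:
        raise ValueError("fewer channels available than min_channels")
    records: list[EliminationRecord] = []
    dropped_order: list[str] = []
    while True:
        cell_errors: dict[tuple[float, int], float] = {}
        best_report = None
        for spacing, count in product(lag_spacings, lag_counts):
            rep = crossvalidate(
                ds, spacing, count, channels=channels, arms=(arm,),
                sub_block=sub_block, **cv_kwargs,
            )
            err = rep.arm_mean_error(arm)
            cell_errors[(spacing, count)] = err
            if best_report is None or err < cell_errors[best_cell]:
                best_report, best_cell = rep, (spacing, count)
        table = score_channels([f.models[arm] for f in best_report.folds])
        drop = _drop_lowest(table) if len(channels) > min_channels else None
        records.append(
            EliminationRecord(
                channels=list(channels),
                cell_errors=cell_errors,
                best_cell=best_cell,
                best_error=cell_errors[best_cell],
                scores=table.scores,
                dropped=drop,
            )
        )
        if log is not None:
            log(
                f"[{arm}] |channels|={len(channels)} "
                f"best cell={best_cell} eps={cell_errors[best_cell]:.4f} "
                f"drop={drop}"
            )
        if drop is None:
            break
        channels.remove(drop)
        dropped_order.append(drop)
    eligible = [
        rec for rec in records if min_channels <= len(rec.channels) <= max_channels
    ]
    best = min(eligible, key=lambda rec: rec.best_error)
    return ArchitectureSearchResult(
        arm=arm,
        records=records,
        selected_channels=list(best.channels),
        selected_lag_spacing=best.best_cell[0],
        selected_n_lags=best.best_cell[1],
        selected_error=best.best_error,
        elimination_order=dropped_order,
    )


def fit_architecture(
    ds: MTPDataset,
    arm: str,
    channels: list[str],
    lag_spacing: float,
    n_lags: int,
    sub_block: int = 2,
) -> MTPModel:
    """Train a final model on all runs at a chosen architecture."""
    bp = ds.bp.pick(channels)
    values = bp.values
    step_s = bp.window_step
    lag_step = max(1, int(round(lag_spacing / step_s)))
    run_of, sb_of = _interval_labels(bp.times, ds.schedule)
    history_ok = np.arange(values.shape[2]) >= n_lags * lag_step
    rows = np.where((sb_of == sub_block) & history_ok)[0]
    sigma = values[:, :, sb_of == sub_block].std(axis=2)
    X, cb, cc, cl = _gather_design(values, rows, lag_step, n_lags)
    inv = 1.0 / sigma.reshape(-1)[cb * values.shape[1] + cc]
    feats = _Lagged(
        X * inv, bp.times[rows], cb, cc, cl, bp.bands, list(bp.ch_names),
        lag_spacing, n_lags, sigma,
    )
    return train_mlr(feats, ds.kin, arm)
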