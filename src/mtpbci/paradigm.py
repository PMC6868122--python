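"""Experimental paradigm: schedules, target geometry, ideal kinematics.

Two virtual arms rest at left/right home positions in a 3D workspace;
three targets per arm sit at the same orthogonal distance from the home
position along the horizontal (X), vertical (Y) and depth (Z) axes.
Offline calibration runs present fully scripted imagined-movement cycles;
online runs present cue-limited movement blocks in which the displayed
arm is driven by the decoder (with optional assistance).

Conventions: timestamps are seconds from session start, sample indices
are 0-based, and epochs cover half-open intervals ``[onset, onset +
duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ARMS = ("left", "right")
TARGET_LABELS = ("X", "Y", "Z")

# epoch kinds
RUN_INIT = "run_init"
BLOCK_VOICE = "block_voice"
HOME_TO_TARGET = "home_to_target"
PAUSE_AT_TARGET = "pause_at_target"
TARGET_TO_HOME = "target_to_home"
PAUSE_AT_HOME = "pause_at_home"
HOLD_AT_ENDPOINT = "hold_at_endpoint"
INTER_RUN_REST = "inter_run_rest"

MOVEMENT_KINDS = frozenset({HOME_TO_TARGET, TARGET_TO_HOME})

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


class DegenerateTrajectoryError(ValueError):
    """Raised when a movement is requested between identical points."""


@dataclass(frozen=True)
class Epoch:
    """One labeled interval of the paradigm timeline."""

    kind: str
    onset: float
    duration: float
    arm: str | None = None
    target: str | None = None
    sub_block: int | None = None
    run: int | None = None
    block: int | None = None

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class TargetLayout:
    """Six-target geometry: per-arm home positions and orthogonal targets.

    Each target lies at the same distance from its arm's home position
    along exactly one coordinate axis.  ``bounds`` is the axis-aligned
    box within which the virtual arms may move (displayed positions are
    clamped to it in closed-loop mode).
    """

    home: Mapping[str, np.ndarray]
    targets: Mapping[tuple[str, str], np.ndarray]
    bounds: np.ndarray  # (2, 3) [min; max]

    @classmethod
    def default(cls, distance: float = 1.0) -> "TargetLayout":
        home = {
            "left": np.array([-1.5, 0.0, 0.0]),
            "right": np.array([1.5, 0.0, 0.0]),
        }
        # X points outward (away from the body midline), Y up, Z forward.
        axis_dir = {
            ("left", "X"): np.array([-1.0, 0.0, 0.0]),
            ("right", "X"): np.array([1.0, 0.0, 0.0]),
            ("left", "Y"): np.array([0.0, 1.0, 0.0]),
            ("right", "Y"): np.array([0.0, 1.0, 0.0]),
            ("left", "Z"): np.array([0.0, 0.0, 1.0]),
            ("right", "Z"): np.array([0.0, 0.0, 1.0]),
        }
        targets = {
            (arm, lab): home[arm] + distance * axis_dir[(arm, lab)]
            for arm in ARMS
            for lab in TARGET_LABELS
        }
        bounds = np.array([[-3.0, -0.5, -0.5], [3.0, 1.5, 1.5]])
        layout = cls(home=home, targets=targets, bounds=bounds)
        layout.validate()
        return layout

    def direction(self, arm: str, target: str) -> np.ndarray:
        """Unit vector from the arm's home toward the named target."""
        d = self.targets[(arm, target)] - self.home[arm]
        return d / np.linalg.norm(d)

    def distance(self, arm: str, target: str) -> float:
        return float(np.linalg.norm(self.targets[(arm, target)] - self.home[arm]))

    def validate(self) -> None:
        dists = [self.distance(arm, lab) for arm in ARMS for lab in TARGET_LABELS]
        if not np.allclose(dists, dists[0]):
            raise ValueError("targets are not equidistant from their homes")
        for arm in ARMS:
            for lab in TARGET_LABELS:
                offset = self.targets[(arm, lab)] - self.home[arm]
                if np.count_nonzero(np.abs(offset) > 1e-12) != 1:
                    raise ValueError(
                        f"target {arm}/{lab} is not along a single axis"
                    )
        pts = list(self.home.values()) + list(self.targets.values())
        lo, hi = self.bounds
        for p in pts:
            if np.any(p < lo) or np.any(p > hi):
                raise ValueError("layout point outside workspace bounds")


@dataclass
class ParadigmSchedule:
    """Ordered, labeled epochs of one offline or online session part."""

    epochs: list[Epoch]
    mode: str  # 'offline' | 'online_assisted' | 'online_direct'

    @property
    def duration(self) -> float:
        return max(e.end for e in self.epochs)

    def run_ids(self) -> list[int]:
        return sorted({e.run for e in self.epochs if e.run is not None})

    def run_epochs(self, run: int) -> list[Epoch]:
        return [e for e in self.epochs if e.run == run]

    def run_duration(self, run: int, include_rest: bool = False) -> float:
        eps = [
            e
            for e in self.run_epochs(run)
            if include_rest or e.kind != INTER_RUN_REST
        ]
        return sum(e.duration for e in eps)

    def blocks(self, run: int) -> list[tuple[int, str, str]]:
        """Ordered (block, arm, target) triples of one run."""
        seen: dict[int, tuple[str, str]] = {}
        for e in self.run_epochs(run):
            if e.block is not None and e.arm is not None and e.block not in seen:
                seen[e.block] = (e.arm, e.target)
        return [(b, *seen[b]) for b in sorted(seen)]

    def movement_epochs(
        self,
        run: int | None = None,
        arm: str | None = None,
        sub_block: int | None = None,
    ) -> list[Epoch]:
        out = []
        for e in self.epochs:
            if e.kind not in MOVEMENT_KINDS:
                continue
            if run is not None and e.run != run:
                continue
            if arm is not None and e.arm != arm:
                continue
            if sub_block is not None and e.sub_block != sub_block:
                continue
            out.append(e)
        return out

    def validate(self) -> None:
        """Check that epochs are contiguous and non-overlapping."""
        eps = sorted(self.epochs, key=lambda e: e.onset)
        for a, b in zip(eps[:-1], eps[1:]):
            if b.onset < a.end - 1e-9:
                raise ValueError(
                    f"overlapping epochs at t={b.onset:.3f} ({a.kind}/{b.kind})"
                )
            if b.onset > a.end + 1e-9:
                raise ValueError(f"gap between epochs at t={a.end:.3f}")

    # -- tab-separated event-table dialect (BIDS-events-like) -------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "onset_s": e.onset,
                "duration_s": e.duration,
                "kind": e.kind,
                "arm": e.arm or "n/a",
                "target": e.target or "n/a",
                "sub_block": e.sub_block if e.sub_block is not None else "n/a",
                "run": e.run if e.run is not None else "n/a",
                "block": e.block if e.block is not None else "n/a",
            }
            for e in self.epochs
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str) -> "ParadigmSchedule":
        def _opt(v, conv=lambda x: x):
            return None if (isinstance(v, str) and v == "n/a") or pd.isna(v) else conv(v)

        epochs = [
            Epoch(
                kind=str(r["kind"]),
                onset=float(r["onset_s"]),
                duration=float(r["duration_s"]),
                arm=_opt(r["arm"], str),
                target=_opt(r["target"], str),
                sub_block=_opt(r["sub_block"], int),
                run=_opt(r["run"], int),
                block=_opt(r["block"], int),
            )
            for _, r in df.iterrows()
        ]
        return cls(epochs=epochs, mode=mode)


def _randomized_blocks(rng: np.random.Generator) -> list[tuple[str, str]]:
    combos = [(arm, lab) for arm in ARMS for lab in TARGET_LABELS]
    order = rng.permutation(len(combos))
    return [combos[i] for i in order]


def build_offline_schedule(
    layout: TargetLayout,
    n_runs: int = 6,
    seed: int = 0,
    *,
    run_init: float = 10.0,
    voice: float = 4.0,
    move: float = 4.0,
    pause: float = 2.0,
    rest: float = 40.0,
) -> ParadigmSchedule:
    """Offline calibration schedule.

    Per run: a 10 s initialization, then six blocks -- one per arm x
    target combination in a seed-randomized order -- each block a 4 s
    voice cue followed by two identical 12 s movement cycles
    (sub-blocks): 4 s home-to-target, 2 s pause, 4 s target-to-home,
    2 s pause.  A 40 s rest follows every run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    epochs: list[Epoch] = []
    t = 0.0
    for run in range(1, n_runs + 1):
        epochs.append(Epoch(RUN_INIT, t, run_init, run=run))
        t += run_init
        for block, (arm, target) in enumerate(_randomized_blocks(rng), start=1):
            common = dict(arm=arm, target=target, run=run, block=block)
            epochs.append(Epoch(BLOCK_VOICE, t, voice, **common))
            t += voice
            for sb in (1, 2):
                for kind, dur in (
                    (HOME_TO_TARGET, move),
                    (PAUSE_AT_TARGET, pause),
                    (TARGET_TO_HOME, move),
                    (PAUSE_AT_HOME, pause),
                ):
                    epochs.append(Epoch(kind, t, dur, sub_block=sb, **common))
                    t += dur
        epochs.append(Epoch(INTER_RUN_REST, t, rest, run=run))
        t += rest
    sched = ParadigmSchedule(epochs=epochs, mode="offline")
    sched.validate()
    return sched


def build_online_schedule(
    layout: TargetLayout,
    n_runs: int = 6,
    seed: int = 0,
    *,
    mode: str = "online_assisted",
    run_init: float = 10.0,
    voice: float = 4.0,
    move_max: float = 7.0,
    hold: float = 2.0,
    pause: float = 4.0,
    rest: float = 40.0,
) -> ParadigmSchedule:
    """Online (closed-loop) schedule at its maximum timing.

    Per block: a 4 s voice cue, then a movement cycle whose maxima are
    7 s forward, 2 s hold at the endpoint, 4 s pause at the target, 7 s
    backward, 2 s hold, 4 s pause at home (movement epochs may end early
    in the simulator when the cue-mute rule fires).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    epochs: list[Epoch] = []
    t = 0.0
    for run in range(1, n_runs + 1):
        epochs.append(Epoch(RUN_INIT, t, run_init, run=run))
        t += run_init
        for block, (arm, target) in enumerate(_randomized_blocks(rng), start=1):
            common = dict(arm=arm, target=target, run=run, block=block)
            epochs.append(Epoch(BLOCK_VOICE, t, voice, **common))
            t += voice
            for kind, dur in (
                (HOME_TO_TARGET, move_max),
                (HOLD_AT_ENDPOINT, hold),
                (PAUSE_AT_TARGET, pause),
                (TARGET_TO_HOME, move_max),
                (HOLD_AT_ENDPOINT, hold),
                (PAUSE_AT_HOME, pause),
            ):
                epochs.append(Epoch(kind, t, dur, **common))
                t += dur
        epochs.append(Epoch(INTER_RUN_REST, t, rest, run=run))
        t += rest
    sched = ParadigmSchedule(epochs=epochs, mode=mode)
    sched.validate()
    return sched


@dataclass
class Trajectory:
    """Single-arm movement template: timestamps, velocity, position."""

    times: np.ndarray  # (T,)
    velocity: np.ndarray  # (T, 3)
    position: np.ndarray  # (T, 3)


def _speed_profile(t: np.ndarray, duration: float, dist: float) -> np.ndarray:
    """Ramp-then-plateau speed covering half the distance in each phase.

    The speed rises linearly from zero until half the home-target
    distance is covered (at 2/3 of the epoch), then stays constant at
    the peak ``1.5 * dist / duration`` until arrival.
    """
    t_ramp = 2.0 * duration / 3.0
    v_peak = 1.5 * dist / duration
    return np.where(t < t_ramp, v_peak * t / t_ramp, v_peak)


def velocity_template(
    home: np.ndarray,
    target: np.ndarray,
    duration: float,
    sample_rate: float,
) -> Trajectory:
    """Ideal velocity/position of one movement epoch.

    Returns ``round(duration * sample_rate) + 1`` samples covering
    ``[0, duration]`` inclusive; the position is the cumulative
    trapezoidal integral of the velocity and reaches ``target`` at the
    final sample.
    """
    home = np.asarray(home, float)
    target = np.asarray(target, float)
    if duration <= 0:
        raise ValueError("duration must be positive")
    delta = target - home
    dist = float(np.linalg.norm(delta))
    if dist == 0.0:
        raise DegenerateTrajectoryError("home and target coincide")
    direction = delta / dist
    n = int(round(duration * sample_rate))
    times = np.arange(n + 1) / sample_rate
    speed = _speed_profile(times, duration, dist)
    vel = speed[:, None] * direction
    # exact integral of the ramp-then-plateau profile
    t_ramp = 2.0 * duration / 3.0
    v_peak = 1.5 * dist / duration
    path = np.where(
        times < t_ramp,
        v_peak * times**2 / (2.0 * t_ramp),
        dist / 2.0 + v_peak * (times - t_ramp),
    )
    pos = home + path[:, None] * direction
    return Trajectory(times=times, velocity=vel, position=pos)


@dataclass
class KinematicsSeries:
    """Session-wide per-arm 3D velocity and position at a fixed rate."""

    times: np.ndarray  # (T,)
    velocity: dict[str, np.ndarray]  # arm -> (T, 3), units/s
    position: dict[str, np.ndarray]  # arm -> (T, 3), units
    sample_rate: float

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.times}
        for arm in self.velocity:
            for i, ax in enumerate("xyz"):
                cols[f"{arm}_v{ax}"] = self.velocity[arm][:, i]
                cols[f"{arm}_p{ax}"] = self.position[arm][:, i]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, sample_rate: float | None = None
    ) -> "KinematicsSeries":
        times = df["time_s"].to_numpy()
        rate = sample_rate or 1.0 / float(np.median(np.diff(times)))
        arms = sorted({c.split("_")[0] for c in df.columns if c != "time_s"})
        vel = {}
        pos = {}
        for arm in arms:
            vel[arm] = np.stack(
                [df[f"{arm}_v{ax}"].to_numpy() for ax in "xyz"], axis=1
            )
            pos[arm] = np.stack(
                [df[f"{arm}_p{ax}"].to_numpy() for ax in "xyz"], axis=1
            )
        return cls(times=times, velocity=vel, position=pos, sample_rate=rate)


def schedule_kinematics(
    schedule: ParadigmSchedule,
    layout: TargetLayout,
    sample_rate: float = 120.0,
) -> KinematicsSeries:
    """Ideal kinematics of a full schedule.

    During movement epochs each arm follows :func:`velocity_template`;
    during pauses and holds the velocity is the zero vector and the
    position is pinned to the epoch's anchor (home or target), so no
    integration error can accumulate across epochs.
    """
    n = int(round(schedule.duration * sample_rate))
    times = np.arange(n) / sample_rate
    vel = {arm: np.zeros((n, 3)) for arm in ARMS}
    pos = {arm: np.tile(layout.home[arm], (n, 1)) for arm in ARMS}
    for e in schedule.epochs:
        if e.arm is None:
            continue
        i0 = int(round(e.onset * sample_rate))
        i1 = min(int(round(e.end * sample_rate)), n)
        if i1 <= i0:
            continue
        home = layout.home[e.arm]
        target = layout.targets[(e.arm, e.target)]
        if e.kind in MOVEMENT_KINDS:
            origin, dest = (
                (home, target) if e.kind == HOME_TO_TARGET else (target, home)
            )
            tmpl = velocity_template(origin, dest, e.duration, sample_rate)
            m = i1 - i0
            vel[e.arm][i0:i1] = tmpl.velocity[:m]
            pos[e.arm][i0:i1] = tmpl.position[:m]
        elif e.kind in (PAUSE_AT_TARGET,):
            pos[e.arm][i0:i1] = target
        elif e.kind in (PAUSE_AT_HOME, BLOCK_VOICE):
            pos[e.arm][i0:i1] = home
        elif e.kind == HOLD_AT_ENDPOINT:
            # ideal kinematics: the arm reached the epoch's endpoint
            prev = pos[e.arm][i0 - 1] if i0 > 0 else home
            pos[e.arm][i0:i1] = prev
    return KinematicsSeries(
        times=times, velocity=vel, position=pos, sample_rate=sample_rate
    )
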