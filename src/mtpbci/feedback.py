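"""Closed-loop machinery: assistance blending, schedule, clamping,
cue muting, and a replayable online-session simulator.

The displayed velocity in assisted runs is a convex combination of the
normalized target and predicted velocity vectors,

    v*_assisted = rho * v*_target + (1 - rho) * v*_predicted,

with rho the assistance fraction (a/100).  The assistance level starts
at 50% and drops by 6 percentage points per run (20% at run six);
direct-feedback runs use 0%.  The displayed position integrates the
assisted velocity at a constant speed scale chosen so that a perfect
decoder traverses home-to-target in the 4 s offline-template time, is
clamped to the workspace box, and ends a movement epoch early when the
hand comes within 20% of the origin-destination distance of its
destination (cue muting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mtp import VelocitySeries, normalize_velocity
from .paradigm import ParadigmSchedule, TargetLayout


@dataclass
class FeedbackConfig:
    assistance: float = 50.0  # percent, ignored in direct mode
    mode: str = "assisted"  # 'assisted' | 'direct'
    mute_threshold: float = 0.20
    bounds: np.ndarray | None = None

    @property
    def rho(self) -> float:
        if self.mode == "direct":
            return 0.0
        return self.assistance / 100.0


def assisted_velocity(
    v_target: np.ndarray, v_predicted: np.ndarray, assistance: float
) -> np.ndarray:
    """Blend normalized target and predicted velocities.

    ``assistance`` is a percentage in [0, 100]; 100 reproduces the
    target vector, 0 the prediction.  Inputs are expected unit-length
    (or zero-flagged), so the output norm never exceeds one.
    """
    if not (0.0 <= assistance <= 100.0):
        raise ValueError("assistance must be in [0, 100]")
    rho = assistance / 100.0
    return rho * np.asarray(v_target, float) + (1.0 - rho) * np.asarray(
        v_predicted, float
    )


def assistance_schedule(run_index: int) -> float:
    """Assistance level (%) for run 1..6: 50% minus 6 points per run."""
    if not (1 <= run_index <= 6):
        raise ValueError("run index must be in 1..6")
    return 50.0 - 6.0 * (run_index - 1)


def clamp_to_workspace(pos: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Componentwise clamp of a position into the workspace box."""
    lo, hi = np.asarray(bounds, float)
    return np.clip(np.asarray(pos, float), lo, hi)


def cue_mute_check(
    pos: np.ndarray,
    origin: np.ndarray,
    destination: np.ndarray,
    threshold: float = 0.20,
) -> bool:
    """True when the hand is within ``threshold`` of the full distance
    of its destination (the auditory cue is muted and the movement epoch
    ends early)."""
    origin = np.asarray(origin, float)
    destination = np.asarray(destination, float)
    dist = np.linalg.norm(destination - origin)
    if dist == 0:
        raise ValueError("degenerate movement: origin equals destination")
    return bool(np.linalg.norm(np.asarray(pos, float) - destination) < threshold * dist)


# ---------------------------------------------------------------------------
# decoders (velocity sources) for replay


class OracleDecoder:
    """Emits the unit direction from the current position to the
    destination -- a perfect controller."""

    def __call__(self, t, arm, pos, origin, destination, rng):
        v, _ = normalize_velocity(np.asarray(destination) - np.asarray(pos))
        return v


class RandomDecoder:
    """Uniformly random unit directions (label-independent control)."""

    def __init__(self, seed: int = 0):
        self._rng = np.random.default_rng(seed)

    def __call__(self, t, arm, pos, origin, destination, rng):
        v = self._rng.standard_normal(3)
        u, _ = normalize_velocity(v)
        return u


class NoisyOracleDecoder:
    """Oracle direction perturbed by isotropic Gaussian noise."""

    def __init__(self, noise_std: float, seed: int = 0):
        self.noise_std = noise_std
        self._rng = np.random.default_rng(seed)

    def __call__(self, t, arm, pos, origin, destination, rng):
        v, _ = normalize_velocity(np.asarray(destination) - np.asarray(pos))
        u, _ = normalize_velocity(v + self.noise_std * self._rng.standard_normal(3))
        return u


class PrerecordedDecoder:
    """Replays a stored velocity stream (e.g. MTP model output)."""

    def __init__(self, series: VelocitySeries):
        self.series = series

    def __call__(self, t, arm, pos, origin, destination, rng):
        i = int(np.clip(np.searchsorted(self.series.times, t), 0,
                        len(self.series.times) - 1))
        return self.series.velocity[i]


# ---------------------------------------------------------------------------
# online simulator


@dataclass
class OnlineLog:
    """Per-step record of one simulated online session."""

    frame: pd.DataFrame
    mode: str

    def movement_rows(self) -> pd.DataFrame:
        return self.frame[self.frame.phase.isin(["forward", "backward"])]

    def trials(self, arm: str | None = None, direction: str = "forward"):
        """Per-trial predicted-velocity arrays and their target labels."""
        rows = self.frame[self.frame.phase == direction]
        if arm is not None:
            rows = rows[rows.arm == arm]
        out = []
        for (run, block), g in rows.groupby(["run", "block"], sort=True):
            v = g[["pred_vx", "pred_vy", "pred_vz"]].to_numpy()
            out.append((g.arm.iloc[0], g.target.iloc[0], v))
        return out

    def to_table(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def simulate_online_session(
    schedule: ParadigmSchedule,
    layout: TargetLayout,
    decoder,
    mode: str = "assisted",
    seed: int = 0,
    rate: float = 40.0,
    template_time: float = 4.0,
    mute_threshold: float = 0.20,
    assistance_override: float | None = None,
) -> OnlineLog:
    """Replay an online session against a velocity source.

    Steps the paradigm clock at the 40 Hz display rate; during movement
    epochs the decoder's normalized velocity is blended with the target
    direction at the run's assistance level, integrated into the
    displayed position (speed scale: home-target distance per 4 s),
    clamped to the workspace, and checked against the cue-mute rule.  On
    mute the movement ends, the 2 s hold begins immediately, and the
    hand is then relocated to the epoch's nominal endpoint for the
    pause, exactly as in the protocol.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate
    rows: list[dict] = []

    # maximum phase durations from the schedule's first block
    def _dur(kind):
        for e in schedule.epochs:
            if e.kind == kind:
                return e.duration
        return 0.0

    voice_d = _dur("block_voice")
    move_max = _dur("home_to_target")
    hold_d = _dur("hold_at_endpoint")
    pause_d = _dur("pause_at_target")
    run_init_d = _dur("run_init")
    rest_d = _dur("inter_run_rest")

    t = 0.0
    for run in schedule.run_ids():
        if assistance_override is not None:
            assist = assistance_override
        elif mode == "direct":
            assist = 0.0
        else:
            assist = assistance_schedule(run)
        t += run_init_d
        for block, arm, target in schedule.blocks(run):
            home = layout.home[arm]
            tgt = layout.targets[(arm, target)]
            dist = np.linalg.norm(tgt - home)
            speed = dist / template_time
            t += voice_d
            pos = home.copy()
            for direction, origin, dest in (
                ("forward", home, tgt),
                ("backward", tgt, home),
            ):
                n_steps = int(round(move_max * rate))
                muted = False
                for _ in range(n_steps):
                    v_raw = np.asarray(
                        decoder(t, arm, pos, origin, dest, rng), float
                    )
                    v_pred, _ = normalize_velocity(v_raw)
                    v_tgt, _ = normalize_velocity(dest - origin)
                    v_ass = assisted_velocity(v_tgt, v_pred, assist)
                    new_pos = pos + v_ass * speed * dt
                    clamped_pos = clamp_to_workspace(new_pos, layout.bounds)
                    clamped = not np.allclose(new_pos, clamped_pos)
                    pos = clamped_pos
                    t += dt
                    muted = cue_mute_check(pos, origin, dest, mute_threshold)
                    rows.append(
                        dict(
                            t=t, run=run, block=block, phase=direction,
                            arm=arm, target=target, assistance=assist,
                            tgt_vx=v_tgt[0], tgt_vy=v_tgt[1], tgt_vz=v_tgt[2],
                            pred_vx=v_pred[0], pred_vy=v_pred[1], pred_vz=v_pred[2],
                            ass_vx=v_ass[0], ass_vy=v_ass[1], ass_vz=v_ass[2],
                            x=pos[0], y=pos[1], z=pos[2],
                            clamped=clamped, muted=muted,
                        )
                    )
                    if muted:
                        break
                # hold at the current endpoint, then relocate for the pause
                for phase, anchor, dur in (
                    ("hold", pos.copy(), hold_d),
                    ("pause", dest, pause_d),
                ):
                    for _ in range(int(round(dur * rate))):
                        t += dt
                        rows.append(
                            dict(
                                t=t, run=run, block=block, phase=phase,
                                arm=arm, target=target, assistance=assist,
                                tgt_vx=0.0, tgt_vy=0.0, tgt_vz=0.0,
                                pred_vx=0.0, pred_vy=0.0, pred_vz=0.0,
                                ass_vx=0.0, ass_vy=0.0, ass_vz=0.0,
                                x=anchor[0], y=anchor[1], z=anchor[2],
                                clamped=False, muted=False,
                            )
                        )
                pos = np.asarray(dest, float).copy()
        t += rest_d
    return OnlineLog(frame=pd.DataFrame(rows), mode=mode)
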