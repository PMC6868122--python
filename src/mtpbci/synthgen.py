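"""Synthetic EEG + kinematics sessions with known ground truth.

No public recordings exist for this protocol, so every decoding stage is
exercised on sessions generated here with a known encoding:

* velocity-encoded sessions (`synthesize_mtp_session`): on designated
  channels a band-limited carrier has amplitude ``sqrt(2 * (c0 + g *
  v(t - delta)))``, so the *windowed band power* -- not the amplitude --
  is affine in the lagged velocity component.  This makes the linear
  band-power decoder correctly specified and enables parameter-recovery
  tests.  All channels additionally carry 1/f background noise, a shared
  common-mode component (exercising the common-average reference) and
  50 Hz line interference.

* class sessions (`synthesize_class_session`): band-limited sensorimotor
  rhythms on designated channels are attenuated multiplicatively during
  task epochs of a given class, emulating contralateral mu/beta
  event-related desynchronization for the FBCSP classifier.

Defaults place the encodings on C3/C4 (contralateral to the moved arm)
with a 100 ms encoding lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import (
    ARMS,
    KinematicsSeries,
    ParadigmSchedule,
    TargetLayout,
    schedule_kinematics,
)
from .preprocess import DEFAULT_MONTAGE, EEGRecording, design_bandpass, apply_fir

MU = (8.0, 12.0)
LOW_BETA = (12.0, 18.0)
HIGH_BETA = (18.0, 28.0)
LOW_GAMMA = (28.0, 40.0)


class EncodingSpecError(ValueError):
    """Raised when an encoding would require a negative carrier power."""


@dataclass(frozen=True)
class EncodingEntry:
    """One channel x band carrier encoding one velocity component."""

    channel: str
    band: tuple[float, float]
    arm: str
    axis: int  # 0=x, 1=y, 2=z
    gain: float  # (units/s)^-1: power change per unit velocity


@dataclass
class EncodingSpec:
    """Where and how strongly velocity modulates band power."""

    entries: list[EncodingEntry]
    baseline_power: float = 1.0  # uV^2, c0
    lag: float = 0.1  # s, encoding lag delta

    def __post_init__(self):
        if self.baseline_power <= 0:
            raise EncodingSpecError("baseline power must be positive")

    @classmethod
    def default(cls, gain: float = 2.0, lag: float = 0.1) -> "EncodingSpec":
        """Contralateral defaults: left-arm velocity on C4, right on C3.

        The three axes of each arm are carried by the mu, low-beta and
        high-beta bands of the contralateral channel.
        """
        entries = []
        for arm, ch in (("left", "C4"), ("right", "C3")):
            for axis, band in enumerate((MU, LOW_BETA, HIGH_BETA)):
                entries.append(EncodingEntry(ch, band, arm, axis, gain))
        return cls(entries=entries, lag=lag)

    @property
    def encoding_channels(self) -> list[str]:
        return sorted({e.channel for e in self.entries})


@dataclass
class NoiseSpec:
    """Background noise model: 1/f-type, common mode, and line noise."""

    one_over_f_exponent: float = 1.0
    channel_scale: float = 2.0  # uV, per-channel broadband std
    common_mode_scale: float = 1.0  # uV, added to all channels
    line_amplitude: float = 0.5  # uV, 50 Hz
    line_freq: float = 50.0

    def __post_init__(self):
        if min(self.channel_scale, self.common_mode_scale, self.line_amplitude) < 0:
            raise ValueError("noise scales must be non-negative")


def one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sfreq: float,
    exponent: float = 1.0,
    scale: float = 1.0,
    f_floor: float = 0.5,
) -> np.ndarray:
    """Gaussian noise spectrally shaped to ~1/f^exponent above f_floor."""
    if scale == 0.0:
        return np.zeros(shape)
    n_ch, n_samp = shape
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    shaping = np.maximum(freqs, f_floor) ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n_samp, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * scale


def _background(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sfreq: float,
    noise: NoiseSpec,
) -> np.ndarray:
    data = one_over_f_noise(
        rng, (n_channels, n_samples), sfreq,
        noise.one_over_f_exponent, noise.channel_scale,
    )
    if noise.common_mode_scale > 0:
        common = one_over_f_noise(
            rng, (1, n_samples), sfreq,
            noise.one_over_f_exponent, noise.common_mode_scale,
        )
        data += common
    if noise.line_amplitude > 0:
        t = np.arange(n_samples) / sfreq
        phase = rng.uniform(0, 2 * np.pi)
        data += noise.line_amplitude * np.sin(
            2 * np.pi * noise.line_freq * t + phase
        )
    return data


def _carrier_freq(band: tuple[float, float]) -> float:
    """Carrier frequency for a band: the even integer nearest its center.

    An even-integer frequency puts an integer number of half-cycles into
    the 250 ms analysis window (also after aliasing of the 2*fc power
    component at 120 samples/s), so the windowed power of the carrier is
    ripple-free and exactly affine in the encoded velocity.
    """
    center = 0.5 * (band[0] + band[1])
    fc = 2.0 * round(center / 2.0)
    if not (band[0] < fc < band[1]):
        fc = center
    return fc


def synthesize_mtp_session(
    schedule: ParadigmSchedule,
    layout: TargetLayout,
    enc: EncodingSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    montage=DEFAULT_MONTAGE,
    sfreq: float = 120.0,
) -> tuple[EEGRecording, KinematicsSeries]:
    """Generate one velocity-encoded EEG session plus its kinematics.

    For each encoding entry the carrier on that channel is
    ``sqrt(2 * (c0 + g * v_axis(t - delta))) * cos(2 pi f_c t + phi)``
    with ``f_c`` the band center, so a 250 ms windowed band power is
    affine in the lagged velocity.  Non-encoding channels carry noise
    only (plus the common-mode component added to all channels).
    """
    enc = enc if enc is not None else EncodingSpec.default()
    noise = noise if noise is not None else NoiseSpec()
    rng = np.random.default_rng(seed)
    kin = schedule_kinematics(schedule, layout, sfreq)
    n_samples = len(kin.times)
    data = _background(rng, len(montage), n_samples, sfreq, noise)
    t = kin.times
    lag_samples = int(round(enc.lag * sfreq))
    for entry in enc.entries:
        if entry.channel not in montage:
            raise ValueError(f"encoding channel {entry.channel!r} not in montage")
        v = kin.velocity[entry.arm][:, entry.axis]
        v_lag = np.concatenate([np.zeros(lag_samples), v])[:n_samples]
        radicand = enc.baseline_power + entry.gain * v_lag
        if np.min(radicand) < 0:
            raise EncodingSpecError(
                f"negative carrier power on {entry.channel}: "
                "reduce gain or raise baseline_power"
            )
        fc = _carrier_freq(entry.band)
        phase = rng.uniform(0, 2 * np.pi)
        data[montage.index(entry.channel)] += np.sqrt(2.0 * radicand) * np.cos(
            2 * np.pi * fc * t + phase
        )
    rec = EEGRecording(data=data, sfreq=sfreq, ch_names=list(montage))
    return rec, kin


@dataclass
class ClassPattern:
    """Per-class multiplicative variance factors for rhythm components.

    Keys are ``(channel, band)`` pairs; the named rhythm's variance is
    multiplied by the factor during task epochs of that class.  A factor
    of 0.5 emulates contralateral event-related desynchronization at a
    2x variance ratio.
    """

    factors: dict[tuple[str, tuple[float, float]], float]

    def __post_init__(self):
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("variance factors must be positive")


def default_class_map() -> dict[str, ClassPattern]:
    """Contralateral mu suppression: left arm -> C4, right arm -> C3."""
    return {
        "left": ClassPattern({("C4", MU): 0.5}),
        "right": ClassPattern({("C3", MU): 0.5}),
    }


DEFAULT_RHYTHMS: dict[tuple[str, tuple[float, float]], float] = {
    ("C3", MU): 3.0,  # uV rhythm std at rest
    ("C4", MU): 3.0,
}


def synthesize_class_session(
    schedule: ParadigmSchedule,
    class_map: dict[str, ClassPattern] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    montage=DEFAULT_MONTAGE,
    sfreq: float = 120.0,
    rhythms: dict | None = None,
) -> tuple[EEGRecording, pd.DataFrame]:
    """Generate an EEG session with class-dependent rhythm variance.

    Each entry of ``rhythms`` places a band-limited oscillatory
    component of the given resting standard deviation (uV) on a channel;
    during the movement cycle of a block whose arm is class ``k`` the
    component's variance is multiplied by that class's factor.  Rest and
    initialization periods are class-independent.

    Returns the recording and a trial table (one row per sub-block
    movement cycle: onset_s, duration_s, label, run, block, sub_block).
    """
    class_map = class_map if class_map is not None else default_class_map()
    noise = noise if noise is not None else NoiseSpec()
    rhythms = rhythms if rhythms is not None else dict(DEFAULT_RHYTHMS)
    rng = np.random.default_rng(seed)
    n_samples = int(round(schedule.duration * sfreq))
    data = _background(rng, len(montage), n_samples, sfreq, noise)

    # task spans per class: the full 12 s movement cycle of each sub-block
    spans: dict[str, list[tuple[float, float]]] = {k: [] for k in class_map}
    trials = []
    for run in schedule.run_ids():
        for block, arm, target in schedule.blocks(run):
            sub_blocks = sorted(
                {
                    e.sub_block
                    for e in schedule.epochs
                    if e.run == run and e.block == block and e.sub_block
                }
            ) or [None]
            for sb in sub_blocks:
                cycle = [
                    e
                    for e in schedule.epochs
                    if e.run == run and e.block == block
                    and e.sub_block == sb and e.kind != "block_voice"
                ]
                if not cycle:  # online-style block without sub-blocks
                    cycle = [
                        e
                        for e in schedule.epochs
                        if e.run == run and e.block == block
                        and e.kind != "block_voice"
                    ]
                onset = min(e.onset for e in cycle)
                end = max(e.end for e in cycle)
                if arm in spans:
                    spans[arm].append((onset, end))
                trials.append(
                    {
                        "onset_s": onset,
                        "duration_s": end - onset,
                        "label": arm,
                        "run": run,
                        "block": block,
                        "sub_block": sb if sb is not None else 1,
                    }
                )

    for (ch, band), base_std in rhythms.items():
        if ch not in montage:
            raise ValueError(f"rhythm channel {ch!r} not in montage")
        taps = design_bandpass(band[0], band[1], sfreq)
        comp = apply_fir(rng.standard_normal((1, n_samples)), taps)[0]
        comp = comp / comp.std() * base_std
        envelope = np.ones(n_samples)
        for label, pattern in class_map.items():
            factor = pattern.factors.get((ch, band))
            if factor is None:
                continue
            for onset, end in spans[label]:
                i0 = int(round(onset * sfreq))
                i1 = min(int(round(end * sfreq)), n_samples)
                envelope[i0:i1] = np.sqrt(factor)
        data[montage.index(ch)] += comp * envelope

    rec = EEGRecording(data=data, sfreq=sfreq, ch_names=list(montage))
    return rec, pd.DataFrame(trials)
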