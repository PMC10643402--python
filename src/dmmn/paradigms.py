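"""Stimulus schedule construction for the pure-tone and duration-MMN paradigms.

Four paradigms are supported:

* **pure_tone** — five pure tones (1, 2, 4, 8, 16 kHz) presented in
  pseudo-random order for tonotopy mapping (500-ms tones, 3-s SOA).
* **oddball** — a single frequency; 50-ms standard tones with 10% of trials
  randomly replaced by a 100-ms deviant, 550-ms SOA.
* **many_standards** — the same frequency presented at ten durations
  (10–225 ms) with equal probability; the adaptation control for the oddball.
* **standard_blocks** — blocks of ten 50-ms tones at a fixed SOA (550 or
  350 ms) separated by 10-s silent gaps, used for the adaptation analysis.

A photostimulation overlay flags a random subset of tones (or *virtual*
silent tones) as followed by a 300-ms laser pulse train.

All randomness is seeded; identical arguments and seed produce a bit-exact
event list.  Onset times are in seconds from the first tone onset, rounded
to microsecond resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Tone frequencies (Hz) used in all in-study paradigms.
FREQUENCIES_HZ = (1000.0, 2000.0, 4000.0, 8000.0, 16000.0)

#: Default duration set (ms) of the many-standards control.
MANY_STANDARDS_DURATIONS_MS = (
    10.0, 25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 175.0, 200.0, 225.0)

ROLES = ("pure", "standard", "deviant", "control", "virtual")

#: Photostimulation pulse train: 10 pulses of 10 ms with 20-ms gaps.
PHOTOSTIM_N_PULSES = 10
PHOTOSTIM_PULSE_MS = 10.0
PHOTOSTIM_GAP_MS = 20.0
#: Total stimulation window (10 x 30-ms period), starting at tone end.
PHOTOSTIM_WINDOW_MS = 300.0


def _round_us(t: float) -> float:
    """Round a time in seconds to microsecond resolution."""
    return round(t, 6)


@dataclass(frozen=True)
class ToneEvent:
    """A single timed tone presentation.

    ``role='virtual'`` marks a silent placeholder tone (no acoustic energy;
    the duration is still recorded so the photostimulation window can be
    anchored to the virtual tone end).
    """

    onset_s: float
    duration_ms: float
    frequency_hz: float
    role: str
    photostim: bool = False
    block_position: int | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.duration_ms <= 0:
            raise ValueError("tone duration must be positive")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_ms / 1000.0


@dataclass(frozen=True)
class StimulusSchedule:
    """An ordered list of :class:`ToneEvent` with paradigm metadata.

    ``f_odd`` records the single tone frequency of an oddball /
    many-standards session.
    """

    events: tuple[ToneEvent, ...]
    paradigm: str
    soa: float
    seed: int | None = None
    session_length_s: float | None = None
    f_odd: float | None = None
    extras: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        onsets = [e.onset_s for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onset times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events])

    @property
    def durations_ms(self) -> np.ndarray:
        return np.array([e.duration_ms for e in self.events])

    @property
    def roles(self) -> list[str]:
        return [e.role for e in self.events]

    def to_frame(self) -> pd.DataFrame:
        """Event table with one row per tone."""
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "duration_ms": [e.duration_ms for e in self.events],
                "frequency_hz": [e.frequency_hz for e in self.events],
                "role": [e.role for e in self.events],
                "photostim": [e.photostim for e in self.events],
                "block_position": [e.block_position for e in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, paradigm: str = "pure_tone",
                 soa: float = float("nan")) -> "StimulusSchedule":
        df = pd.read_csv(path, sep="\t")
        bp = df["block_position"] if "block_position" in df else [None] * len(df)
        events = tuple(
            ToneEvent(
                onset_s=float(r.onset_s),
                duration_ms=float(r.duration_ms),
                frequency_hz=float(r.frequency_hz),
                role=str(r.role),
                photostim=bool(r.photostim),
                block_position=None if pd.isna(p) else int(p),
            )
            for r, p in zip(df.itertuples(), bp)
        )
        return cls(events=events, paradigm=paradigm, soa=soa)


def _n_trials(session_length_s: float, soa: float) -> int:
    # floor with an epsilon so 165 / 0.55 -> 300, not 299
    return int(math.floor(session_length_s / soa + 1e-9))


def make_pure_tone_schedule(
    frequencies=FREQUENCIES_HZ,
    n_repeats: int = 10,
    soa: float = 3.0,
    duration_ms: float = 500.0,
    seed: int = 0,
) -> StimulusSchedule:
    """Pseudo-random pure-tone schedule for tonotopy mapping.

    Each frequency appears exactly ``n_repeats`` times in a seeded random
    permutation, with consecutive onsets spaced by ``soa``.
    """
    frequencies = tuple(float(f) for f in frequencies)
    if not frequencies:
        raise ValueError("frequency list must not be empty")
    if soa <= 0:
        raise ValueError("soa must be positive")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(len(frequencies)), n_repeats)
    rng.shuffle(order)
    events = tuple(
        ToneEvent(_round_us(i * soa), duration_ms, frequencies[j], "pure")
        for i, j in enumerate(order)
    )
    return StimulusSchedule(events, "pure_tone", soa, seed,
                            session_length_s=len(order) * soa)


def make_oddball_schedule(
    frequency: float,
    session_length_s: float = 165.0,
    soa: float = 0.55,
    standard_ms: float = 50.0,
    deviant_ms: float = 100.0,
    deviant_prob: float = 0.1,
    seed: int = 0,
    min_separation: int = 0,
) -> StimulusSchedule:
    """Oddball schedule: repeated standards, rare deviant-duration tones.

    Each trial is independently a deviant with probability ``deviant_prob``
    (seeded Bernoulli draws).  ``min_separation`` optionally suppresses
    deviants closer than that many trials to the previous deviant; the
    default (0) places no constraint.
    """
    if not 0.0 <= deviant_prob <= 1.0:
        raise ValueError("deviant_prob must be in [0, 1]")
    if soa <= 0:
        raise ValueError("soa must be positive")
    rng = np.random.default_rng(seed)
    n = _n_trials(session_length_s, soa)
    is_dev = rng.random(n) < deviant_prob
    if min_separation > 0:
        last = -min_separation - 1
        for i in range(n):
            if is_dev[i]:
                if i - last <= min_separation:
                    is_dev[i] = False
                else:
                    last = i
    events = tuple(
        ToneEvent(
            _round_us(i * soa),
            deviant_ms if d else standard_ms,
            float(frequency),
            "deviant" if d else "standard",
        )
        for i, d in enumerate(is_dev)
    )
    return StimulusSchedule(events, "oddball", soa, seed,
                            session_length_s=session_length_s,
                            f_odd=float(frequency))


def make_many_standards_schedule(
    frequency: float,
    session_length_s: float = 165.0,
    soa: float = 0.55,
    durations_ms=MANY_STANDARDS_DURATIONS_MS,
    seed: int = 0,
    first_duration_ms: float | None = None,
) -> StimulusSchedule:
    """Many-standards control: ten durations, equal probability, random order.

    ``first_duration_ms`` optionally forces the duration of the first tone
    (used by the first-vs-later adaptation control, which requires the
    session to open with a 100-ms tone).
    """
    durations_ms = tuple(float(d) for d in durations_ms)
    if not durations_ms:
        raise ValueError("duration set must not be empty")
    if soa <= 0:
        raise ValueError("soa must be positive")
    if max(durations_ms) >= soa * 1000.0:
        raise ValueError("tone duration must be shorter than the SOA")
    rng = np.random.default_rng(seed)
    n = _n_trials(session_length_s, soa)
    draws = rng.integers(0, len(durations_ms), size=n)
    durs = [durations_ms[j] for j in draws]
    if first_duration_ms is not None and n > 0:
        durs[0] = float(first_duration_ms)
    events = tuple(
        ToneEvent(_round_us(i * soa), d, float(frequency), "control")
        for i, d in enumerate(durs)
    )
    return StimulusSchedule(events, "many_standards", soa, seed,
                            session_length_s=session_length_s,
                            f_odd=float(frequency))


def make_standard_block_schedule(
    frequency: float,
    soa: float = 0.55,
    block_size: int = 10,
    inter_block_s: float = 10.0,
    n_blocks: int = 18,
    duration_ms: float = 50.0,
) -> StimulusSchedule:
    """Standard-tone blocks for the adaptation-by-position analysis.

    Each block is ``block_size`` tones at ``soa`` spacing; the gap between
    the last onset of one block and the first onset of the next is
    ``inter_block_s``.  Events carry 1-based within-block position labels.
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2 (adaptation needs >= 2 positions)")
    if soa <= 0 or inter_block_s <= 0:
        raise ValueError("soa and inter_block_s must be positive")
    events = []
    t = 0.0
    for b in range(n_blocks):
        for p in range(block_size):
            events.append(
                ToneEvent(_round_us(t), duration_ms, float(frequency),
                          "standard", block_position=p + 1)
            )
            t += soa
        t += inter_block_s - soa  # gap measured onset-to-onset
    return StimulusSchedule(tuple(events), "standard_blocks", soa, None,
                            f_odd=float(frequency))


def make_repeated_tone_schedule(
    frequency: float,
    session_length_s: float = 165.0,
    soa: float = 0.55,
    duration_ms: float = 50.0,
    virtual: bool = False,
) -> StimulusSchedule:
    """Uniform 50-ms-tone (or silent *virtual* tone) train at a fixed SOA.

    The base schedule for the photostimulation overlay.
    """
    if soa <= 0:
        raise ValueError("soa must be positive")
    n = _n_trials(session_length_s, soa)
    role = "virtual" if virtual else "standard"
    events = tuple(
        ToneEvent(_round_us(i * soa), duration_ms, float(frequency), role)
        for i in range(n)
    )
    return StimulusSchedule(events, "photostim", soa, None,
                            session_length_s=session_length_s,
                            f_odd=float(frequency))


def make_photostim_schedule(
    base: StimulusSchedule,
    stim_prob: float = 0.1,
    seed: int = 0,
) -> StimulusSchedule:
    """Flag a random fraction of tones as followed by laser stimulation.

    The stimulation window is 300 ms starting at the tone end: ten 10-ms
    pulses with 20-ms inter-pulse gaps (280 ms of the window carries pulse
    onsets-to-offsets activity).
    """
    if not 0.0 <= stim_prob <= 1.0:
        raise ValueError("stim_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    flags = rng.random(len(base.events)) < stim_prob
    events = tuple(
        replace(e, photostim=bool(f)) for e, f in zip(base.events, flags)
    )
    return StimulusSchedule(events, "photostim", base.soa, seed,
                            session_length_s=base.session_length_s,
                            f_odd=base.f_odd)


def photostim_pulse_times_ms() -> np.ndarray:
    """Pulse onset times (ms) relative to the tone end."""
    period = PHOTOSTIM_PULSE_MS + PHOTOSTIM_GAP_MS
    return np.arange(PHOTOSTIM_N_PULSES) * period


def photostim_envelope_ms() -> tuple[float, float]:
    """(active span, total window) of the pulse train in ms.

    The active span runs from the first pulse onset to the last pulse
    offset: 10 pulses x 10 ms + 9 gaps x 20 ms = 280 ms inside the 300-ms
    stimulation window.
    """
    active = (PHOTOSTIM_N_PULSES * PHOTOSTIM_PULSE_MS
              + (PHOTOSTIM_N_PULSES - 1) * PHOTOSTIM_GAP_MS)
    return active, PHOTOSTIM_WINDOW_MS
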