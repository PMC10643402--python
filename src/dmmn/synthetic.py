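"""Ground-truth synthetic data: ROI fluorescence, one-photon movies, LFP.

The generator emulates the phenomenology of marmoset auditory cortex that the
analysis pipeline is built to measure, with every planted parameter recorded
so downstream estimates can be checked against truth:

* **Tonotopic tuning** — each neuron/pixel has a best frequency (BF) from
  {1, 2, 4, 8, 16} kHz and a Gaussian tuning curve on log2 frequency.
* **Calcium dynamics** — a difference-of-exponentials kernel (GCaMP6f-like,
  ~50 ms rise, ~400 ms decay), normalised to unit peak so an impulse of
  height *d* produces a peak ΔF/F of *d*.
* **Onset/offset responses** — separate drive impulses at tone onset and
  tone end, with independent gains.
* **Stimulus-specific adaptation** — a resource-depletion rule: each
  presentation multiplies the resource *a* by (1-u); between presentations
  *a* relaxes back to 1 with time constant tau.  Core-like parameters
  recover almost fully within a 550-ms SOA but not within 350 ms; RPB-like
  parameters (slow recovery) stay strongly suppressed even at 550 ms.
* **Deviance detection** — a phenomenological amplitude injected at tone
  end when the tone's duration deviates from the modal duration of the
  recent history *and* that mode is dominant (a regularity has been
  established).  The dominance gate keeps the many-standards control free
  of injections, so the planted amplitude is exactly the oddball-vs-control
  difference.
* **Neuropil contamination** — recorded ROI fluorescence is
  ``F_roi = F_cell + r_true * F_neuropil + noise`` where the neuropil trace
  carries a scaled population signal plus slow drift; the analysis must
  recover ``r_true`` by robust regression and invert the mixture.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .paradigms import StimulusSchedule

AREA_LABELS = ("core", "ML_CL", "RPB", "CPB")

#: Adaptation presets per cortical area (resource fraction lost per tone
#: ``u`` and recovery time constant ``tau`` in seconds).  Core-like
#: parameters produce negligible steady-state attenuation at SOA 550 ms
#: (~0.1%) but measurable attenuation at 350 ms (~1.2%); the RPB preset
#: (slow recovery) is suppressed ~75% even at 550 ms, independent of tone
#: duration.
AREA_ADAPTATION = {
    "core": {"u": 0.95, "tau": 0.08},
    "ML_CL": {"u": 0.95, "tau": 0.20},
    "RPB": {"u": 0.95, "tau": 2.0},
    "CPB": {"u": 0.95, "tau": 0.30},
}


@dataclass
class NeuronGroundTruth:
    """Planted parameters of one simulated neuron."""

    bf: float = 2000.0
    area_label: str = "core"
    tuning_width_oct: float = 1.0
    onset_gain: float = 0.3
    offset_gain: float = 0.1
    adaptation_u: float = 0.0
    adaptation_tau: float = 0.5
    deviance_amp: float = 0.0
    baseline_f: float = 100.0

    def __post_init__(self):
        if self.onset_gain < 0 or self.offset_gain < 0:
            raise ValueError("gains must be non-negative")
        if not 0.0 <= self.adaptation_u <= 1.0:
            raise ValueError("adaptation_u must be in [0, 1]")
        if self.adaptation_tau <= 0:
            raise ValueError("adaptation_tau must be positive")


@dataclass
class CalciumKernel:
    """Difference-of-exponentials indicator kernel, unit peak amplitude."""

    rise_tau: float = 0.05
    decay_tau: float = 0.4
    amplitude: float = 1.0

    def __post_init__(self):
        if not self.rise_tau < self.decay_tau:
            raise ValueError("rise_tau must be smaller than decay_tau")

    def sample(self, frame_rate: float, length_s: float = 4.0) -> np.ndarray:
        """Kernel sampled at the frame grid, scaled to peak ``amplitude``."""
        t = np.arange(0.0, length_s, 1.0 / frame_rate)
        k = np.exp(-t / self.decay_tau) - np.exp(-t / self.rise_tau)
        peak = k.max()
        if peak <= 0:
            raise ValueError("degenerate kernel")
        return self.amplitude * k / peak


@dataclass
class RoiTraceSet:
    """Simulated (or loaded) per-ROI fluorescence with optional ground truth."""

    f_roi: np.ndarray          # (n_roi, n_frames)
    f_neuropil: np.ndarray     # (n_roi, n_frames)
    frame_rate: float
    schedule: StimulusSchedule
    truth: list[NeuronGroundTruth] | None = None
    r_true: float | None = None
    f_cell: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.f_roi.shape != self.f_neuropil.shape:
            raise ValueError("f_roi and f_neuropil must have equal shape")

    @property
    def n_roi(self) -> int:
        return self.f_roi.shape[0]

    @property
    def n_frames(self) -> int:
        return self.f_roi.shape[1]


def log2_tuning(bf_hz: float, freq_hz: float, width_oct: float) -> float:
    """Gaussian tuning on log2 frequency; equals 1 at the best frequency."""
    x = np.log2(freq_hz / bf_hz)
    return float(np.exp(-(x * x) / (2.0 * width_oct * width_oct)))


def steady_state_adaptation(u: float, tau: float, soa: float) -> float:
    """Fixed point of the depletion/recovery cycle at a constant SOA.

    Solves ``a* = 1 - (1 - a*(1-u)) * exp(-soa/tau)``.
    """
    e = np.exp(-soa / tau)
    return float((1.0 - e) / (1.0 - (1.0 - u) * e))


def relax_resource(a: float, dt: float, tau: float) -> float:
    """Exponential recovery of the resource toward 1 over a silent gap."""
    return 1.0 - (1.0 - a) * float(np.exp(-dt / tau))


def _deviance_triggered(
    duration_ms: float,
    history_ms,
    threshold_ms: float = 25.0,
    window: int = 20,
    dominance: float = 0.6,
    min_history: int = 10,
) -> bool:
    """Whether a tone's duration violates an established duration regularity.

    A regularity exists only when the modal duration accounts for at least
    ``dominance`` of the trailing ``window`` presentations; an equiprobable
    many-standards stream therefore never triggers an injection.
    """
    recent = list(history_ms)[-window:]
    if len(recent) < min_history:
        return False
    mode_ms, count = Counter(recent).most_common(1)[0]
    if count / len(recent) < dominance:
        return False
    return abs(duration_ms - mode_ms) > threshold_ms


def drive_amplitude(
    neuron: NeuronGroundTruth,
    event,
    state: float,
    history_ms=(),
    deviance_threshold_ms: float = 25.0,
) -> tuple[float, float, float]:
    """Onset/offset drive for one tone and the post-depletion resource.

    ``state`` is the adaptation resource *a* at the moment of the tone;
    both drives scale with it.  The returned ``new_state`` reflects the
    depletion ``a <- a * (1 - u)``; recovery across the following silent
    interval is applied separately with :func:`relax_resource`.
    """
    if not 0.0 <= state <= 1.0:
        raise ValueError("adaptation state must be in [0, 1]")
    g = log2_tuning(neuron.bf, event.frequency_hz, neuron.tuning_width_oct)
    onset = neuron.onset_gain * g * state
    offset = neuron.offset_gain * g * state
    if neuron.deviance_amp > 0 and _deviance_triggered(
        event.duration_ms, history_ms, deviance_threshold_ms
    ):
        offset += neuron.deviance_amp * g
    new_state = state * (1.0 - neuron.adaptation_u)
    return onset, offset, new_state


def _drive_impulses(
    schedule: StimulusSchedule,
    neuron: NeuronGroundTruth,
    frame_rate: float,
    n_frames: int,
    deviance_threshold_ms: float = 25.0,
) -> np.ndarray:
    """Impulse train (one value per frame) of onset + offset drives."""
    imp = np.zeros(n_frames)
    a = 1.0
    t_prev = None
    history: list[float] = []
    for ev in schedule.events:
        if t_prev is not None:
            a = relax_resource(a, ev.onset_s - t_prev, neuron.adaptation_tau)
        onset, offset, a = drive_amplitude(
            neuron, ev, a, history, deviance_threshold_ms)
        f_on = int(round(ev.onset_s * frame_rate))
        f_off = int(round(ev.end_s * frame_rate))
        if 0 <= f_on < n_frames:
            imp[f_on] += onset
        if 0 <= f_off < n_frames:
            imp[f_off] += offset
        t_prev = ev.onset_s
        history.append(ev.duration_ms)
    return imp


def simulate_roi_traces(
    schedule: StimulusSchedule,
    neurons: list[NeuronGroundTruth],
    kernel: CalciumKernel | None = None,
    noise_sd: float = 1.0,
    r_true: float = 0.15,
    seed: int = 0,
    frame_rate: float = 30.0,
    pad_s: float = 3.0,
    neuropil_gain: float = 0.15,
    neuropil_baseline: float = 50.0,
    drift_amp: float = 0.2,
    neuropil_noise_sd: float = 0.5,
    chunk_frames: int = 200_000,
) -> RoiTraceSet:
    """Simulate recorded ROI and surrounding-neuropil fluorescence.

    Mixing model: ``F_roi = F_cell + r_true * F_neuropil + noise`` with
    ``F_cell = baseline_f * (1 + kernel (*) drives)``.  The neuropil trace
    shares a scaled population signal plus a slow multiplicative drift, so
    the contamination slope is identifiable by robust regression.  Long
    schedules are convolved in chunks; the output is identical.
    """
    if not 0.0 <= r_true <= 0.5:
        raise ValueError("r_true must be in [0, 0.5]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    kernel = kernel or CalciumKernel()
    rng = np.random.default_rng(seed)
    last = schedule.events[-1]
    n_frames = int(np.ceil((last.end_s + pad_s) * frame_rate))
    k = kernel.sample(frame_rate)

    n_roi = len(neurons)
    dff_cell = np.empty((n_roi, n_frames))
    for i, nr in enumerate(neurons):
        imp = _drive_impulses(schedule, nr, frame_rate, n_frames)
        dff_cell[i] = _chunked_convolve(imp, k, chunk_frames)

    baselines = np.array([nr.baseline_f for nr in neurons])[:, None]
    f_cell = baselines * (1.0 + dff_cell)

    t = np.arange(n_frames) / frame_rate
    pop_dff = dff_cell.mean(axis=0)
    drift = drift_amp * np.sin(2.0 * np.pi * t / 60.0 + rng.uniform(0, 2 * np.pi))
    f_np = neuropil_baseline * (1.0 + neuropil_gain * pop_dff + drift)
    f_neuropil = np.tile(f_np, (n_roi, 1))
    if neuropil_noise_sd > 0:
        f_neuropil += rng.normal(0.0, neuropil_noise_sd,
                                 size=(n_roi, n_frames))

    noise = (rng.normal(0.0, noise_sd, size=(n_roi, n_frames))
             if noise_sd > 0 else 0.0)
    f_roi = f_cell + r_true * f_neuropil + noise
    return RoiTraceSet(
        f_roi=f_roi, f_neuropil=np.asarray(f_neuropil, dtype=float),
        frame_rate=frame_rate, schedule=schedule, truth=list(neurons),
        r_true=r_true, f_cell=f_cell,
    )


def _chunked_convolve(imp: np.ndarray, k: np.ndarray, chunk: int) -> np.ndarray:
    """Causal convolution of an impulse train, processed in bounded chunks."""
    n = imp.size
    if n <= chunk:
        return np.convolve(imp, k)[:n]
    out = np.zeros(n)
    m = k.size
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        seg = np.convolve(imp[s:e], k)
        stop = min(n, e + m - 1)
        out[s:stop] += seg[: stop - s]
    return out


# ---------------------------------------------------------------------------
# One-photon movies
# ---------------------------------------------------------------------------

@dataclass
class MapSpec:
    """Planted pixel-wise best-frequency map and area parameters.

    ``bf_map`` holds one BF (Hz) per pixel; ``area_map`` holds integer
    indices into ``area_labels``.  The default factory lays the five BFs as
    vertical bands along the horizontal (rostro-caudal) axis, low frequency
    rostral to high frequency caudal.
    """

    bf_map: np.ndarray
    area_map: np.ndarray
    area_labels: tuple[str, ...] = ("core",)
    tuning_width_oct: float = 1.0
    onset_gain: float = 0.3
    offset_gain: float = 0.1
    deviance_amp_by_area: dict = field(default_factory=dict)

    @classmethod
    def gradient(cls, frame_size=(64, 64),
                 frequencies=(1000.0, 2000.0, 4000.0, 8000.0, 16000.0),
                 **kw) -> "MapSpec":
        h, w = frame_size
        cols = np.linspace(0, len(frequencies), w, endpoint=False).astype(int)
        bf = np.tile(np.asarray(frequencies)[cols], (h, 1))
        return cls(bf_map=bf, area_map=np.zeros((h, w), dtype=int), **kw)

    @classmethod
    def uniform(cls, frame_size=(64, 64), bf=2000.0, **kw) -> "MapSpec":
        h, w = frame_size
        return cls(bf_map=np.full((h, w), float(bf)),
                   area_map=np.zeros((h, w), dtype=int), **kw)


def simulate_onephoton_movie(
    schedule: StimulusSchedule,
    map_spec: MapSpec,
    kernel: CalciumKernel | None = None,
    frame_rate: float = 30.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    baseline: float = 100.0,
    vignette: float = 0.3,
    pad_s: float = 3.0,
    deviance_threshold_ms: float = 25.0,
) -> np.ndarray:
    """Widefield movie stack (frames, H, W) from a planted tonotopic map.

    Each pixel responds according to its map BF; adaptation state is
    tracked per area with the area's preset parameters; vignetting is a
    radial multiplicative profile on the baseline; noise is Gaussian with a
    shot-like intensity-scaled term.
    """
    kernel = kernel or CalciumKernel()
    rng = np.random.default_rng(seed)
    h, w = map_spec.bf_map.shape
    last = schedule.events[-1]
    n_frames = int(np.ceil((last.end_s + pad_s) * frame_rate))
    k = kernel.sample(frame_rate)

    freqs = sorted({e.frequency_hz for e in schedule.events})
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)
    r2 = r2 / max(r2.max(), 1.0)
    vig = 1.0 - vignette * r2

    dff = np.zeros((n_frames, h, w), dtype=np.float32)
    for ai, label in enumerate(map_spec.area_labels):
        mask = map_spec.area_map == ai
        if not mask.any():
            continue
        params = AREA_ADAPTATION.get(label, {"u": 0.0, "tau": 0.5})
        dev_amp = map_spec.deviance_amp_by_area.get(label, 0.0)
        proto = NeuronGroundTruth(
            bf=freqs[0], area_label=label if label in AREA_LABELS else "core",
            tuning_width_oct=map_spec.tuning_width_oct,
            onset_gain=map_spec.onset_gain, offset_gain=map_spec.offset_gain,
            adaptation_u=params["u"], adaptation_tau=params["tau"],
            deviance_amp=dev_amp,
        )
        # one impulse train per stimulus frequency; pixels differ only by
        # their tuning weight to that frequency
        for f in freqs:
            sub_events = [e for e in schedule.events if e.frequency_hz == f]
            if not sub_events:
                continue
            proto_f = NeuronGroundTruth(
                bf=f, area_label=proto.area_label,
                tuning_width_oct=proto.tuning_width_oct,
                onset_gain=proto.onset_gain, offset_gain=proto.offset_gain,
                adaptation_u=proto.adaptation_u,
                adaptation_tau=proto.adaptation_tau,
                deviance_amp=proto.deviance_amp,
            )
            imp = _freq_impulses(schedule, proto_f, f, frame_rate, n_frames,
                                 deviance_threshold_ms)
            trace = _chunked_convolve(imp, k, 200_000).astype(np.float32)
            weight = np.exp(
                -(np.log2(f / map_spec.bf_map)) ** 2
                / (2.0 * map_spec.tuning_width_oct ** 2)
            ).astype(np.float32)
            weight = np.where(mask, weight, 0.0)
            dff += trace[:, None, None] * weight[None, :, :]

    movie = (baseline * vig[None, :, :]).astype(np.float32) * (1.0 + dff)
    if noise_sd > 0:
        movie = movie + rng.normal(
            0.0, noise_sd, size=movie.shape
        ).astype(np.float32) * np.sqrt(np.maximum(movie, 1.0) / baseline)
    return movie


def _freq_impulses(schedule, neuron, freq, frame_rate, n_frames,
                   deviance_threshold_ms):
    """Impulse train restricted to one frequency; adaptation state is driven
    by the full event stream (tones of other frequencies still deplete)."""
    imp = np.zeros(n_frames)
    a = 1.0
    t_prev = None
    history: list[float] = []
    for ev in schedule.events:
        if t_prev is not None:
            a = relax_resource(a, ev.onset_s - t_prev, neuron.adaptation_tau)
        onset, offset, a = drive_amplitude(neuron, ev, a, history,
                                           deviance_threshold_ms)
        if ev.frequency_hz == freq:
            f_on = int(round(ev.onset_s * frame_rate))
            f_off = int(round(ev.end_s * frame_rate))
            # unit-tuning drive; pixel tuning weight applied by the caller
            g = log2_tuning(neuron.bf, ev.frequency_hz,
                            neuron.tuning_width_oct)
            if g > 0 and 0 <= f_on < n_frames:
                imp[f_on] += onset / g
            if g > 0 and 0 <= f_off < n_frames:
                imp[f_off] += offset / g
        t_prev = ev.onset_s
        history.append(ev.duration_ms)
    return imp


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _biphasic_waveform(sample_rate: float, length_s: float = 0.25) -> np.ndarray:
    """Stereotyped evoked deflection: dominant negative phase peaking ~40 ms
    with a smaller positive rebound ~130 ms (signed 0-200-ms mean ~ -0.19)."""
    t = np.arange(0.0, length_s, 1.0 / sample_rate)
    neg = -np.exp(-((t - 0.040) ** 2) / (2 * 0.020 ** 2))
    pos = 0.2 * np.exp(-((t - 0.130) ** 2) / (2 * 0.025 ** 2))
    return neg + pos


def _one_over_f_noise(n: int, rng: np.random.Generator,
                      sample_rate: float, scale: float) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum, unit-free scale."""
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return scale * x / sd if sd > 0 else x


def simulate_lfp(
    schedule: StimulusSchedule,
    area_params: dict | str = "core",
    sample_rate: float = 24_000.0,
    seed: int = 0,
    amplitude: float = 1.0,
    noise_scale: float = 0.0015,
    pad_s: float = 1.0,
    pre_pad_s: float = 1.0,
    duration_gain_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """LFP voltage trace with per-tone deflections scaled by adaptation.

    Returns ``(trace, t)`` with ``t`` in seconds; the recording starts
    ``pre_pad_s`` before the first tone onset (``t[0] = -pre_pad_s``).
    ``area_params`` is an area label key of :data:`AREA_ADAPTATION` or an
    explicit ``{'u':..., 'tau':...}`` dict.  Each tone evokes the
    stereotyped biphasic waveform scaled by ``amplitude * a`` where *a* is
    the resource state; 1/f background noise is added.  Virtual tones evoke
    nothing.
    """
    if sample_rate < 1000:
        raise ValueError("sample_rate must be >= 1 kHz")
    params = (AREA_ADAPTATION[area_params]
              if isinstance(area_params, str) else dict(area_params))
    rng = np.random.default_rng(seed)
    last = schedule.events[-1]
    n = int(np.ceil((pre_pad_s + last.end_s + pad_s) * sample_rate))
    shift = pre_pad_s
    wf = _biphasic_waveform(sample_rate)
    trace = np.zeros(n)
    a = 1.0
    t_prev = None
    for ev in schedule.events:
        if t_prev is not None:
            a = relax_resource(a, ev.onset_s - t_prev, params["tau"])
        drive = amplitude * a
        if duration_gain_ms is not None:
            drive *= ev.duration_ms / duration_gain_ms
        if ev.role != "virtual":
            i0 = int(round((ev.onset_s + shift) * sample_rate))
            seg = min(wf.size, n - i0)
            if seg > 0:
                trace[i0:i0 + seg] += drive * wf[:seg]
        a *= 1.0 - params["u"]
        t_prev = ev.onset_s
    if noise_scale > 0:
        trace += _one_over_f_noise(n, rng, sample_rate, noise_scale)
    t = np.arange(n) / sample_rate - pre_pad_s
    return trace, t
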