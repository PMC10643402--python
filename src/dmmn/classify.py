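"""Response classification: tone responsiveness, best frequency, selectivity
index, onset/offset types, dMMN responsiveness, tonotopic maps.

All statistical gates use the two-sided Wilcoxon signed-rank test at
P < 0.05 unless stated otherwise, mirroring the conventions of awake-primate
calcium-imaging work: responsiveness additionally requires a run of three
consecutive supra-threshold frames on the trial-averaged trace, and the
two-photon gates require the significant window mean to exceed a ΔF/F₀ of
0.01 so that statistically reliable but negligible responses are not
counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import TrialAlignedResponses


def _signed_rank_p(x: np.ndarray) -> float:
    """Two-sided signed-rank p of paired differences; 1.0 if degenerate."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.allclose(x, 0.0):
        return 1.0
    try:
        return float(stats.wilcoxon(x, alternative="two-sided").pvalue)
    except ValueError:
        return 1.0


@dataclass
class ResponsivenessDiagnostics:
    run_ok: bool
    signed_rank_ok: bool
    p_value: float
    threshold: float
    longest_run: int
    mean_response: float
    flags: list[str] = field(default_factory=list)


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def is_tone_responsive_region(
    trials: TrialAlignedResponses,
    alpha: float = 0.05,
    z: float = 1.96,
    min_run: int = 3,
    response_frames: int | None = None,
    sd_mode: str = "average",
    min_amplitude: float | None = None,
) -> tuple[bool, ResponsivenessDiagnostics]:
    """Two-criteria responsiveness gate for a region or neuron.

    1. the trial-averaged ΔF/F₀ trace has at least ``min_run`` consecutive
       post-onset frames exceeding ``z`` times the baseline-period SD;
    2. the per-trial mean response over the response window is significantly
       larger than baseline (two-sided signed rank at ``alpha`` with a
       positive mean).

    ``sd_mode='average'`` takes the SD of the trial-averaged trace over the
    baseline window (default); ``'per_trial'`` pools single-trial baseline
    SD instead.  ``min_amplitude`` adds the two-photon amplitude gate
    (window-mean ΔF/F₀ must exceed it).
    """
    if trials.n_trials < 6:
        raise ValueError("need >= 6 trials for the signed-rank criterion")
    pre = trials.frame_offsets < 0
    post = trials.frame_offsets >= 0
    avg = trials.values.mean(axis=0)
    if sd_mode == "average":
        sd = avg[pre].std(ddof=0)
    elif sd_mode == "per_trial":
        sd = trials.values[:, pre].std(ddof=0)
    else:
        raise ValueError("sd_mode must be 'average' or 'per_trial'")
    mu = avg[pre].mean()
    thr = mu + z * sd
    flags: list[str] = []
    if sd == 0:
        flags.append("zero baseline SD; run criterion degenerate")
    post_idx = np.flatnonzero(post)
    if response_frames is not None:
        post_idx = post_idx[:response_frames]
    run = _longest_run(avg[post_idx] > thr)
    run_ok = run >= min_run

    win = trials.values[:, post_idx].mean(axis=1)
    p = _signed_rank_p(win)
    if p == 1.0 and np.allclose(win, 0.0):
        flags.append("all-tied paired values; signed-rank undefined")
    sr_ok = (p < alpha) and (win.mean() > 0)
    if min_amplitude is not None:
        sr_ok = sr_ok and (win.mean() > min_amplitude)
    diag = ResponsivenessDiagnostics(
        run_ok=run_ok, signed_rank_ok=sr_ok, p_value=p, threshold=thr,
        longest_run=run, mean_response=float(win.mean()), flags=flags)
    return bool(run_ok and sr_ok), diag


def best_frequency(
    trials_by_freq: dict[float, TrialAlignedResponses],
    response_frames: int = 30,
) -> float:
    """Best frequency: argmax of the window-mean ΔF/F₀ across frequencies.

    Exact ties are broken toward the lower frequency.
    """
    if any(t.n_trials == 0 for t in trials_by_freq.values()):
        raise ValueError("every frequency needs at least one trial")
    best_f, best_v = None, -np.inf
    for f in sorted(trials_by_freq):
        t = trials_by_freq[f]
        post = np.flatnonzero(t.frame_offsets >= 0)[:response_frames]
        v = t.values[:, post].mean()
        if v > best_v:  # strict: ties keep the lower frequency
            best_f, best_v = f, v
    return float(best_f)


def selectivity_index(responses) -> float:
    """Selectivity index: sum of the five responses scaled so the best is 1.

    Negative baseline-subtracted responses are clipped to zero before
    scaling, which guarantees the documented [1, 5] range: 1 when the
    neuron responds to a single frequency, 5 when it responds equally to
    all five.
    """
    r = np.asarray(list(responses), dtype=float)
    best = r.max()
    if best <= 0:
        raise ValueError("SI undefined: best response is not positive")
    r = np.clip(r, 0.0, None)
    return float(np.sum(r / best))


def classify_onset_offset(
    trials: TrialAlignedResponses,
    duration_ms: float,
    alpha: float = 0.05,
    post_window_frames: int = 15,
    pre_window_frames: int = 5,
) -> tuple[bool, bool, dict]:
    """Onset+/offset+ classification at the neuron's best frequency.

    A neuron is onset+ (offset+) when the fluorescence averaged over 15
    frames (0.5 s) after the tone onset (end) significantly exceeds that
    over 5 frames (167 ms) before the onset (end); both flags may hold
    (onset+ offset+ class).  For long tones the onset response window can
    contain the tone end — this overlap is inherent and flagged.
    """
    if trials.n_trials < 6:
        raise ValueError("need >= 6 trials")
    fr = trials.frame_rate
    off = trials.frame_offsets
    diag: dict = {"flags": []}

    def window_mean(first_frame: int, n: int) -> np.ndarray:
        cols = np.flatnonzero((off >= first_frame) & (off < first_frame + n))
        if cols.size < n:
            raise ValueError("window extends beyond the aligned span")
        return trials.values[:, cols].mean(axis=1)

    end_frame = int(round(duration_ms / 1000.0 * fr))
    if end_frame < post_window_frames:
        diag["flags"].append("onset response window overlaps the tone end")

    onset_post = window_mean(0, post_window_frames)
    onset_pre = window_mean(-pre_window_frames, pre_window_frames)
    d_on = onset_post - onset_pre
    p_on = _signed_rank_p(d_on)
    onset_pos = (p_on < alpha) and (d_on.mean() > 0)

    offset_post = window_mean(end_frame, post_window_frames)
    offset_pre = window_mean(end_frame - pre_window_frames, pre_window_frames)
    d_off = offset_post - offset_pre
    p_off = _signed_rank_p(d_off)
    offset_pos = (p_off < alpha) and (d_off.mean() > 0)

    diag.update(p_onset=p_on, p_offset=p_off,
                onset_diff=float(d_on.mean()), offset_diff=float(d_off.mean()))
    return bool(onset_pos), bool(offset_pos), diag


def partition_standard_trials(
    n_standard: int, n_groups: int = 9, seed: int = 0
) -> list[np.ndarray]:
    """Seeded random partition of standard trials into near-equal groups."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_standard)
    return [np.sort(g) for g in np.array_split(perm, n_groups)]


def is_dmmn_responsive(
    oddball: TrialAlignedResponses,
    many_standards: TrialAlignedResponses,
    seed: int = 0,
    alpha: float = 0.05,
    min_amplitude: float = 0.01,
    response_frames: int = 15,
    min_group: int = 5,
) -> tuple[bool, dict]:
    """dMMN-responsiveness gate over twenty trial groups.

    The twenty groups are: the oddball deviant trials; nine seeded random
    near-equal groups of the oddball standards; and the ten duration groups
    of the many-standards paradigm.  The neuron is responsive if any group
    shows a significantly positive post-onset window mean (signed rank,
    two-sided, P < ``alpha``) with a group-mean ΔF/F₀ above
    ``min_amplitude``.  Groups smaller than ``min_group`` are skipped and
    recorded.
    """
    groups: dict[str, np.ndarray] = {}
    odd_roles = oddball.metadata["role"].to_numpy()
    groups["deviant"] = np.flatnonzero(odd_roles == "deviant")
    std_idx = np.flatnonzero(odd_roles == "standard")
    for gi, g in enumerate(partition_standard_trials(std_idx.size, 9, seed)):
        groups[f"standard_{gi + 1}"] = std_idx[g]
    durations = np.unique(many_standards.metadata["duration_ms"].to_numpy())
    for d in durations:
        groups[f"ms_{d:g}ms"] = np.flatnonzero(
            many_standards.metadata["duration_ms"].to_numpy() == d)

    details: dict = {"groups": {}, "skipped": [], "n_groups": len(groups)}
    responsive = False
    for name, idx in groups.items():
        src = many_standards if name.startswith("ms_") else oddball
        if idx.size < min_group:
            details["skipped"].append(name)
            continue
        post = np.flatnonzero(src.frame_offsets >= 0)[:response_frames]
        win = src.values[idx][:, post].mean(axis=1)
        p = _signed_rank_p(win)
        mean = float(win.mean())
        sig = (p < alpha) and (mean > 0) and (mean > min_amplitude)
        details["groups"][name] = {"n": int(idx.size), "p": p, "mean": mean,
                                   "significant": bool(sig)}
        responsive = responsive or sig
    return bool(responsive), details


@dataclass
class NeuronProfile:
    """Classification summary of one neuron/ROI."""

    tone_responsive: bool
    bf: float | None = None
    si: float | None = None
    onset_pos: bool = False
    offset_pos: bool = False
    dmmn_responsive: bool = False
    responses_by_freq: dict = field(default_factory=dict)
    area_label: str | None = None

    @property
    def onset_offset_pos(self) -> bool:
        return self.onset_pos and self.offset_pos


def build_neuron_profile(
    trials_by_freq: dict[float, TrialAlignedResponses],
    tone_duration_ms: float = 500.0,
    alpha: float = 0.05,
    si_response_frames: int = 30,
    si_baseline_frames: int = 15,
    min_amplitude: float = 0.01,
    area_label: str | None = None,
) -> NeuronProfile:
    """Full pure-tone classification of a neuron from per-frequency trials.

    A neuron is tone-responsive when at least one frequency passes the
    signed-rank gate with window-mean ΔF/F₀ above ``min_amplitude``; BF, SI
    and onset/offset flags are computed only for tone-responsive neurons.
    SI uses the 1-s post-onset window minus the 0.5-s pre-onset baseline
    per frequency.
    """
    responsive_any = False
    resp: dict[float, float] = {}
    for f, t in sorted(trials_by_freq.items()):
        post = np.flatnonzero(t.frame_offsets >= 0)[:si_response_frames]
        pre = np.flatnonzero(t.frame_offsets < 0)[-si_baseline_frames:]
        win = t.values[:, post].mean(axis=1)
        base = t.values[:, pre].mean(axis=1)
        resp[f] = float(win.mean() - base.mean())
        p = _signed_rank_p(win)
        if p < alpha and win.mean() > min_amplitude:
            responsive_any = True
    if not responsive_any:
        return NeuronProfile(tone_responsive=False, responses_by_freq=resp,
                             area_label=area_label)
    bf = best_frequency(trials_by_freq, response_frames=si_response_frames)
    try:
        si = selectivity_index([resp[f] for f in sorted(resp)])
    except ValueError:
        si = None
        warnings.warn("SI undefined (best baseline-subtracted response <= 0)",
                      stacklevel=2)
    onset_pos, offset_pos, _ = classify_onset_offset(
        trials_by_freq[bf], tone_duration_ms, alpha=alpha)
    return NeuronProfile(
        tone_responsive=True, bf=bf, si=si, onset_pos=onset_pos,
        offset_pos=offset_pos, responses_by_freq=resp, area_label=area_label)


@dataclass
class BfMap:
    """Pixelwise best-frequency map with quantized display amplitudes."""

    bf: np.ndarray          # (H, W) BF in Hz, NaN where non-responsive
    amplitude: np.ndarray   # (H, W) peak window-mean ΔF/F₀, NaN where masked
    levels: np.ndarray      # (H, W) brightness level 1..n_levels, 0 = masked
    frequencies: tuple


def tonotopic_map(
    amplitude_by_freq: dict[float, np.ndarray],
    mask: np.ndarray | None = None,
    n_levels: int = 5,
) -> BfMap:
    """Pixelwise BF map from per-frequency response-amplitude images.

    Each pixel's BF is the frequency with the maximum window-mean response;
    the peak amplitude is quantized into ``n_levels`` equal brightness bins
    for display.  Pixels outside ``mask`` are set to NaN/level 0.
    """
    freqs = sorted(amplitude_by_freq)
    stack = np.stack([amplitude_by_freq[f] for f in freqs])
    h, w = stack.shape[1:]
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    if not mask.any():
        warnings.warn("empty responsiveness mask; map is empty", stacklevel=2)
    # ties resolved toward the lower frequency (argmax takes the first max)
    idx = np.argmax(stack, axis=0)
    bf = np.asarray(freqs, dtype=float)[idx]
    amp = np.take_along_axis(stack, idx[None], axis=0)[0]
    bf = np.where(mask, bf, np.nan)
    amp = np.where(mask, amp, np.nan)
    levels = np.zeros((h, w), dtype=int)
    if mask.any() and np.nanmax(amp) > 0:
        edges = np.linspace(0.0, np.nanmax(amp), n_levels + 1)
        lv = np.digitize(np.nan_to_num(amp, nan=-1.0), edges[1:-1]) + 1
        levels = np.where(mask, lv, 0)
    return BfMap(bf=bf, amplitude=amp, levels=levels,
                 frequencies=tuple(freqs))
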