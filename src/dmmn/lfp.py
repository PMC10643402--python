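"""Event-related LFP analysis: binning, deviance detection on binned
amplitudes, and the standard-paradigm adaptation analysis.

Raw voltage traces (sampled at >= 1 kHz) are cut into trials and averaged
in non-overlapping 10-ms bins from 100 ms before each tone onset to 500 ms
after it (60 bins); the mean of the pre-onset bins is subtracted per trial
as the baseline.  Deviance detection on the binned amplitudes reuses the
same per-timepoint rank-sum/FDR machinery as the calcium analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deviance import DevianceResult, timecourse_comparison, window_frames
from .paradigms import StimulusSchedule


@dataclass
class BinnedLfp:
    """Trials x bins baseline-subtracted LFP amplitudes.

    ``bin_starts_ms`` gives the left edge of each bin relative to the tone
    onset (default -100, -90, ..., +490 ms: 60 non-overlapping 10-ms bins).
    """

    values: np.ndarray
    bin_starts_ms: np.ndarray
    bin_ms: float
    metadata: pd.DataFrame
    qc: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def select(self, mask) -> "BinnedLfp":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return BinnedLfp(self.values[idx], self.bin_starts_ms, self.bin_ms,
                         self.metadata.iloc[idx].reset_index(drop=True),
                         dict(self.qc))


def bin_lfp(
    trace: np.ndarray,
    sample_rate: float,
    schedule: StimulusSchedule,
    pre_ms: float = 100.0,
    post_ms: float = 500.0,
    bin_ms: float = 10.0,
    subtract_baseline: bool = True,
    trace_start_s: float = 0.0,
) -> BinnedLfp:
    """Bin a raw LFP trace around every tone onset of a schedule.

    Each bin is the mean of its raw samples; the per-trial baseline (mean
    over the pre-onset bins) is subtracted unless ``subtract_baseline`` is
    False.  ``trace_start_s`` is the time of the first sample relative to
    the schedule origin (negative when the recording starts before the
    first tone).  Trials whose window falls outside the recording are
    dropped with a warning.
    """
    if sample_rate < 1000:
        raise ValueError("sample_rate must be >= 1 kHz")
    trace = np.asarray(trace, dtype=float)
    spb = bin_ms / 1000.0 * sample_rate  # samples per bin
    n_bins = int(round((pre_ms + post_ms) / bin_ms))
    bin_starts = -pre_ms + bin_ms * np.arange(n_bins)
    rows, meta = [], []
    n_dropped = 0
    prev_dur = np.nan
    for j, ev in enumerate(schedule.events):
        s0 = (ev.onset_s - trace_start_s - pre_ms / 1000.0) * sample_rate
        vals = np.empty(n_bins)
        lo = int(round(s0))
        hi = int(round(s0 + n_bins * spb))
        if lo < 0 or hi > trace.size:
            n_dropped += 1
            prev_dur = ev.duration_ms
            continue
        for b in range(n_bins):
            a = int(round(s0 + b * spb))
            z = int(round(s0 + (b + 1) * spb))
            vals[b] = trace[a:z].mean()
        if subtract_baseline:
            vals = vals - vals[bin_starts < 0].mean()
        rows.append(vals)
        meta.append(dict(role=ev.role, duration_ms=ev.duration_ms,
                         frequency_hz=ev.frequency_hz,
                         prev_duration_ms=prev_dur, onset_s=ev.onset_s,
                         block_position=ev.block_position, event_index=j))
        prev_dur = ev.duration_ms
    if n_dropped:
        warnings.warn(f"{n_dropped} trials dropped (window outside recording)",
                      stacklevel=2)
    values = np.array(rows) if rows else np.empty((0, n_bins))
    return BinnedLfp(
        values=values, bin_starts_ms=bin_starts, bin_ms=bin_ms,
        metadata=pd.DataFrame(
            meta, columns=["role", "duration_ms", "frequency_hz",
                           "prev_duration_ms", "onset_s", "block_position",
                           "event_index"]),
        qc={"n_dropped": n_dropped},
    )


def lfp_deviance(
    deviant: BinnedLfp,
    control: BinnedLfp,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
) -> DevianceResult:
    """Bin-wise deviance detection on binned LFP amplitudes.

    Identical contract to the calcium :func:`~dmmn.deviance.deviance_timecourse`
    — the two share one implementation parameterised by the time grid.  The
    0–200 ms and 200–400 ms window amplitudes of the difference are exposed
    in ``extras``.
    """
    if not np.array_equal(deviant.bin_starts_ms, control.bin_starts_ms):
        raise ValueError("binned sets must share one bin grid")
    res = timecourse_comparison(deviant.values, control.values,
                                deviant.bin_starts_ms, alpha=alpha,
                                fdr_q=fdr_q)
    res.extras["amp_0_200"] = res.window_amplitude((0.0, 200.0))
    res.extras["amp_200_400"] = res.window_amplitude((200.0, 400.0))
    return res


@dataclass
class AdaptationResult:
    """Per-within-block-position amplitudes and position-1 comparisons."""

    positions: np.ndarray        # 1..block_size
    amplitudes: np.ndarray       # mean window amplitude per position
    block_amplitudes: np.ndarray  # (n_blocks, block_size)
    p_values: np.ndarray         # signed-rank pos 1 vs pos k (k >= 2)
    p_adjusted: np.ndarray       # BH-FDR over positions 2..block_size
    significant: np.ndarray      # adjusted p < alpha per later position
    alpha: float


def adaptation_by_position(
    binned: BinnedLfp,
    window_ms=(0.0, 200.0),
    alpha: float = 0.05,
    min_blocks: int = 6,
) -> AdaptationResult:
    """Adaptation analysis of a standard-block session.

    The amplitude of each trial is its mean binned LFP over ``window_ms``
    after tone onset.  Amplitudes are arranged as blocks x positions; the
    first position is compared with each later position across blocks
    (two-sided Wilcoxon signed rank) with BH-FDR adjustment over the later
    positions.
    """
    pos = binned.metadata["block_position"].to_numpy()
    if np.any(pd.isna(pos)):
        raise ValueError("trials must carry block-position labels")
    pos = pos.astype(int)
    cols = window_frames(binned.bin_starts_ms, window_ms)
    amps = binned.values[:, cols].mean(axis=1)
    positions = np.unique(pos)
    block_size = positions.size
    if binned.n_trials % block_size:
        raise ValueError("incomplete blocks in the binned data")
    n_blocks = binned.n_trials // block_size
    if n_blocks < min_blocks:
        raise ValueError(f"need >= {min_blocks} blocks")
    mat = np.full((n_blocks, block_size), np.nan)
    counters = {p: 0 for p in positions}
    for a, p in zip(amps, pos):
        mat[counters[p], p - 1] = a
        counters[p] += 1
    p_vals = np.empty(block_size - 1)
    for k in range(1, block_size):
        d = mat[:, 0] - mat[:, k]
        if np.allclose(d, 0.0):
            p_vals[k - 1] = 1.0
        else:
            p_vals[k - 1] = stats.wilcoxon(
                d, alternative="two-sided").pvalue
    reject, p_adj, _, _ = multipletests(p_vals, alpha=alpha, method="fdr_bh")
    return AdaptationResult(
        positions=positions, amplitudes=mat.mean(axis=0),
        block_amplitudes=mat, p_values=p_vals, p_adjusted=p_adj,
        significant=reject, alpha=alpha)


def first_vs_later_control(
    sessions: list[tuple[float, float]],
    alpha: float = 0.05,
) -> dict:
    """First 100-ms tone vs. the mean of later 100-ms tones, across sessions.

    ``sessions`` holds one (first amplitude, mean later amplitude) pair per
    many-standards session whose first tone was a 100-ms tone.  With >= 6
    sessions a paired signed-rank test is run; with fewer, only the
    descriptive difference is reported.
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    first = np.array([s[0] for s in sessions], dtype=float)
    later = np.array([s[1] for s in sessions], dtype=float)
    diff = first - later
    out = {"n_sessions": len(sessions), "mean_first": float(first.mean()),
           "mean_later": float(later.mean()),
           "mean_difference": float(diff.mean()), "p_value": None,
           "tested": False}
    if len(sessions) >= 6 and not np.allclose(diff, 0.0):
        out["p_value"] = float(
            stats.wilcoxon(diff, alternative="two-sided").pvalue)
        out["tested"] = True
    return out


def session_first_later_amplitudes(
    binned: BinnedLfp,
    target_duration_ms: float = 100.0,
    window_ms=(0.0, 200.0),
) -> tuple[float, float] | None:
    """(first, mean-of-later) window amplitudes of one session's target tones.

    Returns None when the session's first tone is not a target-duration
    tone or no later target tones exist.
    """
    dur = binned.metadata["duration_ms"].to_numpy(dtype=float)
    if dur.size == 0 or dur[0] != target_duration_ms:
        return None
    idx = np.flatnonzero(dur == target_duration_ms)
    later = idx[idx > 0]
    if later.size == 0:
        return None
    cols = window_frames(binned.bin_starts_ms, window_ms)
    amps = binned.values[:, cols].mean(axis=1)
    return float(amps[0]), float(amps[later].mean())
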