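"""Deviance-detection statistics and the dMMN decomposition.

*Deviance detection* is the response to the deviant (100-ms) tone in the
oddball paradigm minus the response to the 100-ms tone in the many-standards
control at the same frequency.  Per-timepoint significance uses the
two-sided Wilcoxon rank-sum test with Benjamini–Hochberg FDR adjustment
across the timepoints of the aligned window.

The duration-MMN amplitude (deviant minus standard in the oddball paradigm)
decomposes exactly into three components::

    dMMN = deviance detection            (deviant_odd  - control_100)
         + tone difference               (control_100  - control_50)
         + adaptation                    (control_50   - standard_odd)

To avoid baseline contamination from the slowly decaying calcium response
of the preceding tone, control trials are restricted to 100-ms tones whose
immediately preceding tone had a duration of 10, 25 or 50 ms (matching the
50-ms standard that precedes a deviant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import TrialAlignedResponses

#: Default control-trial filter: previous-tone durations (ms) that leave the
#: baseline comparably clean to the oddball 50-ms standard.
ALLOWED_PREV_MS = (10.0, 25.0, 50.0)


def select_control_trials(
    metadata: pd.DataFrame,
    target_duration_ms: float = 100.0,
    allowed_prev_ms=ALLOWED_PREV_MS,
) -> np.ndarray:
    """Indices of many-standards control trials for the deviance statistic.

    Selects target-duration trials whose immediately preceding trial had a
    duration in ``allowed_prev_ms``; a first trial (no predecessor) is never
    selected.  Pass ``allowed_prev_ms=None`` for the permissive mode that
    uses every non-first target-duration tone.
    """
    dur = metadata["duration_ms"].to_numpy(dtype=float)
    prev = metadata["prev_duration_ms"].to_numpy(dtype=float)
    sel = (dur == target_duration_ms) & ~np.isnan(prev)
    if allowed_prev_ms is not None:
        sel &= np.isin(prev, np.asarray(allowed_prev_ms, dtype=float))
    return np.flatnonzero(sel)


@dataclass
class DevianceResult:
    """Per-timepoint deviant/control comparison with FDR control.

    ``mask`` is the reported significance mask: FDR-adjusted two-sided
    P < ``alpha`` *and* a positive deviant-minus-control difference (the
    claim is directional).  ``mask_two_sided`` omits the sign gate.
    """

    deviant_mean: np.ndarray
    control_mean: np.ndarray
    difference: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    mask: np.ndarray
    mask_two_sided: np.ndarray
    n_deviant: int
    n_control: int
    times_ms: np.ndarray
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)

    def window_amplitude(self, window_ms, reference: str = "onset",
                         duration_ms: float | None = None,
                         which: str = "difference") -> float:
        series = getattr(self, which)
        return window_amplitude(series, self.times_ms, window_ms,
                                reference=reference, duration_ms=duration_ms)


def timecourse_comparison(
    deviant: np.ndarray,
    control: np.ndarray,
    times_ms: np.ndarray,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
) -> DevianceResult:
    """Frame/bin-wise rank-sum comparison of two trial sets with BH-FDR.

    ``deviant`` and ``control`` are (trials x timepoints) matrices on the
    same grid; ``times_ms`` gives the start time of each timepoint.  Frames
    where all values are tied get p = 1.
    """
    deviant = np.atleast_2d(np.asarray(deviant, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    if deviant.shape[1] != control.shape[1]:
        raise ValueError("trial matrices must share the timepoint grid")
    if deviant.shape[0] < 4 or control.shape[0] < 4:
        raise ValueError("need >= 4 trials per side for the rank-sum test")
    n_t = deviant.shape[1]
    p = np.ones(n_t)
    for j in range(n_t):
        a, b = deviant[:, j], control[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue  # degenerate frame, keep p = 1
        p[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    reject, p_adj, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    dmean = deviant.mean(axis=0)
    cmean = control.mean(axis=0)
    diff = dmean - cmean
    return DevianceResult(
        deviant_mean=dmean, control_mean=cmean, difference=diff,
        p_values=p, p_adjusted=p_adj,
        mask=reject & (diff > 0), mask_two_sided=reject,
        n_deviant=deviant.shape[0], n_control=control.shape[0],
        times_ms=np.asarray(times_ms, dtype=float), alpha=alpha,
    )


def deviance_timecourse(
    deviant_trials: TrialAlignedResponses,
    control_trials: TrialAlignedResponses,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
) -> DevianceResult:
    """Deviance detection on trial-aligned ΔF/F₀ matrices.

    Thin wrapper over :func:`timecourse_comparison` using the shared frame
    grid of the two aligned trial sets.
    """
    if not np.array_equal(deviant_trials.frame_offsets,
                          control_trials.frame_offsets):
        raise ValueError("trial sets must be aligned on the same frame grid")
    return timecourse_comparison(
        deviant_trials.values, control_trials.values,
        deviant_trials.times_ms, alpha=alpha, fdr_q=fdr_q)


def window_frames(times_ms: np.ndarray, window_ms) -> np.ndarray:
    """Timepoints whose start time lies inside ``window_ms`` (inclusive)."""
    lo, hi = window_ms
    t = np.asarray(times_ms, dtype=float)
    return np.flatnonzero((t >= lo - 1e-9) & (t <= hi + 1e-9))


def window_amplitude(
    series: np.ndarray,
    times_ms: np.ndarray,
    window_ms,
    reference: str = "onset",
    duration_ms: float | None = None,
) -> float:
    """Mean of a per-timepoint series over an analysis window.

    ``window_ms`` is (start, end) in ms relative to the tone onset
    (``reference='onset'``) or the tone end (``reference='tone_end'``,
    which shifts the window by ``duration_ms``).  A timepoint belongs to
    the window when its start time lies inside it, both ends inclusive.
    """
    lo, hi = float(window_ms[0]), float(window_ms[1])
    if reference == "tone_end":
        if duration_ms is None:
            raise ValueError("duration_ms required with reference='tone_end'")
        lo, hi = lo + duration_ms, hi + duration_ms
    elif reference != "onset":
        raise ValueError("reference must be 'onset' or 'tone_end'")
    idx = window_frames(times_ms, (lo, hi))
    if idx.size == 0:
        raise ValueError("window contains no timepoints")
    return float(np.asarray(series, dtype=float)[idx].mean())


@dataclass
class DmmnComponents:
    """The dMMN series and its exact three-component decomposition."""

    dmmn: np.ndarray
    deviance_detection: np.ndarray
    tone_difference: np.ndarray
    adaptation: np.ndarray
    times_ms: np.ndarray | None = None

    def window(self, window_ms, **kw) -> dict[str, float]:
        if self.times_ms is None:
            raise ValueError("no time grid attached")
        return {
            name: window_amplitude(getattr(self, name), self.times_ms,
                                   window_ms, **kw)
            for name in ("dmmn", "deviance_detection", "tone_difference",
                         "adaptation")
        }


def dmmn_decomposition(
    deviant_odd: np.ndarray,
    standard_odd: np.ndarray,
    control_100: np.ndarray,
    control_50: np.ndarray,
    times_ms: np.ndarray | None = None,
) -> DmmnComponents:
    """Exact decomposition of the dMMN into its three components.

    All four inputs are per-timepoint mean response series on one grid.
    The identity ``dmmn = deviance_detection + tone_difference +
    adaptation`` holds exactly (it is a telescoping sum).
    """
    arrs = [np.asarray(a, dtype=float) for a in
            (deviant_odd, standard_odd, control_100, control_50)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("all four series must share one grid")
    dev, std, c100, c50 = arrs
    return DmmnComponents(
        dmmn=dev - std,
        deviance_detection=dev - c100,
        tone_difference=c100 - c50,
        adaptation=c50 - std,
        times_ms=None if times_ms is None else np.asarray(times_ms, float),
    )


def estimate_deviance_amplitude(
    deviant_trials: TrialAlignedResponses,
    control_trials: TrialAlignedResponses,
    kernel_frames: np.ndarray,
    window_ms=(100.0, 300.0),
    target_duration_ms: float = 100.0,
) -> float:
    """Template-based estimate of the deviance amplitude in ΔF/F₀ units.

    The deviant-minus-control mean difference over ``window_ms`` after the
    tone end is divided by the mean of the calcium-kernel template over the
    same frames, where the template accounts for each trial's exact
    frame-snapped tone-end position (tone onsets falling on half-integer
    frames shift the response by one frame on alternating trials).  The
    result is the amplitude of an impulse at tone end that would produce
    the observed difference.
    """
    if not np.array_equal(deviant_trials.frame_offsets,
                          control_trials.frame_offsets):
        raise ValueError("trial sets must share one frame grid")
    fr = deviant_trials.frame_rate
    times = deviant_trials.times_ms
    lo = window_ms[0] + target_duration_ms
    hi = window_ms[1] + target_duration_ms
    cols = window_frames(times, (lo, hi))
    diff = (deviant_trials.values.mean(axis=0)
            - control_trials.values.mean(axis=0))
    k = np.asarray(kernel_frames, dtype=float)
    templates = []
    for _, row in deviant_trials.metadata.iterrows():
        onset_f = int(round(row.onset_s * fr))
        end_f = int(round((row.onset_s + row.duration_ms / 1000.0) * fr))
        rel = end_f - onset_f
        templates.append(np.mean([
            k[f - rel] if f >= rel else 0.0
            for f in deviant_trials.frame_offsets[cols]]))
    template = float(np.mean(templates))
    if template <= 0:
        raise ValueError("window precedes the injected response")
    return float(diff[cols].mean() / template)


# ---------------------------------------------------------------------------
# Pixelwise deviance maps
# ---------------------------------------------------------------------------

@dataclass
class DevianceMap:
    """Per-segment deviance statistics over a binned movie.

    ``amplitude`` holds the window-mean deviant-minus-control difference
    for responsive segments (NaN elsewhere); ``display`` applies the
    half-maximum rendering floor (values below half of the map maximum are
    clamped to that floor) — a display transform only, the data values are
    preserved in ``amplitude``.
    """

    amplitude: np.ndarray
    responsive: np.ndarray
    display: np.ndarray
    results: dict
    status: str = "ok"


def deviance_map(
    deviant_stack: np.ndarray,
    control_stack: np.ndarray,
    times_ms: np.ndarray,
    window_ms=(0.0, 500.0),
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    z: float = 1.96,
    min_run: int = 3,
) -> DevianceMap:
    """Deviance detection per pixel segment of a binned movie.

    Inputs are (trials, timepoints, H, W) ΔF/F₀ stacks on a common grid
    whose pre-onset timepoints (negative ``times_ms``) form the baseline.
    Segments must first show a significant response to the deviant tone
    (the two-criteria responsiveness gate); the deviance statistic is then
    computed on the responsive segments only.
    """
    dv = np.asarray(deviant_stack, dtype=float)
    cv = np.asarray(control_stack, dtype=float)
    h, w = dv.shape[2:]
    pre = np.asarray(times_ms) < 0
    post = ~pre
    amplitude = np.full((h, w), np.nan)
    responsive = np.zeros((h, w), dtype=bool)
    results: dict = {}
    for i in range(h):
        for j in range(w):
            seg_d = dv[:, :, i, j]
            avg = seg_d.mean(axis=0)
            sd = avg[pre].std(ddof=0)
            thr = avg[pre].mean() + z * sd
            run_ok = _run_at_least(avg[post] > thr, min_run)
            win = seg_d[:, post].mean(axis=1)
            try:
                p = stats.wilcoxon(win, alternative="two-sided").pvalue
            except ValueError:
                p = 1.0
            if not (run_ok and p < alpha and win.mean() > 0):
                continue
            responsive[i, j] = True
            res = timecourse_comparison(seg_d, cv[:, :, i, j], times_ms,
                                        alpha=alpha, fdr_q=fdr_q)
            results[(i, j)] = res
            amplitude[i, j] = res.window_amplitude(window_ms)
    if not responsive.any():
        warnings.warn("no responsive segments; deviance map is empty",
                      stacklevel=2)
        return DevianceMap(amplitude, responsive,
                           display=np.full((h, w), np.nan), results={},
                           status="empty")
    vmax = np.nanmax(amplitude)
    floor = vmax / 2.0
    display = np.where(np.isnan(amplitude), np.nan,
                       np.maximum(amplitude, floor))
    return DevianceMap(amplitude=amplitude, responsive=responsive,
                       display=display, results=results)


def _run_at_least(mask: np.ndarray, n: int) -> bool:
    cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        if cur >= n:
            return True
    return False


# ---------------------------------------------------------------------------
# Optogenetic comparison and effect size
# ---------------------------------------------------------------------------

@dataclass
class PhotostimComparison:
    included_mask: np.ndarray
    excluded_mask: np.ndarray
    tone_stim_amplitudes: np.ndarray
    tone_only_amplitudes: np.ndarray
    p_value: float | None
    effect_size: float | None
    status: str = "ok"


def photostim_comparison(
    tone_stim_stack: np.ndarray,
    tone_only_stack: np.ndarray,
    stim_only_stack: np.ndarray,
    times_ms: np.ndarray,
    window_ms=(333.0, 500.0),
    alpha: float = 0.05,
) -> PhotostimComparison:
    """Compare tone responses with vs. without following photostimulation.

    The averaging region is built from segments significantly responsive to
    the tone-plus-stimulation trials, excluding segments that respond to
    the stimulation alone (from the virtual-tone sessions).  Per-trial
    window means over the included region are compared with a two-sided
    rank-sum test, with Cohen's d as the effect size.
    """
    def _resp_mask(stack):
        h, w = stack.shape[2:]
        mask = np.zeros((h, w), dtype=bool)
        pre = np.asarray(times_ms) < 0
        post = ~pre
        for i in range(h):
            for j in range(w):
                seg = stack[:, :, i, j]
                avg = seg.mean(axis=0)
                thr = avg[pre].mean() + 1.96 * avg[pre].std(ddof=0)
                if not _run_at_least(avg[post] > thr, 3):
                    continue
                win = seg[:, post].mean(axis=1)
                try:
                    p = stats.wilcoxon(win, alternative="two-sided").pvalue
                except ValueError:
                    p = 1.0
                mask[i, j] = p < alpha and win.mean() > 0
        return mask

    stim_resp = _resp_mask(np.asarray(tone_stim_stack, float))
    stim_only_resp = _resp_mask(np.asarray(stim_only_stack, float))
    included = stim_resp & ~stim_only_resp
    if not included.any():
        return PhotostimComparison(
            included_mask=included, excluded_mask=stim_only_resp,
            tone_stim_amplitudes=np.array([]),
            tone_only_amplitudes=np.array([]),
            p_value=None, effect_size=None, status="empty-region")
    cols = window_frames(times_ms, window_ms)

    def region_amps(stack):
        region = np.asarray(stack, float)[:, :, included]  # trials, t, pix
        return region[:, cols].mean(axis=(1, 2))

    a = region_amps(tone_stim_stack)
    b = region_amps(tone_only_stack)
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return PhotostimComparison(
        included_mask=included, excluded_mask=stim_only_resp,
        tone_stim_amplitudes=a, tone_only_amplitudes=b,
        p_value=p, effect_size=cohens_d(a, b))


def cohens_d(a, b=None, paired: bool = False) -> float:
    """Cohen's d effect size.

    Unpaired: mean difference over the pooled SD (n-1 weighting).  Paired
    (or single-sample ``a`` of differences): mean over SD of the
    differences.  Raises on zero variance.
    """
    a = np.asarray(a, dtype=float)
    if paired:
        if b is not None:
            a = a - np.asarray(b, dtype=float)
        sd = a.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance; effect size undefined")
        return float(a.mean() / sd)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per sample")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero variance; effect size undefined")
    return float((a.mean() - b.mean()) / pooled)
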