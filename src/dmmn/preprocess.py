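"""Raw fluorescence to trial-aligned ΔF/F₀: binning, neuropil correction,
baseline normalisation, trial alignment.

ΔF/F₀ is ``(F - F0) / F0`` where F₀ is the mean fluorescence over a short
pre-onset baseline window (10 frames / 333 ms in the pure-tone analysis,
5 frames / 167 ms in the dMMN analysis at 30 frames/s).

Neuropil correction follows the two-photon convention: for each ROI the
recorded fluorescence is regressed on the surrounding-neuropil fluorescence
with iteratively reweighted least squares (bisquare weights), excluding
timepoints where the ROI trace exceeds its time-mean plus one SD (i.e.
evoked transients); the median slope over the ROIs of a field is the
contamination factor *r* and the corrected signal is
``F = F_roi - r * F_neuropil``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .paradigms import StimulusSchedule


def bin_movie(movie: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Spatially bin a movie (frames, H, W) or frame (H, W) by block means.

    If the input shape is not an exact multiple of ``out_shape`` the movie
    is padded by edge replication (with a warning) before averaging.
    Binning uses the mean, not the sum, so ΔF/F₀ is unchanged by binning.
    """
    single = movie.ndim == 2
    m = movie[None] if single else movie
    _, h, w = m.shape
    oh, ow = out_shape
    if oh > h or ow > w:
        raise ValueError("out_shape must not exceed the input frame size")
    if h % oh or w % ow:
        ph, pw = (-h) % oh, (-w) % ow
        warnings.warn(
            f"frame size ({h}x{w}) not divisible by {oh}x{ow}; padding by "
            f"edge replication ({ph}, {pw})", stacklevel=2)
        m = np.pad(m, ((0, 0), (0, ph), (0, pw)), mode="edge")
        h, w = m.shape[1:]
    bh, bw = h // oh, w // ow
    out = m.reshape(m.shape[0], oh, bh, ow, bw).mean(axis=(2, 4))
    return out[0] if single else out


@dataclass
class NeuropilCorrection:
    """Result of field-level neuropil decontamination."""

    slopes: np.ndarray          # per-ROI contamination slope (NaN if unfit)
    r: float                    # field contamination factor (median slope)
    corrected: np.ndarray       # (n_roi, n_frames) F = F_roi - r * F_neuropil
    included: np.ndarray        # (n_roi, n_frames) bool, timepoints in the fit
    roi_ok: np.ndarray          # per-ROI bool, contributed to the median
    flags: list[str] = field(default_factory=list)


def _irls_slope(y: np.ndarray, x: np.ndarray) -> float:
    """Bisquare-weighted IRLS regression slope of y on x (with intercept)."""
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=50, tol=1e-8)
    return float(res.params[1])


def neuropil_correct(
    f_roi: np.ndarray,
    f_neuropil: np.ndarray,
    min_points: int = 30,
) -> NeuropilCorrection:
    """Estimate the field contamination factor and decontaminate each ROI.

    Parameters are (n_roi, n_frames) arrays of the recorded ROI and
    surrounding-neuropil fluorescence of one imaging field.  Timepoints
    where ``f_roi`` exceeds its time-mean plus 1 SD are excluded from each
    ROI's regression; ROIs with fewer than ``min_points`` remaining
    timepoints, or with zero-variance neuropil, do not contribute to the
    field median.
    """
    f_roi = np.atleast_2d(np.asarray(f_roi, dtype=float))
    f_neuropil = np.atleast_2d(np.asarray(f_neuropil, dtype=float))
    if f_roi.shape != f_neuropil.shape:
        raise ValueError("f_roi and f_neuropil must have equal shape")
    n_roi, _ = f_roi.shape
    slopes = np.full(n_roi, np.nan)
    roi_ok = np.zeros(n_roi, dtype=bool)
    included = np.zeros_like(f_roi, dtype=bool)
    flags: list[str] = []
    for i in range(n_roi):
        y = f_roi[i]
        x = f_neuropil[i]
        mask = y <= y.mean() + y.std()
        included[i] = mask
        if mask.sum() < min_points:
            flags.append(f"roi {i}: only {int(mask.sum())} timepoints after "
                         "exclusion; dropped from field median")
            warnings.warn(flags[-1], stacklevel=2)
            continue
        if np.ptp(x[mask]) == 0:
            slopes[i] = 0.0
            flags.append(f"roi {i}: zero-variance neuropil; slope set to 0")
            continue
        slopes[i] = _irls_slope(y[mask], x[mask])
        roi_ok[i] = True
    usable = slopes[roi_ok] if roi_ok.any() else slopes[np.isfinite(slopes)]
    if usable.size == 0:
        raise ValueError("no ROI produced a usable contamination slope")
    r = float(np.median(usable))
    corrected = f_roi - r * f_neuropil
    return NeuropilCorrection(slopes=slopes, r=r, corrected=corrected,
                              included=included, roi_ok=roi_ok, flags=flags)


def compute_dff(
    trace: np.ndarray,
    onset_frame: int,
    baseline_frames: int,
    response_frames: int,
) -> tuple[np.ndarray, float, float]:
    """Single-trial ΔF/F₀ row and the (F, F₀) summary pair.

    The row spans ``[onset - baseline_frames, onset + response_frames)``;
    F₀ is the mean over the baseline span, F the mean raw fluorescence over
    the response span.  Raises if F₀ is not positive (the caller excludes
    such trials).
    """
    trace = np.asarray(trace, dtype=float)
    lo = onset_frame - baseline_frames
    hi = onset_frame + response_frames
    if lo < 0 or hi > trace.size:
        raise ValueError("baseline/response window outside the trace")
    f0 = float(trace[lo:onset_frame].mean())
    if f0 <= 0:
        raise ValueError("non-positive baseline F0")
    f = float(trace[onset_frame:hi].mean())
    row = (trace[lo:hi] - f0) / f0
    return row, f, f0


@dataclass
class TrialAlignedResponses:
    """Trials x frames ΔF/F₀ aligned to tone onset (frame offset 0 = onset).

    ``metadata`` has one row per trial: role, duration_ms, frequency_hz,
    prev_duration_ms (NaN for the first trial of a session), onset_s,
    block_position and event_index into the source schedule.
    """

    values: np.ndarray              # (n_trials, n_frames) ΔF/F₀
    frame_offsets: np.ndarray       # frames relative to onset
    frame_rate: float
    metadata: pd.DataFrame
    baseline_frames: int
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.shape[0] != len(self.metadata):
            raise ValueError("metadata must have one row per trial")
        if self.frame_offsets[0] > -1:
            raise ValueError("baseline window must precede frame 0")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Frame start times in ms relative to tone onset."""
        return self.frame_offsets * 1000.0 / self.frame_rate

    def post_onset(self) -> np.ndarray:
        """Columns from tone onset onward."""
        return self.values[:, self.frame_offsets >= 0]

    def select(self, mask) -> "TrialAlignedResponses":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return TrialAlignedResponses(
            values=self.values[idx],
            frame_offsets=self.frame_offsets,
            frame_rate=self.frame_rate,
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
            baseline_frames=self.baseline_frames,
            qc=dict(self.qc),
        )

    def mean_timecourse(self) -> np.ndarray:
        return self.values.mean(axis=0)


def align_trials(
    trace: np.ndarray,
    schedule: StimulusSchedule,
    frame_rate: float = 30.0,
    baseline_frames: int = 5,
    response_frames: int = 15,
    post_frames: int | None = None,
) -> TrialAlignedResponses:
    """Cut one fluorescence trace into per-trial ΔF/F₀ rows.

    Each tone onset is snapped to the nearest acquisition frame (alignment
    error at most half a frame period).  Trials whose window is truncated
    by the recording edges, or whose baseline F₀ is not positive, are
    dropped and counted in ``qc``.  ``post_frames`` (default
    ``response_frames``) sets the length of the stored post-onset span;
    ``response_frames`` is kept in ``qc['response_frames']`` for summary
    windows.
    """
    trace = np.asarray(trace, dtype=float)
    post = int(post_frames) if post_frames is not None else int(response_frames)
    offsets = np.arange(-baseline_frames, post)
    rows, meta = [], []
    n_trunc = n_badf0 = 0
    prev_dur = np.nan
    for j, ev in enumerate(schedule.events):
        onset_frame = int(round(ev.onset_s * frame_rate))
        lo, hi = onset_frame - baseline_frames, onset_frame + post
        if lo < 0 or hi > trace.size:
            n_trunc += 1
            prev_dur = ev.duration_ms
            continue
        f0 = trace[lo:onset_frame].mean()
        if f0 <= 0:
            n_badf0 += 1
            prev_dur = ev.duration_ms
            continue
        rows.append((trace[lo:hi] - f0) / f0)
        meta.append(
            dict(role=ev.role, duration_ms=ev.duration_ms,
                 frequency_hz=ev.frequency_hz, prev_duration_ms=prev_dur,
                 onset_s=ev.onset_s, photostim=ev.photostim,
                 block_position=ev.block_position, event_index=j)
        )
        prev_dur = ev.duration_ms
    if n_trunc:
        warnings.warn(f"{n_trunc} trials dropped (window outside recording)",
                      stacklevel=2)
    values = (np.array(rows) if rows
              else np.empty((0, baseline_frames + post)))
    return TrialAlignedResponses(
        values=values,
        frame_offsets=offsets,
        frame_rate=frame_rate,
        metadata=pd.DataFrame(
            meta, columns=["role", "duration_ms", "frequency_hz",
                           "prev_duration_ms", "onset_s", "photostim",
                           "block_position", "event_index"]),
        baseline_frames=baseline_frames,
        qc={"n_truncated": n_trunc, "n_bad_f0": n_badf0,
            "response_frames": int(response_frames)},
    )


def align_movie_trials(
    movie: np.ndarray,
    schedule: StimulusSchedule,
    frame_rate: float = 30.0,
    baseline_frames: int = 5,
    response_frames: int = 15,
    post_frames: int | None = None,
) -> tuple[np.ndarray, TrialAlignedResponses]:
    """Trial-align every pixel of a movie (frames, H, W).

    Returns ``(stack, template)`` where ``stack`` is
    (n_trials, n_frames, H, W) ΔF/F₀ and ``template`` is the aligned mean
    pixel trace carrying the shared metadata/offsets.
    """
    movie = np.asarray(movie, dtype=float)
    mean_trace = movie.mean(axis=(1, 2))
    template = align_trials(mean_trace, schedule, frame_rate,
                            baseline_frames, response_frames, post_frames)
    post = int(post_frames) if post_frames is not None else int(response_frames)
    stacks = []
    for j in template.metadata["event_index"]:
        ev = schedule.events[int(j)]
        onset_frame = int(round(ev.onset_s * frame_rate))
        lo, hi = onset_frame - baseline_frames, onset_frame + post
        seg = movie[lo:hi]
        f0 = seg[:baseline_frames].mean(axis=0)
        f0 = np.where(f0 > 0, f0, np.nan)
        stacks.append((seg - f0) / f0)
    stack = (np.array(stacks) if stacks
             else np.empty((0, baseline_frames + post) + movie.shape[1:]))
    return stack, template
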