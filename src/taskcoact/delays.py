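"""Stimulus-to-BOLD peak delays with sub-TR parabolic refinement.

For every source event the reference time is the (parabolically refined)
peak of the stimulus series inside the event window — i.e. the modelled
HRF peak of that stimulus.  Candidate BOLD peaks are the local maxima of
the ROI column, irrespective of size, whose integer index lies within a
forward search window (default [0, 9] TRs) of the rounded reference; the
candidate closest in refined time is chosen and the signed difference is
the delay.  Parabolic refinement at window edges can push values slightly
outside the search window, so refined delays are kept on a wider range
(default [-1, 10] TRs) and anything outside is marked invalid rather than
silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .coactivation import SourceEvent
from .errors import ParameterError
from .preprocess import ROITimeSeries
from .stimulus import StimulusSeries

log = logging.getLogger(__name__)

__all__ = [
    "find_local_peaks",
    "parabolic_refine",
    "compute_delays",
    "delay_histogram",
]


def find_local_peaks(series) -> list[int]:
    """Indices of strict local maxima; flat plateaus that stand above both
    flanks contribute their midpoint (rounded down).  Endpoints are never
    peaks.  Series shorter than 3 samples have none."""
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 3:
        return []
    peaks: list[int] = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            # plateau i..j (possibly a single sample); a peak iff it drops after
            if j < n - 1 and y[j + 1] < y[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def parabolic_refine(
    y_minus: float, y_0: float, y_plus: float, t0: float
) -> tuple[float, float]:
    """Vertex of the parabola through three consecutive unit-spaced samples.

    Returns ``(refined_time, refined_amplitude)``.  The offset is
    delta = (y_minus - y_plus) / (2 (y_minus - 2 y_0 + y_plus)); collinear
    samples (zero denominator) give delta = 0.
    """
    denom = y_minus - 2.0 * y_0 + y_plus
    if denom == 0.0:
        return float(t0), float(y_0)
    delta = (y_minus - y_plus) / (2.0 * denom)
    amp = y_0 - 0.25 * (y_minus - y_plus) * delta
    return float(t0 + delta), float(amp)


def _refine_index(y: np.ndarray, k: int) -> tuple[float, float]:
    """Parabolic refinement of index k, falling back to no shift at edges."""
    if 0 < k < y.size - 1:
        return parabolic_refine(y[k - 1], y[k], y[k + 1], float(k))
    return float(k), float(y[k])


def compute_delays(
    stimulus: StimulusSeries,
    bold: ROITimeSeries,
    events: list[SourceEvent],
    search: tuple[int, int] = (0, 9),
    keep: tuple[float, float] = (-1.0, 10.0),
    rois: list[str] | None = None,
    anchor: str = "crossing",
) -> pd.DataFrame:
    """Delay records for every (event, ROI) pair, in TR units.

    The delay itself is always peak-to-peak: refined BOLD peak time minus
    the refined stimulus-series peak inside the event window (the
    modelled HRF peak).  ``anchor`` chooses where the forward search
    window opens: ``"crossing"`` (default) at the source event's
    threshold crossing — the event's time stamp, so the window covers
    0-9 TRs after the stimulus event; ``"peak"`` at the refined stimulus
    peak; ``"onset"`` at the attributed trial's onset (falls back to the
    peak when no trial is attached).
    """
    if bold.n_volumes != stimulus.n_volumes:
        raise ParameterError(
            f"BOLD run length {bold.n_volumes} does not match stimulus "
            f"series length {stimulus.n_volumes}"
        )
    if anchor not in ("crossing", "peak", "onset"):
        raise ParameterError(f"unknown anchor {anchor!r}")
    rois = rois if rois is not None else list(bold.roi_labels)
    sv = stimulus.values
    records = []
    for roi in rois:
        col = bold.column(roi)
        peak_idx = find_local_peaks(col)
        refined = [_refine_index(col, k) for k in peak_idx]
        refined_times = np.array([t for t, _ in refined]) if refined else np.empty(0)
        peak_arr = np.asarray(peak_idx)
        for ev in events:
            w = ev.window
            k_max = int(w[np.argmax(sv[w])])
            stim_time, _ = _refine_index(sv, k_max)
            ev.refined_peak_time = stim_time
            ref = stim_time
            if anchor == "crossing":
                window_anchor = float(ev.crossing_index)
            elif anchor == "onset" and ev.trial_onset_tr is not None:
                window_anchor = ev.trial_onset_tr
            else:
                window_anchor = ref
            lo = int(round(window_anchor)) + search[0]
            hi = int(round(window_anchor)) + search[1]
            cand = np.flatnonzero((peak_arr >= lo) & (peak_arr <= hi))
            base = {
                "subject": bold.subject,
                "session": bold.session,
                "task": bold.task,
                "phase": ev.phase,
                "probe": ev.probe,
                "response": ev.response,
                "roi": roi,
                "trial_id": ev.trial_id,
                "stimulus_peak_time": ref,
            }
            if cand.size == 0:
                records.append(
                    {**base, "bold_peak_time": np.nan, "delay": np.nan,
                     "valid": False, "reason": "no-peak-in-window"}
                )
                continue
            diffs = np.abs(refined_times[cand] - ref)
            # ties broken toward the earlier peak: stable argmin over sorted cand
            best = cand[np.argmin(diffs)]
            bold_time = refined_times[best]
            delay = bold_time - ref
            ok = keep[0] <= delay <= keep[1]
            records.append(
                {**base, "bold_peak_time": bold_time, "delay": delay,
                 "valid": bool(ok),
                 "reason": "" if ok else "outside-keep-range"}
            )
    return pd.DataFrame(records)


def delay_histogram(
    records: pd.DataFrame,
    group_keys: list[str] | tuple[str, ...] = (),
    bin_width: float = 0.5,
    value_range: tuple[float, float] = (-1.0, 10.0),
    smooth_window: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of valid delays per group, plus mode locations.

    Returns ``(histogram, modes)``: the histogram has one row per
    (group, bin) with ``bin_left`` and ``count`` (and the group's invalid
    count replicated in ``n_invalid``); the modes table lists the bin
    centres of local maxima of the moving-average-smoothed counts.
    """
    group_keys = list(group_keys)
    edges = np.arange(value_range[0], value_range[1] + bin_width / 2, bin_width)
    valid = records[records["valid"]]
    if valid.empty:
        warnings.warn("no valid delay records; empty histogram")
        return (
            pd.DataFrame(columns=group_keys + ["bin_left", "count", "n_invalid"]),
            pd.DataFrame(columns=group_keys + ["mode"]),
        )
    groups = (
        valid.groupby(group_keys, observed=True)
        if group_keys
        else [((), valid)]
    )
    hist_rows, mode_rows = [], []
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        counts, _ = np.histogram(sub["delay"], bins=edges)
        if group_keys:
            sel = records
            for k, v in zip(group_keys, key):
                sel = sel[sel[k] == v]
            n_invalid = int((~sel["valid"]).sum())
        else:
            n_invalid = int((~records["valid"]).sum())
        for left, c in zip(edges[:-1], counts):
            row = dict(zip(group_keys, key))
            row.update(bin_left=float(left), count=int(c), n_invalid=n_invalid)
            hist_rows.append(row)
        kernel = np.ones(smooth_window) / smooth_window
        smooth = np.convolve(counts, kernel, mode="same")
        for m in find_local_peaks(np.concatenate([[-np.inf], smooth, [-np.inf]])):
            row = dict(zip(group_keys, key))
            row.update(mode=float(edges[m - 1] + bin_width / 2))
            mode_rows.append(row)
    return pd.DataFrame(hist_rows), pd.DataFrame(mode_rows)


def write_delays(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)
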