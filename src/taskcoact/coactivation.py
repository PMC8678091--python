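"""Source events, target events, and event correlations.

The stimulus series plays the role of the "source" signal: every upward
crossing of a z-threshold (default 1) opens a 5-volume event window,
including the crossing itself, wide enough to span the HRF's positive
peak.  "Target" events are the ROI BOLD values at exactly the same
volumes.  The per-event Pearson correlation of the two 5-sample segments,
averaged within experimental condition and Fisher-transformed, is the
co-activation measure fed to the response model.  The thresholding is the
non-linear step: only the large-amplitude portions of the source signal
contribute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import ROITimeSeries
from .schedule import TrialSchedule
from .stimulus import StimulusSeries

log = logging.getLogger(__name__)

__all__ = [
    "SourceEvent",
    "detect_source_events",
    "extract_target_events",
    "event_correlation",
    "correlate_events",
    "aggregate_cells",
    "fisher_z",
]

#: |mean r| is clamped below 1 by this margin before atanh so that 5-point
#: correlations hitting exactly +/-1 stay finite after the transform.
FISHER_CLAMP = 1e-7

#: events whose nearest preceding same-phase trial is further away than
#: this (seconds) are flagged as implausibly attributed.
MAX_ATTRIBUTION_GAP_S = 12.0


@dataclass
class SourceEvent:
    """One supra-threshold excursion of the stimulus series."""

    crossing_index: int
    segment: np.ndarray  # the 5 stimulus z-values
    trial_id: int | None = None
    phase: str = "encoding"
    probe: str = "n/a"
    response: str = "none"
    trial_onset_tr: float | None = None  # attributed trial onset, TR units
    refined_peak_time: float | None = None  # TR units, filled by delays

    @property
    def window(self) -> np.ndarray:
        return self.crossing_index + np.arange(len(self.segment))


def detect_source_events(
    series: StimulusSeries,
    schedule: TrialSchedule | None = None,
    threshold: float = 1.0,
    window_len: int = 5,
) -> list[SourceEvent]:
    """Find upward threshold crossings and open event windows.

    A crossing is an index k with value[k] > threshold and
    value[k-1] <= threshold (k = 0 qualifies when the series starts above
    threshold), so a sustained plateau yields a single event.  Windows
    that would run past the end of the run are discarded (logged).  When a
    schedule is given, each event inherits the labels of the most recent
    same-phase trial whose onset is at or before the crossing time; an
    encoding event additionally takes the probe type and response of its
    block's probe (the first retrieval trial after the memory set), since
    condition cells are keyed by probe and response in both phases.
    """
    v = series.values
    n = v.size
    above = v > threshold
    crossings = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))

    trials = schedule.phase_trials(series.phase) if schedule is not None else []
    onsets_s = np.array([t.onset_ms / 1000.0 for t in trials])
    retrieval = schedule.phase_trials("retrieval") if schedule is not None else []
    retrieval_onsets = np.array([t.onset_ms for t in retrieval])

    events: list[SourceEvent] = []
    n_discarded = 0
    for k in crossings:
        if k + window_len > n:
            n_discarded += 1
            continue
        ev = SourceEvent(
            crossing_index=int(k),
            segment=v[k : k + window_len].copy(),
            phase=series.phase,
        )
        if trials:
            t_cross = k * series.tr_s
            prior = np.flatnonzero(onsets_s <= t_cross)
            if prior.size:
                trial = trials[prior[-1]]
                if t_cross - onsets_s[prior[-1]] > MAX_ATTRIBUTION_GAP_S:
                    warnings.warn(
                        f"event at volume {k} is {t_cross - onsets_s[prior[-1]]:.1f} s "
                        "after the nearest preceding trial; attribution doubtful"
                    )
                ev.trial_id = trial.trial_id
                ev.probe = trial.probe
                ev.response = trial.response
                ev.trial_onset_tr = trial.onset_ms / 1000.0 / series.tr_s
                if trial.phase == "encoding" and len(retrieval):
                    nxt = np.flatnonzero(retrieval_onsets > trial.onset_ms)
                    if nxt.size:
                        probe_trial = retrieval[nxt[0]]
                        ev.probe = probe_trial.probe
                        ev.response = probe_trial.response
            else:
                warnings.warn(
                    f"event at volume {k} precedes every {series.phase} trial; "
                    "left unattributed"
                )
        events.append(ev)
    if n_discarded:
        log.info(
            "%d event(s) discarded: %d-TR window exceeds run end", n_discarded,
            window_len,
        )
    return events


def extract_target_events(
    bold: ROITimeSeries, events: list[SourceEvent], roi: str
) -> list[np.ndarray]:
    """BOLD segments of one ROI at exactly the source-event windows."""
    col = bold.column(roi)  # raises KeyError for an unknown label
    out = []
    for ev in events:
        w = ev.window
        if w[-1] >= col.size:
            raise ParameterError(
                f"event window {w[0]}..{w[-1]} exceeds BOLD run length {col.size}"
            )
        out.append(col[w])
    return out


def event_correlation(source_segment, target_segment) -> float:
    """Pearson correlation of two equal-length segments.

    Returns NaN (to be excluded from averaging) when either segment has
    zero variance; a 5-sample segment of constant BOLD carries no signal.
    """
    s = np.asarray(source_segment, dtype=float)
    t = np.asarray(target_segment, dtype=float)
    if s.shape != t.shape:
        raise ParameterError(
            f"segment length mismatch: {s.shape} vs {t.shape}"
        )
    if s.std() == 0.0 or t.std() == 0.0:
        log.info("zero-variance segment; correlation recorded as missing")
        return float("nan")
    return float(np.corrcoef(s, t)[0, 1])


def correlate_events(
    series: StimulusSeries,
    bold: ROITimeSeries,
    events: list[SourceEvent],
    rois: list[str] | None = None,
) -> pd.DataFrame:
    """Per-event, per-ROI correlations in long format.

    One row per (event, ROI) with the full condition key.  This is the
    raw material for :func:`aggregate_cells`.
    """
    rois = rois if rois is not None else list(bold.roi_labels)
    rows = []
    for roi in rois:
        targets = extract_target_events(bold, events, roi)
        for ev, tgt in zip(events, targets):
            rows.append(
                {
                    "subject": bold.subject,
                    "session": bold.session,
                    "task": bold.task,
                    "phase": ev.phase,
                    "probe": ev.probe,
                    "response": ev.response,
                    "roi": roi,
                    "trial_id": ev.trial_id,
                    "crossing_index": ev.crossing_index,
                    "r": event_correlation(ev.segment, tgt),
                }
            )
    return pd.DataFrame(rows)


def fisher_z(r, clamp: float = FISHER_CLAMP):
    """atanh with |r| clamped to 1 - clamp so the transform stays finite."""
    r = np.clip(np.asarray(r, dtype=float), -1.0 + clamp, 1.0 - clamp)
    return np.arctanh(r)


CELL_KEYS = ["subject", "session", "task", "phase", "probe", "response", "roi"]


def aggregate_cells(event_correlations: pd.DataFrame) -> pd.DataFrame:
    """Average per-event correlations into condition cells.

    Cells are keyed by (subject, session, task, phase, probe, response,
    ROI).  Missing correlations (zero-variance segments) are excluded and
    ``n_events`` counts only the included ones; the Fisher transform is
    applied to the cell mean.
    """
    df = event_correlations.dropna(subset=["r"])
    n_dropped = len(event_correlations) - len(df)
    if n_dropped:
        log.info("%d degenerate event correlation(s) excluded", n_dropped)
    grouped = (
        df.groupby(CELL_KEYS, observed=True)["r"]
        .agg(mean_r="mean", n_events="count")
        .reset_index()
    )
    grouped["fisher_z"] = fisher_z(grouped["mean_r"].to_numpy())
    return grouped[CELL_KEYS + ["n_events", "mean_r", "fisher_z"]]


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
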