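"""Synthetic "source" time series from stimulus timings.

For one phase (encoding = memory sets, retrieval = probes) the trial
presentations are turned into a 1 kHz indicator train (a boxcar covering
each presentation, or optionally a single impulse at onset), convolved
with the canonical HRF, point-sampled at the volume acquisition times
t = k * TR, and z-scored over the full run.  The result is the source
signal whose supra-threshold excursions define the events used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .errors import DegenerateSeriesError, EmptyPhaseError, ParameterError
from .hrf import HRFParams, canonical_hrf
from .schedule import TrialSchedule

__all__ = ["StimulusSeries", "build_stimulus_series"]


@dataclass
class StimulusSeries:
    """Z-scored stimulus convolution sampled once per volume."""

    values: np.ndarray
    tr_s: float
    phase: str
    onsets_used: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("stimulus series must be one-dimensional")

    @property
    def n_volumes(self) -> int:
        return self.values.size

    def to_tsv(self, path: str | Path) -> None:
        idx = np.arange(self.n_volumes)
        pd.DataFrame(
            {"volume_index": idx, "time_s": idx * self.tr_s, "z_value": self.values}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, phase: str = "encoding") -> "StimulusSeries":
        df = pd.read_csv(path, sep="\t")
        t = df["time_s"].to_numpy()
        tr = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(values=df["z_value"].to_numpy(), tr_s=tr, phase=phase)


def build_stimulus_series(
    schedule: TrialSchedule,
    phase: str,
    hrf_params: HRFParams | None = None,
    stimulus_shape: str = "boxcar",
) -> StimulusSeries:
    """Build the z-scored source series for one phase of one run.

    Parameters
    ----------
    schedule
        The run's trial timeline (times in ms).
    phase
        ``"encoding"`` or ``"retrieval"``; mask trials never enter either
        series.
    stimulus_shape
        ``"boxcar"`` marks the indicator 1 for the full stimulus duration;
        ``"impulse"`` places a single 1 ms pulse at onset.
    """
    if stimulus_shape not in ("boxcar", "impulse"):
        raise ParameterError(f"unknown stimulus_shape {stimulus_shape!r}")
    trials = schedule.phase_trials(phase)
    if not trials:
        raise EmptyPhaseError(f"schedule has no trials of phase {phase!r}")

    hrf_params = hrf_params or HRFParams()
    dt_ms = hrf_params.dt * 1000.0
    n_hi = int(round(schedule.run_duration_ms / dt_ms))
    train = np.zeros(n_hi)
    for t in trials:
        start = int(round(t.onset_ms / dt_ms))
        if stimulus_shape == "impulse":
            stop = start + 1
        else:
            stop = int(round((t.onset_ms + t.duration_ms) / dt_ms))
        train[start : max(stop, start + 1)] = 1.0

    kernel = canonical_hrf(hrf_params)
    conv = fftconvolve(train, kernel)[:n_hi]

    vol_idx = np.round(np.arange(schedule.n_volumes) * schedule.tr_ms / dt_ms)
    sampled = conv[vol_idx.astype(int)]

    sd = sampled.std()  # population (ddof=0) by convention
    if sd < 1e-12:
        raise DegenerateSeriesError(
            f"convolved series for phase {phase!r} has zero variance"
        )
    z = (sampled - sampled.mean()) / sd
    return StimulusSeries(
        values=z,
        tr_s=schedule.tr_ms / 1000.0,
        phase=phase,
        onsets_used=[t.trial_id for t in trials],
    )
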