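"""Trial schedules: the experiment timeline of one fMRI run.

A run presents a sequence of memory sets (encoding phase), masks, and
probes (retrieval phase).  Probes are positive (seen in the preceding
set), lures (perceptually similar but new) or negative (clearly new), and
each elicits a yes/no recognition response.  Times are kept in
milliseconds internally; the on-disk events table is BIDS-style with
onsets and durations in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParameterError

__all__ = ["Trial", "TrialSchedule"]

PHASES = ("encoding", "retrieval", "mask")
PROBES = ("positive", "lure", "negative", "n/a")
RESPONSES = ("yes", "no", "none")

# BIDS trial_type labels <-> (phase, probe)
_TRIAL_TYPE = {
    ("encoding", "n/a"): "memory_set",
    ("mask", "n/a"): "mask",
    ("retrieval", "positive"): "probe_positive",
    ("retrieval", "lure"): "probe_lure",
    ("retrieval", "negative"): "probe_negative",
}
_FROM_TRIAL_TYPE = {v: k for k, v in _TRIAL_TYPE.items()}


@dataclass(frozen=True)
class Trial:
    trial_id: int
    onset_ms: float
    duration_ms: float
    phase: str
    probe: str = "n/a"
    response: str = "none"
    reaction_time_ms: float | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ParameterError(f"unknown phase {self.phase!r}")
        if self.probe not in PROBES:
            raise ParameterError(f"unknown probe {self.probe!r}")
        if self.response not in RESPONSES:
            raise ParameterError(f"unknown response {self.response!r}")
        if self.phase == "encoding" and self.probe != "n/a":
            raise ParameterError("encoding trials must have probe 'n/a'")
        if self.phase == "retrieval" and self.probe == "n/a":
            raise ParameterError("retrieval trials must carry a probe type")


@dataclass
class TrialSchedule:
    """All trials of one run plus the run metadata needed downstream."""

    trials: list[Trial]
    subject: str = "sub-01"
    session: str = "morning"
    task: str = "global"
    n_volumes: int = 709
    tr_ms: float = 1800.0

    def __post_init__(self) -> None:
        if self.tr_ms <= 0 or self.n_volumes <= 0:
            raise ParameterError("n_volumes and tr_ms must be positive")
        run_ms = self.n_volumes * self.tr_ms
        last = -float("inf")
        for t in self.trials:
            if t.onset_ms <= last:
                raise ParameterError("trial onsets must be strictly increasing")
            last = t.onset_ms
            if t.onset_ms + t.duration_ms > run_ms:
                raise ParameterError(
                    f"trial {t.trial_id} extends past the end of the run"
                )

    @property
    def run_duration_ms(self) -> float:
        return self.n_volumes * self.tr_ms

    def phase_trials(self, phase: str) -> list[Trial]:
        return [t for t in self.trials if t.phase == phase]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trial_id": t.trial_id,
                "onset_ms": t.onset_ms,
                "duration_ms": t.duration_ms,
                "phase": t.phase,
                "probe": t.probe,
                "response": t.response,
                "reaction_time_ms": t.reaction_time_ms,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    # BIDS-style events TSV (seconds on disk) + JSON sidecar for metadata
    # ------------------------------------------------------------------
    def to_events_tsv(self, path: str | Path) -> None:
        path = Path(path)
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "onset": t.onset_ms / 1000.0,
                    "duration": t.duration_ms / 1000.0,
                    "trial_type": _TRIAL_TYPE[(t.phase, t.probe)],
                    "response": t.response,
                    "response_time": (
                        "n/a"
                        if t.reaction_time_ms is None
                        else t.reaction_time_ms / 1000.0
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        sidecar = {
            "subject": self.subject,
            "session": self.session,
            "task": self.task,
            "n_volumes": self.n_volumes,
            "tr_ms": self.tr_ms,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_events_tsv(cls, path: str | Path, **metadata) -> "TrialSchedule":
        """Read a BIDS-style events TSV; run metadata comes from the JSON
        sidecar next to it, overridable through keyword arguments."""
        path = Path(path)
        meta: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta.update(json.loads(sidecar.read_text()))
        meta.update(metadata)
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
        trials = []
        for i, row in df.iterrows():
            phase, probe = _FROM_TRIAL_TYPE[row["trial_type"]]
            rt = row.get("response_time")
            trials.append(
                Trial(
                    trial_id=int(i),
                    onset_ms=float(row["onset"]) * 1000.0,
                    duration_ms=float(row["duration"]) * 1000.0,
                    phase=phase,
                    probe=probe,
                    response=(
                        "none" if pd.isna(row.get("response")) else str(row["response"])
                    ),
                    reaction_time_ms=None if pd.isna(rt) else float(rt) * 1000.0,
                )
            )
        return cls(trials=trials, **meta)

    def with_metadata(self, **kwargs) -> "TrialSchedule":
        return TrialSchedule(
            trials=list(self.trials),
            subject=kwargs.get("subject", self.subject),
            session=kwargs.get("session", self.session),
            task=kwargs.get("task", self.task),
            n_volumes=kwargs.get("n_volumes", self.n_volumes),
            tr_ms=kwargs.get("tr_ms", self.tr_ms),
        )
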