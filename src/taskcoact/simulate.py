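"""Synthetic study generator with known ground truth.

Emulates the experimental design end to end — trial schedules with the
study's counts and timings, ROI BOLD runs produced by a forward model
(amplitude-scaled, optionally time-shifted HRF responses plus AR(1) noise
and slow drift), scripted nuisance series, and responses sampled from a
known logistic model — so every pipeline stage can be tested against the
parameters that generated its input.

Design constants (the defaults of :class:`DesignSpec`): 60 memory sets of
1,800 ms; 25 positive, 25 lure and 10 negative probes of 2,000 ms; a
1,000 ms set-to-mask gap; mask-to-probe delays of 2,000-16,000 ms with
mean 6,097 ms (drawn from a truncated exponential whose rate is solved
numerically, since the stated mean sits well below the range midpoint);
709 volumes at TR = 1,800 ms; 90 ROIs.  The mask duration and the
post-probe inter-trial interval are not part of the published timing, so
the generator uses a 500 ms mask and solves the intervals to fill the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import fftconvolve, lfilter
from scipy.special import expit

from .errors import GenerationError, ParameterError
from .hrf import HRFParams, canonical_hrf
from .preprocess import NuisanceSet, ROITimeSeries
from .schedule import Trial, TrialSchedule

__all__ = [
    "DesignSpec",
    "GroundTruth",
    "mask_probe_rate",
    "sample_mask_probe_delays",
    "generate_schedule",
    "generate_bold",
    "generate_responses",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class DesignSpec:
    """Timing and counts of one run of the memory task."""

    n_memory_sets: int = 60
    n_positive: int = 25
    n_lure: int = 25
    n_negative: int = 10
    memory_set_ms: float = 1800.0
    probe_ms: float = 2000.0
    set_mask_gap_ms: float = 1000.0
    mask_ms: float = 500.0
    mask_probe_min_ms: float = 2000.0
    mask_probe_max_ms: float = 16000.0
    mask_probe_mean_ms: float = 6097.0
    n_volumes: int = 709
    tr_ms: float = 1800.0
    n_rois: int = 90
    min_iti_ms: float = 2000.0
    lead_in_ms: float = 3600.0
    tail_margin_ms: float = 18000.0
    # behavioral accuracy and RT (mean, SD in ms) defaults per category
    hit_rate: float = 0.82
    lure_cr_rate: float = 0.74
    neg_cr_rate: float = 0.98
    rt_params: dict = field(
        default_factory=lambda: {
            ("positive", "yes"): (1277.0, 226.0),
            ("positive", "no"): (1452.0, 380.0),
            ("lure", "no"): (1295.0, 201.0),
            ("lure", "yes"): (1392.0, 419.0),
            ("negative", "no"): (992.0, 161.0),
            ("negative", "yes"): (1350.0, 264.0),
        }
    )

    def validate(self) -> None:
        if self.n_memory_sets != self.n_positive + self.n_lure + self.n_negative:
            raise ParameterError(
                "probe counts must sum to the number of memory sets"
            )
        if not (
            self.mask_probe_min_ms
            < self.mask_probe_mean_ms
            < self.mask_probe_max_ms
        ):
            raise ParameterError("mask-to-probe mean must lie inside its range")
        if self.n_volumes <= 0 or self.tr_ms <= 0:
            raise ParameterError("n_volumes and tr_ms must be positive")

    @property
    def run_ms(self) -> float:
        return self.n_volumes * self.tr_ms

    @property
    def roi_labels(self) -> list[str]:
        return [f"roi_{j:03d}" for j in range(1, self.n_rois + 1)]


def mask_probe_rate(spec: DesignSpec) -> float:
    """Rate of the truncated exponential on [min, max] whose mean equals
    the design's stated mask-to-probe average."""
    a, b, m = spec.mask_probe_min_ms, spec.mask_probe_max_ms, spec.mask_probe_mean_ms

    def mean_at(lam: float) -> float:
        span = b - a
        return a + 1.0 / lam - span * np.exp(-lam * span) / (1.0 - np.exp(-lam * span))

    return brentq(lambda lam: mean_at(lam) - m, 1e-8, 1.0)


def sample_mask_probe_delays(
    spec: DesignSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draws from the truncated exponential delay law."""
    lam = mask_probe_rate(spec)
    a, b = spec.mask_probe_min_ms, spec.mask_probe_max_ms
    u = rng.random(n)
    return a - np.log1p(-u * (1.0 - np.exp(-lam * (b - a)))) / lam


def _sample_response(
    probe: str, spec: DesignSpec, rng: np.random.Generator
) -> tuple[str, float]:
    correct_answer = "yes" if probe == "positive" else "no"
    p_correct = {
        "positive": spec.hit_rate,
        "lure": spec.lure_cr_rate,
        "negative": spec.neg_cr_rate,
    }[probe]
    response = (
        correct_answer
        if rng.random() < p_correct
        else ("no" if correct_answer == "yes" else "yes")
    )
    mean, sd = spec.rt_params[(probe, response)]
    rt = max(float(rng.normal(mean, sd)), 200.0)
    return response, rt


def generate_schedule(
    spec: DesignSpec | None = None,
    seed: int = 0,
    subject: str = "sub-01",
    session: str = "morning",
    task: str = "global",
    max_retries: int = 20,
) -> TrialSchedule:
    """One run's trial timeline: memory set, mask, probe, repeated with the
    design's counts, delays and jittered inter-trial intervals.

    Probe types are randomly ordered; mask-to-probe delays follow the
    truncated exponential law; post-probe intervals are drawn (Dirichlet
    over the slack time, plus a 2 s floor) so the run exactly fits the
    volume count.  Retries with a fresh permutation when a draw does not
    fit; deterministic for a given seed.
    """
    spec = spec or DesignSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    probe_types = (
        ["positive"] * spec.n_positive
        + ["lure"] * spec.n_lure
        + ["negative"] * spec.n_negative
    )
    n = spec.n_memory_sets
    for _ in range(max_retries):
        order = [probe_types[i] for i in rng.permutation(n)]
        delays = sample_mask_probe_delays(spec, n, rng)
        fixed = (
            spec.memory_set_ms
            + spec.set_mask_gap_ms
            + spec.mask_ms
            + spec.probe_ms
        ) * n + delays.sum()
        slack = (
            spec.run_ms
            - spec.lead_in_ms
            - spec.tail_margin_ms
            - fixed
            - spec.min_iti_ms * n
        )
        if slack < 0:
            continue
        itis = spec.min_iti_ms + slack * rng.dirichlet(np.ones(n))
        trials: list[Trial] = []
        t = spec.lead_in_ms
        tid = 0
        for i in range(n):
            trials.append(
                Trial(tid, t, spec.memory_set_ms, "encoding")
            )
            tid += 1
            t += spec.memory_set_ms + spec.set_mask_gap_ms
            trials.append(Trial(tid, t, spec.mask_ms, "mask"))
            tid += 1
            t += spec.mask_ms + delays[i]
            response, rt = _sample_response(order[i], spec, rng)
            trials.append(
                Trial(
                    tid, t, spec.probe_ms, "retrieval",
                    probe=order[i], response=response, reaction_time_ms=rt,
                )
            )
            tid += 1
            t += spec.probe_ms + itis[i]
        return TrialSchedule(
            trials=trials,
            subject=subject,
            session=session,
            task=task,
            n_volumes=spec.n_volumes,
            tr_ms=spec.tr_ms,
        )
    raise GenerationError(
        f"could not fit the schedule into {spec.n_volumes} volumes after "
        f"{max_retries} retries"
    )


# ----------------------------------------------------------------------
# Ground truth and the BOLD forward model
# ----------------------------------------------------------------------
@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover.

    ``effects`` has one row per (roi, phase, probe, condition) with the
    response amplitude (units of the noise-free response peak) and the
    response shift in TRs.  ``noise_sd`` is the stationary SD of the AR(1)
    noise, so SNR = amplitude / noise_sd at the response peak.
    ``behavior`` maps model terms (tuples over 'corr', 'phase', 'probe',
    'condition', 'roi') to logit coefficients for P(response = "no");
    coefficients of roi-containing terms are mappings roi -> value.
    """

    effects: pd.DataFrame
    ar1: float = 0.3
    noise_sd: float = 0.5
    drift_amplitude: float = 1.0
    behavior: dict = field(default_factory=lambda: {(): 0.0, ("corr",): 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1 < 1.0:
            raise ParameterError("AR(1) coefficient must lie in (-1, 1)")
        needed = {"roi", "phase", "probe", "condition", "amplitude", "shift_tr"}
        if not needed <= set(self.effects.columns):
            raise ParameterError(f"effects table needs columns {sorted(needed)}")
        if not np.all(np.isfinite(self.effects["amplitude"])):
            raise ParameterError("amplitudes must be finite")

    @classmethod
    def constant(
        cls,
        rois: list[str],
        amplitude: float = 1.0,
        shift_tr: float = 0.0,
        amplitudes: dict | None = None,
        shifts: dict | None = None,
        **kwargs,
    ) -> "GroundTruth":
        """Uniform truth over the full factorial, with optional per-ROI
        overrides (``amplitudes`` / ``shifts`` map roi -> value)."""
        rows = []
        for roi in rois:
            for phase, probes in (
                ("encoding", ["n/a"]),
                ("retrieval", ["positive", "lure", "negative"]),
            ):
                for probe in probes:
                    for condition in ("morning", "evening"):
                        rows.append(
                            {
                                "roi": roi,
                                "phase": phase,
                                "probe": probe,
                                "condition": condition,
                                "amplitude": (amplitudes or {}).get(roi, amplitude),
                                "shift_tr": (shifts or {}).get(roi, shift_tr),
                            }
                        )
        return cls(effects=pd.DataFrame(rows), **kwargs)

    def lookup(self, roi: str, phase: str, probe: str, condition: str):
        sub = self.effects[
            (self.effects["roi"] == roi)
            & (self.effects["phase"] == phase)
            & (self.effects["probe"] == probe)
            & (self.effects["condition"] == condition)
        ]
        if sub.empty:
            raise KeyError(
                f"no ground-truth entry for ({roi}, {phase}, {probe}, {condition})"
            )
        row = sub.iloc[0]
        return float(row["amplitude"]), float(row["shift_tr"])


def _group_regressor(
    trials, schedule: TrialSchedule, hrf_params: HRFParams
) -> np.ndarray:
    """Noise-free response of one stimulus group at 1 kHz, peak-normalised."""
    dt_ms = hrf_params.dt * 1000.0
    n_hi = int(round(schedule.run_duration_ms / dt_ms))
    train = np.zeros(n_hi)
    for t in trials:
        a = int(round(t.onset_ms / dt_ms))
        b = int(round((t.onset_ms + t.duration_ms) / dt_ms))
        train[a : max(b, a + 1)] = 1.0
    conv = fftconvolve(train, canonical_hrf(hrf_params))[:n_hi]
    peak = conv.max()
    return conv / peak if peak > 0 else conv


def generate_bold(
    schedule: TrialSchedule,
    truth: GroundTruth,
    hrf_params: HRFParams | None = None,
) -> tuple[ROITimeSeries, NuisanceSet]:
    """Forward-model a run: per ROI the sum over stimulus groups of
    amplitude x shifted HRF response, plus AR(1) noise and a slow drift.

    Returns the BOLD matrix and a nuisance set holding the drift regressor
    and six scripted motion series.
    """
    hrf_params = hrf_params or HRFParams()
    rng = np.random.default_rng(truth.seed)
    condition = schedule.session
    n_vol = schedule.n_volumes
    tr_ms = schedule.tr_ms
    dt_ms = hrf_params.dt * 1000.0

    groups: dict[tuple[str, str], np.ndarray] = {}
    enc = schedule.phase_trials("encoding")
    if enc:
        groups[("encoding", "n/a")] = _group_regressor(enc, schedule, hrf_params)
    for probe in ("positive", "lure", "negative"):
        sub = [t for t in schedule.phase_trials("retrieval") if t.probe == probe]
        if sub:
            groups[("retrieval", probe)] = _group_regressor(sub, schedule, hrf_params)

    vol_t_ms = np.arange(n_vol) * tr_ms
    rois = sorted(truth.effects["roi"].unique())

    def sample_shifted(reg: np.ndarray, shift_tr: float) -> np.ndarray:
        t = vol_t_ms - shift_tr * tr_ms
        idx = np.round(t / dt_ms).astype(int)
        out = np.zeros(n_vol)
        ok = (idx >= 0) & (idx < reg.size)
        out[ok] = reg[idx[ok]]
        return out

    innov_sd = truth.noise_sd * np.sqrt(1.0 - truth.ar1**2)
    ramp = np.linspace(-0.5, 0.5, n_vol)
    cols = []
    for roi in rois:
        col = np.zeros(n_vol)
        for (phase, probe), reg in groups.items():
            amp, shift = truth.lookup(roi, phase, probe, condition)
            if amp != 0.0:
                col = col + amp * sample_shifted(reg, shift)
        if truth.noise_sd > 0:
            noise = lfilter([1.0], [1.0, -truth.ar1], rng.normal(0.0, innov_sd, n_vol))
            col = col + noise
        if truth.drift_amplitude > 0:
            col = col + truth.drift_amplitude * rng.uniform(-1.0, 1.0) * ramp
        cols.append(col)

    t_norm = np.arange(n_vol) / n_vol
    motion = np.column_stack(
        [
            0.05 * np.sin(2 * np.pi * (k + 1) * t_norm + k)
            + np.cumsum(rng.normal(0.0, 0.002, n_vol))
            for k in range(6)
        ]
    )
    nuisance = NuisanceSet(
        values=np.column_stack([ramp, motion]),
        names=["drift"]
        + ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )
    bold = ROITimeSeries(
        values=np.column_stack(cols),
        roi_labels=rois,
        tr_s=tr_ms / 1000.0,
        subject=schedule.subject,
        session=schedule.session,
        task=schedule.task,
        seed=truth.seed,
    )
    return bold, nuisance


# ----------------------------------------------------------------------
# Response simulation from a known logit model
# ----------------------------------------------------------------------
def _factor_code(level: str, levels: list[str]) -> float:
    """+1 for the first (alphabetical) level, -1 for the second."""
    ordered = sorted(levels)
    return 1.0 if level == ordered[0] else -1.0


def generate_responses(
    cells: pd.DataFrame,
    truth: GroundTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample a yes/no response per cell from the truth's logit model.

    P("no") = logistic(sum over terms of coef x code), where 'corr' codes
    as the cell's fisher_z and two-level factors as +/-1 (alphabetical
    first level positive).  Coefficients of roi-containing terms are
    mappings roi -> value (absent ROIs contribute 0).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    df = cells.copy()
    if "condition" not in df.columns and "session" in df.columns:
        df["condition"] = df["session"]
    level_sets = {
        f: sorted(df[f].astype(str).unique())
        for f in ("phase", "probe", "condition")
        if f in df.columns
    }
    eta = np.zeros(len(df))
    for term, coef in truth.behavior.items():
        x = np.ones(len(df))
        if "corr" in term:
            x = x * df["fisher_z"].to_numpy(float)
        for f in term:
            if f in ("corr", "roi"):
                continue
            codes = df[f].astype(str).map(
                lambda lev: _factor_code(lev, level_sets[f])
            )
            x = x * codes.to_numpy(float)
        if "roi" in term:
            per_roi = df["roi"].map(lambda r: float(coef.get(r, 0.0)))
            x = x * per_roi.to_numpy(float)
            eta += x
        else:
            eta += float(coef) * x
    p_no = expit(eta)
    df["response"] = np.where(rng.random(len(df)) < p_no, "no", "yes")
    df["p_no_true"] = p_no
    return df


# ----------------------------------------------------------------------
# Fixture bundles
# ----------------------------------------------------------------------
def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(
    spec: DesignSpec,
    truth: GroundTruth,
    out_dir: str | Path,
    seed: int = 0,
    subject: str = "sub-01",
    session: str = "morning",
    task: str = "global",
    make_nifti: bool = False,
) -> dict:
    """Write a self-describing synthetic run: events TSV (+ sidecar), ROI
    BOLD TSV, nuisance TSV, ground-truth record and a manifest with
    checksums.  Optionally also a small synthetic 4D NIfTI + label atlas
    for exercising ROI extraction."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = generate_schedule(
        spec, seed=seed, subject=subject, session=session, task=task
    )
    truth = GroundTruth(
        effects=truth.effects,
        ar1=truth.ar1,
        noise_sd=truth.noise_sd,
        drift_amplitude=truth.drift_amplitude,
        behavior=truth.behavior,
        seed=seed,
    )
    bold, nuisance = generate_bold(schedule, truth)

    files = {
        "events": out / "events.tsv",
        "bold": out / "roi_bold.tsv",
        "nuisance": out / "nuisance.tsv",
        "truth": out / "truth.json",
    }
    schedule.to_events_tsv(files["events"])
    bold.to_tsv(files["bold"])
    nuisance.to_tsv(files["nuisance"])
    truth_record = {
        "seed": seed,
        "ar1": truth.ar1,
        "noise_sd": truth.noise_sd,
        "drift_amplitude": truth.drift_amplitude,
        "behavior": {":".join(k) if k else "(Intercept)": v
                     for k, v in truth.behavior.items()},
        "effects": truth.effects.to_dict(orient="records"),
    }
    files["truth"].write_text(json.dumps(truth_record, indent=2))

    if make_nifti:
        import nibabel as nib

        rng = np.random.default_rng(seed)
        shape = (4, 4, 4)
        atlas = np.zeros(shape, dtype=np.int16)
        atlas[:2] = 1
        atlas[2:] = 2
        img = rng.normal(size=shape + (schedule.n_volumes,))
        nib.save(
            nib.Nifti1Image(img.astype(np.float32), np.eye(4)),
            str(out / "synthetic_bold.nii.gz"),
        )
        nib.save(
            nib.Nifti1Image(atlas, np.eye(4)),
            str(out / "synthetic_atlas.nii.gz"),
        )
        files["nifti"] = out / "synthetic_bold.nii.gz"
        files["atlas"] = out / "synthetic_atlas.nii.gz"

    manifest = {
        "seed": seed,
        "subject": subject,
        "session": session,
        "task": task,
        "design": asdict(spec) | {"rt_params": None},
        "files": {
            k: {"path": p.name, "sha256": _sha256(p)} for k, p in files.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
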