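"""Temporal conditioning of ROI BOLD time series.

Covers the per-run steps applied after spatial preprocessing: extracting
atlas-ROI mean time series from a labelled 4D image, linear detrending,
nuisance (motion / global / white-matter / CSF) regression, band-pass
filtering, and a motion-versus-event overlap check.  Spatial steps
(realignment, normalisation, smoothing) belong to dedicated imaging
software and are out of scope here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.signal import detrend as _detrend

from .errors import ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "ROITimeSeries",
    "NuisanceSet",
    "extract_roi_series",
    "condition_series",
    "framewise_displacement",
    "motion_event_overlap",
]


@dataclass
class ROITimeSeries:
    """n_volumes x n_rois matrix of BOLD values plus run metadata."""

    values: np.ndarray
    roi_labels: list[str]
    tr_s: float
    subject: str = "sub-01"
    session: str = "morning"
    task: str = "global"
    seed: int | None = None  # set by the synthetic generator

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("ROI time series must be a 2-D matrix")
        if self.values.shape[1] != len(self.roi_labels):
            raise ParameterError("number of columns must match roi_labels")
        if len(self.roi_labels) < 1:
            raise ParameterError("need at least one ROI")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("ROI time series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def column(self, roi: str) -> np.ndarray:
        try:
            j = self.roi_labels.index(roi)
        except ValueError:
            raise KeyError(f"ROI {roi!r} not present") from None
        return self.values[:, j]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.roi_labels).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, tr_s: float, **meta) -> "ROITimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(
            values=df.to_numpy(float),
            roi_labels=list(df.columns),
            tr_s=tr_s,
            **meta,
        )


@dataclass
class NuisanceSet:
    """Confound regressors sampled once per volume (motion, global signal,
    white matter, CSF, drift ...)."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and len(self.names) == 1:
            self.values = self.values.T
        if not self.names:
            self.names = [f"confound_{j}" for j in range(self.values.shape[1])]
        if self.values.shape[1] != len(self.names):
            raise ParameterError("number of confound columns must match names")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.names).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NuisanceSet":
        df = pd.read_csv(path, sep="\t")
        return cls(values=df.to_numpy(float), names=list(df.columns))


# ----------------------------------------------------------------------
# ROI extraction from a labelled 4D image
# ----------------------------------------------------------------------
def extract_roi_series(
    image4d,
    atlas,
    tr_s: float | None = None,
    labels: list[int] | None = None,
    **meta,
) -> ROITimeSeries:
    """Mean time series per atlas label from a 4D image.

    ``image4d`` and ``atlas`` may be nibabel images, paths, or plain
    arrays; the atlas is a 3-D integer label volume on the same grid.
    Columns are ordered by ascending label.  Labels requested but empty in
    the atlas are dropped with a warning.
    """
    import nibabel as nib

    def _load(obj, ndim):
        if isinstance(obj, (str, Path)):
            obj = nib.load(str(obj))
        if hasattr(obj, "get_fdata"):
            data = np.asanyarray(obj.dataobj)
            hdr_tr = None
            if ndim == 4 and tr_s is None:
                zooms = obj.header.get_zooms()
                hdr_tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
            return np.asarray(data), hdr_tr
        return np.asarray(obj), None

    img, hdr_tr = _load(image4d, 4)
    atl, _ = _load(atlas, 3)
    if img.ndim != 4:
        raise ParameterError("image must be 4-D (x, y, z, time)")
    if atl.shape != img.shape[:3]:
        raise ParameterError(
            f"atlas grid {atl.shape} does not match image grid {img.shape[:3]}"
        )
    atl = atl.astype(int)
    present = np.unique(atl)
    present = present[present > 0]
    wanted = sorted(labels) if labels is not None else list(present)

    n_vol = img.shape[3]
    flat = img.reshape(-1, n_vol)
    atl_flat = atl.reshape(-1)
    cols, names = [], []
    for lab in wanted:
        mask = atl_flat == lab
        if not mask.any():
            warnings.warn(f"atlas label {lab} has no voxels; column dropped")
            log.warning("atlas label %s empty; dropped", lab)
            continue
        cols.append(flat[mask].mean(axis=0))
        names.append(f"roi_{lab:03d}")
    if not cols:
        raise ParameterError("no non-empty atlas labels found")
    return ROITimeSeries(
        values=np.column_stack(cols),
        roi_labels=names,
        tr_s=tr_s if tr_s is not None else (hdr_tr or 1.0),
        **meta,
    )


# ----------------------------------------------------------------------
# Detrend -> nuisance regression -> band-pass
# ----------------------------------------------------------------------
def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep a full-rank subset of columns via pivoted QR."""
    if X.shape[1] == 0:
        return X, names
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        warnings.warn(f"dropping collinear nuisance columns: {dropped}")
        log.warning("dropping collinear nuisance columns: %s", dropped)
    keep = np.sort(piv[:rank])
    return X[:, keep], [names[j] for j in keep]


def condition_series(
    ts: ROITimeSeries,
    nuisance: NuisanceSet | None = None,
    band: tuple[float, float] | None = (0.01, 0.1),
    detrend: bool = True,
) -> ROITimeSeries:
    """Linear detrend, OLS nuisance residualisation, then ideal band-pass.

    The band-pass is a rectangular mask on the discrete Fourier grid
    (frequencies strictly outside [f_lo, f_hi] are zeroed), which also
    removes the DC component, so output columns have mean ~ 0.
    """
    x = ts.values.copy()
    n = x.shape[0]

    if detrend:
        x = _detrend(x, axis=0, type="linear")

    if nuisance is not None:
        if nuisance.n_volumes != n:
            raise ParameterError(
                "nuisance regressors must have the same length as the BOLD run"
            )
        design = np.column_stack([np.ones(n), nuisance.values])
        names = ["intercept"] + list(nuisance.names)
        design, _ = _drop_collinear(design, names)
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta

    if band is not None:
        f_lo, f_hi = band
        nyquist = 1.0 / (2.0 * ts.tr_s)
        if not (0.0 < f_lo < f_hi < nyquist):
            raise ParameterError(
                f"band ({f_lo}, {f_hi}) Hz must satisfy 0 < f_lo < f_hi < "
                f"Nyquist ({nyquist:.4f} Hz)"
            )
        freqs = np.fft.rfftfreq(n, d=ts.tr_s)
        spec = np.fft.rfft(x, axis=0)
        mask = (freqs >= f_lo) & (freqs <= f_hi)
        spec[~mask, :] = 0.0
        x = np.fft.irfft(spec, n=n, axis=0)

    return ROITimeSeries(
        values=x,
        roi_labels=list(ts.roi_labels),
        tr_s=ts.tr_s,
        subject=ts.subject,
        session=ts.session,
        task=ts.task,
    )


# ----------------------------------------------------------------------
# Motion / event overlap QC
# ----------------------------------------------------------------------
def framewise_displacement(
    motion: np.ndarray, rotation_radius_mm: float = 50.0
) -> np.ndarray:
    """Per-volume displacement: max absolute inter-volume difference over
    the translation columns (mm); rotation columns (radians, columns 4-6
    when present) are converted to arc length on a 50 mm sphere.  The
    first volume gets 0."""
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    if motion.shape[0] == 1:
        motion = motion.T
    diffs = np.abs(np.diff(motion, axis=0))
    if motion.shape[1] >= 6:
        diffs[:, 3:6] *= rotation_radius_mm
    fd = np.concatenate([[0.0], diffs.max(axis=1)])
    return fd


def motion_event_overlap(
    motion: NuisanceSet | np.ndarray,
    events,
    displacement_threshold_mm: float = 1.0,
    window: tuple[int, int] = (0, 9),
) -> float:
    """Fraction of supra-threshold motion volumes that fall within
    ``window`` TRs after any source-event crossing.

    A single-column input is taken as a precomputed displacement trace;
    a multi-column input as raw motion parameters.
    """
    values = motion.values if isinstance(motion, NuisanceSet) else np.asarray(motion)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    fd = values[:, 0] if values.shape[1] == 1 else framewise_displacement(values)

    spikes = np.flatnonzero(fd > displacement_threshold_mm)
    if spikes.size == 0:
        return 0.0
    if not events:
        warnings.warn("motion_event_overlap called with no events; returning 0")
        return 0.0
    lo, hi = window
    onsets = np.array([getattr(e, "crossing_index", e) for e in events])
    inside = np.zeros(fd.size, dtype=bool)
    for k in onsets:
        inside[max(0, k + lo) : min(fd.size, k + hi + 1)] = True
    return float(inside[spikes].sum() / spikes.size)
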