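"""Subject-level functional connectivity: scrubbing, confound regression,
band-pass filtering, and Pearson correlation matrices.

Two conditions are produced per subject:

* tb-FC (task-based): the denoised whole series, band [0.009, 0.10] Hz;
* tr-FC (task-residual): HRF-convolved task regressors and their temporal
  derivatives are additionally regressed out and the band is narrowed to
  [0.009, 0.08] Hz, leaving resting-state-like fluctuations.

Motion (6 parameters + first differences), spike regressors for outlying
scans, tissue (white matter / CSF) signals, and task-block indicators are
removed by ordinary least squares before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy import stats as sps

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "DegenerateDesignError",
    "FlaggedRegionError",
    "double_gamma_hrf",
    "boxcar_regressors",
    "hrf_regressors",
    "detect_outlier_scans",
    "build_confound_matrix",
    "regress_confounds",
    "bandpass",
    "correlation_matrix",
    "subject_fc",
    "TB_BAND",
    "TR_BAND",
]

TB_BAND = (0.009, 0.10)
TR_BAND = (0.009, 0.08)

#: head-radius (mm) used to convert rotations to displacements
ROTATION_RADIUS_MM = 50.0


class DegenerateDesignError(ValueError):
    pass


class FlaggedRegionError(ValueError):
    pass


@dataclass
class TimeSeriesMatrix:
    """time x region BOLD-like signal with its sampling interval."""

    values: np.ndarray
    tr_seconds: float
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be 2-D (time x region)")
        if np.isnan(v).any():
            raise ValueError("time series contains missing values")
        if v.shape[1] < 2:
            raise ValueError("need >= 2 regions")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.values = v
        if self.region_labels is None:
            self.region_labels = [f"region_{i:03d}" for i in range(v.shape[1])]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """region x region Pearson correlation matrix for one subject/condition."""

    values: np.ndarray
    condition: str
    subject_id: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("connectivity matrix must have unit diagonal")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)


def double_gamma_hrf(tr_seconds: float, duration: float = 32.0,
                     peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Positive gamma peaking at 6 s minus an undershoot gamma peaking at
    16 s scaled by 1/6; normalised to unit peak.
    """
    t = np.arange(0, duration, tr_seconds)
    # shape a, scale 1 gamma peaks at a-1: use a = peak + 1
    pos = sps.gamma.pdf(t, peak, scale=1.0)
    neg = sps.gamma.pdf(t, undershoot, scale=1.0)
    h = pos - ratio * neg
    return h / np.abs(h).max()


def boxcar_regressors(events: pd.DataFrame, n_timepoints: int,
                      tr_seconds: float) -> pd.DataFrame:
    """One 0/1 boxcar column per condition ('trial_type') in the events table."""
    cols = {}
    for cond, sub in events.groupby("trial_type", sort=True):
        box = np.zeros(n_timepoints)
        for _, row in sub.iterrows():
            a = int(np.floor(row["onset"] / tr_seconds))
            b = int(np.ceil((row["onset"] + row["duration"]) / tr_seconds))
            box[a:min(b, n_timepoints)] = 1.0
        cols[f"block_{cond}"] = box
    return pd.DataFrame(cols)


def hrf_regressors(events: pd.DataFrame, n_timepoints: int,
                   tr_seconds: float) -> pd.DataFrame:
    """HRF-convolved task regressors plus their temporal derivatives."""
    box = boxcar_regressors(events, n_timepoints, tr_seconds)
    hrf = double_gamma_hrf(tr_seconds)
    cols = {}
    for name in box.columns:
        conv = np.convolve(box[name].to_numpy(), hrf)[:n_timepoints]
        cond = name.removeprefix("block_")
        cols[f"task_{cond}"] = conv
        cols[f"task_{cond}_deriv"] = np.gradient(conv)
    return pd.DataFrame(cols)


def detect_outlier_scans(motion_params, global_signal, fd_threshold: float = 0.9,
                         z_threshold: float = 5.0) -> np.ndarray:
    """Flag time points with large framewise displacement or global-signal jumps.

    FD = sum of absolute backward differences of the 3 translations (mm)
    plus the 3 rotations (rad) converted to arc displacement on a 50 mm
    sphere.  The first time point is never flagged by FD.  Global-signal
    changes are z-scored; |z| above ``z_threshold`` flags the scan.
    """
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns "
                         "(3 translations mm, 3 rotations rad)")
    gs = np.asarray(global_signal, dtype=float)
    n = motion.shape[0]
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(n)
    fd[1:] = d[:, :3].sum(axis=1) + ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    mask = fd > fd_threshold
    dg = np.zeros(n)
    dg[1:] = np.diff(gs)
    sd = dg[1:].std()
    if sd > 0:
        z = (dg - dg[1:].mean()) / sd
        mask |= np.abs(z) > z_threshold
    return mask


def build_confound_matrix(motion, scrub_mask, tissue_signals=None,
                          events: pd.DataFrame | None = None,
                          mode: str = "tb", tr_seconds: float = 1.0) -> pd.DataFrame:
    """Assemble the nuisance design for one subject.

    Columns: intercept, 6 motion parameters, their first differences, one
    one-hot spike column per flagged scan, tissue signals, and task-block
    indicator columns.  In tr mode, HRF-convolved task regressors and
    temporal derivatives are appended so task-evoked signal is removed.
    """
    if mode not in ("tb", "tr"):
        raise ValueError(f"mode must be 'tb' or 'tr', got {mode!r}")
    motion = np.asarray(motion, dtype=float)
    n = motion.shape[0]
    if motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    cols = {"intercept": np.ones(n)}
    for j in range(6):
        cols[f"motion_{j}"] = motion[:, j]
    dm = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    for j in range(6):
        cols[f"motion_diff_{j}"] = dm[:, j]
    scrub_mask = np.asarray(scrub_mask, dtype=bool)
    flagged = np.flatnonzero(scrub_mask)
    if flagged.size == n:
        raise DegenerateDesignError("every scan is flagged; design degenerate")
    for t in flagged:
        spike = np.zeros(n)
        spike[t] = 1.0
        cols[f"spike_{t}"] = spike
    if tissue_signals is not None:
        tissue = np.asarray(tissue_signals, dtype=float)
        if tissue.ndim == 1:
            tissue = tissue[:, None]
        for j in range(tissue.shape[1]):
            cols[f"tissue_{j}"] = tissue[:, j]
    if events is not None and len(events):
        box = boxcar_regressors(events, n, tr_seconds)
        for name in box.columns:
            cols[name] = box[name].to_numpy()
        if mode == "tr":
            task = hrf_regressors(events, n, tr_seconds)
            for name in task.columns:
                cols[name] = task[name].to_numpy()
    design = pd.DataFrame(cols)
    x = design.to_numpy()
    if np.linalg.matrix_rank(x) < min(x.shape):
        # tolerated: lstsq handles rank deficiency; only a fully degenerate
        # design (rank 0 beyond intercept with data present) is an error
        if np.linalg.matrix_rank(x) == 0:
            raise DegenerateDesignError("confound design has rank 0")
    return design


def regress_confounds(ts: TimeSeriesMatrix, confounds) -> TimeSeriesMatrix:
    """OLS residuals of every region's series on the confound design."""
    x = confounds.to_numpy() if isinstance(confounds, pd.DataFrame) else np.asarray(confounds, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != ts.n_timepoints:
        raise ValueError("confound design and time series length differ")
    if np.linalg.matrix_rank(x) == 0:
        raise DegenerateDesignError("confound design is all-zero")
    beta, *_ = np.linalg.lstsq(x, ts.values, rcond=None)
    resid = ts.values - x @ beta
    return TimeSeriesMatrix(values=resid, tr_seconds=ts.tr_seconds,
                            region_labels=list(ts.region_labels))


def bandpass(ts: TimeSeriesMatrix, low_hz: float, high_hz: float,
             order: int = 2) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass (filtfilt) applied per region."""
    nyquist = 0.5 / ts.tr_seconds
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist} Hz")
    sos = spsig.butter(order, [low_hz, high_hz], btype="bandpass",
                       fs=1.0 / ts.tr_seconds, output="sos")
    # the default padding is far too short for a 0.009 Hz edge; reflect the
    # series over up to 3 high-pass periods to suppress edge transients
    padlen = int(min(ts.n_timepoints - 1, round(3.0 / (low_hz * ts.tr_seconds))))
    filtered = spsig.sosfiltfilt(sos, ts.values, axis=0, padlen=padlen)
    return TimeSeriesMatrix(values=filtered, tr_seconds=ts.tr_seconds,
                            region_labels=list(ts.region_labels))


def correlation_matrix(ts: TimeSeriesMatrix, condition: str = "tb",
                       subject_id: str | None = None,
                       provenance: dict | None = None) -> ConnectivityMatrix:
    """Pearson correlation of every region pair."""
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.region_labels[i] for i in dead[:5]]
        raise FlaggedRegionError(
            f"zero-variance region(s) after denoising: {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=np.clip(r, -1, 1), condition=condition,
                              subject_id=subject_id,
                              provenance=provenance or {})


def subject_fc(ts: TimeSeriesMatrix, events: pd.DataFrame | None,
               motion, tissue_signals=None, mode: str = "tb",
               fd_threshold: float = 0.9, z_threshold: float = 5.0,
               band: tuple[float, float] | None = None,
               subject_id: str | None = None) -> ConnectivityMatrix:
    """Full single-subject pipeline: scrub -> confounds -> regression ->
    band-pass -> correlation, for one condition (tb or tr)."""
    if band is None:
        band = TB_BAND if mode == "tb" else TR_BAND
    global_signal = ts.values.mean(axis=1)
    mask = detect_outlier_scans(motion, global_signal,
                                fd_threshold=fd_threshold,
                                z_threshold=z_threshold)
    design = build_confound_matrix(motion, mask, tissue_signals=tissue_signals,
                                   events=events, mode=mode,
                                   tr_seconds=ts.tr_seconds)
    clean = regress_confounds(ts, design)
    clean = bandpass(clean, band[0], band[1])
    provenance = {
        "mode": mode,
        "band_hz": list(band),
        "n_flagged_scans": int(mask.sum()),
        "n_confound_columns": design.shape[1],
        "fd_threshold_mm": fd_threshold,
        "global_signal_z_threshold": z_threshold,
    }
    return correlation_matrix(clean, condition=mode, subject_id=subject_id,
                              provenance=provenance)
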