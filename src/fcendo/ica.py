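"""Group spatial ICA, dual-regression back-reconstruction, dice labeling,
and directed semipartial effective functional network connectivity (eFNC).

Group ICA follows the standard temporal-concatenation recipe: each
subject's (time x location) data is reduced over time by PCA, the reduced
blocks are stacked and reduced again to ``n_components`` group dimensions,
and fixed-point ICA (symmetric updates, tanh contrast, restart-selected)
unmixes the group data into spatially independent maps.  Back-reconstruction is the first dual
regression step: a subject's component time courses are the least-squares
projection of its data onto the group spatial maps.

eFNC entry (i, j) is the correlation between target course i and the part
of source course j that is unique to j (its residual after regressing j on
every other course) — a directed "from j to i" association controlling for
the remaining networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA

from .connectivity import (TB_BAND, DegenerateDesignError, TimeSeriesMatrix,
                           bandpass, regress_confounds)

__all__ = [
    "ICSet",
    "EFNCMatrix",
    "group_ica",
    "back_reconstruct",
    "dice_label",
    "efnc_matrix",
]


@dataclass
class ICSet:
    spatial_maps: np.ndarray        # components x locations, z-scored
    group_timecourses: np.ndarray   # total time x components
    n_components: int
    labels: list | None = None

    def __post_init__(self) -> None:
        if self.spatial_maps.shape[0] != self.n_components:
            raise ValueError("component count mismatch")
        if self.group_timecourses.shape[1] != self.n_components:
            raise ValueError("component count mismatch")


@dataclass
class EFNCMatrix:
    """Directed component x component semipartial connectivity.

    values[i, j] = association from source j to target i; diagonal NaN.
    """

    values: np.ndarray
    subject_id: str | None = None
    labels: list | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if np.nanmax(np.abs(off)) > 1 + 1e-9:
            raise ValueError("eFNC entries must lie in [-1, 1]")
        self.values = v


def _zscore_maps(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return maps / sd


def _negentropy(sources: np.ndarray) -> float:
    """Sum of squared logcosh-negentropy proxies over components.

    J(s) ~ (E[log cosh s] - E[log cosh g])^2 for standardized s, g ~ N(0,1);
    higher means further from Gaussian, i.e. a better ICA solution.
    """
    gauss = 0.3745672075244098  # E[log cosh Z], Z standard normal
    s = sources - sources.mean(axis=1, keepdims=True)
    sd = s.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    s /= sd
    return float(np.sum((np.mean(np.log(np.cosh(s)), axis=1) - gauss) ** 2))


def group_ica(subject_timeseries: list[TimeSeriesMatrix], n_components: int = 20,
              seed: int = 0, subject_pca_dim: int = 60,
              max_iter: int = 1000, n_restarts: int = 5) -> ICSet:
    """Two-stage PCA reduction + fixed-point spatial ICA on concatenated data.

    FastICA is restarted ``n_restarts`` times from seed-derived
    initialisations and the solution with the largest total negentropy is
    kept, guarding against occasional convergence to a local optimum that
    leaves one component unseparated.  Components are ordered by the
    variance of their group time courses and sign-fixed so the
    most-loading location is positive; given the same seed the result is
    fully deterministic.
    """
    mats = [np.asarray(ts.values, dtype=float) for ts in subject_timeseries]
    n_loc = mats[0].shape[1]
    if any(m.shape[1] != n_loc for m in mats):
        raise ValueError("all subjects must share the location dimension")
    total_time = sum(m.shape[0] for m in mats)
    if total_time <= n_components:
        raise ValueError("total time must exceed n_components")

    # stage 1: per-subject temporal PCA
    reduced = []
    for m in mats:
        m = m - m.mean(axis=0)
        r = min(subject_pca_dim, m.shape[0] - 1, n_loc)
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        reduced.append(s[:r, None] * vt[:r])
    stacked = np.vstack(reduced)

    # stage 2: group PCA to n_components
    if min(stacked.shape) < n_components or \
            np.linalg.matrix_rank(stacked) < n_components:
        raise ValueError("n_components exceeds the rank of the reduced data")
    u, s, vt = np.linalg.svd(stacked, full_matrices=False)
    group = s[:n_components, None] * vt[:n_components]   # components x locations

    best_maps, best_score = None, -np.inf
    for restart in range(max(1, n_restarts)):
        ica = FastICA(n_components=n_components, algorithm="parallel",
                      fun="logcosh", whiten="unit-variance",
                      max_iter=max_iter,
                      random_state=int(seed) + 1009 * restart)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cand = ica.fit_transform(group.T).T   # components x locations
        score = _negentropy(cand)
        if score > best_score:
            best_maps, best_score = cand, score
    maps = _zscore_maps(best_maps)

    # sign convention: strongest-loading location positive
    for k in range(maps.shape[0]):
        if maps[k, np.argmax(np.abs(maps[k]))] < 0:
            maps[k] *= -1

    concat = np.vstack([m - m.mean(axis=0) for m in mats])
    courses, *_ = np.linalg.lstsq(maps.T, concat.T, rcond=None)
    courses = courses.T                        # total time x components
    order = np.argsort(-courses.var(axis=0), kind="stable")
    return ICSet(spatial_maps=maps[order], group_timecourses=courses[:, order],
                 n_components=n_components)


def back_reconstruct(ic_set: ICSet, subject_ts: TimeSeriesMatrix) -> np.ndarray:
    """Dual-regression step 1: subject component time courses (time x comp)."""
    y = np.asarray(subject_ts.values, dtype=float)
    maps = ic_set.spatial_maps
    if y.shape[1] != maps.shape[1]:
        raise ValueError("subject data and spatial maps disagree on locations")
    y = y - y.mean(axis=0)
    courses, *_ = np.linalg.lstsq(maps.T, y.T, rcond=None)
    return courses.T


def dice_label(spatial_map: np.ndarray, templates: dict[str, np.ndarray],
               z_threshold: float = 1.5) -> tuple[str | None, float]:
    """Label a z-scored map by maximal dice overlap with template masks.

    dice = 2|A∩B| / (|A| + |B|) of the thresholded map against each
    template mask; returns the argmax label and its score, or
    (None, 0.0) with a warning when the thresholded map is empty.
    """
    mask = np.asarray(spatial_map) > z_threshold
    if not mask.any():
        warnings.warn("thresholded spatial map is empty; component unlabeled")
        return None, 0.0
    best_label, best_score = None, -1.0
    for label in sorted(templates):
        t = np.asarray(templates[label], dtype=bool)
        denom = mask.sum() + t.sum()
        score = 2.0 * np.logical_and(mask, t).sum() / denom if denom else 0.0
        if score > best_score:
            best_label, best_score = label, score
    return best_label, float(best_score)


def efnc_matrix(component_timecourses: np.ndarray,
                band: tuple[float, float] = TB_BAND,
                confounds: pd.DataFrame | None = None,
                tr_seconds: float = 1.0,
                subject_id: str | None = None,
                condition_threshold: float = 1e8) -> EFNCMatrix:
    """Directed semipartial connectivity between component time courses.

    Courses are denoised and band-pass filtered like tb-FC, then entry
    (i, j) = corr(course_i, residual of course_j on all other courses).
    """
    tc = np.asarray(component_timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[1] < 3:
        raise ValueError("need a time x component matrix with >= 3 components")
    ts = TimeSeriesMatrix(values=tc, tr_seconds=tr_seconds)
    if confounds is not None:
        ts = regress_confounds(ts, confounds)
    ts = bandpass(ts, band[0], band[1])
    tc = ts.values - ts.values.mean(axis=0)
    k = tc.shape[1]
    sd = tc.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateDesignError("constant component time course")
    if np.linalg.cond(tc / sd) > condition_threshold:
        raise DegenerateDesignError("collinear component time courses")
    values = np.full((k, k), np.nan)
    norm_t = tc / (np.linalg.norm(tc, axis=0) + 1e-300)
    ones = np.ones((tc.shape[0], 1))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            # controls = every component except target i and source j
            controls = np.delete(tc, [i, j], axis=1)
            design = np.hstack([ones, controls])
            beta, *_ = np.linalg.lstsq(design, tc[:, j], rcond=None)
            resid = tc[:, j] - design @ beta
            rn = np.linalg.norm(resid)
            if rn == 0:
                raise DegenerateDesignError(
                    f"component {j} fully explained by the others")
            values[i, j] = float(np.clip(norm_t[:, i] @ (resid / rn),
                                         -1.0, 1.0))
    return EFNCMatrix(values=values, subject_id=subject_id)
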