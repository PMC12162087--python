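"""General linear model: design matrices, PSC normalization, betas, contrasts.

The analysis follows the standard block-design GLM: condition boxcars at TR
resolution convolved with a canonical double-gamma hemodynamic response
function, plus a constant, a linear drift, and (optionally) six nuisance
motion regressors. Time series are converted to percent signal change
before regression; betas come from the pseudoinverse of the design matrix,
estimated per run and averaged across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .stimuli import BlockSchedule

__all__ = [
    "DesignMatrix",
    "ContrastMap",
    "hrf",
    "build_design",
    "to_psc",
    "fit_glm",
    "average_runs",
    "contrast",
    "CONTRASTS",
]

#: the three localizer contrasts: name -> (positive labels, negative labels)
CONTRASTS = {
    "motion2d": (["radial_in", "radial_out", "cw", "ccw"], ["static"]),
    "motion3d": (["coherent"], ["scrambled"]),
    "opponency": (["unpaired"], ["paired"]),
}


@dataclass
class DesignMatrix:
    values: np.ndarray  # timepoints x regressors
    labels: list[str]
    tr: float

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.labels)


@dataclass
class ContrastMap:
    values: np.ndarray  # one value per vertex, PSC units
    name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contrast map contains non-finite values")


def hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel.

    Positive gamma lobe peaking at 6 s minus an undershoot lobe peaking at
    16 s with 1/6 amplitude, sampled every ``tr`` seconds over ``duration``
    and normalized to unit sum (so convolution preserves plateau amplitude).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration, tr)
    k = gamma_dist.pdf(t, a=7.0, scale=1.0) - gamma_dist.pdf(t, a=17.0, scale=1.0) / 6.0
    return k / k.sum()


def _convolve_to_length(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(x, kernel)[: x.shape[0]]


def build_design(
    schedule: BlockSchedule,
    nuisance: np.ndarray | None = None,
    hrf_kernel: np.ndarray | None = None,
) -> DesignMatrix:
    """One hRF-convolved boxcar column per condition + constant + drift.

    Blank blocks are the implicit baseline and get no column. The drift
    column is a ramp normalized to [-0.5, 0.5]; ``nuisance``, when given,
    must be a (timepoints, 6) array of motion regressors.
    """
    if not schedule.blocks:
        raise ValueError("schedule has no blocks")
    conditions = schedule.condition_names()
    if not conditions:
        raise ValueError("schedule has no non-baseline conditions")
    n_t = schedule.n_timepoints
    kernel = hrf(schedule.tr) if hrf_kernel is None else hrf_kernel

    labels_tr = schedule.labels_per_tr()
    cols = []
    for cond in conditions:
        boxcar = (labels_tr == cond).astype(float)
        cols.append(_convolve_to_length(boxcar, kernel))
    cols.append(np.ones(n_t))
    cols.append(np.linspace(-0.5, 0.5, n_t))
    labels = conditions + ["constant", "drift"]

    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.ndim != 2 or nuisance.shape != (n_t, 6):
            raise ValueError(
                f"nuisance must have shape ({n_t}, 6), got {nuisance.shape}"
            )
        cols.extend(nuisance.T)
        labels += [f"nuisance{i}" for i in range(6)]

    return DesignMatrix(np.column_stack(cols), labels, schedule.tr)


def to_psc(ts):
    """Convert a TimeSeriesMatrix to percent signal change.

    psc = 100 * (y - mean) / mean per vertex. Vertices with (near-)zero mean
    cannot be normalized and are rejected with their indices.
    """
    from .synth import TimeSeriesMatrix

    if ts.units == "psc":
        return ts
    means = ts.values.mean(axis=1, keepdims=True)
    bad = np.flatnonzero(np.abs(means[:, 0]) < 1e-12)
    if bad.size:
        raise ValueError(f"zero-mean vertices cannot be converted to PSC: {bad[:10].tolist()}")
    return TimeSeriesMatrix(
        values=100.0 * (ts.values - means) / means, tr=ts.tr, units="psc"
    )


def fit_glm(ts, X: DesignMatrix) -> np.ndarray:
    """Pseudoinverse beta estimates, vertices x regressors.

    Accepts a TimeSeriesMatrix in PSC units (or a bare array of the same
    layout) and returns ``pinv(X) @ y`` for every vertex.
    """
    values = ts if isinstance(ts, np.ndarray) else ts.values
    if not isinstance(ts, np.ndarray) and ts.units != "psc":
        raise ValueError("time series must be in PSC units; call to_psc first")
    if values.shape[1] != X.n_timepoints:
        raise ValueError(
            f"timepoint mismatch: data {values.shape[1]}, design {X.n_timepoints}"
        )
    return values @ np.linalg.pinv(X.values).T


def average_runs(betas_per_run: list[np.ndarray]) -> np.ndarray:
    """Equal-weight mean of per-run beta matrices."""
    if not betas_per_run:
        raise ValueError("no runs to average")
    shapes = {b.shape for b in betas_per_run}
    if len(shapes) != 1:
        raise ValueError(f"runs have inconsistent beta shapes: {shapes}")
    return np.mean(betas_per_run, axis=0)


def contrast(
    betas: np.ndarray,
    labels: list[str],
    positive_labels: list[str],
    negative_labels: list[str],
    name: str = "contrast",
) -> ContrastMap:
    """Mean of positive-label betas minus mean of negative-label betas."""
    for lab in list(positive_labels) + list(negative_labels):
        if lab not in labels:
            raise ValueError(f"unknown design label {lab!r}")
    pos = [labels.index(lab) for lab in positive_labels]
    neg = [labels.index(lab) for lab in negative_labels]
    values = betas[:, pos].mean(axis=1) - betas[:, neg].mean(axis=1)
    return ContrastMap(values=values, name=name)
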