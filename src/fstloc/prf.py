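"""Population receptive field model fitting and the stimulus-contrast model.

The pRF model is a 2D circular Gaussian over the visual field: a vertex's
neural response at each timepoint is the overlap of the aperture mask with
the Gaussian (normalized by the untruncated Gaussian integral), convolved
with the hRF. Fitting is coarse-to-fine: an exhaustive grid over center
position and log-spaced size picks the best seed by variance explained
(scale and offset solved in closed form), then a Nelder-Mead refinement
polishes (x0, y0, sigma). The competing stimulus-contrast (ON/OFF) model
predicts the response from the total stimulated area alone, with no spatial
selectivity; comparing variance explained between the two models flags
vertices whose pRF cannot be resolved within the aperture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .glm import hrf
from .stimuli import ApertureMovie
from .synth import prf_response_matrix

__all__ = [
    "GridSpec",
    "PRFFit",
    "PRFFitter",
    "predict_prf",
    "predict_contrast",
    "fit_prf",
    "fit_contrast",
    "variance_explained",
    "to_polar",
]


@dataclass(frozen=True)
class GridSpec:
    """Coarse-grid settings: 1 deg position steps within +/- the aperture
    radius and 20 log-spaced sizes from 0.25 to 24 deg by default."""

    pos_step: float = 1.0
    sigma_min: float = 0.25
    sigma_max: float = 24.0
    n_sigma: int = 20

    def positions(self, radius: float) -> np.ndarray:
        lim = np.floor(radius / self.pos_step) * self.pos_step
        return np.arange(-lim, lim + self.pos_step / 2, self.pos_step)

    def sigmas(self) -> np.ndarray:
        return np.geomspace(self.sigma_min, self.sigma_max, self.n_sigma)


@dataclass
class PRFFit:
    """Fitted parameters of one vertex under one model ('prf' or 'contrast').

    (x0, y0, sigma) are in degrees of visual angle; rho/theta are the polar
    form of the center (theta in [0, 360), 0 = right horizontal meridian,
    counterclockwise). For the contrast model the spatial parameters are
    NaN. ``scale`` maps the unit prediction to PSC; ``offset`` is the fitted
    additive constant.
    """

    x0: float
    y0: float
    sigma: float
    scale: float
    offset: float
    r2: float
    model: str
    degenerate: bool = False

    @property
    def rho(self) -> float:
        return to_polar(self.x0, self.y0)[0]

    @property
    def theta(self) -> float:
        return to_polar(self.x0, self.y0)[1]

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "x0": self.x0,
            "y0": self.y0,
            "sigma": self.sigma,
            "scale": self.scale,
            "offset": self.offset,
            "r2": self.r2,
            "rho": self.rho,
            "theta": self.theta,
            "degenerate": self.degenerate,
        }


def to_polar(x0: float, y0: float) -> tuple[float, float]:
    """(eccentricity, polar angle deg in [0, 360)); origin maps to (0, 0)."""
    rho = float(np.hypot(x0, y0))
    if rho == 0.0:
        return 0.0, 0.0
    theta = float(np.degrees(np.arctan2(y0, x0)) % 360.0)
    return rho, theta


def predict_prf(
    apertures: ApertureMovie,
    x0: float,
    y0: float,
    sigma: float,
    hrf_kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-scale predicted time course of a Gaussian pRF."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    kernel = hrf(apertures.tr) if hrf_kernel is None else hrf_kernel
    overlap = prf_response_matrix(
        np.array([x0]), np.array([y0]), np.array([sigma]), apertures
    )[0]
    return np.convolve(overlap, kernel)[: overlap.size]


def predict_contrast(
    apertures: ApertureMovie, hrf_kernel: np.ndarray | None = None
) -> np.ndarray:
    """Stimulus-contrast (ON/OFF) prediction: hRF-convolved mask area."""
    kernel = hrf(apertures.tr) if hrf_kernel is None else hrf_kernel
    area = apertures.area()
    return np.convolve(area, kernel)[: area.size]


def variance_explained(y: np.ndarray, yhat: np.ndarray) -> float:
    """R^2 = 1 - SSE/SStot, clipped to [0, 1]; 0 for zero-variance data."""
    if not np.all(np.isfinite(yhat)):
        raise ValueError("prediction contains non-finite values")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    ss_err = float(np.sum((y - yhat) ** 2))
    return float(np.clip(1.0 - ss_err / ss_tot, 0.0, 1.0))


def _fit_scale_offset(y: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    """Closed-form least squares of y on [p, 1]; returns (scale, offset, r2)."""
    pc = p - p.mean()
    denom = float(pc @ pc)
    if denom < 1e-300:
        # constant prediction: only the offset is identifiable
        return 0.0, float(y.mean()), 0.0 if np.ptp(y) else 0.0
    scale = float(pc @ (y - y.mean())) / denom
    offset = float(y.mean() - scale * p.mean())
    return scale, offset, variance_explained(y, scale * p + offset)


class PRFFitter:
    """Coarse-to-fine pRF fitter bound to one aperture movie.

    Precomputes the grid-stage predictions once so that many vertices can
    be fitted cheaply against the same stimulus. Grid points are ordered
    row-major in (x0, y0, sigma) with sigma fastest; ties in variance
    explained resolve to the first-encountered maximum in that order.
    """

    def __init__(
        self,
        apertures: ApertureMovie,
        grid_spec: GridSpec | None = None,
        hrf_kernel: np.ndarray | None = None,
    ):
        self.apertures = apertures
        self.grid_spec = GridSpec() if grid_spec is None else grid_spec
        self.kernel = hrf(apertures.tr) if hrf_kernel is None else hrf_kernel

        pos = self.grid_spec.positions(apertures.radius)
        sig = self.grid_spec.sigmas()
        xx, yy, ss = np.meshgrid(pos, pos, sig, indexing="ij")
        self.grid_params = np.column_stack([xx.ravel(), yy.ravel(), ss.ravel()])

        n_t = apertures.n_timepoints
        preds = np.empty((self.grid_params.shape[0], n_t))
        # chunk over sigma levels to bound the Gaussian raster memory
        n_pos = pos.size * pos.size
        for k, s in enumerate(sig):
            sel = slice(k, None, sig.size)
            overlap = prf_response_matrix(
                xx[:, :, k].ravel(), yy[:, :, k].ravel(),
                np.full(n_pos, s), apertures,
            )
            preds[sel] = np.apply_along_axis(
                lambda v: np.convolve(v, self.kernel)[:n_t], 1, overlap
            )
        self._preds = preds
        pc = preds - preds.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(pc, axis=1)
        self._flat = norms < 1e-12
        norms[self._flat] = 1.0
        self._preds_norm = pc / norms[:, None]

    # -- internal ----------------------------------------------------------

    def _predict(self, x0: float, y0: float, sigma: float) -> np.ndarray:
        overlap = prf_response_matrix(
            np.array([x0]), np.array([y0]), np.array([sigma]), self.apertures
        )[0]
        return np.convolve(overlap, self.kernel)[: overlap.size]

    def grid_stage(self, y: np.ndarray) -> tuple[int, float]:
        """Best grid index and its R^2 (first max in grid order on ties)."""
        yc = y - y.mean()
        norm = np.linalg.norm(yc)
        if norm < 1e-12:
            return 0, 0.0
        r = self._preds_norm @ (yc / norm)
        r[self._flat] = 0.0
        r2 = r * r
        idx = int(np.argmax(r2))
        return idx, float(r2[idx])

    # -- public ------------------------------------------------------------

    def fit(self, y: np.ndarray, refine_tol: float = 1e-4) -> PRFFit:
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0.0:
            mid = self.grid_spec.sigmas()[self.grid_spec.n_sigma // 2]
            return PRFFit(0.0, 0.0, float(mid), 0.0, float(y.mean()) if y.size else 0.0,
                          0.0, "prf", degenerate=True)

        idx, grid_r2 = self.grid_stage(y)
        x0, y0, sigma = self.grid_params[idx]

        # refinement stays inside the search region: centers within the
        # mapped field, sizes within the grid's log range (noisy data would
        # otherwise drift to degenerate, arbitrarily large Gaussians)
        lim = self.apertures.radius
        log_lo = np.log(self.grid_spec.sigma_min)
        log_hi = np.log(self.grid_spec.sigma_max)

        def clamp(p: np.ndarray) -> tuple[float, float, float]:
            return (
                float(np.clip(p[0], -lim, lim)),
                float(np.clip(p[1], -lim, lim)),
                float(np.exp(np.clip(p[2], log_lo, log_hi))),
            )

        def objective(p: np.ndarray) -> float:
            cx, cy, s = clamp(p)
            pred = self._predict(cx, cy, s)
            _, _, r2 = _fit_scale_offset(y, pred)
            return 1.0 - r2

        res = minimize(
            objective,
            x0=np.array([x0, y0, np.log(sigma)]),
            method="Nelder-Mead",
            options={"xatol": refine_tol, "fatol": refine_tol * 1e-2, "maxiter": 400},
        )
        rx, ry, rs = clamp(res.x)
        refined_r2 = 1.0 - float(res.fun)
        if refined_r2 < grid_r2:  # refinement never loses to the grid seed
            rx, ry, rs = float(x0), float(y0), float(sigma)

        pred = self._predict(rx, ry, rs)
        scale, offset, r2 = _fit_scale_offset(y, pred)
        return PRFFit(rx, ry, rs, scale, offset, r2, "prf")


_FITTER_CACHE: dict[tuple[int, GridSpec], PRFFitter] = {}


def fit_prf(
    y: np.ndarray,
    apertures: ApertureMovie,
    grid_spec: GridSpec | None = None,
    refine_tol: float = 1e-4,
) -> PRFFit:
    """Fit the 2D Gaussian pRF model to one PSC time series.

    Convenience wrapper around :class:`PRFFitter`; the fitter (and its
    precomputed grid predictions) is cached per aperture movie.
    """
    spec = GridSpec() if grid_spec is None else grid_spec
    key = (id(apertures), spec)
    if key not in _FITTER_CACHE:
        if len(_FITTER_CACHE) > 4:
            _FITTER_CACHE.clear()
        _FITTER_CACHE[key] = PRFFitter(apertures, spec)
    return _FITTER_CACHE[key].fit(y, refine_tol=refine_tol)


def fit_contrast(y: np.ndarray, apertures: ApertureMovie) -> PRFFit:
    """Fit the stimulus-contrast (ON/OFF) model: scale + offset only."""
    y = np.asarray(y, dtype=float)
    pred = predict_contrast(apertures)
    scale, offset, r2 = _fit_scale_offset(y, pred)
    return PRFFit(
        np.nan, np.nan, np.nan, scale, offset, r2, "contrast",
        degenerate=bool(np.ptp(y) == 0.0),
    )
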