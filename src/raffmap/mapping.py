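"""Voxel-wise TRAFF2 relaxometry fitting.

The signal after a RAFF2 preparation block of total duration ``Tp`` (ms) is
modeled by the three-parameter mono-exponential

    S(Tp) = A * exp(-Tp / TRAFF2) + B

where ``A`` and ``B`` absorb sequence effects (flip angle, repetition time,
imaging-pulse history) and are independent of the preparation duration.  The
saturation-prepared image mimics an infinitely long preparation and enters
the model as ``S = B`` exactly.  Maps are obtained by independent per-voxel
nonlinear least squares on the magnitude signal; no spatial regularization
is applied.

The module is organized statsmodels-style: :class:`Traff2Model` is built
from a :class:`WeightedSeries` and its :meth:`~Traff2Model.fit` returns a
:class:`Traff2Results` carrying the parameter maps, residual-based standard
deviation (SD) maps, convergence flags, and a ``summary()`` table.
``fit_traff2`` / ``fit_monoexp_decay`` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import gammaln


@dataclass
class WeightedSeries:
    """A stack of contrast-weighted magnitude images.

    Attributes
    ----------
    images : ndarray, shape (n_contrasts, ny, nx)
        Magnitude images.
    prep_ms : ndarray, shape (n_contrasts,)
        Per-image preparation duration in ms.  One entry should be 0
        (no preparation) and ``inf`` marks the saturation-prepared image.
    mask : ndarray of bool, shape (ny, nx), optional
        Voxels to fit; all voxels when omitted.
    """

    images: np.ndarray
    prep_ms: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.atleast_3d(np.asarray(self.images, dtype=float))
        self.prep_ms = np.asarray(self.prep_ms, dtype=float).ravel()
        if self.images.shape[0] != self.prep_ms.size:
            raise ValueError(
                f"contrast-count mismatch: {self.images.shape[0]} images vs "
                f"{self.prep_ms.size} prep_ms entries"
            )
        if np.any(self.prep_ms < 0):
            raise ValueError("prep_ms entries must be >= 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.images.shape[1:]:
                raise ValueError("mask shape must match image shape")

    @property
    def n_contrasts(self) -> int:
        return int(self.prep_ms.size)

    @property
    def shape(self) -> tuple:
        return self.images.shape[1:]

    def voxel(self, i: int, j: int) -> np.ndarray:
        return self.images[:, i, j]


# unbiasing constant for the sample SD: E[s] = c4(nu) * sigma at nu degrees
# of freedom.  With the five-contrast protocol nu = n - 3 = 2 and the raw
# residual SD is badly downward biased, so SD maps divide by c4.
def _c4(nu: int) -> float:
    if nu < 1:
        return np.nan
    return float(np.sqrt(2.0 / nu) * np.exp(gammaln((nu + 1) / 2.0) - gammaln(nu / 2.0)))


def _design(prep_ms: np.ndarray, traff2: float) -> np.ndarray:
    """Exponential regressor exp(-Tp/T) with the saturation limit exp(-inf)=0."""
    with np.errstate(over="ignore", under="ignore"):
        e = np.exp(-prep_ms / traff2)
    e[~np.isfinite(prep_ms)] = 0.0
    return e


def traff2_jacobian(a: float, traff2: float, prep_ms: np.ndarray) -> np.ndarray:
    """Jacobian of the three-parameter model wrt (A, B, TRAFF2), rows = contrasts."""
    prep_ms = np.asarray(prep_ms, dtype=float)
    e = _design(prep_ms, traff2)
    tp = np.where(np.isfinite(prep_ms), prep_ms, 0.0)
    return np.column_stack([e, np.ones_like(e), a * tp / traff2**2 * e])


def traff2_crb_sd(a: float, b: float, traff2: float, prep_ms, sigma: float) -> float:
    """Cramer-Rao lower bound on the SD of the TRAFF2 estimate (ms).

    Assumes iid Gaussian noise of standard deviation ``sigma`` on each
    contrast; ``b`` does not enter the Jacobian but is kept for signature
    clarity.
    """
    jac = traff2_jacobian(a, traff2, np.asarray(prep_ms, float))
    cov = np.linalg.inv(jac.T @ jac)
    return float(sigma * np.sqrt(cov[2, 2]))


@dataclass
class FitOptions:
    """Options for the per-voxel trust-region least-squares fit."""

    traff2_bounds: tuple = (1.0, 2000.0)
    max_nfev: int = 200
    xtol: float = 1e-8
    ftol: float = 1e-8
    min_signal: float = 1e-12


class Traff2Results:
    """Per-voxel fit results: parameter maps, SD maps, flags, summaries."""

    def __init__(self, traff2_map, a_map, b_map, residual_map, sd_map, flags,
                 prep_ms, options):
        self.traff2_map = traff2_map
        self.a_map = a_map
        self.b_map = b_map
        #: per-voxel RMS of the fit residuals (signal units)
        self.residual_map = residual_map
        #: per-voxel standard deviation of the TRAFF2 estimate, ms
        self.sd_map = sd_map
        #: dict of boolean maps: converged, at_bound, insufficient_signal
        self.flags = flags
        self.prep_ms = prep_ms
        self.options = options

    @property
    def converged(self) -> np.ndarray:
        return self.flags["converged"]

    def roi_summary(self, label_map: np.ndarray) -> pd.DataFrame:
        """Mean +/- SD of TRAFF2 (and median SD-map value) per ROI label."""
        label_map = np.asarray(label_map)
        rows = []
        for lab in np.unique(label_map):
            if lab == 0:
                continue
            sel = (label_map == lab) & self.converged
            vals = self.traff2_map[sel]
            vals = vals[np.isfinite(vals)]
            rows.append({
                "label": int(lab),
                "n_voxels": int(vals.size),
                "traff2_mean_ms": float(np.mean(vals)) if vals.size else np.nan,
                "traff2_sd_ms": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                "sd_map_median_ms": float(np.nanmedian(self.sd_map[sel])) if vals.size else np.nan,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        conv = self.converged
        vals = self.traff2_map[conv]
        vals = vals[np.isfinite(vals)]
        lines = [
            "TRAFF2 three-parameter fit",
            "==========================",
            f"contrasts (prep ms)   : {np.array2string(self.prep_ms, precision=2)}",
            f"voxels fitted         : {int(np.sum(np.isfinite(self.traff2_map)))}",
            f"voxels converged      : {int(conv.sum())}",
            f"TRAFF2 mean +/- SD    : {np.mean(vals):.2f} +/- "
            f"{np.std(vals, ddof=1) if vals.size > 1 else 0.0:.2f} ms",
            f"median SD-map value   : {np.nanmedian(self.sd_map[conv]):.3f} ms",
            f"median RMS residual   : {np.nanmedian(self.residual_map[conv]):.4g}",
        ]
        return "\n".join(lines)


class Traff2Model:
    """Three-parameter exponential relaxometry model for a weighted series.

    Parameters
    ----------
    series : WeightedSeries
        Magnitude images with per-image preparation durations (ms); at least
        three distinct durations (0 and the saturation sentinel count).
    options : FitOptions, optional

    Notes
    -----
    Initialization: B0 = saturation-image intensity when present, else the
    series minimum; A0 = S(0) - B0; TRAFF2_0 from log-linear regression of
    (S - B0) over the finite nonzero preparation times, clipped to bounds.
    Bounds: TRAFF2 in [1, 2000] ms, A and B >= 0; trust-region reflective
    least squares with analytic Jacobian.
    """

    def __init__(self, series: WeightedSeries, options: FitOptions | None = None):
        if series.n_contrasts < 3:
            raise ValueError(
                f"need >= 3 contrasts for a 3-parameter fit, got {series.n_contrasts}"
            )
        self.series = series
        self.options = options or FitOptions()

    @classmethod
    def from_arrays(cls, images, prep_ms, mask=None, **kw) -> "Traff2Model":
        return cls(WeightedSeries(images=images, prep_ms=prep_ms, mask=mask), **kw)

    # ------------------------------------------------------------------
    def _init_voxel(self, y: np.ndarray) -> tuple:
        prep = self.series.prep_ms
        opts = self.options
        sat = ~np.isfinite(prep)
        if np.any(sat):
            b0 = float(np.mean(y[sat]))
        else:
            b0 = float(np.min(y))
        b0 = max(b0, 0.0)
        zero = prep == 0
        s0 = float(np.mean(y[zero])) if np.any(zero) else float(np.max(y))
        a0 = max(s0 - b0, opts.min_signal)
        fin = np.isfinite(prep) & (prep > 0)
        resid = y[fin] - b0
        tmin, tmax = opts.traff2_bounds
        t0 = 0.25 * (tmin + tmax)
        if np.sum(resid > 0) >= 2:
            tp = prep[fin][resid > 0]
            lr = np.polyfit(tp, np.log(resid[resid > 0]), 1)
            if lr[0] < 0:
                t0 = float(np.clip(-1.0 / lr[0], tmin, tmax))
        return a0, b0, t0

    def _fit_voxel(self, y: np.ndarray):
        prep = self.series.prep_ms
        opts = self.options
        tmin, tmax = opts.traff2_bounds
        a0, b0, t0 = self._init_voxel(y)

        def resid(p):
            a, b, tr = p
            return a * _design(prep, tr) + b - y

        def jac(p):
            a, _, tr = p
            return traff2_jacobian(a, tr, prep)

        sol = least_squares(
            resid, x0=[a0, b0, t0], jac=jac,
            bounds=([0.0, 0.0, tmin], [np.inf, np.inf, tmax]),
            method="trf", xtol=opts.xtol, ftol=opts.ftol, gtol=None,
            max_nfev=opts.max_nfev,
        )
        return sol

    def fit(self) -> Traff2Results:
        series, opts = self.series, self.options
        ny, nx = series.shape
        n = series.n_contrasts
        prep = series.prep_ms
        mask = series.mask if series.mask is not None else np.ones((ny, nx), bool)

        nan = np.full((ny, nx), np.nan)
        traff2_map, a_map, b_map = nan.copy(), nan.copy(), nan.copy()
        residual_map, sd_map = nan.copy(), nan.copy()
        flags = {
            "converged": np.zeros((ny, nx), bool),
            "at_bound": np.zeros((ny, nx), bool),
            "insufficient_signal": np.zeros((ny, nx), bool),
        }
        dof = n - 3
        c4 = _c4(dof) if dof >= 1 else np.nan
        tmin, tmax = opts.traff2_bounds
        tspan = tmax - tmin

        for i, j in zip(*np.nonzero(mask)):
            y = series.images[:, i, j]
            if not np.all(np.isfinite(y)):
                flags["insufficient_signal"][i, j] = True
                continue
            scale = float(np.max(np.abs(y)))
            if scale <= opts.min_signal or np.ptp(y) <= 1e-9 * max(scale, 1.0):
                flags["insufficient_signal"][i, j] = True
                continue
            sol = self._fit_voxel(y)
            a, b, tr = sol.x
            traff2_map[i, j], a_map[i, j], b_map[i, j] = tr, a, b
            ssr = float(np.sum(sol.fun**2))
            residual_map[i, j] = np.sqrt(ssr / n)
            at_bound = (tr - tmin) < 1e-6 * tspan or (tmax - tr) < 1e-6 * tspan
            flags["at_bound"][i, j] = at_bound
            flags["converged"][i, j] = bool(sol.success) and not at_bound
            if dof >= 1:
                jacm = traff2_jacobian(a, tr, prep)
                try:
                    cov = np.linalg.inv(jacm.T @ jacm)
                    sd_map[i, j] = np.sqrt(ssr / dof * cov[2, 2]) / c4
                except np.linalg.LinAlgError:
                    pass
        return Traff2Results(traff2_map, a_map, b_map, residual_map, sd_map,
                             flags, prep, opts)


def fit_traff2(series: WeightedSeries, options: FitOptions | None = None) -> Traff2Results:
    """Voxel-wise three-parameter TRAFF2 fit (wrapper over :class:`Traff2Model`)."""
    return Traff2Model(series, options=options).fit()


def sd_map_from_residuals(fit: Traff2Results, series: WeightedSeries) -> np.ndarray:
    """Recompute the TRAFF2 SD map from the fit residuals.

    The per-voxel standard error is ``sqrt(s2 * [(J'J)^-1]_TT) / c4`` with
    residual variance ``s2 = SSR/(n-3)`` and the c4 small-sample bias
    correction of the residual SD.  Voxels with n <= 3 contrasts are
    undefined (NaN).
    """
    prep = series.prep_ms
    n = prep.size
    dof = n - 3
    sd = np.full(series.shape, np.nan)
    if dof < 1:
        return sd
    c4 = _c4(dof)
    for i, j in zip(*np.nonzero(fit.converged)):
        a, b, tr = fit.a_map[i, j], fit.b_map[i, j], fit.traff2_map[i, j]
        y = series.images[:, i, j]
        r = a * _design(prep, tr) + b - y
        ssr = float(np.sum(r**2))
        jacm = traff2_jacobian(a, tr, prep)
        try:
            cov = np.linalg.inv(jacm.T @ jacm)
        except np.linalg.LinAlgError:
            continue
        sd[i, j] = np.sqrt(ssr / dof * cov[2, 2]) / c4
    return sd


# ----------------------------------------------------------------------
# generic mono-exponential plumbing (e.g. T2-prepared mapping)

def fit_monoexp_decay(series: WeightedSeries, n_params: int = 2,
                      t_bounds: tuple = (1.0, 2000.0)) -> Traff2Results:
    """Generic two- or three-parameter mono-exponential decay fit.

    ``n_params=2`` fits ``S = A*exp(-Tp/T)`` (B pinned at 0), ``n_params=3``
    is the full offset model (same engine as :func:`fit_traff2`).  Results
    reuse :class:`Traff2Results`; ``traff2_map`` holds the generic decay
    time.
    """
    if n_params not in (2, 3):
        raise ValueError("n_params must be 2 or 3")
    if series.n_contrasts < n_params:
        raise ValueError(
            f"need >= {n_params} contrasts for a {n_params}-parameter fit, "
            f"got {series.n_contrasts}"
        )
    if n_params == 3:
        return fit_traff2(series, options=FitOptions(traff2_bounds=t_bounds))

    prep = series.prep_ms
    ny, nx = series.shape
    mask = series.mask if series.mask is not None else np.ones((ny, nx), bool)
    nan = np.full((ny, nx), np.nan)
    t_map, a_map = nan.copy(), nan.copy()
    residual_map, sd_map = nan.copy(), nan.copy()
    flags = {
        "converged": np.zeros((ny, nx), bool),
        "at_bound": np.zeros((ny, nx), bool),
        "insufficient_signal": np.zeros((ny, nx), bool),
    }
    tmin, tmax = t_bounds
    n = prep.size
    for i, j in zip(*np.nonzero(mask)):
        y = series.images[:, i, j]
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) <= 1e-12:
            flags["insufficient_signal"][i, j] = True
            continue
        t0, a0 = loglinear_decay_init(prep, y, t_bounds)

        def resid(p):
            a, tr = p
            return a * _design(prep, tr) - y

        def jac(p):
            a, tr = p
            e = _design(prep, tr)
            tp = np.where(np.isfinite(prep), prep, 0.0)
            return np.column_stack([e, a * tp / tr**2 * e])

        sol = least_squares(resid, x0=[a0, t0], jac=jac,
                            bounds=([0.0, tmin], [np.inf, tmax]), method="trf",
                            xtol=1e-10, ftol=1e-10, gtol=None)
        a, tr = sol.x
        t_map[i, j], a_map[i, j] = tr, a
        residual_map[i, j] = np.sqrt(np.sum(sol.fun**2) / n)
        at_bound = (tr - tmin) < 1e-6 * (tmax - tmin) or (tmax - tr) < 1e-6 * (tmax - tmin)
        flags["at_bound"][i, j] = at_bound
        flags["converged"][i, j] = bool(sol.success) and not at_bound
    return Traff2Results(t_map, a_map, np.zeros((ny, nx)), residual_map, sd_map,
                         flags, prep, FitOptions(traff2_bounds=t_bounds))


def loglinear_decay_init(prep_ms: np.ndarray, y: np.ndarray, t_bounds=(1.0, 2000.0)):
    """Closed-form log-linear initializer for the 2-parameter decay fit."""
    fin = np.isfinite(prep_ms) & (y > 0)
    tmin, tmax = t_bounds
    if np.sum(fin) >= 2:
        slope, intercept = np.polyfit(prep_ms[fin], np.log(y[fin]), 1)
        if slope < 0:
            return float(np.clip(-1.0 / slope, tmin, tmax)), float(np.exp(intercept))
    return 0.25 * (tmin + tmax), float(np.max(y))
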