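"""Coverage correction and cross-sample normalization.

GC bias is removed per sample with a penalized-spline generalized linear
model (Tweedie variance with power 1.5, log link — variance grows as
mu^1.5, between Poisson and gamma, a good fit for binned read counts).
Residuals carry the copy-number signal.  Bins are then filtered on
mappability and GC, and samples are quantile-normalized onto a common
marginal distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "GcCorrectionModel",
    "fit_gc_correction",
    "filter_bins",
    "quantile_normalize",
]


@dataclass
class GcCorrectionModel:
    """Fitted GC-bias model for one sample.

    ``residuals`` are observed − fitted on the response scale by default
    (``resid_deviance`` holds deviance residuals); ``corrected`` adds the
    mean fitted level back so the values stay on the coverage scale and
    positive in expectation, ready for ratio computation.
    """

    link: str
    var_power: float
    fitted: np.ndarray
    residuals: np.ndarray
    resid_deviance: np.ndarray
    corrected: np.ndarray
    edf: float

    def gc_decorrelation(self, gc: np.ndarray) -> float:
        """Spearman correlation between residuals and GC (should be ~0)."""
        return float(stats.spearmanr(self.residuals, gc).statistic)


def fit_gc_correction(values: np.ndarray, gc: np.ndarray, df: int = 10,
                      var_power: float = 1.5, alpha: float = 0.0,
                      max_iter: int = 100) -> GcCorrectionModel:
    """Fit coverage ~ s(GC) with a Tweedie GLM (log link, variance mu^p).

    The smooth is a cubic B-spline basis of ``df`` columns with a
    second-derivative penalty of weight ``alpha``, fitted by iteratively
    reweighted least squares.  A constant GC track degenerates gracefully to
    an intercept-only fit (residuals = values − mean).
    """
    values = np.asarray(values, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if values.shape != gc.shape:
        raise ValueError("coverage and GC tracks differ in length")
    if np.nanmax(values) <= 0:
        raise ValueError("all-zero coverage: nothing to fit")
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")

    if np.ptp(gc) < 1e-9:
        # no covariate variation: fitted curve is the intercept
        fitted = np.full_like(values, values.mean())
        resid = values - fitted
        return GcCorrectionModel(
            link="log", var_power=var_power, fitted=fitted, residuals=resid,
            resid_deviance=resid / np.sqrt(np.maximum(fitted, 1e-9) ** var_power),
            corrected=values.copy(), edf=1.0,
        )

    family = sm.families.Tweedie(var_power=var_power,
                                 link=sm.families.links.Log())
    # spline over the empirical GC quantile (rank) rather than raw GC: a
    # monotone reparameterization that places knots at data quantiles, so
    # every basis interval is equally populated and the fit cannot wiggle
    # in data-sparse GC ranges
    u = (stats.rankdata(gc, method="average") - 0.5) / len(gc)
    smoother = BSplines(u[:, None], df=[df], degree=[3])
    model = GLMGam(values, np.ones((len(values), 1)), smoother=smoother,
                   family=family, alpha=[alpha])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=max_iter)
        except Exception as exc:  # pragma: no cover - IRLS failure path
            raise RuntimeError(f"GC-correction IRLS did not converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError(
            f"GC-correction IRLS did not converge within {max_iter} iterations "
            f"(deviance trace tail: {res.fit_history['deviance'][-3:]})"
        )
    fitted = np.asarray(res.fittedvalues)
    if np.any(fitted <= 0):
        raise RuntimeError("GC fit produced non-positive fitted means")
    resid = values - fitted
    corrected = np.maximum(resid + fitted.mean(), 0.0)
    return GcCorrectionModel(
        link="log", var_power=var_power, fitted=fitted, residuals=resid,
        resid_deviance=np.asarray(res.resid_deviance), corrected=corrected,
        edf=float(res.edf.sum()) if np.ndim(res.edf) else float(res.edf),
    )


def filter_bins(mappability: np.ndarray, gc: np.ndarray,
                gc_quantile: float = 0.08) -> np.ndarray:
    """Shared kept-bin mask: drop zero-mappability bins, then low-GC bins.

    GC filtering removes bins whose GC is strictly below the ``gc_quantile``
    quantile of GC over the bins that survive the mappability rule (strict
    "<", so a degenerate all-tied GC track loses nothing to this rule).
    Returns a boolean mask over the full grid.
    """
    mappability = np.asarray(mappability, dtype=float)
    gc = np.asarray(gc, dtype=float)
    kept = mappability > 0
    if kept.any():
        q = np.quantile(gc[kept], gc_quantile)
        kept = kept & ~(gc < q)  # strict "below" comparison
    if not kept.any():
        raise ValueError("bin filtering removed every bin")
    return kept


def quantile_normalize(matrix: np.ndarray,
                       sample_ids: list | None = None) -> np.ndarray:
    """Classic quantile normalization of a bins × samples matrix.

    Each sample's sorted values are replaced by the across-sample mean of
    sorted values and restored to the original bin order; ties receive the
    average of the reference values over the tied ranks.  Afterwards every
    column has an identical marginal distribution.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a bins x samples matrix with >= 2 samples")
    if np.isnan(X).any():
        bad = np.argwhere(np.isnan(X))[0]
        sid = sample_ids[bad[1]] if sample_ids else f"column {bad[1]}"
        raise ValueError(f"NaN coverage in sample {sid} at bin {bad[0]}")
    n, m = X.shape
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        ranks = stats.rankdata(X[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return out
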