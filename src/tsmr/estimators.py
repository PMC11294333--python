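"""Causal-effect estimators on harmonized summary statistics.

Every method consumes per-SNP pairs (beta_exp, se_exp, beta_out, se_out)
of effects expressed on the same effect allele and returns an estimate of
the causal slope theta in beta_out = theta * beta_exp.

* Wald ratio — beta_out/beta_exp per SNP, SE by the first-order delta
  method (se_out/|beta_exp|).
* IVW — inverse-variance-weighted mean of the ratios with weights
  w_j = beta_exp_j²/se_out_j²; identical to weighted least squares of
  beta_out on beta_exp through the origin.  The fixed-effects SE is
  (Σw)^(−1/2); the multiplicative random-effects SE scales it by
  max(1, sqrt(Q/(k−1))); "auto" picks fixed when Cochran's Q p > 0.05.
* MR-Egger — the same regression with an intercept, which absorbs average
  directional pleiotropy; SNPs are oriented so beta_exp ≥ 0 first, the
  residual scale is floored at 1, and p-values use t with k−2 df.
* Weighted/simple median — the ratio at 50% cumulative weight, consistent
  when at least half the weight comes from valid instruments; SE by a
  seeded parametric bootstrap.
* Simple/weighted mode — the peak of a normal-kernel density over the
  ratios (ZEMPA assumption: the largest group of instruments is valid).

The estimator classes follow the scikit-learn protocol (``fit``,
``get_params``/``set_params``, trailing-underscore fitted attributes);
the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datatypes import MrEstimate, Z95, two_sided_p
from .exceptions import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
    ValidationError,
)

HARMONIZED_NUMERIC = ("beta_exp", "se_exp", "beta_out", "se_out")


def unpack_harmonized(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (beta_exp, se_exp, beta_out, se_out) arrays.

    Accepts a harmonized DataFrame (by column name) or an array of shape
    (k, 4) in that column order.
    """
    if isinstance(X, pd.DataFrame):
        missing = [c for c in HARMONIZED_NUMERIC if c not in X.columns]
        if missing:
            raise ValidationError(f"missing harmonized columns: {missing}")
        arrs = tuple(X[c].to_numpy(dtype=float) for c in HARMONIZED_NUMERIC)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValidationError(
                "expected a harmonized frame or an array of shape (k, 4)"
            )
        arrs = (arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
    bx, sx, by, sy = arrs
    if not np.all(np.isfinite(bx) & np.isfinite(by)):
        raise ValidationError("non-finite effect size")
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValidationError("standard errors must be > 0")
    return bx, sx, by, sy


def _require(k: int, minimum: int, method: str) -> None:
    if k < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {minimum} SNPs, got {k}"
        )


def _ratios(bx: np.ndarray, by: np.ndarray) -> np.ndarray:
    if np.any(bx == 0):
        raise UndefinedRatioError("beta_exp == 0: Wald ratio undefined")
    return by / bx


def wald_ratio(record) -> MrEstimate:
    """Single-SNP causal estimate beta_out/beta_exp.

    SE by the first-order delta method, se_out/|beta_exp| (adequate at the
    F > 10 instrument strength enforced upstream).
    """
    if isinstance(record, pd.DataFrame):
        if len(record) != 1:
            raise ValidationError("wald_ratio takes exactly one record")
        record = record.iloc[0]
    bx, by, sy = (float(record["beta_exp"]), float(record["beta_out"]),
                  float(record["se_out"]))
    if bx == 0:
        raise UndefinedRatioError("beta_exp == 0: Wald ratio undefined")
    return MrEstimate.from_beta_se("wald_ratio", by / bx, sy / abs(bx), nsnp=1)


class _SummaryMr(BaseEstimator):
    """Shared plumbing for summary-data MR estimators."""

    _method = "mr"

    def _set_common(self, beta: float, se: float, k: int,
                    dist: str = "normal", df: int | None = None, **extra):
        est = MrEstimate.from_beta_se(self._method, beta, se, nsnp=k,
                                      dist=dist, df=df, **extra)
        self.beta_ = est.beta
        self.se_ = est.se
        self.ci_low_ = est.ci_low
        self.ci_high_ = est.ci_high
        self.pval_ = est.pval
        self.nsnp_ = est.nsnp
        self.estimate_ = est
        return est


class IVW(_SummaryMr):
    """Inverse-variance-weighted estimator.

    Parameters
    ----------
    model : {"fixed", "random", "auto"}
        SE model.  "auto" applies the Cochran's Q rule: fixed effects when
        the Q p-value exceeds 0.05, multiplicative random effects
        otherwise.  The point estimate is identical under both.
    """

    _method = "ivw"

    def __init__(self, model: str = "auto"):
        self.model = model

    def fit(self, X, y=None):
        if self.model not in ("fixed", "random", "auto"):
            raise ValidationError("model must be fixed, random or auto")
        bx, sx, by, sy = unpack_harmonized(X)
        k = len(bx)
        _require(k, 2, "IVW")
        ratio = _ratios(bx, by)
        w = bx**2 / sy**2
        beta = float(np.sum(w * ratio) / np.sum(w))
        se_fixed = float(np.sum(w) ** -0.5)
        q = float(np.sum(w * (ratio - beta) ** 2))
        q_df = k - 1
        q_pval = float(stats.chi2.sf(q, q_df))
        if self.model == "auto":
            model_used = "fixed" if q_pval > 0.05 else "random"
        else:
            model_used = self.model
        scale = max(1.0, math.sqrt(q / q_df)) if model_used == "random" else 1.0
        self.q_, self.q_df_, self.q_pval_ = q, q_df, q_pval
        self.model_used_ = model_used
        self.se_fixed_ = se_fixed
        self._set_common(beta, se_fixed * scale, k, model=model_used)
        return self


class MREgger(_SummaryMr):
    """MR-Egger regression: weighted fit of beta_out on beta_exp with an
    intercept capturing average directional pleiotropy.

    Fitted attributes include ``intercept_``, ``intercept_se_`` and
    ``intercept_pval_`` alongside the slope (``beta_`` etc.).
    """

    _method = "mr_egger"

    def fit(self, X, y=None):
        bx, sx, by, sy = unpack_harmonized(X)
        k = len(bx)
        _require(k, 3, "MR-Egger")
        # orient so exposure effects are non-negative (InSIDE convention)
        sign = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * sign, by * sign
        if np.allclose(bxo, bxo[0]):
            raise ValidationError(
                "singular design: no variation in |beta_exp|"
            )
        w = 1.0 / sy**2
        design = np.column_stack([np.ones(k), bxo])
        xtw = design.T * w
        a = xtw @ design
        coef = np.linalg.solve(a, xtw @ byo)
        resid = byo - design @ coef
        rss = float(np.sum(w * resid**2))
        scale = max(1.0, rss / (k - 2))
        cov = scale * np.linalg.inv(a)
        intercept, slope = float(coef[0]), float(coef[1])
        se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        self.intercept_ = intercept
        self.intercept_se_ = se_int
        self.intercept_pval_ = float(2 * stats.t.sf(abs(intercept / se_int), k - 2))
        self.rss_ = rss
        self.scale_ = scale
        self._set_common(
            slope, se_slope, k, dist="t", df=k - 2,
            intercept=intercept, intercept_se=se_int,
            intercept_pval=self.intercept_pval_,
        )
        return self


def _weighted_median(ratio: np.ndarray, w: np.ndarray) -> float:
    """Interpolated 50%-cumulative-weight point of the sorted ratios."""
    order = np.argsort(ratio, kind="stable")
    r, ww = ratio[order], w[order]
    s = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    return float(np.interp(0.5, s, r))


class WeightedMedian(_SummaryMr):
    """Weighted (or simple) median estimator.

    ``weights="inverse-variance"`` uses 1/var of each Wald ratio
    (first-order delta method, matching IVW); ``weights="equal"`` gives
    the simple median.  The SE is the standard deviation of the estimate
    over ``n_boot`` parametric-bootstrap resamples of (beta_exp, beta_out).
    """

    _method = "weighted_median"

    def __init__(self, weights: str = "inverse-variance",
                 n_boot: int = 1000, seed: int = 0):
        self.weights = weights
        self.n_boot = n_boot
        self.seed = seed

    def _weights(self, bx, sy):
        if self.weights == "equal":
            return np.ones_like(bx)
        if self.weights != "inverse-variance":
            raise ValidationError("weights must be 'inverse-variance' or 'equal'")
        return bx**2 / sy**2

    def fit(self, X, y=None):
        bx, sx, by, sy = unpack_harmonized(X)
        k = len(bx)
        _require(k, 3, "weighted median")
        ratio = _ratios(bx, by)
        beta = _weighted_median(ratio, self._weights(bx, sy))
        rng = np.random.default_rng(self.seed)
        boot = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxs = bx + sx * rng.standard_normal(k)
            bys = by + sy * rng.standard_normal(k)
            bxs[bxs == 0] = np.finfo(float).tiny  # guard degenerate draw
            boot[b] = _weighted_median(bys / bxs, self._weights(bxs, sy))
        se = float(np.std(boot, ddof=1))
        method = "simple_median" if self.weights == "equal" else "weighted_median"
        self._method = method
        self._set_common(beta, se, k)
        return self


def _mode_bandwidth(ratio: np.ndarray, phi: float) -> float:
    """phi * 0.9 * min(sd, MAD/0.6745) * k^(-1/5).

    MAD = 0 with positive spread would zero the bandwidth, so the sd is
    used alone in that case; bandwidth 0 only for identical ratios.
    """
    k = len(ratio)
    sd = float(np.std(ratio, ddof=1))
    mad = float(np.median(np.abs(ratio - np.median(ratio)))) / 0.6745
    spread = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * spread * k ** (-0.2)


def _kde_mode(ratio: np.ndarray, w: np.ndarray, h: float) -> float:
    """Argmax of the weighted normal-kernel density."""
    w = w / np.sum(w)

    def dens(x):
        return np.sum(w * np.exp(-0.5 * ((x - ratio) / h) ** 2), axis=-1)

    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, 2048)
    vals = dens(grid[:, None])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda x: -dens(np.array([x])),
                                   bounds=(lo, hi), method="bounded")
    return float(res.x)


class ModeEstimator(_SummaryMr):
    """Mode-based estimator (simple or weighted kernel-density mode).

    ``phi`` scales the kernel bandwidth (default 1).  If every ratio is
    identical the bandwidth is zero; the common ratio is returned with
    SE 0 and ``degenerate_ = True``.
    """

    _method = "mode"

    def __init__(self, kind: str = "weighted", phi: float = 1.0,
                 n_boot: int = 1000, seed: int = 0):
        self.kind = kind
        self.phi = phi
        self.n_boot = n_boot
        self.seed = seed

    def _weights(self, bx, sy):
        if self.kind == "simple":
            return np.ones_like(bx)
        if self.kind != "weighted":
            raise ValidationError("kind must be 'simple' or 'weighted'")
        return bx**2 / sy**2

    def fit(self, X, y=None):
        if self.phi <= 0:
            raise ValidationError("phi must be positive")
        bx, sx, by, sy = unpack_harmonized(X)
        k = len(bx)
        _require(k, 3, "mode estimator")
        ratio = _ratios(bx, by)
        self._method = f"{self.kind}_mode"
        h = _mode_bandwidth(ratio, self.phi)
        if h == 0:
            self.degenerate_ = True
            self._set_common(float(ratio[0]), 0.0, k)
            return self
        self.degenerate_ = False
        beta = _kde_mode(ratio, self._weights(bx, sy), h)
        rng = np.random.default_rng(self.seed)
        boot = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxs = bx + sx * rng.standard_normal(k)
            bys = by + sy * rng.standard_normal(k)
            bxs[bxs == 0] = np.finfo(float).tiny
            rb = bys / bxs
            hb = _mode_bandwidth(rb, self.phi)
            if hb == 0:
                boot[b] = float(rb[0])
            else:
                boot[b] = _kde_mode(rb, self._weights(bxs, sy), hb)
        se = float(np.std(boot, ddof=1))
        self._set_common(beta, se, k)
        return self


# ---------------------------------------------------------------------------
# functional wrappers

def ivw(records, model: str = "auto") -> MrEstimate:
    """IVW estimate; see :class:`IVW`."""
    return IVW(model=model).fit(records).estimate_


def mr_egger(records) -> MrEstimate:
    """MR-Egger slope + intercept; see :class:`MREgger`."""
    return MREgger().fit(records).estimate_


def weighted_median(records, weights: str = "inverse-variance",
                    n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted-median estimate; see :class:`WeightedMedian`."""
    return WeightedMedian(weights=weights, n_boot=n_boot, seed=seed).fit(
        records).estimate_


def mode_estimators(records, kind: str = "weighted", phi: float = 1.0,
                    n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Mode-based estimate; see :class:`ModeEstimator`."""
    return ModeEstimator(kind=kind, phi=phi, n_boot=n_boot, seed=seed).fit(
        records).estimate_
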