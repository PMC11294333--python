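"""MR-PRESSO: pleiotropy residual sum and outlier test.

Three nested tests on the harmonized per-SNP effects:

* **Global test** — the observed leave-one-out residual sum of squares,
  RSS = Σ_j (beta_out_j − beta_loo(−j)·beta_exp_j)² / se_out_j², compared
  against its parametric null distribution: in each of ``nb_distribution``
  replicates both exposure and outcome betas are redrawn from normals
  centred on (beta_exp_j, beta_loo(−j)·beta_exp_j) and the RSS recomputed
  identically.  p = (1 + #{RSS* ≥ RSS_obs}) / (nb + 1) — the add-one form,
  so p is never exactly 0.
* **Outlier test** — the same comparison per SNP residual; SNPs whose
  Bonferroni-adjusted p falls below the significance threshold
  (p < threshold/k) are flagged as pleiotropic outliers.
* **Distortion test** — how much (in percent) removing the outliers moves
  the IVW estimate, referenced to removing random same-size subsets of
  inliers.

All randomness flows from a single seed; a fixed seed makes the whole
result bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MrEstimate
from .estimators import IVW, unpack_harmonized, _ratios
from .exceptions import InsufficientInstrumentsError, ValidationError
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class PressoConfig:
    """Simulation settings for MR-PRESSO."""

    nb_distribution: int = 3000
    signif_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.nb_distribution < 100:
            raise ValidationError("nb_distribution must be >= 100")
        if not (0 < self.signif_threshold < 1):
            raise ValidationError("signif_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class PressoResult:
    rss_observed: float
    global_pval: float
    per_snp_pval: tuple[float, ...]
    outlier_indices: tuple[str, ...]
    corrected_estimate: MrEstimate | None
    distortion_coefficient: float | None   # percent shift of the IVW slope
    distortion_pval: float | None

    def to_dict(self) -> dict:
        return {
            "rss_observed": self.rss_observed,
            "global_pval": self.global_pval,
            "per_snp_pval": list(self.per_snp_pval),
            "outlier_indices": list(self.outlier_indices),
            "corrected_estimate": (None if self.corrected_estimate is None
                                   else self.corrected_estimate.to_dict()),
            "distortion_coefficient": self.distortion_coefficient,
            "distortion_pval": self.distortion_pval,
        }


def _loo_slopes(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """IVW slope omitting each SNP, vectorised.

    Works on 1-d arrays or on (nb, k) replicate matrices (sy broadcast).
    """
    w = bx**2 / sy**2
    ratio = by / bx
    sw = np.sum(w, axis=-1, keepdims=True)
    swr = np.sum(w * ratio, axis=-1, keepdims=True)
    return (swr - w * ratio) / (sw - w)


def _rss_terms(bx, by, sy):
    slopes = _loo_slopes(bx, by, sy)
    return (by - slopes * bx) ** 2 / sy**2


def _distortion(arr: np.ndarray, outlier_mask: np.ndarray, nb: int,
                rng: np.random.Generator):
    """Corrected IVW estimate, percent distortion, and its null p-value.

    The null compares the observed shift to shifts from excluding random
    inlier subsets of the same size as the outlier set.
    """
    full_beta = IVW(model="auto").fit(arr).estimate_.beta
    inlier_idx = np.flatnonzero(~outlier_mask)
    n_out = int(outlier_mask.sum())
    if n_out == 0:
        corrected = IVW(model="auto").fit(arr).estimate_
        return corrected, 0.0, 1.0
    if len(inlier_idx) < 2:
        raise InsufficientInstrumentsError("fewer than 2 non-outlier SNPs remain")
    corrected = IVW(model="auto").fit(arr[inlier_idx]).estimate_
    coef_obs = 100.0 * (corrected.beta - full_beta) / abs(full_beta)
    draws = np.empty(nb)
    for b in range(nb):
        drop = rng.choice(inlier_idx, size=n_out, replace=False)
        keep = np.setdiff1d(inlier_idx, drop)
        sub_beta = IVW(model="fixed").fit(arr[keep]).estimate_.beta
        draws[b] = 100.0 * (sub_beta - full_beta) / abs(full_beta)
    # add-one form keeps the p-value in (0, 1] at finite nb
    pval = float((1 + np.sum(np.abs(draws) >= abs(coef_obs))) / (nb + 1))
    return corrected, float(coef_obs), pval


class MRPRESSO(BaseEstimator):
    """Run the full MR-PRESSO procedure on harmonized records.

    Fitted attributes: ``rss_observed_``, ``global_pval_``,
    ``per_snp_pval_``, ``outlier_mask_``, ``outlier_snps_``,
    ``corrected_estimate_``, ``distortion_coefficient_``,
    ``distortion_pval_`` and the assembled ``result_``.
    """

    def __init__(self, nb_distribution: int = 3000,
                 signif_threshold: float = 0.05, seed: int = 0):
        self.nb_distribution = nb_distribution
        self.signif_threshold = signif_threshold
        self.seed = seed

    def fit(self, X, y=None):
        PressoConfig(self.nb_distribution, self.signif_threshold, self.seed)
        bx, sx, by, sy = unpack_harmonized(X)
        k = len(bx)
        if k < 4:
            raise InsufficientInstrumentsError(
                f"MR-PRESSO needs at least 4 SNPs, got {k}"
            )
        _ratios(bx, by)  # reject beta_exp == 0
        if isinstance(X, pd.DataFrame) and "snp_id" in X.columns:
            ids = X["snp_id"].astype(str).to_numpy()
        else:
            ids = np.array([str(i) for i in range(k)])

        nb = self.nb_distribution
        rng = np.random.default_rng(self.seed)

        obs_terms = _rss_terms(bx, by, sy)
        rss_obs = float(np.sum(obs_terms))
        expected_out = _loo_slopes(bx, by, sy) * bx

        bx_star = bx + sx * rng.standard_normal((nb, k))
        by_star = expected_out + sy * rng.standard_normal((nb, k))
        bx_star[bx_star == 0] = np.finfo(float).tiny
        star_terms = _rss_terms(bx_star, by_star, sy)
        rss_star = star_terms.sum(axis=1)

        self.rss_observed_ = rss_obs
        self.global_pval_ = float((1 + np.sum(rss_star >= rss_obs)) / (nb + 1))
        self.per_snp_pval_ = (1 + np.sum(star_terms >= obs_terms, axis=0)) / (nb + 1)
        self.outlier_mask_ = self.per_snp_pval_ < self.signif_threshold / k
        self.outlier_snps_ = tuple(ids[self.outlier_mask_])

        # distortion test ---------------------------------------------------
        arr = np.column_stack([bx, sx, by, sy])
        (self.corrected_estimate_, self.distortion_coefficient_,
         self.distortion_pval_) = _distortion(arr, self.outlier_mask_, nb, rng)

        self.result_ = PressoResult(
            rss_observed=self.rss_observed_,
            global_pval=self.global_pval_,
            per_snp_pval=tuple(float(p) for p in self.per_snp_pval_),
            outlier_indices=self.outlier_snps_,
            corrected_estimate=self.corrected_estimate_,
            distortion_coefficient=self.distortion_coefficient_,
            distortion_pval=self.distortion_pval_,
        )
        return self


# ---------------------------------------------------------------------------
# functional wrappers mirroring the three published sub-tests

def presso_global(records, config: PressoConfig | None = None):
    """(rss_observed, global_pval)."""
    config = config or PressoConfig()
    m = MRPRESSO(config.nb_distribution, config.signif_threshold,
                 config.seed).fit(records)
    return m.rss_observed_, m.global_pval_


def presso_outliers(records, config: PressoConfig | None = None):
    """(per_snp_pval, outlier snp ids)."""
    config = config or PressoConfig()
    m = MRPRESSO(config.nb_distribution, config.signif_threshold,
                 config.seed).fit(records)
    return m.per_snp_pval_, list(m.outlier_snps_)


def presso_distortion(records, outlier_indices,
                      config: PressoConfig | None = None):
    """Distortion test for an explicit outlier set.

    Returns (corrected_estimate, distortion_coefficient, distortion_pval).
    """
    config = config or PressoConfig()
    bx, sx, by, sy = unpack_harmonized(records)
    if isinstance(records, pd.DataFrame) and "snp_id" in records.columns:
        ids = records["snp_id"].astype(str).to_numpy()
    else:
        ids = np.array([str(i) for i in range(len(bx))])
    unknown = set(map(str, outlier_indices)) - set(ids)
    if unknown:
        raise ValidationError(f"outlier ids not in input: {sorted(unknown)}")
    mask = np.isin(ids, list(map(str, outlier_indices)))
    arr = np.column_stack([bx, sx, by, sy])
    rng = np.random.default_rng(config.seed)
    return _distortion(arr, mask, config.nb_distribution, rng)


def run_presso(records, config: PressoConfig | None = None) -> PressoResult:
    """Full three-part MR-PRESSO result."""
    config = config or PressoConfig()
    return MRPRESSO(config.nb_distribution, config.signif_threshold,
                    config.seed).fit(records).result_
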