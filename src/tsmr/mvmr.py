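"""Multivariable MR: joint regression of outcome effects on several
exposures' SNP effects.

With p exposures and k SNPs, the outcome betas are regressed on the k×p
exposure-beta matrix (weights 1/se_out², no intercept for IVW, with an
intercept for the Egger variant).  Each coefficient is the direct effect
of its exposure on the outcome holding the others fixed, which is how
measured pleiotropic pathways (smoking, BMI, ...) are adjusted away.

Instrument strength per exposure is *conditional*: the exposure's betas
are first residualised on the other exposures' betas, and the total-F
formula is applied to the residuals — a strongly instrumented exposure
that merely duplicates another contributes no conditional strength.
Cross-exposure sampling covariance of the SNP effects is taken as zero
(the exposures come from separate GWAS samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import MrEstimate, Z95, two_sided_p
from .estimators import IVW
from .exceptions import CollinearityError, ValidationError
from .instruments import total_f_from_r2


@dataclass
class MvmrDataset:
    """Row-aligned multi-exposure summary data.

    ``exposure_eafs`` (k×p) and ``exposure_n`` (per exposure) are optional
    and only needed for conditional instrument strength.
    """

    snp_ids: list[str]
    exposure_betas: np.ndarray      # k x p
    exposure_ses: np.ndarray        # k x p
    outcome_beta: np.ndarray        # k
    outcome_se: np.ndarray          # k
    exposure_labels: list[str]
    exposure_eafs: np.ndarray | None = None
    exposure_n: np.ndarray | None = None

    def __post_init__(self):
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        self.outcome_beta = np.asarray(self.outcome_beta, float)
        self.outcome_se = np.asarray(self.outcome_se, float)
        k, p = self.exposure_betas.shape
        if self.exposure_ses.shape != (k, p):
            raise ValidationError("exposure_ses shape mismatch")
        if len(self.snp_ids) != k or len(self.outcome_beta) != k \
                or len(self.outcome_se) != k:
            raise ValidationError("rows not aligned to snp_ids")
        if len(self.exposure_labels) != p:
            raise ValidationError("need one label per exposure")
        if k < p + 2:
            raise ValidationError(f"need at least p+2={p + 2} SNPs, got {k}")
        if np.any(self.outcome_se <= 0) or np.any(self.exposure_ses <= 0):
            raise ValidationError("standard errors must be > 0")
        if self.exposure_eafs is not None:
            self.exposure_eafs = np.atleast_2d(np.asarray(self.exposure_eafs, float))
            if self.exposure_eafs.shape != (k, p):
                raise ValidationError("exposure_eafs shape mismatch")
        if self.exposure_n is not None:
            self.exposure_n = np.asarray(self.exposure_n, float)
            if self.exposure_n.shape != (p,):
                raise ValidationError("exposure_n must have one entry per exposure")

    @property
    def k(self) -> int:
        return self.exposure_betas.shape[0]

    @property
    def p(self) -> int:
        return self.exposure_betas.shape[1]


@dataclass(frozen=True)
class MvmrResult:
    """Per-exposure adjusted estimates plus joint diagnostics."""

    method: str
    estimates: tuple[MrEstimate, ...]       # one per exposure
    q: float
    q_df: int
    q_pval: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    conditional_f: tuple[float, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([e.to_dict() for e in self.estimates])
        df.insert(0, "exposure", [e.method.split(":", 1)[1] for e in self.estimates])
        df["method"] = self.method
        df["q"] = self.q
        df["q_pval"] = self.q_pval
        df["mv_intercept"] = np.nan if self.intercept is None else self.intercept
        df["mv_intercept_pval"] = (np.nan if self.intercept_pval is None
                                   else self.intercept_pval)
        if self.conditional_f is not None:
            df["conditional_f"] = list(self.conditional_f)
        for col in ("intercept", "intercept_se", "intercept_pval", "model"):
            if col in df and df[col].isna().all():
                df = df.drop(columns=col)
        return df


def _check_rank(design: np.ndarray, labels: list[str]) -> None:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            "rank-deficient design among exposures: " + ", ".join(labels)
        )


class _MvmrBase(BaseEstimator):
    _with_intercept = False
    _method = "mvmr_ivw"

    def fit(self, data: MvmrDataset, y=None):
        k, p = data.k, data.p
        if self._with_intercept and k < p + 3:
            raise ValidationError(f"Egger variant needs at least p+3 SNPs")
        bX = data.exposure_betas.copy()
        by = data.outcome_beta.copy()
        if self._with_intercept:
            # orient each SNP so the first exposure's beta is non-negative
            sign = np.where(bX[:, 0] < 0, -1.0, 1.0)
            bX = bX * sign[:, None]
            by = by * sign
        w = 1.0 / data.outcome_se**2
        design = (np.column_stack([np.ones(k), bX])
                  if self._with_intercept else bX)
        _check_rank(design * np.sqrt(w)[:, None], data.exposure_labels)
        xtw = design.T * w
        a = xtw @ design
        coef = np.linalg.solve(a, xtw @ by)
        resid = by - design @ coef
        q = float(np.sum(w * resid**2))
        df = k - design.shape[1]
        scale = max(1.0, q / df)
        cov = scale * np.linalg.inv(a)
        ses = np.sqrt(np.diag(cov))
        offset = 1 if self._with_intercept else 0
        dist = "t" if self._with_intercept else "normal"
        estimates = tuple(
            MrEstimate.from_beta_se(
                f"{self._method}:{label}", coef[offset + i], ses[offset + i],
                nsnp=k, dist=dist, df=df,
            )
            for i, label in enumerate(data.exposure_labels)
        )
        self.coefs_ = coef[offset:]
        self.ses_ = ses[offset:]
        self.q_ = q
        self.q_df_ = df
        self.q_pval_ = float(stats.chi2.sf(q, df))
        self.scale_ = scale
        if self._with_intercept:
            self.intercept_ = float(coef[0])
            self.intercept_se_ = float(ses[0])
            self.intercept_pval_ = float(
                2 * stats.t.sf(abs(coef[0] / ses[0]), df)
            )
        else:
            self.intercept_ = self.intercept_se_ = self.intercept_pval_ = None
        cond_f = None
        if data.exposure_eafs is not None and data.exposure_n is not None:
            cond_f = tuple(conditional_f(data))
        self.conditional_f_ = cond_f
        self.result_ = MvmrResult(
            method=self._method,
            estimates=estimates,
            q=q, q_df=df, q_pval=self.q_pval_,
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_pval=self.intercept_pval_,
            conditional_f=cond_f,
        )
        return self


class MVMRIVW(_MvmrBase):
    """Multivariable IVW: origin-constrained weighted multiple regression."""

    _with_intercept = False
    _method = "mvmr_ivw"


class MVMREgger(_MvmrBase):
    """Multivariable Egger: adds an intercept as the joint pleiotropy check."""

    _with_intercept = True
    _method = "mvmr_egger"


def mvmr_ivw(data: MvmrDataset) -> MvmrResult:
    """Multivariable IVW result; see :class:`MVMRIVW`."""
    return MVMRIVW().fit(data).result_


def mvmr_egger(data: MvmrDataset) -> MvmrResult:
    """Multivariable Egger result; see :class:`MVMREgger`."""
    return MVMREgger().fit(data).result_


def conditional_f(data: MvmrDataset, assume_zero_crosscov: bool = True) -> np.ndarray:
    """Conditional instrument strength per exposure.

    Each exposure's betas are residualised on the other exposures' betas
    (WLS, weights 1/se_out², no intercept); the residuals then go through
    the variance-explained formula R²_j = 2·eaf_j·(1−eaf_j)·resid_j² and
    the total-F formula with that exposure's sample size.  With a single
    exposure this reduces exactly to the univariable total F.
    """
    if not assume_zero_crosscov:
        raise ValidationError(
            "cross-exposure sampling covariances are not part of the data "
            "model; only assume_zero_crosscov=True is supported"
        )
    if data.exposure_eafs is None or data.exposure_n is None:
        raise ValidationError(
            "conditional_f needs exposure_eafs and exposure_n on the dataset"
        )
    k, p = data.k, data.p
    w = 1.0 / data.outcome_se**2
    out = np.empty(p)
    for i in range(p):
        target = data.exposure_betas[:, i]
        others = np.delete(data.exposure_betas, i, axis=1)
        if others.shape[1] == 0:
            resid = target
        else:
            _check_rank(others * np.sqrt(w)[:, None],
                        [data.exposure_labels[j] for j in range(p) if j != i])
            xtw = others.T * w
            coef = np.linalg.solve(xtw @ others, xtw @ target)
            resid = target - others @ coef
        eaf = data.exposure_eafs[:, i]
        r2 = float(np.sum(2.0 * eaf * (1.0 - eaf) * resid**2))
        r2 = min(r2, 1.0 - 1e-12)
        out[i] = total_f_from_r2(r2, int(data.exposure_n[i]), k)
    return out


def univariable_reduction(data: MvmrDataset) -> MrEstimate:
    """Single-exposure MVMR as a plain IVW fit (consistency check)."""
    if data.p != 1:
        raise ValidationError("reduction applies to a single exposure")
    arr = np.column_stack([
        data.exposure_betas[:, 0], data.exposure_ses[:, 0],
        data.outcome_beta, data.outcome_se,
    ])
    return IVW(model="fixed").fit(arr).estimate_
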