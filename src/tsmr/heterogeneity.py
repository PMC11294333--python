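"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q measures how much the per-SNP Wald ratios disagree beyond
sampling noise; its p-value drives the fixed- vs random-effects choice for
IVW (p > 0.05 -> fixed).  The Egger-flavoured Q (Rücker's Q') uses the
residuals of the intercept regression.  The Egger intercept itself is the
first-line horizontal-pleiotropy check, and leave-one-out refits flag any
single SNP that drives the pooled estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MrEstimate
from .estimators import IVW, MREgger, unpack_harmonized, _ratios, _require
from .exceptions import ValidationError


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str          # "ivw" or "egger"
    q: float
    df: int
    pval: float
    model_choice: str    # "fixed" when pval > 0.05 else "random"

    def to_dict(self) -> dict:
        return {"method": self.method, "q": self.q, "df": self.df,
                "pval": self.pval, "model_choice": self.model_choice}


@dataclass(frozen=True)
class EggerInterceptTest:
    intercept: float
    se: float
    pval: float
    verdict: str         # "no-pleiotropy-evidence" iff pval > 0.05


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Per-SNP-omitted IVW refits plus the full-set reference estimate."""

    table: pd.DataFrame           # snp_id, beta, se, ci_low, ci_high, pval, flagged
    full_estimate: MrEstimate

    @property
    def influential(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "snp_id"].tolist()


def cochran_q(records, fit: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q for the IVW fit or Rücker's Q' for the Egger fit.

    IVW: Q = Σ w_j (ratio_j − beta_ivw)² with w_j = beta_exp²/se_out²,
    df = k−1.  Egger: weighted residual sum of squares of the intercept
    regression, df = k−2.  Model choice is fixed iff p > 0.05 (strict).
    """
    bx, sx, by, sy = unpack_harmonized(records)
    k = len(bx)
    if fit == "ivw":
        _require(k, 2, "Cochran's Q (IVW)")
        m = IVW(model="fixed").fit(records)
        q, df = m.q_, k - 1
    elif fit == "egger":
        _require(k, 3, "Cochran's Q (Egger)")
        m = MREgger().fit(records)
        q, df = m.rss_, k - 2
    else:
        raise ValidationError("fit must be 'ivw' or 'egger'")
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(
        method=fit, q=float(q), df=df, pval=pval,
        model_choice="fixed" if pval > 0.05 else "random",
    )


def egger_intercept_test(records) -> EggerInterceptTest:
    """Egger intercept with its t-test and the pleiotropy verdict."""
    m = MREgger().fit(records)
    verdict = ("no-pleiotropy-evidence" if m.intercept_pval_ > 0.05
               else "pleiotropy")
    return EggerInterceptTest(
        intercept=m.intercept_, se=m.intercept_se_,
        pval=m.intercept_pval_, verdict=verdict,
    )


def leave_one_out(records, model: str | None = None) -> LeaveOneOutResult:
    """IVW refits omitting each SNP in turn.

    The SE model is resolved once on the full set (via the Q rule when
    ``model`` is None) and reused for every subset so the k curves stay
    comparable.  A refit is flagged when its estimate leaves the full-set
    CI or flips sign.
    """
    if isinstance(records, pd.DataFrame):
        ids = records["snp_id"].astype(str).tolist() if "snp_id" in records else [
            str(i) for i in range(len(records))]
    else:
        ids = [str(i) for i in range(np.asarray(records).shape[0])]
    bx, sx, by, sy = unpack_harmonized(records)
    k = len(bx)
    _require(k, 3, "leave-one-out")
    full_fit = IVW(model=model or "auto").fit(records)
    fixed_model = full_fit.model_used_
    full = full_fit.estimate_
    rows = []
    arr = np.column_stack([bx, sx, by, sy])
    for j in range(k):
        sub = np.delete(arr, j, axis=0)
        est = IVW(model=fixed_model).fit(sub).estimate_
        flagged = (
            est.beta < full.ci_low
            or est.beta > full.ci_high
            or (est.beta * full.beta < 0)
        )
        rows.append(
            {"snp_id": ids[j], "beta": est.beta, "se": est.se,
             "ci_low": est.ci_low, "ci_high": est.ci_high,
             "pval": est.pval, "flagged": bool(flagged)}
        )
    return LeaveOneOutResult(table=pd.DataFrame(rows), full_estimate=full)
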