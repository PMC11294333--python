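"""Core data model: per-SNP summary statistics and causal-effect estimates.

A GWAS summary-statistic table holds one row per SNP with the fields every
downstream step needs (alleles, effect-allele frequency, beta, SE, p, N).
The canonical in-memory container is a :class:`pandas.DataFrame` with fixed
column names, wrapped by :class:`SummaryStatTable` which enforces the row
invariants; :class:`SummaryStatRecord` is the row-level view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of a summary-statistic frame
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: 95% two-sided normal quantile used for every confidence interval
Z95 = 1.959964


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def validation_errors(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if not self.snp_id:
            errs.append("empty snp_id")
        for label, allele in (("effect_allele", self.effect_allele),
                              ("other_allele", self.other_allele)):
            if allele not in VALID_ALLELES:
                errs.append(f"{label} {allele!r} not one of A/C/G/T")
        if (self.effect_allele in VALID_ALLELES
                and self.effect_allele == self.other_allele):
            errs.append("effect_allele equals other_allele")
        if not math.isfinite(self.beta):
            errs.append("beta not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            errs.append("se must be > 0")
        if not (math.isfinite(self.pval) and 0 < self.pval <= 1):
            errs.append("pval must lie in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            errs.append("eaf must lie in (0, 1) when present")
        if self.pos is not None and self.pos < 1:
            errs.append("pos must be >= 1 (1-based)")
        if self.n is not None and self.n < 1:
            errs.append("n must be positive")
        return errs


@dataclass(frozen=True)
class RowRejection:
    """Why a parsed input row was rejected."""

    row_index: int
    snp_id: str
    reasons: tuple[str, ...]


class SummaryStatTable:
    """A validated table of per-SNP summary statistics for one trait.

    Parameters
    ----------
    df
        Frame with (a subset of) :data:`CANONICAL_COLUMNS`; missing optional
        columns are added as all-missing.
    trait_label
        Human-readable trait name.
    n_total
        Study sample size, used when per-record ``n`` is missing.
    rejections
        Row-level rejection report carried along from the reader.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        trait_label: str = "",
        n_total: int | None = None,
        rejections: Sequence[RowRejection] = (),
    ) -> None:
        if n_total is not None and n_total <= 0:
            raise ValidationError("n_total must be positive")
        df = df.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        df["snp_id"] = df["snp_id"].astype(str)
        for col in ("eaf", "beta", "se", "pval"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        for col in ("pos", "n"):
            df[col] = pd.array(pd.to_numeric(df[col], errors="raise"),
                               dtype="Int64")
        dup = df["snp_id"].duplicated()
        if dup.any():
            raise ValidationError(
                "duplicate snp_id: " + ", ".join(df.loc[dup, "snp_id"].unique())
            )
        self.df = df
        self.trait_label = trait_label
        self.n_total = n_total
        self.rejections = list(rejections)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SummaryStatTable({self.trait_label!r}, {len(self)} SNPs, "
                f"n_total={self.n_total})")

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    @property
    def records(self) -> list[SummaryStatRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                SummaryStatRecord(
                    snp_id=row.snp_id,
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    beta=float(row.beta),
                    se=float(row.se),
                    pval=float(row.pval),
                    chrom=None if pd.isna(row.chrom) else str(row.chrom),
                    pos=None if pd.isna(row.pos) else int(row.pos),
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    n=None if pd.isna(row.n) else int(row.n),
                )
            )
        return out

    @classmethod
    def from_records(
        cls,
        records: Iterable[SummaryStatRecord],
        trait_label: str = "",
        n_total: int | None = None,
    ) -> "SummaryStatTable":
        records = list(records)
        for rec in records:
            errs = rec.validation_errors()
            if errs:
                raise ValidationError(f"{rec.snp_id}: " + "; ".join(errs))
        df = pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in records],
                "chrom": [r.chrom for r in records],
                "pos": [r.pos for r in records],
                "effect_allele": [r.effect_allele for r in records],
                "other_allele": [r.other_allele for r in records],
                "eaf": [r.eaf for r in records],
                "beta": [r.beta for r in records],
                "se": [r.se for r in records],
                "pval": [r.pval for r in records],
                "n": [r.n for r in records],
            }
        )
        return cls(df, trait_label=trait_label, n_total=n_total)

    def subset(self, keep: Sequence[bool] | pd.Series) -> "SummaryStatTable":
        """Row-subset preserving order, label and n_total."""
        keep = np.asarray(keep, dtype=bool)
        return SummaryStatTable(
            self.df.loc[keep], trait_label=self.trait_label, n_total=self.n_total
        )


def two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal p-value for a z statistic."""
    return 2.0 * stats.norm.sf(np.abs(z))


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate from one MR method.

    ``beta`` is on the log-odds (or SD) scale of the outcome per unit of
    exposure; ``odds_ratio`` and its CI are ``exp``-transformed.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    model: str | None = None
    degenerate: bool = False

    @classmethod
    def from_beta_se(
        cls,
        method: str,
        beta: float,
        se: float,
        nsnp: int,
        dist: str = "normal",
        df: int | None = None,
        **extra,
    ) -> "MrEstimate":
        """Build an estimate from a point value and SE.

        ``dist`` selects the reference distribution for the p-value
        ("normal" or "t" with ``df``); the CI multiplier is always
        :data:`Z95`.
        """
        beta = float(beta)
        se = float(se)
        if se > 0:
            z = beta / se
            if dist == "t":
                pval = float(2.0 * stats.t.sf(abs(z), df))
            else:
                pval = float(two_sided_p(z))
        else:  # degenerate consensus (all ratios identical)
            pval = 1.0 if beta == 0 else 0.0
            extra.setdefault("degenerate", True)
        lo, hi = beta - Z95 * se, beta + Z95 * se
        return cls(
            method=method,
            beta=beta,
            se=se,
            ci_low=lo,
            ci_high=hi,
            pval=pval,
            nsnp=int(nsnp),
            odds_ratio=math.exp(beta),
            or_ci_low=math.exp(lo),
            or_ci_high=math.exp(hi),
            **extra,
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "nsnp": self.nsnp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_pval": self.intercept_pval,
            "model": self.model,
        }

    def replace(self, **kw) -> "MrEstimate":
        return replace(self, **kw)


def estimates_frame(estimates: Iterable[MrEstimate]) -> pd.DataFrame:
    """Stack estimates into the canonical results table."""
    return pd.DataFrame([e.to_dict() for e in estimates])
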