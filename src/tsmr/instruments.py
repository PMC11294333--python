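"""Instrument (IV) selection and instrument-strength statistics.

Selection follows standard MR practice: keep SNPs below the genome-wide
significance threshold (strict ``<``), then greedily clump so that no two
retained instruments are in linkage disequilibrium.  Clumping without an
LD matrix is window-only (every SNP within the window of a better hit is
removed — the conservative reading when no reference panel is available);
with a user-supplied r² matrix only pairs exceeding the r² cutoff are
removed.

Strength is summarised per SNP as F = beta²/se² (the squared Wald z) and
in aggregate through the variance explained,

    R²_j = 2·eaf_j·(1−eaf_j)·beta_j²,   total R² = Σ_j R²_j,
    total F = ((N−K−1)/K) · R²/(1−R²),

with N the exposure sample size and K the number of instruments.  F > 10
is the conventional bar for a stable instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import SummaryStatRecord, SummaryStatTable
from .exceptions import ValidationError


@dataclass(frozen=True)
class InstrumentSelectionConfig:
    """Thresholds used during instrument selection."""

    p_threshold: float = 5e-8
    clump_window_kb: int = 10_000
    clump_r2: float = 0.001
    outcome_p_exclusion: float = 5e-8

    def __post_init__(self):
        if not (0 < self.p_threshold <= 1):
            raise ValidationError("p_threshold must lie in (0, 1]")
        if not (0 < self.outcome_p_exclusion <= 1):
            raise ValidationError("outcome_p_exclusion must lie in (0, 1]")
        if self.clump_window_kb <= 0:
            raise ValidationError("clump_window_kb must be positive")
        if not (0 < self.clump_r2 <= 1):
            raise ValidationError("clump_r2 must lie in (0, 1]")


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-SNP and aggregate instrument strength."""

    per_snp_f: tuple[float, ...]
    per_snp_r2: tuple[float, ...]
    total_r2: float
    total_f: float
    k: int
    n: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "total_r2": self.total_r2,
            "total_f": self.total_f,
            "min_per_snp_f": min(self.per_snp_f) if self.per_snp_f else None,
        }


def significance_filter(
    table: SummaryStatTable, p_threshold: float = 5e-8
) -> SummaryStatTable:
    """Keep rows with ``pval < p_threshold`` (strict), order preserved."""
    return table.subset(table.df["pval"].to_numpy() < p_threshold)


def clump(
    table: SummaryStatTable,
    config: InstrumentSelectionConfig | None = None,
    ld: pd.DataFrame | None = None,
) -> SummaryStatTable:
    """Greedy p-value clumping.

    Repeatedly pick the remaining SNP with the smallest p-value (ties broken
    by chrom, pos, snp_id — deterministic without a seed) and remove every
    other SNP within ``clump_window_kb`` on the same chromosome whose r²
    with it exceeds ``clump_r2`` (when ``ld`` is given) or unconditionally
    within the window (when it is not).  With ``ld`` given and positions
    missing, the r² rule is applied genome-wide.
    """
    config = config or InstrumentSelectionConfig()
    df = table.df
    k = len(df)
    if k <= 1:
        return table.subset(np.ones(k, dtype=bool))

    have_pos = df["pos"].notna().to_numpy() & df["chrom"].notna().to_numpy()
    if ld is None and not have_pos.all():
        missing = df.loc[~have_pos, "snp_id"].tolist()
        raise ValidationError(
            "window clumping needs chrom+pos; missing for: " + ", ".join(missing)
        )
    use_window = have_pos.all()

    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(dtype=float, na_value=np.nan)
    pval = df["pval"].to_numpy()
    ids = df["snp_id"].to_numpy()
    window = config.clump_window_kb * 1000.0

    # deterministic ordering: pval, then (chrom, pos, snp_id)
    order = sorted(
        range(k), key=lambda i: (pval[i], chrom[i], pos[i] if use_window else 0, ids[i])
    )
    alive = np.ones(k, dtype=bool)
    kept = np.zeros(k, dtype=bool)
    for i in order:
        if not alive[i]:
            continue
        kept[i] = True
        alive[i] = False
        for j in range(k):
            if not alive[j]:
                continue
            in_window = (
                use_window
                and chrom[j] == chrom[i]
                and abs(pos[j] - pos[i]) <= window
            )
            if ld is not None:
                r2 = 0.0
                if ids[i] in ld.index and ids[j] in ld.columns:
                    r2 = float(ld.loc[ids[i], ids[j]])
                conflict = r2 > config.clump_r2 and (in_window or not use_window)
            else:
                conflict = in_window
            if conflict:
                alive[j] = False
    return table.subset(kept)


def exclude_outcome_associated(
    harmonized: pd.DataFrame, outcome_p_exclusion: float = 5e-8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split harmonized records on outcome-association.

    SNPs whose *outcome* p-value falls below the threshold violate the
    exclusion-restriction assumption (they are genome-wide hits for the
    outcome in their own right) and are removed; both partitions are
    returned so the report can list them.
    """
    removed_mask = harmonized["pval_out"].to_numpy() < outcome_p_exclusion
    kept = harmonized.loc[~removed_mask].copy()
    removed = harmonized.loc[removed_mask].copy()
    removed["flags"] = [
        set(f) | {"excluded_outcome_assoc"} for f in removed["flags"]
    ]
    return kept, removed


def per_snp_f(record: SummaryStatRecord | float, se: float | None = None):
    """Per-SNP F statistic, beta²/se² (the squared Wald z-score).

    Accepts a record, or ``per_snp_f(beta, se)`` with scalars/arrays.
    """
    if se is None:
        beta, se = record.beta, record.se
    else:
        beta = record
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("se must be > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def total_f_from_r2(total_r2: float, n: int, k: int) -> float:
    """Aggregate F from total variance explained: ((N−K−1)/K)·R²/(1−R²)."""
    if not (0 <= total_r2 < 1):
        raise ValidationError("total_r2 must lie in [0, 1)")
    if n <= k + 1:
        raise ValidationError("need n > k + 1")
    return (n - k - 1) / k * total_r2 / (1.0 - total_r2)


def instrument_strength(
    table: SummaryStatTable, n: int | None = None
) -> InstrumentStrength:
    """Per-SNP and total instrument strength for an exposure table.

    ``n`` defaults to the table's ``n_total``.  Requires eaf on every SNP;
    missing eaf is reported loudly per SNP, never imputed.
    """
    if n is None:
        n = table.n_total
    if n is None:
        raise ValidationError("exposure sample size n is required")
    df = table.df
    missing = df.loc[df["eaf"].isna(), "snp_id"].tolist()
    if missing:
        raise ValidationError("missing eaf for: " + ", ".join(missing))
    k = len(df)
    if k == 0:
        raise ValidationError("empty instrument set")
    eaf = df["eaf"].to_numpy()
    beta = df["beta"].to_numpy()
    se = df["se"].to_numpy()
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    total_r2 = float(r2.sum())
    if total_r2 >= 1:
        raise ValidationError(f"total_r2 = {total_r2:.3f} >= 1: implausible input")
    return InstrumentStrength(
        per_snp_f=tuple((beta / se) ** 2),
        per_snp_r2=tuple(r2),
        total_r2=total_r2,
        total_f=total_f_from_r2(total_r2, int(n), k),
        k=k,
        n=int(n),
    )
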