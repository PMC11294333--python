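"""Delimited-text readers/writers for GWAS summary statistics.

Column naming differs wildly between GWAS resources, so the reader is
driven by a *dialect*: a mapping from the roles the package needs
(``snp_id``, ``effect_allele``, ``beta``, ...) to the column names of the
file at hand.  Built-in dialects cover the package's own canonical layout
("plain"), TwoSampleMR-style exposure/outcome frames ("twosamplemr"), and
a tabular GWAS-VCF export ("gwas-vcf-lite", with -log10 p-values).

Rows violating a record invariant (se <= 0, p outside (0,1], bad alleles,
duplicate ids...) are rejected with a per-row reason list attached to the
returned table — never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    CANONICAL_COLUMNS,
    RowRejection,
    SummaryStatTable,
    VALID_ALLELES,
)
from .exceptions import ConfigError, DialectError

REQUIRED_ROLES = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_ROLES = ("chrom", "pos", "eaf", "n")

#: text sentinel for a missing value in canonical output
NA_SENTINEL = "NA"


@dataclass(frozen=True)
class Dialect:
    """Mapping from column roles to the column names of a concrete file."""

    name: str
    columns: Mapping[str, str]
    #: p-value column holds -log10(p) instead of p
    pval_neglog10: bool = False

    def column_for(self, role: str) -> str | None:
        return self.columns.get(role)


def _plain() -> Dialect:
    return Dialect("plain", {role: role for role in REQUIRED_ROLES + OPTIONAL_ROLES})


def _twosamplemr(suffix: str = ".exposure") -> Dialect:
    cols = {
        "snp_id": "SNP",
        "chrom": f"chr{suffix}",
        "pos": f"pos{suffix}",
        "effect_allele": f"effect_allele{suffix}",
        "other_allele": f"other_allele{suffix}",
        "eaf": f"eaf{suffix}",
        "beta": f"beta{suffix}",
        "se": f"se{suffix}",
        "pval": f"pval{suffix}",
        "n": f"samplesize{suffix}",
    }
    return Dialect(f"twosamplemr{suffix}", cols)


def _gwas_vcf_lite() -> Dialect:
    return Dialect(
        "gwas-vcf-lite",
        {
            "snp_id": "ID",
            "chrom": "CHROM",
            "pos": "POS",
            "effect_allele": "ALT",
            "other_allele": "REF",
            "eaf": "AF",
            "beta": "ES",
            "se": "SE",
            "pval": "LP",
            "n": "SS",
        },
        pval_neglog10=True,
    )


def get_dialect(name: str | Dialect, suffix: str = ".exposure") -> Dialect:
    """Resolve a dialect by name; ``suffix`` applies to "twosamplemr"."""
    if isinstance(name, Dialect):
        return name
    if name == "plain":
        return _plain()
    if name == "twosamplemr":
        return _twosamplemr(suffix)
    if name == "twosamplemr-outcome":
        return _twosamplemr(".outcome")
    if name == "gwas-vcf-lite":
        return _gwas_vcf_lite()
    raise ConfigError(f"unknown dialect {name!r}")


def _parse_float(raw: str | float) -> float | None:
    """Parse a numeric cell; '' / 'NA' / NaN -> None; unparseable -> ValueError."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in ("", NA_SENTINEL, "NaN", "nan", "."):
        return None
    return float(s)  # may raise ValueError


def read_summary_stats(
    path,
    dialect: str | Dialect = "plain",
    trait_label: str = "",
    n_total: int | None = None,
    sep: str | None = None,
) -> SummaryStatTable:
    """Read a delimited summary-statistic file under a column dialect.

    The delimiter is sniffed (TSV and CSV both accepted) unless ``sep``
    is given.  Returns a validated table; rejected rows are listed in
    ``table.rejections`` with their reasons.
    """
    d = get_dialect(dialect)
    raw = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        dtype=str,
        keep_default_na=False,
    )
    for role in REQUIRED_ROLES:
        col = d.column_for(role)
        if col is None or col not in raw.columns:
            raise DialectError(
                f"dialect {d.name!r}: required role {role!r} "
                f"maps to missing column {col!r}"
            )

    rows: list[dict] = []
    rejections: list[RowRejection] = []
    seen: set[str] = set()
    for idx, row in raw.iterrows():
        reasons: list[str] = []

        def cell(role: str):
            col = d.column_for(role)
            if col is None or col not in raw.columns:
                return None
            return row[col]

        snp_id = str(cell("snp_id") or "").strip()
        if not snp_id:
            reasons.append("empty snp_id")
        elif snp_id in seen:
            reasons.append("duplicate snp_id")

        alleles = {}
        for role in ("effect_allele", "other_allele"):
            a = str(cell(role) or "").strip().upper()
            alleles[role] = a
            if a not in VALID_ALLELES:
                reasons.append(f"{role} {a!r} not one of A/C/G/T")
        if (alleles["effect_allele"] in VALID_ALLELES
                and alleles["effect_allele"] == alleles["other_allele"]):
            reasons.append("effect_allele equals other_allele")

        nums: dict[str, float | None] = {}
        for role in ("beta", "se", "pval", "eaf", "pos", "n"):
            try:
                nums[role] = _parse_float(cell(role))
            except ValueError:
                nums[role] = None
                reasons.append(f"unparseable numeric for {role}")
        for role in ("beta", "se", "pval"):
            if nums[role] is None and f"unparseable numeric for {role}" not in reasons:
                reasons.append(f"missing {role}")

        pval = nums["pval"]
        if pval is not None and d.pval_neglog10:
            pval = 10.0 ** (-pval)
        if nums["se"] is not None and not nums["se"] > 0:
            reasons.append("se must be > 0")
        if pval is not None and not (0 < pval <= 1):
            reasons.append("pval must lie in (0, 1]")
        if nums["eaf"] is not None and not (0 < nums["eaf"] < 1):
            reasons.append("eaf must lie in (0, 1) when present")
        if nums["pos"] is not None and nums["pos"] < 1:
            reasons.append("pos must be >= 1")
        if nums["n"] is not None and nums["n"] < 1:
            reasons.append("n must be positive")

        if reasons:
            rejections.append(RowRejection(int(idx), snp_id, tuple(reasons)))
            continue
        seen.add(snp_id)
        chrom_raw = cell("chrom")
        chrom = None if chrom_raw is None or str(chrom_raw).strip() in (
            "", NA_SENTINEL) else str(chrom_raw).strip()
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "pos": None if nums["pos"] is None else int(nums["pos"]),
                "effect_allele": alleles["effect_allele"],
                "other_allele": alleles["other_allele"],
                "eaf": nums["eaf"],
                "beta": nums["beta"],
                "se": nums["se"],
                "pval": pval,
                "n": None if nums["n"] is None else int(nums["n"]),
            }
        )
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    return SummaryStatTable(
        df, trait_label=trait_label, n_total=n_total, rejections=rejections
    )


def _fmt(value, is_int: bool = False) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return NA_SENTINEL
    if is_int:
        return str(int(value))
    if isinstance(value, float):
        return format(value, ".17g")
    return str(value)


def write_summary_stats(table: SummaryStatTable, path) -> None:
    """Write a table as canonical TSV (plain dialect, "NA" for missing).

    Floats are printed with 17 significant digits so that
    ``read(write(t))`` round-trips every field exactly.
    """
    df = table.df
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].astype(str),
            "chrom": [_fmt(v) for v in df["chrom"]],
            "pos": [_fmt(v, is_int=True) for v in df["pos"]],
            "effect_allele": df["effect_allele"],
            "other_allele": df["other_allele"],
            "eaf": [_fmt(v) for v in df["eaf"]],
            "beta": [_fmt(v) for v in df["beta"]],
            "se": [_fmt(v) for v in df["se"]],
            "pval": [_fmt(v) for v in df["pval"]],
            "n": [_fmt(v, is_int=True) for v in df["n"]],
        }
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a 3-column (snp_a, snp_b, r2) TSV into a symmetric r² frame."""
    long = pd.read_csv(path, sep=None, engine="python")
    if long.shape[1] < 3:
        raise ConfigError("LD file needs 3 columns: snp_a, snp_b, r2")
    long.columns = ["snp_a", "snp_b", "r2"] + list(long.columns[3:])
    ids = sorted(set(long["snp_a"]) | set(long["snp_b"]))
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for row in long.itertuples(index=False):
        mat.loc[row.snp_a, row.snp_b] = float(row.r2)
        mat.loc[row.snp_b, row.snp_a] = float(row.r2)
    np.fill_diagonal(mat.values, 1.0)
    return mat
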