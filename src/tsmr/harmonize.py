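"""Harmonization of exposure and outcome effects onto a shared effect allele.

Two GWAS may report the same SNP with the alleles in either order and on
either strand.  Harmonization rewrites the outcome association so that its
effect allele matches the exposure's: a swapped pair negates the outcome
beta and reflects its frequency; a strand-complement pair is complemented
first.  Palindromic SNPs (A/T or C/G) are strand-ambiguous — the listed
alleles cannot distinguish a flip from a strand difference — and are either
dropped (the default, matching conservative practice) or resolved by
comparing effect-allele frequencies, dropping any SNP whose frequency is
too close to 0.5 to call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import SummaryStatTable
from .exceptions import ValidationError

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "pval_exp", "eaf_exp",
    "beta_out", "se_out", "pval_out", "eaf_out",
    "flags", "kept", "reason",
)


@dataclass(frozen=True)
class HarmonizationPolicy:
    """How to treat palindromic SNPs.

    ``palindromic_action`` is "drop" or "infer_by_eaf"; under inference a
    SNP is still dropped when either frequency lies within
    ``0.5 ± eaf_ambiguity_band`` (inclusive) or is missing.
    """

    palindromic_action: str = "drop"
    eaf_ambiguity_band: float = 0.08

    def __post_init__(self):
        if self.palindromic_action not in ("drop", "infer_by_eaf"):
            raise ValidationError(
                "palindromic_action must be 'drop' or 'infer_by_eaf'"
            )
        if not (0 < self.eaf_ambiguity_band < 0.5):
            raise ValidationError("eaf_ambiguity_band must lie in (0, 0.5)")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or C/G pairs are their own strand complement."""
    return COMPLEMENT.get(effect_allele) == other_allele


def flip_outcome(row: pd.Series) -> pd.Series:
    """Re-express the outcome side on the opposite effect allele.

    Negates ``beta_out``, reflects ``eaf_out`` and toggles the ``flipped``
    flag; applying it twice restores the record exactly (involution).
    """
    out = row.copy()
    out["beta_out"] = -row["beta_out"]
    if pd.notna(row.get("eaf_out")):
        out["eaf_out"] = 1.0 - row["eaf_out"]
    flags = set(row["flags"])
    flags ^= {"flipped"}
    out["flags"] = flags
    return out


def _ambiguous(eaf, band: float) -> bool:
    return pd.isna(eaf) or (0.5 - band) <= eaf <= (0.5 + band)


def harmonize(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    policy: HarmonizationPolicy | None = None,
) -> pd.DataFrame:
    """Align outcome effects onto the exposure's effect allele.

    Returns one row per SNP shared by both tables (exposure order) with
    exposure- and outcome-side statistics on identical alleles, a ``flags``
    set, a ``kept`` boolean, and a machine-readable exclusion ``reason``
    for dropped rows.  SNPs absent from either table are omitted.
    """
    policy = policy or HarmonizationPolicy()
    out_by_id = {r["snp_id"]: r for _, r in outcome.df.iterrows()}
    rows = []
    for _, exp in exposure.df.iterrows():
        out = out_by_id.get(exp["snp_id"])
        if out is None:
            continue
        ea, oa = exp["effect_allele"], exp["other_allele"]
        ea2, oa2 = out["effect_allele"], out["other_allele"]
        flags: set[str] = set()
        kept, reason = True, ""
        beta_out, se_out = float(out["beta"]), float(out["se"])
        pval_out = float(out["pval"])
        eaf_out = out["eaf"]
        flip = False

        if is_palindromic(ea, oa):
            flags.add("palindromic")
            if {ea2, oa2} != {ea, oa}:
                kept, reason = False, "incompatible alleles"
            elif policy.palindromic_action == "drop":
                flags.add("dropped_palindromic")
                kept, reason = False, "palindromic"
            else:
                # align by the listed order first, then check frequencies
                if (ea2, oa2) == (oa, ea):
                    flip = True
                # ambiguity is symmetric around 0.5, so alignment order
                # does not matter for the band check
                if _ambiguous(exp["eaf"], policy.eaf_ambiguity_band) or _ambiguous(
                    eaf_out, policy.eaf_ambiguity_band
                ):
                    flags.add("dropped_palindromic")
                    kept, reason = False, "palindromic_ambiguous_eaf"
                    flip = False
                else:
                    aligned_eaf = 1.0 - eaf_out if flip else eaf_out
                    if (exp["eaf"] - 0.5) * (aligned_eaf - 0.5) < 0:
                        flip = not flip
        else:
            comp = (COMPLEMENT[ea2], COMPLEMENT[oa2])
            if (ea2, oa2) == (ea, oa):
                pass
            elif (ea2, oa2) == (oa, ea):
                flip = True
            elif comp == (ea, oa):
                pass
            elif comp == (oa, ea):
                flip = True
            else:
                kept, reason = False, "incompatible alleles"

        if flip:
            beta_out = -beta_out
            if pd.notna(eaf_out):
                eaf_out = 1.0 - eaf_out
            flags.add("flipped")

        rows.append(
            {
                "snp_id": exp["snp_id"],
                "chrom": exp["chrom"],
                "pos": exp["pos"],
                "effect_allele": ea,
                "other_allele": oa,
                "beta_exp": float(exp["beta"]),
                "se_exp": float(exp["se"]),
                "pval_exp": float(exp["pval"]),
                "eaf_exp": exp["eaf"],
                "beta_out": beta_out,
                "se_out": se_out,
                "pval_out": pval_out,
                "eaf_out": eaf_out,
                "flags": flags,
                "kept": kept,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS))


def kept_records(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows still in play for estimation."""
    return harmonized.loc[harmonized["kept"]].reset_index(drop=True)


def harmonization_report(harmonized: pd.DataFrame) -> pd.Series:
    """Counts per flag category plus kept/shared totals."""
    flag_names = (
        "flipped", "palindromic", "dropped_palindromic",
        "excluded_outcome_assoc", "excluded_outlier",
    )
    counts = {"shared": len(harmonized)}
    for name in flag_names:
        counts[name] = int(sum(name in f for f in harmonized["flags"]))
    counts["incompatible_alleles"] = int(
        (harmonized["reason"] == "incompatible alleles").sum()
    )
    counts["kept"] = int(harmonized["kept"].sum())
    return pd.Series(counts, name="count")


def write_harmonized(harmonized: pd.DataFrame, path) -> None:
    """Write harmonized records as TSV (flags joined with ';')."""
    out = harmonized.copy()
    out["flags"] = [";".join(sorted(f)) for f in out["flags"]]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g",
               lineterminator="\n")


def read_harmonized(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_harmonized`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    df["flags"] = [
        set(str(f).split(";")) - {"", "nan"} if pd.notna(f) else set()
        for f in df["flags"]
    ]
    df["kept"] = df["kept"].astype(bool)
    df["reason"] = df["reason"].fillna("")
    return df
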