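"""End-to-end orchestration of the MR workflow.

``analyze_pair`` runs one direction on in-memory tables:

    significance filter -> clumping -> harmonization (palindromes) ->
    outcome-association exclusion -> MR-PRESSO outlier removal ->
    instrument strength -> estimators (IVW model via the Q rule) ->
    heterogeneity -> Egger intercept -> leave-one-out -> power

Every SNP that enters the analysis receives exactly one entry in the
filter ledger with a machine-readable reason (a partition of the input).
``run_univariable``/``run_bidirectional``/``run_mvmr`` wrap file loading,
config handling and report writing; all randomness flows from the single
config seed through a SeedSequence split per component.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import MrEstimate, SummaryStatTable, estimates_frame
from .estimators import (
    IVW,
    MREgger,
    ModeEstimator,
    WeightedMedian,
)
from .exceptions import ConfigError, InsufficientInstrumentsError
from .gwas_io import read_ld_matrix, read_summary_stats
from .harmonize import (
    HarmonizationPolicy,
    harmonization_report,
    harmonize,
    kept_records,
    write_harmonized,
)
from .heterogeneity import (
    EggerInterceptTest,
    HeterogeneityResult,
    LeaveOneOutResult,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
)
from .instruments import (
    InstrumentSelectionConfig,
    InstrumentStrength,
    clump,
    exclude_outcome_associated,
    instrument_strength,
    significance_filter,
)
from .mvmr import MvmrDataset, MVMREgger, MVMRIVW, MvmrResult, conditional_f
from .power import mr_power_binary
from .presso import MRPRESSO, PressoConfig, PressoResult


@dataclass(frozen=True)
class PowerSpec:
    """Outcome case/control counts for the analytic power stage."""

    n_cases: int
    n_controls: int
    alpha: float = 0.05


@dataclass
class AnalysisConfig:
    """Configuration of a full (possibly bidirectional) analysis."""

    exposure_path: str
    outcome_path: str
    exposure_dialect: str = "plain"
    outcome_dialect: str = "plain"
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    n_exposure: int | None = None
    selection: InstrumentSelectionConfig = field(
        default_factory=InstrumentSelectionConfig)
    policy: HarmonizationPolicy = field(default_factory=HarmonizationPolicy)
    methods: tuple[str, ...] = (
        "ivw", "mr_egger", "weighted_median", "simple_mode", "weighted_mode")
    model: str = "auto"
    n_boot: int = 1000
    presso_nb: int = 3000
    presso_threshold: float = 0.05
    run_presso: bool = True
    power: PowerSpec | None = None
    ld_path: str | None = None
    bidirectional: bool = False
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            if "selection" in raw:
                raw["selection"] = InstrumentSelectionConfig(**raw["selection"])
            if "policy" in raw:
                raw["policy"] = HarmonizationPolicy(**raw["policy"])
            if raw.get("power"):
                raw["power"] = PowerSpec(**raw["power"])
            if "methods" in raw:
                raw["methods"] = tuple(raw["methods"])
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _component_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-component seeds derived from the config seed."""
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("presso", "weighted_median", "simple_mode", "weighted_mode")
    return {name: int(s & 0x7FFFFFFF) for name, s in zip(names, state)}


@dataclass
class ReportBundle:
    """Everything one direction of the analysis produced."""

    exposure_label: str
    outcome_label: str
    harmonized: pd.DataFrame
    report: pd.Series
    estimates: list[MrEstimate]
    heterogeneity: list[HeterogeneityResult]
    egger_intercept: EggerInterceptTest | None
    loo: LeaveOneOutResult | None
    presso: PressoResult | None
    strength: InstrumentStrength | None
    power: float | None
    ledger: pd.DataFrame
    n_instruments: int

    @property
    def estimates_frame(self) -> pd.DataFrame:
        return estimates_frame(self.estimates)

    def write(self, outdir) -> None:
        """Serialise the bundle as deterministic TSV/JSON files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.estimates_frame.to_csv(
            outdir / "estimates.tsv", sep="\t", index=False,
            float_format="%.10g", lineterminator="\n")
        pd.DataFrame([h.to_dict() for h in self.heterogeneity]).to_csv(
            outdir / "heterogeneity.tsv", sep="\t", index=False,
            float_format="%.10g", lineterminator="\n")
        self.report.to_csv(outdir / "harmonization_report.tsv", sep="\t",
                           lineterminator="\n")
        write_harmonized(self.harmonized, outdir / "harmonized.tsv")
        if self.loo is not None:
            self.loo.table.to_csv(outdir / "leave_one_out.tsv", sep="\t",
                                  index=False, float_format="%.10g",
                                  lineterminator="\n")
        blobs = {
            "strength.json": None if self.strength is None
            else self.strength.to_dict(),
            "presso.json": None if self.presso is None
            else self.presso.to_dict(),
            "power.json": None if self.power is None
            else {"power": self.power, "power_percent": 100.0 * self.power},
            "egger_intercept.json": None if self.egger_intercept is None
            else asdict(self.egger_intercept),
        }
        for name, blob in blobs.items():
            if blob is not None:
                (outdir / name).write_text(
                    json.dumps(blob, sort_keys=True, indent=1) + "\n")
        with open(outdir / "filter_ledger.jsonl", "w") as fh:
            for rec in self.ledger.to_dict("records"):
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


_METHOD_MIN = {"ivw": 2, "mr_egger": 3, "weighted_median": 3,
               "simple_median": 3, "simple_mode": 3, "weighted_mode": 3}


def analyze_pair(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    selection: InstrumentSelectionConfig | None = None,
    policy: HarmonizationPolicy | None = None,
    methods: tuple[str, ...] = (
        "ivw", "mr_egger", "weighted_median", "simple_mode", "weighted_mode"),
    model: str = "auto",
    n_boot: int = 1000,
    presso_nb: int = 3000,
    presso_threshold: float = 0.05,
    run_presso: bool = True,
    power: PowerSpec | None = None,
    ld: pd.DataFrame | None = None,
    seed: int = 0,
) -> ReportBundle:
    """One direction of the two-sample MR workflow on in-memory tables."""
    selection = selection or InstrumentSelectionConfig()
    policy = policy or HarmonizationPolicy()
    seeds = _component_seeds(seed)
    ledger_rows: list[dict] = []

    def log(snp, stage, status, reason):
        ledger_rows.append(
            {"snp_id": str(snp), "stage": stage, "status": status,
             "reason": reason})

    # 1. significance filter
    significant = significance_filter(exposure, selection.p_threshold)
    sig_ids = set(significant.snp_ids)
    for snp in exposure.snp_ids:
        if snp not in sig_ids:
            log(snp, "significance", "removed", "pval_above_threshold")

    # 2. clumping
    clumped = clump(significant, selection, ld=ld)
    kept_ids = set(clumped.snp_ids)
    for snp in significant.snp_ids:
        if snp not in kept_ids:
            log(snp, "clump", "removed", "linkage_disequilibrium_window")

    # 3. harmonization
    harmonized = harmonize(clumped, outcome, policy)
    matched = set(harmonized["snp_id"])
    for snp in clumped.snp_ids:
        if snp not in matched:
            log(snp, "merge", "removed", "absent_from_outcome")
    for row in harmonized.itertuples(index=False):
        if not row.kept:
            log(row.snp_id, "harmonize", "removed",
                row.reason.replace(" ", "_"))
    working = kept_records(harmonized)

    # 4. outcome-association exclusion
    working, removed = exclude_outcome_associated(
        working, selection.outcome_p_exclusion)
    for row in removed.itertuples(index=False):
        log(row.snp_id, "outcome_association", "removed",
            "genome_wide_outcome_hit")
        idx = harmonized.index[harmonized["snp_id"] == row.snp_id][0]
        harmonized.at[idx, "kept"] = False
        harmonized.at[idx, "reason"] = "outcome_associated"
        harmonized.at[idx, "flags"] = set(harmonized.at[idx, "flags"]) | {
            "excluded_outcome_assoc"}

    # 5. MR-PRESSO outlier removal
    presso_result: PressoResult | None = None
    if run_presso and len(working) >= 4:
        presso_result = MRPRESSO(
            nb_distribution=presso_nb, signif_threshold=presso_threshold,
            seed=seeds["presso"],
        ).fit(working).result_
        outliers = set(presso_result.outlier_indices)
        for snp in outliers:
            log(snp, "presso", "removed", "presso_outlier")
            idx = harmonized.index[harmonized["snp_id"] == snp][0]
            harmonized.at[idx, "kept"] = False
            harmonized.at[idx, "reason"] = "presso_outlier"
            harmonized.at[idx, "flags"] = set(harmonized.at[idx, "flags"]) | {
                "excluded_outlier"}
        working = working.loc[~working["snp_id"].isin(outliers)].reset_index(
            drop=True)

    for snp in working["snp_id"]:
        log(snp, "final", "kept", "instrument")

    ledger = pd.DataFrame(
        ledger_rows, columns=["snp_id", "stage", "status", "reason"])
    k = len(working)
    if k < 2:
        err = InsufficientInstrumentsError(
            f"only {k} instruments survive filtering")
        err.ledger = ledger
        raise err

    # 6. instrument strength (needs eaf; reported as None when absent)
    strength: InstrumentStrength | None = None
    if working["eaf_exp"].notna().all() and exposure.n_total is not None:
        strength_table = SummaryStatTable(
            working.rename(columns={
                "beta_exp": "beta", "se_exp": "se", "pval_exp": "pval",
                "eaf_exp": "eaf"})[
                ["snp_id", "effect_allele", "other_allele", "eaf", "beta",
                 "se", "pval"]],
            n_total=exposure.n_total,
        )
        strength = instrument_strength(strength_table)

    # 7. estimators
    estimates: list[MrEstimate] = []
    fitters = {
        "ivw": lambda: IVW(model=model),
        "mr_egger": lambda: MREgger(),
        "weighted_median": lambda: WeightedMedian(
            n_boot=n_boot, seed=seeds["weighted_median"]),
        "simple_median": lambda: WeightedMedian(
            weights="equal", n_boot=n_boot, seed=seeds["weighted_median"]),
        "simple_mode": lambda: ModeEstimator(
            kind="simple", n_boot=n_boot, seed=seeds["simple_mode"]),
        "weighted_mode": lambda: ModeEstimator(
            kind="weighted", n_boot=n_boot, seed=seeds["weighted_mode"]),
    }
    for name in methods:
        if name not in fitters:
            raise ConfigError(f"unknown estimator {name!r}")
        if k >= _METHOD_MIN[name]:
            estimates.append(fitters[name]().fit(working).estimate_)

    # 8. heterogeneity, intercept, leave-one-out
    heterogeneity = [cochran_q(working, "ivw")]
    egger_int: EggerInterceptTest | None = None
    loo: LeaveOneOutResult | None = None
    if k >= 3:
        heterogeneity.append(cochran_q(working, "egger"))
        egger_int = egger_intercept_test(working)
        loo = leave_one_out(working, model=model)

    # 9. analytic power at the fitted IVW odds ratio
    power_value: float | None = None
    if power is not None and strength is not None:
        ivw_est = next((e for e in estimates if e.method == "ivw"), None)
        if ivw_est is not None:
            n_out = power.n_cases + power.n_controls
            power_value = mr_power_binary(
                n_out, strength.total_r2, math.exp(ivw_est.beta),
                power.n_cases / n_out, power.alpha)

    return ReportBundle(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        harmonized=harmonized,
        report=harmonization_report(harmonized),
        estimates=estimates,
        heterogeneity=heterogeneity,
        egger_intercept=egger_int,
        loo=loo,
        presso=presso_result,
        strength=strength,
        power=power_value,
        ledger=ledger,
        n_instruments=k,
    )


def _load_tables(config: AnalysisConfig):
    for path in (config.exposure_path, config.outcome_path):
        if not Path(path).exists():
            raise ConfigError(f"input file not found: {path}")
    exposure = read_summary_stats(
        config.exposure_path, config.exposure_dialect,
        trait_label=config.exposure_label, n_total=config.n_exposure)
    outcome = read_summary_stats(
        config.outcome_path, config.outcome_dialect,
        trait_label=config.outcome_label)
    return exposure, outcome


def _analyze_config(config, exposure, outcome, ld):
    return analyze_pair(
        exposure, outcome,
        selection=config.selection, policy=config.policy,
        methods=config.methods, model=config.model, n_boot=config.n_boot,
        presso_nb=config.presso_nb, presso_threshold=config.presso_threshold,
        run_presso=config.run_presso, power=config.power, ld=ld,
        seed=config.seed,
    )


def run_univariable(config: AnalysisConfig) -> ReportBundle:
    """Load the configured tables, run one direction, write the bundle."""
    exposure, outcome = _load_tables(config)
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    bundle = _analyze_config(config, exposure, outcome, ld)
    if config.outdir:
        bundle.write(Path(config.outdir) / "forward")
    return bundle


def run_bidirectional(config: AnalysisConfig) -> dict[str, ReportBundle]:
    """Forward and reverse analyses with direction-specific selection."""
    exposure, outcome = _load_tables(config)
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    forward = _analyze_config(config, exposure, outcome, ld)
    reverse = analyze_pair(
        outcome, exposure,
        selection=config.selection, policy=config.policy,
        methods=config.methods, model=config.model, n_boot=config.n_boot,
        presso_nb=config.presso_nb, presso_threshold=config.presso_threshold,
        run_presso=config.run_presso, power=None, ld=ld, seed=config.seed,
    )
    if config.outdir:
        forward.write(Path(config.outdir) / "forward")
        reverse.write(Path(config.outdir) / "reverse")
    return {"forward": forward, "reverse": reverse}


# ---------------------------------------------------------------------------
# multivariable workflow

@dataclass
class MvmrReport:
    dataset: MvmrDataset
    ivw: MvmrResult
    egger: MvmrResult
    conditional_f: tuple[float, ...] | None

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.ivw.to_frame(), self.egger.to_frame()], ignore_index=True)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "mvmr.tsv", sep="\t", index=False,
                               float_format="%.10g", lineterminator="\n")


def build_mvmr_dataset(
    exposures: list[SummaryStatTable],
    outcome: SummaryStatTable,
    selection: InstrumentSelectionConfig | None = None,
    policy: HarmonizationPolicy | None = None,
) -> MvmrDataset:
    """Joint instrument selection + harmonization across several exposures.

    Instruments are the union of each exposure's genome-wide-significant
    SNPs, re-clumped jointly on the smallest p-value per SNP, restricted
    to SNPs present in every exposure and the outcome, then aligned onto
    the first exposure's effect alleles (palindromes handled per policy).
    """
    selection = selection or InstrumentSelectionConfig()
    policy = policy or HarmonizationPolicy()
    if len(exposures) < 2:
        raise ConfigError("multivariable MR needs at least two exposures")

    pooled: dict[str, dict] = {}
    for table in exposures:
        sig = significance_filter(table, selection.p_threshold)
        for rec in sig.df.itertuples(index=False):
            cur = pooled.get(rec.snp_id)
            if cur is None or rec.pval < cur["pval"]:
                pooled[rec.snp_id] = {
                    "snp_id": rec.snp_id, "chrom": rec.chrom, "pos": rec.pos,
                    "effect_allele": rec.effect_allele,
                    "other_allele": rec.other_allele, "eaf": rec.eaf,
                    "beta": rec.beta, "se": rec.se, "pval": rec.pval,
                    "n": rec.n}
    if not pooled:
        raise InsufficientInstrumentsError("no genome-wide-significant SNPs")
    union = SummaryStatTable(pd.DataFrame(list(pooled.values())))
    selected = set(clump(union, selection).snp_ids)

    common = selected
    for table in exposures:
        common = common & set(table.snp_ids)
    common = common & set(outcome.snp_ids)
    if len(common) < len(exposures) + 2:
        raise InsufficientInstrumentsError(
            f"only {len(common)} SNPs shared across all datasets")

    first = exposures[0].subset(
        [s in common for s in exposures[0].snp_ids])
    h_out = kept_records(harmonize(first, outcome, policy))
    aligned = {"outcome": h_out}
    for i, table in enumerate(exposures[1:], start=1):
        aligned[f"exp{i}"] = kept_records(harmonize(first, table, policy))
    ids = set(h_out["snp_id"])
    for key, frame in aligned.items():
        ids &= set(frame["snp_id"])
    ids = [s for s in first.snp_ids if s in ids]
    if len(ids) < len(exposures) + 2:
        raise InsufficientInstrumentsError(
            f"only {len(ids)} SNPs survive joint harmonization")

    def rows(frame, cols):
        sub = frame.set_index("snp_id").loc[ids]
        return tuple(sub[c].to_numpy(dtype=float) for c in cols)

    b_out, se_out = rows(h_out, ["beta_out", "se_out"])
    b1, se1, eaf1 = rows(h_out, ["beta_exp", "se_exp", "eaf_exp"])
    betas, ses, eafs, ns = [b1], [se1], [eaf1], [exposures[0].n_total]
    for i in range(1, len(exposures)):
        b, s, e = rows(aligned[f"exp{i}"], ["beta_out", "se_out", "eaf_out"])
        betas.append(b)
        ses.append(s)
        eafs.append(e)
        ns.append(exposures[i].n_total)
    have_n = all(n is not None for n in ns)
    have_eaf = all(np.all(np.isfinite(e)) for e in eafs)
    return MvmrDataset(
        snp_ids=ids,
        exposure_betas=np.column_stack(betas),
        exposure_ses=np.column_stack(ses),
        outcome_beta=b_out,
        outcome_se=se_out,
        exposure_labels=[t.trait_label or f"exposure_{i}"
                         for i, t in enumerate(exposures)],
        exposure_eafs=np.column_stack(eafs) if have_eaf else None,
        exposure_n=np.array(ns, dtype=float) if have_n else None,
    )


def analyze_mvmr(
    exposures: list[SummaryStatTable],
    outcome: SummaryStatTable,
    selection: InstrumentSelectionConfig | None = None,
    policy: HarmonizationPolicy | None = None,
) -> MvmrReport:
    """Joint selection + multivariable IVW/Egger + conditional F."""
    data = build_mvmr_dataset(exposures, outcome, selection, policy)
    ivw_res = MVMRIVW().fit(data).result_
    egger_res = MVMREgger().fit(data).result_
    cond = None
    if data.exposure_eafs is not None and data.exposure_n is not None:
        cond = tuple(conditional_f(data))
    return MvmrReport(dataset=data, ivw=ivw_res, egger=egger_res,
                      conditional_f=cond)


def run_mvmr(
    config: AnalysisConfig,
    covariate_paths: list[str],
    covariate_dialects: list[str] | None = None,
) -> MvmrReport:
    """File-based multivariable run: primary exposure + covariate exposures."""
    for path in covariate_paths:
        if not Path(path).exists():
            raise ConfigError(f"covariate file not found: {path}")
    exposure, outcome = _load_tables(config)
    dialects = covariate_dialects or ["plain"] * len(covariate_paths)
    covs = [
        read_summary_stats(p, d, trait_label=Path(p).stem)
        for p, d in zip(covariate_paths, dialects)
    ]
    report = analyze_mvmr([exposure, *covs], outcome,
                          config.selection, config.policy)
    if config.outdir:
        report.write(Path(config.outdir) / "mvmr")
    return report
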