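"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure the MR pipeline assumes: independent
SNPs with allele-frequency-determined standard errors,

    se = (2 * maf * (1 − maf) * N)^(−1/2),

true exposure effects drawn from a zero-centred normal and truncated
(by rejection sampling) so that every instrument passes genome-wide
significance with probability ≈ 1, per-SNP pleiotropic effects expressed
on the exposure-increasing allele (balanced or directional depending on
the mean), optional gross outliers displaced
by a fixed number of outcome SEs, palindromic allele pairs, and random
swapping/strand-complementing of the outcome table's alleles so that
harmonization is genuinely exercised.

Defaults mirror the study conditions of the motivating analysis: 80
exposure instruments, a true causal log-OR of log(1.41), exposure N of
602,604, outcome N of 97,173, a 17.5% palindromic fraction, and no
pleiotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SummaryStatTable
from .exceptions import ValidationError
from .mvmr import MvmrDataset

#: z for the genome-wide threshold p < 5e-8
_Z_GW = float(stats.norm.isf(2.5e-8))
#: margin added so the *observed* beta passes the threshold w.p. ~1
_Z_MARGIN = 4.0

_NONPALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic exposure/outcome pair."""

    n_snps: int = 80
    theta: float = math.log(1.41)
    n_exposure: int = 602_604
    n_outcome: int = 97_173
    maf_range: tuple[float, float] = (0.05, 0.5)
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.05
    n_outliers: int = 0
    outlier_shift_sds: float = 10.0
    palindromic_fraction: float = 0.175
    scramble_alleles: bool = True
    effect_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValidationError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        for name in ("pleiotropy_fraction", "palindromic_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not (0 <= self.n_outliers <= self.n_snps):
            raise ValidationError("n_outliers must lie in [0, n_snps]")
        if self.outlier_shift_sds <= 0:
            raise ValidationError("outlier_shift_sds must be positive")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValidationError("sample sizes must exceed 1")


def _truncated_effects(rng: np.random.Generator, sd: float,
                       thresholds: np.ndarray, max_batches: int = 500
                       ) -> np.ndarray:
    """Draw b ~ N(0, sd²) conditional on |b| > threshold, per SNP.

    Rejection sampling in vectorised batches, capped at ``max_batches``
    rounds of 1000 draws per unfilled SNP.
    """
    k = len(thresholds)
    out = np.full(k, np.nan)
    for _ in range(max_batches):
        unfilled = np.isnan(out)
        if not unfilled.any():
            return out
        idx = np.flatnonzero(unfilled)
        draws = rng.normal(0.0, sd, size=(len(idx), 1000))
        ok = np.abs(draws) > thresholds[idx, None]
        has = ok.any(axis=1)
        first = ok.argmax(axis=1)
        out[idx[has]] = draws[np.arange(len(idx))[has], first[has]]
    raise ValidationError(
        "rejection sampling failed: significance threshold implies "
        "implausibly large effects for the given effect_sd/sample size"
    )


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def simulate_pair(
    config: SimulationConfig,
) -> tuple[SummaryStatTable, SummaryStatTable, pd.DataFrame]:
    """Generate an (exposure, outcome, truth) triple.

    The truth frame records per SNP the latent quantities: maf, the true
    exposure effect, the pleiotropic effect, outlier and palindromic
    labels, and how the outcome table's alleles were re-expressed.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snps

    maf = rng.uniform(*config.maf_range, size=k)
    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)

    thresholds = (_Z_GW + _Z_MARGIN) * se_exp
    b_true = _truncated_effects(rng, config.effect_sd, thresholds)

    has_pleio = rng.random(k) < config.pleiotropy_fraction
    alpha = np.where(
        has_pleio,
        rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k),
        0.0,
    )
    # pleiotropy acts on the exposure-increasing allele, so a non-zero mean
    # is directional in the sense the Egger intercept measures
    out_true = config.theta * b_true + np.sign(b_true) * alpha

    beta_exp = b_true + se_exp * rng.standard_normal(k)
    beta_out = out_true + se_out * rng.standard_normal(k)

    is_outlier = np.zeros(k, dtype=bool)
    if config.n_outliers:
        chosen = rng.choice(k, size=config.n_outliers, replace=False)
        is_outlier[chosen] = True
        signs = rng.choice([-1.0, 1.0], size=config.n_outliers)
        beta_out[chosen] += signs * config.outlier_shift_sds * se_out[chosen]

    is_palindromic = rng.random(k) < config.palindromic_fraction
    pal_pairs = [_PALINDROMIC[i] for i in rng.integers(0, 4, size=k)]
    non_pairs = [_NONPALINDROMIC[i] for i in rng.integers(0, 8, size=k)]
    ea = np.array([p[0] if ispal else n[0]
                   for ispal, p, n in zip(is_palindromic, pal_pairs, non_pairs)])
    oa = np.array([p[1] if ispal else n[1]
                   for ispal, p, n in zip(is_palindromic, pal_pairs, non_pairs)])

    eaf_exp = maf.copy()
    eaf_out = np.clip(eaf_exp + rng.normal(0, 0.005, size=k), 0.01, 0.99)

    # outcome-table representation: possibly swap and/or strand-complement
    swap = (rng.random(k) < 0.5) if config.scramble_alleles else np.zeros(k, bool)
    comp = (rng.random(k) < 0.5) if config.scramble_alleles else np.zeros(k, bool)
    ea_out, oa_out = ea.copy(), oa.copy()
    beta_out_listed = beta_out.copy()
    eaf_out_listed = eaf_out.copy()
    for j in range(k):
        if swap[j]:
            ea_out[j], oa_out[j] = oa_out[j], ea_out[j]
            beta_out_listed[j] = -beta_out_listed[j]
            eaf_out_listed[j] = 1.0 - eaf_out_listed[j]
        if comp[j]:
            ea_out[j] = _COMP[ea_out[j]]
            oa_out[j] = _COMP[oa_out[j]]

    snp_ids = [f"rs{j + 1:06d}" for j in range(k)]
    chrom = [str(j % 22 + 1) for j in range(k)]
    pos = [(j // 22 + 1) * 20_000_000 + j for j in range(k)]

    exposure = SummaryStatTable(
        pd.DataFrame({
            "snp_id": snp_ids, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": eaf_exp,
            "beta": beta_exp, "se": se_exp, "pval": _pvals(beta_exp, se_exp),
            "n": config.n_exposure,
        }),
        trait_label="simulated_exposure",
        n_total=config.n_exposure,
    )
    outcome = SummaryStatTable(
        pd.DataFrame({
            "snp_id": snp_ids, "chrom": chrom, "pos": pos,
            "effect_allele": ea_out, "other_allele": oa_out,
            "eaf": eaf_out_listed, "beta": beta_out_listed, "se": se_out,
            "pval": _pvals(beta_out_listed, se_out), "n": config.n_outcome,
        }),
        trait_label="simulated_outcome",
        n_total=config.n_outcome,
    )
    truth = pd.DataFrame({
        "snp_id": snp_ids, "maf": maf, "b_true": b_true,
        "pleiotropy": alpha, "is_outlier": is_outlier,
        "is_palindromic": is_palindromic, "swapped": swap,
        "complemented": comp, "theta": config.theta,
    })
    return exposure, outcome, truth


def simulate_mvmr(
    config: SimulationConfig,
    theta2: float = 0.0,
    instrument_share: float = 0.5,
    effect_corr: float = 0.0,
    second_label: str = "covariate",
) -> tuple[MvmrDataset, pd.DataFrame]:
    """Two-exposure dataset with a configurable confounding path.

    The second exposure has non-zero SNP effects on ``instrument_share``
    of the SNPs; ``effect_corr`` couples those effects to the first
    exposure's (g = effect_corr·b + noise), and ``theta2`` is the second
    exposure's causal effect on the outcome.  ``theta2 * effect_corr != 0``
    creates directional pleiotropy from the first exposure's viewpoint:
    its univariable IVW is biased while the joint model is not.
    """
    if not (0 <= instrument_share <= 1):
        raise ValidationError("instrument_share must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    k = config.n_snps

    maf = rng.uniform(*config.maf_range, size=k)
    se1 = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se2 = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)

    thresholds = (_Z_GW + _Z_MARGIN) * se1
    b1 = _truncated_effects(rng, config.effect_sd, thresholds)
    shared = rng.random(k) < instrument_share
    g = np.where(
        shared,
        effect_corr * b1 + rng.normal(0, config.effect_sd / 2, size=k),
        0.0,
    )
    y_true = config.theta * b1 + theta2 * g

    beta1 = b1 + se1 * rng.standard_normal(k)
    beta2 = g + se2 * rng.standard_normal(k)
    beta_y = y_true + se_y * rng.standard_normal(k)

    snp_ids = [f"rs{j + 1:06d}" for j in range(k)]
    data = MvmrDataset(
        snp_ids=snp_ids,
        exposure_betas=np.column_stack([beta1, beta2]),
        exposure_ses=np.column_stack([se1, se2]),
        outcome_beta=beta_y,
        outcome_se=se_y,
        exposure_labels=["exposure", second_label],
        exposure_eafs=np.column_stack([maf, maf]),
        exposure_n=np.array([config.n_exposure, config.n_exposure]),
    )
    truth = pd.DataFrame({
        "snp_id": snp_ids, "maf": maf, "b1_true": b1, "b2_true": g,
        "shared": shared, "theta": config.theta, "theta2": theta2,
    })
    return data, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    """Persist the latent truth labels as TSV."""
    truth.to_csv(path, sep="\t", index=False, float_format="%.17g",
                 lineterminator="\n")
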