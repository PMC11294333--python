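"""Multivariable MR and conditional instrument strength."""

import numpy as np
import pytest

from tsmr import (
    MvmrDataset,
    conditional_f,
    instrument_strength,
    ivw,
    mvmr_egger,
    mvmr_ivw,
    simulate_mvmr,
)
from tsmr.datatypes import SummaryStatTable
from tsmr.exceptions import CollinearityError, ValidationError

from conftest import clean_sim_config


def _dataset(rng, k=20, coefs=(0.5, 0.0), noise=0.0, intercept=0.0,
             with_strength=True):
    p = len(coefs)
    betas = rng.uniform(0.05, 0.3, size=(k, p)) * rng.choice([-1, 1], (k, p))
    ses = np.full((k, p), 0.01)
    se_y = rng.uniform(0.01, 0.05, k)
    by = intercept + betas @ np.asarray(coefs) + noise * rng.normal(0, se_y)
    maf = rng.uniform(0.1, 0.5, size=(k, p))
    return MvmrDataset(
        snp_ids=[f"rs{i}" for i in range(k)],
        exposure_betas=betas,
        exposure_ses=ses,
        outcome_beta=by,
        outcome_se=se_y,
        exposure_labels=[f"exp{j}" for j in range(p)],
        exposure_eafs=maf if with_strength else None,
        exposure_n=np.full(p, 200_000.0) if with_strength else None,
    )


def test_exact_linear_system_recovered(rng):
    data = _dataset(rng, coefs=(0.5, 0.0))
    res = mvmr_ivw(data)
    assert res.estimates[0].beta == pytest.approx(0.5, abs=1e-12)
    assert res.estimates[1].beta == pytest.approx(0.0, abs=1e-12)
    assert res.q == pytest.approx(0.0, abs=1e-18)


def test_single_exposure_reduces_to_univariable_ivw(rng):
    data = _dataset(rng, coefs=(0.4,), noise=1.0)
    uni = ivw(
        np.column_stack([data.exposure_betas[:, 0], data.exposure_ses[:, 0],
                         data.outcome_beta, data.outcome_se]),
        model="fixed",
    )
    res = mvmr_ivw(data)
    assert res.estimates[0].beta == pytest.approx(uni.beta, abs=1e-12)


def test_row_order_invariance(rng):
    data = _dataset(rng, coefs=(0.3, 0.2), noise=1.0)
    perm = rng.permutation(data.k)
    shuffled = MvmrDataset(
        snp_ids=[data.snp_ids[i] for i in perm],
        exposure_betas=data.exposure_betas[perm],
        exposure_ses=data.exposure_ses[perm],
        outcome_beta=data.outcome_beta[perm],
        outcome_se=data.outcome_se[perm],
        exposure_labels=data.exposure_labels,
    )
    a, b = mvmr_ivw(data), mvmr_ivw(shuffled)
    for ea, eb in zip(a.estimates, b.estimates):
        assert ea.beta == pytest.approx(eb.beta, abs=1e-12)


def test_egger_recovers_exact_affine_model(rng):
    data = _dataset(rng, coefs=(0.3, -0.2))
    # affine in the *oriented* betas: build outcome after orientation
    sign = np.where(data.exposure_betas[:, 0] < 0, -1.0, 1.0)
    oriented = data.exposure_betas * sign[:, None]
    data.outcome_beta = (0.05 + oriented @ np.array([0.3, -0.2])) * sign
    res = mvmr_egger(data)
    assert res.intercept == pytest.approx(0.05, abs=1e-12)
    assert res.estimates[0].beta == pytest.approx(0.3, abs=1e-12)
    assert res.estimates[1].beta == pytest.approx(-0.2, abs=1e-12)


def test_egger_orientation_invariance(rng):
    data = _dataset(rng, coefs=(0.3, 0.1), noise=1.0)
    negated = MvmrDataset(
        snp_ids=data.snp_ids,
        exposure_betas=-data.exposure_betas,
        exposure_ses=data.exposure_ses,
        outcome_beta=-data.outcome_beta,
        outcome_se=data.outcome_se,
        exposure_labels=data.exposure_labels,
    )
    a, b = mvmr_egger(data), mvmr_egger(negated)
    assert a.intercept == pytest.approx(b.intercept, abs=1e-12)
    for ea, eb in zip(a.estimates, b.estimates):
        assert ea.beta == pytest.approx(eb.beta, abs=1e-12)


def test_collinear_exposures_rejected(rng):
    data = _dataset(rng, coefs=(0.3, 0.1))
    data.exposure_betas[:, 1] = 2.0 * data.exposure_betas[:, 0]
    with pytest.raises(CollinearityError, match="exp0"):
        mvmr_ivw(data)


def test_q_weakly_decreases_with_informative_exposure(rng):
    full = _dataset(rng, coefs=(0.3, 0.4), noise=1.0)
    reduced = MvmrDataset(
        snp_ids=full.snp_ids,
        exposure_betas=full.exposure_betas[:, :1],
        exposure_ses=full.exposure_ses[:, :1],
        outcome_beta=full.outcome_beta,
        outcome_se=full.outcome_se,
        exposure_labels=full.exposure_labels[:1],
    )
    assert mvmr_ivw(full).q <= mvmr_ivw(reduced).q + 1e-12


class TestConditionalF:
    def test_single_exposure_equals_total_f(self, rng):
        import pandas as pd

        data = _dataset(rng, coefs=(0.4,), noise=1.0)
        table = SummaryStatTable(
            pd.DataFrame({
                "snp_id": data.snp_ids,
                "effect_allele": "A", "other_allele": "G",
                "eaf": data.exposure_eafs[:, 0],
                "beta": data.exposure_betas[:, 0],
                "se": data.exposure_ses[:, 0],
                "pval": 1e-9,
            }),
            n_total=200_000,
        )
        assert conditional_f(data)[0] == pytest.approx(
            instrument_strength(table).total_f, rel=1e-12)

    def test_orthogonal_exposures_keep_marginal_strength(self):
        cfg = clean_sim_config(n_snps=60, theta=0.3, seed=11)
        data, _ = simulate_mvmr(cfg, theta2=0.2, instrument_share=0.5,
                                effect_corr=0.0)
        cond = conditional_f(data)
        solo = MvmrDataset(
            snp_ids=data.snp_ids,
            exposure_betas=data.exposure_betas[:, :1],
            exposure_ses=data.exposure_ses[:, :1],
            outcome_beta=data.outcome_beta,
            outcome_se=data.outcome_se,
            exposure_labels=data.exposure_labels[:1],
            exposure_eafs=data.exposure_eafs[:, :1],
            exposure_n=data.exposure_n[:1],
        )
        marginal = conditional_f(solo)[0]
        assert cond[0] == pytest.approx(marginal, rel=0.15)

    def test_duplicated_exposure_collapses(self, rng):
        data = _dataset(rng, coefs=(0.3, 0.0), noise=1.0)
        data.exposure_betas[:, 1] = (
            data.exposure_betas[:, 0] + rng.normal(0, 0.002, data.k))
        cond = conditional_f(data)
        solo = _dataset(rng, coefs=(0.3,), noise=1.0)
        assert cond[0] < 1.0 and cond[1] < 1.0

    def test_requires_strength_inputs(self, rng):
        data = _dataset(rng, coefs=(0.3, 0.1), with_strength=False)
        with pytest.raises(ValidationError, match="exposure_eafs"):
            conditional_f(data)

    def test_nonzero_crosscov_unsupported(self, rng):
        data = _dataset(rng, coefs=(0.3, 0.1))
        with pytest.raises(ValidationError, match="crosscov"):
            conditional_f(data, assume_zero_crosscov=False)


def test_dataset_invariants():
    with pytest.raises(ValidationError, match="p\\+2"):
        MvmrDataset(
            snp_ids=["a", "b", "c"],
            exposure_betas=np.ones((3, 2)),
            exposure_ses=np.ones((3, 2)),
            outcome_beta=np.ones(3),
            outcome_se=np.ones(3),
            exposure_labels=["x", "y"],
        )
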