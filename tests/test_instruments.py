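"""Instrument selection (significance filter, clumping) and strength."""

import numpy as np
import pandas as pd
import pytest

from tsmr import (
    InstrumentSelectionConfig,
    clump,
    exclude_outcome_associated,
    instrument_strength,
    per_snp_f,
    significance_filter,
    total_f_from_r2,
)
from tsmr.datatypes import SummaryStatTable
from tsmr.exceptions import ValidationError

from conftest import make_harmonized


def _table(pvals, chrom=None, pos=None, eaf=None, beta=None, n_total=None):
    k = len(pvals)
    return SummaryStatTable(
        pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(k)],
                "chrom": chrom if chrom is not None else ["1"] * k,
                "pos": pos if pos is not None else list(range(1, k + 1)),
                "effect_allele": ["A"] * k,
                "other_allele": ["G"] * k,
                "eaf": eaf if eaf is not None else [0.3] * k,
                "beta": beta if beta is not None else [0.1] * k,
                "se": [0.01] * k,
                "pval": pvals,
            }
        ),
        n_total=n_total,
    )


class TestSignificanceFilter:
    def test_strict_threshold(self):
        table = _table([1e-9, 1e-7, 1e-10])
        assert significance_filter(table).snp_ids == ["rs0", "rs2"]

    def test_boundary_excluded(self):
        assert len(significance_filter(_table([5e-8]))) == 0

    def test_null_snps_never_survive(self, rng):
        pvals = rng.uniform(size=1000)
        assert len(significance_filter(_table(list(pvals)))) == 0


class TestClump:
    def test_window_rule_keeps_best(self):
        table = _table([1e-10, 1e-9], pos=[100_000, 105_000])
        kept = clump(table)
        assert kept.snp_ids == ["rs0"]

    def test_supplied_low_r2_keeps_both(self):
        table = _table([1e-10, 1e-9], pos=[100_000, 105_000])
        ld = pd.DataFrame([[1.0, 0.0005], [0.0005, 1.0]],
                          index=["rs0", "rs1"], columns=["rs0", "rs1"])
        assert clump(table, ld=ld).snp_ids == ["rs0", "rs1"]

    def test_missing_positions_named(self):
        table = _table([1e-10, 1e-9], pos=[100_000, None])
        with pytest.raises(ValidationError, match="rs1"):
            clump(table)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_reference(self, seed):
        """Greedy clumping equals an independent re-enumeration of the rule."""
        rng = np.random.default_rng(seed)
        k = 20
        chrom = [str(c) for c in rng.integers(1, 4, size=k)]
        pos = list(rng.integers(1, 30_000_000, size=k))
        pvals = list(rng.uniform(1e-12, 1e-8, size=k))
        r2 = rng.uniform(0, 0.01, size=(k, k))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ids = [f"rs{i}" for i in range(k)]
        ld = pd.DataFrame(r2, index=ids, columns=ids)
        cfg = InstrumentSelectionConfig(clump_window_kb=5000, clump_r2=0.004)
        table = _table(pvals, chrom=chrom, pos=pos)

        # brute-force reference implementing the stated greedy rule directly
        window = cfg.clump_window_kb * 1000
        remaining = sorted(range(k),
                           key=lambda i: (pvals[i], chrom[i], pos[i], ids[i]))
        remaining = list(remaining)
        kept_ref = []
        while remaining:
            best = remaining.pop(0)
            kept_ref.append(ids[best])
            remaining = [
                j for j in remaining
                if not (chrom[j] == chrom[best]
                        and abs(pos[j] - pos[best]) <= window
                        and r2[best, j] > cfg.clump_r2)
            ]
        assert clump(table, cfg, ld=ld).snp_ids == sorted(
            kept_ref, key=lambda s: ids.index(s))

    def test_output_subset_and_pairwise_valid(self, rng):
        k = 40
        table = _table(
            list(rng.uniform(1e-12, 1e-8, size=k)),
            chrom=[str(c) for c in rng.integers(1, 3, size=k)],
            pos=list(rng.integers(1, 50_000_000, size=k)),
        )
        kept = clump(table)
        assert set(kept.snp_ids) <= set(table.snp_ids)
        df = kept.df
        for i in range(len(df)):
            for j in range(i + 1, len(df)):
                if df["chrom"].iloc[i] == df["chrom"].iloc[j]:
                    assert abs(int(df["pos"].iloc[i]) - int(df["pos"].iloc[j])) \
                        > 10_000 * 1000


class TestOutcomeExclusion:
    def test_partition(self):
        h = make_harmonized([0.1, 0.1], [0.01, 0.01], [0.05, 0.05],
                            [0.02, 0.02])
        h["pval_out"] = [6.87e-18, 0.3]
        h["flags"] = [set(), set()]
        kept, removed = exclude_outcome_associated(h)
        assert removed["snp_id"].tolist() == ["rs0"]
        assert kept["snp_id"].tolist() == ["rs1"]
        assert "excluded_outcome_assoc" in removed["flags"].iloc[0]

    def test_all_removed_leaves_empty(self):
        h = make_harmonized([0.1], [0.01], [0.5], [0.02])
        h["pval_out"] = [1e-20]
        h["flags"] = [set()]
        kept, removed = exclude_outcome_associated(h)
        assert len(kept) == 0 and len(removed) == 1


class TestStrength:
    def test_per_snp_f_values(self):
        assert per_snp_f(0.1, 0.01) == pytest.approx(100.0)
        assert per_snp_f(0.0, 0.01) == 0.0

    def test_per_snp_f_is_squared_wald_z(self, rng):
        beta = rng.normal(size=50)
        se = rng.uniform(0.01, 0.1, size=50)
        np.testing.assert_allclose(per_snp_f(beta, se), (beta / se) ** 2)

    def test_single_snp_r2(self):
        table = _table([1e-9], eaf=[0.5], beta=[0.2], n_total=1000)
        s = instrument_strength(table)
        assert s.per_snp_r2[0] == pytest.approx(0.02)

    def test_zero_r2_gives_zero_f(self):
        assert total_f_from_r2(0.0, 1000, 10) == 0.0

    def test_published_formula_inputs(self):
        """Total F from the printed discovery inputs lands at ~282."""
        f = total_f_from_r2(0.0282, 602_604, 62)
        assert f == pytest.approx(282.01, abs=0.01)
        assert abs(f - 282.43) < 0.5  # printed value from unrounded R²

    def test_monotone_in_r2_and_n(self):
        base = total_f_from_r2(0.02, 100_000, 50)
        assert total_f_from_r2(0.03, 100_000, 50) > base
        assert total_f_from_r2(0.02, 200_000, 50) > base

    def test_missing_eaf_is_loud(self):
        table = _table([1e-9, 1e-9], eaf=[0.3, None], n_total=1000)
        with pytest.raises(ValidationError, match="rs1"):
            instrument_strength(table)

    def test_genome_wide_instruments_are_strong(self):
        """Any SNP passing p < 5e-8 has F comfortably above 10."""
        from scipy import stats

        z = stats.norm.isf(2.5e-8)
        assert z**2 > 10  # squared Wald z at the threshold
        table = _table([1e-9] * 3, beta=[0.06, 0.07, 0.08])
        s = instrument_strength(
            SummaryStatTable(table.df, n_total=100_000))
        assert min(s.per_snp_f) > 10
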