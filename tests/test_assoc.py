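"""Kinship, structure covariates, mixed-model scans, consistency groups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import haplogp as hg
from haplogp.simdata import Qtl

from .conftest import random_snp_matrix
from . import oracles


def _geno_from_codes(codes):
    codes = np.asarray(codes, float)
    return hg.SnpMatrix(
        line_ids=[f"L{i}" for i in range(codes.shape[0])],
        snp_ids=[f"S{j}" for j in range(codes.shape[1])],
        chrom=np.array(["1"] * codes.shape[1], dtype=object),
        pos=np.arange(1, codes.shape[1] + 1) * 10,
        codes=codes,
    )


class TestKinship:
    def test_duplicate_line_rows_identical(self):
        rng = np.random.default_rng(0)
        codes = rng.choice([1.0, -1.0], size=(20, 50))
        codes[1] = codes[0]
        K = hg.vanraden_kinship(_geno_from_codes(codes)).matrix
        np.testing.assert_allclose(K[0], K[1])
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_hand_computed_small_matrix(self):
        codes = np.array([
            [1.0, -1.0, 1.0],
            [1.0, 1.0, -1.0],
            [-1.0, 1.0, 1.0],
            [-1.0, -1.0, -1.0],
        ])
        # alt dosage x = 1 - code; p = mean(x)/2; Z = x - 2p
        x = 1.0 - codes
        p = x.mean(axis=0) / 2.0
        Z = x - 2.0 * p
        expected = Z @ Z.T / (2.0 * np.sum(p * (1 - p)))
        K = hg.vanraden_kinship(_geno_from_codes(codes)).matrix
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_inbred_diagonal_near_two(self):
        cfg = hg.SimConfig(n_lines=300, n_chrom=2, snps_per_chrom=50, seed=21,
                           missing_rate=0.0)
        geno = hg.simulate_genotypes(cfg)
        K = hg.vanraden_kinship(geno).matrix
        # fully inbred lines: mean diagonal ~ 1 + f = 2 on the outbred scale
        assert abs(np.diag(K).mean() - 2.0) < 0.3

    def test_monomorphic_columns_dropped_with_warning(self):
        codes = np.column_stack([
            np.ones(30), np.repeat([1.0, -1.0], 15),
        ])
        with pytest.warns(UserWarning, match="monomorphic"):
            K = hg.vanraden_kinship(_geno_from_codes(codes))
        assert np.isfinite(K.matrix).all()


class TestPcaCovariates:
    def test_two_founder_groups_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(1)
        g1 = rng.choice([1.0, -1.0], size=80)
        g2 = -g1
        codes = np.vstack([
            np.tile(g1, (40, 1)), np.tile(g2, (40, 1)),
        ]) + 0.0
        flip = rng.random(codes.shape) < 0.05
        codes = np.where(flip, -codes, codes)
        scores, _ = hg.pca_covariates(_geno_from_codes(codes))
        labels = np.repeat([0, 1], 40)
        assert silhouette_score(scores.iloc[:, :1], labels) > 0.8

    def test_bic_selects_zero_pcs_under_independence(self):
        rng = np.random.default_rng(2)
        zeros = 0
        for _ in range(50):
            codes = rng.choice([1.0, -1.0], size=(100, 60))
            y = rng.normal(size=100)
            _, k = hg.pca_covariates(_geno_from_codes(codes), y, max_pcs=5)
            zeros += k == 0
        assert zeros >= 40

    def test_duplicate_lines_identical_scores(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([1.0, -1.0], size=(30, 40))
        codes[5] = codes[4]
        scores, _ = hg.pca_covariates(_geno_from_codes(codes))
        np.testing.assert_allclose(scores.iloc[4], scores.iloc[5], atol=1e-8)


class TestMlmScan:
    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(4)
        codes = rng.choice([1.0, -1.0], size=(80, 30))
        geno = _geno_from_codes(codes)
        y = pd.Series(rng.normal(size=80), index=geno.line_ids)
        K = hg.KinshipMatrix(np.eye(80), geno.line_ids, "identity")
        res = hg.mlm_scan_snp(y, geno, K)
        for _, row in res.iterrows():
            j = geno.snp_ids.index(row["locus"])
            ols = sps.linregress(codes[:, j], y.to_numpy())
            assert row["p_value"] == pytest.approx(ols.pvalue, abs=1e-6)

    def test_planted_qtl_detected(self):
        # QTL at ~10% of the entry-mean phenotypic variance, scanned on the
        # across-environment mean; kinship from the other chromosome
        # (leave-one-chromosome-out) to avoid proximal contamination
        detections = 0
        for seed in range(10):
            cfg = hg.SimConfig(n_lines=500, n_chrom=2, snps_per_chrom=100,
                               seed=seed, missing_rate=0.0,
                               qtl_spec=[Qtl(0, 1.0, 0.2)], h2_target=0.5)
            geno = hg.simulate_genotypes(cfg)
            records, _ = hg.simulate_trials(geno, cfg)
            adj = hg.adjust_gy_block_effects(records)
            y = adj.values.droplevel(0, axis=1).mean(axis=1)
            loco = geno.subset_snps(np.where(geno.chrom == "2")[0])
            K = hg.vanraden_kinship(loco)
            res = hg.mlm_scan_snp(y, geno, K)
            p0 = res.loc[res["locus"] == geno.snp_ids[0], "p_value"].iloc[0]
            if p0 < 1e-4:
                detections += 1
        assert detections >= 9

    def test_allele_label_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(5)
        codes = rng.choice([1.0, -1.0], size=(60, 10))
        geno = _geno_from_codes(codes)
        y = pd.Series(rng.normal(size=60), index=geno.line_ids)
        K = hg.vanraden_kinship(geno)
        res1 = hg.mlm_scan_snp(y, geno, K)
        flipped = codes.copy()
        flipped[:, 3] *= -1.0
        res2 = hg.mlm_scan_snp(y, _geno_from_codes(flipped), K)
        assert res1.loc[3, "p_value"] == pytest.approx(res2.loc[3, "p_value"], rel=1e-9)
        assert res1.loc[3, "effect"] == pytest.approx(-res2.loc[3, "effect"], rel=1e-9)


class TestHapScan:
    def _block_data(self, seed=0, n=200, delta=0.0):
        rng = np.random.default_rng(seed)
        carrier = rng.random(n) < 0.5
        inc = np.column_stack([carrier, ~carrier]).astype(np.int8)
        H = hg.HapMatrix(
            line_ids=[f"L{i}" for i in range(n)],
            incidence=inc,
            columns=pd.DataFrame(
                {"block": ["HB1.1", "HB1.1"], "allele": ["AA", "TT"],
                 "freq": [carrier.mean(), 1 - carrier.mean()]}
            ),
            missing=np.zeros((n, 1), dtype=bool),
            block_names=["HB1.1"],
            block_of_col=np.array([0, 0]),
        )
        y = pd.Series(rng.normal(size=n) + delta * carrier, index=H.line_ids)
        return H, y, carrier

    def test_two_allele_block_equals_single_dummy_test(self):
        H, y, carrier = self._block_data(seed=6, delta=0.5)
        K = hg.KinshipMatrix(np.eye(len(y)), list(y.index), "identity")
        res = hg.mlm_scan_hap(y, H, K)
        ols = sps.linregress(carrier.astype(float), y.to_numpy())
        assert res.loc[0, "p_value"] == pytest.approx(ols.pvalue, abs=1e-6)
        assert res.loc[0, "df"] == 1

    def test_null_block_p_roughly_uniform(self):
        pvals = []
        for seed in range(60):
            H, y, _ = self._block_data(seed=seed, delta=0.0)
            K = hg.KinshipMatrix(np.eye(len(y)), list(y.index), "identity")
            pvals.append(hg.mlm_scan_hap(y, H, K).loc[0, "p_value"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_block_r2_at_least_member_snp_r2(self):
        cfg = hg.SimConfig(n_lines=250, n_chrom=1, snps_per_chrom=6,
                           block_size_range=(3, 3), seed=31, missing_rate=0.0,
                           founder_haplotypes_per_block=3,
                           qtl_spec=[Qtl(0, 1.0, 0.2, level="block")])
        geno = hg.simulate_genotypes(cfg)
        records, _ = hg.simulate_trials(geno, cfg)
        adj = hg.adjust_gy_block_effects(records)
        y = adj.values[("EYT1", "B-5IR")]
        blocks = hg.build_blocks(geno)
        H = hg.call_haplotypes(geno, blocks, hap_freq_min=0.0)
        K = hg.KinshipMatrix(np.eye(geno.n_lines), geno.line_ids, "identity")
        hap = hg.mlm_scan_hap(y, H, K)
        snp = hg.mlm_scan_snp(y, geno, K)
        for _, brow in hap.iterrows():
            block = next(b for b in blocks if b.name == brow["locus"])
            if any(H.missing[:, blocks.index(block)]):
                continue
            member_r2 = snp[snp["locus"].isin(block.snp_ids)]["r2"]
            assert brow["r2"] >= member_r2.max() - 1e-8

    def test_hap_scan_mean_r2_beats_snp_scan_on_multiallelic_qtl(self):
        cfg = hg.SimConfig(n_lines=400, n_chrom=2, snps_per_chrom=12,
                           block_size_range=(3, 3), seed=33, missing_rate=0.0,
                           founder_haplotypes_per_block=4,
                           qtl_spec=[Qtl(1, 1.0, 0.25, level="block")],
                           h2_target=0.6)
        geno = hg.simulate_genotypes(cfg)
        records, _ = hg.simulate_trials(geno, cfg)
        adj = hg.adjust_gy_block_effects(records)
        y = adj.values[("EYT1", "B-5IR")]
        blocks = hg.build_blocks(geno)
        H = hg.call_haplotypes(geno, blocks)
        K = hg.vanraden_kinship(geno)
        hap = hg.mlm_scan_hap(y, H, K)
        snp = hg.mlm_scan_snp(y, geno, K)
        assert hap["r2"].mean() > snp["r2"].mean()


class TestClassifyGroups:
    def _results(self, sig):
        rows = []
        for eyt in ("EYT1", "EYT2"):
            for env in ("A", "B"):
                rows.append({"locus": "HB1.1", "eyt": eyt, "env": env,
                             "p_value": 1e-9 if (eyt, env) in sig else 0.9})
        return pd.DataFrame(rows)

    def test_single_trial_is_group1(self):
        res = hg.classify_groups(self._results({("EYT1", "A")}), 1e-3)
        assert res.loc[0, "group"] == 1

    def test_single_env_across_eyts_is_group2(self):
        res = hg.classify_groups(
            self._results({("EYT1", "A"), ("EYT2", "A")}), 1e-3
        )
        assert res.loc[0, "group"] == 2

    def test_nowhere_significant_excluded(self):
        res = hg.classify_groups(self._results(set()), 1e-3)
        assert res.empty

    def test_all_patterns_match_rule_table_oracle(self):
        from itertools import product

        trials = [(e, v) for e in ("EYT1", "EYT2") for v in ("A", "B")]
        for mask in product([False, True], repeat=4):
            sig = {t for t, m in zip(trials, mask) if m}
            res = hg.classify_groups(self._results(sig), 1e-3)
            expect = oracles.group_rule(sig)
            if expect is None:
                assert res.empty
            else:
                assert res.loc[0, "group"] == expect
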