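"""Kernels, mixed-model fitting, cross-validation and model comparison."""

import numpy as np
import pandas as pd
import pytest

import haplogp as hg
from haplogp.simdata import Qtl

from .conftest import random_snp_matrix


def _geno(rng, n=40, m=30):
    return random_snp_matrix(rng, n_lines=n, n_snps=m)


class TestKernels:
    def test_single_snp_hand_example_before_scaling(self):
        geno = hg.SnpMatrix(
            line_ids=["a", "b"], snp_ids=["S1"],
            chrom=np.array(["1"], dtype=object), pos=np.array([100]),
            codes=np.array([[1.0], [-1.0]]),
        )
        K = hg.kernel_additive(geno, scale=False)
        np.testing.assert_allclose(K.matrix, [[1.0, -1.0], [-1.0, 1.0]])

    def test_duplicate_lines_maximal_off_diagonal(self):
        rng = np.random.default_rng(0)
        geno = _geno(rng)
        geno.codes[1] = geno.codes[0]
        K = hg.kernel_additive(geno).matrix
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_haplotype_kernel_counts_shared_alleles(self):
        inc = np.array([
            [1, 0, 1, 0, 1],
            [1, 0, 1, 0, 1],
            [0, 1, 0, 1, 0],
        ], dtype=np.int8)
        H = hg.HapMatrix(
            line_ids=["a", "b", "c"], incidence=inc,
            columns=pd.DataFrame({"block": ["B1", "B1", "B2", "B2", "B3"],
                                  "allele": list("AGCTA"),
                                  "freq": [0.6, 0.4, 0.6, 0.4, 0.6]}),
            missing=np.zeros((3, 3), dtype=bool),
            block_names=["B1", "B2", "B3"],
            block_of_col=np.array([0, 0, 1, 1, 2]),
        )
        K = hg.kernel_haplotype(H, scale=False).matrix
        assert K[0, 1] == pytest.approx(3.0)   # share all 3 blocks
        assert K[0, 2] == pytest.approx(0.0)   # disjoint haplotypes

    def test_gaussian_kernel_formula_and_extremes(self):
        geno = hg.SnpMatrix(
            line_ids=["a", "b"], snp_ids=[f"S{j}" for j in range(5)],
            chrom=np.array(["1"] * 5, dtype=object),
            pos=np.arange(1, 6) * 10,
            codes=np.vstack([np.ones(5), -np.ones(5)]),
        )
        K = hg.kernel_gaussian(geno, theta=0.7)
        # maximally different lines: D = sqrt((1/(4m)) * m * 4) = 1
        assert K.matrix[0, 1] == pytest.approx(np.exp(-1.0 / 0.7))
        assert K.matrix[0, 0] == pytest.approx(1.0)

    def test_gaussian_monotone_in_distance(self):
        rng = np.random.default_rng(1)
        geno = _geno(rng, n=25)
        K = hg.kernel_gaussian(geno)
        S = np.nan_to_num(geno.codes)
        sq = ((S[:, None, :] - S[None, :, :]) ** 2).sum(-1)
        iu = np.triu_indices(25, k=1)
        order = np.argsort(sq[iu])
        kvals = K.matrix[iu][order]
        assert (np.diff(kvals) <= 1e-12).all()

    def test_all_kernels_symmetric_psd_unit_diag(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            geno = _geno(rng)
            blocks = [hg.HapBlock(name="HB1.1", chrom="1", snp_indices=[0, 1])]
            H = hg.call_haplotypes(geno, blocks, hap_freq_min=0.0)
            for kern in (hg.kernel_additive(geno), hg.kernel_haplotype(H),
                         hg.kernel_gaussian(geno), hg.kernel_gaussian(H)):
                M = kern.matrix
                np.testing.assert_allclose(M, M.T)
                assert np.linalg.eigvalsh(M).min() > -1e-8
                if kern.kind in ("G_MG", "G_HG"):
                    np.testing.assert_allclose(np.diag(M), 1.0)
                    assert (M > 0).all() and (M <= 1 + 1e-12).all()


class TestFitModel:
    def _sim(self, seed=0, n=200, qtl=None, h2=0.5):
        cfg = hg.SimConfig(n_lines=n, n_chrom=2, snps_per_chrom=20, seed=seed,
                           missing_rate=0.0, qtl_spec=qtl or (), h2_target=h2)
        geno = hg.simulate_genotypes(cfg)
        records, truth = hg.simulate_trials(geno, cfg)
        adj = hg.adjust_gy_block_effects(records)
        y = adj.values.droplevel(0, axis=1)
        return geno, y, truth

    def test_identity_kernel_predicts_environment_means(self):
        geno, y, _ = self._sim(seed=3, n=80)
        kern = hg.Kernel(np.eye(80), "G_M", list(geno.line_ids))
        spec = hg.ModelSpec.from_id(1, epistasis=False)
        train = list(y.index[:60])
        test = list(y.index[60:])
        fit = hg.fit_model(spec, y, [kern], backend="reml", train_lines=train)
        pred = hg.predict(fit, test)
        # no information transfers to held-out lines: predictions flat per env
        assert float(pred.std(axis=0).max()) < 1e-6
        expect = y.loc[train].mean(axis=0)
        got = pred.iloc[0]
        # intercept absorbs the train mean; envs keep their relative offsets
        np.testing.assert_allclose(
            got - got.mean(), expect - expect.mean(), atol=1e-6
        )

    def test_gibbs_matches_reml_single_kernel(self):
        geno, y, _ = self._sim(seed=4, n=150)
        kern = hg.kernel_additive(geno)
        spec = hg.ModelSpec.from_id(1, epistasis=False)
        train = list(y.index[:120])
        test = list(y.index[120:])
        fit_r = hg.fit_model(spec, y, [kern], backend="reml", train_lines=train)
        fit_g = hg.fit_model(spec, y, [kern], backend="gibbs", train_lines=train,
                             chain=hg.ChainSettings(3000, 600), seed=9)
        pr = hg.predict(fit_r, test).to_numpy().ravel()
        pg = hg.predict(fit_g, test).to_numpy().ravel()
        assert np.corrcoef(pr, pg)[0, 1] > 0.99

    def test_fit_deterministic_under_seed(self):
        geno, y, _ = self._sim(seed=5, n=100)
        kern = hg.kernel_additive(geno)
        spec = hg.ModelSpec.from_id(1, epistasis=False)
        f1 = hg.fit_model(spec, y, [kern], seed=7, chain=hg.ChainSettings(500, 100))
        f2 = hg.fit_model(spec, y, [kern], seed=7, chain=hg.ChainSettings(500, 100))
        np.testing.assert_array_equal(f1.beta, f2.beta)
        np.testing.assert_array_equal(f1.u["G_M"], f2.u["G_M"])

    def test_fixed_qtl_beta_recovered_when_kernel_excludes_it(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 250
            codes = rng.choice([1.0, -1.0], size=(n, 41))
            geno = hg.SnpMatrix(
                line_ids=[f"L{i}" for i in range(n)],
                snp_ids=[f"S{j}" for j in range(41)],
                chrom=np.array(["1"] * 41, dtype=object),
                pos=np.arange(1, 42) * 10, codes=codes,
            )
            x = codes[:, 0]
            background = hg.kernel_additive(geno.subset_snps(np.arange(1, 41)))
            beta_true = 1.0
            u = rng.standard_normal(40) / np.sqrt(40)
            poly = codes[:, 1:] @ u
            yv = beta_true * x + poly + rng.normal(0, 1.0, n)
            y = pd.Series(yv, index=geno.line_ids)
            fixed = pd.DataFrame({"qtl": x}, index=geno.line_ids)
            spec = hg.ModelSpec.from_id(3, epistasis=False)
            fit = hg.fit_model(spec, y, [background], fixed_loci=fixed,
                               chain=hg.ChainSettings(1500, 300), seed=seed)
            errs.append(fit.beta[1] - beta_true)
        assert abs(np.mean(errs)) < 0.25 * 1.0

    def test_epistasis_kernel_enters_as_extra_random_term(self):
        geno, y, _ = self._sim(seed=6, n=120)
        km = hg.kernel_additive(geno)
        ke = hg.kernel_gaussian(geno, kind="epistasis")
        spec = hg.ModelSpec.from_id(2)
        fit = hg.fit_model(spec, y, [km, ke], chain=hg.ChainSettings(800, 200),
                           seed=3)
        assert set(fit.u) == {"G_M", "epistasis"}
        assert fit.var_components["epistasis"] > 0


class TestCrossValidation:
    def test_same_seed_identical_accuracy_vectors(self):
        cfg = hg.SimConfig(n_lines=100, n_chrom=1, snps_per_chrom=10, seed=8,
                           missing_rate=0.0)
        geno = hg.simulate_genotypes(cfg)
        records, _ = hg.simulate_trials(geno, cfg)
        y = hg.adjust_gy_block_effects(records).values.droplevel(0, axis=1)
        kern = hg.kernel_additive(geno)
        spec = hg.ModelSpec.from_id(1, epistasis=False)
        a = hg.cross_validate(spec, y, [kern], repeats=4, seed=5, backend="reml")
        b = hg.cross_validate(spec, y, [kern], repeats=4, seed=5, backend="reml")
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        assert a.split_hashes == b.split_hashes

    def test_pure_noise_accuracy_near_zero(self):
        rng = np.random.default_rng(9)
        cfg = hg.SimConfig(n_lines=200, n_chrom=1, snps_per_chrom=10, seed=10,
                           missing_rate=0.0)
        geno = hg.simulate_genotypes(cfg)
        y = pd.DataFrame(rng.normal(size=(200, 5)),
                         index=geno.line_ids,
                         columns=[f"E{i}" for i in range(5)])
        kern = hg.kernel_additive(geno)
        spec = hg.ModelSpec.from_id(1, epistasis=False)
        res = hg.cross_validate(spec, y, [kern], repeats=20, seed=3, backend="reml")
        n_test = 20
        assert abs(res.mean) < 2.0 / np.sqrt(n_test * 5 * res.n_repeats) + 0.05

    def test_accuracy_increases_with_heritability(self):
        means = {}
        for h2 in (0.1, 0.7):
            accs = []
            for seed in range(4):
                cfg = hg.SimConfig(n_lines=250, n_chrom=2, snps_per_chrom=25,
                                   seed=seed, missing_rate=0.0, h2_target=h2)
                geno = hg.simulate_genotypes(cfg)
                records, _ = hg.simulate_trials(geno, cfg)
                y = hg.adjust_gy_block_effects(records).values.droplevel(0, axis=1)
                kern = hg.kernel_additive(geno)
                spec = hg.ModelSpec.from_id(1, epistasis=False)
                res = hg.cross_validate(spec, y, [kern], repeats=10, seed=4,
                                        backend="reml")
                accs.append(res.mean)
            means[h2] = np.mean(accs)
        assert means[0.7] > means[0.1]


class TestCompareModels:
    def _cv(self, model_id, accs, hashes):
        return hg.CVResult(model_id=model_id, accuracies=np.asarray(accs),
                           split_hashes=hashes, n_repeats=len(accs))

    def test_identical_models_zero_differences(self):
        h = ["a", "b", "c", "d"]
        accs = [0.3, 0.4, 0.35, 0.45]
        table = hg.compare_models([self._cv(1, accs, h), self._cv(2, accs, h)])
        assert table.loc[1, "diff_vs_base"] == pytest.approx(0.0)
        assert not table.loc[1, "exceeds_lsd"]

    def test_known_offset_recovered_exactly(self):
        h = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(11)
        base = rng.uniform(0.2, 0.5, 10)
        table = hg.compare_models(
            [self._cv(1, base, h), self._cv(4, base + 0.07, h)]
        )
        assert table.loc[1, "diff_vs_base"] == pytest.approx(0.07)
        assert table.loc[1, "exceeds_lsd"]

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError, match="split"):
            hg.compare_models([
                self._cv(1, [0.3, 0.4], ["a", "b"]),
                self._cv(2, [0.3, 0.4], ["a", "c"]),
            ])
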