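"""Mixed-linear-model association scans for SNPs and haplotype blocks.

The model per trial is ``y = X b + m a + Z u + e`` with ``u ~ N(0, K s2g)``
and ``e ~ N(0, I s2e)``: fixed covariates X (intercept, principal
components chosen by BIC, optional line-level covariate means and gene
markers), a marker or haplotype term, and a random polygenic term whose
covariance is the VanRaden genomic relationship matrix.  REML is solved
exactly on the null model through a single eigendecomposition of K
(EMMA-style); the resulting variance ratio is reused for every marker
(the P3D/EMMAX approximation; exact per-marker REML is available via
``p3d=False``).

Significant loci are classified across trials into the four consistency
groups: (1) significant in a single trial year only, (2) strictly in one
environment across years, (3) in multiple environments of each of several
years, (4) across years but in varying environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .ldblocks import HapMatrix, SnpMatrix


@dataclass
class KinshipMatrix:
    matrix: np.ndarray
    line_ids: list[str]
    method: str = "vanraden"

    def __post_init__(self) -> None:
        G = np.asarray(self.matrix, float)
        if not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        self.matrix = (G + G.T) / 2.0


@dataclass
class MlmFit:
    """Null-model REML fit: variance components and the spectral pieces."""

    sigma_g2: float
    sigma_e2: float
    loglik: float
    beta: np.ndarray
    delta: float                       # s2e / s2g
    eigvals: np.ndarray = field(repr=False, default=None)
    eigvecs: np.ndarray = field(repr=False, default=None)

    @property
    def lam(self) -> float:
        """Variance ratio s2g / s2e."""
        return self.sigma_g2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf


# ---------------------------------------------------------------------------
# kinship and structure covariates
# ---------------------------------------------------------------------------

def vanraden_kinship(geno: SnpMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship: G = Z Z' / (2 sum p(1-p)).

    Z is the alternate-allele dosage matrix column-centered by twice the
    allele frequency; missing genotypes contribute zero after centering.
    Monomorphic SNPs are dropped with a warning.  On a fully inbred panel
    the diagonal averages about 1 + f = 2 on this (outbred) scale.
    """
    dosage = (1.0 - geno.codes) / 2.0 * 2.0          # alt-allele count in 0..2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosage, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.all():
        warnings.warn(
            f"dropping {int((~poly).sum())} monomorphic/all-missing SNPs "
            "from the kinship computation", stacklevel=2,
        )
    dosage, p = dosage[:, poly], p[poly]
    Z = np.where(np.isnan(dosage), 0.0, dosage - 2.0 * p)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("no polymorphic SNPs for kinship")
    G = Z @ Z.T / denom
    return KinshipMatrix(matrix=G, line_ids=list(geno.line_ids))


def pca_covariates(
    geno: SnpMatrix, y: np.ndarray | pd.Series | None = None, max_pcs: int = 10
) -> tuple[pd.DataFrame, int | None]:
    """Centered-genotype principal component scores and a BIC-chosen count.

    Missing genotypes are mean-imputed for the PCA only.  When a phenotype
    is supplied, k in 0..max_pcs is chosen by minimizing the BIC of the
    phenotype-on-PCs regression; otherwise k is None and all ``max_pcs``
    score columns are returned for the caller to choose from.
    """
    X = geno.codes.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    inds = np.where(np.isnan(X))
    X[inds] = mu[inds[1]]
    X = X - X.mean(axis=0)
    n = X.shape[0]
    max_pcs = int(min(max_pcs, n - 2, X.shape[1]))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :max_pcs] * s[:max_pcs]
    table = pd.DataFrame(
        scores, index=geno.line_ids, columns=[f"PC{i+1}" for i in range(max_pcs)]
    )
    if y is None:
        return table, None
    yv = np.asarray(y, float)
    best_k, best_bic = 0, np.inf
    for k in range(max_pcs + 1):
        Xk = np.column_stack([np.ones(n), scores[:, :k]])
        beta, *_ = np.linalg.lstsq(Xk, yv, rcond=None)
        rss = float(np.sum((yv - Xk @ beta) ** 2))
        bic = n * np.log(rss / n) + (k + 1) * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_k = bic, k
    return table, best_k


# ---------------------------------------------------------------------------
# REML via the spectral decomposition of K
# ---------------------------------------------------------------------------

def _reml_loglik(log_delta: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    delta = np.exp(log_delta)
    n, q = Xt.shape
    w = 1.0 / (s + delta)
    XtW = Xt * w[:, None]
    A = Xt.T @ XtW
    beta = np.linalg.solve(A, XtW.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    nq = n - q
    sign, logdet_a = np.linalg.slogdet(A)
    _, logdet_x = np.linalg.slogdet(Xt.T @ Xt)
    ll = 0.5 * (
        nq * np.log(nq / (2 * np.pi)) - nq - nq * np.log(rss)
        - np.sum(np.log(s + delta)) - logdet_a + logdet_x
    )
    return ll


def fit_mlm_null(y: np.ndarray, X: np.ndarray, K: KinshipMatrix) -> MlmFit:
    """Exact REML for the null mixed model via one eigendecomposition of K."""
    yv = np.asarray(y, float)
    Xv = np.atleast_2d(np.asarray(X, float))
    s, U = np.linalg.eigh(K.matrix)
    s = np.clip(s, 0.0, None)
    yt, Xt = U.T @ yv, U.T @ Xv
    grid = np.linspace(np.log(1e-5), np.log(1e5), 40)
    lls = [_reml_loglik(g, s, yt, Xt) for g in grid]
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, s, yt, Xt), bounds=(lo, hi), method="bounded"
    )
    log_delta = float(res.x)
    delta = float(np.exp(log_delta))
    n, q = Xt.shape
    w = 1.0 / (s + delta)
    XtW = Xt * w[:, None]
    A = Xt.T @ XtW
    beta = np.linalg.solve(A, XtW.T @ yt)
    r = yt - Xt @ beta
    sigma_g2 = float(np.sum(w * r * r) / (n - q))
    return MlmFit(
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        loglik=float(-res.fun),
        beta=beta,
        delta=delta,
        eigvals=s,
        eigvecs=U,
    )


def _whitened(fit: MlmFit, y: np.ndarray, X: np.ndarray):
    """Rotate and whiten data under the fitted null covariance."""
    sw = 1.0 / np.sqrt(fit.eigvals + fit.delta)
    ys = (fit.eigvecs.T @ y) * sw
    Xs = (fit.eigvecs.T @ X) * sw[:, None]
    return ys, Xs


def _residualize(Xs: np.ndarray, V: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Xs, V, rcond=None)
    return V - Xs @ coef


def _assemble_covars(n: int, line_ids: list[str], covars: pd.DataFrame | None):
    X = np.ones((n, 1))
    if covars is not None and covars.shape[1] > 0:
        C = covars.reindex(line_ids).to_numpy(float)
        C = np.where(np.isnan(C), np.nanmean(C, axis=0), C)
        keep, R = [], [np.ones(n)]
        for j in range(C.shape[1]):
            col = C[:, j]
            B = np.column_stack(R)
            res = col - B @ np.linalg.lstsq(B, col, rcond=None)[0]
            if np.linalg.norm(res) > 1e-8 * max(np.linalg.norm(col), 1.0):
                keep.append(j)
                R.append(col)
            else:
                warnings.warn(
                    f"dropping collinear covariate {covars.columns[j]!r}",
                    stacklevel=3,
                )
        X = np.column_stack([np.ones(n), C[:, keep]]) if keep else X
    return X


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def mlm_scan_snp(
    y: pd.Series,
    geno: SnpMatrix,
    K: KinshipMatrix,
    covars: pd.DataFrame | None = None,
    trial: tuple[str, str] | None = None,
    p3d: bool = True,
) -> pd.DataFrame:
    """Single-marker mixed-model scan for one trial's adjusted means.

    Returns per SNP the Wald/F p-value for the marker effect, the marker
    R^2 on the whitened scale, and the allele effect (half the difference
    between the homozygote means) in trait units and % of the trial mean.
    """
    line_ids = list(geno.line_ids)
    yv = y.reindex(line_ids).to_numpy(float)
    ok = ~np.isnan(yv)
    if not ok.all():
        geno = geno.subset_lines(np.where(ok)[0])
        line_ids = list(geno.line_ids)
        K = KinshipMatrix(K.matrix[np.ix_(ok, ok)], line_ids, K.method)
        yv = yv[ok]
    n = yv.size
    X = _assemble_covars(n, line_ids, covars)
    fit = fit_mlm_null(yv, X, K)
    M = geno.codes.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(M, axis=0)
    all_missing = np.isnan(mu)
    mu = np.where(all_missing, 0.0, mu)
    inds = np.where(np.isnan(M))
    M[inds] = mu[inds[1]]

    rows = []
    trial_mean = float(np.mean(yv))
    if p3d:
        ys, Xs = _whitened(fit, yv, X)
        Ms = (fit.eigvecs.T @ M) * (1.0 / np.sqrt(fit.eigvals + fit.delta))[:, None]
        y_r = _residualize(Xs, ys[:, None])[:, 0]
        M_r = _residualize(Xs, Ms)
        tss = float(y_r @ y_r)
        mm = np.einsum("ij,ij->j", M_r, M_r)
        my = M_r.T @ y_r
        df2 = n - X.shape[1] - 1
        for j in range(geno.n_snps):
            if all_missing[j] or mm[j] <= 1e-12:
                continue
            ess = my[j] ** 2 / mm[j]
            rss1 = tss - ess
            fstat = ess / (rss1 / df2)
            p = float(sps.f.sf(fstat, 1, df2))
            alpha = my[j] / mm[j]
            rows.append(
                {
                    "locus": geno.snp_ids[j],
                    "chrom": geno.chrom[j],
                    "pos": int(geno.pos[j]),
                    "p_value": max(p, np.finfo(float).tiny),
                    "r2": ess / tss if tss > 0 else 0.0,
                    "effect": float(alpha),
                    "effect_pct": float(alpha / trial_mean * 100.0),
                }
            )
    else:
        for j in range(geno.n_snps):
            if all_missing[j]:
                continue
            Xj = np.column_stack([X, M[:, j]])
            fit_j = fit_mlm_null(yv, Xj, K)
            ys, Xs = _whitened(fit_j, yv, Xj)
            y_r0 = _residualize(Xs[:, :-1], ys[:, None])[:, 0]
            m_r = _residualize(Xs[:, :-1], Xs[:, -1:])[:, 0]
            tss = float(y_r0 @ y_r0)
            mm = float(m_r @ m_r)
            if mm <= 1e-12:
                continue
            ess = float(m_r @ y_r0) ** 2 / mm
            df2 = n - Xj.shape[1]
            fstat = ess / ((tss - ess) / df2)
            p = float(sps.f.sf(fstat, 1, df2))
            rows.append(
                {
                    "locus": geno.snp_ids[j],
                    "chrom": geno.chrom[j],
                    "pos": int(geno.pos[j]),
                    "p_value": max(p, np.finfo(float).tiny),
                    "r2": ess / tss if tss > 0 else 0.0,
                    "effect": float((m_r @ y_r0) / mm),
                    "effect_pct": float((m_r @ y_r0) / mm / trial_mean * 100.0),
                }
            )
    out = pd.DataFrame(rows)
    if trial is not None and not out.empty:
        out.insert(1, "eyt", trial[0])
        out.insert(2, "env", trial[1])
    return out


def mlm_scan_hap(
    y: pd.Series,
    H: HapMatrix,
    K: KinshipMatrix,
    covars: pd.DataFrame | None = None,
    trial: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Haplotype-block mixed-model scan: omnibus F-test per block.

    The omnibus test jointly tests the (a-1) incidence columns of a block's
    common alleles (most frequent allele as reference) with a - 1 numerator
    degrees of freedom; per-allele effects are reported descriptively as
    the allele-mean deviation from the block mean, absolute and as % of the
    trial mean.  Lines missing the block are frequency-imputed for the test
    only; blocks with fewer than two common alleles are skipped.
    """
    line_ids = list(H.line_ids)
    yv = y.reindex(line_ids).to_numpy(float)
    ok = ~np.isnan(yv)
    idx = np.where(ok)[0]
    inc = H.incidence[idx].astype(float)
    miss = H.missing[idx]
    Km = KinshipMatrix(K.matrix[np.ix_(ok, ok)], [line_ids[i] for i in idx], K.method)
    yv = yv[idx]
    n = yv.size
    X = _assemble_covars(n, [line_ids[i] for i in idx], covars)
    fit = fit_mlm_null(yv, X, Km)
    ys, Xs = _whitened(fit, yv, X)
    y_r = _residualize(Xs, ys[:, None])[:, 0]
    tss = float(y_r @ y_r)
    sw = 1.0 / np.sqrt(fit.eigvals + fit.delta)
    trial_mean = float(np.mean(yv))

    rows = []
    for b, name in enumerate(H.block_names):
        cols = np.where(H.block_of_col == b)[0]
        if cols.size < 2:
            continue
        freqs = H.columns.loc[cols, "freq"].to_numpy(float)
        order = np.argsort(-freqs, kind="stable")
        tested = cols[order[1:]]                    # drop reference allele
        D = inc[:, tested].copy()
        bm = miss[:, b]
        if bm.any():
            if H.scores is not None:
                D[bm] = H.scores[idx][np.ix_(bm, tested)]
            else:
                D[bm] = freqs[order[1:]]            # marginal frequencies
        Ds = (fit.eigvecs.T @ D) * sw[:, None]
        D_r = _residualize(Xs, Ds)
        q, _ = np.linalg.qr(D_r)
        proj = q.T @ y_r
        ess = float(proj @ proj)
        dfn = tested.size
        df2 = n - X.shape[1] - dfn
        rss1 = tss - ess
        if rss1 <= 0 or df2 <= 0:
            continue
        fstat = (ess / dfn) / (rss1 / df2)
        p = float(sps.f.sf(fstat, dfn, df2))
        called = ~bm
        y_called = yv[called]
        block_mean = float(np.mean(y_called)) if called.any() else np.nan
        effects = {}
        for c in cols:
            carriers = inc[called, c] == 1
            if carriers.sum() == 0:
                continue
            eff = float(np.mean(y_called[carriers]) - block_mean)
            effects[H.columns.loc[c, "allele"]] = (
                eff, eff / trial_mean * 100.0
            )
        rows.append(
            {
                "locus": name,
                "p_value": max(p, np.finfo(float).tiny),
                "r2": ess / tss if tss > 0 else 0.0,
                "df": dfn,
                "allele_effects": effects,
            }
        )
    out = pd.DataFrame(rows)
    if trial is not None and not out.empty:
        out.insert(1, "eyt", trial[0])
        out.insert(2, "env", trial[1])
    return out


# ---------------------------------------------------------------------------
# significance and consistency groups
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Default genome-wide threshold; the per-test alpha under Bonferroni."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def classify_groups(results: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Assign each significant locus to one of the four consistency groups.

    1: significant in only one EYT; 2: in >= 2 EYTs but always the same
    single environment; 3: in >= 2 EYTs with multiple environments in each;
    4: in >= 2 EYTs in varying environments.  Loci significant nowhere are
    excluded.
    """
    sig = results[results["p_value"] <= p_threshold]
    rows = []
    for locus, ldf in sig.groupby("locus", sort=True):
        eyts = ldf["eyt"].unique()
        if eyts.size == 1:
            group = 1
        else:
            envs_all = set(ldf["env"])
            envs_per_eyt = ldf.groupby("eyt")["env"].nunique()
            if len(envs_all) == 1:
                group = 2
            elif (envs_per_eyt >= 2).all():
                group = 3
            else:
                group = 4
        rows.append(
            {
                "locus": locus,
                "group": group,
                "n_eyts": int(eyts.size),
                "n_trials": int(ldf.shape[0]),
                "min_p": float(ldf["p_value"].min()),
            }
        )
    return pd.DataFrame(rows, columns=["locus", "group", "n_eyts", "n_trials", "min_p"])
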