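"""G-BLUP genomic prediction with four relationship matrices.

The prediction model is ``y = X b + Z u + e`` with ``u ~ N(0, G s2g)`` and
``e ~ N(0, I s2e)``; y stacks adjusted entry means over the environments of
one trial year and X carries one intercept per environment plus optional
GWAS-derived locus columns.  Four relationship matrices are supported:

* G_M  = M M' on marker codes {1, 0, -1} (Model 1);
* G_H  = H H' on binary haplotype-allele incidence (Model 2);
* G_MG = exp(-D/theta) with D the Euclidean marker distance normalised by
  1/(4m) so D is in [0, 1] (Model 3);
* G_HG = the same Gaussian kernel on haplotype scores, normalised by 1/m
  because binary scores differ by at most 1 per column (Model 4).

Models 3 and 4 add predefined GWAS loci (marker dosages, or haplotype
incidence columns with the reference allele dropped) as fixed effects, and
an optional epistasis term enters as an extra Gaussian-kernel random
effect (RKHS regression).  Inference is a Gibbs sampler with flat priors
on fixed effects and scaled-inverse-chi-square priors on variances,
deterministic under a fixed seed; a closed-form REML backend is available
for single-kernel models.  Balanced multi-environment stacks are collapsed
to per-line means around estimated environment intercepts, which is exact
for whole-line cross-validation.

Cross-validation holds out whole lines (all their environment records),
predicts them from the remainder, and scores the Pearson correlation in
the test set; model comparisons require byte-identical split sequences.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .ldblocks import HapMatrix, SnpMatrix

KERNEL_KINDS = ("G_M", "G_H", "G_MG", "G_HG", "epistasis")


@dataclass
class Kernel:
    matrix: np.ndarray
    kind: str
    line_ids: list[str]
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        K = np.asarray(self.matrix, float)
        self.matrix = (K + K.T) / 2.0

    def min_eig(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix).min())


@dataclass
class ChainSettings:
    n_iter: int = 6000
    burn_in: int = 1000
    nu: float = 5.0


@dataclass
class ModelSpec:
    """One of the four prediction-model configurations."""

    model_id: int
    kernel_kind: str
    fixed_loci_kind: str | None    # None, "markers" or "haplotypes"
    epistasis: bool

    _TABLE = {
        1: ("G_M", None, False),
        2: ("G_H", None, True),
        3: ("G_MG", "markers", True),
        4: ("G_HG", "haplotypes", True),
    }

    @classmethod
    def from_id(cls, model_id: int, epistasis: bool | None = None) -> "ModelSpec":
        kind, fixed, epi = cls._TABLE[model_id]
        if epistasis is not None:
            epi = epistasis
        return cls(model_id=model_id, kernel_kind=kind,
                   fixed_loci_kind=fixed, epistasis=epi)


@dataclass
class MixedFitBayes:
    """Posterior summaries (or REML estimates) of the kernel mixed model."""

    beta: np.ndarray                 # intercept + fixed-locus coefficients
    env_means: pd.Series
    u: dict                          # kernel kind -> posterior-mean values (train)
    var_components: dict             # kind -> variance; "residual" included
    train_lines: list[str]
    backend: str
    chain: ChainSettings | None = None
    _predict_state: dict = field(default_factory=dict, repr=False)


@dataclass
class CVResult:
    model_id: int
    accuracies: np.ndarray
    split_hashes: list[str]
    n_repeats: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def kernel_additive(geno: SnpMatrix, scale: bool = True) -> Kernel:
    """G_M = M M' on codes {1, 0, -1}; missing codes enter as 0."""
    M = np.nan_to_num(geno.codes, nan=0.0)
    if not np.any(M != 0):
        raise ValueError("genotype matrix has no variation")
    G = M @ M.T
    if scale:
        G *= G.shape[0] / np.trace(G)
    return Kernel(G, "G_M", list(geno.line_ids))


def _hap_scores(H: HapMatrix, impute_missing: bool) -> np.ndarray:
    """Incidence scores; missing blocks frequency-imputed for kernels only.

    A line missing a block (uncalled member SNP) has an all-zero incidence
    row there; for relationship matrices that would register as "shares
    nothing", so the expected incidence (the allele frequency) is used
    instead — the haplotype analogue of frequency-centered zeros for
    missing marker dosages.
    """
    if impute_missing and H.scores is not None:
        return np.asarray(H.scores, float)
    S = H.incidence.astype(float)
    if impute_missing and H.missing.any():
        freqs = H.columns["freq"].to_numpy(float)
        for b in range(H.missing.shape[1]):
            rows = H.missing[:, b]
            if not rows.any():
                continue
            cols = np.where(H.block_of_col == b)[0]
            S[np.ix_(rows, cols)] = freqs[cols]
    return S


def kernel_haplotype(H: HapMatrix, scale: bool = True,
                     impute_missing: bool = True) -> Kernel:
    """G_H = H H'; entry (i, j) counts shared haplotype alleles."""
    inc = _hap_scores(H, impute_missing)
    if np.any(inc.sum(axis=1) == 0):
        warnings.warn("lines with no called haplotype alleles", stacklevel=2)
    G = inc @ inc.T
    if scale:
        tr = np.trace(G)
        if tr <= 0:
            raise ValueError("haplotype incidence matrix is all zero")
        G *= G.shape[0] / tr
    return Kernel(G, "G_H", list(H.line_ids))


def _gaussian_from_scores(S: np.ndarray, normalizer: float, theta, kind: str,
                          line_ids: list[str]) -> Kernel:
    sq = np.sum(S ** 2, axis=1)
    D2 = np.clip(sq[:, None] + sq[None, :] - 2.0 * (S @ S.T), 0.0, None)
    D = np.sqrt(normalizer * D2)
    if theta == "auto":
        off = D[np.triu_indices_from(D, k=1)]
        theta = float(np.median(off)) if off.size else 1.0
        theta = max(theta, 1e-8)
    if theta <= 0:
        raise ValueError("theta must be positive")
    G = np.exp(-D / theta)
    np.fill_diagonal(G, 1.0)
    return Kernel(G, kind, list(line_ids), theta=float(theta))


def kernel_gaussian(scores, theta="auto", kind: str | None = None) -> Kernel:
    """Gaussian kernel G_ij = exp(-D_ij / theta) on marker or haplotype scores.

    For marker codes the squared distance is normalised by 1/(4m) (codes
    differ by at most 2), for binary haplotype scores by 1/m, so D lies in
    [0, 1] either way.  ``theta='auto'`` uses the median off-diagonal
    distance.
    """
    if isinstance(scores, SnpMatrix):
        S = np.nan_to_num(scores.codes, nan=0.0)
        m = S.shape[1]
        return _gaussian_from_scores(S, 1.0 / (4.0 * m), theta,
                                     kind or "G_MG", scores.line_ids)
    if isinstance(scores, HapMatrix):
        S = _hap_scores(scores, impute_missing=True)
        m = max(S.shape[1], 1)
        return _gaussian_from_scores(S, 1.0 / m, theta,
                                     kind or "G_HG", scores.line_ids)
    S = np.asarray(scores, float)
    m = S.shape[1]
    span = np.nanmax(S) - np.nanmin(S) if S.size else 1.0
    norm = 1.0 / (m * max(span, 1.0) ** 2)
    ids = [f"L{i}" for i in range(S.shape[0])]
    return _gaussian_from_scores(np.nan_to_num(S), norm, theta, kind or "G_MG", ids)


def bend_kernel(K: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Raise negative eigenvalues to ``floor`` (with a warning)."""
    vals, vecs = np.linalg.eigh(K)
    if vals.min() >= -1e-8:
        return K
    warnings.warn("bending non-PSD kernel", stacklevel=2)
    return (vecs * np.clip(vals, floor, None)) @ vecs.T


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _collapse(y: pd.DataFrame | pd.Series, train_lines: list[str]):
    """Environment intercepts from training lines and centered line means."""
    if isinstance(y, pd.Series):
        y = y.to_frame(name="E1")
    env_means = y.loc[train_lines].mean(axis=0)
    w_all = y.mean(axis=1) - float(env_means.mean())
    return env_means, w_all


def _prune_collinear(X: np.ndarray, names: list[str]):
    keep = []
    for j in range(X.shape[1]):
        B = X[:, keep] if keep else np.zeros((X.shape[0], 0))
        B = np.column_stack([np.ones(X.shape[0]), B])
        res = X[:, j] - B @ np.linalg.lstsq(B, X[:, j], rcond=None)[0]
        if np.linalg.norm(res) > 1e-8 * max(np.linalg.norm(X[:, j]), 1.0):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear fixed-locus column {names[j]!r}",
                          stacklevel=3)
    return keep


def _reml_single(w: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Closed-form REML for one kernel; returns (beta, alpha, s2g, s2e)."""
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    wt, Xt = U.T @ w, U.T @ X
    n, q = Xt.shape

    def negll(logd):
        d = np.exp(logd)
        wgt = 1.0 / (s + d)
        A = Xt.T @ (Xt * wgt[:, None])
        beta = np.linalg.solve(A, (Xt * wgt[:, None]).T @ wt)
        r = wt - Xt @ beta
        rss = float(np.sum(wgt * r * r))
        nq = n - q
        _, logdet_a = np.linalg.slogdet(A)
        _, logdet_x = np.linalg.slogdet(Xt.T @ Xt)
        return -0.5 * (nq * np.log(nq / (2 * np.pi)) - nq - nq * np.log(rss)
                       - np.sum(np.log(s + d)) - logdet_a + logdet_x)

    grid = np.linspace(np.log(1e-5), np.log(1e5), 30)
    vals = [negll(g) for g in grid]
    i = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        negll, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded",
    )
    d = float(np.exp(res.x))
    wgt = 1.0 / (s + d)
    A = Xt.T @ (Xt * wgt[:, None])
    beta = np.linalg.solve(A, (Xt * wgt[:, None]).T @ wt)
    r = wt - Xt @ beta
    s2g = float(np.sum(wgt * r * r) / (n - q))
    alpha = U @ (wgt * r)          # (K + dI)^-1 (w - X beta)
    return beta, alpha, s2g, d * s2g


def fit_model(
    spec: ModelSpec,
    y: pd.DataFrame | pd.Series,
    kernels: list[Kernel],
    fixed_loci: pd.DataFrame | None = None,
    chain: ChainSettings | None = None,
    seed: int = 0,
    backend: str = "gibbs",
    train_lines: list[str] | None = None,
) -> MixedFitBayes:
    """Fit one prediction model on (a training subset of) one trial year.

    ``y`` is lines x environments (wide adjusted means) or a Series for a
    single environment.  ``fixed_loci`` holds line-indexed fixed-effect
    columns (marker dosages or haplotype incidence).  ``backend`` is
    "gibbs" (default) or "reml" (single-kernel models only).
    """
    chain = chain or ChainSettings()
    if isinstance(y, pd.Series):
        y = y.to_frame(name="E1")
    lines = list(y.index)
    train = train_lines if train_lines is not None else lines
    env_means, w_all = _collapse(y, train)
    w = w_all.loc[train].to_numpy(float)
    n = w.size
    if np.isnan(w).any():
        raise ValueError("training phenotypes contain missing values")

    Xcols, names = [np.ones(n)], ["intercept"]
    centers: dict[str, float] = {}
    if fixed_loci is not None and fixed_loci.shape[1] > 0:
        F = fixed_loci.reindex(train).to_numpy(float)
        F = np.where(np.isnan(F), np.nanmean(F, axis=0), F)
        mu = F.mean(axis=0)
        Fc = F - mu
        keep = _prune_collinear(Fc, list(fixed_loci.columns))
        for j in keep:
            Xcols.append(Fc[:, j])
            names.append(str(fixed_loci.columns[j]))
            centers[str(fixed_loci.columns[j])] = float(mu[j])
    X = np.column_stack(Xcols)

    Ks, kinds = [], []
    tr_idx_per_kernel = []
    for kern in kernels:
        idx = [kern.line_ids.index(l) for l in train]
        K = kern.matrix[np.ix_(idx, idx)]
        vals = np.linalg.eigvalsh(K)
        if vals.min() < -1e-8:
            K = bend_kernel(K)
        Ks.append(K)
        kinds.append(kern.kind)
        tr_idx_per_kernel.append(idx)

    var_w = float(np.var(w)) if np.var(w) > 0 else 1.0
    if backend == "reml":
        if len(Ks) != 1:
            raise ValueError("the REML backend supports single-kernel models")
        beta, alpha, s2g, s2e = _reml_single(w, X, Ks[0])
        u_tr = Ks[0] @ alpha
        fit = MixedFitBayes(
            beta=beta, env_means=env_means, u={kinds[0]: u_tr},
            var_components={kinds[0]: s2g, "residual": s2e},
            train_lines=list(train), backend="reml", chain=None,
        )
        fit._predict_state = {
            "alphas": {kinds[0]: alpha}, "names": names, "centers": centers,
            "kernels": kernels, "tr_idx": tr_idx_per_kernel, "y_index": lines,
        }
        return fit

    rng = np.random.default_rng(seed)
    eigs = []
    for K in Ks:
        lam, E = np.linalg.eigh(K)
        keepers = lam > 1e-8
        eigs.append((lam[keepers], E[:, keepers]))
    q = X.shape[1]
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX + 1e-10 * np.eye(q))
    chol_b = np.linalg.cholesky(XtX_inv)
    nu = chain.nu
    # prior modes: half the phenotypic variance to the residual, the rest
    # split over the kernels (scaled by their mean eigenvalue)
    tau_e = 0.5 * var_w
    tau_k = [0.5 * var_w / (len(Ks) * max(float(np.mean(lam)), 1e-8))
             for lam, _ in eigs]
    beta = XtX_inv @ (X.T @ w)
    d_list = [np.zeros(lam.size) for lam, _ in eigs]
    u_list = [np.zeros(n) for _ in Ks]
    s2e = tau_e
    s2k = list(tau_k)
    sum_beta = np.zeros(q)
    sum_u = [np.zeros(n) for _ in Ks]
    sum_s2 = np.zeros(len(Ks) + 1)
    kept = 0
    for it in range(chain.n_iter):
        r_b = w - sum(u_list)
        beta = XtX_inv @ (X.T @ r_b) + chol_b @ rng.standard_normal(q) * np.sqrt(s2e)
        xb = X @ beta
        for k, (lam, E) in enumerate(eigs):
            r_k = w - xb - sum(u_list[j] for j in range(len(Ks)) if j != k)
            proj = E.T @ r_k
            post_var = 1.0 / (1.0 / s2e + 1.0 / (lam * s2k[k]))
            post_mean = post_var * proj / s2e
            d_list[k] = post_mean + np.sqrt(post_var) * rng.standard_normal(lam.size)
            u_list[k] = E @ d_list[k]
            ssq = float(np.sum(d_list[k] ** 2 / lam))
            s2k[k] = (tau_k[k] * (nu + 2.0) + ssq) / rng.chisquare(nu + lam.size)
            if s2k[k] > 1e6 * var_w:
                raise RuntimeError("divergent chain: kernel variance exploded")
        resid = w - xb - sum(u_list)
        rss = float(resid @ resid)
        s2e = (tau_e * (nu + 2.0) + rss) / rng.chisquare(nu + n)
        if it >= chain.burn_in:
            kept += 1
            sum_beta += beta
            for k in range(len(Ks)):
                sum_u[k] += u_list[k]
            sum_s2[:-1] += np.asarray(s2k)
            sum_s2[-1] += s2e
    if kept == 0:
        raise ValueError("chain produced no post-burn-in samples")
    beta_m = sum_beta / kept
    u_m = [su / kept for su in sum_u]
    var_components = {kinds[k]: float(sum_s2[k] / kept) for k in range(len(Ks))}
    var_components["residual"] = float(sum_s2[-1] / kept)
    alphas = {}
    for k, K in enumerate(Ks):
        lam, E = eigs[k]
        # GP projection weights: K_tr^+ u_tr on the retained eigenspace
        alphas[kinds[k]] = E @ ((E.T @ u_m[k]) / lam)
    fit = MixedFitBayes(
        beta=beta_m, env_means=env_means,
        u={kinds[k]: u_m[k] for k in range(len(Ks))},
        var_components=var_components,
        train_lines=list(train), backend="gibbs", chain=chain,
    )
    fit._predict_state = {
        "alphas": alphas, "names": names, "centers": centers,
        "kernels": kernels, "tr_idx": tr_idx_per_kernel, "y_index": lines,
    }
    return fit


def predict(
    fit: MixedFitBayes,
    lines: list[str],
    fixed_loci: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Predicted values for ``lines`` in every environment of the fit."""
    st = fit._predict_state
    kernels: list[Kernel] = st["kernels"]
    g = np.zeros(len(lines))
    train = fit.train_lines
    for kern, tr_idx in zip(kernels, st["tr_idx"]):
        alpha = st["alphas"][kern.kind]
        te_idx = [kern.line_ids.index(l) for l in lines]
        K_cross = kern.matrix[np.ix_(te_idx, tr_idx)]
        g = g + K_cross @ alpha
    fx = np.full(len(lines), fit.beta[0])
    if len(fit.beta) > 1:
        if fixed_loci is None:
            raise ValueError("fit has fixed-locus terms; fixed_loci required")
        F = fixed_loci.reindex(lines)[st["names"][1:]].to_numpy(float)
        F = np.where(np.isnan(F), 0.0, F)
        F = F - np.array([st["centers"][nm] for nm in st["names"][1:]])
        fx = fx + F @ fit.beta[1:]
    base = g + fx
    out = pd.DataFrame(
        {env: base + fit.env_means[env] - float(fit.env_means.mean())
         for env in fit.env_means.index},
        index=lines,
    )
    return out


# ---------------------------------------------------------------------------
# cross-validation and model comparison
# ---------------------------------------------------------------------------

def _test_accuracy(obs: pd.DataFrame, pred: pd.DataFrame) -> float:
    """Pooled within-environment Pearson correlation on the test set.

    Observed and predicted test records are centered per environment before
    correlating, so the accuracy measures genetic signal rather than the
    (known) environment mean differences.  Constant predictions score 0.
    """
    o = obs.to_numpy(float)
    p = pred.to_numpy(float)
    oc = o - np.nanmean(o, axis=0, keepdims=True)
    pc = p - np.nanmean(p, axis=0, keepdims=True)
    ov, pv = oc.ravel(), pc.ravel()
    okm = ~np.isnan(ov)
    ov, pv = ov[okm], pv[okm]
    if ov.size < 2 or np.std(pv) == 0 or np.std(ov) == 0:
        return 0.0
    return float(np.corrcoef(ov, pv)[0, 1])


def _split_hash(test_lines: list[str]) -> str:
    h = hashlib.sha1(",".join(sorted(test_lines)).encode())
    return h.hexdigest()[:16]


def cross_validate(
    spec: ModelSpec,
    y: pd.DataFrame,
    kernels: list[Kernel],
    fixed_loci: pd.DataFrame | None = None,
    repeats: int = 100,
    test_frac: float = 0.10,
    seed: int = 0,
    backend: str = "gibbs",
    chain: ChainSettings | None = None,
) -> CVResult:
    """Repeated whole-line 90/10 cross-validation within one trial year.

    Per repeat, a seeded 10% of lines is masked in every environment, the
    model is refit on the remainder and the Pearson correlation between
    observed and predicted values over all test records is recorded.
    Constant predictions score 0 (flagged by NaN-free contract).
    """
    lines = list(y.index)
    n_test = max(int(round(test_frac * len(lines))), 1)
    if n_test < 2:
        raise ValueError("test sets need at least 2 lines")
    accs, hashes = [], []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        test_idx = rng.choice(len(lines), size=n_test, replace=False)
        test = [lines[i] for i in sorted(test_idx)]
        train = [l for l in lines if l not in set(test)]
        fit = fit_model(
            spec, y, kernels, fixed_loci=fixed_loci, chain=chain,
            seed=int(rng.integers(2 ** 31 - 1)), backend=backend,
            train_lines=train,
        )
        pred = predict(fit, test, fixed_loci=fixed_loci)
        obs = y.loc[test, pred.columns]
        accs.append(_test_accuracy(obs, pred))
        hashes.append(_split_hash(test))
    return CVResult(
        model_id=spec.model_id, accuracies=np.asarray(accs),
        split_hashes=hashes, n_repeats=repeats,
    )


def compare_models(results: list[CVResult], alpha: float = 0.05) -> pd.DataFrame:
    """Paired model comparison: means, differences vs the first model, LSD.

    All CV results must come from byte-identical split sequences (asserted
    by split-hash equality).  The LSD uses the paired-repeat variance of
    the accuracy differences.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    ref = results[0]
    for r in results[1:]:
        if r.split_hashes != ref.split_hashes:
            raise ValueError("model comparisons require identical split sequences")
    r_n = ref.n_repeats
    tcrit = sps.t.ppf(1 - alpha / 2, r_n - 1)
    rows = []
    for r in results:
        d = r.accuracies - ref.accuracies
        sd_d = float(np.std(d, ddof=1)) if r is not ref else 0.0
        lsd = tcrit * sd_d / np.sqrt(r_n) if r is not ref else 0.0
        rows.append(
            {
                "model_id": r.model_id,
                "mean_accuracy": r.mean,
                "sd_accuracy": r.sd,
                "diff_vs_base": float(np.mean(d)),
                "pct_change_vs_base": float(np.mean(d) / abs(ref.mean) * 100.0)
                if ref.mean != 0 else np.nan,
                "lsd": float(lsd),
                "exceeds_lsd": bool(abs(np.mean(d)) > lsd) if r is not ref else False,
            }
        )
    return pd.DataFrame(rows)
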