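"""Synthetic genotypes, trial designs and phenotypes with known ground truth.

The generator emulates the structure of multi-environment elite yield
trials of fully inbred wheat lines: SNPs organised in linkage blocks of a
few markers each (drawn from small founder-haplotype pools, so within-block
D' is high and between-block LD is ~0), five contrasting environments per
trial year with strong genotype-by-environment interaction, additive QTL
with per-environment effect vectors, planted two-locus epistasis, an
alpha-lattice plot structure (incomplete blocks inside replicates) with two
repeated check entries in every incomplete block, and a residual variance
tuned so the across-environment broad-sense heritability of entry means
hits a target value.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ldblocks import SnpMatrix

_BASES = np.array(list("ACGT"))
_DEFAULT_ENVS = ("B-5IR", "F-5IR", "B-2IR", "SD", "HS")
# per-environment mean grain yield, kg/ha (optimum -> severe stress)
_DEFAULT_ENV_MEANS = (7000.0, 6700.0, 3900.0, 2500.0, 3500.0)


@dataclass
class Qtl:
    """One additive QTL: locus index, per-env effect direction, variance share.

    ``effects`` gives the relative per-environment effect pattern (scalar or
    length ``n_envs``); it is rescaled so the QTL contributes ``var_share``
    of the target genetic variance (averaged over environments).  A constant
    pattern gives a "consistent" QTL, a one-hot pattern an
    "environment-specific" one.

    ``level`` selects the causal unit: a single SNP (``locus`` indexes a
    SNP column) or a whole LD block (``locus`` indexes a simulated founder
    block), in which case every founder haplotype of the block gets its own
    drawn allelic effect — a multi-allelic QTL that single biallelic
    markers tag only partially.
    """

    locus: int
    effects: object = 1.0
    var_share: float = 0.05
    level: str = "snp"

    def __post_init__(self) -> None:
        if self.level not in ("snp", "block"):
            raise ValueError("Qtl.level must be 'snp' or 'block'")


@dataclass
class EpiPair:
    """Planted two-locus interaction: effect (kg/ha) on the product of codes."""

    loci: tuple[int, int]
    effect: float = 100.0


@dataclass
class SimConfig:
    n_lines: int = 500
    n_chrom: int = 3
    snps_per_chrom: int = 40
    block_size_range: tuple[int, int] = (2, 9)
    founder_haplotypes_per_block: int = 3
    maf_min: float = 0.15
    n_years: int = 1
    n_envs: int = 5
    env_means: tuple = _DEFAULT_ENV_MEANS
    n_reps: int = 3
    block_size_field: int = 28
    n_checks: int = 2
    qtl_spec: tuple = ()
    epistasis_spec: tuple = ()
    h2_target: float = 0.5
    seed: int = 0
    # nuisance scales (kg/ha)
    genetic_sd: float = 300.0
    gxe_sd: float = 150.0
    rep_sd: float = 50.0
    iblock_sd: float = 100.0
    year_sd: float = 100.0
    missing_rate: float = 0.05
    check_values: tuple = (0.0, 150.0)
    make_covariates: bool = False
    # causal unit of the polygenic background: per-block founder-haplotype
    # effects ("haplotypes", the architecture the analysis assumes) or iid
    # per-SNP effects ("markers")
    polygenic_basis: str = "haplotypes"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_min < 0.5):
            raise ValueError("maf_min must lie in (0, 0.5)")
        if not (0.0 < self.h2_target < 1.0):
            raise ValueError("h2_target must lie strictly in (0, 1)")
        for name in ("n_lines", "n_chrom", "snps_per_chrom", "n_years",
                     "n_envs", "n_reps", "block_size_field", "n_checks",
                     "founder_haplotypes_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.qtl_spec = tuple(
            q if isinstance(q, Qtl) else Qtl(*q) for q in self.qtl_spec
        )
        self.epistasis_spec = tuple(
            e if isinstance(e, EpiPair) else EpiPair(*e) for e in self.epistasis_spec
        )
        if sum(q.var_share for q in self.qtl_spec) >= 1.0:
            raise ValueError("QTL variance shares must sum to < 1")
        if len(self.env_means) < self.n_envs:
            raise ValueError("env_means shorter than n_envs")

    @property
    def env_names(self) -> list[str]:
        if self.n_envs == 5:
            return list(_DEFAULT_ENVS)
        return [f"E{i+1}" for i in range(self.n_envs)]

    @property
    def eyt_names(self) -> list[str]:
        return [f"EYT{i+1}" for i in range(self.n_years)]


@dataclass
class SimTruth:
    qtl_loci: list[int]
    qtl_effects: np.ndarray           # (n_qtl, n_envs), kg/ha per code unit
    epistatic_pairs: list[tuple[int, int]]
    epistatic_effects: list[float]
    polygenic_values: np.ndarray      # (n_lines,)
    genetic_values: np.ndarray        # (n_lines, n_envs), total genetic
    realized_h2: float                # across-env broad-sense H2 implied
    sigma_g2: float = 0.0
    sigma_ge2: float = 0.0
    sigma_e2: float = 0.0
    ld_blocks: list[list[int]] = field(default_factory=list)
    check_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_block(rng: np.random.Generator, n_lines: int, k: int,
                n_founders: int, maf_min: float, max_tries: int = 500) -> np.ndarray:
    """Codes (n_lines, k) for one LD block from a founder-haplotype pool."""
    for _ in range(max_tries):
        founders = rng.choice((1.0, -1.0), size=(n_founders, k))
        if n_founders >= 2:
            # keep every SNP polymorphic within the pool
            for col in range(k):
                while np.all(founders[:, col] == founders[0, col]):
                    founders[:, col] = rng.choice((1.0, -1.0), size=n_founders)
        probs = rng.dirichlet(np.full(n_founders, 2.0))
        assign = rng.choice(n_founders, size=n_lines, p=probs)
        codes = founders[assign]
        p_alt = (codes == -1.0).mean(axis=0)
        if np.all(np.minimum(p_alt, 1 - p_alt) >= maf_min):
            return codes, assign
    raise ValueError(
        f"could not satisfy MAF >= {maf_min} with a pool of "
        f"{n_founders} founder haplotype(s); the pool is too small"
    )


def simulate_genotypes(cfg: SimConfig) -> SnpMatrix:
    """Fully homozygous inbred genotypes coded {1, -1} in LD blocks.

    SNPs within a block come from a shared founder-haplotype pool, so
    adjacent SNPs are in strong LD; blocks are drawn independently, so
    between-block LD is ~0.  All realized MAF >= ``cfg.maf_min`` (checked
    before the optional missingness mask is applied).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.block_size_range
    codes_cols, chroms, positions, snp_ids = [], [], [], []
    ld_blocks: list[list[int]] = []
    block_assigns: list[np.ndarray] = []
    col = 0
    for ci in range(cfg.n_chrom):
        chrom = str(ci + 1)
        pos = int(rng.integers(10_000, 50_000))
        remaining = cfg.snps_per_chrom
        while remaining > 0:
            k = min(int(rng.integers(lo, hi + 1)), remaining)
            block_codes, block_assign = _draw_block(
                rng, cfg.n_lines, k, cfg.founder_haplotypes_per_block, cfg.maf_min
            )
            block_assigns.append(block_assign)
            member_idx = []
            for j in range(k):
                codes_cols.append(block_codes[:, j])
                chroms.append(chrom)
                positions.append(pos)
                snp_ids.append(f"S{chrom}_{pos}")
                member_idx.append(col)
                col += 1
                pos += int(rng.integers(50, 500))
            ld_blocks.append(member_idx)
            pos += int(rng.integers(50_000, 200_000))
            remaining -= k
    codes = np.column_stack(codes_cols)
    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes = np.where(mask, np.nan, codes)
    n_snps = codes.shape[1]
    ref = _BASES[rng.integers(0, 4, size=n_snps)]
    alt = np.array(
        [rng.choice([b for b in _BASES if b != r]) for r in ref], dtype=object
    )
    geno = SnpMatrix(
        line_ids=[f"L{i+1:04d}" for i in range(cfg.n_lines)],
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions),
        codes=codes,
        ref=ref.astype(object),
        alt=alt,
    )
    geno.ld_blocks = ld_blocks  # true block structure, for downstream truth
    geno.ld_block_assign = block_assigns  # founder haplotype per line per block
    return geno


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def _genetic_values(geno: SnpMatrix, cfg: SimConfig, rng: np.random.Generator):
    """Per-line per-env genetic values and the scaled QTL effect matrix."""
    n, e = cfg.n_lines, cfg.n_envs
    vg = cfg.genetic_sd ** 2
    shares = sum(q.var_share for q in cfg.qtl_spec)
    codes = np.nan_to_num(geno.codes, nan=0.0)
    assigns = getattr(geno, "ld_block_assign", None)
    ld_blocks = getattr(geno, "ld_blocks", [])
    # blocks carrying a planted QTL are excluded from the polygenic
    # background, so a QTL's variance share is exactly its locus's genetic
    # contribution (recoverable by OLS) and not confounded with block-mates
    excluded_blocks: set[int] = set()
    for q in cfg.qtl_spec:
        if q.level == "block":
            excluded_blocks.add(q.locus)
        else:
            for bi, members in enumerate(ld_blocks):
                if q.locus in members:
                    excluded_blocks.add(bi)
    # polygenic background: many small effects attached either to founder
    # haplotype alleles per LD block or to individual markers, so genomic
    # relationship matrices from the same data capture it
    if cfg.polygenic_basis == "haplotypes" and assigns:
        poly = np.zeros(n)
        for bi, assign in enumerate(assigns):
            effs = rng.normal(0.0, 1.0, size=int(assign.max()) + 1)
            if bi in excluded_blocks:
                continue
            poly += effs[assign]
    elif cfg.polygenic_basis in ("haplotypes", "markers"):
        b = rng.normal(0.0, 1.0, size=codes.shape[1])
        for bi in excluded_blocks:
            b[ld_blocks[bi]] = 0.0
        poly = codes @ b
    else:
        raise ValueError("polygenic_basis must be 'haplotypes' or 'markers'")
    sd = poly.std()
    target_sd = np.sqrt(max(1.0 - shares, 0.0) * vg)
    poly = poly * (target_sd / sd) if sd > 0 else np.zeros(n)
    poly = poly - poly.mean()
    G = np.tile(poly[:, None], (1, e)).astype(float)
    qtl_eff = np.zeros((len(cfg.qtl_spec), e))
    for qi, q in enumerate(cfg.qtl_spec):
        u = np.broadcast_to(np.asarray(q.effects, dtype=float), (e,)).copy()
        if q.level == "block":
            assigns = getattr(geno, "ld_block_assign", None)
            if assigns is None or q.locus >= len(assigns):
                raise ValueError(f"block QTL {q.locus} has no founder assignment")
            assign = assigns[q.locus]
            allelic = rng.normal(0.0, 1.0, size=int(assign.max()) + 1)
            x = allelic[assign]
            x = x - x.mean()
        else:
            if np.any(np.isnan(geno.codes[:, q.locus])):
                raise ValueError(f"QTL locus {q.locus} has missing genotypes")
            x = codes[:, q.locus]
        xvar = x.var()
        if xvar <= 0:
            raise ValueError(f"QTL locus {q.locus} is monomorphic")
        denom = np.mean(u ** 2) * xvar
        scale = np.sqrt(q.var_share * vg / denom) if denom > 0 else 0.0
        qtl_eff[qi] = scale * u
        G += np.outer(x, qtl_eff[qi])
    epi_pairs, epi_effs = [], []
    for ep in cfg.epistasis_spec:
        i, j = ep.loci
        G += (ep.effect * codes[:, i] * codes[:, j])[:, None]
        epi_pairs.append((int(i), int(j)))
        epi_effs.append(float(ep.effect))
    if cfg.gxe_sd > 0:
        G += rng.normal(0.0, cfg.gxe_sd, size=(n, e))
    return G, poly, qtl_eff, epi_pairs, epi_effs


def _tuned_residual_sd(G: np.ndarray, cfg: SimConfig):
    """Residual SD hitting the across-env broad-sense H2 target.

    H2 = s2_G / (s2_G + s2_GE/e + s2_eps/(e r)) on an entry-mean basis, so
    s2_eps = e*r*s2_G*(1/H2 - 1) - r*s2_GE; infeasible targets (too much
    G x E) are clamped with a warning and the realized H2 is recorded.
    """
    e, r = cfg.n_envs, cfg.n_reps
    row = G.mean(axis=1, keepdims=True)
    colc = G - row
    colc = colc - colc.mean(axis=0, keepdims=True)
    s2_g = float(row.var())
    s2_ge = float(colc.var())
    s2_eps = e * r * s2_g * (1.0 / cfg.h2_target - 1.0) - r * s2_ge
    if s2_eps <= 0:
        warnings.warn(
            "h2_target infeasible given the G x E variance; residual variance "
            "clamped near zero", stacklevel=2,
        )
        s2_eps = 1e-6 * max(s2_g, 1.0)
    realized = s2_g / (s2_g + s2_ge / e + s2_eps / (e * r))
    return float(np.sqrt(s2_eps)), realized, s2_g, s2_ge


def simulate_trials(geno: SnpMatrix, cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Plot-level phenotype records for all trials plus the ground truth.

    Each trial (EYT x environment) is laid out as an alpha lattice:
    ``n_reps`` replicates, each splitting the entries into incomplete blocks
    of ``block_size_field`` entries, with the ``n_checks`` check entries
    planted in every incomplete block.  Check lines carry fixed genetic
    values that are not driven by any QTL.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    G, poly, qtl_eff, epi_pairs, epi_effs = _genetic_values(geno, cfg, rng)
    sigma_eps, realized_h2, s2_g, s2_ge = _tuned_residual_sd(G, cfg)
    env_names = cfg.env_names
    env_means = np.asarray(cfg.env_means[: cfg.n_envs], dtype=float)
    check_ids = [f"CHECK{i+1}" for i in range(cfg.n_checks)]
    check_vals = np.asarray(cfg.check_values[: cfg.n_checks], dtype=float)
    lines = list(geno.line_ids)
    n = len(lines)
    n_blocks = int(np.ceil(n / cfg.block_size_field))

    rows: list[tuple] = []
    for yi, eyt in enumerate(cfg.eyt_names):
        year_eff = rng.normal(0.0, cfg.year_sd) if cfg.n_years > 1 else 0.0
        for ei, env in enumerate(env_names):
            base = env_means[ei] + year_eff
            for rep in range(1, cfg.n_reps + 1):
                rep_eff = rng.normal(0.0, cfg.rep_sd)
                order = rng.permutation(n)
                block_effs = rng.normal(0.0, cfg.iblock_sd, size=n_blocks)
                for b in range(n_blocks):
                    members = order[b * cfg.block_size_field:(b + 1) * cfg.block_size_field]
                    for li in members:
                        val = (base + rep_eff + block_effs[b] + G[li, ei]
                               + rng.normal(0.0, sigma_eps))
                        rows.append((lines[li], eyt, env, rep, b + 1, "GY", val, False))
                    for ci, cid in enumerate(check_ids):
                        val = (base + rep_eff + block_effs[b] + check_vals[ci]
                               + rng.normal(0.0, sigma_eps))
                        rows.append((cid, eyt, env, rep, b + 1, "GY", val, True))
    records = pd.DataFrame(
        rows,
        columns=["line", "eyt", "env", "rep", "block", "trait", "value", "is_check"],
    )
    if cfg.make_covariates:
        records = pd.concat(
            [records, _covariate_records(cfg, rng, lines, check_ids)],
            ignore_index=True,
        )
    truth = SimTruth(
        qtl_loci=[q.locus for q in cfg.qtl_spec],
        qtl_effects=qtl_eff,
        epistatic_pairs=epi_pairs,
        epistatic_effects=epi_effs,
        polygenic_values=poly,
        genetic_values=G,
        realized_h2=realized_h2,
        sigma_g2=s2_g,
        sigma_ge2=s2_ge,
        sigma_e2=sigma_eps ** 2,
        ld_blocks=getattr(geno, "ld_blocks", []),
        check_ids=check_ids,
    )
    return records, truth


def _covariate_records(cfg, rng, lines, check_ids) -> pd.DataFrame:
    """Days-to-heading and plant-height records, one plot set per trial."""
    rows = []
    n = len(lines)
    specs = {"DH": (75.0, 3.0, 2.0, 1.0), "PH": (100.0, 8.0, 3.0, 2.0)}
    for trait, (mu, line_sd, trial_sd, noise_sd) in specs.items():
        line_eff = rng.normal(0.0, line_sd, size=n)
        check_eff = rng.normal(0.0, line_sd, size=len(check_ids))
        for eyt in cfg.eyt_names:
            for env in cfg.env_names:
                off = rng.normal(0.0, trial_sd)
                for rep in range(1, cfg.n_reps + 1):
                    for li, line in enumerate(lines):
                        rows.append((line, eyt, env, rep, 1, trait,
                                     mu + off + line_eff[li] + rng.normal(0, noise_sd),
                                     False))
                    for ci, cid in enumerate(check_ids):
                        rows.append((cid, eyt, env, rep, 1, trait,
                                     mu + off + check_eff[ci] + rng.normal(0, noise_sd),
                                     True))
    return pd.DataFrame(
        rows,
        columns=["line", "eyt", "env", "rep", "block", "trait", "value", "is_check"],
    )
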