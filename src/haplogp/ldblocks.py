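"""SNP filtering, pairwise D' with confidence intervals, and haplotype blocks.

Haplotype blocks are runs of adjacent SNPs whose pairwise D' 95% confidence
intervals satisfy the strong-LD rule (lower bound >= 0.6 and upper bound
>= 0.95); a candidate span becomes a block when at least 95% of its
informative pairwise comparisons are in strong LD.  The confidence interval
is computed from the multinomial likelihood of |D'| evaluated on a grid of
101 points, with 5% cumulative-likelihood tails on each side.  Blocks are
named ``HB<chrom>.<serial>`` with the serial incrementing along the
chromosome.

Lines are assumed fully inbred: residual heterozygous calls are treated as
missing for LD and haplotype calling, so haplotype phase is known from the
homozygous genotype calls alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# genotype codes: 1 = hom reference, 0 = heterozygous, -1 = hom alternate
CODE_REF = 1
CODE_HET = 0
CODE_ALT = -1

STRONG_LD = "strong LD"
INCONCLUSIVE = "inconclusive"
STRONG_RECOMB = "strong recombination"

DPRIME_GRID = np.linspace(0.0, 1.0, 101)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SnpMatrix:
    """Lines x biallelic SNPs, coded {1, 0, -1} with NaN for missing calls."""

    line_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray          # str per SNP
    pos: np.ndarray            # 1-based bp, non-decreasing within chromosome
    codes: np.ndarray          # float (n_lines, n_snps); NaN = missing
    ref: np.ndarray | None = None   # reference base per SNP
    alt: np.ndarray | None = None   # alternate base per SNP

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.ref is None:
            self.ref = np.array(["A"] * self.n_snps, dtype=object)
        if self.alt is None:
            self.alt = np.array(["B"] * self.n_snps, dtype=object)
        valid = np.isnan(self.codes) | np.isin(self.codes, (1.0, 0.0, -1.0))
        if not valid.all():
            raise ValueError("genotype codes must be in {1, 0, -1} or NaN")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP; alt dosage is (1 - code)/2."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_alt = np.nanmean((1.0 - self.codes) / 2.0, axis=0)
        p_alt = np.where(np.isnan(p_alt), 0.0, p_alt)
        return np.minimum(p_alt, 1.0 - p_alt)

    def subset_snps(self, idx: np.ndarray) -> "SnpMatrix":
        idx = np.asarray(idx)
        return SnpMatrix(
            line_ids=list(self.line_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            codes=self.codes[:, idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def subset_lines(self, idx: np.ndarray) -> "SnpMatrix":
        idx = np.asarray(idx)
        return SnpMatrix(
            line_ids=[self.line_ids[i] for i in idx],
            snp_ids=list(self.snp_ids),
            chrom=self.chrom,
            pos=self.pos,
            codes=self.codes[idx, :],
            ref=self.ref,
            alt=self.alt,
        )


@dataclass
class LDStats:
    snp_i: int
    snp_j: int
    d_prime: float
    ci_low: float
    ci_high: float
    n_informative: int
    klass: str
    flagged: bool = False


@dataclass
class HapBlock:
    name: str
    chrom: str
    snp_indices: list[int]           # indices into the (filtered) SnpMatrix
    snp_ids: list[str] = field(default_factory=list)
    start: int = 0
    end: int = 0
    alleles: list[str] = field(default_factory=list)
    freqs: list[float] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclass
class HapMatrix:
    """Binary line x haplotype-allele incidence with block bookkeeping.

    ``incidence`` is the strict call (no imputation): a line missing any
    member SNP of a block has all zeros there and is flagged in
    ``missing``.  ``scores`` is a soft companion used only for relationship
    matrices: for missing blocks it holds the probability of each allele
    conditional on whichever member SNPs were observed (allele frequencies
    restricted to the compatible alleles).
    """

    line_ids: list[str]
    incidence: np.ndarray            # (n_lines, n_columns) in {0, 1}
    columns: pd.DataFrame            # block, allele, freq per column
    missing: np.ndarray              # (n_lines, n_blocks) bool
    block_names: list[str]
    block_of_col: np.ndarray         # block index per column
    scores: np.ndarray | None = None  # float incidence with soft dosages

    @property
    def n_lines(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_columns(self) -> int:
        return self.incidence.shape[1]

    def block_columns(self, block: str) -> np.ndarray:
        b = self.block_names.index(block)
        return np.where(self.block_of_col == b)[0]


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

def filter_snps(
    geno: SnpMatrix,
    max_missing: float = 0.40,
    maf_min: float = 0.15,
) -> SnpMatrix:
    """Retain SNPs with missingness <= ``max_missing`` and MAF >= ``maf_min``.

    Both bounds are inclusive for retention (a SNP with exactly 40% missing
    data or MAF exactly at the floor is kept).  SNP order is preserved.
    """
    miss = geno.missing_fraction()
    maf = geno.maf()
    keep = np.where((miss <= max_missing + 1e-12) & (maf >= maf_min - 1e-12))[0]
    if keep.size == 0:
        warnings.warn("no SNPs pass the missingness/MAF filters", stacklevel=2)
    return geno.subset_snps(keep)


# ---------------------------------------------------------------------------
# D' and its likelihood-grid confidence interval
# ---------------------------------------------------------------------------

def _dprime_from_counts(n11: float, n12: float, n21: float, n22: float):
    n = n11 + n12 + n21 + n22
    pa = (n11 + n12) / n
    pb = (n11 + n21) / n
    d = n11 / n - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return 0.0, 1.0, pa, pb
    return abs(d) / dmax, (1.0 if d >= 0 else -1.0), pa, pb


def dprime_ci_from_counts(
    counts: np.ndarray, conf: float = 0.95
) -> tuple[float, float, float]:
    """D' and its confidence interval from a 2x2 haplotype count table.

    The likelihood of |D'| is evaluated at 101 grid points with allele
    frequencies fixed at their observed values; the bounds cut ``(1-conf)/...``
    -- concretely a 5% cumulative-likelihood tail on each side at the default
    ``conf=0.95``, the convention of the Haploview/Gabriel block definition.
    """
    counts = np.asarray(counts, dtype=float)
    n11, n12 = counts[0, 0], counts[0, 1]
    n21, n22 = counts[1, 0], counts[1, 1]
    dprime, sign, pa, pb = _dprime_from_counts(n11, n12, n21, n22)
    if pa >= 1 or pa <= 0 or pb >= 1 or pb <= 0:
        # monomorphic locus: D' undefined, CI spans the whole interval
        return 0.0, 0.0, 1.0
    if sign >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dgrid = sign * DPRIME_GRID * dmax
    f11 = np.clip(pa * pb + dgrid, 1e-12, None)
    f12 = np.clip(pa * (1 - pb) - dgrid, 1e-12, None)
    f21 = np.clip((1 - pa) * pb - dgrid, 1e-12, None)
    f22 = np.clip((1 - pa) * (1 - pb) + dgrid, 1e-12, None)
    ll = n11 * np.log(f11) + n12 * np.log(f12) + n21 * np.log(f21) + n22 * np.log(f22)
    lik = np.exp(ll - ll.max())
    lik /= lik.sum()
    csum = np.cumsum(lik)
    tail = 1.0 - conf  # 5% cumulative likelihood per side at conf=0.95
    low_idx = int(np.searchsorted(csum, tail))
    upper_tail = lik[::-1].cumsum()[::-1]  # P(|D'| >= grid point)
    high_candidates = np.where(upper_tail >= tail)[0]
    high_idx = int(high_candidates[-1]) if high_candidates.size else 0
    return float(dprime), float(DPRIME_GRID[low_idx]), float(DPRIME_GRID[high_idx])


def haplotype_counts(geno: SnpMatrix, i: int, j: int) -> tuple[np.ndarray, int]:
    """2x2 haplotype counts from lines homozygous at both SNPs."""
    ci = geno.codes[:, i]
    cj = geno.codes[:, j]
    ok = np.isin(ci, (1.0, -1.0)) & np.isin(cj, (1.0, -1.0))
    a = ci[ok] == 1.0
    b = cj[ok] == 1.0
    counts = np.array(
        [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ],
        dtype=float,
    )
    return counts, int(ok.sum())


def dprime_ci(geno: SnpMatrix, i: int, j: int, conf: float = 0.95) -> LDStats:
    """D' with likelihood-grid CI for one SNP pair; classifies the pair."""
    counts, n_inf = haplotype_counts(geno, i, j)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if n_inf < 2 or np.any(row == n_inf) or np.any(col == n_inf):
        return LDStats(i, j, 0.0, 0.0, 1.0, n_inf, INCONCLUSIVE, flagged=True)
    dprime, lo, hi = dprime_ci_from_counts(counts, conf)
    stats = LDStats(i, j, dprime, lo, hi, n_inf, INCONCLUSIVE)
    stats.klass = classify_pair(stats)
    return stats


def classify_pair(
    ld: LDStats,
    lower_min: float = 0.6,
    upper_min: float = 0.95,
    recomb_max: float = 0.9,
) -> str:
    """Strong LD / inconclusive / strong recombination from the CI bounds."""
    if ld.flagged:
        return INCONCLUSIVE
    if ld.ci_low >= lower_min and ld.ci_high >= upper_min:
        return STRONG_LD
    if ld.ci_high < recomb_max:
        return STRONG_RECOMB
    return INCONCLUSIVE


# ---------------------------------------------------------------------------
# block construction
# ---------------------------------------------------------------------------

def build_blocks(
    geno: SnpMatrix,
    strong_frac: float = 0.95,
    max_block_snps: int = 50,
    lower_min: float = 0.6,
    upper_min: float = 0.95,
    recomb_max: float = 0.9,
    conf: float = 0.95,
) -> list[HapBlock]:
    """Greedy non-overlapping block construction per chromosome.

    A contiguous span of >= 2 SNPs is a candidate block when at least
    ``strong_frac`` of its informative (non-inconclusive) pairwise
    comparisons are in strong LD (and it has at least one informative
    pair).  Candidates are accepted greedily, longest span first, ties
    broken leftmost.  Blocks are named ``HB<chrom_number>.<serial>`` with
    serials assigned in positional order along each chromosome; the
    chromosome number is its 1-based rank in order of appearance.
    """
    blocks: list[HapBlock] = []
    chroms = list(pd.unique(geno.chrom))
    for chrom_rank, chrom in enumerate(chroms, start=1):
        idx = np.where(geno.chrom == chrom)[0]
        L = idx.size
        if L < 2:
            continue
        win = min(max_block_snps, L)
        strong = np.zeros((L, L), dtype=np.int64)
        informative = np.zeros((L, L), dtype=np.int64)
        for a in range(L):
            for b in range(a + 1, min(a + win, L)):
                st = dprime_ci(geno, int(idx[a]), int(idx[b]), conf)
                k = classify_pair(st, lower_min, upper_min, recomb_max)
                if k != INCONCLUSIVE:
                    informative[a, b] = informative[b, a] = 1
                    if k == STRONG_LD:
                        strong[a, b] = strong[b, a] = 1
        ps = np.zeros((L + 1, L + 1), dtype=np.int64)
        pi = np.zeros((L + 1, L + 1), dtype=np.int64)
        ps[1:, 1:] = strong.cumsum(0).cumsum(1)
        pi[1:, 1:] = informative.cumsum(0).cumsum(1)

        def _pairsum(P, s, e):  # sum over unordered pairs in span [s, e]
            rect = P[e + 1, e + 1] - P[s, e + 1] - P[e + 1, s] + P[s, s]
            return rect // 2

        candidates = []
        for s in range(L):
            for e in range(s + 1, min(s + win, L)):
                n_inf = _pairsum(pi, s, e)
                if n_inf == 0:
                    continue
                n_str = _pairsum(ps, s, e)
                if n_str / n_inf >= strong_frac - 1e-12:
                    candidates.append((e - s + 1, s, e))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        used = np.zeros(L, dtype=bool)
        accepted = []
        for _, s, e in candidates:
            if used[s:e + 1].any():
                continue
            used[s:e + 1] = True
            accepted.append((s, e))
        accepted.sort()
        for serial, (s, e) in enumerate(accepted, start=1):
            members = [int(g) for g in idx[s:e + 1]]
            blocks.append(
                HapBlock(
                    name=f"HB{chrom_rank}.{serial}",
                    chrom=str(chrom),
                    snp_indices=members,
                    snp_ids=[geno.snp_ids[g] for g in members],
                    start=int(geno.pos[members[0]]),
                    end=int(geno.pos[members[-1]]),
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# haplotype calling
# ---------------------------------------------------------------------------

def call_haplotypes(
    geno: SnpMatrix,
    blocks: list[HapBlock],
    hap_freq_min: float = 0.05,
) -> HapMatrix:
    """Per-line haplotype allele strings and the binary incidence matrix.

    A line with a heterozygous or missing call at any member SNP is missing
    for that block (no imputation).  Alleles rarer than ``hap_freq_min``
    among called lines are pooled into a rare class that gets no incidence
    column, so per block each line has at most one entry equal to 1.
    """
    n = geno.n_lines
    missing = np.zeros((n, len(blocks)), dtype=bool)
    cols_inc: list[np.ndarray] = []
    cols_score: list[np.ndarray] = []
    col_meta: list[tuple[str, str, float]] = []
    block_of_col: list[int] = []
    for b, block in enumerate(blocks):
        sub = geno.codes[:, block.snp_indices]
        k = sub.shape[1]
        valid = np.all((sub == 1.0) | (sub == -1.0), axis=1)
        missing[:, b] = ~valid
        refs = geno.ref[block.snp_indices]
        alts = geno.alt[block.snp_indices]
        strings = np.array([""] * n, dtype=object)
        for li in np.where(valid)[0]:
            bases = [refs[j] if sub[li, j] == 1.0 else alts[j] for j in range(k)]
            strings[li] = "".join(bases)
        called = strings[valid]
        if called.size == 0:
            block.alleles, block.freqs = [], []
            continue
        alleles, counts = np.unique(called, return_counts=True)
        freqs = counts / called.size
        order = np.argsort(-freqs, kind="stable")
        alleles, freqs = alleles[order], freqs[order]
        block.alleles = [str(a) for a in alleles]
        block.freqs = [float(f) for f in freqs]
        common = [(str(a), float(f)) for a, f in zip(alleles, freqs)
                  if f >= hap_freq_min]
        if not common:
            continue
        # soft dosages for uncalled lines: allele frequencies restricted to
        # the alleles compatible with the observed member SNPs
        soft = np.zeros((n, len(common)))
        for li in np.where(~valid)[0]:
            obs = [(j, refs[j] if sub[li, j] == 1.0 else alts[j])
                   for j in range(k) if sub[li, j] in (1.0, -1.0)]
            compat_mass = 0.0
            weights = np.zeros(len(alleles))
            for ai, (allele, freq) in enumerate(zip(alleles, freqs)):
                if all(allele[j] == base for j, base in obs):
                    weights[ai] = freq
                    compat_mass += freq
            if compat_mass <= 0:
                weights, compat_mass = freqs.copy(), 1.0
            for ci, (astr, _) in enumerate(common):
                ai = int(np.where(alleles == astr)[0][0])
                soft[li, ci] = weights[ai] / compat_mass
        for ci, (allele, freq) in enumerate(common):
            inc = np.zeros(n, dtype=np.int8)
            inc[(strings == allele) & valid] = 1
            cols_inc.append(inc)
            cols_score.append(np.where(valid, inc.astype(float), soft[:, ci]))
            col_meta.append((block.name, allele, freq))
            block_of_col.append(b)
    incidence = (
        np.column_stack(cols_inc) if cols_inc else np.zeros((n, 0), dtype=np.int8)
    )
    scores = (
        np.column_stack(cols_score) if cols_score else np.zeros((n, 0))
    )
    columns = pd.DataFrame(col_meta, columns=["block", "allele", "freq"])
    return HapMatrix(
        line_ids=list(geno.line_ids),
        incidence=incidence,
        columns=columns,
        missing=missing,
        block_names=[bl.name for bl in blocks],
        block_of_col=np.asarray(block_of_col, dtype=int),
        scores=scores,
    )


def blocks_table(blocks: list[HapBlock]) -> pd.DataFrame:
    """Tidy block summary (name, chrom, start, end, n_snps, snp ids)."""
    rows = [
        {
            "name": b.name,
            "chrom": b.chrom,
            "start": b.start,
            "end": b.end,
            "n_snps": b.n_snps,
            "snp_ids": ",".join(b.snp_ids),
        }
        for b in blocks
    ]
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "n_snps", "snp_ids"])
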