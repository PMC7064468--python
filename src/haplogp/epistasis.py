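"""Two- and three-locus interaction scans on adjusted entry means.

Each locus is treated as a categorical factor (biallelic SNP codes or
haplotype-allele classes).  For a pair, an ordinary least-squares model
with both main effects is compared against the model adding the full
interaction term; the interaction block is F-tested and the additional
variance it explains is reported as dR2 = R2_full - R2_mains (sequential
sums of squares, mains first).  For a triple, the base model holds all
mains and two-way interactions and the three-way block is tested, so only
genuine third-order signal is scored.  Kinship is not included (an
adjusted-means OLS scan); tuples with any sparse genotype-combination cell
are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class InteractionResult:
    loci: tuple
    p_value: float
    delta_r2: float
    df: int


def _dummies(levels: np.ndarray) -> np.ndarray:
    """Full-rank treatment dummies (reference = first observed level)."""
    uniq = np.unique(levels)
    return (levels[:, None] == uniq[None, 1:]).astype(float)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r), int(rank)


def _interaction_columns(mats: list[np.ndarray]) -> np.ndarray:
    """All elementwise products across one column from each factor."""
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(out.shape[0], -1)
    return out


def interaction_scan(
    y: pd.Series | np.ndarray,
    loci: np.ndarray,
    locus_names: list[str] | None = None,
    order: int = 2,
    p_cut: float = 0.001,
    pairs: list[tuple] | None = None,
    min_cell: int = 5,
    report_all: bool = False,
) -> pd.DataFrame:
    """Scan locus tuples for epistatic interactions.

    ``loci`` is a lines x L array of genotype classes (any hashable codes;
    NaN marks missing).  By default all C(L, order) tuples are scanned;
    ``pairs`` restricts the scan to the given tuples.  Tuples are reported
    when the interaction F-test has p < ``p_cut`` (or always, with
    ``report_all``); any tuple with a genotype-combination cell count below
    ``min_cell`` is skipped.  Results are symmetric under locus
    permutation.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    yv = np.asarray(y, float)
    L = loci.shape[1]
    names = locus_names if locus_names is not None else [str(i) for i in range(L)]
    tuples = pairs if pairs is not None else list(combinations(range(L), order))
    rows = []
    for tup in tuples:
        tup = tuple(sorted(tup))
        cols = loci[:, tup].astype(float)
        ok = ~np.isnan(yv) & ~np.isnan(cols).any(axis=1)
        if ok.sum() <= order * 4:
            continue
        yt = yv[ok]
        sub = cols[ok]
        # cell counts over the full factorial of observed levels
        combos = [np.unique(sub[:, k], return_inverse=True) for k in range(order)]
        shape = tuple(len(u) for u, _ in combos)
        if any(s < 2 for s in shape):
            continue
        flat = np.ravel_multi_index([inv for _, inv in combos], shape)
        counts = np.bincount(flat, minlength=int(np.prod(shape)))
        if counts.min() < min_cell:
            rows.append(
                {"loci": tuple(names[i] for i in tup), "p_value": np.nan,
                 "delta_r2": np.nan, "df": 0, "skipped": "sparse cell"}
            )
            continue
        mats = [_dummies(sub[:, k]) for k in range(order)]
        n = yt.size
        base_cols = [np.ones((n, 1))] + mats
        if order == 3:
            for a, b in combinations(range(3), 2):
                base_cols.append(_interaction_columns([mats[a], mats[b]]))
        X0 = np.column_stack(base_cols)
        inter = _interaction_columns(mats)
        X1 = np.column_stack([X0, inter])
        tssv = yt - yt.mean()
        tss = float(tssv @ tssv)
        if tss <= 0:
            continue
        rss0, rank0 = _rss(X0, yt)
        rss1, rank1 = _rss(X1, yt)
        dfn = rank1 - rank0
        df2 = n - rank1
        if dfn < 1 or df2 < 1 or rss1 <= 0:
            continue
        fstat = ((rss0 - rss1) / dfn) / (rss1 / df2)
        p = float(sps.f.sf(fstat, dfn, df2))
        d_r2 = max((rss0 - rss1) / tss, 0.0)
        if report_all or p < p_cut:
            rows.append(
                {"loci": tuple(names[i] for i in tup), "p_value": p,
                 "delta_r2": d_r2, "df": dfn, "skipped": ""}
            )
    return pd.DataFrame(rows, columns=["loci", "p_value", "delta_r2", "df", "skipped"])


def epistatic_variance_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and range of dR2 among significant tuples (optionally per trial)."""
    if results.empty:
        return pd.DataFrame(columns=["n", "mean_delta_r2", "min_delta_r2", "max_delta_r2"])
    sig = results[results["skipped"] == ""] if "skipped" in results else results
    sig = sig.dropna(subset=["delta_r2"])
    group = sig.groupby(["eyt", "env"]) if {"eyt", "env"} <= set(sig.columns) else [((), sig)]
    rows = []
    for key, g in group:
        row = {
            "n": g.shape[0],
            "mean_delta_r2": float(g["delta_r2"].mean()),
            "min_delta_r2": float(g["delta_r2"].min()),
            "max_delta_r2": float(g["delta_r2"].max()),
        }
        if key:
            row["eyt"], row["env"] = key
        rows.append(row)
    return pd.DataFrame(rows)
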