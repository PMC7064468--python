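"""Check-based field adjustment, adjusted entry means, ANOVA and heritability.

Grain-yield plots are adjusted for incomplete-block effects within each
replicate of each trial using the two repeated check varieties: every value
in a block is shifted by minus (block check mean - trial check mean), i.e. a
moving-check adjustment, and entry means are then taken over replicates.
Covariate traits (days to heading, plant height) are put on a common scale
across trials with Y = (Y_ij - Y_i) + Y_all, where Y_i is the check mean of
trial i and Y_all the check mean over all trials.

The factorial ANOVA (Rep, Geno, Env, Geno:Env, Residuals) treats all
factors as fixed and is computed from marginal/cell means, which is exact
on balanced lattices and an available-case approximation otherwise.
Broad-sense heritability on an entry-mean basis is derived from the
expected mean squares of that fit:

    H2 = s2_G / (s2_G + s2_GE / e + s2_eps / (e * r))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AdjMeans:
    """Adjusted entry means: lines x trials, one trait."""

    values: pd.DataFrame         # index = line, columns = MultiIndex (eyt, env)
    trait: str

    @property
    def trials(self) -> list[tuple[str, str]]:
        return list(self.values.columns)

    def eyt(self, eyt: str) -> pd.DataFrame:
        """Lines x environments for one EYT."""
        sub = self.values.loc[:, self.values.columns.get_level_values(0) == eyt]
        sub = sub.copy()
        sub.columns = sub.columns.get_level_values(1)
        return sub


@dataclass
class AnovaTable:
    table: pd.DataFrame          # rows Rep/Geno/Env/Geno:Env/Residuals

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _trial_frames(records: pd.DataFrame, trait: str):
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    return sub


# ---------------------------------------------------------------------------
# adjustment
# ---------------------------------------------------------------------------

def adjust_gy_block_effects(
    records: pd.DataFrame,
    trial: tuple[str, str] | None = None,
    trait: str = "GY",
) -> AdjMeans:
    """Check-based incomplete-block adjustment and entry means per trial.

    ``trial`` restricts the computation to one (eyt, env); by default all
    trials present in ``records`` are adjusted.  Every incomplete block must
    contain at least one check plot.
    """
    sub = _trial_frames(records, trait).copy()
    if trial is not None:
        sub = sub[(sub["eyt"] == trial[0]) & (sub["env"] == trial[1])]
        if sub.empty:
            raise ValueError(f"trial {trial} not present")
    out: dict[tuple[str, str], pd.Series] = {}
    for (eyt, env), tdf in sub.groupby(["eyt", "env"], sort=True):
        checks = tdf[tdf["is_check"]]
        if checks.empty:
            raise ValueError(f"trial ({eyt}, {env}) has no check plots")
        trial_check_mean = checks["value"].mean()
        adj = tdf.copy()
        for (rep, block), bdf in tdf.groupby(["rep", "block"]):
            bchecks = bdf[bdf["is_check"]]
            if bchecks.empty:
                raise ValueError(
                    f"block {block} of rep {rep} in trial ({eyt}, {env}) "
                    "contains no check plot"
                )
            shift = bchecks["value"].mean() - trial_check_mean
            adj.loc[bdf.index, "value"] = bdf["value"] - shift
        entries = adj[~adj["is_check"]]
        out[(eyt, env)] = entries.groupby("line")["value"].mean()
    values = pd.DataFrame(out)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["eyt", "env"])
    return AdjMeans(values=values.sort_index(), trait=trait)


def adjust_covariate_means(records: pd.DataFrame, trait: str) -> AdjMeans:
    """Common-scale covariate means: Y = (Y_ij - Y_i) + Y_all.

    Y_ij is the entry mean in trial i (over replicates), Y_i the check mean
    of that trial and Y_all the check mean over all trials.
    """
    if trait not in ("DH", "PH"):
        raise ValueError("covariate adjustment is defined for DH and PH")
    sub = _trial_frames(records, trait)
    checks = sub[sub["is_check"]]
    if checks.empty:
        raise ValueError("no check plots for covariate adjustment")
    y_all = checks["value"].mean()
    out: dict[tuple[str, str], pd.Series] = {}
    for (eyt, env), tdf in sub.groupby(["eyt", "env"], sort=True):
        tchecks = tdf[tdf["is_check"]]
        if tchecks.empty:
            raise ValueError(f"trial ({eyt}, {env}) has no check plots")
        y_i = tchecks["value"].mean()
        entry_means = tdf[~tdf["is_check"]].groupby("line")["value"].mean()
        out[(eyt, env)] = entry_means - y_i + y_all
    values = pd.DataFrame(out)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["eyt", "env"])
    return AdjMeans(values=values.sort_index(), trait=trait)


# ---------------------------------------------------------------------------
# ANOVA and heritability
# ---------------------------------------------------------------------------

def anova_factorial(records: pd.DataFrame, eyt: str | None = None,
                    trait: str = "GY", include_checks: bool = False) -> AnovaTable:
    """Least-squares factorial ANOVA with terms Rep, Geno, Env, Geno:Env.

    F for every term uses the single residual mean square.  Sums of squares
    are computed from (available-case) marginal and cell means, exact under
    balance.
    """
    sub = _trial_frames(records, trait)
    if eyt is not None:
        sub = sub[sub["eyt"] == eyt]
    if not include_checks:
        sub = sub[~sub["is_check"]]
    sub = sub.dropna(subset=["value"])
    y = sub["value"].to_numpy(float)
    n = y.size
    factors = {"Rep": sub["rep"], "Geno": sub["line"], "Env": sub["env"]}
    levels = {k: v.nunique() for k, v in factors.items()}
    for k, nl in levels.items():
        if nl < 2:
            raise ValueError(f"factor {k} has a single level")
    grand = y.mean()
    ss_tot = float(((y - grand) ** 2).sum())

    def _ss(by) -> float:
        g = sub.groupby(by)["value"]
        m, c = g.mean(), g.size()
        return float((c * (m - grand) ** 2).sum())

    ss = {k: _ss(v) for k, v in factors.items()}
    ss_cells = _ss([sub["line"], sub["env"]])
    ss_ge = max(ss_cells - ss["Geno"] - ss["Env"], 0.0)
    df = {
        "Rep": levels["Rep"] - 1,
        "Geno": levels["Geno"] - 1,
        "Env": levels["Env"] - 1,
        "Geno:Env": (levels["Geno"] - 1) * (levels["Env"] - 1),
    }
    ss["Geno:Env"] = ss_ge
    ss_res = max(ss_tot - sum(ss.values()), 0.0)
    df_res = n - 1 - sum(df.values())
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (need replication)")
    ms_res = ss_res / df_res
    rows = []
    for term in ("Rep", "Geno", "Env", "Geno:Env"):
        ms = ss[term] / df[term]
        f = ms / ms_res if ms_res > 0 else np.inf
        p = float(sps.f.sf(f, df[term], df_res)) if np.isfinite(f) else 0.0
        rows.append((term, df[term], ss[term], ms, f, p))
    rows.append(("Residuals", df_res, ss_res, ms_res, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "Df", "SumSq", "MeanSq", "F", "Pr(>F)"]
    ).set_index("term")
    return AnovaTable(table=table)


def broad_sense_h2(records: pd.DataFrame, trait: str = "GY") -> pd.Series:
    """Across-environment broad-sense heritability per EYT, clipped to [0, 1].

    Variance components come from the expected mean squares of the fixed
    factorial fit: s2_eps = MS_res, s2_GE = (MS_GE - MS_res)/r,
    s2_G = (MS_G - MS_GE)/(e r).  Negative component estimates are clipped
    at zero with a warning.
    """
    sub = _trial_frames(records, trait)
    sub = sub[~sub["is_check"]]
    out = {}
    for eyt, edf in sub.groupby("eyt", sort=True):
        tab = anova_factorial(edf, trait=trait).table
        e = edf["env"].nunique()
        g = edf["line"].nunique()
        r = edf.shape[0] / (e * g)     # mean replicates per cell
        ms_g = tab.loc["Geno", "MeanSq"]
        ms_ge = tab.loc["Geno:Env", "MeanSq"]
        ms_res = tab.loc["Residuals", "MeanSq"]
        s2_eps = ms_res
        s2_ge = (ms_ge - ms_res) / r
        s2_g = (ms_g - ms_ge) / (e * r)
        if s2_ge < 0 or s2_g < 0:
            warnings.warn(
                f"negative variance component estimate in {eyt}; clipped at 0",
                stacklevel=2,
            )
        s2_ge, s2_g = max(s2_ge, 0.0), max(s2_g, 0.0)
        denom = s2_g + s2_ge / e + s2_eps / (e * r)
        out[eyt] = float(np.clip(s2_g / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return pd.Series(out, name=f"H2_{trait}")
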