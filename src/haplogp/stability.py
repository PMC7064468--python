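"""Yield-stability indices across environments within one trial year.

Two classical indices are computed from adjusted entry means:

* Lin & Binns superiority index ``Pi = sum_j (X_ij - M_j)^2 / (2 E)``,
  where ``M_j`` is the best entry mean in environment j and E the number of
  environments.  Low Pi marks lines that are both high yielding and stable;
  Pi = 0 iff the line attains the environment maximum everywhere.  (Note
  the 2E denominator; a 2(E-1) variant exists in the literature.)

* Eberhart & Russell regression: the slope ``b_i`` of a line's means on the
  environmental index ``I_j`` (environment mean minus grand mean), with the
  mean squared deviation from that regression as auxiliary output.  b = 1
  denotes average stability; the slope is the "ER coefficient" reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pheno import AdjMeans


def superiority_index(adj: AdjMeans, eyt: str) -> pd.DataFrame:
    """Lin-Binns Pi per line for one EYT (environments as columns).

    Lines missing in some environments are computed over the available ones
    with E reduced accordingly and flagged in the ``partial`` column.
    """
    X = adj.eyt(eyt)
    if X.shape[1] < 2:
        raise ValueError("Pi needs at least 2 environments")
    M = X.max(axis=0)
    sq = (X - M) ** 2
    e_avail = X.notna().sum(axis=1)
    if (e_avail < 2).any():
        raise ValueError("a line has values in fewer than 2 environments")
    pi = sq.sum(axis=1, skipna=True) / (2.0 * e_avail)
    return pd.DataFrame(
        {
            "eyt": eyt,
            "Pi": pi,
            "mean_gy": X.mean(axis=1),
            "partial": e_avail < X.shape[1],
        }
    )


def eberhart_russell(adj: AdjMeans, eyt: str) -> pd.DataFrame:
    """Eberhart-Russell slope and deviation mean square per line, one EYT."""
    X = adj.eyt(eyt)
    e = X.shape[1]
    if e < 3:
        raise ValueError("Eberhart-Russell regression needs >= 3 environments")
    if X.isna().any().any():
        raise ValueError("Eberhart-Russell regression requires complete data")
    I = X.mean(axis=0) - X.to_numpy().mean()
    denom = float((I ** 2).sum())
    if denom <= 0:
        raise ValueError("all environmental indices are zero; slope undefined")
    b = (X * I).sum(axis=1) / denom
    fitted = np.add.outer(X.mean(axis=1).to_numpy(), np.zeros(e)) + np.outer(
        b.to_numpy(), I.to_numpy()
    )
    resid = X.to_numpy() - fitted
    dev = (resid ** 2).sum(axis=1) / max(e - 2, 1)
    return pd.DataFrame(
        {
            "eyt": eyt,
            "ER_slope": b,
            "ER_dev": dev,
            "mean_gy": X.mean(axis=1),
        },
        index=X.index,
    )


def stability_results(adj: AdjMeans, eyt: str) -> pd.DataFrame:
    """Joined Pi and ER table per line for one EYT."""
    pi = superiority_index(adj, eyt)
    er = eberhart_russell(adj, eyt)
    return pi.join(er[["ER_slope", "ER_dev"]])


def stability_vs_mean(results: pd.DataFrame) -> pd.Series:
    """Pearson correlations of mean GY with -Pi and with the ER slope.

    The Pi correlation is computed on -Pi so that a positive value means
    "higher yielding lines are more superior/stable", matching the sign
    convention used when Pi is discussed as a selection index.  Zero
    variance in an index yields NaN with a flag.
    """
    if results.shape[0] < 3:
        raise ValueError("need at least 3 lines for correlations")
    out: dict[str, float] = {}
    mean_gy = results["mean_gy"]
    for name, col in (("corr_mean_negPi", -results["Pi"]),
                      ("corr_mean_ER", results.get("ER_slope"))):
        if col is None:
            continue
        if col.std() == 0 or mean_gy.std() == 0:
            out[name] = np.nan
            out[name + "_undefined"] = True
        else:
            out[name] = float(np.corrcoef(mean_gy, col)[0, 1])
            out[name + "_undefined"] = False
    return pd.Series(out)
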