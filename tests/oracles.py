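"""Independent brute-force oracles used by the test suite.

Deliberately written as plain loops, separate from the package's vectorised
implementations.
"""

import numpy as np


def dprime_direct(counts):
    """D' from a 2x2 haplotype count table by the textbook formula."""
    n = float(counts.sum())
    pa = (counts[0, 0] + counts[0, 1]) / n
    pb = (counts[0, 0] + counts[1, 0]) / n
    d = counts[0, 0] / n - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return 0.0
    return abs(d) / dmax


def dprime_ci_grid(counts, n_grid=101, tail=0.05):
    """Likelihood-grid CI for |D'|: cumulative 5% tails, plain loops."""
    n = float(counts.sum())
    pa = (counts[0, 0] + counts[0, 1]) / n
    pb = (counts[0, 0] + counts[1, 0]) / n
    d_obs = counts[0, 0] / n - pa * pb
    sign = 1.0 if d_obs >= 0 else -1.0
    if d_obs >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    grid = [i / (n_grid - 1) for i in range(n_grid)]
    logliks = []
    for gp in grid:
        d = sign * gp * dmax
        fs = [pa * pb + d, pa * (1 - pb) - d, (1 - pa) * pb - d,
              (1 - pa) * (1 - pb) + d]
        cs = [counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]]
        ll = 0.0
        for f, c in zip(fs, cs):
            ll += c * np.log(max(f, 1e-12))
        logliks.append(ll)
    m = max(logliks)
    liks = [np.exp(v - m) for v in logliks]
    total = sum(liks)
    liks = [v / total for v in liks]
    acc, low = 0.0, grid[-1]
    for gp, lk in zip(grid, liks):
        acc += lk
        if acc >= tail:
            low = gp
            break
    acc, high = 0.0, grid[0]
    for gp, lk in zip(reversed(grid), reversed(liks)):
        acc += lk
        if acc >= tail:
            high = gp
            break
    return low, high


def classify_rule(ci_low, ci_high, lower_min=0.6, upper_min=0.95, recomb_max=0.9):
    if ci_low >= lower_min and ci_high >= upper_min:
        return "strong LD"
    if ci_high < recomb_max:
        return "strong recombination"
    return "inconclusive"


def pair_class(codes, i, j):
    """Pair classification from homozygous calls, via the oracle CI."""
    n11 = n12 = n21 = n22 = 0
    for li in range(codes.shape[0]):
        a, b = codes[li, i], codes[li, j]
        if a == 1 and b == 1:
            n11 += 1
        elif a == 1 and b == -1:
            n12 += 1
        elif a == -1 and b == 1:
            n21 += 1
        elif a == -1 and b == -1:
            n22 += 1
    counts = np.array([[n11, n12], [n21, n22]], float)
    tot = counts.sum()
    if tot < 2:
        return "inconclusive"
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if rows.max() == tot or cols.max() == tot:
        return "inconclusive"
    low, high = dprime_ci_grid(counts)
    return classify_rule(low, high)


def exhaustive_blocks(codes, max_span=50, strong_frac=0.95):
    """Enumerate every contiguous span; greedy longest-first acceptance.

    Returns the accepted spans as sorted (start, end) index pairs (indices
    into the SNP order of one chromosome).
    """
    L = codes.shape[1]
    klass = {}
    for i in range(L):
        for j in range(i + 1, L):
            klass[(i, j)] = pair_class(codes, i, j)
    candidates = []
    for s in range(L):
        for e in range(s + 1, min(s + max_span, L)):
            n_strong = n_inf = 0
            for i in range(s, e + 1):
                for j in range(i + 1, e + 1):
                    k = klass[(i, j)]
                    if k != "inconclusive":
                        n_inf += 1
                        if k == "strong LD":
                            n_strong += 1
            if n_inf > 0 and n_strong / n_inf >= strong_frac - 1e-12:
                candidates.append((e - s + 1, s, e))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    used = [False] * L
    accepted = []
    for _, s, e in candidates:
        if any(used[s:e + 1]):
            continue
        for k in range(s, e + 1):
            used[k] = True
        accepted.append((s, e))
    return sorted(accepted)


def pi_brute(X):
    """Lin-Binns Pi with explicit loops; X is lines x environments."""
    n, e = X.shape
    maxima = [max(X[i, j] for i in range(n)) for j in range(e)]
    out = []
    for i in range(n):
        acc = 0.0
        for j in range(e):
            acc += (X[i, j] - maxima[j]) ** 2
        out.append(acc / (2.0 * e))
    return np.array(out)


def er_brute(X):
    """Eberhart-Russell slopes and deviation mean squares, explicit loops."""
    n, e = X.shape
    env_means = [sum(X[i, j] for i in range(n)) / n for j in range(e)]
    grand = sum(env_means) / e
    I = [m - grand for m in env_means]
    denom = sum(v * v for v in I)
    slopes, devs = [], []
    for i in range(n):
        b = sum(X[i, j] * I[j] for j in range(e)) / denom
        xbar = sum(X[i, j] for j in range(e)) / e
        ss = sum((X[i, j] - xbar - b * I[j]) ** 2 for j in range(e))
        slopes.append(b)
        devs.append(ss / max(e - 2, 1))
    return np.array(slopes), np.array(devs)


def group_rule(sig_trials):
    """Consistency group for one locus from its set of (eyt, env) hits."""
    if not sig_trials:
        return None
    eyts = {t[0] for t in sig_trials}
    if len(eyts) == 1:
        return 1
    envs = {t[1] for t in sig_trials}
    if len(envs) == 1:
        return 2
    envs_per_eyt = {}
    for eyt, env in sig_trials:
        envs_per_eyt.setdefault(eyt, set()).add(env)
    if all(len(v) >= 2 for v in envs_per_eyt.values()):
        return 3
    return 4
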