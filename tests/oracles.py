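"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, per-window loops,
textbook DP) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(x, y):
        return sum(1.0 if xi > yi else (0.5 if xi == yi else 0.0)
                   for xi in x for yi in y)

    u_obs = u_stat(a, b)
    mu = n1 * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(x, y) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def wilcoxon_exact(diffs) -> tuple[float, float]:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return w_obs, count / 2 ** n


def spearman_exact(x, y) -> tuple[float, float]:
    """Exact two-sided permutation p for Spearman rho, full enumeration."""
    rx = rankdata(x)
    ry = rankdata(y)

    def rho(u, v):
        return float(np.corrcoef(u, v)[0, 1])

    r_obs = rho(rx, ry)
    count = total = 0
    for perm in itertools.permutations(range(len(ry))):
        if abs(rho(rx, ry[list(perm)])) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return r_obs, count / total


def auc_pair_counting(tumor, normal) -> float:
    """AUC as the tie-adjusted fraction of tumor > normal pairs."""
    wins = ties = 0
    for t in tumor:
        for n in normal:
            if t > n:
                wins += 1
            elif t == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(tumor) * len(normal))


def km_hand_table(times, events):
    """Product-limit estimate computed step by step from the definition."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out_t.append(float(t))
        out_s.append(s)
    return out_t, out_s


def gbw_hand(times, events, group) -> float:
    """At-risk-weighted log-rank z computed directly from its definition."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    num = var = 0.0
    for t in sorted(set(times[events == 1])):
        risk = times >= t
        n = int(risk.sum())
        n1 = int((risk & (group == 1)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (group == 1)).sum())
        num += n * (d1 - d * n1 / n)
        if n > 1:
            var += n * n * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return num / var ** 0.5 if var > 0 else 0.0


def cpg_islands_naive(seq, min_length=200, gc_min=0.5, oe_min=0.6,
                      window=200, step=1):
    """Per-window loop island finder: scan, collect passing windows, merge."""
    seq = seq.upper()
    passing = []
    for s in range(0, len(seq) - window + 1, step):
        w = seq[s:s + window]
        gc = (w.count("C") + w.count("G")) / window
        exp = w.count("C") * w.count("G") / window
        oe = (w.count("CG") / exp) if exp > 0 else 0.0
        if gc >= gc_min and oe >= oe_min:
            passing.append((s, s + window))
    merged = []
    for s, e in sorted(passing):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_length]


def needleman_wunsch_affine(a, b, match=1.0, mismatch=-1.0,
                            gap_open=-2.0, gap_extend=-0.5,
                            bisulfite=False):
    """Gotoh global alignment score; optional reference-C vs query-T match."""
    la, lb = len(a), len(b)
    neg = float("-inf")
    m = np.full((la + 1, lb + 1), neg)
    ix = np.full((la + 1, lb + 1), neg)  # gap in b (consume a)
    iy = np.full((la + 1, lb + 1), neg)  # gap in a (consume b)
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        ix[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, lb + 1):
        iy[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            if a[i - 1] == b[j - 1] or (
                bisulfite and a[i - 1] == "C" and b[j - 1] == "T"
            ):
                s = match
            else:
                s = mismatch
            m[i, j] = max(m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1]) + s
            ix[i, j] = max(m[i - 1, j] + gap_open, ix[i - 1, j] + gap_extend,
                           iy[i - 1, j] + gap_open)
            iy[i, j] = max(m[i, j - 1] + gap_open, iy[i, j - 1] + gap_extend,
                           ix[i, j - 1] + gap_open)
    return max(m[la, lb], ix[la, lb], iy[la, lb])
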