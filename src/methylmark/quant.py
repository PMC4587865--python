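"""Expression and staining quantification, plus shared nonparametric statistics.

Covers efficiency-corrected delta-Ct relative expression against one or more
reference genes, group summaries (average relative expression, ARE), the
immunohistochemistry H-score, and the exact small-sample nonparametric tests
(Mann-Whitney, Wilcoxon signed-rank, Spearman) used throughout the package.

Relative quantification follows the efficiency-corrected delta-Ct model: a
transcript measured at cycle threshold Ct with primer amplification factor E
(E = 2 for a perfectly efficient primer pair) has abundance proportional to
E**(-Ct). The relative expression of a target against a set of reference
genes is the ratio of the target abundance to the geometric mean of the
reference abundances; with a single reference and E = 2 this reduces to the
textbook 2**(-dCt).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats


__all__ = [
    "QpcrMeasurement",
    "RelativeExpression",
    "IhcScore",
    "GroupSummary",
    "TestResult",
    "relative_expression",
    "group_summary",
    "h_score",
    "spearman",
    "mann_whitney",
    "wilcoxon_paired",
]


# ---------------------------------------------------------------------------
# qPCR quantification
# ---------------------------------------------------------------------------

@dataclass
class QpcrMeasurement:
    """Replicate Ct values for one gene in one sample.

    Parameters
    ----------
    sample : str
        Sample identifier.
    gene : str
        Gene (primer pair) identifier.
    cts : sequence of float
        Replicate cycle-threshold values; combined by arithmetic mean.
    efficiency : float
        Per-cycle amplification factor of the primer pair; 2.0 for an ideal
        primer, realistic values fall in (1, 2.2].
    max_ct_spread : float
        Replicates further apart than this (cycles) set the ``flagged``
        attribute; a QC convention, the measurement is still usable.
    """

    sample: str
    gene: str
    cts: Sequence[float]
    efficiency: float = 2.0
    max_ct_spread: float = 0.5
    flagged: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        cts = np.asarray(self.cts, dtype=float)
        if cts.size == 0:
            raise ValueError("at least one Ct replicate required")
        if np.any(cts <= 0):
            raise ValueError("Ct values must be positive")
        if not 1.0 < self.efficiency <= 2.2:
            raise ValueError(f"efficiency {self.efficiency} outside (1, 2.2]")
        if cts.size > 1 and float(cts.max() - cts.min()) > self.max_ct_spread:
            self.flagged = True

    @property
    def mean_ct(self) -> float:
        return float(np.mean(np.asarray(self.cts, dtype=float)))

    @property
    def quantity(self) -> float:
        """Abundance proportional to efficiency**(-mean Ct)."""
        return float(self.efficiency ** (-self.mean_ct))


@dataclass(frozen=True)
class RelativeExpression:
    """Efficiency-corrected relative expression of a target vs references."""

    sample: str
    gene: str
    value: float
    log2_value: float


def relative_expression(
    target: QpcrMeasurement, refs: Sequence[QpcrMeasurement]
) -> RelativeExpression:
    """Efficiency-corrected delta-Ct relative expression.

    The target quantity ``E_t**(-Ct_t)`` is divided by the geometric mean of
    the reference quantities ``E_r**(-Ct_r)``. A single reference reduces to
    the plain delta-Ct ratio; with all efficiencies equal to 2 this is
    ``2**(-(Ct_t - Ct_ref))``.
    """
    if len(refs) == 0:
        raise ValueError("at least one reference gene measurement is required")
    # geometric mean computed in log space for numerical stability
    log_ref = float(np.mean([-r.mean_ct * math.log2(r.efficiency) for r in refs]))
    log_target = -target.mean_ct * math.log2(target.efficiency)
    log2_value = log_target - log_ref
    return RelativeExpression(
        sample=target.sample,
        gene=target.gene,
        value=float(2.0 ** log2_value),
        log2_value=float(log2_value),
    )


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """ARE +/- SEM per group, their ratio, and a nonparametric p-value.

    Means are arithmetic on the linear scale (the convention for reporting
    average relative expression), while the test runs on log2 values where
    the distributions are closer to symmetric.
    """

    are_a: float
    sem_a: float
    are_b: float
    sem_b: float
    ratio: float
    statistic: float
    p_value: float
    test: str


def group_summary(
    group_a: Sequence[RelativeExpression],
    group_b: Sequence[RelativeExpression],
    paired: bool = False,
) -> GroupSummary:
    """Summarise two groups of relative-expression values and test them.

    Unpaired groups are compared with a two-sided Mann-Whitney test, paired
    groups (matched by sample id) with a Wilcoxon signed-rank test; both run
    on the log2 values.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two values")
    va = np.array([r.value for r in group_a])
    vb = np.array([r.value for r in group_b])
    la = np.array([r.log2_value for r in group_a])
    lb = np.array([r.log2_value for r in group_b])
    if paired:
        ids_a = [r.sample for r in group_a]
        ids_b = [r.sample for r in group_b]
        if sorted(ids_a) != sorted(ids_b):
            raise ValueError("paired mode requires matched sample ids")
        order = {s: i for i, s in enumerate(ids_b)}
        lb = lb[[order[s] for s in ids_a]]
        res = wilcoxon_paired(la - lb)
        test = "wilcoxon_signed_rank"
    else:
        res = mann_whitney(la, lb)
        test = "mann_whitney"
    sem = lambda v: float(np.std(v, ddof=1) / math.sqrt(len(v)))
    return GroupSummary(
        are_a=float(va.mean()),
        sem_a=sem(va),
        are_b=float(vb.mean()),
        sem_b=sem(vb),
        ratio=float(va.mean() / vb.mean()),
        statistic=res.statistic,
        p_value=res.p_value,
        test=test,
    )


# ---------------------------------------------------------------------------
# Immunohistochemistry H-score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IhcScore:
    sample: str
    percents: tuple[float, float, float, float]
    h_score: float


def h_score(percents: Sequence[float], sample: str = "") -> IhcScore:
    """H-score: sum of staining intensity (0-3) times percent cells.

    ``percents`` gives the percentage of cells at intensities 0, 1, 2, 3 and
    must sum to 100 (+/- 0.5 rounding slack). The score ranges 0-300.
    """
    p = np.asarray(percents, dtype=float)
    if p.shape != (4,):
        raise ValueError("need exactly four intensity percentages (0..3)")
    if np.any(p < 0):
        raise ValueError("percentages must be non-negative")
    if abs(p.sum() - 100.0) > 0.5:
        raise ValueError(f"percentages sum to {p.sum():.2f}, expected 100")
    score = float(1 * p[1] + 2 * p[2] + 3 * p[3])
    return IhcScore(sample=sample, percents=tuple(p), h_score=score)


# ---------------------------------------------------------------------------
# Shared nonparametric tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p-value when both groups have n <= 20 and there are no ties across
    the pooled sample; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), f"mann_whitney_{method}")


def wilcoxon_paired(diffs: Sequence[float], exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. For n <= ``exact_max_n`` the exact null
    distribution of the positive-rank sum is computed by a generating-function
    convolution over the (average, possibly tied) ranks, so ties among the
    absolute differences are handled exactly; larger n falls back to the
    tie-corrected normal approximation. All-zero input returns p = 1 with a
    warning (no evidence of any difference).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference vector")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value reported as 1")
        return TestResult(0.0, 1.0, "wilcoxon_degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_max_n:
        # ranks are k/2 with integer k; double them for an integer-support DP
        weights = np.rint(2 * ranks).astype(np.int64)
        total = int(weights.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for w in weights:
            shifted = np.zeros_like(dist)
            shifted[w:] = dist[: total + 1 - w]
            dist = dist + shifted
        dist /= 2.0 ** n
        w2 = int(round(2 * w_pos))
        p_low = float(dist[: w2 + 1].sum())
        p_high = float(dist[w2:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult(w_pos, p, "wilcoxon_exact")
    res = stats.wilcoxon(d, alternative="two-sided", method="approx")
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon_normal")


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman(x: Sequence[float], y: Sequence[float], exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with an exact permutation p for small n.

    For n <= ``exact_max_n`` the two-sided p-value enumerates all n!
    permutations of one rank vector (ties handled through average ranks);
    larger samples use the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input has undefined rank correlation")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = _all_permutations(n)
        ry_perm = ry[perms]  # (n!, n)
        rx_c = rx - rx.mean()
        ry_c = ry_perm - ry.mean()
        denom = math.sqrt(float((rx_c ** 2).sum())) * np.sqrt((ry_c ** 2).sum(axis=1))
        rho_all = (ry_c @ rx_c) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        return TestResult(rho, p, "spearman_exact")
    if abs(rho) >= 1.0:
        return TestResult(rho, 0.0, "spearman_t")
    t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return TestResult(rho, p, "spearman_t")
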