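"""Kaplan-Meier relapse-free-survival comparison between methylation groups.

The Gehan-Breslow-Wilcoxon test is the at-risk-weighted log-rank statistic
(weight = number at risk at each event time), which emphasizes early
survival differences; its asymptotic p comes from a 1-df chi-squared, with
a seeded permutation p available for small samples.

``cutoff_scan`` reproduces the best-cutoff search used when a methylation
score must be dichotomized: survival records are truncated at a follow-up
horizon (events beyond it become censored at the horizon), each candidate
cutoff splits patients at score >= c vs < c, and the cutoff with the
smallest Gehan-Breslow-Wilcoxon p wins. Because the minimum over cutoffs is
taken without correction, the selected p-value is optimistic; the report
carries an explicit multiplicity caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "KmCurve",
    "GbwResult",
    "ScanResult",
    "km_estimate",
    "gbw_test",
    "cutoff_scan",
    "truncate_followup",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = (60.0, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0)

MULTIPLICITY_NOTE = (
    "best cutoff selected as the minimum p over the scanned set without "
    "multiple-testing correction; the selected p-value is optimistic"
)


@dataclass
class KmCurve:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator (flat at 1 if nothing fails)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tl = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    at_risk = np.array([(times >= t).sum() for t in tl])
    return KmCurve(times=tl, survival=surv, at_risk=at_risk)


@dataclass(frozen=True)
class GbwResult:
    statistic: float  # chi-squared (1 df)
    z: float
    p_value: float
    method: str


def _gbw_statistic(times, events, group) -> float:
    """Signed, normalized Gehan-Breslow-Wilcoxon z for group==1 vs group==0.

    At every distinct event time t_j with d_j events, n_j at risk overall and
    n1j at risk in group 1: the observed-minus-expected group-1 events
    (hypergeometric mean d_j * n1j/n_j) are weighted by n_j and normalized by
    the summed weighted hypergeometric variances (Breslow tie convention).
    """
    event_times = np.unique(times[events == 1])
    num = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n_j = int(at_risk.sum())
        n1j = int((at_risk & (group == 1)).sum())
        d_j = int(((times == t) & (events == 1)).sum())
        d1j = int(((times == t) & (events == 1) & (group == 1)).sum())
        e1j = d_j * n1j / n_j
        if n_j > 1:
            v1j = d_j * (n1j / n_j) * (1 - n1j / n_j) * (n_j - d_j) / (n_j - 1)
        else:
            v1j = 0.0
        num += n_j * (d1j - e1j)
        var += n_j ** 2 * v1j
    if var <= 0:
        return 0.0
    return num / np.sqrt(var)


def gbw_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    permutation: bool = False,
    n_perm: int = 2000,
    seed: int = 0,
) -> GbwResult:
    """Two-sided Gehan-Breslow-Wilcoxon test between two survival groups.

    Each group is a DataFrame with ``time`` and ``event`` columns. The
    default p comes from chi-squared(1); ``permutation=True`` instead
    permutes group labels (seeded) — preferable for small samples.
    """
    for g in (group_a, group_b):
        if not {"time", "event"} <= set(g.columns):
            raise ValueError("groups need 'time' and 'event' columns")
    times = np.concatenate([group_a["time"].to_numpy(float),
                            group_b["time"].to_numpy(float)])
    events = np.concatenate([group_a["event"].to_numpy(int),
                             group_b["event"].to_numpy(int)])
    group = np.concatenate([np.zeros(len(group_a), int), np.ones(len(group_b), int)])
    if events.sum() == 0:
        raise ValueError("no events in either group")
    z = _gbw_statistic(times, events, group)
    chi2 = z ** 2
    if permutation:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(group)
            if abs(_gbw_statistic(times, events, perm)) >= abs(z) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        return GbwResult(float(chi2), float(z), float(p), "permutation")
    p = float(stats.chi2.sf(chi2, df=1))
    return GbwResult(float(chi2), float(z), p, "chi2")


def truncate_followup(table: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administrative censoring at the follow-up horizon.

    Records with time beyond the horizon are censored at the horizon
    (whatever happened later is outside the analysis window).
    """
    out = table.copy()
    late = out["time"] > horizon
    out.loc[late, "event"] = 0
    out.loc[late, "time"] = horizon
    return out


@dataclass
class ScanResult:
    table: pd.DataFrame = field(repr=False)
    best_cutoff: float
    best_p: float
    note: str = MULTIPLICITY_NOTE


def cutoff_scan(
    table: pd.DataFrame,
    cutoffs=DEFAULT_CUTOFFS,
    horizon: float = 10.0,
    score_col: str = "nams",
) -> ScanResult:
    """Scan dichotomization cutoffs on a methylation score against survival.

    For each cutoff c, patients split into score >= c vs < c groups; the
    Gehan-Breslow-Wilcoxon p (on records truncated at ``horizon`` years) is
    recorded. Cutoffs leaving an empty group are skipped with a warning. The
    best cutoff minimizes p; the result carries a multiplicity caveat.
    """
    cutoffs = list(cutoffs)
    if len(cutoffs) < 2:
        raise ValueError("need at least two cutoffs to scan")
    required = {score_col, "time", "event"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    data = truncate_followup(table[[score_col, "time", "event"]].dropna(), horizon)
    rows = []
    for c in cutoffs:
        high = data[data[score_col] >= c]
        low = data[data[score_col] < c]
        if high.empty or low.empty:
            warnings.warn(f"cutoff {c} leaves an empty group; skipped")
            continue
        try:
            res = gbw_test(low, high)
        except ValueError:
            warnings.warn(f"cutoff {c} has no events; skipped")
            continue
        rows.append({"cutoff": c, "n_high": len(high), "n_low": len(low),
                     "chi2": res.statistic, "p": res.p_value})
    if not rows:
        raise ValueError("no cutoff produced two comparable groups")
    scan = pd.DataFrame(rows)
    best = scan.loc[scan["p"].idxmin()]
    return ScanResult(table=scan, best_cutoff=float(best["cutoff"]),
                      best_p=float(best["p"]))
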