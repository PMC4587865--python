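"""Demethylating-drug reactivation screen on log2 expression matrices.

The screen finds probes induced by a demethylating agent (e.g. decitabine)
in cancer cell lines but not in a non-tumorigenic control line. Per cell
line, a variance-moderated two-sample t compares drug vs vehicle replicates;
candidates must pass fold-change and significance thresholds, in the same
direction, in every designated cancer line while failing at least one of the
two criteria in the non-tumorigenic line (the strictest reading would drop
borderline genes the biology retains).

The moderated t shrinks each probe's pooled variance toward the across-probe
mean with a configurable prior degrees of freedom, stabilising small-sample
(2-3 replicate) designs; Welch's t is available as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


__all__ = [
    "ExpressionMatrix",
    "CandidateSet",
    "OverlapReport",
    "differential_response",
    "select_candidates",
    "overlap_report",
    "cross_dataset_validation",
]

CANCER = "cancer"
NON_TUMORIGENIC = "non_tumorigenic"
DRUG = "drug"
VEHICLE = "vehicle"


@dataclass
class ExpressionMatrix:
    """Log2 probe x sample matrix with per-sample annotation.

    ``values``: DataFrame indexed by probe id, columns are sample ids.
    ``annotation``: DataFrame indexed by sample id with columns
    ``cell_line``, ``cls`` (cancer / non_tumorigenic), ``treatment``
    (drug / vehicle), ``replicate``.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.annotation.index):
            missing = set(self.values.columns) - set(self.annotation.index)
            raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")
        required = {"cell_line", "cls", "treatment"}
        if not required <= set(self.annotation.columns):
            raise ValueError(f"annotation must have columns {sorted(required)}")
        if self.values.index.hasnans or self.values.index.duplicated().any():
            raise ValueError("probe ids must be unique and non-missing")

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.annotation["cell_line"]))

    def line_class(self, cell_line: str) -> str:
        cls = self.annotation.loc[
            self.annotation["cell_line"] == cell_line, "cls"
        ].unique()
        if len(cls) != 1:
            raise ValueError(f"ambiguous class for cell line {cell_line!r}")
        return str(cls[0])

    def columns_for(self, cell_line: str, treatment: str) -> list[str]:
        ann = self.annotation
        mask = (ann["cell_line"] == cell_line) & (ann["treatment"] == treatment)
        cols = [s for s in ann.index[mask] if s in self.values.columns]
        return cols


def differential_response(
    matrix: ExpressionMatrix,
    cell_line: str,
    method: str = "shrinkage",
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-probe drug-vs-vehicle fold change, t, p and BH FDR for one line.

    ``fold_change`` is mean(drug) - mean(vehicle) on the log2 scale. With
    ``method="shrinkage"`` the pooled per-probe variance is moderated toward
    the across-probe mean variance s0^2 with ``prior_df`` prior degrees of
    freedom (t has df + prior_df degrees of freedom); ``method="welch"``
    uses Welch's unequal-variance t.
    """
    if cell_line not in matrix.cell_lines:
        raise ValueError(f"unknown cell line {cell_line!r}")
    drug_cols = matrix.columns_for(cell_line, DRUG)
    veh_cols = matrix.columns_for(cell_line, VEHICLE)
    if len(drug_cols) < 2 or len(veh_cols) < 2:
        raise ValueError(
            f"cell line {cell_line!r} needs >=2 replicates per arm "
            f"(got {len(drug_cols)} drug, {len(veh_cols)} vehicle)"
        )
    x = matrix.values[drug_cols].to_numpy(float)
    y = matrix.values[veh_cols].to_numpy(float)
    n1, n2 = x.shape[1], y.shape[1]
    fc = x.mean(axis=1) - y.mean(axis=1)

    if method == "welch":
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    elif method == "shrinkage":
        df = n1 + n2 - 2
        s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / df
        s2_prior = float(s2.mean())
        s2_mod = (prior_df * s2_prior + df * s2) / (prior_df + df)
        se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        t = np.where(se > 0, fc / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    fdr = stats.false_discovery_control(p)
    return pd.DataFrame(
        {"fold_change": fc, "t": t, "p": p, "fdr": fdr}, index=matrix.values.index
    )


@dataclass
class CandidateSet:
    """Up- and downregulated candidate probe sets with the per-line table."""

    up: list[str]
    down: list[str]
    table: pd.DataFrame = field(repr=False)

    @property
    def all(self) -> list[str]:
        return self.up + self.down


def _passes(res: pd.DataFrame, log2_fold_min: float, p_max: float) -> pd.DataFrame:
    up = (res["fold_change"] >= log2_fold_min) & (res["p"] <= p_max)
    down = (res["fold_change"] <= -log2_fold_min) & (res["p"] <= p_max)
    return pd.DataFrame({"up": up, "down": down})


def select_candidates(
    results: Mapping[str, pd.DataFrame],
    cancer_lines: Sequence[str],
    ntb_line: str,
    fold_min: float = 1.5,
    p_max: float = 0.05,
) -> CandidateSet:
    """Probes altered in every cancer line (same direction) but not the NTB line.

    A probe is a candidate when |fold| >= log2(fold_min) and p <= p_max in
    each cancer line with consistent direction, and it does NOT satisfy both
    criteria (in that direction) in the non-tumorigenic line.
    """
    if not results:
        raise ValueError("empty results mapping")
    if not cancer_lines:
        raise ValueError("need at least one cancer line")
    missing = [l for l in [*cancer_lines, ntb_line] if l not in results]
    if missing:
        raise ValueError(f"results missing for lines: {missing}")
    thr = float(np.log2(fold_min))
    flags = {line: _passes(results[line], thr, p_max) for line in results}
    idx = results[ntb_line].index
    up_all = np.logical_and.reduce([flags[l]["up"].to_numpy() for l in cancer_lines])
    down_all = np.logical_and.reduce(
        [flags[l]["down"].to_numpy() for l in cancer_lines]
    )
    ntb = flags[ntb_line]
    up = up_all & ~ntb["up"].to_numpy()
    down = down_all & ~ntb["down"].to_numpy()

    cols = {}
    for line in results:
        cols[f"fold_{line}"] = results[line]["fold_change"]
        cols[f"p_{line}"] = results[line]["p"]
        cols[f"fdr_{line}"] = results[line]["fdr"]
    table = pd.DataFrame(cols, index=idx)
    table["candidate_up"] = up
    table["candidate_down"] = down
    return CandidateSet(
        up=list(idx[up]), down=list(idx[down]), table=table
    )


@dataclass(frozen=True)
class OverlapReport:
    common: frozenset
    a_only: frozenset
    b_only: frozenset
    pct_a: float
    pct_b: float


def overlap_report(set_a: Sequence, set_b: Sequence) -> OverlapReport:
    """Exact partition of two probe sets with per-set overlap percentages."""
    a, b = frozenset(set_a), frozenset(set_b)
    common = a & b
    pct = lambda s: 100.0 * len(common) / len(s) if s else 0.0
    return OverlapReport(
        common=common, a_only=a - common, b_only=b - common,
        pct_a=pct(a), pct_b=pct(b),
    )


def cross_dataset_validation(
    candidates: Sequence[str],
    external: ExpressionMatrix,
    p_max: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Fraction of candidates upregulated in an external paired drug/vehicle set.

    For every candidate probe, drug-minus-vehicle differences are computed per
    cell line (means across replicates when present) and tested with a paired
    t across lines; a candidate validates when p < ``p_max`` and the mean
    difference is positive.
    """
    lines = external.cell_lines
    if len(lines) < 3:
        raise ValueError("paired t needs >= 3 drug/vehicle pairs")
    candidates = [c for c in candidates]
    probes = [c for c in candidates if c in external.values.index]
    if not probes:
        raise ValueError("no candidate probes found in external matrix")
    diffs = np.empty((len(probes), len(lines)))
    for j, line in enumerate(lines):
        d = external.values.loc[probes, external.columns_for(line, DRUG)].mean(axis=1)
        v = external.values.loc[probes, external.columns_for(line, VEHICLE)].mean(axis=1)
        diffs[:, j] = (d - v).to_numpy()
    t, p = stats.ttest_1samp(diffs, 0.0, axis=1)
    mean_diff = diffs.mean(axis=1)
    validated = (p < p_max) & (mean_diff > 0)
    table = pd.DataFrame(
        {"mean_diff": mean_diff, "t": t, "p": p, "validated": validated}, index=probes
    )
    return float(validated.mean()), table
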