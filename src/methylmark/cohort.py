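"""Array-cohort methylation biomarker evaluation.

Works on per-sample methylation score tables (two array probes per gene,
tumor and normal groups, optional clinical covariates). The pipeline is:

1. ``average_probes`` — per-sample mean of the two probe scores, with the
   inter-probe Spearman correlation as a concordance diagnostic.
2. ``nams_normalize`` — normalized average methylation score (NAMS): the
   per-dataset rescaling that maps the lowest average score to 0 and the
   highest to 100. Two readings of the in-between mapping are provided:
   a plain affine min-max (``linear``) and an endpoint-anchored logistic
   squash (``logistic``); both are rank-preserving.
3. ``call_methylation`` — a tumor is hypermethylated when its NAMS exceeds
   the normal-group mean by more than ``margin`` (default 30; strict
   inequality), hypomethylated when more than ``margin`` below, neutral
   otherwise. Frequencies reported overall and by grade.
4. ``roc_discriminate`` — empirical tumor-vs-normal ROC over midpoint
   thresholds, trapezoid AUC, stratified-bootstrap CI, and an operating
   point that maximizes sensitivity subject to 100% specificity (Youden's J
   available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import spearman

__all__ = [
    "RocResult",
    "CallSummary",
    "average_probes",
    "nams_normalize",
    "call_methylation",
    "above_max_normal",
    "roc_discriminate",
]

TUMOR = "tumor"
NORMAL = "normal"


def _require_columns(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table missing columns: {missing}")


def average_probes(
    table: pd.DataFrame, probe_ids: tuple[str, str]
) -> tuple[pd.DataFrame, float]:
    """Arithmetic mean of the two probe scores per sample.

    Returns a copy of the table with an ``avg_score`` column and the
    inter-probe Spearman rho (a concordance diagnostic for whether averaging
    the probes is sensible).
    """
    p1, p2 = probe_ids
    _require_columns(table, [p1, p2])
    out = table.copy()
    out["avg_score"] = (out[p1].astype(float) + out[p2].astype(float)) / 2.0
    rho = spearman(out[p1].to_numpy(float), out[p2].to_numpy(float)).statistic
    return out, float(rho)


def _nams_one(scores: np.ndarray, mode: str, k: float) -> np.ndarray:
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        raise ValueError("constant scores cannot be normalized")
    if mode == "linear":
        return 100.0 * (scores - lo) / (hi - lo)
    if mode == "logistic":
        # logistic squash centered at the midrange, steepness k per score SD,
        # then re-anchored so the endpoints hit exactly 0 and 100
        mid = (lo + hi) / 2.0
        sd = float(scores.std(ddof=0)) or 1.0
        f = 1.0 / (1.0 + np.exp(-k * (scores - mid) / sd))
        f_lo = 1.0 / (1.0 + np.exp(-k * (lo - mid) / sd))
        f_hi = 1.0 / (1.0 + np.exp(-k * (hi - mid) / sd))
        return 100.0 * (f - f_lo) / (f_hi - f_lo)
    raise ValueError(f"unknown NAMS mode {mode!r}")


def nams_normalize(
    table: pd.DataFrame,
    mode: str = "linear",
    k: float = 1.0,
    dataset_col: str | None = None,
) -> pd.DataFrame:
    """Rescale ``avg_score`` to NAMS in [0, 100], min -> 0 and max -> 100.

    When ``dataset_col`` names a column, each dataset is normalized
    independently and then pooled (multi-cohort harmonization); otherwise the
    whole table is one dataset.
    """
    _require_columns(table, ["avg_score"])
    out = table.copy()
    if dataset_col is not None and dataset_col in out.columns:
        nams = np.empty(len(out))
        for _, idx in out.groupby(dataset_col, sort=False).groups.items():
            loc = out.index.get_indexer(idx)
            nams[loc] = _nams_one(out.loc[idx, "avg_score"].to_numpy(float), mode, k)
        out["nams"] = nams
    else:
        out["nams"] = _nams_one(out["avg_score"].to_numpy(float), mode, k)
    return out


@dataclass
class CallSummary:
    """Hyper/hypo/neutral calls with overall and per-grade frequencies."""

    calls: pd.DataFrame = field(repr=False)
    normal_mean: float
    margin: float
    frequency: pd.DataFrame = field(repr=False)

    @property
    def hyper_percent(self) -> float:
        row = self.frequency.loc["all"]
        return float(row["hyper_pct"])


def call_methylation(table: pd.DataFrame, margin: float = 30.0) -> CallSummary:
    """Call tumors hyper/hypo-methylated against the normal-group NAMS mean.

    A tumor is *hyper* when NAMS - normal_mean > margin (strictly), *hypo*
    when < -margin, neutral otherwise. Frequencies (percent of the tumor
    group) are reported overall and, when a ``grade`` column is present, per
    grade.
    """
    _require_columns(table, ["nams", "group"])
    normals = table.loc[table["group"] == NORMAL, "nams"]
    if normals.empty:
        raise ValueError("no normal samples; a normal reference is required")
    normal_mean = float(normals.mean())
    tumors = table[table["group"] == TUMOR].copy()
    margin_vals = tumors["nams"].to_numpy(float) - normal_mean
    call = np.where(margin_vals > margin, "hyper",
                    np.where(margin_vals < -margin, "hypo", "neutral"))
    tumors["margin"] = margin_vals
    tumors["call"] = call

    def freq(sub: pd.DataFrame) -> dict:
        n = len(sub)
        h = int((sub["call"] == "hyper").sum())
        l = int((sub["call"] == "hypo").sum())
        return {
            "n": n,
            "hyper": h,
            "hypo": l,
            "neutral": n - h - l,
            "hyper_pct": 100.0 * h / n if n else 0.0,
            "hypo_pct": 100.0 * l / n if n else 0.0,
        }

    rows = {"all": freq(tumors)}
    if "grade" in tumors.columns:
        for g, sub in tumors.groupby("grade", dropna=True):
            rows[f"grade_{g}"] = freq(sub)
    frequency = pd.DataFrame(rows).T
    return CallSummary(
        calls=tumors, normal_mean=normal_mean, margin=margin, frequency=frequency
    )


def above_max_normal(table: pd.DataFrame) -> tuple[float, float]:
    """Percent of tumors above the highest normal NAMS, and the group-mean gap."""
    _require_columns(table, ["nams", "group"])
    normals = table.loc[table["group"] == NORMAL, "nams"]
    tumors = table.loc[table["group"] == TUMOR, "nams"]
    if normals.empty:
        raise ValueError("no normal samples")
    if tumors.empty:
        raise ValueError("no tumor samples")
    pct = 100.0 * float((tumors > normals.max()).mean())
    return pct, float(tumors.mean() - normals.mean())


@dataclass
class RocResult:
    """Empirical ROC with trapezoid AUC, bootstrap CI and an operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    operating_threshold: float
    operating_sensitivity: float
    operating_specificity: float


def _roc_curve(tumor: np.ndarray, normal: np.ndarray) -> tuple[np.ndarray, ...]:
    # candidate thresholds: midpoints between consecutive unique pooled
    # values, plus sentinels below the minimum and above the maximum
    values = np.unique(np.concatenate([tumor, normal]))
    mids = (values[:-1] + values[1:]) / 2.0 if values.size > 1 else np.array([])
    thresholds = np.concatenate([[values[0] - 1.0], mids, [values[-1] + 1.0]])
    # searchsorted on the sorted groups gives counts >= / < each threshold
    tumor_sorted = np.sort(tumor)
    normal_sorted = np.sort(normal)
    sens = 1.0 - np.searchsorted(tumor_sorted, thresholds, side="left") / tumor.size
    spec = np.searchsorted(normal_sorted, thresholds, side="left") / normal.size
    return thresholds, sens, spec


def _auc(sens: np.ndarray, spec: np.ndarray) -> float:
    fpr = 1.0 - spec
    # vertical runs (equal fpr) must be traversed in increasing sensitivity
    order = np.lexsort((sens, fpr))
    return float(abs(np.trapezoid(sens[order], fpr[order])))


def roc_discriminate(
    table: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    operating: str = "max_spec",
) -> RocResult:
    """Tumor-vs-normal ROC on NAMS with a 100%-specificity operating point.

    ``operating="max_spec"`` picks the smallest threshold with specificity
    1.0 (maximizing sensitivity under perfect specificity, the convention
    when a diagnostic must not flag healthy individuals); ``"youden"`` picks
    the threshold maximizing sensitivity + specificity - 1. The AUC CI is a
    stratified bootstrap (seeded).
    """
    _require_columns(table, ["nams", "group"])
    tumor = table.loc[table["group"] == TUMOR, "nams"].to_numpy(float)
    normal = table.loc[table["group"] == NORMAL, "nams"].to_numpy(float)
    if tumor.size == 0 or normal.size == 0:
        raise ValueError("both tumor and normal groups must be non-empty")
    thresholds, sens, spec = _roc_curve(tumor, normal)
    auc = _auc(sens, spec)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        tb = rng.choice(tumor, tumor.size, replace=True)
        nb = rng.choice(normal, normal.size, replace=True)
        _, s_b, sp_b = _roc_curve(tb, nb)
        boots[i] = _auc(s_b, sp_b)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    if operating == "max_spec":
        perfect = spec >= 1.0
        cand = np.flatnonzero(perfect)
        i_op = int(cand[np.argmin(thresholds[cand])])
    elif operating == "youden":
        i_op = int(np.argmax(sens + spec - 1.0))
    else:
        raise ValueError(f"unknown operating-point rule {operating!r}")
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=ci,
        operating_threshold=float(thresholds[i_op]),
        operating_sensitivity=float(sens[i_op]),
        operating_specificity=float(spec[i_op]),
    )
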