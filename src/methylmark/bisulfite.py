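"""Per-CpG methylation quantification from cloned bisulfite-sequencing reads.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T)
while methylated CpG cytosines stay C. Each cloned read is therefore aligned
against the *unconverted* reference with bisulfite-aware scoring: at non-CpG
positions a reference C aligned to a clone T counts as a match (expected
conversion), while at declared CpG sites C<->C is read as a methylated call
and C<->T as unmethylated. The fraction of converted non-CpG cytosines is
the conversion rate, the standard completeness QC for bisulfite experiments.

A sample is typically a handful of clones (five in the classic design); its
overall percent methylation pools all non-missing CpG calls across clones,
which equals the average of per-clone percentages when no call is missing
and degrades gracefully when some are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .quant import TestResult, mann_whitney, spearman, wilcoxon_paired

__all__ = [
    "BisulfiteReference",
    "CloneAlignment",
    "BisulfiteSample",
    "LowIdentityError",
    "align_clone",
    "qc_filter",
    "sample_methylation",
    "compare_groups",
    "compare_paired",
    "correlate_expression",
    "METHYLATED",
    "UNMETHYLATED",
    "MISSING",
]

METHYLATED = 1
UNMETHYLATED = 0
MISSING = -1


class LowIdentityError(ValueError):
    """Clone alignment identity below the hard floor; clone is non-specific."""


@dataclass(frozen=True)
class BisulfiteReference:
    """Unconverted reference subsequence with its CpG cytosine offsets."""

    sequence: str
    cpg_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for o in self.cpg_offsets:
            if not (0 <= o < len(seq) - 1 and seq[o] == "C" and seq[o + 1] == "G"):
                raise ValueError(f"offset {o} is not a CpG dinucleotide cytosine")

    @property
    def converted(self) -> str:
        """Fully converted bisulfite image: every non-CpG C becomes T."""
        chars = list(self.sequence)
        cpg = set(self.cpg_offsets)
        for i, c in enumerate(chars):
            if c == "C" and i not in cpg:
                chars[i] = "T"
        return "".join(chars)

    @property
    def non_cpg_c_offsets(self) -> tuple[int, ...]:
        cpg = set(self.cpg_offsets)
        return tuple(
            i for i, c in enumerate(self.sequence) if c == "C" and i not in cpg
        )


@dataclass
class CloneAlignment:
    clone_id: str
    calls: np.ndarray  # per reference CpG: METHYLATED / UNMETHYLATED / MISSING
    conversion_rate: float
    identity: float

    @property
    def n_methylated(self) -> int:
        return int(np.sum(self.calls == METHYLATED))

    @property
    def n_called(self) -> int:
        return int(np.sum(self.calls != MISSING))


@dataclass
class BisulfiteSample:
    """All retained clone alignments of one biological sample."""

    sample_id: str
    group: str
    alignments: list[CloneAlignment] = field(default_factory=list)

    @property
    def call_matrix(self) -> np.ndarray:
        return np.array([a.calls for a in self.alignments])

    @property
    def per_cpg_fraction(self) -> np.ndarray:
        m = self.call_matrix
        meth = (m == METHYLATED).sum(axis=0)
        called = (m != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, meth / np.maximum(called, 1), np.nan)

    @property
    def percent_methylation(self) -> float:
        m = self.call_matrix
        called = int((m != MISSING).sum())
        if called == 0:
            raise ValueError(f"sample {self.sample_id!r} has no callable CpGs")
        return 100.0 * int((m == METHYLATED).sum()) / called


def _aligner() -> Align.PairwiseAligner:
    # asymmetric scoring: reference C aligned to clone T is the expected
    # bisulfite conversion and scores as a match; the reverse (ref T, clone C)
    # stays a mismatch
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = 1.0 if a == b else -1.0
    mat["C", "T"] = 1.0
    for x in "ACGTN":
        mat["N", x] = 0.0
        mat[x, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _aligner()


def align_clone(
    clone_seq: str,
    ref: BisulfiteReference,
    clone_id: str = "",
    identity_floor: float = 0.6,
) -> CloneAlignment:
    """Globally align one clone to the unconverted reference and call CpGs.

    Returns the per-CpG calls, the non-CpG conversion rate, and the alignment
    identity (fraction of reference bases whose aligned clone base matches,
    counting the expected C->T conversion as a match). Raises
    :class:`LowIdentityError` below ``identity_floor``.
    """
    clone_seq = clone_seq.upper()
    if not clone_seq:
        raise ValueError("empty clone sequence")
    aln = _ALIGNER.align(ref.sequence, clone_seq)[0]
    idx = aln.indices  # (2, columns); -1 marks a gap
    ref_to_query: dict[int, str] = {}
    for col in range(idx.shape[1]):
        r, q = int(idx[0, col]), int(idx[1, col])
        if r >= 0:
            ref_to_query[r] = clone_seq[q] if q >= 0 else "-"

    matches = 0
    for i, rbase in enumerate(ref.sequence):
        qbase = ref_to_query.get(i, "-")
        if qbase == rbase or (rbase == "C" and qbase == "T"):
            matches += 1
    identity = matches / len(ref.sequence)
    if identity < identity_floor:
        raise LowIdentityError(
            f"clone {clone_id!r} identity {identity:.2f} below floor {identity_floor}"
        )

    calls = np.full(len(ref.cpg_offsets), MISSING, dtype=int)
    for k, o in enumerate(ref.cpg_offsets):
        q = ref_to_query.get(o, "-")
        if q == "C":
            calls[k] = METHYLATED
        elif q == "T":
            calls[k] = UNMETHYLATED

    converted = retained = 0
    for o in ref.non_cpg_c_offsets:
        q = ref_to_query.get(o, "-")
        if q == "T":
            converted += 1
        elif q == "C":
            retained += 1
    denom = converted + retained
    conversion = converted / denom if denom else 1.0
    return CloneAlignment(
        clone_id=clone_id, calls=calls, conversion_rate=conversion, identity=identity
    )


def qc_filter(
    alignments: Sequence[CloneAlignment],
    min_conversion: float = 0.95,
    min_identity: float = 0.90,
) -> tuple[list[CloneAlignment], list[dict]]:
    """Drop clones failing conversion or identity thresholds.

    Returns the retained alignments (calls untouched) and a per-clone QC
    report. An empty retained list means the whole sample is invalid; the
    caller decides whether that is fatal.
    """
    retained: list[CloneAlignment] = []
    report: list[dict] = []
    for a in alignments:
        reasons = []
        if a.conversion_rate < min_conversion:
            reasons.append(f"conversion {a.conversion_rate:.3f} < {min_conversion}")
        if a.identity < min_identity:
            reasons.append(f"identity {a.identity:.3f} < {min_identity}")
        report.append(
            {
                "clone_id": a.clone_id,
                "conversion_rate": a.conversion_rate,
                "identity": a.identity,
                "retained": not reasons,
                "reasons": "; ".join(reasons),
            }
        )
        if not reasons:
            retained.append(a)
    if alignments and not retained:
        warnings.warn("all clones failed QC; sample is invalid")
    return retained, report


def sample_methylation(sample: BisulfiteSample) -> tuple[np.ndarray, float]:
    """Per-CpG methylation fractions and pooled overall percent."""
    if not sample.alignments:
        raise ValueError(f"sample {sample.sample_id!r} has no retained clones")
    return sample.per_cpg_fraction, sample.percent_methylation


def compare_groups(
    samples_a: Sequence[BisulfiteSample], samples_b: Sequence[BisulfiteSample]
) -> TestResult:
    """Mann-Whitney test on per-sample overall percent methylation."""
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 samples per group")
    return mann_whitney(
        [s.percent_methylation for s in samples_a],
        [s.percent_methylation for s in samples_b],
    )


def compare_paired(tumor: BisulfiteSample, normal: BisulfiteSample) -> TestResult:
    """Wilcoxon signed-rank test over the paired per-CpG fractions.

    Within one tumor/normal tissue pair the CpG sites are the replicated
    unit, so the test pairs the per-CpG methylation fractions of the two
    samples.
    """
    ft = tumor.per_cpg_fraction
    fn = normal.per_cpg_fraction
    if ft.shape != fn.shape:
        raise ValueError("samples were quantified on different CpG grids")
    ok = ~np.isnan(ft) & ~np.isnan(fn)
    return wilcoxon_paired(ft[ok] - fn[ok])


def correlate_expression(
    percents: Sequence[float], log2_expression: Sequence[float]
) -> TestResult:
    """Spearman correlation between methylation percent and log2 expression."""
    if len(percents) < 5:
        raise ValueError("need at least 5 paired observations")
    return spearman(percents, log2_expression)
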