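"""CpG-island detection and TSS-relative promoter region extraction.

Island detection follows the classic sliding-window criteria (Gardiner-Garden
& Frommer): a window passes if its GC fraction and its observed/expected CpG
ratio (Exp = countC * countG / window length) both exceed thresholds;
overlapping passing windows are merged and merged runs at least ``min_length``
long are reported with whole-island statistics.

TSS-relative coordinate convention (used everywhere in this package)
--------------------------------------------------------------------
Coordinates are integers with **0 = the TSS base itself**; negative values
are upstream, positive downstream. Regions are inclusive at both ends, so the
span ``start_rel..end_rel`` contains ``end_rel - start_rel + 1`` bases (e.g.
-290..+117 is 408 bases). On-disk interval formats (BED) are 0-based
half-open; conversion happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


__all__ = [
    "GenomicSequence",
    "CpGIsland",
    "RegionSpec",
    "find_cpg_islands",
    "extract_region",
    "annotate_candidates",
    "cpg_offsets_of",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA sequence with a declared TSS position.

    ``tss_offset`` is the 0-based index of the TSS base within ``residues``.
    """

    id: str
    residues: str
    tss_offset: int = 0

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        object.__setattr__(self, "residues", seq)
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in sequence {self.id!r}")
        if not 0 <= self.tss_offset < len(seq):
            raise ValueError(
                f"tss_offset {self.tss_offset} outside sequence of length {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CpGIsland:
    """A detected island in 0-based half-open sequence coordinates."""

    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionSpec:
    """A TSS-relative analysis region with its CpG cytosine offsets.

    ``cpg_offsets`` are 0-based positions *within the extracted region* of
    cytosines followed by G.
    """

    start_rel: int
    end_rel: int
    cpg_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        offs = tuple(self.cpg_offsets)
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("cpg_offsets must be strictly increasing")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)


def cpg_offsets_of(seq: str) -> tuple[int, ...]:
    """0-based positions of every CpG-dinucleotide cytosine in ``seq``."""
    s = seq.upper()
    return tuple(i for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G")


def _window_stats(seq: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    """(gc fraction, obs/exp CpG) for every window start, via cumulative sums."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(len(arr), dtype=np.int64)
    if len(arr) > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
    starts = np.arange(len(arr) - window + 1)
    n_c = cum_c[starts + window] - cum_c[starts]
    n_g = cum_g[starts + window] - cum_g[starts]
    # CpGs counted within the window only (a CpG straddling the right edge
    # belongs to the next window)
    n_cg = cum_cg[starts + window - 1] - cum_cg[starts]
    gc = (n_c + n_g) / window
    expected = n_c * n_g / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, n_cg / np.where(expected > 0, expected, 1), 0.0)
    return gc, oe


def find_cpg_islands(
    seq: GenomicSequence | str,
    min_length: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
    window: int = 200,
    step: int = 1,
) -> list[CpGIsland]:
    """Scan for CpG islands with sliding-window criteria and merge hits.

    Windows of ``window`` bases taken every ``step`` bases pass when
    GC >= ``gc_min`` and ObsCpG/ExpCpG >= ``oe_min``; the union of passing
    windows is merged into maximal runs, and runs >= ``min_length`` are
    returned with statistics recomputed over the whole merged interval.
    """
    residues = seq.residues if isinstance(seq, GenomicSequence) else seq.upper()
    if window > len(residues):
        raise ValueError(f"window {window} exceeds sequence length {len(residues)}")
    if step < 1:
        raise ValueError("step must be >= 1")
    gc, oe = _window_stats(residues, window)
    starts = np.arange(0, len(residues) - window + 1, step)
    passing = starts[(gc[starts] >= gc_min) & (oe[starts] >= oe_min)]
    islands: list[CpGIsland] = []
    for s0, e0 in _merge_intervals([(s, s + window) for s in passing]):
        if e0 - s0 < min_length:
            continue
        sub = residues[s0:e0]
        n_c = sub.count("C")
        n_g = sub.count("G")
        n_cg = sub.count("CG")
        expected = n_c * n_g / len(sub)
        islands.append(
            CpGIsland(
                start=int(s0),
                end=int(e0),
                gc_fraction=(n_c + n_g) / len(sub),
                obs_exp_cpg=(n_cg / expected) if expected > 0 else 0.0,
            )
        )
    return islands


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def rel_to_index(seq: GenomicSequence, rel: int) -> int:
    """Map a TSS-relative coordinate (0 = TSS base) to a sequence index."""
    return seq.tss_offset + rel


def extract_region(
    seq: GenomicSequence, start_rel: int, end_rel: int
) -> tuple[RegionSpec, str]:
    """Extract an inclusive TSS-relative region and enumerate its CpGs.

    Returns the :class:`RegionSpec` (with CpG cytosine offsets relative to
    the region start) and the extracted subsequence of length
    ``end_rel - start_rel + 1``.
    """
    if end_rel < start_rel:
        raise ValueError("end_rel must be >= start_rel")
    i0 = rel_to_index(seq, start_rel)
    i1 = rel_to_index(seq, end_rel) + 1
    if i0 < 0 or i1 > len(seq):
        raise ValueError(
            f"region {start_rel}..{end_rel} falls outside sequence {seq.id!r}"
        )
    sub = seq.residues[i0:i1]
    # a trailing C whose G lies just beyond the region still counts as a CpG
    lookahead = seq.residues[i0 : min(i1 + 1, len(seq))]
    offs = tuple(o for o in cpg_offsets_of(lookahead) if o < len(sub))
    return RegionSpec(start_rel=start_rel, end_rel=end_rel, cpg_offsets=offs), sub


def annotate_candidates(
    candidates: Sequence[str],
    promoters: Mapping[str, GenomicSequence],
    w_up: int = 1500,
    w_down: int = 500,
    **island_kwargs,
) -> dict[str, bool]:
    """Flag candidates whose promoter carries a CpG island near the TSS.

    A candidate is flagged when at least one detected island overlaps the
    window [TSS - w_up, TSS + w_down] (TSS-relative, inclusive). Raises if a
    candidate has no promoter sequence.
    """
    flags: dict[str, bool] = {}
    for gene in candidates:
        if gene not in promoters:
            raise KeyError(f"no promoter sequence provided for candidate {gene!r}")
        seq = promoters[gene]
        lo = max(0, seq.tss_offset - w_up)
        hi = min(len(seq), seq.tss_offset + w_down + 1)
        islands = find_cpg_islands(seq, **island_kwargs)
        flags[gene] = any(isl.start < hi and isl.end > lo for isl in islands)
    return flags
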