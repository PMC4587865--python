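"""Readers and writers for the formats shared across the pipeline.

Conventions: expression matrices are tab-delimited (probes in rows, a header
row of sample ids) with a sidecar CSV annotation; sequences travel as FASTA
(Biopython); cohort tables as CSV; islands as BED (0-based half-open);
methylation grids as a lollipop-style TSV. Every CLI run writes a JSON
manifest recording inputs, parameters, seed and outputs so it can be
reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .bisulfite import METHYLATED, MISSING, UNMETHYLATED, BisulfiteSample
from .cpgtools import CpGIsland, GenomicSequence
from .screen import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_fasta",
    "write_fasta",
    "read_cohort",
    "write_cohort",
    "write_bed",
    "write_methylation_grid",
    "write_manifest",
]


class FormatError(ValueError):
    """Raised when an input file fails to parse with an actionable message."""


def read_expression(matrix_path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited log2 matrix plus its CSV sample annotation."""
    matrix_path, annotation_path = Path(matrix_path), Path(annotation_path)
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message formatting
        raise FormatError(f"{matrix_path}: cannot parse matrix ({exc})") from exc
    if values.empty:
        raise FormatError(f"{matrix_path}: matrix has no data rows")
    try:
        annotation = pd.read_csv(annotation_path, index_col=0)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{annotation_path}: cannot parse annotation ({exc})") from exc
    for col in ("cell_line", "cls", "treatment"):
        if col not in annotation.columns:
            raise FormatError(
                f"{annotation_path}: missing required column {col!r} "
                f"(found {list(annotation.columns)})"
            )
    return ExpressionMatrix(values=values, annotation=annotation)


def write_expression(
    matrix: ExpressionMatrix, matrix_path: str | Path, annotation_path: str | Path
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t")
    matrix.annotation.to_csv(annotation_path)


def read_fasta(path: str | Path, tss_offset: int | None = None):
    """Read FASTA records; with ``tss_offset`` returns GenomicSequence objects."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if tss_offset is None:
        return {r.id: str(r.seq).upper() for r in records}
    return {
        r.id: GenomicSequence(id=r.id, residues=str(r.seq), tss_offset=tss_offset)
        for r in records
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


COHORT_REQUIRED = ("sample", "group")


def read_cohort(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{path}: cannot parse cohort CSV ({exc})") from exc
    missing = [c for c in COHORT_REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_bed(islands: Iterable[CpGIsland], name: str, path: str | Path) -> None:
    """Write islands as BED (0-based half-open, score = ObsCpG/ExpCpG x 100)."""
    with open(path, "w") as fh:
        for i, isl in enumerate(islands):
            score = min(1000, int(round(isl.obs_exp_cpg * 100)))
            fh.write(f"{name}\t{isl.start}\t{isl.end}\tCpG_island_{i + 1}\t{score}\t+\n")


_GLYPH = {METHYLATED: "●", UNMETHYLATED: "○", MISSING: "·"}


def write_methylation_grid(samples: Sequence[BisulfiteSample], path: str | Path) -> None:
    """Lollipop-style TSV grid: one row per clone, one column per CpG."""
    with open(path, "w") as fh:
        fh.write("sample\tgroup\tclone\tpattern\tpercent\n")
        for s in samples:
            for a in s.alignments:
                pattern = "".join(_GLYPH[int(c)] for c in a.calls)
                called = max(a.n_called, 1)
                fh.write(
                    f"{s.sample_id}\t{s.group}\t{a.clone_id}\t{pattern}\t"
                    f"{100.0 * a.n_methylated / called:.1f}\n"
                )
            fh.write(
                f"{s.sample_id}\t{s.group}\tALL\t\t{s.percent_methylation:.1f}\n"
            )


def write_manifest(
    path: str | Path,
    subcommand: str,
    inputs: Mapping[str, str],
    parameters: Mapping,
    outputs: Sequence[str],
    seed: int | None,
) -> None:
    manifest = {
        "tool": "methylmark",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": dict(inputs),
        "parameters": {k: v for k, v in parameters.items()},
        "seed": seed,
        "outputs": list(outputs),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
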