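"""Readers and writers for the pipeline's on-disk formats.

Everything downstream consumes the types defined here: gene-by-sample
expression tables (TSV, optionally GEO series-matrix style with ``!``
comment lines), transcript FASTA (normalized to the RNA alphabet), paired
FASTQ (plain or gzip), and YAML run configuration.
"""

from __future__ import annotations

import gzip
import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "ExpressionMatrix",
    "GeneRecord",
    "ReadPair",
    "ParseError",
    "ValidationError",
    "read_expression_table",
    "write_expression_table",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "load_run_config",
]

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """A file could not be parsed into the declared structure."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One transcript: identifier plus RNA sequence (T mapped to U)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"gene {self.gene_id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"gene {self.gene_id!r}: non-RNA characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    @classmethod
    def from_raw(cls, gene_id: str, raw_sequence: str) -> "GeneRecord":
        """Normalize an input sequence (any case, DNA or RNA) to RNA."""
        return cls(gene_id, raw_sequence.upper().replace("T", "U"))


@dataclass(frozen=True)
class ReadPair:
    """A mate pair from two synchronized FASTQ files (qualities ignored)."""

    read_id: str
    mate1: str
    mate2: str

    def __post_init__(self) -> None:
        for name, seq in (("mate1", self.mate1), ("mate2", self.mate2)):
            if not seq:
                raise ValidationError(f"read {self.read_id!r}: empty {name}")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"read {self.read_id!r}: invalid characters {sorted(bad)} in {name}"
                )


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric table with a platform tag.

    ``values`` is a dense non-negative float array of shape
    ``(len(gene_ids), len(sample_ids))``; for arrays the entries are
    fluorescence signals (RMA output upstream), for RNA-seq they are
    normalized read counts. ``log_transformed`` records whether a log2
    transform has already been applied.
    """

    platform: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.platform not in ("array", "rnaseq"):
            raise ValidationError(f"unknown platform {self.platform!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if not self.log_transformed and np.any(self.values < 0):
            raise ValidationError("negative values in a non-log matrix")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("non-finite values in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def mean_per_gene(self) -> pd.Series:
        """Arithmetic mean over samples, on the matrix's native scale."""
        return pd.Series(self.values.mean(axis=1), index=self.gene_ids)


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen:
            out.append(x)
        seen.add(x)
    return out


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(
    path: str | Path,
    platform: str,
    *,
    delimiter: str = "\t",
    log_transformed: bool = False,
    skip_bang_comments: bool = True,
) -> ExpressionMatrix:
    """Read a delimited gene-by-sample table.

    First column holds gene identifiers, the header row sample identifiers.
    GEO series-matrix style files are supported: lines starting with ``!``
    (and blank lines) are skipped when ``skip_bang_comments`` is true.
    """
    path = Path(path)
    with open(path, "rt") as fh:
        lines = [
            ln
            for ln in fh
            if ln.strip() and not (skip_bang_comments and ln.startswith("!"))
        ]
    if not lines:
        raise ParseError(f"{path}: no data lines")
    try:
        df = pd.read_csv(
            io.StringIO("".join(lines)),
            sep=delimiter,
            index_col=0,
            dtype={0: str},
        )
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    non_numeric = df.columns[df.dtypes == object]
    if len(non_numeric):
        raise ParseError(
            f"{path}: non-numeric entries in column(s) {list(non_numeric)[:3]}"
        )
    gene_ids = [str(g).strip().strip('"') for g in df.index]
    sample_ids = [str(s).strip().strip('"') for s in df.columns]
    return ExpressionMatrix(
        platform=platform,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=df.to_numpy(dtype=float),
        log_transformed=log_transformed,
    )


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, *, delimiter: str = "\t"
) -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GeneRecord]:
    """Read transcript FASTA; header token up to first whitespace is the id."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValidationError(f"{path}: empty sequence under header {rec.id!r}")
        records.append(GeneRecord.from_raw(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Sequence[GeneRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _strip_mate_suffix(read_id: str) -> str:
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized mate pairs from two FASTQ files (plain or gzip).

    Raises at the first desynchronized id or when one file ends early.
    """
    with _open_text(path1) as fh1, _open_text(path2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for n, (r1, r2) in enumerate(itertools.zip_longest(it1, it2), start=1):
            if r1 is None or r2 is None:
                raise ParseError(
                    f"unequal record counts: one mate file ended before record {n}"
                )
            id1, id2 = _strip_mate_suffix(r1.id), _strip_mate_suffix(r2.id)
            if id1 != id2:
                raise ParseError(
                    f"desynchronized mate ids at record {n}: {r1.id!r} vs {r2.id!r}"
                )
            yield ReadPair(id1, str(r1.seq).upper(), str(r2.seq).upper())


def write_fastq_pairs(
    pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "wt") as f1, open(path2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.mate1}\n+\n{'I' * len(p.mate1)}\n")
            f2.write(f"@{p.read_id}/2\n{p.mate2}\n+\n{'I' * len(p.mate2)}\n")


# ---------------------------------------------------------------------------
# run configuration


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path, "rt") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: top level of run config must be a mapping")
    return cfg
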