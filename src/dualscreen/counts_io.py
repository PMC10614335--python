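"""Count-table handling and exact-match guide counting.

Sample descriptors follow the grammar ``library.replicate.bin`` (for FACS
screens, e.g. ``NT.1.high``) or ``library.replicate.timepoint`` (growth
screens, e.g. ``anchor.2.day0``). Count tables are TSVs with an
``element_id`` column followed by one integer column per sample.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from dualscreen.library_design import DualLibrary, GuideRecord

__all__ = [
    "CountTable",
    "ReadLayout",
    "SampleKey",
    "count_guides",
    "read_count_table",
    "write_count_table",
    "merge_tables",
    "read_fastq",
]


@dataclass(frozen=True)
class SampleKey:
    """Parsed ``library.replicate.bin`` sample descriptor."""

    library: str
    replicate: str
    bin: str

    @classmethod
    def parse(cls, descriptor: str) -> "SampleKey":
        parts = descriptor.split(".")
        if len(parts) != 3:
            raise ValueError(
                f"sample descriptor {descriptor!r} is not of the form "
                "'library.replicate.bin'"
            )
        return cls(*parts)

    def __str__(self) -> str:
        return f"{self.library}.{self.replicate}.{self.bin}"


@dataclass
class CountTable:
    """Element x sample matrix of non-negative integer read counts."""

    elements: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not self.elements:
            raise ValueError("CountTable requires at least one element")
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("duplicate element_id in CountTable")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample descriptor in CountTable")
        if self.counts.shape != (len(self.elements), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.elements)} elements x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.isfinite(self.counts.astype(float)).all():
                raise ValueError("counts must be finite integers")
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column(self, sample: str) -> np.ndarray:
        try:
            j = self.samples.index(sample)
        except ValueError:
            raise KeyError(
                f"sample {sample!r} not in table (have {self.samples})"
            ) from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "element_id", self.elements)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        if "element_id" not in df.columns:
            raise ValueError("count table needs an 'element_id' column")
        samples = [c for c in df.columns if c != "element_id"]
        if not samples:
            raise ValueError("count table has no sample columns")
        counts = df[samples].to_numpy()
        if counts.dtype == object or not np.issubdtype(
            counts.dtype, np.number
        ):
            raise ValueError("non-numeric counts in table")
        return cls(
            elements=[str(e) for e in df["element_id"]],
            samples=[str(s) for s in samples],
            counts=counts,
        )


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table; rejects ragged or non-integer input."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed count table {path}: {exc}") from exc
    return CountTable.from_frame(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def merge_tables(tables: Sequence[CountTable]) -> CountTable:
    """Column-wise concatenation of tables over identical element lists."""
    if not tables:
        raise ValueError("no tables to merge")
    first = tables[0]
    for t in tables[1:]:
        if t.elements != first.elements:
            extra = set(t.elements) ^ set(first.elements)
            raise ValueError(
                "element lists differ between tables; symmetric difference "
                f"(up to 10 shown): {sorted(extra)[:10]}"
            )
    samples: list[str] = []
    for t in tables:
        samples.extend(t.samples)
    return CountTable(
        elements=list(first.elements),
        samples=samples,
        counts=np.hstack([t.counts for t in tables]),
    )


# ---------------------------------------------------------------------------
# Guide counting from reads


@dataclass
class ReadLayout:
    """Where the variable protospacer sits within a read.

    The protospacer is the segment immediately following the first
    occurrence of the 5' constant ``anchor``; candidate lengths are tried
    longest-first.
    """

    anchor: str
    protospacer_lengths: tuple[int, ...] = (20, 19)

    def __post_init__(self) -> None:
        self.anchor = self.anchor.upper()
        self.protospacer_lengths = tuple(
            sorted(set(self.protospacer_lengths), reverse=True)
        )


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercase strings) from FASTQ, plain or gzip."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield str(record.seq).upper()


def _as_sequences(reads: Iterable) -> Iterator[str]:
    for read in reads:
        if isinstance(read, str):
            yield read.upper()
        else:  # SeqRecord or Seq
            yield str(getattr(read, "seq", read)).upper()


def count_guides(
    reads: Iterable,
    library: DualLibrary | Sequence[GuideRecord],
    layout: ReadLayout,
    sample: str = "sample",
) -> tuple[CountTable, int]:
    """Count exact protospacer matches per library element.

    A read is counted for an element iff the segment immediately after the
    5' constant anchor exactly matches that element's protospacer. Reads
    with no anchor, or whose post-anchor segment matches no protospacer at
    any configured length, increment the unmatched tally. Matched +
    unmatched always equals the number of input reads.
    """
    elements = (
        library.elements if isinstance(library, DualLibrary) else list(library)
    )
    index: dict[str, str] = {}
    for rec in elements:
        if rec.protospacer in index:
            raise ValueError(
                f"duplicate protospacer {rec.protospacer!r} "
                f"({index[rec.protospacer]} vs {rec.element_id})"
            )
        index[rec.protospacer] = rec.element_id

    counts = {rec.element_id: 0 for rec in elements}
    unmatched = 0
    anchor = layout.anchor
    anchor_len = len(anchor)
    for seq in _as_sequences(reads):
        pos = seq.find(anchor)
        if pos == -1:
            unmatched += 1
            continue
        start = pos + anchor_len
        for length in layout.protospacer_lengths:
            candidate = seq[start : start + length]
            if len(candidate) == length and candidate in index:
                counts[index[candidate]] += 1
                break
        else:
            unmatched += 1

    table = CountTable(
        elements=[rec.element_id for rec in elements],
        samples=[sample],
        counts=np.array(
            [[counts[rec.element_id]] for rec in elements], dtype=np.int64
        ),
    )
    return table, unmatched
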