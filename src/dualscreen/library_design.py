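"""In-silico dual-guide library construction.

Covers the two cloning-facing computations of the dual-guide design:

* annealing-oligo generation for inserting a fixed guide into the anchor
  cassette (custom 5'/3' overhangs around the protospacer), and
* restriction-site attrition — variable-library elements whose protospacer
  (in its optional vector context) contains a BamHI or NotI site are lost
  when the library is digested for fixed-guide insertion.

Also provides TSV/FASTA I/O for guide libraries and the transformant
coverage arithmetic used when electroporating a library at scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GuideRecord",
    "OligoPair",
    "DualLibrary",
    "BuildReport",
    "InvalidSequenceError",
    "RESTRICTION_ENZYMES",
    "FORWARD_PREFIX",
    "FORWARD_SUFFIX",
    "REVERSE_PREFIX",
    "REVERSE_SUFFIX",
    "reverse_complement",
    "validate_protospacer",
    "make_annealing_oligos",
    "protospacer_from_oligos",
    "find_restriction_sites",
    "build_dual_library",
    "transformants_required",
    "read_library_tsv",
    "write_library_tsv",
    "write_library_fasta",
    "write_build_report",
]


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or characters outside ACGT."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Constant overhangs for annealing oligos around the fixed protospacer.
FORWARD_PREFIX = "ATG"
FORWARD_SUFFIX = "GTTTCAGAGC"
REVERSE_PREFIX = "TTAGCTCTGAAAC"
REVERSE_SUFFIX = "CATGTTT"

#: Recognition sequences of the enzymes used to open the variable library.
RESTRICTION_ENZYMES = {
    "BamHI": "GGATCC",
    "NotI": "GCGGCCGC",
}


def _clean_dna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it is non-empty plain ACGT."""
    if not isinstance(seq, str) or not seq:
        raise InvalidSequenceError(f"{what} must be a non-empty string")
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise InvalidSequenceError(
            f"{what} contains non-ACGT characters: {sorted(bad)}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain ACGT string."""
    return _clean_dna(seq)[::-1].translate(_COMPLEMENT)


def validate_protospacer(protospacer: str) -> str:
    """Return the uppercased protospacer, raising on invalid characters."""
    return _clean_dna(protospacer, what="protospacer")


@dataclass(frozen=True)
class GuideRecord:
    """One library element: a gene label and its targeting protospacer."""

    element_id: str
    gene: str
    protospacer: str
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "protospacer", validate_protospacer(self.protospacer)
        )


@dataclass(frozen=True)
class OligoPair:
    """Forward/reverse annealing oligos for one protospacer."""

    forward: str
    reverse: str


@dataclass
class DualLibrary:
    """A variable-guide library sharing one fixed anchor protospacer.

    ``context5``/``context3`` are the optional vector flanks each
    protospacer was embedded in during the restriction scan.
    """

    fixed_guide: str
    elements: list[GuideRecord]
    context5: str = ""
    context3: str = ""

    def __post_init__(self) -> None:
        self.fixed_guide = validate_protospacer(self.fixed_guide)
        ids = [e.element_id for e in self.elements]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate element_id values: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class BuildReport:
    """Attrition bookkeeping from :func:`build_dual_library`."""

    n_input: int
    lost_ids: list[str] = field(default_factory=list)

    @property
    def n_lost_restriction(self) -> int:
        return len(self.lost_ids)

    @property
    def fraction_lost(self) -> float:
        return self.n_lost_restriction / self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_lost_restriction": self.n_lost_restriction,
            "fraction_lost": self.fraction_lost,
            "lost_ids": list(self.lost_ids),
        }


def make_annealing_oligos(guide: GuideRecord | str) -> OligoPair:
    """Annealing oligos with cloning overhangs for a fixed-guide insert.

    forward = ``ATG`` + protospacer + ``GTTTCAGAGC``;
    reverse = ``TTAGCTCTGAAAC`` + revcomp(protospacer) + ``CATGTTT``.
    """
    protospacer = (
        guide.protospacer if isinstance(guide, GuideRecord) else guide
    )
    protospacer = validate_protospacer(protospacer)
    forward = FORWARD_PREFIX + protospacer + FORWARD_SUFFIX
    reverse = REVERSE_PREFIX + reverse_complement(protospacer) + REVERSE_SUFFIX
    return OligoPair(forward=forward, reverse=reverse)


def protospacer_from_oligos(pair: OligoPair) -> str:
    """Recover the protospacer from an oligo pair, checking consistency."""
    fwd, rev = pair.forward, pair.reverse
    if not (fwd.startswith(FORWARD_PREFIX) and fwd.endswith(FORWARD_SUFFIX)):
        raise InvalidSequenceError("forward oligo lacks expected overhangs")
    if not (rev.startswith(REVERSE_PREFIX) and rev.endswith(REVERSE_SUFFIX)):
        raise InvalidSequenceError("reverse oligo lacks expected overhangs")
    from_fwd = fwd[len(FORWARD_PREFIX) : len(fwd) - len(FORWARD_SUFFIX)]
    from_rev = rev[len(REVERSE_PREFIX) : len(rev) - len(REVERSE_SUFFIX)]
    if reverse_complement(from_rev) != from_fwd:
        raise InvalidSequenceError("oligo pair is internally inconsistent")
    return from_fwd


def _resolve_enzymes(
    enzymes: Iterable[str] | dict[str, str] | None,
) -> dict[str, str]:
    if enzymes is None:
        return dict(RESTRICTION_ENZYMES)
    if isinstance(enzymes, dict):
        out = {name: _clean_dna(site, what=f"site for {name}")
               for name, site in enzymes.items()}
        return out
    out = {}
    for name in enzymes:
        if name not in RESTRICTION_ENZYMES:
            raise KeyError(
                f"unknown enzyme {name!r}: supply its recognition sequence "
                "explicitly via a {name: site} mapping"
            )
        out[name] = RESTRICTION_ENZYMES[name]
    return out


def _is_palindromic(site: str) -> bool:
    return site == reverse_complement(site)


def find_restriction_sites(
    sequence: str,
    enzymes: Iterable[str] | dict[str, str] | None = None,
    *,
    both_strands: bool = True,
) -> list[tuple[str, int]]:
    """All exact (overlapping) enzyme-site occurrences in ``sequence``.

    Returns ``(enzyme_name, 0-based start)`` tuples in ascending position
    order (ties by enzyme name). Palindromic sites are scanned on one
    strand only; non-palindromic sites are additionally searched as their
    reverse complement when ``both_strands`` is set, reported at the
    top-strand coordinate of the match.
    """
    sequence = _clean_dna(sequence)
    table = _resolve_enzymes(enzymes)
    hits: list[tuple[str, int]] = []
    for name, site in table.items():
        patterns = {site}
        if both_strands and not _is_palindromic(site):
            patterns.add(reverse_complement(site))
        for pattern in patterns:
            start = sequence.find(pattern)
            while start != -1:
                hits.append((name, start))
                start = sequence.find(pattern, start + 1)
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def build_dual_library(
    parent: Sequence[GuideRecord],
    fixed_guide: str,
    context5: str = "",
    context3: str = "",
    enzymes: Iterable[str] | dict[str, str] | None = None,
) -> tuple[DualLibrary, BuildReport]:
    """Attach ``fixed_guide`` to every parent element that survives digestion.

    Each parent protospacer is embedded as ``context5 + protospacer +
    context3`` and scanned for restriction sites; elements with a hit are
    dropped and recorded in the :class:`BuildReport`. The fixed guide is
    scanned in the same context first and rejected outright if it carries a
    site (the anchor cassette would self-digest).
    """
    if not parent:
        raise ValueError("parent library is empty")
    fixed_guide = validate_protospacer(fixed_guide)
    context5 = _clean_dna(context5, what="context5") if context5 else ""
    context3 = _clean_dna(context3, what="context3") if context3 else ""

    def embedded(protospacer: str) -> str:
        return context5 + protospacer + context3

    if find_restriction_sites(embedded(fixed_guide), enzymes):
        raise ValueError(
            "fixed guide contains a restriction site in its cassette "
            "context and would self-digest"
        )

    kept: list[GuideRecord] = []
    lost: list[str] = []
    for rec in parent:
        if find_restriction_sites(embedded(rec.protospacer), enzymes):
            lost.append(rec.element_id)
        else:
            kept.append(rec)
    library = DualLibrary(
        fixed_guide=fixed_guide,
        elements=kept,
        context5=context5,
        context3=context3,
    )
    report = BuildReport(n_input=len(parent), lost_ids=lost)
    return library, report


def transformants_required(n_elements: int, coverage: int) -> int:
    """Transformant count needed to hold ``n_elements`` at ``coverage``-fold."""
    if int(n_elements) != n_elements or int(coverage) != coverage:
        raise ValueError("n_elements and coverage must be integers")
    n_elements, coverage = int(n_elements), int(coverage)
    if n_elements <= 0 or coverage <= 0:
        raise ValueError("n_elements and coverage must be positive")
    return n_elements * coverage


# ---------------------------------------------------------------------------
# I/O

LIBRARY_COLUMNS = ["element_id", "gene", "protospacer", "is_negative_control"]


def read_library_tsv(path: str | Path) -> list[GuideRecord]:
    """Load a guide library from TSV (columns: element_id, gene,
    protospacer, is_negative_control)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library TSV missing columns: {sorted(missing)}")
    truthy = {"1", "true", "yes"}
    records = [
        GuideRecord(
            element_id=row.element_id,
            gene=row.gene,
            protospacer=row.protospacer,
            is_negative_control=str(row.is_negative_control).strip().lower()
            in truthy,
        )
        for row in df.itertuples(index=False)
    ]
    ids = [r.element_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate element_id values in library TSV")
    return records


def write_library_tsv(
    records: Sequence[GuideRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "element_id": [r.element_id for r in records],
            "gene": [r.gene for r in records],
            "protospacer": [r.protospacer for r in records],
            "is_negative_control": [
                int(r.is_negative_control) for r in records
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_library_fasta(
    records: Sequence[GuideRecord], path: str | Path
) -> None:
    """Export protospacers as FASTA (id = element_id, description = gene)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqs = [
        SeqRecord(Seq(r.protospacer), id=r.element_id, description=r.gene)
        for r in records
    ]
    seqio_write(seqs, str(path), "fasta")


def write_build_report(
    report: BuildReport,
    parent: Sequence[GuideRecord],
    out_dir: str | Path,
) -> None:
    """Write ``build_report.json`` plus a TSV of lost elements."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "build_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    lost = set(report.lost_ids)
    write_library_tsv(
        [r for r in parent if r.element_id in lost],
        out_dir / "lost_elements.tsv",
    )
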