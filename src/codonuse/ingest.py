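"""Reading and quality-filtering of CDS FASTA files.

A usable coding sequence must be in frame (length a multiple of three),
start with ATG, end with a stop codon, contain no internal stop and no
ambiguous bases.  Sequences failing any rule are rejected under the
first failing reason, in a fixed precedence, so filter reports are
deterministic.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .genetic_code import STOP_CODONS

#: Rejection reasons in precedence order: a sequence failing several
#: rules is counted once, under the first one here that it fails.
REJECTION_REASONS: tuple[str, ...] = (
    "bad_length",
    "ambiguous_base",
    "no_start",
    "bad_stop",
    "internal_stop",
)

PASS = "pass"


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence: identifier, species tag and nucleotides."""

    id: str
    species: str
    seq: str


@dataclass
class CdsCollection:
    """An ordered, species-tagged set of coding sequences."""

    species: str
    records: list[CdsRecord] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass.

    ``rejections`` maps each reason to the ids rejected for it; every
    input sequence is either retained or counted under exactly one
    reason, so ``n_input == n_retained + sum of rejection counts``.
    """

    species: str
    n_input: int
    n_retained: int
    rejections: dict[str, list[str]] = field(default_factory=dict)

    @property
    def rejection_counts(self) -> dict[str, int]:
        return {r: len(ids) for r, ids in self.rejections.items()}


def _normalize(seq: str) -> str:
    # RNA-alphabet input is accepted; U is mapped to T.
    return seq.upper().replace("U", "T")


def read_cds_fasta(path: str | Path, species: str) -> list[CdsRecord]:
    """Read a (optionally gzipped) CDS FASTA verbatim, without filtering.

    Sequences are uppercased and U mapped to T; record order is file
    order.  Duplicate ids are disambiguated by appending ``.2``, ``.3``
    ... to later occurrences, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CDS FASTA not found: {path}")
    opener = gzip.open if _is_gzip(path) else open
    records: list[CdsRecord] = []
    seen: dict[str, int] = {}
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rid = rec.id
            if rid in seen:
                seen[rid] += 1
                new_id = f"{rid}.{seen[rid]}"
                warnings.warn(
                    f"duplicate FASTA id {rid!r} in {path.name}; "
                    f"renamed to {new_id!r}",
                    stacklevel=2,
                )
                rid = new_id
            else:
                seen[rid] = 1
            records.append(CdsRecord(rid, species, _normalize(str(rec.seq))))
    return records


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def validate_cds(seq: str, min_length: int = 0) -> str:
    """Return ``"pass"`` or the first-failing rejection reason.

    Precedence: bad_length, ambiguous_base, no_start, bad_stop,
    internal_stop.  ``min_length`` (nucleotides) is an optional extra
    length floor; sequences below it are rejected as bad_length.
    """
    s = _normalize(seq)
    if len(s) == 0 or len(s) % 3 != 0 or len(s) < min_length:
        return "bad_length"
    if any(b not in "ACGT" for b in s):
        return "ambiguous_base"
    if not s.startswith("ATG"):
        return "no_start"
    if s[-3:] not in STOP_CODONS:
        return "bad_stop"
    for i in range(0, len(s) - 3, 3):
        if s[i : i + 3] in STOP_CODONS:
            return "internal_stop"
    return PASS


def filter_collection(
    raw: list[CdsRecord],
    species: str | None = None,
    min_length: int = 0,
) -> tuple[CdsCollection, FilterReport]:
    """Split raw records into a validated collection and a report.

    Retained records keep their input order.  An all-rejected input
    yields an empty collection (with a warning), not an error.
    """
    if species is None:
        species = raw[0].species if raw else ""
    kept: list[CdsRecord] = []
    rejections: dict[str, list[str]] = {}
    for rec in raw:
        verdict = validate_cds(rec.seq, min_length=min_length)
        if verdict == PASS:
            kept.append(CdsRecord(rec.id, species, _normalize(rec.seq)))
        else:
            rejections.setdefault(verdict, []).append(rec.id)
    if raw and not kept:
        warnings.warn(
            f"all {len(raw)} sequences rejected for species {species!r}",
            stacklevel=2,
        )
    report = FilterReport(
        species=species,
        n_input=len(raw),
        n_retained=len(kept),
        rejections=rejections,
    )
    return CdsCollection(species, kept), report


def write_fasta(collection: CdsCollection, path: str | Path) -> None:
    """Write a collection back out as plain FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in collection:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


def filter_report_frame(reports: list[FilterReport]) -> pd.DataFrame:
    """Tabulate filter reports: one row per species, one column per reason."""
    rows = []
    for rep in reports:
        row: dict[str, object] = {
            "species": rep.species,
            "n_input": rep.n_input,
            "n_retained": rep.n_retained,
        }
        for reason in REJECTION_REASONS:
            row[reason] = len(rep.rejections.get(reason, []))
        rows.append(row)
    return pd.DataFrame(rows)
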