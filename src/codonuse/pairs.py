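"""Codon-pair usage: pair counts, RSCPU and high-frequency pairs.

Adjacent in-frame codon pairs (3,721 = 61 x 61 ordered types) are
tallied per gene with a step of one codon and no pairs across gene
boundaries.  Synonymous codon-pair families are the pairs encoding the
same ordered amino-acid pair, of size ``n_i = deg(a) * deg(b)``, and
RSCPU is the pair count divided by the family mean — the codon-pair
analogue of RSCU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import CODON_TO_AA, DEGENERACY, SENSE_CODON_PAIRS, STOP_CODONS
from .ingest import CdsCollection
from .metrics import _sense_codons_of


@dataclass
class PairCounts:
    """Tallies over all 3,721 ordered sense-codon pairs."""

    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {p: 0 for p in SENSE_CODON_PAIRS}
    )

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class RscpuEntry:
    """One codon pair: its dipeptide family, count, RSCPU and share."""

    pair: tuple[str, str]
    family: tuple[str, str]
    n_i: int
    x_i: int
    rscpu: float
    share: float


@dataclass
class RscpuTable:
    """RSCPU values grouped by ordered amino-acid-pair family.

    Within every observed family the RSCPU values sum to the family
    size ``n_i`` (mean 1).  Families never observed are listed in
    ``missing_families`` and have no entries.
    """

    entries: dict[tuple[str, str], RscpuEntry]
    missing_families: tuple[tuple[str, str], ...] = ()


def pair_family(pair: tuple[str, str]) -> tuple[str, str]:
    """The ordered amino-acid pair (dipeptide) a codon pair encodes."""
    return (CODON_TO_AA[pair[0]], CODON_TO_AA[pair[1]])


#: dipeptide family -> its synonymous codon pairs, in lexicographic order.
FAMILY_TO_PAIRS: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {}
for _pair in SENSE_CODON_PAIRS:
    FAMILY_TO_PAIRS.setdefault(pair_family(_pair), ())
FAMILY_TO_PAIRS = {
    fam: tuple(p for p in SENSE_CODON_PAIRS if pair_family(p) == fam)
    for fam in FAMILY_TO_PAIRS
}


def family_size(family: tuple[str, str]) -> int:
    """Number of synonymous codon pairs: deg(a) * deg(b)."""
    return DEGENERACY[family[0]] * DEGENERACY[family[1]]


def count_codon_pairs(collection: CdsCollection) -> PairCounts:
    """Tally adjacent ordered codon pairs within each gene.

    The terminal stop codon is dropped first, so no pair involves a
    stop; a gene with s sense codons contributes s - 1 pairs.
    """
    pc = PairCounts()
    for rec in collection:
        codons = _sense_codons_of(rec.seq)
        for a, b in zip(codons, codons[1:]):
            if a in STOP_CODONS or b in STOP_CODONS:
                continue  # defensive; validated input has no internal stops
            pc.counts[(a, b)] += 1
    return pc


def rscpu(pair_counts: PairCounts) -> RscpuTable:
    """Relative synonymous codon pair usage.

    For pair *i* in a dipeptide family of size ``n_i`` with count
    ``x_i``: ``RSCPU_i = x_i / (family_total / n_i)``.
    """
    family_totals: dict[tuple[str, str], int] = {}
    for pair, x in pair_counts.counts.items():
        fam = pair_family(pair)
        family_totals[fam] = family_totals.get(fam, 0) + x
    entries: dict[tuple[str, str], RscpuEntry] = {}
    missing: list[tuple[str, str]] = []
    for fam in sorted(family_totals):
        total = family_totals[fam]
        if total == 0:
            missing.append(fam)
            continue
        n_i = family_size(fam)
        for pair in FAMILY_TO_PAIRS[fam]:
            x = pair_counts.counts[pair]
            entries[pair] = RscpuEntry(
                pair=pair,
                family=fam,
                n_i=n_i,
                x_i=x,
                rscpu=n_i * x / total,
                share=x / total,
            )
    return RscpuTable(entries=entries, missing_families=tuple(missing))


def high_frequency_pairs(
    table: RscpuTable,
    rscpu_threshold: float = 1.5,
    share_threshold: float = 0.60,
) -> list[RscpuEntry]:
    """Flag pairs with RSCPU over 1.5 or family share over 60%.

    Both thresholds strict; output sorted by descending RSCPU, ties by
    lexicographic pair.
    """
    flagged = [
        e
        for e in table.entries.values()
        if e.rscpu > rscpu_threshold or e.share > share_threshold
    ]
    flagged.sort(key=lambda e: (-e.rscpu, e.pair))
    return flagged


def rscpu_frame(
    table: RscpuTable,
    rscpu_threshold: float = 1.5,
    share_threshold: float = 0.60,
) -> pd.DataFrame:
    """Tabulate a full RSCPU table with a flagged column."""
    rows = []
    for pair in SENSE_CODON_PAIRS:
        e = table.entries.get(pair)
        if e is None:
            continue
        rows.append(
            {
                "codon_pair": f"{pair[0]}-{pair[1]}",
                "aa_pair": f"{e.family[0]}{e.family[1]}",
                "x_i": e.x_i,
                "n_i": e.n_i,
                "rscpu": e.rscpu,
                "share": e.share,
                "flagged": e.rscpu > rscpu_threshold or e.share > share_threshold,
            }
        )
    return pd.DataFrame(rows)
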