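"""Codon-level indices: codon counts, GC content, GC3s, RSCU, ENc.

These are the per-gene and per-species quantities behind a classic
codon-usage study: positional GC content, relative synonymous codon
usage (RSCU, Sharp & Li), Wright's effective number of codons (ENc),
and the high-frequency codon rules (RSCU > 1.5 or family share > 60%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    ENC_CLASSES,
    SENSE_CODONS,
    STOP_CODONS,
)
from .ingest import CdsCollection, CdsRecord


@dataclass
class CodonCounts:
    """Integer tallies over the 61 sense codons.

    All 61 codons are always present as keys (zero allowed); stop
    codons never appear.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SENSE_CODONS}
    )

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = {c: self.counts[c] + other.counts[c] for c in SENSE_CODONS}
        return CodonCounts(merged)


@dataclass(frozen=True)
class GcProfile:
    """GC percentages: overall and at the three codon positions."""

    gc: float
    gc1: float
    gc2: float
    gc3: float


@dataclass
class RscuTable:
    """RSCU values and within-family shares for the 59 degenerate codons.

    Codons of families never observed are absent (reported in
    ``missing_families``), not zero: an RSCU of 0 means the family was
    used but never through that codon.
    """

    rscu: dict[str, float]
    share: dict[str, float]
    missing_families: tuple[str, ...] = ()


@dataclass(frozen=True)
class GeneMetrics:
    """Per-gene profile: GC by position, GC12, GC3s and ENc.

    ``gc3s`` and ``enc`` are ``None`` when undefined (no degenerate
    codons, or an ENc degeneracy class with no usable amino acid).
    """

    gene_id: str
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float | None
    enc: float | None


@dataclass(frozen=True)
class SpeciesSummary:
    """One species row of the per-species GC/ENc summary table."""

    species: str
    n_genes: int
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float | None
    enc_mean: float | None


@dataclass
class HighFreqCodonSet:
    """Codons flagged high-frequency, ordered by descending RSCU.

    Each entry is ``(codon, rscu, family_share)``; ``n`` is the set
    size.
    """

    entries: list[tuple[str, float, float]]

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    @property
    def n(self) -> int:
        return len(self.entries)


def _sense_codons_of(seq: str) -> list[str]:
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons.pop()
    return codons


def count_codons(item: CdsRecord | CdsCollection | str) -> CodonCounts:
    """Tally in-frame sense codons; the terminal stop codon is excluded.

    Accepts a single record, a raw sequence string, or a collection
    (summed over genes).
    """
    if isinstance(item, CdsCollection):
        total = CodonCounts()
        for rec in item:
            total = total + count_codons(rec)
        return total
    seq = item.seq if isinstance(item, CdsRecord) else item
    cc = CodonCounts()
    for codon in _sense_codons_of(seq):
        cc.counts[codon] += 1
    return cc


def gc_content(
    seqs: list[str] | list[CdsRecord] | CdsCollection | str,
    scope: str = "sense",
) -> GcProfile:
    """Overall and positional GC percentages over a set of sequences.

    ``scope="sense"`` drops each gene's terminal stop codon before
    counting (the default used everywhere downstream);
    ``scope="with-stop"`` keeps it.
    """
    if scope not in ("sense", "with-stop"):
        raise ValueError(f"unknown scope {scope!r}")
    if isinstance(seqs, (str, CdsRecord)):
        seqs = [seqs]
    pos_gc = [0, 0, 0]
    pos_n = [0, 0, 0]
    for item in seqs:
        seq = item.seq if isinstance(item, CdsRecord) else item
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if scope == "sense" and codons and codons[-1] in STOP_CODONS:
            codons.pop()
        for codon in codons:
            for k in range(3):
                pos_n[k] += 1
                if codon[k] in "GC":
                    pos_gc[k] += 1
    if sum(pos_n) == 0:
        raise ValueError("no codons in scope: GC content undefined")
    gcs = [100.0 * pos_gc[k] / pos_n[k] for k in range(3)]
    overall = 100.0 * sum(pos_gc) / sum(pos_n)
    return GcProfile(gc=overall, gc1=gcs[0], gc2=gcs[1], gc3=gcs[2])


def gc3s(counts: CodonCounts) -> float | None:
    """GC percentage at synonymous third positions.

    Restricted to codons of amino acids with two or more synonyms
    (Met and Trp excluded; stop codons are never counted).  Returns
    ``None`` when no degenerate codon was observed.
    """
    n_total = 0
    n_gc = 0
    for codon, x in counts.counts.items():
        if DEGENERACY[CODON_TO_AA[codon]] < 2:
            continue
        n_total += x
        if codon[2] in "GC":
            n_gc += x
    if n_total == 0:
        return None
    return 100.0 * n_gc / n_total


def rscu(counts: CodonCounts) -> RscuTable:
    """Relative synonymous codon usage per Sharp & Li.

    For codon *c* in a family of size *k*:
    ``RSCU(c) = k * count(c) / family_total``; the family share is
    ``count(c) / family_total``.  Six-fold families (Leu, Ser, Arg) are
    single families of size 6.
    """
    values: dict[str, float] = {}
    shares: dict[str, float] = {}
    missing: list[str] = []
    for aa, codons in AA_TO_CODONS.items():
        k = len(codons)
        if k < 2:
            continue
        total = sum(counts.counts[c] for c in codons)
        if total == 0:
            missing.append(aa)
            continue
        for c in codons:
            shares[c] = counts.counts[c] / total
            values[c] = k * counts.counts[c] / total
    return RscuTable(rscu=values, share=shares, missing_families=tuple(missing))


def enc(counts: CodonCounts) -> float | None:
    """Wright's effective number of codons (ENc), in [20, 61].

    Per amino acid with family size >= 2 and n >= 2 observations, the
    codon homozygosity is estimated as ``F = (n * sum(p^2) - 1) / (n - 1)``
    with p the within-family codon frequencies.  Class means are taken
    over the 2-, 3-, 4- and 6-fold degeneracy classes and combined as
    ``ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``, capped at 61.  Amino acids
    with n <= 1 or F <= 0 are dropped; a missing 3-fold mean (Ile
    unobserved) is replaced by ``(F2 + F4) / 2``; any other empty class
    renders ENc undefined (``None``).
    """
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for k, aas in ENC_CLASSES.items():
        for aa in aas:
            codons = AA_TO_CODONS[aa]
            n = sum(counts.counts[c] for c in codons)
            if n <= 1:
                continue
            sum_p2 = sum((counts.counts[c] / n) ** 2 for c in codons)
            f_hat = (n * sum_p2 - 1) / (n - 1)
            if f_hat <= 0:
                continue
            class_f[k].append(f_hat)
    means: dict[int, float | None] = {
        k: (sum(v) / len(v) if v else None) for k, v in class_f.items()
    }
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2
    if any(means[k] is None for k in (2, 3, 4, 6)):
        return None
    value = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(value, 61.0)


def gene_metrics(record: CdsRecord) -> GeneMetrics:
    """Combine the per-gene indices (sense-codon scope throughout)."""
    profile = gc_content(record, scope="sense")
    counts = count_codons(record)
    return GeneMetrics(
        gene_id=record.id,
        gc=profile.gc,
        gc1=profile.gc1,
        gc2=profile.gc2,
        gc3=profile.gc3,
        gc12=(profile.gc1 + profile.gc2) / 2,
        gc3s=gc3s(counts),
        enc=enc(counts),
    )


def species_summary(
    collection: CdsCollection, gc_aggregation: str = "pooled"
) -> SpeciesSummary:
    """Aggregate a collection into one species summary row.

    ``gc_aggregation="pooled"`` computes GC fields over the
    concatenated sense codons of all genes; ``"gene_mean"`` averages
    the per-gene values instead.  ENc is always the unweighted mean of
    defined per-gene values.
    """
    if collection.n_genes == 0:
        raise ValueError(f"empty collection for species {collection.species!r}")
    if gc_aggregation not in ("pooled", "gene_mean"):
        raise ValueError(f"unknown gc_aggregation {gc_aggregation!r}")
    per_gene = [gene_metrics(rec) for rec in collection]
    if gc_aggregation == "pooled":
        profile = gc_content(list(collection.records), scope="sense")
        pooled_gc3s = gc3s(count_codons(collection))
        gc_fields = (profile.gc, profile.gc1, profile.gc2, profile.gc3, pooled_gc3s)
    else:
        def _mean(vals):
            vals = [v for v in vals if v is not None]
            return sum(vals) / len(vals) if vals else None

        gc_fields = (
            _mean([m.gc for m in per_gene]),
            _mean([m.gc1 for m in per_gene]),
            _mean([m.gc2 for m in per_gene]),
            _mean([m.gc3 for m in per_gene]),
            _mean([m.gc3s for m in per_gene]),
        )
    enc_values = [m.enc for m in per_gene if m.enc is not None]
    return SpeciesSummary(
        species=collection.species,
        n_genes=collection.n_genes,
        gc=gc_fields[0],
        gc1=gc_fields[1],
        gc2=gc_fields[2],
        gc3=gc_fields[3],
        gc3s=gc_fields[4],
        enc_mean=sum(enc_values) / len(enc_values) if enc_values else None,
    )


def summary_frame(summaries: list[SpeciesSummary]) -> pd.DataFrame:
    """Species summaries as a table (the Genes/GC/.../ENC schema)."""
    return pd.DataFrame(
        [
            {
                "species": s.species,
                "n_genes": s.n_genes,
                "gc": s.gc,
                "gc1": s.gc1,
                "gc2": s.gc2,
                "gc3": s.gc3,
                "gc3s": s.gc3s,
                "enc_mean": s.enc_mean,
            }
            for s in summaries
        ]
    )


def high_frequency_codons(
    table: RscuTable,
    rscu_threshold: float = 1.5,
    share_threshold: float = 0.60,
) -> HighFreqCodonSet:
    """Flag codons with RSCU over 1.5 or family share over 60%.

    Both thresholds are strict inequalities.  The result is ordered by
    descending RSCU, ties broken by codon lexicographic order.
    """
    flagged = [
        (c, table.rscu[c], table.share[c])
        for c in table.rscu
        if table.rscu[c] > rscu_threshold or table.share[c] > share_threshold
    ]
    flagged.sort(key=lambda e: (-e[1], e[0]))
    return HighFreqCodonSet(flagged)


def codon_set_composition(codons) -> dict[str, float]:
    """First- and third-base A/T vs G/C percentages of a codon set."""
    codons = list(codons)
    if not codons:
        raise ValueError("empty codon set")
    n = len(codons)
    first_gc = sum(1 for c in codons if c[0] in "GC")
    third_gc = sum(1 for c in codons if c[2] in "GC")
    return {
        "first_at": 100.0 * (n - first_gc) / n,
        "first_gc": 100.0 * first_gc / n,
        "third_at": 100.0 * (n - third_gc) / n,
        "third_gc": 100.0 * third_gc / n,
    }
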