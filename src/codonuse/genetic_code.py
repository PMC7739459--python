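"""Standard genetic code tables used throughout the package.

Everything here is derived at import time from Biopython's standard
(NCBI table 1) codon table, so the 61 sense codons, the synonymous
families and the degeneracy classes are guaranteed consistent with the
canonical code rather than hand-typed.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES: str = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons: TAA, TAG, TGA.
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: codon -> one-letter amino acid, for the 61 sense codons.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: The 61 sense codons in lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: one-letter amino acid -> its synonymous codons (lexicographic).
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
AA_TO_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in sorted(AA_TO_CODONS)
}

#: one-letter amino acid -> family size (degeneracy), 1..6.
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: Amino acids encoded by a single codon (Met/ATG and Trp/TGG).
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, k in DEGENERACY.items() if k == 1
)

#: The 59 codons belonging to families of size >= 2 (61 minus ATG, TGG).
DEGENERATE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] > 1
)

#: Fixed column order for RSCU feature vectors: amino acids alphabetical
#: by one-letter code, codons alphabetical within each family.
RSCU_CODON_ORDER: tuple[str, ...] = tuple(
    c
    for aa in sorted(AA_TO_CODONS)
    if DEGENERACY[aa] > 1
    for c in AA_TO_CODONS[aa]
)

#: Amino acids per degeneracy class, as used by the effective-number-of-
#: codons estimator: 9 two-fold, 1 three-fold (Ile), 5 four-fold,
#: 3 six-fold (Leu, Ser, Arg).
ENC_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(aa for aa, d in DEGENERACY.items() if d == k) for k in (2, 3, 4, 6)
}

#: The 16 ordered dinucleotides, lexicographic (AA, AC, ..., TT).
DINUCLEOTIDES: tuple[str, ...] = tuple(x + y for x in BASES for y in BASES)

#: All 3,721 ordered sense-codon pairs.
SENSE_CODON_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in SENSE_CODONS for b in SENSE_CODONS
)

assert len(SENSE_CODONS) == 61
assert len(DEGENERATE_CODONS) == 59
assert len(SENSE_CODON_PAIRS) == 3721
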