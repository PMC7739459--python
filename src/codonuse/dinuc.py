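"""Dinucleotide frequency-profile signatures and Pearson distances.

Each species is summarised by 16 odds-ratio-style values
``p_xy = f_xy / (f_x * f_y)`` computed from a one-base sliding window
over its filtered coding sequences (windows never cross gene
boundaries).  The 16-dimensional profile is the species signature;
pairwise Pearson correlation over signatures quantifies how similar
two species' sequence composition is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import BASES, DINUCLEOTIDES
from .ingest import CdsCollection


@dataclass
class DinucProfile:
    """Per-species dinucleotide frequencies and frequency profile.

    ``f_xy`` are the 16 dinucleotide frequencies (windows / total
    windows), ``f_x`` the 4 base frequencies, ``p_xy`` the profile
    values ``f_xy / (f_x * f_y)`` in fixed lexicographic order
    (AA, AC, ..., TT).  A pair whose base frequency is zero gets
    ``p_xy = 0`` and is listed in ``zero_flagged``.
    """

    species: str
    f_xy: dict[str, float]
    f_x: dict[str, float]
    p_xy: dict[str, float]
    n_windows: int
    l_total: int
    zero_flagged: tuple[str, ...] = ()

    @property
    def vector(self) -> np.ndarray:
        """The 16-component signature in fixed order."""
        return np.array([self.p_xy[d] for d in DINUCLEOTIDES])


def dinucleotide_freqs(
    collection: CdsCollection,
) -> tuple[dict[str, float], dict[str, float]]:
    """Dinucleotide and base frequencies over a collection.

    Windows slide by one base within each sequence; a gene of length L
    contributes L - 1 windows, so ``f_xy = count(xy) / sum(L_i - 1)``
    and ``f_x = count(x) / sum(L_i)``.
    """
    if len(collection) == 0:
        raise ValueError(
            f"empty collection for species {collection.species!r}"
        )
    di_counts = {d: 0 for d in DINUCLEOTIDES}
    base_counts = {b: 0 for b in BASES}
    n_windows = 0
    l_total = 0
    for rec in collection:
        seq = rec.seq
        l_total += len(seq)
        n_windows += max(len(seq) - 1, 0)
        for b in seq:
            base_counts[b] += 1
        for i in range(len(seq) - 1):
            di_counts[seq[i : i + 2]] += 1
    if n_windows == 0:
        raise ValueError("no dinucleotide windows (all sequences length < 2)")
    f_xy = {d: c / n_windows for d, c in di_counts.items()}
    f_x = {b: c / l_total for b, c in base_counts.items()}
    return f_xy, f_x


def dinuc_profile(
    f_xy: dict[str, float],
    f_x: dict[str, float],
    species: str = "",
    n_windows: int = 0,
    l_total: int = 0,
) -> DinucProfile:
    """Form the 16-component frequency profile ``p_xy = f_xy/(f_x f_y)``."""
    p_xy: dict[str, float] = {}
    flagged: list[str] = []
    for d in DINUCLEOTIDES:
        denom = f_x[d[0]] * f_x[d[1]]
        if denom == 0:
            p_xy[d] = 0.0
            flagged.append(d)
        else:
            p_xy[d] = f_xy[d] / denom
    return DinucProfile(
        species=species,
        f_xy=dict(f_xy),
        f_x=dict(f_x),
        p_xy=p_xy,
        n_windows=n_windows,
        l_total=l_total,
        zero_flagged=tuple(flagged),
    )


def species_profile(collection: CdsCollection) -> DinucProfile:
    """Convenience: frequencies plus profile for one collection."""
    f_xy, f_x = dinucleotide_freqs(collection)
    n_windows = sum(max(len(r.seq) - 1, 0) for r in collection)
    l_total = sum(len(r.seq) for r in collection)
    return dinuc_profile(
        f_xy, f_x, species=collection.species,
        n_windows=n_windows, l_total=l_total,
    )


def pearson_r(x, y) -> float:
    """Pearson correlation in raw-moment form.

    ``r = (Sxy - Sx*Sy/N) / sqrt((Sxx - Sx^2/N)(Syy - Sy^2/N))`` —
    numerically equal to the usual covariance form.  Zero variance in
    either vector is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r needs two equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("pearson_r needs at least 2 points")
    sxx = np.sum(x * x) - np.sum(x) ** 2 / n
    syy = np.sum(y * y) - np.sum(y) ** 2 / n
    if sxx <= 0 or syy <= 0:
        raise ValueError("pearson_r undefined: zero variance")
    sxy = np.sum(x * y) - np.sum(x) * np.sum(y) / n
    return float(sxy / np.sqrt(sxx * syy))


def correlation_matrix(profiles: list[DinucProfile]) -> pd.DataFrame:
    """Pairwise Pearson r over species signatures.

    Symmetric with unit diagonal; species order follows the input.
    """
    if len(profiles) < 2:
        raise ValueError("correlation matrix needs at least 2 species")
    labels = [p.species for p in profiles]
    vectors = [p.vector for p in profiles]
    n = len(labels)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_r(vectors[i], vectors[j])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=labels, columns=labels)


def signature_frame(profiles: list[DinucProfile]) -> pd.DataFrame:
    """Signatures as a table: one species row, 16 fixed-order columns."""
    return pd.DataFrame(
        [[p.p_xy[d] for d in DINUCLEOTIDES] for p in profiles],
        index=[p.species for p in profiles],
        columns=list(DINUCLEOTIDES),
    )
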