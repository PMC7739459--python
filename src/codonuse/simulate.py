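"""Seeded synthetic CDS collections with controllable codon usage.

The generator emulates the input the analysis expects — multi-gene CDS
sets with tunable synonymous-codon preferences, GC3 composition, gene
number and length, and deliberate quality defects — so every pipeline
stage is testable without real genome downloads.  Each gene draws from
its own random stream derived from the master seed, so adding or
removing one gene does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import AA_TO_CODONS, SINGLE_CODON_AAS, STOP_CODONS
from .ingest import CdsCollection, CdsRecord

#: Defect kinds the generator can inject, in draw order.
DEFECT_KINDS: tuple[str, ...] = (
    "no_start",
    "bad_stop",
    "internal_stop",
    "ambiguous_base",
    "bad_length",
)

_AAS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))
_STOPS: tuple[str, ...] = tuple(sorted(STOP_CODONS))


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic species.

    ``length_range`` is the body length in codons (between the ATG
    start and the stop), inclusive.  ``family_weights`` maps each amino
    acid to per-codon sampling weights; if omitted and ``concentration``
    is set, weights are drawn once per family from a symmetric
    Dirichlet (small concentration = strong bias); otherwise usage is
    uniform within families.  ``target_gc3`` overrides the weights at
    third positions, steering realized GC3 toward the target.
    ``defect_rates`` inject quality defects per gene (mutually
    exclusive; rates must sum to at most 1).
    """

    species: str = "synthetic"
    n_genes: int = 100
    length_range: tuple[int, int] = (100, 400)
    family_weights: dict[str, dict[str, float]] | None = None
    concentration: float | None = None
    target_gc3: float | None = None
    aa_mode: str = "uniform"  # "uniform" or "cycle" (all 20 in rotation)
    defect_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length_range")
        if self.target_gc3 is not None and not 0 <= self.target_gc3 <= 1:
            raise ValueError("target_gc3 must lie in [0, 1]")
        if self.aa_mode not in ("uniform", "cycle"):
            raise ValueError(f"unknown aa_mode {self.aa_mode!r}")
        bad = set(self.defect_rates) - set(DEFECT_KINDS)
        if bad:
            raise ValueError(f"unknown defect kinds: {sorted(bad)}")
        if any(r < 0 or r > 1 for r in self.defect_rates.values()):
            raise ValueError("defect rates must lie in [0, 1]")
        if sum(self.defect_rates.values()) > 1 + 1e-12:
            raise ValueError("defect rates must sum to at most 1")


def single_codon_weights(choice: str = "first") -> dict[str, dict[str, float]]:
    """Weights putting all mass on one codon per family.

    With ``choice="first"`` the lexicographically first codon of each
    family is used.  A collection generated this way has minimal codon
    diversity: exactly one codon per amino acid, hence ENc = 20.
    """
    if choice != "first":
        raise ValueError(f"unknown choice {choice!r}")
    return {aa: {codons[0]: 1.0} for aa, codons in AA_TO_CODONS.items()}


def resolve_weights(spec: GeneratorSpec) -> dict[str, dict[str, float]]:
    """The normalized per-family codon weights a spec implies."""
    if spec.family_weights is not None:
        out: dict[str, dict[str, float]] = {}
        for aa, codons in AA_TO_CODONS.items():
            given = spec.family_weights.get(aa, {})
            unknown = set(given) - set(codons)
            if unknown:
                raise ValueError(f"codons {sorted(unknown)} not in family {aa}")
            w = np.array([given.get(c, 0.0) for c in codons], dtype=float)
            if np.any(w < 0):
                raise ValueError(f"negative weight in family {aa}")
            if w.sum() == 0:
                w = np.ones(len(codons))
            out[aa] = dict(zip(codons, w / w.sum()))
        return out
    if spec.concentration is not None:
        rng = np.random.default_rng([spec.seed, 104729])
        out = {}
        for aa in _AAS:
            codons = AA_TO_CODONS[aa]
            w = rng.dirichlet(np.full(len(codons), spec.concentration))
            out[aa] = dict(zip(codons, w))
        return out
    return {
        aa: {c: 1.0 / len(codons) for c in codons}
        for aa, codons in AA_TO_CODONS.items()
    }


def weights_hash(weights: dict[str, dict[str, float]]) -> str:
    """Short deterministic digest of a weight model."""
    payload = json.dumps(
        {aa: {c: round(v, 12) for c, v in sorted(w.items())}
         for aa, w in sorted(weights.items())},
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _gc3_adjusted_prob(spec: GeneratorSpec) -> float | None:
    """Per-position probability of a GC-ending codon hitting target GC3.

    Met and Trp force a G third base; the remaining families all offer
    both a GC- and an AT-ending option, so the controllable positions
    compensate for the forced ones.
    """
    if spec.target_gc3 is None:
        return None
    p_forced = len(SINGLE_CODON_AAS) / len(_AAS)  # uniform/cycle aa draw
    q = (spec.target_gc3 - p_forced) / (1.0 - p_forced)
    return float(np.clip(q, 0.0, 1.0))


def _sample_codon(
    aa: str,
    weights: dict[str, dict[str, float]],
    gc3_prob: float | None,
    rng: np.random.Generator,
) -> str:
    codons = AA_TO_CODONS[aa]
    if gc3_prob is not None and len(codons) > 1:
        gc_end = [c for c in codons if c[2] in "GC"]
        at_end = [c for c in codons if c[2] in "AT"]
        subset = gc_end if rng.random() < gc3_prob else at_end
        if not subset:
            subset = codons
        return subset[rng.integers(len(subset))]
    w = np.array([weights[aa][c] for c in codons])
    return codons[rng.choice(len(codons), p=w)]


def _inject_defect(
    codons: list[str], defect: str, rng: np.random.Generator
) -> str:
    """Apply one defect to an assembled [ATG, body..., stop] codon list."""
    seq = "".join(codons)
    if defect == "no_start":
        return "TTG" + seq[3:]
    if defect == "bad_stop":
        return seq[:-3] + "AAA"
    if defect == "internal_stop":
        body_slots = len(codons) - 2  # positions between start and stop
        k = 1 + int(rng.integers(body_slots)) if body_slots > 0 else 0
        return seq[: 3 * k] + _STOPS[rng.integers(3)] + seq[3 * (k + 1) :]
    if defect == "ambiguous_base":
        pos = int(rng.integers(3, len(seq) - 3)) if len(seq) > 6 else 0
        return seq[:pos] + "N" + seq[pos + 1 :]
    if defect == "bad_length":
        return seq[:-1]
    raise ValueError(f"unknown defect {defect!r}")


def generate_collection(
    spec: GeneratorSpec,
) -> tuple[CdsCollection, dict[str, str]]:
    """Generate a raw (pre-filter, possibly defective) collection.

    Returns the collection and a truth table mapping every gene id to
    its injected defect kind (``"pass"`` for clean genes) — an exact
    oracle for the downstream filter report.
    """
    weights = resolve_weights(spec)
    gc3_prob = _gc3_adjusted_prob(spec)
    rates = [spec.defect_rates.get(k, 0.0) for k in DEFECT_KINDS]
    cum = np.cumsum(rates)
    records: list[CdsRecord] = []
    truth: dict[str, str] = {}
    lo, hi = spec.length_range
    for g in range(spec.n_genes):
        rng = np.random.default_rng([spec.seed, g])
        body_len = int(rng.integers(lo, hi + 1))
        if spec.aa_mode == "cycle":
            aas = [_AAS[(g + i) % len(_AAS)] for i in range(body_len)]
        else:
            aas = [_AAS[i] for i in rng.integers(len(_AAS), size=body_len)]
        codons = ["ATG"]
        codons += [_sample_codon(aa, weights, gc3_prob, rng) for aa in aas]
        codons.append(_STOPS[rng.integers(3)])
        u = rng.random()
        defect = "pass"
        for k, kind in enumerate(DEFECT_KINDS):
            if u < cum[k] and rates[k] > 0:
                defect = kind
                break
        seq = _inject_defect(codons, defect, rng) if defect != "pass" else (
            "".join(codons)
        )
        gene_id = f"{spec.species}_g{g:05d}"
        records.append(CdsRecord(gene_id, spec.species, seq))
        truth[gene_id] = defect
    return CdsCollection(spec.species, records), truth


def generate_biased_pair(
    spec_a: GeneratorSpec,
    spec_b: GeneratorSpec,
    divergence: float,
) -> tuple[CdsCollection, CdsCollection]:
    """Two collections whose usage models differ by a controlled amount.

    Species A uses spec_a's weight model.  Species B uses a geometric
    interpolation between spec_a's and spec_b's models:
    divergence 0 gives identical models, 1 gives spec_b's model, and
    larger values extrapolate — expected signature correlation and
    RSCU similarity fall monotonically as divergence grows.
    """
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    w_a = resolve_weights(spec_a)
    w_b = resolve_weights(spec_b)
    eps = 1e-9
    w_b_eff: dict[str, dict[str, float]] = {}
    for aa, codons in AA_TO_CODONS.items():
        la = np.log(np.array([w_a[aa][c] for c in codons]) + eps)
        lb = np.log(np.array([w_b[aa][c] for c in codons]) + eps)
        w = np.exp(la + divergence * (lb - la))
        w /= w.sum()
        w_b_eff[aa] = dict(zip(codons, w))
    spec_b_eff = GeneratorSpec(
        species=spec_b.species,
        n_genes=spec_b.n_genes,
        length_range=spec_b.length_range,
        family_weights=w_b_eff,
        target_gc3=spec_b.target_gc3,
        aa_mode=spec_b.aa_mode,
        defect_rates=spec_b.defect_rates,
        seed=spec_b.seed,
    )
    spec_a_eff = GeneratorSpec(
        species=spec_a.species,
        n_genes=spec_a.n_genes,
        length_range=spec_a.length_range,
        family_weights=w_a,
        target_gc3=spec_a.target_gc3,
        aa_mode=spec_a.aa_mode,
        defect_rates=spec_a.defect_rates,
        seed=spec_a.seed,
    )
    coll_a, _ = generate_collection(spec_a_eff)
    coll_b, _ = generate_collection(spec_b_eff)
    return coll_a, coll_b
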