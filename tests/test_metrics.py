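"""Codon counts, GC content, RSCU, ENc and high-frequency codon rules."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from codonuse import (
    CdsRecord,
    codon_set_composition,
    count_codons,
    enc,
    gc3s,
    gc_content,
    gene_metrics,
    high_frequency_codons,
    rscu,
    species_summary,
)
from codonuse.genetic_code import (
    AA_TO_CODONS,
    DEGENERACY,
    ENC_CLASSES,
    SENSE_CODONS,
)
from codonuse.metrics import CodonCounts
from conftest import make_collection


def counts_of(**kw) -> CodonCounts:
    cc = CodonCounts()
    cc.counts.update(kw)
    return cc


# Random codon-count tables over all 61 codons.
count_tables = st.fixed_dictionaries(
    {}, optional={c: st.integers(0, 50) for c in SENSE_CODONS}
)


class TestCountCodons:
    def test_hand_scan_excludes_terminal_stop(self):
        cc = count_codons("ATGGATTAA")
        assert cc.counts["ATG"] == 1 and cc.counts["GAT"] == 1
        assert cc.n_codons == 2

    def test_empty_collection_all_zero(self):
        cc = count_codons(make_collection({}))
        assert cc.n_codons == 0
        assert set(cc.counts) == set(SENSE_CODONS)

    def test_additivity_over_collections(self, tiny_collection):
        a = make_collection({"g1": tiny_collection.records[0].seq})
        b = make_collection(
            {r.id: r.seq for r in tiny_collection.records[1:]}
        )
        merged = count_codons(a) + count_codons(b)
        assert merged.counts == count_codons(tiny_collection).counts


class TestGcContent:
    def test_hand_count_with_stop_scope(self):
        p = gc_content("ATGGATTAA", scope="with-stop")
        assert p.gc == pytest.approx(100 * 2 / 9)
        assert p.gc1 == pytest.approx(100 / 3)
        assert p.gc2 == 0.0
        assert p.gc3 == pytest.approx(100 / 3)

    def test_saturation(self):
        p = gc_content("GCGGCCGGC", scope="with-stop")
        assert (p.gc, p.gc1, p.gc2, p.gc3) == (100.0, 100.0, 100.0, 100.0)

    def test_positional_partition(self, tiny_collection):
        p = gc_content(list(tiny_collection.records), scope="sense")
        assert p.gc == pytest.approx((p.gc1 + p.gc2 + p.gc3) / 3)

    def test_zero_length_scope_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            gc_content("TAA", scope="sense")  # lone stop codon


class TestGc3s:
    def test_met_excluded_from_synonymous_positions(self):
        assert gc3s(counts_of(ATG=5, TTT=1, TTC=1)) == pytest.approx(50.0)

    def test_only_singleton_families_is_undefined(self):
        assert gc3s(counts_of(ATG=3, TGG=2)) is None

    def test_single_gc_ending_codon(self):
        assert gc3s(counts_of(GCG=4)) == pytest.approx(100.0)


class TestRscu:
    def test_phe_family_hand_values(self):
        t = rscu(counts_of(TTT=3, TTC=1))
        assert t.rscu["TTT"] == pytest.approx(1.5)
        assert t.rscu["TTC"] == pytest.approx(0.5)
        assert t.share["TTT"] == pytest.approx(0.75)

    def test_even_usage_gives_unit_rscu(self):
        t = rscu(counts_of(GGT=2, GGC=2, GGA=2, GGG=2))
        assert all(t.rscu[c] == pytest.approx(1.0) for c in AA_TO_CODONS["G"])

    def test_complete_bias_attains_family_size(self):
        t = rscu(counts_of(TTT=4))
        assert t.rscu["TTT"] == pytest.approx(2.0)
        assert t.rscu["TTC"] == 0.0

    def test_unobserved_families_missing_not_zero(self):
        t = rscu(counts_of(TTT=1, TTC=1))
        assert "GGT" not in t.rscu
        assert "G" in t.missing_families

    @given(count_tables)
    def test_family_sums_and_scale_invariance(self, table):
        """Observed family RSCU sums equal the family size; shares sum
        to 1; tripling all counts changes nothing."""
        cc = counts_of(**table)
        t = rscu(cc)
        for aa, codons in AA_TO_CODONS.items():
            if len(codons) < 2 or aa in t.missing_families:
                continue
            assert sum(t.rscu[c] for c in codons) == pytest.approx(
                len(codons), abs=1e-9
            )
            assert sum(t.share[c] for c in codons) == pytest.approx(
                1.0, abs=1e-9
            )
        scaled = rscu(counts_of(**{c: 3 * x for c, x in table.items()}))
        assert scaled.rscu == pytest.approx(t.rscu)


def brute_force_enc(counts: CodonCounts) -> float | None:
    """Literal re-evaluation of the homozygosity estimator, kept
    independent of the implementation."""
    means = {}
    for k, aas in ENC_CLASSES.items():
        fs = []
        for aa in aas:
            ns = [counts.counts[c] for c in AA_TO_CODONS[aa]]
            n = sum(ns)
            if n < 2:
                continue
            f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
            if f > 0:
                fs.append(f)
        means[k] = sum(fs) / len(fs) if fs else None
    if means[3] is None and None not in (means[2], means[4]):
        means[3] = (means[2] + means[4]) / 2
    if None in means.values():
        return None
    return min(61.0, 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6])


class TestEnc:
    def test_one_codon_per_amino_acid_gives_20(self):
        table = {codons[0]: 3 for codons in AA_TO_CODONS.values()}
        assert enc(counts_of(**table)) == pytest.approx(20.0, abs=1e-12)

    def test_near_uniform_usage_approaches_61(self):
        table = {c: 1000 for c in SENSE_CODONS}
        value = enc(counts_of(**table))
        assert value == pytest.approx(61.0, abs=0.5)

    def test_insufficient_families_undefined(self):
        assert enc(counts_of(TTT=5, TTC=5)) is None  # no 4-/6-fold usage

    def test_missing_isoleucine_falls_back_to_class_average(self):
        table = {codons[0]: 4 for aa, codons in AA_TO_CODONS.items() if aa != "I"}
        assert enc(counts_of(**table)) is not None

    @given(count_tables)
    def test_matches_brute_force_and_bounds(self, table):
        cc = counts_of(**table)
        value = enc(cc)
        expected = brute_force_enc(cc)
        if expected is None:
            assert value is None
        else:
            assert value == pytest.approx(expected, abs=1e-12)
            assert 20.0 - 1e-9 <= value <= 61.0

    def test_enc_strictly_decreases_with_family_skew(self):
        """Skewing one family's usage, all else fixed, lowers ENc."""
        base = {codons[0]: 6 for codons in AA_TO_CODONS.values()}
        base.update({c: 6 for c in AA_TO_CODONS["G"]})  # Gly even
        even = enc(counts_of(**base))
        skews = [(9, 5, 5, 5), (12, 4, 4, 4), (18, 2, 2, 2), (24, 0, 0, 0)]
        values = []
        for skew in skews:
            table = dict(base)
            table.update(dict(zip(AA_TO_CODONS["G"], skew)))
            values.append(enc(counts_of(**table)))
        assert all(v is not None for v in values)
        assert all(a > b for a, b in zip([even] + values, values))


class TestGeneMetrics:
    def test_hand_counted_sense_scope(self):
        m = gene_metrics(CdsRecord("g", "sp", "ATGGATTAA"))
        # sense codons ATG, GAT: position bases (A,G), (T,A), (G,T)
        assert m.gc1 == pytest.approx(50.0)
        assert m.gc2 == pytest.approx(0.0)
        assert m.gc12 == pytest.approx(25.0)

    def test_independent_of_collection_position(self, tiny_collection):
        recs = tiny_collection.records
        assert gene_metrics(recs[0]) == gene_metrics(recs[0])


class TestSpeciesSummary:
    def test_singleton_equals_gene_fields(self):
        coll = make_collection({"g": "ATGGATGCTTTTTAA"})
        s = species_summary(coll)
        m = gene_metrics(coll.records[0])
        assert s.gc == pytest.approx(m.gc)
        assert s.gc3s == pytest.approx(m.gc3s)
        assert s.n_genes == 1

    def test_pooled_gc_of_equal_length_genes_averages(self):
        # two equal-length genes, one 40% GC body, one 60%
        a = "ATG" + "GATAAA" * 5 + "TAA"
        b = "ATG" + "GGTCAT" * 5 + "TAA"
        coll = make_collection({"a": a, "b": b})
        s = species_summary(coll)
        ga = gc_content(a, scope="sense").gc
        gb = gc_content(b, scope="sense").gc
        assert s.gc == pytest.approx((ga + gb) / 2)

    def test_schema_columns(self, tiny_collection):
        from codonuse.metrics import summary_frame

        frame = summary_frame([species_summary(tiny_collection)])
        assert list(frame.columns) == [
            "species", "n_genes", "gc", "gc1", "gc2", "gc3", "gc3s", "enc_mean",
        ]

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            species_summary(make_collection({}))


class TestHighFrequencyCodons:
    def test_rscu_rule_flags(self):
        t = rscu(counts_of(CGT=1, CGC=1, CGA=1, CGG=1, AGA=8, AGG=1))
        hf = high_frequency_codons(t)
        # AGA: RSCU = 6*8/13 = 3.69 -> flagged
        assert "AGA" in hf.codons

    def test_share_rule_flags_without_rscu_rule(self):
        # 2-fold family split 61/39: RSCU 1.22 <= 1.5 but share > 0.60
        t = rscu(counts_of(TTT=61, TTC=39))
        hf = high_frequency_codons(t)
        assert hf.codons == ("TTT",)
        assert t.rscu["TTT"] == pytest.approx(1.22)

    def test_thresholds_are_strict(self):
        # RSCU exactly 1.5 and share exactly 0.60 must NOT flag
        t = rscu(counts_of(GGT=3, GGC=3, GGA=1, GGG=1))
        assert t.rscu["GGT"] == pytest.approx(1.5)
        t2 = rscu(counts_of(TTT=3, TTC=2))
        assert t2.share["TTT"] == pytest.approx(0.60)
        assert high_frequency_codons(t).n == 0
        assert high_frequency_codons(t2).n == 0

    def test_uniform_usage_flags_nothing(self):
        table = {c: 7 for c in SENSE_CODONS}
        assert high_frequency_codons(rscu(counts_of(**table))).n == 0

    def test_ordering_descending_rscu_then_codon(self):
        t = rscu(counts_of(TTT=9, TTC=1, GGT=9, GGC=1, GGA=1, GGG=1))
        hf = high_frequency_codons(t)
        assert hf.codons == ("GGT", "TTT")  # 3.0 then 1.8


class TestCodonSetComposition:
    def test_shared_high_frequency_codon_set(self):
        """The 11 codons shared by all eight citrus species: 91% end in
        A/T, 36.4% start with G/C."""
        shared = [
            "AGA", "GTT", "GCT", "TCT", "TTG", "ATT",
            "GAT", "CAT", "AAT", "TTT", "TAT",
        ]
        comp = codon_set_composition(shared)
        assert round(comp["third_at"]) == 91
        assert round(comp["first_gc"], 1) == 36.4
        assert comp["first_at"] + comp["first_gc"] == pytest.approx(100.0)
        assert comp["third_at"] + comp["third_gc"] == pytest.approx(100.0)

    def test_single_gc_codon(self):
        assert codon_set_composition(["GCG"])["third_gc"] == 100.0

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            codon_set_composition([])
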