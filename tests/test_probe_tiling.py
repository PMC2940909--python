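import math
from fractions import Fraction

import numpy as np
import pytest

from exontile import (
    DesignParams,
    ExclusionReason,
    SequenceRecord,
    allocate_probe_counts,
    build_kmer_index,
    complexity_ok,
    cross_hybridizing,
    design_array,
    make_unigene_set,
    reverse_complement,
    tile_gene,
    uniform_fallback,
)
from exontile.exon_map import ExonProvenance, ExonStructure
from exontile.probe_tiling import canonical_kmer


class TestComplexity:
    @pytest.mark.parametrize("window,expected", [
        ("A" * 25, False),                 # entropy 0
        ("ACGT" * 6 + "A", True),          # entropy ~2 bits (counts 7,6,6,6)
        ("AT" * 12 + "A", False),          # dinucleotide repeat covers 25
        ("AAAAAAAAAAAAAGTCGTCGGCATC", False),  # homopolymer run 13 > 12
        ("AAAAAAAAAAAAGTCGTCGGCATCA", True),   # run 12 allowed
    ])
    def test_rules(self, window, expected, params):
        assert complexity_ok(window, params) is expected

    def test_entropy_example_by_hand(self, params):
        # counts 7,6,6,6 over 25 -> H = -(7/25 log 7/25 + 3 * 6/25 log 6/25)
        window = "ACGT" * 6 + "A"
        h = -(7 / 25 * math.log2(7 / 25) + 3 * (6 / 25) * math.log2(6 / 25))
        assert h > 1.9
        assert complexity_ok(window, params)


class TestKmerIndex:
    def test_single_record_single_kmer(self):
        rec = SequenceRecord(id="g", sequence="ACGTACGTACGTACGTACGTACGTA"[:25])
        index = build_kmer_index([rec], 25)
        assert len(index) == 1
        assert index[canonical_kmer(rec.sequence)] == {"g"}

    def test_identical_records_share_all_kmers(self):
        seq = "ACGGTTCAGGCATTACGGATCCGGATACGGTCA"
        a = SequenceRecord(id="a", sequence=seq)
        b = SequenceRecord(id="b", sequence=seq)
        index = build_kmer_index([a, b], 18)
        assert all(owners == {"a", "b"} for owners in index.values())

    def test_reverse_complement_shares_canonical_kmers(self):
        seq = "ACGGTTCAGGCATTACGGATCCGGATACGGTCA"
        a = SequenceRecord(id="a", sequence=seq)
        b = SequenceRecord(id="b", sequence=reverse_complement(seq))
        index = build_kmer_index([a, b], 18)
        # brute-force canonicalisation check: same canonical k-mer sets
        assert all(owners == {"a", "b"} for owners in index.values())


class TestCrossHyb:
    def make_indexes(self, records):
        return build_kmer_index(records, 25), build_kmer_index(records, 18)

    def test_unique_window_not_flagged(self):
        fx = make_unigene_set(3, length_range=(200, 200), seed=2,
                              plant_evidence=False)
        i25, i18 = self.make_indexes(fx.records)
        window = fx.records[0].sequence[:25]
        assert not cross_hybridizing(window, fx.records[0].id, i25, i18)

    def test_verbatim_shared_window_flagged(self):
        fx = make_unigene_set(2, length_range=(200, 200), seed=2,
                              plant_evidence=False)
        a, b = fx.records
        shared = a.sequence[50:75]
        b2 = SequenceRecord(id=b.id, sequence=b.sequence + shared)
        i25, i18 = self.make_indexes([a, b2])
        assert cross_hybridizing(shared, a.id, i25, i18)

    def test_seed_rule_two_other_genes(self):
        fx = make_unigene_set(4, length_range=(200, 200), seed=6,
                              plant_evidence=False)
        a, b, c, d = fx.records
        seed18 = a.sequence[10:28]
        b2 = SequenceRecord(id=b.id, sequence=b.sequence + seed18)
        c2 = SequenceRecord(id=c.id, sequence=c.sequence + seed18)
        i25, i18 = self.make_indexes([a, b2, c2, d])
        window = a.sequence[5:30]  # contains the shared 18-mer
        assert cross_hybridizing(window, a.id, i25, i18)
        # only one other gene carrying it is not enough for the seed rule
        i25b, i18b = self.make_indexes([a, b2, d])
        assert not cross_hybridizing(window, a.id, i25b, i18b)


def reference_largest_remainder(usable, n):
    """Exact-fraction largest-remainder apportionment oracle."""
    total = sum(usable)
    if total == 0:
        return [0] * len(usable)
    if total <= n:
        return list(usable)
    quotas = [Fraction(n * u, total) for u in usable]
    counts = [min(int(q), u) for q, u in zip(quotas, usable)]
    order = sorted(range(len(usable)), key=lambda i: (-(quotas[i] - int(quotas[i])), i))
    short = n - sum(counts)
    while short:
        progressed = False
        for i in order:
            if short and counts[i] < usable[i]:
                counts[i] += 1
                short -= 1
                progressed = True
        if not progressed:
            break
    return counts


def structure(sizes):
    exons, pos = [], 0
    for s in sizes:
        exons.append((pos, pos + s))
        pos += s
    return ExonStructure(record_id="g", exons=tuple(exons),
                         provenance=ExonProvenance.ALIGNMENT_DERIVED)


class TestAllocation:
    @pytest.mark.parametrize("sizes,n,expected", [
        ([524], 15, [15]),            # one exon takes all 15
        ([324, 324, 324], 15, [5, 5, 5]),
        ([524, 124], 15, [13, 2]),    # usable 500/100: oracle gives 13,2
        ([30, 30], 15, [6, 6]),       # fewer offsets than probes
        ([20, 524], 15, None),        # exon shorter than a probe gets 0
    ])
    def test_against_oracle(self, sizes, n, expected):
        s = structure(sizes)
        usable = [max(0, (e - b) - 24) for b, e in s.exons]
        got = allocate_probe_counts(s, n)
        assert got == reference_largest_remainder(usable, n)
        if expected is not None:
            assert got == expected

    def test_oracle_agreement_randomised(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            sizes = rng.integers(10, 400, size=rng.integers(1, 6)).tolist()
            n = int(rng.integers(1, 40))
            s = structure(sizes)
            usable = [max(0, (e - b) - 24) for b, e in s.exons]
            assert allocate_probe_counts(s, n) == reference_largest_remainder(usable, n)

    def test_count_law(self):
        s = structure([300, 180, 90])
        counts = allocate_probe_counts(s, 15)
        assert sum(counts) == 15


class TestTileGene:
    def indexes(self, records):
        return build_kmer_index(records, 25), build_kmer_index(records, 18)

    def test_unique_gene_gets_full_count_single_set(self, unigene_50):
        records = unigene_50.records
        i25, i18 = self.indexes(records)
        rec = records[0]
        result = tile_gene(rec, uniform_fallback(rec), i25, i18)
        assert not isinstance(result, ExclusionReason)
        assert sum(len(ps.probes) for ps in result) == 15
        assert len(result) == 1

    def test_too_small_record_excluded(self):
        rec = SequenceRecord(id="tiny", sequence="ACGTGGCATCGATCGGATCCGGATACGGTC"[:30])
        i25, i18 = self.indexes([rec])
        assert tile_gene(rec, uniform_fallback(rec), i25, i18) is ExclusionReason.TOO_SMALL

    def test_all_low_complexity_excluded(self):
        rec = SequenceRecord(id="polyA", sequence="A" * 400)
        i25, i18 = self.indexes([rec])
        assert (
            tile_gene(rec, uniform_fallback(rec), i25, i18)
            is ExclusionReason.LOW_COMPLEXITY
        )

    def test_verbatim_copy_indistinguishable(self):
        fx = make_unigene_set(3, length_range=(600, 600), seed=4,
                              plant_evidence=False)
        a = fx.records[0]
        copy = SequenceRecord(id="copycat", sequence=a.sequence)
        records = fx.records + [copy]
        i25, i18 = self.indexes(records)
        assert (
            tile_gene(copy, uniform_fallback(copy), i25, i18)
            is ExclusionReason.INDISTINGUISHABLE
        )

    def test_probe_sequence_fidelity_antisense(self, unigene_50, design_50):
        seqs = {r.id: r.sequence for r in unigene_50.records}
        for ps in design_50.probe_sets[:10]:
            for p in ps.probes:
                window = seqs[ps.gene_id][p.start:p.start + 25]
                assert p.sequence == reverse_complement(window)

    def test_sense_strand_option(self, unigene_50):
        params = DesignParams(probe_strand="sense")
        rec = unigene_50.records[0]
        i25, i18 = self.indexes(unigene_50.records)
        result = tile_gene(rec, uniform_fallback(rec), i25, i18, params)
        probe = result[0].probes[0]
        assert probe.sequence == rec.sequence[probe.start:probe.start + 25]

    def test_multi_exon_gene_gets_one_set_per_exon(self, unigene_50):
        rec = unigene_50.records[1]
        exons = ExonStructure(
            record_id=rec.id,
            exons=((0, 400), (400, len(rec.sequence))),
            provenance=ExonProvenance.ALIGNMENT_DERIVED,
        )
        i25, i18 = self.indexes(unigene_50.records)
        result = tile_gene(rec, exons, i25, i18)
        assert [ps.exon_index for ps in result] == [0, 1]
        assert sum(len(ps.probes) for ps in result) == 15


class TestDesignArray:
    def test_fifty_unique_genes_fully_represented(self, design_50):
        assert design_50.summary() == {
            "genes_represented": 50,
            "probe_sets": 50,
            "probes": 750,
            "genes_excluded": 0,
        }

    def test_low_complexity_gene_isolated(self):
        fx = make_unigene_set(5, length_range=(600, 600), seed=5,
                              plant_evidence=False)
        records = fx.records + [SequenceRecord(id="allA", sequence="A" * 600)]
        design = design_array(records)
        assert ("allA", ExclusionReason.LOW_COMPLEXITY) in design.exclusions
        assert len(design.represented_genes) == 5

    def test_empty_input_empty_design(self):
        design = design_array([])
        assert design.summary() == {
            "genes_represented": 0, "probe_sets": 0, "probes": 0, "genes_excluded": 0,
        }

    def test_every_gene_represented_xor_excluded(self):
        fx = make_unigene_set(8, length_range=(500, 700), dup_fraction=0.25,
                              seed=10, plant_evidence=False)
        design = design_array(fx.records)
        represented = set(design.represented_genes)
        excluded = {g for g, _ in design.exclusions}
        assert represented | excluded == {r.id for r in fx.records}
        assert not represented & excluded

    def test_capacity_exceeded_hard_error(self, unigene_50):
        params = DesignParams(max_probes_total=100)
        with pytest.raises(ValueError, match="capacity"):
            design_array(unigene_50.records, params=params)

    def test_uniqueness_guarantee_brute_force(self, unigene_50, design_50):
        """No selected probe's 25-mer occurs in any other gene, checked by
        direct substring scan over both strands."""
        seqs = {r.id: r.sequence for r in unigene_50.records}
        for ps in design_50.probe_sets:
            others = [s for gid, s in seqs.items() if gid != ps.gene_id]
            haystack = "#".join(others)
            haystack_rc = reverse_complement(haystack.replace("#", "N"))
            for p in ps.probes:
                window = seqs[ps.gene_id][p.start:p.start + 25]
                assert window not in haystack
                assert window not in haystack_rc

    def test_determinism_byte_identical(self, unigene_50):
        d1 = design_array(unigene_50.records)
        d2 = design_array(unigene_50.records)
        assert d1.probe_sets == d2.probe_sets
        assert d1.exclusions == d2.exclusions
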