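import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from _oracles import em_reference
from conftest import random_sequence
from hlaase.alleles import AlleleSequence, reference_from_sequences
from hlaase.errors import ParameterError
from hlaase.quantify import (
    EquivalenceClassTable,
    build_index,
    classify_reads,
    em_quantify,
)
from hlaase.simulate import simulate_allele_pair, simulate_gene_reads

K = 31


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _popcount_masks(index):
    return np.array([bin(int(m)).count("1") for m in index.masks])


class TestKmerIndex:
    def test_single_allele_indexes_length_minus_k_plus_one_kmers(self):
        allele = AlleleSequence(
            name="A*01:01", gene="A", sequence=random_sequence(100, 5)
        )
        index = build_index([allele], k=K)
        assert len(index.codes) == 100 - K + 1

    def test_substitution_yields_k_allele_specific_kmers_per_allele(
        self, two_allele_reference
    ):
        reference, _pos = two_allele_reference
        index = build_index(reference, k=K)
        specific = _popcount_masks(index) == 1
        # the site sits >= k from both ends: exactly k specific k-mers each
        assert specific.sum() == 2 * K

    def test_edge_substitution_yields_fewer_specific_kmers(self):
        seq1 = random_sequence(200, 31)
        seq2 = ("T" if seq1[0] != "T" else "G") + seq1[1:]
        ref = reference_from_sequences(
            [
                AlleleSequence(name="A*01:01", gene="A", sequence=seq1),
                AlleleSequence(name="A*02:01", gene="A", sequence=seq2),
            ]
        )
        specific = _popcount_masks(build_index(ref, k=K)) == 1
        assert specific.sum() == 2  # only the terminal k-mer differs per allele

    def test_all_n_sequence_contributes_no_kmers(self):
        alleles = [
            AlleleSequence(name="A*01:01", gene="A", sequence="N" * 100),
            AlleleSequence(
                name="A*02:01", gene="A", sequence=random_sequence(100, 6)
            ),
        ]
        index = build_index(alleles, k=K)
        assert np.all(index.masks == 2)  # only the second allele's bit

    def test_k_larger_than_shortest_sequence_rejected(self, two_allele_reference):
        reference, _ = two_allele_reference
        short = AlleleSequence(name="B*07:02", gene="B", sequence="ACGTACGTACGTACG")
        with pytest.raises(ParameterError, match="shortest"):
            build_index(list(reference.sequences) + [short], k=K)

    def test_k_below_minimum_rejected(self, two_allele_reference):
        reference, _ = two_allele_reference
        with pytest.raises(ParameterError, match="k must be"):
            build_index(reference, k=9)


class TestClassifyReads:
    def test_read_over_substitution_is_allele_specific(self, two_allele_reference):
        reference, pos = two_allele_reference
        a1, a2 = reference.representatives("A")
        read = a1.sequence[pos - 50 : pos + 50]
        table = classify_reads([read], build_index(reference, k=K))
        assert table.classes["A"] == {frozenset({a1.name}): 1}

    def test_shared_region_read_hits_both_alleles(self, two_allele_reference):
        reference, _pos = two_allele_reference
        a1, a2 = reference.representatives("A")
        read = a1.sequence[:60]  # far from the substitution at 100
        table = classify_reads([read], build_index(reference, k=K))
        assert table.classes["A"] == {frozenset({a1.name, a2.name}): 1}

    def test_reverse_complement_read_classifies_identically(
        self, two_allele_reference
    ):
        reference, pos = two_allele_reference
        a1, _ = reference.representatives("A")
        read = a1.sequence[pos - 50 : pos + 50]
        index = build_index(reference, k=K)
        fwd = classify_reads([read], index)
        rev = classify_reads([_revcomp(read)], index)
        assert fwd.classes == rev.classes

    def test_unrelated_random_read_is_discarded(self, two_allele_reference):
        reference, _ = two_allele_reference
        read = random_sequence(100, 999)
        table = classify_reads([read], build_index(reference, k=K))
        assert table.classes == {}
        assert table.discarded == 1 and table.n_reads == 1

    def test_read_shorter_than_k_discarded_with_warning(self, two_allele_reference):
        reference, _ = two_allele_reference
        index = build_index(reference, k=K)
        with pytest.warns(UserWarning, match="shorter than k"):
            table = classify_reads(["ACGTACGT"], index)
        assert table.discarded == 1 and table.too_short == 1

    def test_total_reads_equals_classes_plus_discarded(self, two_allele_reference):
        reference, pos = two_allele_reference
        a1, a2 = reference.representatives("A")
        reads = [
            a1.sequence[pos - 40 : pos + 40],
            a2.sequence[:70],
            random_sequence(80, 1234),
        ]
        table = classify_reads(reads, build_index(reference, k=K))
        assert table.total_assigned() + table.discarded == table.n_reads == 3

    def test_paired_mates_intersect_and_singletons_allowed(
        self, two_allele_reference
    ):
        reference, pos = two_allele_reference
        a1, a2 = reference.representatives("A")
        index = build_index(reference, k=K)
        # mate1 allele-specific, mate2 shared: pair resolves to the allele
        table = classify_reads(
            [a1.sequence[pos - 40 : pos + 40]], index, reads2=[a1.sequence[:60]]
        )
        assert table.classes["A"] == {frozenset({a1.name}): 1}
        # mate2 unmatched junk: the informative mate alone decides
        table = classify_reads(
            [a1.sequence[pos - 40 : pos + 40]],
            index,
            reads2=[random_sequence(60, 77)],
        )
        assert table.classes["A"] == {frozenset({a1.name}): 1}

    def test_cross_gene_ambiguous_reads_are_discarded(self):
        shared = random_sequence(150, 50)
        ref = reference_from_sequences(
            [
                AlleleSequence(name="A*01:01", gene="A", sequence=shared),
                AlleleSequence(
                    name="A*02:01", gene="A", sequence=random_sequence(150, 51)
                ),
                AlleleSequence(name="B*07:02", gene="B", sequence=shared),
                AlleleSequence(
                    name="B*08:01", gene="B", sequence=random_sequence(150, 52)
                ),
            ]
        )
        table = classify_reads([shared[10:110]], build_index(ref, k=K))
        assert table.cross_gene == 1 and table.discarded == 1
        assert table.classes == {}


class TestEmQuantify:
    def _quant(self, classes, reference):
        table = EquivalenceClassTable(
            classes={"A": classes}, n_reads=sum(classes.values())
        )
        return em_quantify(table, reference)["A"]

    def test_single_allele_class_takes_all_reads(self, two_allele_reference):
        reference, _ = two_allele_reference
        a1, a2 = (s.name for s in reference.representatives("A"))
        q = self._quant({frozenset({a1}): 50}, reference)
        assert q.est_counts[0] == pytest.approx(50.0)
        assert q.afs[0] == pytest.approx(1.0)

    def test_symmetric_classes_split_evenly(self, two_allele_reference):
        reference, _ = two_allele_reference
        a1, a2 = (s.name for s in reference.representatives("A"))
        q = self._quant(
            {
                frozenset({a1}): 10,
                frozenset({a2}): 10,
                frozenset({a1, a2}): 20,
            },
            reference,
        )
        assert q.est_counts == pytest.approx([20.0, 20.0])
        assert q.afs == pytest.approx([0.5, 0.5])

    def test_em_fixed_point_matches_closed_form_and_reference_em(
        self, two_allele_reference
    ):
        # c_A = 30 + 60 c_A / 100 has the fixed point c_A = 75
        reference, _ = two_allele_reference
        a1, a2 = (s.name for s in reference.representatives("A"))
        classes = {
            frozenset({a1}): 30,
            frozenset({a2}): 10,
            frozenset({a1, a2}): 60,
        }
        q = self._quant(classes, reference)
        assert q.est_counts == pytest.approx([75.0, 25.0], abs=1e-4)
        assert q.afs == pytest.approx([0.75, 0.25], abs=1e-6)
        oracle = em_reference(classes, [a1, a2])
        assert q.est_counts == pytest.approx(oracle, abs=1e-4)

    def test_log_likelihood_is_non_decreasing(self, two_allele_reference):
        reference, _ = two_allele_reference
        a1, a2 = (s.name for s in reference.representatives("A"))
        q = self._quant(
            {frozenset({a1}): 37, frozenset({a2}): 3, frozenset({a1, a2}): 91},
            reference,
        )
        lls = q.log_likelihoods
        assert len(lls) > 1
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_zero_reads_flags_gene_not_assessable(self, two_allele_reference):
        reference, _ = two_allele_reference
        table = EquivalenceClassTable(classes={}, n_reads=0)
        q = em_quantify(table, reference)["A"]
        assert not q.assessable
        assert q.total == 0.0

    @settings(
        max_examples=40,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        n_a=st.integers(0, 80),
        n_b=st.integers(0, 80),
        n_shared=st.integers(0, 80),
    )
    def test_counts_conserved_for_random_tables(
        self, two_allele_reference, n_a, n_b, n_shared
    ):
        if n_a + n_b + n_shared == 0:
            return
        reference, _ = two_allele_reference
        a1, a2 = (s.name for s in reference.representatives("A"))
        classes = {}
        if n_a:
            classes[frozenset({a1})] = n_a
        if n_b:
            classes[frozenset({a2})] = n_b
        if n_shared:
            classes[frozenset({a1, a2})] = n_shared
        q = self._quant(classes, reference)
        assert q.total == pytest.approx(n_a + n_b + n_shared, rel=1e-6)


class TestRecovery:
    @pytest.mark.parametrize("true_af", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_simulated_af_recovered_within_003(self, true_af):
        a1, a2 = simulate_allele_pair(seed=100)
        reference = reference_from_sequences([a1, a2])
        index = build_index(reference, k=K)
        reads = simulate_gene_reads(
            a1, a2, true_af, n_reads=2000, error_rate=1e-3, seed=int(true_af * 1000)
        )
        table = classify_reads(reads.reads, index)
        q = em_quantify(table, reference)["A"]
        assert q.afs[0] == pytest.approx(true_af, abs=0.03)
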