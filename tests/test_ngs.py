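"""Amplicon indel classification: edit distance, anchoring, summaries."""

import gzip
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editquant import ngs
from editquant.errors import EditQuantError
from editquant.synthetic import IndelAllele, ReadSimSpec, simulate_reads

dna = st.text(alphabet="ACGT", max_size=8)


def oracle_distance(a: str, b: str) -> int:
    """Exhaustive-recursion Levenshtein oracle for short strings."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
        )

    return rec(len(a), len(b))


class TestEditDistance:
    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=dna, b=dna)
    def test_matches_exhaustive_oracle(self, a, b):
        assert ngs.edit_distance(a, b) == oracle_distance(a, b)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(s=dna)
    def test_identity_and_empty(self, s):
        assert ngs.edit_distance(s, s) == 0
        assert ngs.edit_distance(s, "") == len(s)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=dna, b=dna, c=dna)
    def test_symmetry_and_triangle_inequality(self, a, b, c):
        assert ngs.edit_distance(a, b) == ngs.edit_distance(b, a)
        assert ngs.edit_distance(a, c) <= ngs.edit_distance(a, b) + ngs.edit_distance(b, c)

    def test_known_value(self):
        assert ngs.edit_distance("GATTACA", "GATCA") == 2

    def test_n_matches_only_n(self):
        assert ngs.edit_distance("AN", "AN") == 0
        assert ngs.edit_distance("AN", "AC") == 1

    def test_agrees_with_edlib_on_long_random_strings(self, rng):
        edlib = pytest.importorskip("edlib")
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 200))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 200))))
            assert ngs.edit_distance(a, b) == edlib.align(a, b)["editDistance"]


class TestExtraction:
    def _read(self, locus, insert=None):
        return (locus.sense_primer + (insert if insert is not None else locus.wild_type)
                + ngs.reverse_complement(locus.antisense_primer))

    def test_constructed_read_yields_wild_type(self, locus):
        assert ngs.extract_target(self._read(locus), locus) == locus.wild_type

    def test_reverse_complement_read_yields_wild_type(self, locus):
        rc = ngs.reverse_complement(self._read(locus))
        assert ngs.extract_target(rc, locus) == locus.wild_type

    def test_missing_antisense_anchor_gives_none(self, locus):
        read = locus.sense_primer + locus.wild_type
        assert ngs.extract_target(read, locus) is None

    def test_misordered_anchors_give_none(self, locus):
        # antisense binding site precedes the sense primer; neither this
        # strand nor its reverse complement carries an amplifiable anchor pair
        read = ngs.reverse_complement(locus.antisense_primer) + "ACGT" + locus.sense_primer
        assert ngs.extract_target(read, locus) is None

    def test_multiple_anchors_use_first_pair(self, locus):
        double = self._read(locus) + self._read(locus, insert="AAAA")
        assert ngs.extract_target(double, locus) == locus.wild_type

    def test_fuzzy_primer_matching_is_opt_in(self, locus):
        mutated_primer = "C" + locus.sense_primer[1:] if locus.sense_primer[0] != "C" \
            else "A" + locus.sense_primer[1:]
        read = mutated_primer + locus.wild_type + ngs.reverse_complement(locus.antisense_primer)
        assert ngs.extract_target(read, locus) is None
        assert ngs.extract_target(read, locus, max_mismatch=1) == locus.wild_type


class TestClassification:
    def _read(self, locus, insert):
        return (locus.sense_primer + insert
                + ngs.reverse_complement(locus.antisense_primer))

    def test_exact_wild_type(self, locus):
        rc = ngs.classify_read(self._read(locus, locus.wild_type), locus)
        assert (rc.status, rc.edit_distance, rc.size_delta) == ("wildtype", 0, 0)

    @pytest.mark.parametrize("size", [8, 66])
    def test_contiguous_deletion(self, locus, size):
        mutant = locus.wild_type[: 20] + locus.wild_type[20 + size:]
        rc = ngs.classify_read(self._read(locus, mutant), locus)
        assert rc.status == "deletion"
        assert rc.size_delta == -size
        assert rc.edit_distance == size

    def test_insertion_with_substitutions_bound(self, locus):
        k = 12
        mutant = locus.wild_type[:30] + "A" * k + locus.wild_type[30:]
        mutant = "T" + mutant[1:]  # one substitution on top
        rc = ngs.classify_read(self._read(locus, mutant), locus)
        assert rc.status == "insertion"
        assert rc.size_delta == k
        assert abs(rc.size_delta) <= rc.edit_distance <= k + 1

    def test_net_zero_length_mutant_is_complex(self, locus):
        wt = locus.wild_type
        mutant = "".join(
            {"A": "C", "C": "G", "G": "T", "T": "A"}[b] if i in (10, 40, 70) else b
            for i, b in enumerate(wt))
        rc = ngs.classify_read(self._read(locus, mutant), locus)
        assert rc.status == "complex"
        assert rc.size_delta == 0 and rc.edit_distance == 3

    def test_subthreshold_changes_are_wild_type(self, locus):
        wt = locus.wild_type
        mutant = ("C" if wt[0] != "C" else "G") + wt[1:]
        rc = ngs.classify_read(self._read(locus, mutant), locus)
        assert rc.status == "wildtype" and rc.edit_distance == 1

    def test_unanchored_read_is_no_target(self, locus):
        rc = ngs.classify_read("ACGT" * 30, locus)
        assert rc.status == "no_target" and rc.extracted == ""


class TestSummaries:
    def test_exact_mutation_percentage(self, locus):
        deleted = locus.wild_type[:40] + locus.wild_type[50:]
        reads = [locus.sense_primer + locus.wild_type
                 + ngs.reverse_complement(locus.antisense_primer)] * 800
        reads += [locus.sense_primer + deleted
                  + ngs.reverse_complement(locus.antisense_primer)] * 200
        s = ngs.summarize_mutations(reads, locus)
        assert s.percent_mutant == pytest.approx(20.0)
        assert s.counts["deletion"] == 200
        assert s.unique_deletions == {deleted: 10}
        assert s.deletion_size_hist == {10: 1}

    def test_error_free_wild_type_reads_have_zero_percent(self, locus):
        reads, _ = simulate_reads(ReadSimSpec(locus=locus, per_base_error=0.0,
                                              n_reads=300, seed=1))
        assert ngs.summarize_mutations(reads, locus).percent_mutant == 0.0

    def test_subthreshold_substitution_errors_stay_wild_type(self, locus):
        # at most 2 substitutions per read < stringency 3 -> all wild type
        rng = np.random.default_rng(5)
        reads = []
        for _ in range(200):
            wt = list(locus.wild_type)
            for pos in rng.choice(len(wt), size=rng.integers(0, 3), replace=False):
                wt[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[wt[pos]]
            reads.append(locus.sense_primer + "".join(wt)
                         + ngs.reverse_complement(locus.antisense_primer))
        assert ngs.summarize_mutations(reads, locus).percent_mutant == 0.0

    def test_strand_invariance_of_summary(self, locus):
        reads, _ = simulate_reads(ReadSimSpec(
            locus=locus,
            mutant_alleles=(IndelAllele(position=50, size=8, frequency=0.25),),
            per_base_error=0.004, n_reads=500, seed=3))
        seqs = [seq for _, seq in reads]
        s1 = ngs.summarize_mutations(seqs, locus)
        s2 = ngs.summarize_mutations([ngs.reverse_complement(s) for s in seqs], locus)
        assert s1.counts == s2.counts
        assert s1.unique_deletions == s2.unique_deletions
        assert s1.percent_mutant == s2.percent_mutant

    def test_simulated_fraction_within_binomial_interval(self, locus):
        f, n = 0.3, 10_000
        reads, truth = simulate_reads(ReadSimSpec(
            locus=locus,
            mutant_alleles=(IndelAllele(position=45, size=10, frequency=f),),
            per_base_error=0.0, n_reads=n, seed=9))
        s = ngs.summarize_mutations(reads, locus)
        half_width = 1.96 * np.sqrt(f * (1 - f) / n) * 100
        assert s.percent_mutant == pytest.approx(100 * f, abs=half_width)
        # with zero sequencing error the classifier must agree with the truth labels
        assert s.counts["deletion"] == sum(t != "wildtype" for t in truth)

    def test_no_target_reads_raise(self, locus):
        with pytest.raises(EditQuantError):
            ngs.summarize_mutations(["ACGT" * 10], locus)


@pytest.mark.parametrize("test,bg,expected", [
    (26.4, 3.2, 23.2),
    (15.0, 3.2, 11.8),
    (7.5, 7.5, 0.0),
])
def test_background_subtraction(test, bg, expected):
    corrected = ngs.background_subtract(test, bg)
    assert float(corrected) == pytest.approx(expected)
    assert not corrected.negative


def test_background_subtraction_flags_negative():
    assert ngs.background_subtract(1.0, 3.2).negative


def test_io_roundtrip(tmp_path, locus):
    fasta = tmp_path / "reads.fasta"
    fasta.write_text(">r1\nACGTACGT\n>r2\nTTTT\n")
    assert list(ngs.read_sequences(fasta)) == [("r1", "ACGTACGT"), ("r2", "TTTT")]

    fq_gz = tmp_path / "reads.fastq.gz"
    with gzip.open(fq_gz, "wt") as fh:
        fh.write("@r1\nACGT\n+\nIIII\n")
    assert list(ngs.read_sequences(fq_gz)) == [("r1", "ACGT")]

    yaml_path = tmp_path / "locus.yaml"
    yaml_path.write_text(
        f"name: roundtrip\nwild_type: {locus.wild_type}\n"
        f"sense_primer: {locus.sense_primer}\nantisense_primer: {locus.antisense_primer}\n"
        "stringency: 4\n")
    loaded = ngs.LocusConfig.from_file(yaml_path)
    assert loaded.stringency == 4 and loaded.wild_type == locus.wild_type

    reads = [locus.sense_primer + locus.wild_type
             + ngs.reverse_complement(locus.antisense_primer)] * 5
    summary = ngs.summarize_mutations(reads, locus)
    paths = ngs.write_summary(summary, tmp_path / "out")
    for p in paths.values():
        assert p.exists()
    assert "percent_mutant,0.0000" in paths["summary"].read_text()
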