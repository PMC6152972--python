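"""Mapper and folder against independent brute-force oracles."""

import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirnaforge import seqcore
from mirnaforge.seqcore import (GenomeIndex, duplex_geometry, fold,
                                gff3_to_interval, interval_to_gff3, map_exact,
                                reverse_complement)
from mirnaforge.synthetic_data import build_hairpin

# ---------------------------------------------------------------------------
# exact mapping
# ---------------------------------------------------------------------------


def naive_scan(read, sequences):
    """Brute-force zero-mismatch occurrence scan over both strands."""
    hits = []
    for name in sorted(sequences):
        seq = sequences[name]
        for strand, query in (("+", read), ("-", reverse_complement(read))):
            start = seq.find(query)
            while start >= 0:
                hits.append((name, (start, start + len(read)), strand))
                start = seq.find(query, start + 1)
    hits.sort(key=lambda h: (h[0], h[1][0], h[2]))
    return hits


dna = st.text(alphabet="ACGT", min_size=18, max_size=30)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=60, max_size=400), dna,
       st.integers(0, 10**6))
def test_map_exact_equals_naive_scan(genome, read, pos_seed):
    # plant the read somewhere so hits are not vacuously empty
    pos = pos_seed % (len(genome) - len(read) + 1)
    genome = genome[:pos] + read + genome[pos + len(read):]
    index = GenomeIndex({"chr1": genome}, k=18)
    assert map_exact(read, index) == naive_scan(read, {"chr1": genome})


def test_map_exact_multi_hit_and_misses():
    core = "ACGTACGTACGTACGTAGCT"
    genome = ("TTTT" + core + "GGGG") * 3
    index = GenomeIndex({"chr1": genome}, k=18)
    hits = map_exact(core, index)
    assert len(hits) == 3
    assert all(genome[s:e] == core for _, (s, e), _ in hits)
    assert map_exact("A" * 20, index) == []
    assert map_exact(core[:-1] + "N", index) == []


def test_map_exact_reports_minus_strand():
    insert = "TTGACCGTAGCATCGGATCCGA"
    genome = "CACA" * 10 + reverse_complement(insert) + "GTGT" * 10
    index = GenomeIndex({"chr1": genome}, k=18)
    hits = map_exact(insert, index)
    assert [h[2] for h in hits] == ["-"]
    (_, (s, e), _) = hits[0]
    assert reverse_complement(genome[s:e]) == insert


def test_empty_index_is_empty_result_not_error():
    index = GenomeIndex({}, k=18)
    assert map_exact("ACGT" * 5, index) == []


# ---------------------------------------------------------------------------
# folding oracles
# ---------------------------------------------------------------------------

PAIR = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
        ("G", "U"): 1, ("U", "G"): 1}


def enumerate_structures(seq):
    """Every nested structure (as a frozenset of pairs), min loop 3."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def structs(i, j):
        if j - i < 4:
            return [frozenset()]
        out = list(structs(i + 1, j))
        for k in range(i + 4, j + 1):
            if (seq[i], seq[k]) in PAIR:
                for inner in structs(i + 1, k - 1):
                    for outer in structs(k + 1, j):
                        out.append(frozenset({(i, k)}) | inner | outer)
        return out

    return structs(0, n - 1)


def score_structure(seq, pairs):
    total = sum(PAIR[(seq[i], seq[j])] for i, j in pairs)
    total += 0.5 * sum(1 for i, j in pairs if (i + 1, j - 1) in pairs)
    return total


def oracle_best_score(seq):
    """Exhaustive-enumeration optimum (practical up to ~13 nt)."""
    return max((score_structure(seq, s) for s in enumerate_structures(seq)),
               default=0.0)


def memo_best_score(seq):
    """Independent recursive oracle usable to ~25 nt: position-anchored
    choice of partner, stacking handled via a paired-context flag."""

    @lru_cache(maxsize=None)
    def paired(i, j):  # best score of [i, j] given (i, j) is a pair
        if j - i < 4 or (seq[i], seq[j]) not in PAIR:
            return -np.inf
        w = PAIR[(seq[i], seq[j])]
        return w + max(free(i + 1, j - 1), paired(i + 1, j - 1) + 0.5)

    @lru_cache(maxsize=None)
    def free(i, j):  # best score of [i, j], no outside constraint
        if j - i < 4:
            return 0.0
        best = free(i + 1, j)
        for k in range(i + 4, j + 1):
            p = paired(i, k)
            if p > -np.inf:
                best = max(best, p + free(k + 1, j))
        return best

    return free(0, len(seq) - 1)


@pytest.mark.parametrize("seq,expected_pairs", [
    ("GGGAAACCC", 3),
    ("AAAAAAAAAA", 0),
    ("GCGCAAAGCGC", 4),  # palindromic stem, minimal 3-nt loop
])
def test_fold_known_structures(seq, expected_pairs):
    fr = fold(seq)
    assert fr.n_pairs == expected_pairs


def test_fold_score_matches_enumeration():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGU"))
    for _ in range(60):
        seq = "".join(bases[rng.integers(0, 4, size=rng.integers(6, 13))])
        assert fold(seq).score == pytest.approx(oracle_best_score(seq))


def test_fold_score_matches_recursive_oracle():
    rng = np.random.default_rng(8)
    bases = np.array(list("ACGU"))
    for _ in range(60):
        seq = "".join(bases[rng.integers(0, 4, size=rng.integers(8, 21))])
        assert fold(seq).score == pytest.approx(memo_best_score(seq))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGU", min_size=1, max_size=60))
def test_fold_pairing_is_nested_involution(seq):
    fr = fold(seq)
    pairing = fr.pairing
    opened = []
    for i, j in enumerate(pairing):
        if j >= 0:
            assert pairing[j] == i          # involution
            assert j != i
            if j > i:
                assert j - i > seqcore.MIN_LOOP
                opened.append((i, j))
    for (a, b), (c, d) in itertools.combinations(opened, 2):
        assert (b < c) or (d < a) or (a < c and d < b) or (c < a and b < d)


def test_fold_rejects_invalid_alphabet():
    with pytest.raises(ValueError, match="position 2"):
        fold("ACXGU")


def test_constructed_hairpin_fully_paired():
    hp = build_hairpin("UGACCGUAGCAUCGGAUCCGAU", loop_len=8)
    fr = fold(hp.precursor)
    assert all(fr.pairing[p] >= 0 for p in range(*hp.mature))
    assert fr.hairpin_arms is not None
    geo = duplex_geometry(fr, hp.mature, hp.star)
    assert geo.paired_fraction == 1.0


# ---------------------------------------------------------------------------
# duplex geometry
# ---------------------------------------------------------------------------

def test_duplex_geometry_perfect_and_bulged():
    hp = build_hairpin("UGACCGUAGCAUCGGAUCCGAU", loop_len=8)
    geo = duplex_geometry(fold(hp.precursor), hp.mature, hp.star)
    assert (geo.space, geo.max_bulge) == (8, 0)

    hp5 = build_hairpin("UGACCGUAGCAUCGGAUCCGAU", loop_len=8,
                        bulges=[("star", 10, 5)])
    geo5 = duplex_geometry(fold(hp5.precursor), hp5.mature, hp5.star)
    assert geo5.max_bulge == 5

    hp36 = build_hairpin("UGACCGUAGCAUCGGAUCCGAU", loop_len=36)
    geo36 = duplex_geometry(fold(hp36.precursor), hp36.mature, hp36.star)
    assert geo36.space == 36


def test_duplex_geometry_rejects_overlapping_arms():
    fr = fold("GGGAAACCC")
    with pytest.raises(ValueError, match="overlap"):
        duplex_geometry(fr, (0, 5), (3, 9))


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

@given(st.integers(0, 10**6), st.integers(1, 1000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_gff3_round_trip(start, length):
    end = start + length
    assert gff3_to_interval(*interval_to_gff3(start, end)) == (start, end)
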