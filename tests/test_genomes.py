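"""Operator algebra, accessible-mutant combinatorics and genome I/O."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invwalk import (
    Genome,
    MutationOp,
    accessible_mutant_census,
    apply_op,
    conjugate_segment,
    count_operations,
    enumerate_mutants,
    enumerate_operations,
    hamming_distance,
    invariant_inversion_count,
    invert,
    max_accessible_mutants,
    mean_invariant_fraction,
    permute_segment,
    point_mutate,
    read_genomes,
    write_genomes,
)
from invwalk.genomes import all_genomes, segment_indices


def g(s, topology="circular"):
    return Genome.from_string(s, topology)


# --- elementary operator examples -----------------------------------------


@pytest.mark.parametrize(
    "func,origin,i,j,expected",
    [
        (conjugate_segment, "0000", 1, 4, "1111"),
        (conjugate_segment, "011010", 2, 4, "000110"),
        (permute_segment, "0000", 1, 4, "0000"),
        (permute_segment, "011010", 2, 4, "001110"),
        (permute_segment, "011010", 3, 3, "011010"),
        (invert, "0000", 2, 2, "0100"),  # i == j is a single bit flip
        (invert, "011010", 2, 4, "010010"),
        (invert, "0110", 4, 2, "1110"),  # wraparound segment 4,1,2
        (invert, "0000", 1, 4, "1111"),
    ],
)
def test_operator_examples(func, origin, i, j, expected):
    assert str(func(g(origin), i, j)) == expected


def test_point_mutation_flips_exactly_one_locus():
    assert str(point_mutate(g("0000"), 3)) == "0010"
    gx = g("011010")
    for i in range(1, 7):
        assert hamming_distance(gx, point_mutate(gx, i)) == 1
        assert point_mutate(point_mutate(gx, i), i) == gx
        assert point_mutate(gx, i) == invert(gx, i, i)


@settings(max_examples=200, derandomize=True)
@given(
    bits=st.lists(st.integers(0, 1), min_size=2, max_size=12),
    i=st.integers(1, 12),
    j=st.integers(1, 12),
)
def test_inversion_factorisation_and_involution(bits, i, j):
    """Î = Ĉ∘P̂ = P̂∘Ĉ, and every operator is an involution."""
    N = len(bits)
    i, j = (i - 1) % N + 1, (j - 1) % N + 1
    gx = Genome(tuple(bits))
    inv = invert(gx, i, j)
    assert inv == conjugate_segment(permute_segment(gx, i, j), i, j)
    assert inv == permute_segment(conjugate_segment(gx, i, j), i, j)
    assert invert(inv, i, j) == gx
    assert conjugate_segment(conjugate_segment(gx, i, j), i, j) == gx
    assert 0 <= hamming_distance(gx, inv) <= N


def _oracle_invert(s: str, i: int, j: int) -> str:
    """Independent rotate-to-linearise / reverse-complement / rotate-back."""
    N = len(s)
    rot = s[i - 1 :] + s[: i - 1]  # segment now starts at position 0
    L = ((j - i) % N) + 1
    seg = rot[:L]
    rc = "".join("1" if c == "0" else "0" for c in reversed(seg))
    out = rc + rot[L:]
    return out[N - (i - 1) :] + out[: N - (i - 1)]


def test_invert_matches_rotation_oracle_exhaustively():
    for N in range(2, 7):
        for bits in itertools.product("01", repeat=N):
            s = "".join(bits)
            for i in range(1, N + 1):
                for j in range(1, N + 1):
                    assert str(invert(g(s), i, j)) == _oracle_invert(s, i, j)


def test_inversions_do_not_commute():
    """Overlapping inversions applied in different orders can differ."""
    witnesses = [
        gx
        for gx in all_genomes(4)
        if invert(invert(gx, 2, 3), 2, 4) != invert(invert(gx, 2, 4), 2, 3)
    ]
    assert witnesses  # e.g. 0000 -> 0100 vs 0001


# --- accessible mutants ---------------------------------------------------


def test_accessible_mutants_of_uniform_genome(standard_genomes):
    zero = standard_genomes[0]
    ms = enumerate_mutants(zero, "inversion")
    assert ms.D == 13 and zero not in ms
    assert ms.D == max_accessible_mutants(4)


def test_alternating_genome_cannot_reach_1001(standard_genomes):
    ms = enumerate_mutants(g("0101"), "inversion")
    assert g("1001") not in ms


def test_point_mutant_count_is_N():
    for gx in (g("0101"), g("110010"), g("01", "linear")):
        assert enumerate_mutants(gx, "point").D == len(gx)


def test_min_inversion_D_exceeds_max_point_D_at_N4():
    Ds = [enumerate_mutants(gx, "inversion").D for gx in all_genomes(4)]
    assert min(Ds) == 7 and min(Ds) >= 4


def test_inversion_mutants_contain_point_mutants():
    for N in range(2, 7):
        for gx in all_genomes(N):
            inv = enumerate_mutants(gx, "inversion").mutants
            pnt = enumerate_mutants(gx, "point").mutants
            assert pnt <= inv


def test_size_limited_inversions_s1_equal_point_mutations(rng):
    for _ in range(5):
        gx = Genome.from_array(rng.integers(0, 2, 8, dtype=np.uint8))
        assert (
            enumerate_mutants(gx, "inversion", max_segment=1).mutants
            == enumerate_mutants(gx, "point").mutants
        )


# --- census and operation counts ------------------------------------------


def test_census_small_rows_and_total():
    assert dict(accessible_mutant_census(2, "inversion")) == {2: 2, 3: 2}
    assert dict(accessible_mutant_census(3, "inversion")) == {5: 6, 7: 2}
    assert dict(accessible_mutant_census(5, "point")) == {5: 32}
    for N in (4, 6):
        census = accessible_mutant_census(N, "inversion")
        assert sum(census.values()) == 2**N
        assert max(census) == max_accessible_mutants(N)
        assert census[max(census)] == 2  # only the two uniform genomes


@pytest.mark.parametrize(
    "N,kind,topology,expected",
    [
        (4, "inversion", "circular", 16),
        (4, "inversion", "linear", 10),
        (4, "point", "circular", 4),
        (7, "inversion", "circular", 49),
        (7, "inversion", "linear", 28),
    ],
)
def test_count_operations(N, kind, topology, expected):
    assert count_operations(N, kind, topology) == expected
    assert (
        len(list(enumerate_operations(N, kind, topology))) == expected
    )


def test_invariant_inversions():
    assert invariant_inversion_count(g("01")) == 2
    for gx in all_genomes(5):
        c = invariant_inversion_count(gx)
        assert 0 <= c <= 25
        by_apply = sum(
            1
            for op in enumerate_operations(5, "inversion")
            if apply_op(gx, op) == gx
        )
        assert c == by_apply


def test_mean_invariant_fraction_approaches_1_over_N():
    # exact small-N expectation: (1/N) * (1 - 2**-(N//2))
    for N in (2, 4, 6, 8):
        expected = (1 - 2.0 ** -(N // 2)) / N
        assert mean_invariant_fraction(N) == pytest.approx(expected)


# --- errors and I/O -------------------------------------------------------


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        Genome.from_string("01a1")
    with pytest.raises(ValueError):
        Genome((0,))
    with pytest.raises(ValueError):
        invert(g("0110", "linear"), 3, 2)  # linear genomes reject i > j
    with pytest.raises(ValueError):
        invert(g("0110"), 0, 2)
    with pytest.raises(ValueError):
        point_mutate(g("0110"), 5)
    with pytest.raises(ValueError):
        hamming_distance(g("01"), g("011"))
    with pytest.raises(ValueError):
        MutationOp("point", 1, 2)
    with pytest.raises(ValueError):
        list(enumerate_operations(4, "inversion", max_segment=5))
    with pytest.raises(ValueError):
        accessible_mutant_census(25, "inversion")


def test_segment_indices_wraparound():
    assert segment_indices(4, 4, 2).tolist() == [3, 0, 1]
    assert segment_indices(4, 2, 4, "linear").tolist() == [1, 2, 3]


def test_genome_io_roundtrip(tmp_path):
    genomes = [g("0101"), g("111000")]
    for name in ("genomes.txt", "genomes.fasta"):
        path = tmp_path / name
        write_genomes(genomes, path)
        back = read_genomes(path)
        assert back == genomes
    (tmp_path / "bad.txt").write_text("01x0\n")
    with pytest.raises(ValueError):
        read_genomes(tmp_path / "bad.txt")
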