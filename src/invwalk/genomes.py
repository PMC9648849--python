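"""Binary genomes and structural mutation operators.

Genomes are fixed-length sequences over the two-letter alphabet {0, 1},
standing in for a double-stranded DNA molecule in which the two digital
nucleotides are complementary (``x̄_i = 1 - x_i``).  The chromosome is
either *circular* (periodic index arithmetic, ``x_{N+i} = x_i``) or
*linear*.

Two mutation operators act on a genome:

``point``
    flip a single locus,
``inversion``
    reverse-complement the segment between loci *i* and *j* (inclusive).
    On a circular chromosome *i* > *j* denotes the wrap-around arc, so
    there are exactly N**2 ordered-pair operations; on a linear
    chromosome *i* <= *j* is required, giving N(N+1)/2.

An inversion factors into two commuting sub-operations: *conjugation*
(complement every locus of the segment) and *permutation* (reverse the
segment in place).  Loci are 1-based in every public interface.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

Topology = Literal["circular", "linear"]
OperatorKind = Literal["point", "inversion"]

TOPOLOGIES = ("circular", "linear")
OPERATOR_KINDS = ("point", "inversion")

#: guard for exhaustive 2**N enumerations (census, full networks)
DEFAULT_ENUMERATION_CAP = 20


@dataclass(frozen=True)
class Genome:
    """An immutable binary genome with circular or linear topology."""

    bits: tuple[int, ...]
    topology: Topology = "circular"

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if len(bits) < 2:
            raise ValueError(f"genome length must be >= 2, got {len(bits)}")
        if any(b not in (0, 1) for b in bits):
            raise ValueError("genome bits must all be 0 or 1")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "bits", bits)

    @classmethod
    def from_string(cls, s: str, topology: Topology = "circular") -> "Genome":
        bad = set(s) - {"0", "1"}
        if bad:
            raise ValueError(
                f"genome string may contain only '0'/'1', found {sorted(bad)!r}"
            )
        return cls(tuple(int(c) for c in s), topology)

    @classmethod
    def from_array(cls, arr: np.ndarray, topology: Topology = "circular") -> "Genome":
        return cls(tuple(int(b) for b in np.asarray(arr)), topology)

    def to_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.uint8)

    def complement(self) -> "Genome":
        """The complementary strand x̄, with x̄_i = 1 - x_i."""
        return Genome(tuple(1 - b for b in self.bits), self.topology)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def N(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class MutationOp:
    """One operator application, identified by kind and 1-based loci (i, j).

    For point mutations j == i.  For inversions on circular genomes,
    (i, j) and (j, i) denote the two complementary arcs and are distinct
    operations.
    """

    kind: OperatorKind
    i: int
    j: int

    def __post_init__(self) -> None:
        if self.kind not in OPERATOR_KINDS:
            raise ValueError(f"unknown operator kind {self.kind!r}")
        if self.kind == "point" and self.i != self.j:
            raise ValueError("point mutation requires j == i")

    @classmethod
    def point(cls, i: int) -> "MutationOp":
        return cls("point", i, i)

    @classmethod
    def inversion(cls, i: int, j: int) -> "MutationOp":
        return cls("inversion", i, j)

    def segment_length(self, N: int, topology: Topology = "circular") -> int:
        if self.kind == "point":
            return 1
        if topology == "circular":
            return ((self.j - self.i) % N) + 1
        return self.j - self.i + 1


@dataclass(frozen=True)
class MutantSet:
    """Accessible mutants N_v(x): distinct one-step mutants of ``origin``.

    ``origin`` itself is never a member (invariant operations are
    dropped), so ``D == |mutants|`` is the accessible-mutant count
    D_v(x).
    """

    origin: Genome
    kind: OperatorKind
    mutants: frozenset[Genome]

    @property
    def D(self) -> int:
        return len(self.mutants)

    def __contains__(self, g: Genome) -> bool:
        return g in self.mutants

    def __iter__(self) -> Iterator[Genome]:
        return iter(self.mutants)


def _check_locus(i: int, N: int) -> None:
    if not 1 <= i <= N:
        raise ValueError(f"locus {i} out of range 1..{N}")


def segment_indices(N: int, i: int, j: int, topology: Topology = "circular") -> np.ndarray:
    """0-based index array of the forward walk i, i+1, ..., j (inclusive)."""
    _check_locus(i, N)
    _check_locus(j, N)
    if topology == "linear":
        if i > j:
            raise ValueError(f"linear genome requires i <= j, got ({i}, {j})")
        return np.arange(i - 1, j)
    L = ((j - i) % N) + 1
    return (i - 1 + np.arange(L)) % N


def conjugate_segment(g: Genome, i: int, j: int) -> Genome:
    """Complement every locus of the segment i..j (operator Ĉ)."""
    idx = segment_indices(len(g), i, j, g.topology)
    arr = g.to_array()
    arr[idx] = 1 - arr[idx]
    return Genome.from_array(arr, g.topology)


def permute_segment(g: Genome, i: int, j: int) -> Genome:
    """Reverse the segment i..j in place (operator P̂)."""
    idx = segment_indices(len(g), i, j, g.topology)
    arr = g.to_array()
    arr[idx] = arr[idx][::-1]
    return Genome.from_array(arr, g.topology)


def invert(g: Genome, i: int, j: int) -> Genome:
    """Reverse-complement the segment i..j (the inversion Î = Ĉ∘P̂ = P̂∘Ĉ).

    Equivalent to the two-pointer update y_l <- 1 - x_u walking l forward
    from i and u backward from j (modular on circular genomes).  With
    i == j this is a single bit flip, i.e. a point mutation.
    """
    idx = segment_indices(len(g), i, j, g.topology)
    arr = g.to_array()
    arr[idx] = 1 - arr[idx][::-1]
    return Genome.from_array(arr, g.topology)


def point_mutate(g: Genome, i: int) -> Genome:
    """Flip the single locus i."""
    _check_locus(i, len(g))
    arr = g.to_array()
    arr[i - 1] ^= 1
    return Genome.from_array(arr, g.topology)


def apply_op(g: Genome, op: MutationOp) -> Genome:
    if op.kind == "point":
        return point_mutate(g, op.i)
    return invert(g, op.i, op.j)


def hamming_distance(g: Genome, h: Genome) -> int:
    if len(g) != len(h):
        raise ValueError(f"length mismatch: {len(g)} vs {len(h)}")
    return int(np.count_nonzero(g.to_array() != h.to_array()))


def count_operations(N: int, kind: OperatorKind, topology: Topology = "circular") -> int:
    """Total number of operator applications on a genome of length N.

    N point mutations; N**2 circular inversions (ordered locus pairs);
    N(N+1)/2 linear inversions.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if kind == "point":
        return N
    if topology == "circular":
        return N * N
    return N * (N + 1) // 2


def enumerate_operations(
    N: int,
    kind: OperatorKind,
    topology: Topology = "circular",
    max_segment: int | None = None,
) -> Iterator[MutationOp]:
    """Yield every operator application, optionally size-limited.

    ``max_segment`` caps the inversion segment length at s <= N (the
    size-limited variant); it does not affect point mutations.
    """
    if max_segment is not None and not 1 <= max_segment <= N:
        raise ValueError(f"max_segment must be in [1, {N}], got {max_segment}")
    if kind == "point":
        for i in range(1, N + 1):
            yield MutationOp.point(i)
        return
    s = N if max_segment is None else max_segment
    if topology == "circular":
        for i in range(1, N + 1):
            for L in range(1, s + 1):
                j = (i - 1 + L - 1) % N + 1
                yield MutationOp.inversion(i, j)
    else:
        for i in range(1, N + 1):
            for j in range(i, min(i + s - 1, N) + 1):
                yield MutationOp.inversion(i, j)


def enumerate_mutants(
    g: Genome, kind: OperatorKind, max_segment: int | None = None
) -> MutantSet:
    """All distinct genomes reachable by one operator application.

    Invariant applications (result == input) are excluded, so for
    inversions D_v(x) < N**2 in general, while for point mutations
    D_P(x) = N always.
    """
    mutants: set[Genome] = set()
    for op in enumerate_operations(len(g), kind, g.topology, max_segment):
        m = apply_op(g, op)
        if m != g:
            mutants.add(m)
    return MutantSet(origin=g, kind=kind, mutants=frozenset(mutants))


def _all_bit_arrays(N: int) -> np.ndarray:
    """(2**N, N) uint8 array of every genome, row v = binary digits of v."""
    vals = np.arange(2**N, dtype=np.uint32)
    return ((vals[:, None] >> np.arange(N - 1, -1, -1, dtype=np.uint32)) & 1).astype(
        np.uint8
    )


def _segment_index_table(
    N: int, topology: Topology, max_segment: int | None = None
) -> list[np.ndarray]:
    s = N if max_segment is None else max_segment
    idx_list: list[np.ndarray] = []
    if topology == "circular":
        for L in range(1, s + 1):
            for i0 in range(N):
                idx_list.append((i0 + np.arange(L)) % N)
    else:
        for L in range(1, s + 1):
            for i0 in range(N - L + 1):
                idx_list.append(i0 + np.arange(L))
    return idx_list


def _distinct_inversion_mutants(bits: np.ndarray, idx_list: list[np.ndarray]) -> int:
    """Count distinct one-inversion mutants of ``bits`` (excluding itself)."""
    seen = set()
    self_key = bits.tobytes()
    for idx in idx_list:
        m = bits.copy()
        m[idx] = 1 - bits[idx][::-1]
        seen.add(m.tobytes())
    seen.discard(self_key)
    return len(seen)


def accessible_mutant_census(
    N: int,
    kind: OperatorKind,
    topology: Topology = "circular",
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> Counter[int]:
    """Accessible-mutant census over all 2**N genomes.

    Returns a Counter mapping each D_v value to the number of genomes
    attaining it; counts sum to 2**N.  For point mutations this is
    always {N: 2**N}.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if N > cap:
        raise ValueError(f"N={N} exceeds the exhaustive-enumeration cap {cap}")
    if kind == "point":
        return Counter({N: 2**N})
    idx_list = _segment_index_table(N, topology)
    census: Counter[int] = Counter()
    for bits in _all_bit_arrays(N):
        census[_distinct_inversion_mutants(bits, idx_list)] += 1
    return census


def max_accessible_mutants(N: int) -> int:
    """The maximum D_I over circular genomes of length N: N**2 - N + 1.

    Attained exactly by the two uniform genomes 00...0 and 11...1.
    """
    return N * N - N + 1


def invariant_inversion_count(g: Genome) -> int:
    """Number of ordered (i, j) inversion pairs that leave g unchanged.

    An inversion is invariant iff its segment is anti-palindromic
    (x at position t differs from x at the mirrored position for every
    t); odd-length segments always change their middle locus, so only
    even segment lengths contribute.  Circular genomes only.
    """
    if g.topology != "circular":
        raise ValueError("invariant_inversion_count requires a circular genome")
    N = len(g)
    arr = g.to_array()
    count = 0
    for L in range(2, N + 1, 2):
        offs = np.arange(L)
        for i0 in range(N):
            seg = arr[(i0 + offs) % N]
            if bool(np.all(seg != seg[::-1])):
                count += 1
    return count


def mean_invariant_fraction(N: int, cap: int = DEFAULT_ENUMERATION_CAP) -> float:
    """Mean fraction of invariant inversions over all circular genomes.

    Converges to 1/N as N grows (each even segment length L is invariant
    with probability 2**(-L/2) under a uniform random genome).
    """
    if N > cap:
        raise ValueError(f"N={N} exceeds the exhaustive-enumeration cap {cap}")
    total = 0
    for bits in _all_bit_arrays(N):
        total += invariant_inversion_count(Genome.from_array(bits))
    return total / (2**N * N * N)


# ---------------------------------------------------------------------------
# genome I/O: plain 0/1 strings, one per line, or FASTA with a {0,1} alphabet
# ---------------------------------------------------------------------------


def read_genomes(
    path: str | Path,
    topology: Topology = "circular",
    fmt: Literal["lines", "fasta"] | None = None,
) -> list[Genome]:
    """Read genomes from a text file.

    ``fmt`` defaults by extension: ``.fa``/``.fasta`` -> FASTA,
    anything else -> one 0/1 string per line.  Topology is metadata and
    is supplied by the caller, not encoded in the records.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta") else "lines"
    if fmt == "fasta":
        from Bio import SeqIO

        return [
            Genome.from_string(str(rec.seq), topology)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(Genome.from_string(line, topology))
    return out


def write_genomes(
    genomes: list[Genome],
    path: str | Path,
    fmt: Literal["lines", "fasta"] | None = None,
) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta") else "lines"
    if fmt == "fasta":
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(str(g)), id=f"g{k}", description="")
            for k, g in enumerate(genomes)
        ]
        seqio_write(records, str(path), "fasta")
    else:
        path.write_text("".join(f"{g}\n" for g in genomes))


def all_genomes(N: int, topology: Topology = "circular",
                cap: int = DEFAULT_ENUMERATION_CAP) -> Iterator[Genome]:
    """Iterate over the full genotype space {0,1}**N."""
    if N > cap:
        raise ValueError(f"N={N} exceeds the exhaustive-enumeration cap {cap}")
    for bits in itertools.product((0, 1), repeat=N):
        yield Genome(bits, topology)
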