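"""NK fitness landscapes with adjacent or random epistatic neighbourhoods.

The fitness of a length-N binary genome is the mean of N component
functions, ``f(x) = (1/N) sum_i f_i(x_i, x_{i1}, ..., x_{iK})``, where
each component depends on its own locus and K others (its epistatic
neighbourhood) and takes i.i.d. uniform values in [0, 1).  K tunes the
landscape's ruggedness, from the single-peaked additive case K = 0 to
the fully random landscape K = N - 1.

Component values are realised by a counter-free keyed generator:
per-landscape random 64-bit tables are drawn once from a seeded PCG64,
the (K+1)-bit substate of a component selects one table word per input
locus, the words are XOR-combined (tabulation hashing) and passed
through a splitmix64 finalizer to yield a uniform deviate.  This makes
evaluation a pure function of (seed, component, substate), works for K
up to N - 1 without storing 2**(K+1) values, and supports exact
incremental evaluation: flipping locus j XORs a precomputed delta word
into every component that reads locus j.

The optional ``table`` backend memoises the same keyed function into an
explicit (N, 2**(K+1)) value table for small K; both backends return
bit-identical fitness values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .genomes import Genome, MutationOp, OperatorKind, Topology, segment_indices

NeighbourhoodModel = Literal["adjacent", "random"]
NEIGHBOURHOOD_MODELS = ("adjacent", "random")

#: maximum number of memoised component values for the auto table backend
DEFAULT_TABLE_BUDGET = 1 << 22

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)


def _finalize(z: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer, vectorised over uint64 arrays (wrapping)."""
    z = z + _GOLDEN
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    return z ^ (z >> _U64(31))


def _u01(z: np.ndarray) -> np.ndarray:
    """Map uint64 words to uniform deviates in [0, 1) (53-bit mantissa)."""
    return (z >> _U64(11)).astype(np.float64) * (2.0**-53)


@dataclass(frozen=True)
class EpistasisMap:
    """Which loci feed each fitness component.

    ``loci`` has shape (N, K+1); row i lists the inputs of component i
    in key order, starting with locus i itself followed by its K
    neighbours (0-based).
    """

    model: NeighbourhoodModel
    loci: np.ndarray

    @property
    def N(self) -> int:
        return self.loci.shape[0]

    @property
    def K(self) -> int:
        return self.loci.shape[1] - 1

    def neighbours(self, i: int) -> np.ndarray:
        """The K loci (0-based) interacting with locus i, in stored order."""
        return self.loci[i, 1:]

    @staticmethod
    def adjacent(N: int, K: int) -> "EpistasisMap":
        """Neighbours of locus i are i+1, ..., i+K modulo N."""
        _check_NK(N, K)
        loci = (np.arange(N)[:, None] + np.arange(K + 1)[None, :]) % N
        return EpistasisMap("adjacent", loci)

    @staticmethod
    def random(N: int, K: int, rng: np.random.Generator) -> "EpistasisMap":
        """K distinct neighbours drawn uniformly from the other N-1 loci."""
        _check_NK(N, K)
        loci = np.empty((N, K + 1), dtype=np.int64)
        for i in range(N):
            others = np.delete(np.arange(N), i)
            loci[i, 0] = i
            loci[i, 1:] = rng.choice(others, size=K, replace=False)
        return EpistasisMap("random", loci)


def _check_NK(N: int, K: int) -> None:
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0 <= K <= N - 1:
        raise ValueError(f"K must be in [0, {N - 1}], got {K}")


class OpScan(NamedTuple):
    """Fitness of every operator application at one genome.

    One entry per application (so degenerate and invariant applications
    appear as often as they are performable); ``changed`` counts the
    loci each application actually flips (0 for invariant inversions,
    whose ``fitness`` equals the origin's exactly).
    """

    i: np.ndarray
    j: np.ndarray
    fitness: np.ndarray
    changed: np.ndarray


class NKLandscape:
    """A seeded NK fitness landscape.

    Parameters
    ----------
    N, K : int
        Genome length and epistatic coupling, 0 <= K <= N-1.
    model : {"adjacent", "random"}
        Epistatic neighbourhood scheme.
    seed : int
        Reproducibility seed; it derives both the random neighbourhood
        (for ``model="random"``) and the component-value tables.
    backend : {"auto", "keyed", "table"}
        "table" memoises all N * 2**(K+1) component values; "auto"
        picks "table" when that fits ``table_budget`` and "keyed"
        otherwise.  Values are identical across backends.
    """

    def __init__(
        self,
        N: int,
        K: int,
        model: NeighbourhoodModel = "adjacent",
        seed: int = 0,
        backend: Literal["auto", "keyed", "table"] = "auto",
        table_budget: int = DEFAULT_TABLE_BUDGET,
    ) -> None:
        _check_NK(N, K)
        if model not in NEIGHBOURHOOD_MODELS:
            raise ValueError(f"unknown neighbourhood model {model!r}")
        self.seed = int(seed)
        self.model = model
        nbr_ss, tab_ss = np.random.SeedSequence(self.seed).spawn(2)
        if model == "adjacent":
            self.epistasis = EpistasisMap.adjacent(N, K)
        else:
            self.epistasis = EpistasisMap.random(N, K, np.random.default_rng(nbr_ss))
        rng = np.random.Generator(np.random.PCG64(tab_ss))
        # one random word per (component, input position, input state)
        self._table = rng.integers(
            0, np.iinfo(np.uint64).max, size=(N, K + 1, 2), dtype=np.uint64,
            endpoint=True,
        )
        # flip_delta[j, c]: XOR-delta applied to component c's key when
        # locus j flips (zero where c does not read j)
        d = self._table[:, :, 0] ^ self._table[:, :, 1]
        fd = np.zeros((N, N), dtype=np.uint64)
        comp_idx = np.repeat(np.arange(N), K + 1)
        fd[self.epistasis.loci.ravel(), comp_idx] = d.ravel()
        self._flip_delta = fd
        if backend == "auto":
            backend = "table" if K <= 25 and N * 2 ** (K + 1) <= table_budget else "keyed"
        if backend not in ("keyed", "table"):
            raise ValueError(f"unknown backend {backend!r}")
        self.backend = backend
        self._value_table: np.ndarray | None = None
        if backend == "table":
            if N * 2 ** (K + 1) > table_budget:
                raise ValueError(
                    f"table backend needs {N * 2 ** (K + 1)} values, "
                    f"budget is {table_budget}"
                )
            states = np.arange(2 ** (K + 1), dtype=np.uint64)
            # bit t of a packed substate is the state of input position t
            bits = (states[None, :, None] >> np.arange(K + 1, dtype=np.uint64)) & _U64(1)
            sel = np.where(
                bits.astype(bool),
                self._table[:, None, :, 1],
                self._table[:, None, :, 0],
            )
            keys = np.bitwise_xor.reduce(sel, axis=2)
            self._value_table = _u01(_finalize(keys))

    # -- basic geometry ----------------------------------------------------

    @property
    def N(self) -> int:
        return self.epistasis.N

    @property
    def K(self) -> int:
        return self.epistasis.K

    # -- evaluation --------------------------------------------------------

    def _as_bits(self, g: "Genome | np.ndarray") -> np.ndarray:
        bits = g.to_array() if isinstance(g, Genome) else np.asarray(g, dtype=np.uint8)
        if bits.shape != (self.N,):
            raise ValueError(f"genome length {bits.shape} does not match N={self.N}")
        return bits

    def component_keys(self, g: "Genome | np.ndarray") -> np.ndarray:
        """uint64 tabulation key per component (the incremental state)."""
        bits = self._as_bits(g)
        B = bits[self.epistasis.loci]
        sel = np.where(B.astype(bool), self._table[:, :, 1], self._table[:, :, 0])
        return np.bitwise_xor.reduce(sel, axis=1)

    def fitness_from_keys(self, keys: np.ndarray) -> float:
        return float(_u01(_finalize(keys)).mean())

    def flip_keys(self, keys: np.ndarray, flips: np.ndarray) -> np.ndarray:
        """Component keys after flipping the (0-based) loci in ``flips``."""
        if len(flips) == 0:
            return keys
        return keys ^ np.bitwise_xor.reduce(self._flip_delta[flips], axis=0)

    def component_values(self, g: "Genome | np.ndarray") -> np.ndarray:
        """The N component fitness values f_i in [0, 1)."""
        if self._value_table is not None:
            bits = self._as_bits(g)
            B = bits[self.epistasis.loci].astype(np.uint64)
            state = np.bitwise_or.reduce(
                B << np.arange(self.K + 1, dtype=np.uint64)[None, :], axis=1
            )
            return self._value_table[np.arange(self.N), state]
        return _u01(_finalize(self.component_keys(g)))

    def fitness(self, g: "Genome | np.ndarray") -> float:
        """Total fitness f(x) in [0, 1): the mean of the N components."""
        return float(self.component_values(g).mean())

    # -- incremental evaluation -------------------------------------------

    def op_flip_loci(
        self,
        bits: np.ndarray,
        i: int,
        j: int,
        kind: OperatorKind,
        topology: Topology = "circular",
    ) -> np.ndarray:
        """0-based loci whose value changes under the operator (i, j).

        For an inversion, position p of the segment changes iff the
        current bit at p equals the bit at the mirrored position (the
        incoming value is the complement of the mirror).  Applying the
        operator is then exactly flipping this locus set.
        """
        if kind == "point":
            return np.array([i - 1])
        idx = segment_indices(self.N, i, j, topology)
        seg = bits[idx]
        return idx[seg == seg[::-1]]

    def fitness_delta(self, g: "Genome | np.ndarray", op: MutationOp,
                      topology: Topology | None = None) -> float:
        """f(mutant) - f(g), recomputing only the affected components."""
        bits = self._as_bits(g)
        if topology is None:
            topology = g.topology if isinstance(g, Genome) else "circular"
        keys = self.component_keys(bits)
        f = self.fitness_from_keys(keys)
        flips = self.op_flip_loci(bits, op.i, op.j, op.kind, topology)
        if len(flips) == 0:
            return 0.0
        return self.fitness_from_keys(self.flip_keys(keys, flips)) - f

    def op_scan(
        self,
        g: "Genome | np.ndarray",
        kind: OperatorKind,
        topology: Topology = "circular",
        max_segment: int | None = None,
        keys: np.ndarray | None = None,
    ) -> OpScan:
        """Mutant fitness for *every* operator application at ``g``.

        The scan enumerates applications (N for point mutations, N*s for
        circular inversions with segment cap s, triangular counts for
        linear genomes) and returns each mutant's exact total fitness,
        computed incrementally from XOR deltas.
        """
        bits = self._as_bits(g)
        if isinstance(g, Genome):
            topology = g.topology
        N = self.N
        if keys is None:
            keys = self.component_keys(bits)
        if kind == "point":
            new_keys = keys[None, :] ^ self._flip_delta
            ii = np.arange(1, N + 1)
            return OpScan(
                i=ii,
                j=ii.copy(),
                fitness=_u01(_finalize(new_keys)).mean(axis=1),
                changed=np.ones(N, dtype=np.int64),
            )
        s = N if max_segment is None else max_segment
        if not 1 <= s <= N:
            raise ValueError(f"max_segment must be in [1, {N}], got {s}")
        zero = _U64(0)
        parts_i, parts_j, parts_f, parts_c = [], [], [], []
        for L in range(1, s + 1):
            if topology == "circular":
                starts = np.arange(N)
                idx = (starts[:, None] + np.arange(L)[None, :]) % N
            else:
                starts = np.arange(N - L + 1)
                idx = starts[:, None] + np.arange(L)[None, :]
            seg = bits[idx]
            ch = seg == seg[:, ::-1]
            delta = np.bitwise_xor.reduce(
                np.where(ch[:, :, None], self._flip_delta[idx], zero), axis=1
            )
            parts_i.append(starts + 1)
            parts_j.append(idx[:, -1] + 1)
            parts_f.append(_u01(_finalize(keys[None, :] ^ delta)).mean(axis=1))
            parts_c.append(ch.sum(axis=1))
        return OpScan(
            i=np.concatenate(parts_i),
            j=np.concatenate(parts_j),
            fitness=np.concatenate(parts_f),
            changed=np.concatenate(parts_c),
        )

    # -- serialisation -----------------------------------------------------

    def spec_dict(self) -> dict:
        return {
            "N": self.N,
            "K": self.K,
            "model": self.model,
            "seed": self.seed,
            "backend": self.backend,
        }

    def to_json(self) -> str:
        return json.dumps(self.spec_dict())

    @classmethod
    def from_json(cls, s: str) -> "NKLandscape":
        return cls(**json.loads(s))

    def __repr__(self) -> str:
        return (
            f"NKLandscape(N={self.N}, K={self.K}, model={self.model!r}, "
            f"seed={self.seed}, backend={self.backend!r})"
        )


def make_landscape(
    N: int,
    K: int,
    model: NeighbourhoodModel = "adjacent",
    seed: int = 0,
    backend: Literal["auto", "keyed", "table"] = "auto",
) -> NKLandscape:
    """Construct a reproducible NK landscape (see :class:`NKLandscape`)."""
    return NKLandscape(N, K, model=model, seed=seed, backend=backend)


def total_fitness(landscape: NKLandscape, g: "Genome | np.ndarray") -> float:
    """Eq.-style functional alias for ``landscape.fitness(g)``."""
    return landscape.fitness(g)
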