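"""SSWM adaptive walks and the mean-final-fitness experiment.

In the strong-selection weak-mutation regime a monomorphic population
is a single genotype that sequentially fixes strictly beneficial
mutations: operator applications are proposed uniformly at random
(loci drawn from a PRNG) and a proposal is accepted iff the mutant is
strictly fitter.  The walk ends at a certified local optimum, i.e. a
genotype all of whose accessible mutants have strictly lower fitness,
verified by an exhaustive sweep over every operator application.

Rather than waiting for random proposals to exhaust a near-optimal
genotype, the walk interleaves proposal batches with exhaustive sweeps:
when a batch produces no acceptance, all applications are scanned and,
if strictly fitter mutants exist, one is chosen uniformly among the
fitter *applications*.  Conditioned on acceptance, a uniform random
proposal is itself uniform over the fitter applications, so this
fallback leaves the walk's distribution unchanged while making
termination sound and fast.  The final sweep that finds no fitter
application doubles as the local-optimum certificate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genomes import Genome, MutationOp, OperatorKind, Topology
from .landscapes import NeighbourhoodModel, NKLandscape

_MODEL_INDEX = {"adjacent": 0, "random": 1}
_PROPOSAL_CHUNK = 128


@dataclass(frozen=True)
class WalkConfig:
    """Configuration of one SSWM adaptive walk.

    ``max_segment`` is the optional inversion size cap s <= N (s = 1
    makes inversions behave as point mutations).  ``proposal_batch`` is
    the number of random proposals tried per step before falling back
    to an exhaustive sweep; it affects speed only, not the walk's
    distribution.  ``max_steps`` is a safety bound on accepted steps.
    """

    kind: OperatorKind = "point"
    topology: Topology = "circular"
    max_segment: int | None = None
    proposal_batch: int | None = None
    max_steps: int = 1_000_000
    record_trajectory: bool = True


@dataclass(frozen=True)
class WalkResult:
    """One SSWM trajectory, ending at a (certified) local optimum."""

    start: Genome
    steps: tuple[tuple[MutationOp, float], ...]
    final: Genome
    final_fitness: float
    certified: bool
    n_proposals: int
    n_sweeps: int

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def certify_local_optimum(
    landscape: NKLandscape,
    g: "Genome | np.ndarray",
    kind: OperatorKind,
    topology: Topology | None = None,
    max_segment: int | None = None,
) -> bool:
    """True iff every accessible mutant of g is strictly less fit.

    Invariant inversions (mutant == g) are not accessible mutants and
    are ignored; all remaining applications are evaluated exhaustively.
    """
    if topology is None:
        topology = g.topology if isinstance(g, Genome) else "circular"
    f = landscape.fitness(g)
    scan = landscape.op_scan(g, kind, topology, max_segment)
    real = scan.changed > 0
    return bool(np.all(scan.fitness[real] < f))


class _ProposalDrawer:
    """Uniform draws over the operator-application space."""

    def __init__(self, N: int, cfg: WalkConfig):
        self.N = N
        self.kind = cfg.kind
        s = N if cfg.max_segment is None else cfg.max_segment
        if not 1 <= s <= N:
            raise ValueError(f"max_segment must be in [1, {N}], got {cfg.max_segment}")
        self.s = s
        if cfg.kind == "point":
            self.num_ops = N
        elif cfg.topology == "circular":
            self.num_ops = N * s
        else:
            # linear: pairs i <= j with segment length <= s
            pairs = [
                (i, j)
                for i in range(1, N + 1)
                for j in range(i, min(i + s - 1, N) + 1)
            ]
            self._pairs = np.array(pairs)
            self.num_ops = len(pairs)
        self.topology = cfg.topology

    def draw(self, rng: np.random.Generator, k: int) -> tuple[np.ndarray, np.ndarray]:
        """k uniform (i, j) locus pairs (1-based)."""
        if self.kind == "point":
            ii = rng.integers(1, self.N + 1, size=k)
            return ii, ii
        if self.topology == "circular":
            ii = rng.integers(1, self.N + 1, size=k)
            Ls = rng.integers(1, self.s + 1, size=k)
            jj = (ii - 1 + Ls - 1) % self.N + 1
            return ii, jj
        picks = self._pairs[rng.integers(0, self.num_ops, size=k)]
        return picks[:, 0], picks[:, 1]


def sswm_walk(
    landscape: NKLandscape,
    config: WalkConfig,
    start: "Genome | np.ndarray | None" = None,
    seed: "int | np.random.SeedSequence | None" = None,
) -> WalkResult:
    """Run one SSWM adaptive walk to a certified local optimum.

    ``start`` defaults to a uniform random genome drawn from ``seed``;
    identical (landscape seed, walk seed, config) give identical
    trajectories.
    """
    N = landscape.N
    rng = np.random.default_rng(seed)
    if start is None:
        bits = rng.integers(0, 2, size=N, dtype=np.uint8)
    elif isinstance(start, Genome):
        if start.topology != config.topology:
            raise ValueError(
                f"start topology {start.topology!r} != config topology "
                f"{config.topology!r}"
            )
        bits = start.to_array()
    else:
        bits = np.asarray(start, dtype=np.uint8).copy()
    if bits.shape != (N,):
        raise ValueError(f"start genome length {bits.shape} does not match N={N}")
    start_genome = Genome.from_array(bits, config.topology)

    drawer = _ProposalDrawer(N, config)
    batch = config.proposal_batch if config.proposal_batch is not None else drawer.num_ops

    keys = landscape.component_keys(bits)
    f = landscape.fitness_from_keys(keys)
    steps: list[tuple[MutationOp, float]] = []
    n_proposals = 0
    n_sweeps = 0
    certified = False
    n_accepted = 0

    while True:
        if n_accepted > config.max_steps:
            raise RuntimeError(
                f"walk exceeded max_steps={config.max_steps} accepted steps"
            )
        accepted: tuple[int, int, np.ndarray, np.ndarray, float] | None = None
        drawn = 0
        while drawn < batch and accepted is None:
            k = min(_PROPOSAL_CHUNK, batch - drawn)
            ii, jj = drawer.draw(rng, k)
            for i, j in zip(ii, jj):
                n_proposals += 1
                flips = landscape.op_flip_loci(bits, int(i), int(j), config.kind,
                                               config.topology)
                if len(flips) == 0:
                    continue  # invariant inversion: a wasted proposal
                new_keys = landscape.flip_keys(keys, flips)
                f_new = landscape.fitness_from_keys(new_keys)
                if f_new > f:
                    accepted = (int(i), int(j), flips, new_keys, f_new)
                    break
            drawn += k
        if accepted is None:
            # exhaustive sweep: certification, or a uniform fitter pick
            n_sweeps += 1
            scan = landscape.op_scan(bits, config.kind, config.topology,
                                     config.max_segment, keys=keys)
            fitter = np.flatnonzero(scan.fitness > f)
            if fitter.size == 0:
                real = scan.changed > 0
                certified = bool(np.all(scan.fitness[real] < f))
                break
            pick = int(fitter[rng.integers(fitter.size)])
            i, j = int(scan.i[pick]), int(scan.j[pick])
            flips = landscape.op_flip_loci(bits, i, j, config.kind, config.topology)
            accepted = (i, j, flips, landscape.flip_keys(keys, flips),
                        float(scan.fitness[pick]))
        i, j, flips, keys, f = accepted
        bits[flips] ^= 1
        n_accepted += 1
        if config.record_trajectory:
            steps.append((MutationOp(config.kind, i, j), f))

    return WalkResult(
        start=start_genome,
        steps=tuple(steps),
        final=Genome.from_array(bits, config.topology),
        final_fitness=f,
        certified=certified,
        n_proposals=n_proposals,
        n_sweeps=n_sweeps,
    )


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-(K, model, operator) aggregates of replicate adaptive walks.

    ``table`` has one row per condition with columns
    N, K, model, operator, n, mean_f, se_f.
    """

    table: pd.DataFrame

    def mean_fitness(self, K: int, model: str, operator: str) -> float:
        t = self.table
        row = t[(t.K == K) & (t.model == model) & (t.operator == operator)]
        if len(row) != 1:
            raise KeyError(f"no unique row for K={K}, {model}, {operator}")
        return float(row.mean_f.iloc[0])

    def delta_f(self) -> pd.DataFrame:
        """Fitness gain of inversions over point mutations per (model, K).

        delta_f = <f_I>_K - <f_P>_K, with the standard error combined
        in quadrature.
        """
        t = self.table
        wide = t.pivot_table(index=["model", "K"], columns="operator",
                             values=["mean_f", "se_f"])
        out = pd.DataFrame(
            {
                "delta_f": wide[("mean_f", "inversion")] - wide[("mean_f", "point")],
                "se": np.hypot(wide[("se_f", "inversion")], wide[("se_f", "point")]),
            }
        ).reset_index()
        return out

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def replicate_seeds(
    master_seed: int, model: NeighbourhoodModel, K: int, replicate: int, n_words: int
) -> np.ndarray:
    """Deterministic per-replicate seed words (paired across operators).

    Words are derived from (master seed, model, K, replicate) so the
    landscape and start genome of replicate r are shared by the point
    and inversion arms, and redrawn for each (K, model).
    """
    ss = np.random.SeedSequence(
        int(master_seed), spawn_key=(_MODEL_INDEX[model], int(K), int(replicate))
    )
    return ss.generate_state(n_words)


def run_experiment(
    N: int,
    Ks: Sequence[int],
    models: Sequence[NeighbourhoodModel] = ("adjacent", "random"),
    operators: Sequence[OperatorKind] = ("point", "inversion"),
    n: int = 100,
    seed: int = 0,
    topology: Topology = "circular",
    max_segment: int | None = None,
    config: WalkConfig | None = None,
) -> ExperimentSummary:
    """Replicated paired adaptive-walk experiment (the <f_v>_K curves).

    For each (model, K) and replicate r, one landscape and one random
    start genome are drawn and shared across operators; each operator
    then runs an independent SSWM walk.  Means and standard errors of
    the final (local-optimum) fitness are aggregated per condition.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = config or WalkConfig()
    rows = []
    for model in models:
        for K in Ks:
            finals: dict[str, list[float]] = {op: [] for op in operators}
            for r in range(n):
                words = replicate_seeds(seed, model, K, r, 2 + len(operators))
                lsc = NKLandscape(N, K, model=model, seed=int(words[0] % 2**31))
                start = np.random.default_rng(int(words[1])).integers(
                    0, 2, size=N, dtype=np.uint8
                )
                for oi, op in enumerate(operators):
                    cfg = replace(base, kind=op, topology=topology,
                                  max_segment=max_segment if op == "inversion" else None,
                                  record_trajectory=False)
                    res = sswm_walk(lsc, cfg, start=start, seed=int(words[2 + oi]))
                    finals[op].append(res.final_fitness)
            for op in operators:
                arr = np.asarray(finals[op])
                rows.append(
                    {
                        "N": N,
                        "K": K,
                        "model": model,
                        "operator": op,
                        "n": n,
                        "mean_f": arr.mean(),
                        "se_f": arr.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                    }
                )
    return ExperimentSummary(table=pd.DataFrame(rows))
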