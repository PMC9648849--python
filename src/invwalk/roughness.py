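"""Local landscape roughness under an operator's one-step neighbourhood.

The local roughness of genotype x is the root-mean-square fitness
change over *all* operator applications at x — the edge set of the
mutation multigraph, not the set of distinct mutants.  Degenerate
inversions therefore weight their shared mutant once per application,
and invariant inversions contribute zero terms while remaining in the
denominator (N**2 for circular inversions, N for point mutations).
It measures deviation from fitness additivity: on an additive (K = 0)
landscape seen through point mutations it stays small and grows
roughly linearly with K, while inversions see a rougher surface at
every K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomes import Genome, OperatorKind, Topology
from .landscapes import NeighbourhoodModel, NKLandscape
from .walks import replicate_seeds


def local_roughness(
    landscape: NKLandscape,
    g: "Genome | np.ndarray",
    kind: OperatorKind,
    topology: Topology | None = None,
    max_segment: int | None = None,
) -> float:
    """RMS fitness variation over every operator application at g."""
    if topology is None:
        topology = g.topology if isinstance(g, Genome) else "circular"
    f = landscape.fitness(g)
    scan = landscape.op_scan(g, kind, topology, max_segment)
    return float(np.sqrt(np.mean((f - scan.fitness) ** 2)))


@dataclass(frozen=True)
class RoughnessSummary:
    """Mean local roughness per (K, model, operator) condition.

    ``table`` columns: N, K, model, operator, n_landscapes, n_genomes,
    mean_xi, se_xi.  The standard error is across landscape instances
    (each instance contributing the mean over its sampled genomes).
    """

    table: pd.DataFrame

    def mean_xi(self, K: int, model: str, operator: str) -> float:
        t = self.table
        row = t[(t.K == K) & (t.model == model) & (t.operator == operator)]
        if len(row) != 1:
            raise KeyError(f"no unique row for K={K}, {model}, {operator}")
        return float(row.mean_xi.iloc[0])

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def mean_roughness(
    N: int,
    Ks: Sequence[int],
    models: Sequence[NeighbourhoodModel] = ("adjacent", "random"),
    kinds: Sequence[OperatorKind] = ("point", "inversion"),
    n_landscapes: int = 100,
    n_genomes: int = 10,
    seed: int = 0,
    topology: Topology = "circular",
    max_segment: int | None = None,
) -> RoughnessSummary:
    """Average local roughness over landscape instances and genomes.

    For each (model, K) condition, ``n_landscapes`` seeded landscapes
    are drawn; on each, roughness is averaged over ``n_genomes``
    uniformly sampled genomes (the genotype space cannot be enumerated
    at realistic N).  Landscape instances and sample genomes are shared
    across operator kinds so the point/inversion contrast is paired.
    """
    rows = []
    for model in models:
        for K in Ks:
            per_kind: dict[str, list[float]] = {k: [] for k in kinds}
            for inst in range(n_landscapes):
                words = replicate_seeds(seed, model, K, inst, 2)
                lsc = NKLandscape(N, K, model=model, seed=int(words[0] % 2**31))
                grng = np.random.default_rng(int(words[1]))
                genomes = grng.integers(0, 2, size=(n_genomes, N), dtype=np.uint8)
                for kind in kinds:
                    xi = [
                        local_roughness(lsc, gbits, kind, topology,
                                        max_segment if kind == "inversion" else None)
                        for gbits in genomes
                    ]
                    per_kind[kind].append(float(np.mean(xi)))
            for kind in kinds:
                arr = np.asarray(per_kind[kind])
                rows.append(
                    {
                        "N": N,
                        "K": K,
                        "model": model,
                        "operator": kind,
                        "n_landscapes": n_landscapes,
                        "n_genomes": n_genomes,
                        "mean_xi": arr.mean(),
                        "se_xi": arr.std(ddof=1) / np.sqrt(n_landscapes)
                        if n_landscapes > 1
                        else np.nan,
                    }
                )
    return RoughnessSummary(table=pd.DataFrame(rows))
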