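"""Synthetic bipartite network generators and published reference records.

Generators cover the wiring archetypes used throughout the package's
analyses: the bipartite Erdos-Renyi null (independent links at a fixed
density), an exponential configuration model (geometric targets-per-
controller, partners drawn uniformly) emulating naturally occurring
controller networks, and the degenerate one-to-one / one-to-many layouts.
All are reproducible: the same seed yields byte-identical edge lists.

``table1_reference`` carries the published summary statistics of ten real
controller-target networks (human/yeast/E. coli transcription-factor,
kinase and miRNA networks from interaction databases and the literature,
plus a kinase-inhibitor panel); these parameterize generators and serve as
reference inputs for aggregate checks, not as downloadable data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .degree import GeometricModel
from .network import BipartiteNetwork

__all__ = [
    "EnsembleSpec",
    "Table1Record",
    "TABLE1",
    "DATABASE_NETWORKS",
    "LITERATURE_NETWORKS",
    "bipartite_er",
    "exponential_configuration",
    "one_to_one",
    "one_to_many",
    "table1_reference",
]


def _cname(i: int) -> str:
    return f"c{i:05d}"


def _tname(j: int) -> str:
    return f"t{j:05d}"


def bipartite_er(M: int, N: int, D: float, seed: int = 0, name: str = "er") -> BipartiteNetwork:
    """Bipartite Erdos-Renyi graph: each of the M*N links present
    independently with probability D."""
    if not (0 <= D <= 1):
        raise ValueError("D must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((M, N)) < D
    rows, cols = np.nonzero(mask)
    links = [(_cname(i), _tname(j)) for i, j in zip(rows.tolist(), cols.tolist())]
    return BipartiteNetwork(
        [_cname(i) for i in range(M)], [_tname(j) for j in range(N)], links, name=name
    )


def exponential_configuration(
    M: int, N: int, mean_kout: float, seed: int = 0, name: str = "expcfg"
) -> BipartiteNetwork:
    """Geometric out-degrees, partners uniform: a 'biological-like' wiring.

    Each controller draws k_out from a geometric with the given mean
    (capped at N) and connects to that many distinct uniformly chosen
    targets; in-degrees then follow a binomial mixture whose mean satisfies
    link conservation <k_in> = L/N.
    """
    if mean_kout < 1:
        raise ValueError("mean_kout must be >= 1")
    model = GeometricModel.from_mean(mean_kout)
    rng = np.random.default_rng(seed)
    links = []
    for i in range(M):
        while True:
            k = model.ppf(float(rng.uniform(np.finfo(float).tiny, 1.0)))
            if k <= N:
                break
        for j in rng.choice(N, size=k, replace=False):
            links.append((_cname(i), _tname(int(j))))
    return BipartiteNetwork(
        [_cname(i) for i in range(M)], [_tname(j) for j in range(N)], links, name=name
    )


def one_to_one(n: int, name: str = "one_to_one") -> BipartiteNetwork:
    """Identity wiring: controller i -> target i, M = N = n."""
    links = [(_cname(i), _tname(i)) for i in range(n)]
    return BipartiteNetwork(
        [_cname(i) for i in range(n)], [_tname(j) for j in range(n)], links, name=name
    )


def one_to_many(M: int, N: int, name: str = "one_to_many") -> BipartiteNetwork:
    """Partition wiring: targets split into M blocks, one controller each
    (every target has exactly one incoming link)."""
    if N < M:
        raise ValueError("one_to_many requires N >= M")
    bounds = np.linspace(0, N, M + 1).astype(int)
    links = []
    for i in range(M):
        for j in range(bounds[i], bounds[i + 1]):
            links.append((_cname(i), _tname(j)))
    return BipartiteNetwork(
        [_cname(i) for i in range(M)], [_tname(j) for j in range(N)], links, name=name
    )


@dataclass(frozen=True)
class EnsembleSpec:
    """A reproducible family of generated networks."""

    M: int
    N: int
    generator: str = "bipartite_er"
    param: float = 0.1  # density for ER, mean k_out for the configuration model
    n_replicates: int = 1
    seed: int = 0

    def generate(self) -> Iterator[BipartiteNetwork]:
        rng = np.random.default_rng(self.seed)
        for r in range(self.n_replicates):
            sub = int(rng.integers(2**31))
            if self.generator == "bipartite_er":
                yield bipartite_er(self.M, self.N, self.param, seed=sub, name=f"er_{r}")
            elif self.generator == "exponential_configuration":
                yield exponential_configuration(
                    self.M, self.N, self.param, seed=sub, name=f"expcfg_{r}"
                )
            elif self.generator == "one_to_one":
                yield one_to_one(self.M, name=f"one_to_one_{r}")
            elif self.generator == "one_to_many":
                yield one_to_many(self.M, self.N, name=f"one_to_many_{r}")
            else:
                raise ValueError(f"unknown generator {self.generator!r}")


@dataclass(frozen=True)
class Table1Record:
    """Published summary row for one real controller-target network.

    Percentages are stored as printed (percent units); fields absent from
    the publication are None.  ``source`` distinguishes literature node
    counts from database-derived networks and the drug panel.
    """

    label: str
    M: int
    N: int
    mn_pct: float
    mean_k_out: float | None
    mean_k_in: float | None
    density_pct: float | None
    stc_pct: float | None
    po_pct: float | None
    source: str


TABLE1: dict[str, Table1Record] = {
    r.label: r
    for r in [
        Table1Record("human_TF_lit", 1800, 20500, 8.8, None, None, None, None, None, "literature"),
        Table1Record("human_kinase_lit", 518, 6150, 8.4, None, None, None, None, None, "literature"),
        Table1Record("human_miRNA_lit", 940, 11890, 7.9, None, None, None, None, None, "literature"),
        Table1Record("human_TF", 389, 9284, 4.2, 181.0, 7.6, 1.9, 98.0, 4.5, "database"),
        Table1Record("human_kinase", 264, 988, 26.7, 8.9, 2.4, 0.9, 73.0, 7.1, "database"),
        Table1Record("human_miRNA", 153, 9448, 1.6, 359.0, 5.8, 3.5, 95.0, 7.1, "database"),
        Table1Record("yeast_TF", 186, 6297, 3.0, 229.0, 6.8, 3.6, 98.0, 6.3, "database"),
        Table1Record("yeast_kinase", 88, 1341, 6.6, 46.0, 3.0, 3.5, 85.0, 8.3, "database"),
        Table1Record("ecoli_TF", 169, 1495, 11.3, 20.0, 2.3, 1.3, 74.0, 1.1, "database"),
        Table1Record("drug_KI", 38, 316, 12.0, 78.8, 9.48, 25.0, 100.0, 33.8, "drug"),
    ]
}

DATABASE_NETWORKS = (
    "human_TF",
    "human_kinase",
    "human_miRNA",
    "yeast_TF",
    "yeast_kinase",
    "ecoli_TF",
)
LITERATURE_NETWORKS = ("human_TF_lit", "human_kinase_lit", "human_miRNA_lit")


def table1_reference(label: str) -> Table1Record:
    """Published parameter record for one of the ten reference networks."""
    try:
        return TABLE1[label]
    except KeyError:
        raise ValueError(
            f"unknown network label {label!r}; choose from {sorted(TABLE1)}"
        ) from None
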