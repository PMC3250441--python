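"""Network-wide statistics for bipartite controller-target networks.

Implements the statistic bundle used to compare control networks across
systems: node counts and their ratio, link density, mean links per node,
the two overlap measures (shared targets per controller and pairwise
overlap of target sets), giant-component fraction and the fraction of
dual-role nodes.

Two identities tie the link-level quantities together.  With M controllers,
N targets and L links,

    D = L / (M N) = <k_in> / M = <k_out> / N          (density identity)
    M / N = <k_in> / <k_out>                          (ratio identity)

both exact consequences of link conservation sum(k_out) = sum(k_in) = L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import BipartiteNetwork, degree_sequences

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkSummary",
    "summarize",
    "shared_targets_per_controller",
    "pairwise_overlap",
    "connected_components",
    "dual_role_fraction",
    "implied_mean_kin",
    "implied_mean_kout",
    "mn_ratio_from_degrees",
]


@dataclass(frozen=True)
class NetworkSummary:
    """One-network statistic bundle (the standard comparison table row)."""

    name: str
    M: int
    N: int
    L: int
    mn_ratio: float
    density: float
    mean_k_in: float
    mean_k_out: float
    stc_mean: float
    po_mean: float
    giant_fraction: float
    dual_role_fraction: float

    def as_row(self) -> dict:
        """Row with the comparison-table column names; percentages to one
        decimal place."""
        return {
            "Network": self.name,
            "Controllers (M)": self.M,
            "Targets (N)": self.N,
            "M/N (%)": round(100 * self.mn_ratio, 1),
            "Outgoing links from controllers (mean k_out)": round(self.mean_k_out, 2),
            "Incoming links per target (mean k_in)": round(self.mean_k_in, 2),
            "Link density (%)": round(100 * self.density, 1),
            "Shared targets per controller (mean %)": round(100 * self.stc_mean, 1),
            "Pairwise overlap of targets (mean %)": round(100 * self.po_mean, 1),
            "Giant component (%)": round(100 * self.giant_fraction, 1),
            "Dual-role targets (%)": round(100 * self.dual_role_fraction, 1),
        }


def implied_mean_kin(M: int, N: int, mean_k_out: float) -> float:
    """<k_in> implied by link conservation: <k_in> = M <k_out> / N."""
    return M * mean_k_out / N


def implied_mean_kout(M: int, N: int, mean_k_in: float) -> float:
    """<k_out> implied by link conservation: <k_out> = N <k_in> / M."""
    return N * mean_k_in / M


def mn_ratio_from_degrees(mean_k_in: float, mean_k_out: float) -> float:
    """Controller/target ratio from mean link counts: M/N = <k_in>/<k_out>."""
    if mean_k_out <= 0:
        raise ValueError("mean_k_out must be positive")
    return mean_k_in / mean_k_out


def shared_targets_per_controller(net: BipartiteNetwork) -> list[float]:
    """Fraction of each controller's targets also hit by another controller.

    Controllers with zero targets are excluded (and logged): the fraction is
    undefined for an empty target set.  Returns one value per scored
    controller, in controller order.
    """
    nb = net.out_neighbors()
    kin: dict[str, int] = {t: 0 for t in net.targets}
    for c, t in net.links:
        kin[t] += 1
    vals: list[float] = []
    skipped = 0
    for c in net.controllers:
        tset = nb[c]
        if not tset:
            skipped += 1
            continue
        shared = sum(1 for t in tset if kin[t] >= 2)
        vals.append(shared / len(tset))
    if skipped:
        logger.info("shared_targets_per_controller: skipped %d zero-target controllers", skipped)
    return vals


def pairwise_overlap(net: BipartiteNetwork) -> np.ndarray:
    """Directional target-set overlap matrix over ordered controller pairs.

    Entry (i, j) is |T(x_i) & T(x_j)| / |T(x_i)|; the matrix is generally
    asymmetric.  Diagonal entries are NaN (a controller is not paired with
    itself); rows for zero-target controllers are NaN and excluded from
    means downstream.
    """
    ctrl = [c for c in net.controllers]
    nb = net.out_neighbors()
    m = len(ctrl)
    out = np.full((m, m), np.nan)
    sets = [nb[c] for c in ctrl]
    for i in range(m):
        if not sets[i]:
            continue
        for j in range(m):
            if i == j:
                continue
            out[i, j] = len(sets[i] & sets[j]) / len(sets[i])
    return out


def po_mean(net: BipartiteNetwork, *, ordered: bool = True) -> float:
    """Mean pairwise overlap.

    ``ordered=True`` (default) averages the directional measure over all
    ordered pairs; ``ordered=False`` averages the symmetrized value
    (mean of the two directions) over unordered pairs, which gives the same
    number but is exposed for comparability with symmetric conventions.
    """
    mat = pairwise_overlap(net)
    vals = mat[~np.isnan(mat)]
    if vals.size == 0:
        return 0.0
    if ordered:
        return float(vals.mean())
    m = mat.shape[0]
    acc = []
    for i in range(m):
        for j in range(i + 1, m):
            a, b = mat[i, j], mat[j, i]
            if np.isnan(a) or np.isnan(b):
                continue
            acc.append(0.5 * (a + b))
    return float(np.mean(acc)) if acc else 0.0


def connected_components(net: BipartiteNetwork) -> tuple[list[set[str]], float]:
    """Components of the undirected bipartite graph and the giant fraction.

    Dual-role nodes are one node of the graph, so the denominator is the
    size of the union of the two layers.
    """
    g = nx.Graph()
    g.add_nodes_from(net.controllers)
    g.add_nodes_from(net.targets)
    g.add_edges_from(net.links)
    comps = sorted((set(c) for c in nx.connected_components(g)), key=len, reverse=True)
    n_nodes = g.number_of_nodes()
    giant = len(comps[0]) / n_nodes if comps else 0.0
    return comps, giant


def dual_role_fraction(net: BipartiteNetwork) -> float:
    """Fraction of targets that also appear in the controller layer."""
    return len(set(net.targets) & set(net.controllers)) / net.N


def summarize(net: BipartiteNetwork, *, ordered_pairs: bool = True) -> NetworkSummary:
    """Compute the full statistic bundle for one network.

    Raises if either layer is empty.  The density and ratio identities hold
    by construction (they are arithmetic consequences of L, M, N).
    """
    if net.M == 0 or net.N == 0:
        raise ValueError("summarize requires at least one controller and one target")
    kout, kin = degree_sequences(net)
    stc = shared_targets_per_controller(net)
    _, giant = connected_components(net)
    return NetworkSummary(
        name=net.name,
        M=net.M,
        N=net.N,
        L=net.L,
        mn_ratio=net.M / net.N,
        density=net.density,
        mean_k_in=kin.mean,
        mean_k_out=kout.mean,
        stc_mean=float(np.mean(stc)) if stc else 0.0,
        po_mean=po_mean(net, ordered=ordered_pairs),
        giant_fraction=giant,
        dual_role_fraction=dual_role_fraction(net),
    )
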