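"""Bipartite controller-target network container and edge-list I/O.

A controller-target network is a directed bipartite graph: one layer of
controller nodes (transcription factors, miRNAs, kinases, drugs) and one
layer of target nodes (genes, transcripts, substrates, drug targets), with
every link pointing controller -> target.  A molecule may appear in both
layers (a kinase that is itself phosphorylated); the two roles are tracked
independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "DegreeSequence",
    "read_edge_list",
    "write_edge_list",
    "write_biadjacency_csv",
    "degree_sequences",
]


class EdgeListFormatError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """Directed bipartite graph of M controllers and N targets.

    Parameters
    ----------
    controllers, targets : sequence of str
        Node identifiers for each layer, in a stable order.  An identifier
        may occur in both layers (dual-role node).
    links : iterable of (controller, target) pairs
        Directed links; duplicates are collapsed.
    name : str
        Free-text label.
    """

    controllers: tuple[str, ...]
    targets: tuple[str, ...]
    links: frozenset[tuple[str, str]]
    name: str = ""

    def __init__(
        self,
        controllers: Iterable[str],
        targets: Iterable[str],
        links: Iterable[tuple[str, str]],
        name: str = "",
    ) -> None:
        ctrl = tuple(dict.fromkeys(str(c) for c in controllers))
        tgt = tuple(dict.fromkeys(str(t) for t in targets))
        lk = frozenset((str(c), str(t)) for c, t in links)
        cset, tset = set(ctrl), set(tgt)
        for c, t in lk:
            if c not in cset:
                raise ValueError(f"link source {c!r} is not a registered controller")
            if t not in tset:
                raise ValueError(f"link target {t!r} is not a registered target")
        object.__setattr__(self, "controllers", ctrl)
        object.__setattr__(self, "targets", tgt)
        object.__setattr__(self, "links", lk)
        object.__setattr__(self, "name", name)

    # -- counts ---------------------------------------------------------
    @property
    def M(self) -> int:
        """Number of controller nodes."""
        return len(self.controllers)

    @property
    def N(self) -> int:
        """Number of target nodes."""
        return len(self.targets)

    @property
    def L(self) -> int:
        """Number of directed links."""
        return len(self.links)

    @property
    def density(self) -> float:
        """Link density D = L / (M*N)."""
        return self.L / (self.M * self.N)

    # -- adjacency ------------------------------------------------------
    def targets_of(self, controller: str) -> frozenset[str]:
        return frozenset(t for c, t in self.links if c == controller)

    def controllers_of(self, target: str) -> frozenset[str]:
        return frozenset(c for c, t in self.links if t == target)

    def out_neighbors(self) -> dict[str, set[str]]:
        """Map controller -> set of its targets (all controllers present)."""
        nb: dict[str, set[str]] = {c: set() for c in self.controllers}
        for c, t in self.links:
            nb[c].add(t)
        return nb

    def in_neighbors(self) -> dict[str, set[str]]:
        """Map target -> set of its controllers (all targets present)."""
        nb: dict[str, set[str]] = {t: set() for t in self.targets}
        for c, t in self.links:
            nb[t].add(c)
        return nb

    def biadjacency(self):
        """Dense 0/1 matrix, rows = controllers, columns = targets, both in
        stored order."""
        import numpy as np

        ci = {c: i for i, c in enumerate(self.controllers)}
        tj = {t: j for j, t in enumerate(self.targets)}
        A = np.zeros((self.M, self.N), dtype=np.int8)
        for c, t in self.links:
            A[ci[c], tj[t]] = 1
        return A

    def induced_subnetwork(
        self, controllers: Sequence[str], name: str = ""
    ) -> "BipartiteNetwork":
        """Subnetwork on the given controllers and every target they hit."""
        keep = set(controllers)
        links = [(c, t) for c, t in self.links if c in keep]
        tgts = sorted({t for _, t in links})
        ordered = [c for c in self.controllers if c in keep]
        return BipartiteNetwork(ordered, tgts, links, name=name)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = f" {self.name!r}" if self.name else ""
        return f"<BipartiteNetwork{lab} M={self.M} N={self.N} L={self.L}>"


@dataclass(frozen=True)
class DegreeSequence:
    """Per-node link counts for one layer of a bipartite network.

    ``side`` is ``"out"`` for controller out-degrees (targets per
    controller, k_out) or ``"in"`` for target in-degrees (controllers per
    target, k_in).  Zero-degree nodes are included.
    """

    values: tuple[int, ...]
    side: str = "in"

    def __post_init__(self) -> None:
        if self.side not in ("in", "out"):
            raise ValueError("side must be 'in' or 'out'")
        if any(v < 0 for v in self.values):
            raise ValueError("degrees must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @property
    def total(self) -> int:
        return int(sum(self.values))

    @property
    def mean(self) -> float:
        if not self.values:
            raise ValueError("empty degree sequence has no mean")
        return self.total / len(self.values)

    def nonzero(self) -> "DegreeSequence":
        """Sequence restricted to k >= 1 (the support of the geometric fit)."""
        return DegreeSequence(tuple(v for v in self.values if v > 0), self.side)


def degree_sequences(net: BipartiteNetwork) -> tuple[DegreeSequence, DegreeSequence]:
    """Return (k_out per controller, k_in per target), zero-degree included."""
    kout = {c: 0 for c in net.controllers}
    kin = {t: 0 for t in net.targets}
    for c, t in net.links:
        kout[c] += 1
        kin[t] += 1
    return (
        DegreeSequence(tuple(kout[c] for c in net.controllers), "out"),
        DegreeSequence(tuple(kin[t] for t in net.targets), "in"),
    )


def read_edge_list(
    path: str | Path,
    *,
    sep: str = "\t",
    controller_col: int = 0,
    target_col: int = 1,
    comment: str = "#",
    name: str | None = None,
) -> BipartiteNetwork:
    """Read a delimited controller->target edge list.

    One link per row; lines starting with ``comment`` are skipped; duplicate
    rows are collapsed (the count is logged and stored on the returned
    network as ``read_edge_list.last_duplicates``).
    """
    path = Path(path)
    links: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    duplicates = 0
    ncol = max(controller_col, target_col) + 1
    with open(path) as fh:
        any_line = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            any_line = True
            parts = line.split(sep)
            if len(parts) < ncol:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected at least {ncol} columns, got {len(parts)}"
                )
            c = parts[controller_col].strip()
            t = parts[target_col].strip()
            if not c or not t:
                raise EdgeListFormatError(f"{path}:{lineno}: empty node identifier")
            pair = (c, t)
            if pair in seen:
                duplicates += 1
                continue
            seen.add(pair)
            links.append(pair)
    if not any_line:
        raise EdgeListFormatError(f"{path}: empty edge-list file")
    controllers = dict.fromkeys(c for c, _ in links)
    targets = dict.fromkeys(t for _, t in links)
    if duplicates:
        logger.info("read_edge_list(%s): collapsed %d duplicate rows", path, duplicates)
    read_edge_list.last_duplicates = duplicates  # type: ignore[attr-defined]
    return BipartiteNetwork(
        controllers, targets, links, name=name if name is not None else path.stem
    )


read_edge_list.last_duplicates = 0  # type: ignore[attr-defined]


def write_edge_list(net: BipartiteNetwork, path: str | Path, *, sep: str = "\t") -> None:
    """Write links sorted lexicographically (controller, then target) so the
    output is byte-stable for a given network."""
    path = Path(path)
    with open(path, "w") as fh:
        for c, t in sorted(net.links):
            fh.write(f"{c}{sep}{t}\n")


def write_biadjacency_csv(net: BipartiteNetwork, path: str | Path) -> None:
    """Export the 0/1 biadjacency matrix as CSV; rows are controllers and
    columns targets, each in lexicographic order."""
    import pandas as pd

    ctrl = sorted(net.controllers)
    tgt = sorted(net.targets)
    nb = net.out_neighbors()
    data = [[1 if t in nb[c] else 0 for t in tgt] for c in ctrl]
    pd.DataFrame(data, index=ctrl, columns=tgt).to_csv(path, index_label="controller")
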