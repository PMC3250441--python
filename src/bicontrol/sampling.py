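"""Simulated drug-target libraries and biomimetic subset selection.

A fully profiled inhibitor library is emulated as a bipartite graph whose
targets-per-compound (k_out) and compounds-per-target (k_in) marginals
follow prescribed distributions: degrees are drawn by inverse-transform
sampling of the model cdf and the resulting out-stubs and in-stubs are
paired at random (a bipartite configuration model), with stub totals
reconciled and duplicate links rewired so the result is a simple graph.

Two subset-selection routes extract a biomimetic compound set:

* rejection sampling toward an exponential (geometric) k_out distribution
  with a reduced mean k_out_BM, mimicking natural controller layers;
* an exact binary integer program, minimize sum(x) s.t. A x >= b, where b
  is a ranked incoming-link profile assigning the most incoming links to
  the highest-priority targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .degree import GeometricModel
from .network import BipartiteNetwork, degree_sequences

logger = logging.getLogger(__name__)

__all__ = [
    "LibrarySpec",
    "BiomimeticCriteria",
    "SelectionProblem",
    "SelectionResult",
    "SubsampleReport",
    "simulate_library",
    "inverse_transform_sample",
    "rejection_subsample",
    "build_incoming_link_profile",
    "lp_select_subset",
]


@dataclass(frozen=True)
class LibrarySpec:
    """Prescription for a simulated compound library.

    ``kin_model=None`` uses a geometric in-degree model whose mean is
    matched to the out-side by link conservation, <k_in> = M <k_out> / N.
    """

    n_controllers: int = 1500
    n_targets: int = 518
    kout_model: GeometricModel = field(default_factory=lambda: GeometricModel.from_mean(55.0))
    kin_model: GeometricModel | None = None
    seed: int = 0

    def resolved_kin_model(self) -> GeometricModel:
        if self.kin_model is not None:
            return self.kin_model
        mean_kin = self.n_controllers * self.kout_model.mu / self.n_targets
        return GeometricModel.from_mean(max(1.0, mean_kin))


def inverse_transform_sample(model: GeometricModel, u: float) -> int:
    """Smallest k with cdf(k) >= u: k = ceil(log(1-u)/log(1-p))."""
    return model.ppf(u)


def _sample_degrees(
    model: GeometricModel, n: int, cap: int, rng: np.random.Generator,
    max_retries: int = 1000,
) -> np.ndarray:
    """Inverse-transform degree draws, resampling any node demanding more
    partners than exist on the other side."""
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        for attempt in range(max_retries):
            k = model.ppf(float(rng.uniform(np.finfo(float).tiny, 1.0)))
            if k <= cap:
                out[i] = k
                break
        else:
            raise RuntimeError(
                f"could not draw a feasible degree <= {cap} after {max_retries} tries"
            )
    return out


def _reconcile_stub_totals(
    kout: np.ndarray,
    kin: np.ndarray,
    kout_model: GeometricModel,
    kin_model: GeometricModel,
    cap_out: int,
    cap_in: int,
    rng: np.random.Generator,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-draw random nodes' degrees on the deficit side until the stub
    totals agree to within one (accepting only gap-reducing redraws)."""
    for _ in range(max_iter):
        gap = int(kout.sum() - kin.sum())
        if abs(gap) <= 1:
            break
        if gap > 0:  # in-side is short
            j = rng.integers(len(kin))
            k = kin_model.ppf(float(rng.uniform(np.finfo(float).tiny, 1.0)))
            if k <= cap_in and abs(gap - (k - kin[j])) < abs(gap):
                kin[j] = k
        else:
            i = rng.integers(len(kout))
            k = kout_model.ppf(float(rng.uniform(np.finfo(float).tiny, 1.0)))
            if k <= cap_out and abs(gap + (k - kout[i])) < abs(gap):
                kout[i] = k
    else:
        # close the residual gap directly on one node (logged; marginals
        # perturbed by a single degree)
        gap = int(kout.sum() - kin.sum())
        j = int(np.argmax(kin)) if gap > 0 else int(np.argmax(kout))
        if gap > 0:
            kin[j] = int(np.clip(kin[j] + gap, 1, cap_in))
        else:
            kout[j] = int(np.clip(kout[j] - gap, 1, cap_out))
        logger.warning("stub reconciliation hit the iteration cap; forced a %d-stub fix", gap)
    # discard the final odd stub from the larger side
    gap = int(kout.sum() - kin.sum())
    if gap == 1:
        i = int(np.argmax(kout > 1)) if (kout > 1).any() else int(rng.integers(len(kout)))
        kout[i] -= 1
    elif gap == -1:
        j = int(np.argmax(kin > 1)) if (kin > 1).any() else int(rng.integers(len(kin)))
        kin[j] -= 1
    return kout, kin


def simulate_library(spec: LibrarySpec) -> BipartiteNetwork:
    """Simulate a fully profiled library with the prescribed marginals.

    Out- and in-degrees are drawn by inverse-transform sampling, stub totals
    reconciled, and stubs paired uniformly at random.  Colliding (duplicate)
    links are repaired by local pair swaps that preserve both degree
    sequences; unresolvable duplicates after a retry cap are dropped and
    logged.
    """
    rng = np.random.default_rng(spec.seed)
    M, N = spec.n_controllers, spec.n_targets
    kin_model = spec.resolved_kin_model()
    kout = _sample_degrees(spec.kout_model, M, N, rng)
    kin = _sample_degrees(kin_model, N, M, rng)
    kout, kin = _reconcile_stub_totals(
        kout, kin, spec.kout_model, kin_model, N, M, rng
    )
    controllers = [f"d{i:05d}" for i in range(M)]
    targets = [f"t{j:04d}" for j in range(N)]
    out_stubs = np.repeat(np.arange(M), kout)
    in_stubs = np.repeat(np.arange(N), kin)
    rng.shuffle(in_stubs)
    from collections import Counter

    cnt = Counter(zip(out_stubs.tolist(), in_stubs.tolist()))
    uniq = list(cnt)  # candidate swap partners, refreshed lazily
    dropped = 0
    for pair in [p for p, m in cnt.items() if m > 1]:
        while cnt[pair] > 1:
            c, t = pair
            fixed = False
            for _ in range(500):
                other = uniq[int(rng.integers(len(uniq)))]
                c2, t2 = other
                if cnt.get(other, 0) != 1 or c2 == c or t2 == t:
                    continue
                if cnt.get((c, t2), 0) or cnt.get((c2, t), 0):
                    continue
                # swap one extra (c,t) copy and (c2,t2) into (c,t2), (c2,t);
                # every node keeps its degree
                cnt[pair] -= 1
                del cnt[other]
                cnt[(c, t2)] = 1
                cnt[(c2, t)] = 1
                uniq.append((c, t2))
                uniq.append((c2, t))
                fixed = True
                break
            if not fixed:
                cnt[pair] -= 1
                dropped += 1
    if dropped:
        logger.info("simulate_library: dropped %d unresolvable duplicate links", dropped)
    links = [(controllers[c], targets[t]) for c, t in cnt]
    return BipartiteNetwork(controllers, targets, links, name="simulated_library")


@dataclass(frozen=True)
class BiomimeticCriteria:
    """What the kept compound subset should look like."""

    kout_bm: float
    subset_size: int
    target_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.kout_bm <= 0 or self.subset_size <= 0:
            raise ValueError("kout_bm and subset_size must be positive")
        if not (0 <= self.target_coverage <= 1):
            raise ValueError("target_coverage must lie in [0, 1]")


@dataclass(frozen=True)
class SubsampleReport:
    coverage: float
    mean_k_out: float
    mean_k_in_covered: float
    n_kept: int
    n_targets_covered: int


def rejection_subsample(
    library: BipartiteNetwork, criteria: BiomimeticCriteria, seed: int = 0
) -> tuple[BipartiteNetwork, SubsampleReport]:
    """Keep compounds by rejection toward geometric k_out with mean kout_bm.

    A compound with k_out = k drawn from the library is kept with
    probability f_BM(k) / (c f_lib(k)), f_BM the geometric pmf with mean
    ``criteria.kout_bm``, f_lib the library's empirical k_out pmf and c the
    rejection constant; the kept set's k_out is then f_BM restricted to the
    library support.  Stops at ``subset_size`` kept compounds.  Returns the
    induced subnetwork (kept controllers + every target they hit) and a
    coverage/degree report.
    """
    if library.L == 0:
        raise ValueError("empty library")
    kout_seq, _ = degree_sequences(library)
    kouts = np.asarray(kout_seq.values)
    if criteria.kout_bm > kouts.max():
        raise ValueError(
            f"kout_bm = {criteria.kout_bm} exceeds the library's maximum "
            f"k_out = {kouts.max()}; criteria unreachable"
        )
    f_bm = GeometricModel.from_mean(max(1.0, criteria.kout_bm))
    levels, counts = np.unique(kouts, return_counts=True)
    f_lib = dict(zip(levels.tolist(), (counts / counts.sum()).tolist()))
    w = {k: float(f_bm.pmf(k)) / f_lib[k] for k in f_lib}
    c = max(w.values())
    if c == 0:
        raise ValueError("biomimetic pmf has no mass on the library support")
    accept = {k: wk / c for k, wk in w.items()}
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    kept_set: set[int] = set()
    ctrl = list(library.controllers)
    max_draws = 10_000 * criteria.subset_size
    for _ in range(max_draws):
        i = int(rng.integers(len(ctrl)))
        if i in kept_set:
            continue
        if rng.random() < accept[int(kouts[i])]:
            kept_set.add(i)
            kept.append(ctrl[i])
            if len(kept) == criteria.subset_size:
                break
    else:
        raise RuntimeError(
            "rejection sampling failed to reach the requested subset size; "
            "kout_bm is likely unattainable from the library's k_out support"
        )
    sub = library.induced_subnetwork(kept, name="biomimetic_subset")
    covered = sub.N
    coverage = covered / library.N
    mean_kout = sub.L / sub.M
    mean_kin = sub.L / covered if covered else 0.0
    if coverage < criteria.target_coverage:
        warnings.warn(
            f"realized coverage {coverage:.3f} below requested "
            f"{criteria.target_coverage:.3f}"
        )
    return sub, SubsampleReport(coverage, mean_kout, mean_kin, len(kept), covered)


def build_incoming_link_profile(
    desired_pdf, ranked_targets, budget: int
) -> np.ndarray:
    """Ranked integer incoming-link demands b with sum(b) = budget.

    ``desired_pdf`` is a GeometricModel (evaluated at ranks 1..N) or a
    tabulated non-increasing weight vector.  Weights are scaled to the link
    budget and rounded by largest remainder; the result is sorted
    non-increasing so the top-ranked target demands the most links.
    """
    n = len(ranked_targets)
    if n == 0:
        raise ValueError("ranked_targets is empty")
    if isinstance(desired_pdf, GeometricModel):
        weights = np.asarray(desired_pdf.pmf(np.arange(1, n + 1)), dtype=float)
    else:
        weights = np.asarray(desired_pdf, dtype=float)
        if weights.shape != (n,):
            raise ValueError("tabulated pdf length must match ranked_targets")
    if np.any(np.diff(weights) > 1e-12):
        raise ValueError("desired pdf must be monotonically non-increasing")
    if weights.sum() <= 0:
        raise ValueError("pdf has no mass")
    scaled = budget * weights / weights.sum()
    base = np.floor(scaled).astype(int)
    short = budget - int(base.sum())
    if short > 0:
        order = np.argsort(-(scaled - base), kind="stable")
        base[order[:short]] += 1
    return np.sort(base)[::-1]


@dataclass
class SelectionProblem:
    """Binary set-selection instance: minimize sum(x) s.t. A x >= b.

    ``adjacency`` has one row per target and one column per controller;
    ``profile`` is the per-target demanded incoming links, in row order.
    """

    adjacency: np.ndarray
    profile: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        self.profile = np.asarray(self.profile)
        if self.adjacency.ndim != 2:
            raise ValueError("adjacency must be 2-D (targets x controllers)")
        if self.profile.shape != (self.adjacency.shape[0],):
            raise ValueError("profile length must equal the number of targets")

    @classmethod
    def from_network(
        cls, net: BipartiteNetwork, profile: np.ndarray
    ) -> "SelectionProblem":
        return cls(net.biadjacency().T, profile)


@dataclass(frozen=True)
class SelectionResult:
    x: np.ndarray
    objective: int
    realized: np.ndarray
    alternative_exists: bool


def _solve_milp(A: np.ndarray, b: np.ndarray, extra: list[LinearConstraint]):
    m = A.shape[1]
    cons = [LinearConstraint(A, b, np.inf)] + extra
    res = milp(
        c=np.ones(m),
        constraints=cons,
        integrality=np.ones(m),
        bounds=Bounds(0, 1),
    )
    return res


def lp_select_subset(problem: SelectionProblem) -> SelectionResult:
    """Exact minimal controller subset meeting the incoming-link profile.

    Solved as a binary integer program.  Raises on infeasibility, listing
    the targets that cannot be served even by the full controller set.
    Degeneracy is probed by re-solving with the found subset excluded at the
    same objective; ``alternative_exists`` reports whether another optimum
    was found.
    """
    A = problem.adjacency.astype(float)
    b = problem.profile.astype(float)
    full = A @ np.ones(A.shape[1])
    bad = np.nonzero(full < b)[0]
    if bad.size:
        raise ValueError(
            f"infeasible profile: targets at rows {bad.tolist()} demand more "
            "incoming links than the full controller set provides"
        )
    res = _solve_milp(A, b, [])
    if res.status != 0:  # pragma: no cover - guarded by feasibility pre-check
        raise RuntimeError(f"ILP solver failed: {res.message}")
    x = np.round(res.x).astype(int)
    objective = int(x.sum())
    realized = (A @ x).astype(int)
    # no-good cut: sum_{i in S} x_i - sum_{i not in S} x_i <= |S| - 1
    cut = LinearConstraint(2 * x - 1, -np.inf, objective - 1)
    cap = LinearConstraint(np.ones_like(x), 0, objective)
    res2 = _solve_milp(A, b, [cut, cap])
    alternative = bool(res2.status == 0 and round(res2.fun) == objective)
    return SelectionResult(x, objective, realized, alternative)
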