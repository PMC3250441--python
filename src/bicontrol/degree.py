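"""Degree-distribution models, fits and degree-preserving randomization.

Biological controller-target networks mostly show exponentially distributed
links per node; the discrete analogue is the geometric distribution on
k = 1, 2, 3, ... with pmf p (1-p)^(k-1) and mean 1/p.  The null model is a
bipartite Erdos-Renyi graph, whose marginal degrees are Binomial and, for
large networks, approximately Poisson with lambda = M D (targets) or N D
(controllers).  Because a node with no links is invisible to most of the
analyses, the zero-degree class is excluded (and the pmf renormalized over
k >= 1 by default) wherever a model distribution is compared with data.

Fitting follows the method-of-moments convention of the field: the
geometric parameter is p = 1/mean(k) over the zero-excluded sequence.  The
exponential-vs-scale-free comparison is a least-squares fit of log relative
frequency against k (exponential) or log k (scale-free), scored by R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .network import BipartiteNetwork, DegreeSequence, degree_sequences

__all__ = [
    "GeometricModel",
    "PoissonNull",
    "BinomialNull",
    "FitReport",
    "GeometricDegreeModel",
    "GeometricDegreeResults",
    "fit_geometric",
    "geometric_cdf",
    "normalized_ecdf",
    "poisson_null_histogram",
    "fit_models_r2",
    "degree_preserving_randomize",
    "kout_kin_correlation_z",
]


# ---------------------------------------------------------------------------
# model distributions on links-per-node
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class GeometricModel:
    """Geometric links-per-node distribution, support k = 1, 2, 3, ...

    pmf(k) = p (1-p)^(k-1); mean mu = 1/p.
    """

    p: float

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("p must be in (0, 1]")

    @property
    def mu(self) -> float:
        return 1.0 / self.p

    @classmethod
    def from_mean(cls, mu: float) -> "GeometricModel":
        if mu < 1:
            raise ValueError("geometric mean must be >= 1")
        return cls(1.0 / mu)

    def pmf(self, k) -> np.ndarray:
        k = np.asarray(k)
        out = np.where(k >= 1, self.p * (1 - self.p) ** (k - 1), 0.0)
        return out

    def cdf(self, k) -> np.ndarray:
        k = np.asarray(k)
        return np.where(k >= 1, 1.0 - (1 - self.p) ** k, 0.0)

    def ppf(self, u: float) -> int:
        """Smallest k with cdf(k) >= u (inverse-transform sampling)."""
        if not (0 < u < 1):
            raise ValueError("u must lie strictly in (0, 1)")
        if self.p == 1.0:
            return 1
        return max(1, math.ceil(math.log1p(-u) / math.log1p(-self.p)))

    @property
    def mean(self) -> float:
        return self.mu


@dataclass(frozen=True)
class PoissonNull:
    """Poisson links-per-node null (bipartite random-graph approximation).

    lambda = M D for target in-degrees, N D for controller out-degrees.
    With ``zero_excluded`` the pmf is restricted to k >= 1 and, when
    ``renormalized`` (default), divided by 1 - e^-lambda.
    """

    lam: float
    zero_excluded: bool = True
    renormalized: bool = True

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def mean(self) -> float:
        if self.zero_excluded and self.renormalized:
            return self.lam / (1 - math.exp(-self.lam))
        return self.lam

    def pmf(self, k) -> np.ndarray:
        k = np.asarray(k)
        base = sps.poisson.pmf(k, self.lam)
        if self.zero_excluded:
            base = np.where(k >= 1, base, 0.0)
            if self.renormalized:
                base = base / (1 - math.exp(-self.lam))
        return base


@dataclass(frozen=True)
class BinomialNull:
    """Exact Binomial(n, D) links-per-node null for small bipartite graphs.

    The Poisson form above is its large-network limit; at M or N around 10
    the difference is visible, so the exact form is kept available.
    """

    n: int
    d: float
    zero_excluded: bool = True
    renormalized: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.d <= 1):
            raise ValueError("d must be in [0, 1]")

    @property
    def mean(self) -> float:
        m = self.n * self.d
        if self.zero_excluded and self.renormalized:
            p0 = (1 - self.d) ** self.n
            return m / (1 - p0)
        return m

    def pmf(self, k) -> np.ndarray:
        k = np.asarray(k)
        base = sps.binom.pmf(k, self.n, self.d)
        if self.zero_excluded:
            base = np.where(k >= 1, base, 0.0)
            if self.renormalized:
                base = base / (1 - (1 - self.d) ** self.n)
        return base


# ---------------------------------------------------------------------------
# geometric fitting (Model / Results interface)
# ---------------------------------------------------------------------------
class GeometricDegreeModel:
    """Geometric model for an observed links-per-node sequence.

    Zero-degree nodes are dropped before fitting (the geometric support
    starts at 1).  ``fit`` uses the method of moments, p = 1/mean, which for
    the geometric coincides with maximum likelihood.
    """

    def __init__(self, degrees: DegreeSequence | np.ndarray | list):
        if isinstance(degrees, DegreeSequence):
            vals = np.asarray(degrees.values, dtype=float)
        else:
            vals = np.asarray(degrees, dtype=float)
        self.n_zero = int(np.sum(vals == 0))
        self.endog = vals[vals > 0]
        if self.endog.size == 0:
            raise ValueError("no nonzero degrees to fit")

    def fit(self) -> "GeometricDegreeResults":
        mean = float(self.endog.mean())
        p = 1.0 / mean
        n = self.endog.size
        # asymptotic SE of p-hat = 1/mean via the delta method
        se = p * math.sqrt(max(0.0, 1 - p) / n)
        return GeometricDegreeResults(self, GeometricModel(p), se)


@dataclass(frozen=True)
class GeometricDegreeResults:
    model_data: GeometricDegreeModel
    dist: GeometricModel
    bse: float

    @property
    def params(self) -> dict[str, float]:
        return {"p": self.dist.p, "mu": self.dist.mu}

    @property
    def nobs(self) -> int:
        return self.model_data.endog.size

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = sps.norm.ppf(1 - alpha / 2)
        return (self.dist.p - z * self.bse, self.dist.p + z * self.bse)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Geometric degree-distribution fit",
            "=" * 46,
            f"{'nobs (k >= 1)':<28}{self.nobs:>18}",
            f"{'zero-degree dropped':<28}{self.model_data.n_zero:>18}",
            f"{'p (success prob.)':<28}{self.dist.p:>18.6f}",
            f"{'std err (p)':<28}{self.bse:>18.6f}",
            f"{'95% CI (p)':<28}{f'[{lo:.4f}, {hi:.4f}]':>18}",
            f"{'mu = 1/p (mean links)':<28}{self.dist.mu:>18.4f}",
        ]
        return "\n".join(lines)


def fit_geometric(degrees: DegreeSequence | np.ndarray | list) -> GeometricModel:
    """Moment fit of the geometric model: p = 1/mean of the k>=1 values."""
    return GeometricDegreeModel(degrees).fit().dist


def geometric_cdf(k: int, model: GeometricModel) -> float:
    """P(K <= k) = 1 - (1-p)^k for k >= 1."""
    if k < 1:
        raise ValueError("geometric support starts at k = 1")
    return float(1.0 - (1 - model.p) ** k)


# ---------------------------------------------------------------------------
# empirical distribution displays
# ---------------------------------------------------------------------------
def normalized_ecdf(degrees: DegreeSequence | np.ndarray | list) -> np.ndarray:
    """Empirical cdf with the degree axis normalized by the sequence mean.

    Returns an array of (k/<k>, F(k)) rows, one per distinct degree, with no
    binning, suitable for overlay on the mean-normalized geometric cdf
    (which approaches the standard exponential cdf for mu >> 1).
    """
    vals = np.asarray(
        degrees.values if isinstance(degrees, DegreeSequence) else degrees, dtype=float
    )
    if vals.size == 0:
        raise ValueError("empty degree sequence")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("sequence mean must be positive")
    ks, counts = np.unique(vals, return_counts=True)
    cdf = np.cumsum(counts) / vals.size
    return np.column_stack([ks / mean, cdf])


def poisson_null_histogram(
    M: int, N: int, D: float, side: str, bins: np.ndarray | int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Expected Poisson degree frequencies for a bipartite random graph.

    lambda = M D for ``side='target'`` (in-degrees) and N D for
    ``side='controller'`` (out-degrees).  ``bins`` is either an integer
    number of equal-width bins over the distribution's bulk or explicit bin
    edges matching the observed data's binning; returns (edges, expected
    frequency mass per bin).
    """
    if not (0 < D <= 1):
        raise ValueError("D must lie in (0, 1]")
    if side not in ("controller", "target"):
        raise ValueError("side must be 'controller' or 'target'")
    lam = M * D if side == "target" else N * D
    kmax = int(sps.poisson.ppf(1 - 1e-9, lam)) + 1
    if np.isscalar(bins):
        edges = np.linspace(0, kmax, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    ks = np.arange(0, math.ceil(edges[-1]))
    pmf = sps.poisson.pmf(ks, lam)
    idx = np.searchsorted(edges, ks, side="right") - 1
    keep = (idx >= 0) & (idx < len(edges) - 1)  # right-open bins
    freq = np.zeros(len(edges) - 1)
    np.add.at(freq, idx[keep], pmf[keep])
    return edges, freq


@dataclass(frozen=True)
class FitReport:
    """Goodness of fit of one candidate degree-distribution shape."""

    model_name: str
    params: dict[str, float]
    r_squared: float
    transform: str


def fit_models_r2(degrees: DegreeSequence | np.ndarray | list) -> list[FitReport]:
    """Compare exponential and scale-free shapes by linearized least squares.

    Relative degree frequencies are computed on the k >= 1 support; empty
    cells are dropped (log undefined).  The exponential candidate fits
    log f(k) ~ a + b k, the scale-free candidate log f(k) ~ a + b log k; the
    report with the larger R^2 wins.  Requires at least 5 distinct degrees.
    """
    vals = np.asarray(
        degrees.values if isinstance(degrees, DegreeSequence) else degrees, dtype=float
    )
    vals = vals[vals >= 1]
    ks, counts = np.unique(vals, return_counts=True)
    if ks.size < 5:
        raise ValueError("need at least 5 distinct degree values to compare fits")
    freq = counts / counts.sum()
    logf = np.log(freq)

    def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return slope, intercept, r2

    b_exp, a_exp, r2_exp = _ols(ks, logf)
    b_sf, a_sf, r2_sf = _ols(np.log(ks), logf)
    return [
        FitReport("exponential", {"slope": b_exp, "intercept": a_exp}, r2_exp, "log(f) vs k"),
        FitReport("scale_free", {"slope": b_sf, "intercept": a_sf}, r2_sf, "log(f) vs log(k)"),
    ]


# ---------------------------------------------------------------------------
# degree-preserving randomization
# ---------------------------------------------------------------------------
def degree_preserving_randomize(
    net: BipartiteNetwork, n_swaps: int | None = None, seed: int = 0
) -> BipartiteNetwork:
    """Randomize wiring by repeated double-edge swaps, preserving degrees.

    A swap picks two links (c1,t1), (c2,t2) and rewires them to (c1,t2),
    (c2,t1); swaps that would duplicate an existing link are rejected.  Both
    degree sequences (and hence M, N, L, D, <k_in>, <k_out>) are conserved
    exactly.  Default attempt count is 10 L.
    """
    if n_swaps is None:
        n_swaps = 10 * net.L
    if n_swaps <= 0:
        raise ValueError("n_swaps must be positive")
    if net.L < 2:
        return net
    rng = np.random.default_rng(seed)
    edges = sorted(net.links)
    edge_set = set(edges)
    n_edges = len(edges)
    accepted = 0
    for _ in range(n_swaps):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        c1, t1 = edges[i]
        c2, t2 = edges[j]
        if t1 == t2 or c1 == c2:
            continue
        new1, new2 = (c1, t2), (c2, t1)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((c1, t1))
        edge_set.discard((c2, t2))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i], edges[j] = new1, new2
        accepted += 1
    return BipartiteNetwork(
        net.controllers, net.targets, edge_set, name=f"{net.name}:randomized"
    )


def kout_kin_correlation_z(
    net: BipartiteNetwork, n_random: int = 30, seed: int = 0
):
    """z-scores of link counts per (k_out, k_in) degree class vs randomized.

    Each link falls in the class (out-degree of its controller, in-degree of
    its target); degrees are node properties conserved by the randomization,
    so the class grid is fixed.  For each class, z = (observed count - mean
    over ``n_random`` degree-preserving randomizations) / SD; classes with
    zero SD get z = 0 and are flagged.

    Returns (z, kout_levels, kin_levels, zero_sd_mask).
    """
    if n_random < 2:
        raise ValueError("n_random must be at least 2")
    kout_map: dict[str, int] = {c: 0 for c in net.controllers}
    kin_map: dict[str, int] = {t: 0 for t in net.targets}
    for c, t in net.links:
        kout_map[c] += 1
        kin_map[t] += 1
    kout_levels = np.array(sorted({v for v in kout_map.values() if v > 0}))
    kin_levels = np.array(sorted({v for v in kin_map.values() if v > 0}))
    oi = {v: i for i, v in enumerate(kout_levels)}
    tj = {v: j for j, v in enumerate(kin_levels)}

    def class_counts(links) -> np.ndarray:
        cnt = np.zeros((len(kout_levels), len(kin_levels)))
        for c, t in links:
            cnt[oi[kout_map[c]], tj[kin_map[t]]] += 1
        return cnt

    observed = class_counts(net.links)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_random, *observed.shape))
    for r in range(n_random):
        rnet = degree_preserving_randomize(net, seed=int(rng.integers(2**31)))
        reps[r] = class_counts(rnet.links)
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1)
    zero_sd = sd == 0
    z = np.zeros_like(observed, dtype=float)
    ok = ~zero_sd
    z[ok] = (observed[ok] - mean[ok]) / sd[ok]
    return z, kout_levels, kin_levels, zero_sd


def network_degree_models(net: BipartiteNetwork) -> dict[str, GeometricModel]:
    """Convenience: geometric fits of both layers of a network."""
    kout, kin = degree_sequences(net)
    return {"out": fit_geometric(kout), "in": fit_geometric(kin)}
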