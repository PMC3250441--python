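"""Boolean bipartite signalling model: robustness and output-state entropy.

M controller nodes carry binary states; each of N target nodes computes a
single-step Boolean function of the controllers linked to it:

    OR        active iff at least one linked controller is active,
    AND       active iff all linked controllers are active,
    MAJORITY  active iff strictly more than half are active.

Links are unweighted and there is no feedback; dynamics are a single step.
A target left with no incoming links is inactive under every rule.

Two quantities characterize a wiring:

* Robustness to link deletion.  Over a uniform random input and a uniform
  choice of gamma deleted links, the fraction of (signal-receiving) targets
  whose output is unchanged.  For the OR rule a target with k incoming
  links is "fragile" with respect to one specific link only in the single
  input state with that controller active and the other k-1 inactive, so
  the per-link flip probability is 2^-k, and to first order in gamma/L

      F_gamma(k) = k (gamma / L) 2^-k,      R(k) = 1 - F_gamma(k).

  The AND rule gives identical values by the input-complement symmetry
  OR(x) = NOT AND(NOT x); MAJORITY is handled by simulation only.

* Number of output states.  Omega is the number of distinct output vectors
  reachable over all 2^M inputs (at most 2^M, attained by a one-to-one
  wiring).  For large networks it is estimated from the single-node output
  entropy: under OR the output is 0 only when all k inputs are 0, so
  q0 = 2^-k, q1 = 1 - q0,

      S(k) = -q0 log2 q0 - q1 log2 q1   [bits],
      log2 Omega ~= N <S>,

  where <S> is the expectation over the incoming-degree distribution
  restricted to k >= 1.  Expanding -(1-q0) log2 (1-q0) in powers of
  q0 = 2^-k gives a series in the primitives E[2^(-eta k)] and
  E[k 2^(-eta k)], truncated at a finite order eta (default 3); those
  expectations have closed forms for geometric and zero-excluded Poisson
  degree models.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd

from .degree import BinomialNull, GeometricModel, PoissonNull
from .network import BipartiteNetwork

__all__ = [
    "RULES",
    "BooleanConfig",
    "RobustnessResult",
    "EntropyResult",
    "BooleanBipartiteModel",
    "evaluate",
    "count_output_states",
    "robustness_simulation",
    "robustness_exhaustive",
    "p_fragile",
    "robustness_closed_form",
    "entropy_single_node",
    "expected_value",
    "mean_robustness",
    "mean_entropy",
    "omega_estimate",
    "robustness_profile",
    "entropy_profile",
    "fig3_sweep",
]

RULES = ("OR", "AND", "MAJORITY")
Rule = Literal["OR", "AND", "MAJORITY"]
LN2 = math.log(2.0)


@dataclass(frozen=True)
class BooleanConfig:
    """Simulation settings: rule, deleted-link fraction gamma/N, trials, seed."""

    rule: Rule = "OR"
    mutation_fraction: float = 0.1
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        if self.mutation_fraction < 0:
            raise ValueError("mutation_fraction must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def gamma(self, N: int) -> int:
        return int(round(self.mutation_fraction * N))


@dataclass(frozen=True)
class RobustnessResult:
    """Closed-form robustness profile over incoming degree."""

    per_k: dict[int, float]
    mean_R: float
    gamma: int
    L: float


@dataclass(frozen=True)
class EntropyResult:
    """Entropy profile over incoming degree and the output-state estimate."""

    per_k: dict[int, float]
    mean_S: float
    log2_omega: float
    eta: int | None


# ---------------------------------------------------------------------------
# rule evaluation on biadjacency matrices
# ---------------------------------------------------------------------------
def _apply_rule(counts: np.ndarray, kin: np.ndarray, rule: Rule) -> np.ndarray:
    """Outputs from per-target active-input counts; kin = 0 is always 0."""
    if rule == "OR":
        return (counts >= 1).astype(np.int8)
    if rule == "AND":
        return ((kin >= 1) & (counts == kin)).astype(np.int8)
    if rule == "MAJORITY":
        return (2 * counts > kin).astype(np.int8)
    raise ValueError(f"unknown rule {rule!r}")


def _outputs(B: np.ndarray, X: np.ndarray, rule: Rule) -> np.ndarray:
    """Output states for a batch of inputs.  B is (M, N) 0/1; X is (..., M)."""
    kin = B.sum(axis=0)
    counts = X @ B
    return _apply_rule(counts, kin, rule)


def evaluate(
    net: BipartiteNetwork, input_state, rule: Rule = "OR"
) -> np.ndarray:
    """Single-step output vector over targets for one controller state."""
    x = np.asarray(input_state, dtype=np.int64)
    if x.shape != (net.M,):
        raise ValueError(f"input_state must have length M = {net.M}")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("input_state must be binary")
    return _outputs(net.biadjacency(), x, rule)


# ---------------------------------------------------------------------------
# output-state counting
# ---------------------------------------------------------------------------
def _count_output_states_matrix(B: np.ndarray, rule: Rule) -> int:
    M = B.shape[0]
    kin = B.sum(axis=0)
    seen: set[bytes] = set()
    chunk = 1 << min(M, 14)
    total = 1 << M
    bits = np.arange(M)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        X = ((idx[:, None] >> bits) & 1).astype(np.int64)
        Y = _apply_rule(X @ B, kin, rule)
        for row in np.packbits(Y, axis=1):
            seen.add(row.tobytes())
    return len(seen)


def count_output_states(net: BipartiteNetwork, rule: Rule = "OR") -> int:
    """Exact Omega: distinct output vectors over all 2^M inputs (M <= 22)."""
    if net.M > 22:
        raise ValueError(
            "exhaustive enumeration limited to M <= 22; use omega_estimate "
            "with a fitted degree model for larger networks"
        )
    return _count_output_states_matrix(net.biadjacency(), rule)


# ---------------------------------------------------------------------------
# robustness: simulation and exact enumeration
# ---------------------------------------------------------------------------
def _fraction_unchanged(
    B: np.ndarray, x: np.ndarray, delete_idx: np.ndarray, rule: Rule,
    link_rows: np.ndarray, link_cols: np.ndarray,
) -> float:
    kin = B.sum(axis=0)
    active = kin >= 1
    if not active.any():
        return 1.0
    y0 = _apply_rule(x @ B, kin, rule)
    B2 = B.copy()
    B2[link_rows[delete_idx], link_cols[delete_idx]] = 0
    kin2 = B2.sum(axis=0)
    y1 = _apply_rule(x @ B2, kin2, rule)
    return float(np.mean(y0[active] == y1[active]))


def robustness_simulation(net: BipartiteNetwork, cfg: BooleanConfig) -> float:
    """Monte-Carlo robustness of one wiring.

    Each trial draws a fresh uniform input and a fresh uniform set of gamma
    distinct links to delete, and scores the fraction of signal-receiving
    targets (k_in >= 1 in the intact network) whose output is unchanged.
    Returns the mean over ``cfg.n_trials`` trials.
    """
    B = net.biadjacency().astype(np.int64)
    gamma = cfg.gamma(net.N)
    if gamma > net.L:
        raise ValueError(f"gamma = {gamma} exceeds the link count L = {net.L}")
    if gamma == 0:
        return 1.0
    rng = np.random.default_rng(cfg.seed)
    rows, cols = np.nonzero(B)
    out = 0.0
    for _ in range(cfg.n_trials):
        x = rng.integers(0, 2, size=net.M)
        dele = rng.choice(len(rows), size=gamma, replace=False)
        out += _fraction_unchanged(B, x, dele, cfg.rule, rows, cols)
    return out / cfg.n_trials


def robustness_exhaustive(
    net: BipartiteNetwork, gamma: int, rule: Rule = "OR"
) -> float:
    """Exact expected robustness over all inputs x all gamma-subsets of links.

    Feasible only for small networks (2^M inputs times C(L, gamma) deletion
    sets).
    """
    if gamma > net.L:
        raise ValueError("gamma exceeds L")
    if gamma == 0:
        return 1.0
    B = net.biadjacency().astype(np.int64)
    rows, cols = np.nonzero(B)
    subsets = list(itertools.combinations(range(len(rows)), gamma))
    total = 0.0
    n = 0
    for bits in itertools.product((0, 1), repeat=net.M):
        x = np.array(bits, dtype=np.int64)
        for sub in subsets:
            total += _fraction_unchanged(B, x, np.array(sub), rule, rows, cols)
            n += 1
    return total / n


def p_fragile(k: int, rule: Rule = "OR") -> float:
    """Probability that deleting one specific incoming link flips a target.

    Over uniform inputs, the OR rule flips only in the state with the
    deleted link's controller active and the remaining k-1 inactive:
    p = 2^-k.  AND is identical by the complement symmetry.  No analytic
    form is provided for MAJORITY (simulate instead).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rule == "MAJORITY":
        raise ValueError("MAJORITY has no closed form here; use simulation")
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    return 2.0 ** (-k)


def robustness_closed_form(k: int, gamma: int, L: float) -> float:
    """First-order closed form R(k) = 1 - k (gamma/L) 2^-k.

    gamma/L is the chance a given link is among the deleted ones; a target
    with k links is hit through any of them and flips with probability 2^-k
    per hit.  Valid for gamma << L.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if gamma < 0 or gamma > L:
        raise ValueError("need 0 <= gamma <= L")
    if L <= 0:
        raise ValueError("L must be positive")
    return 1.0 - k * (gamma / L) * 2.0 ** (-k)


# ---------------------------------------------------------------------------
# entropy and output-state estimate
# ---------------------------------------------------------------------------
def entropy_single_node(
    k: int, rule: Rule = "OR", eta: int | None = None
) -> float:
    """Output entropy (bits) of one target with k incoming links.

    Exact: binary entropy at q0 = 2^-k.  With ``eta`` given, the power
    series of -(1-q0) log2(1-q0) is truncated at that order:

        S(k) ~= k 2^-k + (1/ln 2) sum_{e=1..eta} (2^(-e k) - 2^(-(e+1) k))/e
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rule == "MAJORITY":
        raise ValueError("MAJORITY entropy is not derived; use enumeration")
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    q0 = 2.0 ** (-k)
    if eta is None:
        if q0 == 0.0:  # underflow at very large k; entropy is 0 in the limit
            return 0.0
        q1 = 1.0 - q0
        return float(-q0 * math.log2(q0) - (q1 * math.log2(q1) if q1 > 0 else 0.0))
    if eta < 1:
        raise ValueError("eta must be >= 1")
    s = k * q0
    for e in range(1, eta + 1):
        s += (2.0 ** (-e * k) - 2.0 ** (-(e + 1) * k)) / (e * LN2)
    return float(s)


DegreeDist = GeometricModel | PoissonNull | BinomialNull


def expected_value(
    f_class: str | Callable[[np.ndarray], np.ndarray],
    model: DegreeDist,
    eta: int = 1,
    *,
    k_max: int = 10_000,
) -> float:
    """Expectation over a links-per-node model restricted to k >= 1.

    ``f_class`` may be one of the named primitives ``"2^-nk"`` (E[2^(-eta k)])
    and ``"k*2^-nk"`` (E[k 2^(-eta k)]) — closed forms are used for the
    geometric and zero-excluded Poisson models — or an arbitrary callable
    f(k), evaluated by direct summation.
    """
    a = 2.0 ** (-eta)
    if isinstance(model, GeometricModel) and f_class in ("2^-nk", "k*2^-nk"):
        p = model.p
        r = (1 - p) * a
        if r >= 1:
            raise ValueError("divergent parameter combination")
        if f_class == "2^-nk":
            return p * a / (1 - r)
        return p * a / (1 - r) ** 2
    if (
        isinstance(model, PoissonNull)
        and model.zero_excluded
        and f_class in ("2^-nk", "k*2^-nk")
    ):
        lam = model.lam
        norm = (1 - math.exp(-lam)) if model.renormalized else 1.0
        if f_class == "2^-nk":
            return math.exp(-lam) * (math.exp(lam * a) - 1) / norm
        return math.exp(-lam) * lam * a * math.exp(lam * a) / norm
    # numeric summation fallback (also the cross-check path for tests)
    if callable(f_class):
        f = f_class
    elif f_class == "2^-nk":
        f = lambda k: a**k  # noqa: E731
    elif f_class == "k*2^-nk":
        f = lambda k: k * a**k  # noqa: E731
    else:
        raise ValueError(f"unknown f_class {f_class!r}")
    if isinstance(model, BinomialNull):
        ks = np.arange(1, model.n + 1)
    else:
        ks = np.arange(1, k_max + 1)
    w = model.pmf(ks)
    return float(np.sum(w * np.asarray(f(ks.astype(float)))))


def mean_robustness(model: DegreeDist, gamma: int, L: float) -> float:
    """R-bar = 1 - (gamma/L) E[k 2^-k] over the incoming-degree model."""
    if L <= 0:
        raise ValueError("L must be positive")
    return 1.0 - (gamma / L) * expected_value("k*2^-nk", model, eta=1)


def mean_entropy(model: DegreeDist, eta: int | None = 3) -> float:
    """<S> in bits over the incoming-degree model (k >= 1).

    ``eta`` truncates the entropy series (default 3); ``eta=None`` uses the
    exact per-k entropy summed numerically.
    """
    if eta is None:
        return expected_value(
            lambda k: np.array([entropy_single_node(int(ki)) for ki in np.atleast_1d(k)]),
            model,
        )
    s = expected_value("k*2^-nk", model, eta=1)
    for e in range(1, eta + 1):
        s += (expected_value("2^-nk", model, eta=e) - expected_value("2^-nk", model, eta=e + 1)) / (
            e * LN2
        )
    return s


def omega_estimate(model: DegreeDist, N: int, eta: int | None = 3) -> float:
    """log2 of the estimated number of unique output states: N <S(k_in)>.

    Returned in log2 form to avoid overflow at biological N.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return N * mean_entropy(model, eta=eta)


def robustness_profile(
    model: DegreeDist, gamma: int, L: float, k_max: int = 20
) -> RobustnessResult:
    per_k = {k: robustness_closed_form(k, gamma, L) for k in range(1, k_max + 1)}
    return RobustnessResult(per_k, mean_robustness(model, gamma, L), gamma, L)


def entropy_profile(
    model: DegreeDist, N: int, eta: int | None = 3, k_max: int = 20
) -> EntropyResult:
    per_k = {k: entropy_single_node(k, eta=eta) for k in range(1, k_max + 1)}
    s = mean_entropy(model, eta=eta)
    return EntropyResult(per_k, s, N * s, eta)


# ---------------------------------------------------------------------------
# ensemble sweep over <k_in> (simulation + closed form)
# ---------------------------------------------------------------------------
def fig3_sweep(
    M: int = 10,
    N: int = 10,
    mutation_fraction: float = 0.1,
    k_in_grid: Iterable[float] = tuple(range(1, 9)),
    n_trials: int = 1000,
    rules: tuple[Rule, ...] = ("OR", "AND", "MAJORITY"),
    seed: int = 0,
    eta: int = 3,
    count_states: bool = True,
) -> pd.DataFrame:
    """Ensemble sweep of robustness and output states against <k_in>.

    For each grid value of <k_in>, bipartite Erdos-Renyi networks with
    density D = <k_in>/M are drawn fresh each trial; every trial draws one
    uniform input and one uniform set of gamma = round(mutation_fraction*N)
    links to delete.  Columns per rule: simulated mean robustness ``R_sim``
    (with Monte-Carlo standard error ``R_sim_se``) and mean output-state
    count ``omega_sim``.  Closed-form columns (OR rule): ``R_closed``
    evaluated on the analytic zero-excluded Binomial(M, D) incoming-degree
    law with L = N <k_in>, ``R_closed_paired`` the same per-k formula
    averaged over the realized degree sequences of the simulated ensemble,
    and ``log2_omega_closed`` = N <S> with the entropy series truncated at
    ``eta``.  Infeasible grid points (<k_in> > M) are skipped with a warning.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for kin in k_in_grid:
        if kin > M or kin <= 0:
            warnings.warn(f"<k_in> = {kin} infeasible for M = {M}; skipped")
            continue
        D = kin / M
        gamma = int(round(mutation_fraction * N))
        L_exp = N * kin
        row: dict[str, float] = {"k_in": kin, "gamma": gamma}
        acc = {r: [] for r in rules}
        omega = {r: [] for r in rules}
        paired = []
        for _ in range(n_trials):
            B = (rng.random((M, N)) < D).astype(np.int64)
            L_real = int(B.sum())
            r_, c_ = np.nonzero(B)
            x = rng.integers(0, 2, size=M)
            g = min(gamma, L_real)
            dele = rng.choice(L_real, size=g, replace=False) if g else np.array([], int)
            for rule in rules:
                acc[rule].append(_fraction_unchanged(B, x, dele, rule, r_, c_))
                if count_states:
                    omega[rule].append(_count_output_states_matrix(B, rule))
            kin_seq = B.sum(axis=0)
            nz = kin_seq[kin_seq >= 1]
            if L_real > 0 and nz.size:
                frag = np.mean(nz * 2.0 ** (-nz.astype(float)))
                paired.append(1.0 - (g / L_real) * frag)
            else:
                paired.append(1.0)
        for rule in rules:
            a = np.asarray(acc[rule])
            row[f"R_sim_{rule}"] = a.mean()
            row[f"R_sim_se_{rule}"] = a.std(ddof=1) / math.sqrt(len(a))
            if count_states:
                row[f"omega_sim_{rule}"] = float(np.mean(omega[rule]))
        model = BinomialNull(M, D)
        row["R_closed"] = mean_robustness(model, gamma, L_exp)
        row["R_closed_paired"] = float(np.mean(paired))
        row["log2_omega_closed"] = omega_estimate(model, N, eta=eta)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------
class BooleanBipartiteModel:
    """One wiring + one rule, with the model's quantities as methods."""

    def __init__(self, net: BipartiteNetwork, rule: Rule = "OR"):
        if rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        self.net = net
        self.rule = rule

    def evaluate(self, input_state) -> np.ndarray:
        return evaluate(self.net, input_state, self.rule)

    def count_output_states(self) -> int:
        return count_output_states(self.net, self.rule)

    def simulate_robustness(self, cfg: BooleanConfig | None = None, **kw) -> float:
        if cfg is None:
            cfg = BooleanConfig(rule=self.rule, **kw)
        return robustness_simulation(self.net, cfg)

    def exhaustive_robustness(self, gamma: int) -> float:
        return robustness_exhaustive(self.net, gamma, self.rule)
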