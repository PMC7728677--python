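"""Continuous-time Markov model of karyotype evolution on a phylogeny.

A lineage's karyotype is summarized by a state (i, system): the diploid
chromosome number ``i`` (even; both fusion classes merge two chromosome
pairs, so i moves in steps of two) and the sex-chromosome system, either
plain ``XY`` or ``neoXY`` (an X-autosome fusion product).  Four transitions
are permitted:

* ``delta`` -- AA-fusion:      (i, sys)   -> (i-2, sys)
* ``gamma`` -- autosome fission: (i, sys) -> (i+2, sys)
* ``sigma`` -- SA-fusion:      (i, XY)    -> (i-2, neoXY)
* ``rho``   -- neoXY decay:    (i, neoXY) -> (i, XY)

SA-fusions are only available to plain-XY lineages: a neoXY lineage must
first revert (rho) before fusing with another autosome's sex partner.
Transitions that would leave the configured diploid-number bounds get rate
zero, so the chain reflects off the boundaries by omission.

This module provides the state space and generator matrix, the Felsenstein
pruning log-likelihood of tip data, marginal ancestral-state probabilities,
and box-constrained maximum-likelihood estimation of the four rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.special import logsumexp

from .null_model import Karyotype

__all__ = [
    "KaryoState",
    "RateParams",
    "StateSpace",
    "TreeIndex",
    "FitResult",
    "FittingError",
    "build_state_space",
    "build_rate_matrix",
    "transition_probs",
    "state_karyotype",
    "index_tree",
    "tip_state_vector",
    "pruning_loglik",
    "ancestral_marginals",
    "fit_rates",
]

logger = logging.getLogger(__name__)

SYSTEMS = ("XY", "neoXY")

#: Lower box bound for rate estimation; effectively zero on the scale of
#: any realistic tree while keeping the likelihood surface smooth.
RATE_FLOOR = 1e-8


@dataclass(frozen=True, order=True)
class KaryoState:
    """A (diploid chromosome number, sex-chromosome system) Markov state."""

    i: int
    system: str

    def __post_init__(self) -> None:
        if self.i % 2 != 0 or self.i < 0:
            raise ValueError(f"diploid number must be a non-negative even "
                             f"integer, got {self.i}")
        if self.system not in SYSTEMS:
            raise ValueError(f"system must be one of {SYSTEMS}, got {self.system!r}")

    @property
    def label(self) -> str:
        return f"{self.i}{self.system}"

    @classmethod
    def from_label(cls, label: str) -> "KaryoState":
        s = label.strip()
        digits = "".join(ch for ch in s if ch.isdigit())
        system = s[len(digits):]
        if system not in SYSTEMS:
            # tolerate case variants such as "neoxy"
            lowered = system.lower()
            match = {sys.lower(): sys for sys in SYSTEMS}.get(lowered)
            if match is None:
                raise ValueError(f"cannot parse karyotype state label {label!r}")
            system = match
        return cls(i=int(digits), system=system)


@dataclass(frozen=True)
class RateParams:
    """Transition rates of the karyotype chain, per unit branch length."""

    delta: float   # AA-fusion
    gamma: float   # autosome fission
    sigma: float   # SA-fusion
    rho: float     # neoXY -> XY reversion

    def __post_init__(self) -> None:
        for name in ("delta", "gamma", "sigma", "rho"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")
            object.__setattr__(self, name, float(v))

    def as_array(self) -> np.ndarray:
        return np.array([self.delta, self.gamma, self.sigma, self.rho])

    def as_dict(self) -> dict[str, float]:
        return {"delta": self.delta, "gamma": self.gamma,
                "sigma": self.sigma, "rho": self.rho}


@dataclass(frozen=True)
class StateSpace:
    """Ordered state space over an even diploid-number interval."""

    min_i: int
    max_i: int
    states: tuple[KaryoState, ...]

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, state: KaryoState) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise KeyError(
                f"state {state.label} outside space [{self.min_i}, {self.max_i}]"
            ) from None

    def __contains__(self, state: KaryoState) -> bool:
        return state in self._index

    @property
    def _index(self) -> dict[KaryoState, int]:
        # tiny dict; rebuilt on demand to keep the dataclass frozen/hashable
        return {s: k for k, s in enumerate(self.states)}

    def labels(self) -> list[str]:
        return [s.label for s in self.states]


def build_state_space(min_i: int = 6, max_i: int = 12) -> StateSpace:
    """All (i, system) states with even i in [min_i, max_i].

    Ordered ascending in i with XY before neoXY, so the layout is
    deterministic.  ``min_i`` must be at least 4 (one autosome pair plus
    the sex pair).
    """
    if min_i % 2 != 0 or max_i % 2 != 0:
        raise ValueError(f"bounds must be even, got [{min_i}, {max_i}]")
    if min_i > max_i:
        raise ValueError(f"inverted bounds [{min_i}, {max_i}]")
    if min_i < 4:
        raise ValueError(f"min_i must be >= 4, got {min_i}")
    states = tuple(
        KaryoState(i=i, system=sys)
        for i in range(min_i, max_i + 1, 2)
        for sys in SYSTEMS
    )
    return StateSpace(min_i=min_i, max_i=max_i, states=states)


def build_rate_matrix(space: StateSpace, r: RateParams) -> np.ndarray:
    """Generator matrix Q over ``space`` with the four permitted moves.

    Off-diagonals hold the transition rates; each diagonal is minus its row
    sum.  Moves that would leave the diploid-number bounds are omitted
    (rate zero), i.e. the boundaries reflect.
    """
    n = space.n
    Q = np.zeros((n, n))
    for a, s in enumerate(space.states):
        down = KaryoState(s.i - 2, s.system) if s.i - 2 >= space.min_i else None
        up = KaryoState(s.i + 2, s.system) if s.i + 2 <= space.max_i else None
        if down is not None:
            Q[a, space.index(down)] += r.delta
        if up is not None:
            Q[a, space.index(up)] += r.gamma
        if s.system == "XY" and s.i - 2 >= space.min_i:
            Q[a, space.index(KaryoState(s.i - 2, "neoXY"))] += r.sigma
        if s.system == "neoXY":
            Q[a, space.index(KaryoState(s.i, "XY"))] += r.rho
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def classify_transition(space: StateSpace, a: int, b: int) -> str:
    """Name the event class of a permitted jump from state a to state b."""
    sa, sb = space.states[a], space.states[b]
    if sa.system == sb.system and sb.i == sa.i - 2:
        return "AA-fusion"
    if sa.system == sb.system and sb.i == sa.i + 2:
        return "fission"
    if sa.system == "XY" and sb.system == "neoXY" and sb.i == sa.i - 2:
        return "SA-fusion"
    if sa.system == "neoXY" and sb.system == "XY" and sb.i == sa.i:
        return "neoXY-decay"
    raise ValueError(f"{sa.label} -> {sb.label} is not a permitted transition")


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix exp(Q t) for a branch of length t."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if t == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    rows = P.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-10):
        raise ArithmeticError("rows of expm(Q t) failed to sum to 1")
    P /= rows[:, None]
    return P


def state_karyotype(state: KaryoState) -> Karyotype:
    """Karyotype used to weight the SA-fusion null for a Markov state.

    Both XY and neoXY lineages are treated as carrying one X/one Y (the
    neo-sex chromosome counts as the sex pair), so Da = i - 2.
    """
    return Karyotype(da=state.i - 2, xs=1, y=1)


# ---------------------------------------------------------------------------
# tree indexing and pruning


@dataclass
class TreeIndex:
    """Flat postorder view of a rooted dendropy tree.

    ``parent[v]`` indexes the parent of node v (-1 for the root, which is
    the last postorder entry); ``edge_length[v]`` is the length of the edge
    above v.  Tips map taxon labels to node indices.
    """

    tree: dendropy.Tree
    nodes: list
    parent: np.ndarray
    children: list[list[int]]
    edge_length: np.ndarray
    tip_index: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_tips(self) -> int:
        return len(self.tip_index)

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    @property
    def total_length(self) -> float:
        return float(self.edge_length[: self.root].sum())


def index_tree(tree: dendropy.Tree) -> TreeIndex:
    """Build a postorder index of ``tree``; branch lengths are mandatory."""
    nodes = list(tree.postorder_node_iter())
    order = {id(nd): k for k, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    lengths = np.zeros(len(nodes))
    children: list[list[int]] = [[] for _ in nodes]
    tip_index: dict[str, int] = {}
    for k, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[k] = order[id(nd.parent_node)]
            if nd.edge.length is None:
                raise ValueError(
                    "tree has an edge without a branch length; the karyotype "
                    "chain is time-dependent and needs lengths everywhere"
                )
            if nd.edge.length < 0:
                raise ValueError(f"negative branch length {nd.edge.length}")
            lengths[k] = float(nd.edge.length)
            children[parent[k]].append(k)
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is None:
                raise ValueError("tree has an unlabeled tip")
            if label in tip_index:
                raise ValueError(f"duplicate tip label {label!r}")
            tip_index[label] = k
    return TreeIndex(tree=tree, nodes=nodes, parent=parent, children=children,
                     edge_length=lengths, tip_index=tip_index)


def _as_state_map(tips) -> dict[str, KaryoState]:
    """Accept a {taxon: KaryoState} dict or a (taxon, diploid_number,
    system) DataFrame and return the dict form."""
    if isinstance(tips, dict):
        return tips
    if isinstance(tips, pd.DataFrame):
        out = {}
        for row in tips.itertuples(index=False):
            out[str(row.taxon)] = KaryoState(int(row.diploid_number),
                                             str(row.system))
        return out
    raise TypeError(f"unsupported tip-state container {type(tips)!r}")


def tip_state_vector(idx: TreeIndex, tips, space: StateSpace) -> np.ndarray:
    """Per-tip state indices aligned with the tree index.

    Returns an int array over all nodes; internal entries are -1.
    """
    states = _as_state_map(tips)
    out = np.full(idx.n_nodes, -1, dtype=int)
    missing = sorted(set(idx.tip_index) - set(states))
    if missing:
        raise ValueError(f"no karyotype state for tip(s): {', '.join(missing)}")
    for label, v in idx.tip_index.items():
        st = states[label]
        if st not in space:
            raise ValueError(
                f"tip {label!r} has state {st.label} outside the state space "
                f"[{space.min_i}, {space.max_i}]"
            )
        out[v] = space.index(st)
    return out


def _root_log_prior(root, space: StateSpace) -> np.ndarray:
    """Log prior over root states: fixed state, 'flat', or an array."""
    n = space.n
    if isinstance(root, KaryoState):
        lp = np.full(n, -np.inf)
        lp[space.index(root)] = 0.0
        return lp
    if isinstance(root, str) and root == "flat":
        return np.full(n, -np.log(n))
    arr = np.asarray(root, dtype=float)
    if arr.shape != (n,) or arr.min() < 0 or not np.isclose(arr.sum(), 1.0):
        raise ValueError("root prior must be a KaryoState, 'flat', or a "
                         "probability vector over the state space")
    with np.errstate(divide="ignore"):
        return np.log(arr)


def _edge_probs(idx: TreeIndex, Q: np.ndarray) -> list:
    """Per-node transition matrix across the edge above each node."""
    cache: dict[float, np.ndarray] = {}
    out: list = [None] * idx.n_nodes
    for v in range(idx.n_nodes):
        if idx.parent[v] < 0:
            continue
        t = float(idx.edge_length[v])
        if t not in cache:
            cache[t] = transition_probs(Q, t)
        out[v] = cache[t]
    return out


def _pruning_partials(idx: TreeIndex, tip_idx: np.ndarray, nstates: int,
                      P: list) -> tuple[np.ndarray, np.ndarray]:
    """Postorder partial likelihoods with per-node log rescaling.

    Returns (partials, log_scale): partials[v] is the conditional
    likelihood of the data below v given each state at v, rescaled so its
    maximum is 1; log_scale[v] accumulates the subtree's log rescaling.
    """
    L = np.zeros((idx.n_nodes, nstates))
    log_scale = np.zeros(idx.n_nodes)
    for v in range(idx.n_nodes):
        if idx.is_tip(v):
            L[v, tip_idx[v]] = 1.0
            continue
        vec = np.ones(nstates)
        for c in idx.children[v]:
            vec = vec * (P[c] @ L[c])
            log_scale[v] += log_scale[c]
        m = vec.max()
        if m <= 0:
            # impossible data below this node under Q; signal with -inf
            L[v] = 0.0
            log_scale[v] = -np.inf
            continue
        L[v] = vec / m
        log_scale[v] += np.log(m)
    return L, log_scale


def pruning_loglik(tree, tips, space: StateSpace, Q: np.ndarray,
                   root="flat") -> float:
    """Felsenstein pruning log-likelihood of tip karyotypes under Q.

    ``root`` is a fixed :class:`KaryoState`, the string ``"flat"``, or a
    probability vector over the state space.  With a fixed root only that
    state's root partial contributes.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    tip_idx = tip_state_vector(idx, tips, space)
    P = _edge_probs(idx, Q)
    L, log_scale = _pruning_partials(idx, tip_idx, space.n, P)
    lp = _root_log_prior(root, space)
    r = idx.root
    if not np.isfinite(log_scale[r]):
        return -np.inf
    with np.errstate(divide="ignore"):
        terms = lp + np.log(L[r])
    if np.all(np.isneginf(terms)):
        return -np.inf
    return float(logsumexp(terms) + log_scale[r])


def ancestral_marginals(tree, tips, space: StateSpace, Q: np.ndarray,
                        root="flat") -> np.ndarray:
    """Marginal posterior state probabilities at every node.

    Standard up-down algorithm: postorder partials combined with preorder
    "outside" messages.  Row v is the posterior distribution of node v's
    state given all tip data; rows sum to one.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    tip_idx = tip_state_vector(idx, tips, space)
    P = _edge_probs(idx, Q)
    L, _ = _pruning_partials(idx, tip_idx, space.n, P)
    prior = np.exp(_root_log_prior(root, space))

    down = np.zeros_like(L)          # outside message arriving at each node
    post = np.zeros_like(L)
    r = idx.root
    down[r] = prior
    for v in range(idx.n_nodes - 1, -1, -1):   # preorder (reverse postorder)
        vec = down[v] * L[v]
        s = vec.sum()
        if s <= 0:
            raise ArithmeticError("zero likelihood; data impossible under Q")
        post[v] = vec / s
        for c in idx.children[v]:
            sib = down[v].copy()
            for c2 in idx.children[v]:
                if c2 != c:
                    sib = sib * (P[c2] @ L[c2])
            down[c] = sib @ P[c]
    return post


# ---------------------------------------------------------------------------
# maximum-likelihood rate estimation


class FittingError(RuntimeError):
    """Raised when no optimizer restart converges; carries the best point."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class FitResult:
    """Maximum-likelihood rates and diagnostics."""

    rates: RateParams
    loglik: float
    converged: bool
    n_starts: int
    start_logliks: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"rates": self.rates.as_dict(), "loglik": self.loglik,
                "converged": self.converged, "n_starts": self.n_starts}


def fit_rates(tree, tips, space: StateSpace, root="flat", *,
              include_rho: bool = True, n_starts: int = 4, seed: int = 0,
              upper: float = 1e3, gtol: float = 1e-6) -> FitResult:
    """Box-constrained ML estimation of the four karyotype-chain rates.

    Optimizes over log-rates with L-BFGS-B from ``n_starts`` starting
    points (one moderate default plus log-uniform random draws).  With
    ``include_rho=False`` the neoXY reversion rate is pinned to zero,
    mirroring the sensitivity analysis of dropping that transition.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    tip_idx = tip_state_vector(idx, tips, space)
    del tip_idx  # validation only; pruning revalidates cheaply
    rng = np.random.default_rng(seed)
    free = 4 if include_rho else 3

    def unpack(x: np.ndarray) -> RateParams:
        r = np.exp(x)
        if include_rho:
            return RateParams(*r)
        return RateParams(r[0], r[1], r[2], 0.0)

    def nll(x: np.ndarray) -> float:
        Q = build_rate_matrix(space, unpack(x))
        ll = pruning_loglik(idx, tips, space, Q, root=root)
        return -ll if np.isfinite(ll) else 1e12

    lo, hi = np.log(RATE_FLOOR), np.log(upper)
    starts = [np.full(free, np.log(0.5))]
    starts += [rng.uniform(np.log(1e-3), np.log(10.0), size=free)
               for _ in range(max(0, n_starts - 1))]

    best = None
    start_lls = []
    any_ok = False
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * free,
                       options={"gtol": gtol, "maxiter": 500})
        ll = -res.fun
        start_lls.append(ll)
        any_ok = any_ok or bool(res.success)
        if best is None or ll > best[1]:
            best = (unpack(res.x), ll, bool(res.success))
    rates, ll, ok = best
    logger.info("fit_rates: loglik=%.6f rates=%s converged=%s", ll,
                rates.as_dict(), any_ok)
    result = FitResult(rates=rates, loglik=ll, converged=any_ok,
                       n_starts=len(starts), start_logliks=start_lls)
    if not any_ok:
        raise FittingError("no optimizer restart converged", best=result)
    return result
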