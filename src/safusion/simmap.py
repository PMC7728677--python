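"""Stochastic character maps of karyotype histories.

A stochastic map is one full realization of the karyotype chain along a
phylogeny: every branch carries an ordered list of (state, duration)
segments, and each boundary between segments is a dated transition event
(AA-fusion, SA-fusion, fission or neoXY decay).  Maps come from two
sources:

* :func:`simulate_forward` runs the chain root-to-tips unconditionally
  (exponential waiting times, competing transitions) -- used to generate
  synthetic ground truth;
* :func:`sample_conditional_maps` draws histories *conditional on observed
  tip states*: node states are sampled from the pruning conditionals
  root-to-tips, then each branch path is drawn conditional on its two
  endpoints by uniformization.

Summaries extract the proportion of total tree length spent in each state
and the event tallies; combining the time-in-state weights with the
closed-form fusion null gives the clade-level expected SA-fusion
proportion, which :func:`clade_report` compares against the observed
proportion across maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import (
    KaryoState,
    StateSpace,
    TreeIndex,
    _edge_probs,
    _pruning_partials,
    _root_log_prior,
    classify_transition,
    index_tree,
    tip_state_vector,
)
from .null_model import SexBias, p_sa
from .markov import state_karyotype

__all__ = [
    "Event",
    "StochasticMap",
    "MapSummary",
    "CladeReport",
    "simulate_forward",
    "sample_conditional_maps",
    "summarize_map",
    "expected_sa_proportion",
    "observed_sa_proportion",
    "clade_report",
]

_DUR_ATOL = 1e-9


@dataclass(frozen=True)
class Event:
    """A dated transition on a branch.

    ``node`` indexes the child end of the branch in the tree's postorder
    index; ``time`` is measured from the parent end of that branch.
    """

    node: int
    time: float
    source: int
    target: int
    kind: str


@dataclass
class StochasticMap:
    """A piecewise-constant state history over a whole tree.

    ``segments[v]`` lists (state index, duration) pairs along the edge
    above node v, ordered parent to child; the root's list is empty.
    Events are derived from the segment boundaries.
    """

    index: TreeIndex
    space: StateSpace
    root_state: int
    segments: list[list[tuple[int, float]]]

    events: list[Event] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.events:
            self.events = self._derive_events()
        self.validate()

    def _derive_events(self) -> list[Event]:
        out = []
        for v in range(self.index.n_nodes):
            segs = self.segments[v]
            t = 0.0
            for (a, da), (b, _db) in zip(segs, segs[1:]):
                t += da
                out.append(Event(node=v, time=t, source=a, target=b,
                                 kind=classify_transition(self.space, a, b)))
        return out

    def validate(self) -> None:
        for v in range(self.index.n_nodes):
            segs = self.segments[v]
            if v == self.index.root:
                if segs:
                    raise ValueError("root carries no edge; its segment "
                                     "list must be empty")
                continue
            if not segs:
                raise ValueError(f"node {v} has an edge but no segments")
            total = sum(d for _, d in segs)
            blen = float(self.index.edge_length[v])
            if abs(total - blen) > _DUR_ATOL * max(1.0, blen):
                raise ValueError(
                    f"segments on edge above node {v} sum to {total}, "
                    f"branch length is {blen}"
                )
            for (a, _), (b, _) in zip(segs, segs[1:]):
                classify_transition(self.space, a, b)  # raises if not allowed

    def node_state(self, v: int) -> int:
        """State at node v (child end of its edge; root state for the root)."""
        if v == self.index.root:
            return self.root_state
        return self.segments[v][-1][0]

    def parent_state(self, v: int) -> int:
        return self.node_state(self.index.parent[v])

    def tip_states(self) -> dict[str, KaryoState]:
        return {label: self.space.states[self.node_state(v)]
                for label, v in self.index.tip_index.items()}


@dataclass
class MapSummary:
    """Time-in-state proportions and event tallies of one map."""

    time_in_state: np.ndarray        # proportions over the state space
    counts: dict[str, int]
    total_length: float
    space: StateSpace

    def __post_init__(self) -> None:
        tot = float(self.time_in_state.sum())
        if abs(tot - 1.0) > 1e-12:
            raise ValueError(f"time-in-state proportions sum to {tot}, not 1")


def simulate_forward(tree, Q: np.ndarray, space: StateSpace,
                     root_state: KaryoState, seed=None) -> StochasticMap:
    """Simulate the karyotype chain forward over the tree.

    Exact Gillespie simulation along each branch: exponential waiting
    times with the current state's total exit rate, competing transitions
    chosen in proportion to their rates.  Deterministic under ``seed``
    (an int or a numpy Generator).
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    a0 = space.index(root_state)
    exit_rate = -Q.diagonal()
    segments: list[list[tuple[int, float]]] = [[] for _ in range(idx.n_nodes)]
    state_at: np.ndarray = np.full(idx.n_nodes, -1, dtype=int)
    state_at[idx.root] = a0

    # preorder: root is the last postorder entry
    for v in range(idx.n_nodes - 1, -1, -1):
        if v == idx.root:
            continue
        a = state_at[idx.parent[v]]
        t_left = float(idx.edge_length[v])
        segs: list[tuple[int, float]] = []
        while True:
            r = exit_rate[a]
            wait = rng.exponential(1.0 / r) if r > 0 else np.inf
            if wait >= t_left:
                segs.append((a, t_left))
                break
            segs.append((a, wait))
            t_left -= wait
            w = Q[a].copy()
            w[a] = 0.0
            a = int(rng.choice(len(w), p=w / w.sum()))
        if not segs:       # zero-length branch
            segs = [(a, 0.0)]
        segments[v] = segs
        state_at[v] = a
    return StochasticMap(index=idx, space=space, root_state=a0,
                         segments=segments)


# ---------------------------------------------------------------------------
# endpoint-conditioned path sampling (uniformization)


class _PathSampler:
    """Samples CTMC paths on a branch conditional on both endpoints.

    Uniformization: embed the chain in a Poisson process with rate
    ``Lambda = max exit rate`` and jump matrix ``R = I + Q / Lambda``.
    Conditional on endpoints (a, b) and branch length t, the number of
    (possibly virtual) jumps N has mass proportional to
    ``Poisson(Lambda t){n} * (R^n)[a, b]``; given N = n the interior
    states form a Markov bridge under R and the jump times are uniform
    order statistics.  Virtual (self) jumps are discarded at the end.
    When every rate is zero the path is trivially constant.
    """

    _MAX_POW = 4096

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.n = Q.shape[0]
        self.lam = float(-Q.diagonal().min())
        if self.lam > 0:
            self.R = np.eye(self.n) + Q / self.lam
        else:
            self.R = np.eye(self.n)
        self._pows = [np.eye(self.n), self.R.copy()]

    def rpow(self, k: int) -> np.ndarray:
        while len(self._pows) <= k:
            if len(self._pows) > self._MAX_POW:
                raise ArithmeticError("uniformization power cap exceeded")
            self._pows.append(self._pows[-1] @ self.R)
        return self._pows[k]

    def _sample_n_jumps(self, a: int, b: int, t: float, p_ab: float,
                        rng: np.random.Generator) -> int:
        lam_t = self.lam * t
        u = rng.uniform() * p_ab
        pois = np.exp(-lam_t)       # Poisson(lam t) pmf at 0, then recurred
        acc = 0.0
        n = 0
        cap = int(lam_t + 12.0 * np.sqrt(lam_t + 1.0) + 50)
        while True:
            acc += pois * self.rpow(n)[a, b]
            if acc >= u or n >= cap:
                return n
            n += 1
            pois *= lam_t / n

    def sample_path(self, a: int, b: int, t: float, p_ab: float,
                    rng: np.random.Generator) -> list[tuple[int, float]]:
        """One endpoint-conditioned path as (state, duration) segments."""
        if t == 0.0 or self.lam == 0.0:
            if a != b:
                raise ArithmeticError(
                    "endpoints differ on a branch the chain cannot cross"
                )
            return [(a, t)]
        n = self._sample_n_jumps(a, b, t, p_ab, rng)
        if n == 0:
            return [(a, t)]
        # Markov bridge over the uniformized jump chain
        states = [a]
        for k in range(1, n):
            w = self.R[states[-1]] * self.rpow(n - k)[:, b]
            s = w.sum()
            if s <= 0:
                raise ArithmeticError("bridge step with zero mass")
            states.append(int(rng.choice(self.n, p=w / s)))
        states.append(b)
        times = np.sort(rng.uniform(0.0, t, size=n))
        # merge virtual jumps into segments
        segs: list[tuple[int, float]] = []
        cur, t0 = states[0], 0.0
        for k in range(1, n + 1):
            if states[k] != cur:
                segs.append((cur, float(times[k - 1] - t0)))
                cur, t0 = states[k], float(times[k - 1])
        segs.append((cur, float(t - t0)))
        return segs


def _sample_node_states(idx: TreeIndex, L: np.ndarray, P: list,
                        prior: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw a joint node-state assignment from the pruning conditionals."""
    states = np.full(idx.n_nodes, -1, dtype=int)
    w = prior * L[idx.root]
    s = w.sum()
    if s <= 0:
        raise ArithmeticError("zero likelihood at the root")
    states[idx.root] = int(rng.choice(len(w), p=w / s))
    for v in range(idx.n_nodes - 1, -1, -1):
        if v == idx.root:
            continue
        a = states[idx.parent[v]]
        w = P[v][a] * L[v]
        s = w.sum()
        if s <= 0:
            raise ArithmeticError(
                f"no state at node {v} is compatible with its parent"
            )
        states[v] = int(rng.choice(len(w), p=w / s))
    return states


def sample_conditional_maps(tree, tips, space: StateSpace, Q: np.ndarray,
                            root="flat", n_maps: int = 100,
                            seed=None) -> list[StochasticMap]:
    """Stochastic maps conditional on the observed tip karyotypes.

    Each map is an exact draw from the distribution of histories given the
    tip data: a joint node-state sample from the pruning conditionals,
    then an endpoint-conditioned uniformization path on every branch.
    Every returned map reproduces the tip states exactly.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    tip_idx = tip_state_vector(idx, tips, space)
    P = _edge_probs(idx, Q)
    L, log_scale = _pruning_partials(idx, tip_idx, space.n, P)
    if not np.isfinite(log_scale[idx.root]):
        raise ArithmeticError("tip data have zero likelihood under Q")
    prior = np.exp(_root_log_prior(root, space))
    sampler = _PathSampler(Q)

    maps = []
    for _ in range(n_maps):
        node_state = _sample_node_states(idx, L, P, prior, rng)
        segments: list[list[tuple[int, float]]] = \
            [[] for _ in range(idx.n_nodes)]
        for v in range(idx.n_nodes):
            if v == idx.root:
                continue
            a = node_state[idx.parent[v]]
            b = node_state[v]
            t = float(idx.edge_length[v])
            segments[v] = sampler.sample_path(a, b, t, P[v][a, b], rng)
        maps.append(StochasticMap(index=idx, space=space,
                                  root_state=int(node_state[idx.root]),
                                  segments=segments))
    return maps


# ---------------------------------------------------------------------------
# summaries and the clade-level comparison


EVENT_KINDS = ("AA-fusion", "SA-fusion", "fission", "neoXY-decay")


def summarize_map(smap: StochasticMap, space: StateSpace | None = None
                  ) -> MapSummary:
    """Time-in-state proportions and event tallies of one map."""
    space = space or smap.space
    occ = np.zeros(space.n)
    for v in range(smap.index.n_nodes):
        for s, d in smap.segments[v]:
            occ[s] += d
    total = float(occ.sum())
    if total <= 0:
        raise ValueError("map has zero total branch length")
    counts = {k: 0 for k in EVENT_KINDS}
    for ev in smap.events:
        counts[ev.kind] += 1
    return MapSummary(time_in_state=occ / total, counts=counts,
                      total_length=total, space=space)


def expected_sa_proportion(summary: MapSummary,
                           b: SexBias | float | None = None) -> float:
    """Time-weighted null expectation of the SA-fusion proportion.

    Each state's occupancy weight multiplies the closed-form P(SA) of the
    karyotype it implies (Da = i - 2 with an X/Y pair for both XY and
    neoXY lineages).
    """
    weights = summary.time_in_state
    return float(sum(
        w * p_sa(state_karyotype(s), b)
        for w, s in zip(weights, summary.space.states) if w > 0
    ))


def observed_sa_proportion(summary: MapSummary) -> float | None:
    """Realized SA share among fusion events: SA / (SA + AA).

    Returns ``None`` for a fusion-free map (the proportion is undefined);
    the model has no SS transition, so SS events never enter.
    """
    n_sa = summary.counts["SA-fusion"]
    n_aa = summary.counts["AA-fusion"]
    if n_sa + n_aa == 0:
        return None
    return n_sa / (n_sa + n_aa)


@dataclass
class CladeReport:
    """Observed vs expected SA-fusion proportions across stochastic maps."""

    expected_mean: float
    expected_interval: tuple[float, float]
    observed_mean: float | None
    observed_interval: tuple[float, float] | None
    mean_sa_count: float
    n_maps: int
    n_excluded: int                 # fusion-free maps dropped from observed
    level: float
    overlap: bool | None

    def as_dict(self) -> dict:
        return {
            "expected_mean": self.expected_mean,
            "expected_interval": list(self.expected_interval),
            "observed_mean": self.observed_mean,
            "observed_interval": (None if self.observed_interval is None
                                  else list(self.observed_interval)),
            "mean_sa_count": self.mean_sa_count,
            "n_maps": self.n_maps,
            "n_excluded": self.n_excluded,
            "level": self.level,
            "overlap": self.overlap,
        }


def _interval(x: np.ndarray, level: float) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0
    q = np.quantile(x, [lo, 1.0 - lo])
    return float(q[0]), float(q[1])


def clade_report(maps: list[StochasticMap], space: StateSpace | None = None,
                 b: SexBias | float | None = None,
                 level: float = 0.95) -> CladeReport:
    """Compare observed and expected SA-fusion proportions across maps.

    Per map, the expected proportion is the time-weighted null and the
    observed proportion is SA / (SA + AA); means and equal-tail credible
    intervals are taken across maps.  Fusion-free maps contribute to the
    expected side but are excluded (and counted) on the observed side.
    ``overlap`` reports whether the two intervals intersect.
    """
    if len(maps) < 2:
        raise ValueError("clade_report needs at least 2 maps")
    space = space or maps[0].space
    expected, observed, sa_counts = [], [], []
    for m in maps:
        s = summarize_map(m, space)
        expected.append(expected_sa_proportion(s, b))
        obs = observed_sa_proportion(s)
        if obs is not None:
            observed.append(obs)
        sa_counts.append(s.counts["SA-fusion"])
    expected = np.asarray(expected)
    e_int = _interval(expected, level)
    if observed:
        observed = np.asarray(observed)
        o_int = _interval(observed, level)
        overlap = (e_int[0] <= o_int[1]) and (o_int[0] <= e_int[1])
        o_mean = float(observed.mean())
    else:
        o_int, o_mean, overlap = None, None, None
    return CladeReport(
        expected_mean=float(expected.mean()),
        expected_interval=e_int,
        observed_mean=o_mean,
        observed_interval=o_int,
        mean_sa_count=float(np.mean(sa_counts)),
        n_maps=len(maps),
        n_excluded=len(maps) - (0 if o_mean is None else len(observed)),
        level=level,
        overlap=overlap,
    )
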