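"""Stochastic maps: forward simulation, conditional sampling, summaries."""

import math

import dendropy
import numpy as np
import pytest
from scipy.stats import kstest

from safusion.markov import (
    KaryoState,
    RateParams,
    ancestral_marginals,
    build_rate_matrix,
    build_state_space,
    index_tree,
    transition_probs,
)
from safusion.simmap import (
    StochasticMap,
    clade_report,
    expected_sa_proportion,
    observed_sa_proportion,
    sample_conditional_maps,
    simulate_forward,
    summarize_map,
)
from safusion.synthetic import TreeSpec, yule_tree

ROOT = KaryoState(12, "XY")


def cherry(t=1.0):
    return dendropy.Tree.get(data=f"(A:{t},B:{t});", schema="newick")


def test_forward_zero_rates_is_constant(space):
    Q = build_rate_matrix(space, RateParams(0, 0, 0, 0))
    tree = cherry(2.0)
    m = simulate_forward(tree, Q, space, ROOT, seed=0)
    assert not m.events
    for v in range(m.index.n_nodes):
        segs = m.segments[v]
        if v != m.index.root:
            assert segs == [(space.index(ROOT), 2.0)]


def test_forward_rho_only_from_xy_never_moves(space):
    Q = build_rate_matrix(space, RateParams(0, 0, 0, 5.0))
    m = simulate_forward(cherry(50.0), Q, space, ROOT, seed=1)
    assert not m.events


def test_forward_segments_tile_branches(space, rates):
    Q = build_rate_matrix(space, rates)
    tree = yule_tree(TreeSpec(n_tips=12, seed=4))
    m = simulate_forward(tree, Q, space, ROOT, seed=2)
    # StochasticMap.validate() runs in the constructor; re-check durations
    for v in range(m.index.n_nodes):
        if v != m.index.root:
            assert sum(d for _, d in m.segments[v]) == pytest.approx(
                float(m.index.edge_length[v]), abs=1e-9)
    assert all(d >= 0 for segs in m.segments for _, d in segs)


def test_forward_mean_event_count_poisson(space):
    """With slow symmetric rates, events arrive at ~(delta+gamma+sigma)
    per unit length: total count over many replicates matches the Poisson
    thinning expectation within Monte-Carlo error."""
    wide = build_state_space(6, 16)
    rate = 0.01
    Q = build_rate_matrix(wide, RateParams(rate, rate, rate, 0.0))
    tree = yule_tree(TreeSpec(n_tips=8, seed=6))
    L = index_tree(tree).total_length
    rng = np.random.default_rng(7)
    counts = [len(simulate_forward(tree, Q, wide, ROOT, seed=rng).events)
              for _ in range(2000)]
    mean = float(np.mean(counts))
    se = float(np.std(counts, ddof=1)) / math.sqrt(len(counts))
    assert abs(mean - 3 * rate * L) <= 4 * se


def test_forward_endpoint_distribution_matches_expm(space, rates):
    """Empirical tip-state frequencies on a single branch agree with the
    matrix-exponential row of the generator."""
    Q = build_rate_matrix(space, rates)
    t = 0.8
    P_row = transition_probs(Q, t)[space.index(ROOT)]
    tree = cherry(t)
    idx = index_tree(tree)
    tip_a = idx.tip_index["A"]
    rng = np.random.default_rng(8)
    n = 20_000
    freq = np.zeros(space.n)
    for _ in range(n):
        m = simulate_forward(idx, Q, space, ROOT, seed=rng)
        freq[m.node_state(tip_a)] += 1
    freq /= n
    se = np.sqrt(P_row * (1 - P_row) / n)
    assert np.all(np.abs(freq - P_row) <= 4 * se + 1e-12)


def test_conditional_zero_rates_constant(space):
    Q = build_rate_matrix(space, RateParams(0, 0, 0, 0))
    tips = {"A": ROOT, "B": ROOT}
    maps = sample_conditional_maps(cherry(), tips, space, Q, ROOT,
                                   n_maps=5, seed=0)
    for m in maps:
        assert not m.events
        assert m.tip_states() == tips


def test_conditional_maps_reproduce_tips(space, rates, three_taxon_tree,
                                         three_taxon_tips):
    Q = build_rate_matrix(space, rates)
    maps = sample_conditional_maps(three_taxon_tree, three_taxon_tips, space,
                                   Q, "flat", n_maps=25, seed=3)
    assert all(m.tip_states() == three_taxon_tips for m in maps)


def test_conditional_maps_seed_deterministic(space, rates, three_taxon_tree,
                                             three_taxon_tips):
    Q = build_rate_matrix(space, rates)
    a = sample_conditional_maps(three_taxon_tree, three_taxon_tips, space, Q,
                                "flat", n_maps=4, seed=11)
    b = sample_conditional_maps(three_taxon_tree, three_taxon_tips, space, Q,
                                "flat", n_maps=4, seed=11)
    assert [m.segments for m in a] == [m.segments for m in b]


def test_conditional_jump_time_law(space):
    """rho-only chain conditioned on neoXY -> XY over one branch: exactly
    one real jump whose time follows a truncated exponential."""
    rho, t = 1.4, 1.0
    Q = build_rate_matrix(space, RateParams(0, 0, 0, rho))
    tips = {"A": KaryoState(12, "XY"), "B": KaryoState(12, "neoXY")}
    root = KaryoState(12, "neoXY")
    maps = sample_conditional_maps(cherry(t), tips, space, Q, root,
                                   n_maps=10_000, seed=5)
    idx = maps[0].index
    tip_a = idx.tip_index["A"]
    times = []
    for m in maps:
        evs = [e for e in m.events if e.node == tip_a]
        assert len(evs) == 1 and evs[0].kind == "neoXY-decay"
        # the B edge stays neoXY throughout
        assert len(m.segments[idx.tip_index["B"]]) == 1
        times.append(evs[0].time)

    def trunc_exp_cdf(x):
        return (1 - np.exp(-rho * np.asarray(x))) / (1 - math.exp(-rho * t))

    assert kstest(times, trunc_exp_cdf).pvalue > 0.01


def test_conditional_node_frequencies_match_marginals(space, rates):
    """Node-state frequencies across maps reproduce the pruning-based
    marginal ancestral probabilities within binomial error."""
    tree = dendropy.Tree.get(
        data="((A:0.2,B:0.6):0.3,(C:0.5,D:0.1):0.7);", schema="newick")
    tips = {"A": KaryoState(8, "XY"), "B": KaryoState(10, "neoXY"),
            "C": KaryoState(12, "XY"), "D": KaryoState(10, "XY")}
    Q = build_rate_matrix(space, rates)
    post = ancestral_marginals(tree, tips, space, Q, "flat")
    n = 2000
    maps = sample_conditional_maps(tree, tips, space, Q, "flat",
                                   n_maps=n, seed=13)
    idx = maps[0].index
    for v in range(idx.n_nodes):
        if idx.is_tip(v):
            continue
        freq = np.bincount([m.node_state(v) for m in maps],
                           minlength=space.n) / n
        se = np.sqrt(post[v] * (1 - post[v]) / n)
        assert np.all(np.abs(freq - post[v]) <= 4 * se + 1e-9)


# ---------------------------------------------------------------------------
# summaries


def one_branch_map(space, segs, root_label="10XY"):
    tree = dendropy.Tree.get(data="(A:2.0,B:2.0);", schema="newick")
    idx = index_tree(tree)
    root_state = space.index(KaryoState.from_label(root_label))
    segments = [[] for _ in range(idx.n_nodes)]
    segments[idx.tip_index["A"]] = segs
    segments[idx.tip_index["B"]] = [(root_state, 2.0)]
    return StochasticMap(index=idx, space=space, root_state=root_state,
                         segments=segments)


def test_summary_constant_map(space):
    m = one_branch_map(space, [(space.index(KaryoState(10, "XY")), 2.0)])
    s = summarize_map(m)
    assert s.time_in_state[space.index(KaryoState(10, "XY"))] == 1.0
    assert sum(s.counts.values()) == 0


def test_summary_midpoint_sa_event(space):
    a = space.index(KaryoState(10, "XY"))
    b = space.index(KaryoState(8, "neoXY"))
    m = one_branch_map(space, [(a, 1.0), (b, 1.0)])
    s = summarize_map(m)
    assert s.counts["SA-fusion"] == 1
    assert s.time_in_state[a] == pytest.approx(0.75)   # 1 + full B branch
    assert s.time_in_state[b] == pytest.approx(0.25)


def test_summary_additive_over_branches(space, rates):
    Q = build_rate_matrix(space, rates)
    tree = yule_tree(TreeSpec(n_tips=10, seed=9))
    m = simulate_forward(tree, Q, space, ROOT, seed=10)
    s = summarize_map(m)
    occ = np.zeros(space.n)
    for v in range(m.index.n_nodes):
        for st, d in m.segments[v]:
            occ[st] += d
    assert np.allclose(s.time_in_state, occ / occ.sum(), atol=1e-12)
    assert s.total_length == pytest.approx(m.index.total_length)


def test_inconsistent_segments_rejected(space):
    a = space.index(KaryoState(10, "XY"))
    with pytest.raises(ValueError, match="sum"):
        one_branch_map(space, [(a, 0.5)])


def test_expected_sa_proportion_weighting(space):
    a = space.index(KaryoState(8, "XY"))     # Da=6 -> p_sa = 0.5
    m = one_branch_map(space, [(a, 2.0)], root_label="8XY")
    s = summarize_map(m)
    assert expected_sa_proportion(s, 0.5) == pytest.approx(0.5)
    # equal weight on p_sa = 0.5 and p_sa = 0.25 averages to 0.375
    c = space.index(KaryoState(12, "XY"))    # placeholder for the mix below
    s.time_in_state = np.zeros(space.n)
    s.time_in_state[a] = 0.5
    s.time_in_state[c] = 0.5
    from safusion.null_model import Karyotype, p_sa
    expect = 0.5 * 0.5 + 0.5 * p_sa(Karyotype(10, 1, 1), 0.5)
    assert expected_sa_proportion(s, 0.5) == pytest.approx(expect)
    # the neoXY label carries the same karyotype weight
    s2 = summarize_map(m)
    s2.time_in_state = np.zeros(space.n)
    s2.time_in_state[space.index(KaryoState(8, "neoXY"))] = 1.0
    assert expected_sa_proportion(s2, 0.5) == pytest.approx(0.5)


def test_observed_sa_proportion_cases(space):
    m = one_branch_map(space, [(space.index(KaryoState(10, "XY")), 2.0)])
    s = summarize_map(m)
    s.counts = {"SA-fusion": 4, "AA-fusion": 6, "fission": 3, "neoXY-decay": 0}
    assert observed_sa_proportion(s) == pytest.approx(0.4)
    s.counts = {"SA-fusion": 3, "AA-fusion": 0, "fission": 0, "neoXY-decay": 0}
    assert observed_sa_proportion(s) == 1.0
    s.counts = {"SA-fusion": 0, "AA-fusion": 0, "fission": 5, "neoXY-decay": 1}
    assert observed_sa_proportion(s) is None


def test_clade_report_identical_maps(space, rates):
    Q = build_rate_matrix(space, rates)
    tree = yule_tree(TreeSpec(n_tips=10, seed=14))
    m = simulate_forward(tree, Q, space, ROOT, seed=15)
    rep = clade_report([m, m, m], b=0.5)
    assert rep.expected_interval[0] == rep.expected_interval[1]
    assert rep.expected_mean == pytest.approx(
        expected_sa_proportion(summarize_map(m), 0.5))
    assert rep.n_maps == 3


def test_clade_report_fusion_free(space):
    Q = build_rate_matrix(space, RateParams(0, 0, 0, 0))
    maps = sample_conditional_maps(cherry(), {"A": ROOT, "B": ROOT}, space,
                                   Q, ROOT, n_maps=3, seed=0)
    rep = clade_report(maps, b=0.5)
    assert rep.observed_mean is None
    assert rep.overlap is None
    assert rep.n_excluded == 3
    with pytest.raises(ValueError):
        clade_report(maps[:1])
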