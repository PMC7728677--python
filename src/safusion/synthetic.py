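"""Synthetic trees and karyotype datasets with known ground truth.

Every stage of the clade-level pipeline can be exercised without external
data: a pure-birth (Yule) tree stands in for a dated ultrametric
phylogeny, and the karyotype chain is simulated forward along it so the
full history -- rates, per-branch paths, event tallies and tip states --
is known exactly.  The default geometry (120 tips, unit depth, diploid
numbers bounded in [6, 12], root fixed at 12 chromosomes with a plain XY
system) matches the scale of a moderately sized insect clade with a
handful of neoXY lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .markov import (
    KaryoState,
    RateParams,
    StateSpace,
    build_rate_matrix,
    build_state_space,
)
from .simmap import StochasticMap, simulate_forward

__all__ = ["TreeSpec", "SyntheticDataset", "yule_tree", "synthesize",
           "DEFAULT_RATES", "DEFAULT_ROOT"]

#: Default generating rates: fusions and fissions at about one event per
#: unit of branch length, SA-fusions at half that, and a reversion rate
#: fast enough that neoXY lineages stay a minority of tips.
DEFAULT_RATES = RateParams(delta=1.0, gamma=1.0, sigma=0.5, rho=4.0)

#: Default root condition: the ancestral karyotype has 12 chromosomes and
#: a plain XY system.
DEFAULT_ROOT = KaryoState(12, "XY")


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of a simulated pure-birth tree."""

    n_tips: int = 120
    birth_rate: float = 1.0
    seed: int = 0
    scale: float | None = 1.0       # rescale to this root-to-tip depth

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError(f"need at least 2 tips, got {self.n_tips}")
        if self.birth_rate <= 0:
            raise ValueError(f"birth rate must be > 0, got {self.birth_rate}")
        if self.scale is not None and self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")


@dataclass
class SyntheticDataset:
    """A simulated dataset with its complete generating history."""

    tree: dendropy.Tree
    true_rates: RateParams
    true_history: StochasticMap
    tip_states: pd.DataFrame        # columns: taxon, diploid_number, system
    space: StateSpace


def yule_tree(spec: TreeSpec) -> dendropy.Tree:
    """Simulate an ultrametric pure-birth tree.

    Standard Yule construction: starting from two lineages, each
    speciation waits an Exp(k * birth_rate) time and splits a uniformly
    chosen extant lineage; after the last split the tips are extended by
    one further Exp(n * birth_rate) draw so no tip sits exactly on a
    node.  Deterministic under ``spec.seed``; optionally rescaled to a
    fixed root-to-tip depth.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < spec.n_tips:
        t += rng.exponential(1.0 / (spec.birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        parent.edge.length = t - parent.birth_time
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            child.birth_time = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (spec.birth_rate * len(active)))
    for leaf in active:
        leaf.edge.length = t_end - leaf.birth_time
    for j, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"t{j + 1}")
    if spec.scale is not None:
        factor = spec.scale / t_end
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    for nd in tree.preorder_node_iter():
        if hasattr(nd, "birth_time"):
            del nd.birth_time
    return tree


def synthesize(spec: TreeSpec | None = None,
               rates: RateParams = DEFAULT_RATES,
               root_state: KaryoState = DEFAULT_ROOT,
               space: StateSpace | None = None,
               seed: int | None = None) -> SyntheticDataset:
    """Simulate a full karyotype dataset on a fresh Yule tree.

    The tree seed comes from ``spec``; the history seed defaults to
    ``spec.seed + 1`` so tree shape and character history use distinct
    streams.  Returns the tree, generating rates, complete per-branch
    history, and the tip-state table every downstream stage consumes.
    """
    spec = spec or TreeSpec()
    space = space or build_state_space(6, 12)
    if root_state not in space:
        raise ValueError(f"root state {root_state.label} outside the space")
    tree = yule_tree(spec)
    Q = build_rate_matrix(space, rates)
    history_seed = spec.seed + 1 if seed is None else seed
    history = simulate_forward(tree, Q, space, root_state, seed=history_seed)
    rows = [
        {"taxon": label, "diploid_number": st.i, "system": st.system}
        for label, st in sorted(history.tip_states().items())
    ]
    tips = pd.DataFrame(rows, columns=["taxon", "diploid_number", "system"])
    return SyntheticDataset(tree=tree, true_rates=rates, true_history=history,
                            tip_states=tips, space=space)
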