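"""File formats: Newick trees, tip-state tables, map serialization, reports.

Trees are plain Newick with mandatory branch lengths (the karyotype chain
is time-dependent, so a tree without lengths is rejected rather than
silently given unit branches).  Tip karyotypes are CSV with a strict
(taxon, diploid_number, system) header.  Stochastic maps round-trip in two
forms: a SIMMAP-style annotated Newick in which each branch length is
replaced by a ``{state,duration:state,duration:...}`` list ordered parent
to child, and a lossless JSON document.  Reports serialize to JSON or TSV
with the effective run configuration embedded for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .markov import KaryoState, StateSpace, build_state_space, index_tree
from .simmap import StochasticMap

__all__ = [
    "FormatError",
    "read_newick",
    "write_newick",
    "read_tip_states",
    "write_tip_states",
    "to_simmap_newick",
    "from_simmap_newick",
    "map_to_json",
    "map_from_json",
    "write_report",
]


class FormatError(ValueError):
    """An input file violates its expected format."""


# ---------------------------------------------------------------------------
# trees


def read_newick(path, require_lengths: bool = True) -> dendropy.Tree:
    """Read a rooted Newick tree; labels must be unique, lengths present."""
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"{path}: malformed Newick ({exc})") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()
              if lf.taxon is not None]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate tip label(s) "
                          f"{', '.join(sorted(dupes))}")
    if require_lengths:
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                raise FormatError(
                    f"{path}: edge above "
                    f"{nd.taxon.label if nd.taxon else 'an internal node'} "
                    f"has no branch length"
                )
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)
    )


# ---------------------------------------------------------------------------
# tip-state tables

_TIP_COLUMNS = ["taxon", "diploid_number", "system"]


def read_tip_states(path) -> pd.DataFrame:
    """Read a (taxon, diploid_number, system) CSV of tip karyotypes.

    Systems are normalized case-insensitively to {XY, neoXY}; diploid
    numbers must be even integers.  Errors name the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != _TIP_COLUMNS:
        raise FormatError(
            f"{path}: expected header {','.join(_TIP_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    norm = {"xy": "XY", "neoxy": "neoXY"}
    systems = []
    for k, row in df.iterrows():
        sys_raw = str(row["system"]).strip()
        sys = norm.get(sys_raw.lower())
        if sys is None:
            raise FormatError(
                f"{path} row {k + 1} ({row['taxon']}): unknown sex system "
                f"{sys_raw!r}; expected XY or neoXY"
            )
        systems.append(sys)
        n = row["diploid_number"]
        if float(n) != int(n) or int(n) % 2 != 0:
            raise FormatError(
                f"{path} row {k + 1} ({row['taxon']}): diploid number {n} "
                f"must be an even integer"
            )
    out = df.copy()
    out["system"] = systems
    out["diploid_number"] = out["diploid_number"].astype(int)
    out["taxon"] = out["taxon"].astype(str)
    dupes = out["taxon"][out["taxon"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate taxon row(s) "
                          f"{', '.join(sorted(set(dupes)))}")
    return out


def write_tip_states(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_TIP_COLUMNS)


# ---------------------------------------------------------------------------
# stochastic-map serialization


def to_simmap_newick(smap: StochasticMap) -> str:
    """Serialize a map as SIMMAP-style Newick.

    Each branch length is replaced by ``{state,dur:state,dur}`` with
    segments ordered parent to child; states use labels like ``12XY``.
    """
    idx = smap.index
    order = {id(nd): k for k, nd in enumerate(idx.nodes)}

    def seg_string(v: int) -> str:
        parts = [f"{smap.space.states[s].label},{float(d)!r}"
                 for s, d in smap.segments[v]]
        return "{" + ":".join(parts) + "}"

    def render(nd) -> str:
        v = order[id(nd)]
        if not nd.child_nodes():
            return f"{nd.taxon.label}:{seg_string(v)}"
        inner = ",".join(render(c) for c in nd.child_nodes())
        if v == idx.root:
            return f"({inner})"
        return f"({inner}):{seg_string(v)}"

    return render(idx.nodes[idx.root]) + ";"


class _SimmapParser:
    """Recursive-descent parser for the SIMMAP-style dialect above."""

    def __init__(self, text: str, space: StateSpace):
        self.text = text.strip()
        self.pos = 0
        self.space = space
        self.segments: dict[int, list[tuple[int, float]]] = {}
        self.taxa = dendropy.TaxonNamespace()

    def fail(self, msg: str):
        raise FormatError(f"simmap parse error at position {self.pos}: {msg}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            self.fail(f"expected {ch!r}, found {self.peek()!r}")
        self.pos += 1

    def label(self) -> str:
        start = self.pos
        while self.peek() and self.peek() not in "(),:;{}":
            self.pos += 1
        return self.text[start:self.pos]

    def segs(self) -> list[tuple[int, float]]:
        self.expect("{")
        out = []
        while True:
            chunk_start = self.pos
            while self.peek() and self.peek() not in ":}":
                self.pos += 1
            chunk = self.text[chunk_start:self.pos]
            try:
                state_label, dur = chunk.rsplit(",", 1)
                s = self.space.index(KaryoState.from_label(state_label))
                out.append((s, float(dur)))
            except (ValueError, KeyError):
                self.fail(f"bad segment {chunk!r}")
            if self.peek() == ":":
                self.pos += 1
                continue
            self.expect("}")
            return out

    def clade(self) -> dendropy.Node:
        node = dendropy.Node()
        if self.peek() == "(":
            self.pos += 1
            node.add_child(self.clade())
            while self.peek() == ",":
                self.pos += 1
                node.add_child(self.clade())
            self.expect(")")
            self.label()  # optional internal label, discarded
        else:
            name = self.label()
            if not name:
                self.fail("empty tip label")
            node.taxon = self.taxa.new_taxon(label=name)
        if self.peek() == ":":
            self.pos += 1
            segs = self.segs()
            self.segments[id(node)] = segs
            node.edge.length = sum(d for _, d in segs)
        return node

    def parse(self) -> tuple[dendropy.Tree, dict[int, list]]:
        root = self.clade()
        self.expect(";")
        tree = dendropy.Tree(taxon_namespace=self.taxa)
        tree.seed_node = root
        return tree, self.segments


def from_simmap_newick(text: str, space: StateSpace) -> StochasticMap:
    """Parse the SIMMAP-style dialect back into a :class:`StochasticMap`."""
    tree, by_node = _SimmapParser(text, space).parse()
    idx = index_tree(tree)
    segments: list[list[tuple[int, float]]] = [[] for _ in range(idx.n_nodes)]
    for v, nd in enumerate(idx.nodes):
        if v == idx.root:
            continue
        segs = by_node.get(id(nd))
        if segs is None:
            raise FormatError("a non-root edge lacks a segment annotation")
        segments[v] = segs
    first_child = idx.children[idx.root][0]
    root_state = segments[first_child][0][0]
    return StochasticMap(index=idx, space=space, root_state=root_state,
                         segments=segments)


def map_to_json(smap: StochasticMap) -> dict:
    """Lossless JSON form of a map (tree, space bounds, segments)."""
    idx = smap.index
    return {
        "newick": idx.tree.as_string(schema="newick", suppress_rooting=True,
                                     unquoted_underscores=True).strip(),
        "space": {"min_i": smap.space.min_i, "max_i": smap.space.max_i},
        "root_state": smap.space.states[smap.root_state].label,
        "segments": {
            str(v): [[smap.space.states[s].label, d]
                     for s, d in smap.segments[v]]
            for v in range(idx.n_nodes) if v != idx.root
        },
    }


def map_from_json(doc: dict) -> StochasticMap:
    space = build_state_space(doc["space"]["min_i"], doc["space"]["max_i"])
    tree = dendropy.Tree.get(data=doc["newick"], schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    idx = index_tree(tree)
    segments: list[list[tuple[int, float]]] = [[] for _ in range(idx.n_nodes)]
    for key, segs in doc["segments"].items():
        segments[int(key)] = [
            (space.index(KaryoState.from_label(lbl)), float(d))
            for lbl, d in segs
        ]
    root_state = space.index(KaryoState.from_label(doc["root_state"]))
    return StochasticMap(index=idx, space=space, root_state=root_state,
                         segments=segments)


# ---------------------------------------------------------------------------
# reports


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    return x


def write_report(report, path, fmt: str = "json", config: dict | None = None
                 ) -> None:
    """Write a result object (anything with ``as_dict``) to JSON or TSV.

    The effective run configuration, including all seeds, is embedded
    under ``"config"`` so any output can be regenerated.
    """
    doc = report.as_dict() if hasattr(report, "as_dict") else dict(report)
    doc = _jsonify(doc)
    if config is not None:
        doc["config"] = _jsonify(config)
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif fmt == "tsv":
        flat = _flatten(doc)
        lines = ["\t".join(str(k) for k in flat)] + \
                ["\t".join(json.dumps(v) if isinstance(v, (list, dict))
                           else str(v) for v in flat.values())]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _flatten(doc: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in doc.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out
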