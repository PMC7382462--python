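"""Ancestral-state reconstruction by parsimony over a 5-letter alphabet.

Unit-cost Sankoff dynamic programming over a rooted species tree with the
alphabet {A, C, G, T, -}: gap is an ordinary fifth state, and multifurcating
nodes are handled natively rather than arbitrarily resolved. Alignment
columns with more than one gap are discarded before reconstruction because
of alignment uncertainty. For every node the full MPR set — the states
attained in at least one most-parsimonious reconstruction — is reported,
via the standard down-pass / up-pass (inside / outside cost) decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .core import InputError

ALPHABET = ("A", "C", "G", "T", "-")
_STATE_INDEX = {s: k for k, s in enumerate(ALPHABET)}
INF = float("inf")


@dataclass
class TipStates:
    """Observed tip alleles for one alignment column.

    ``states`` maps species name to a state in {A, C, G, T, -}; species
    absent from the mapping are treated as fully ambiguous.
    """

    site_id: str
    states: dict[str, str]

    def __post_init__(self) -> None:
        for sp, st in self.states.items():
            if st not in _STATE_INDEX:
                raise InputError(
                    f"site {self.site_id}: state {st!r} for {sp} not in "
                    f"{ALPHABET}")

    @property
    def n_gaps(self) -> int:
        return sum(1 for s in self.states.values() if s == "-")


def filter_gap_columns(columns: list[TipStates]) -> list[TipStates]:
    """Discard columns with more than one gap (alignment uncertainty)."""
    kept = [c for c in columns if c.n_gaps < 2]
    return kept


def fitch_states(tree: dendropy.Tree, tips: TipStates
                 ) -> tuple[int, dict[str, set[str]]]:
    """Minimum-change ancestral reconstruction (unit-cost Sankoff).

    Returns (parsimony score, MPR state sets per node). Internal nodes are
    keyed by their dendropy label if set, else ``node<i>`` in preorder;
    leaves are keyed by taxon label. Tips listed in ``tips`` but absent
    from the tree are an error; tree tips absent from ``tips`` are fully
    ambiguous.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    extra = set(tips.states) - leaf_labels
    if extra:
        raise InputError(f"tip labels not in tree: {sorted(extra)}")

    nodes = list(tree.preorder_node_iter())
    names: dict[int, str] = {}
    for k, nd in enumerate(nodes):
        if nd.is_leaf():
            names[id(nd)] = nd.taxon.label
        else:
            names[id(nd)] = nd.label if nd.label else f"node{k}"

    # down-pass: D[v][s] = min changes in the subtree of v given state s at v
    down: dict[int, np.ndarray] = {}
    # M[child][s] = min_t (D[child][t] + [s != t]), cached for the up-pass
    m_cost: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            st = tips.states.get(nd.taxon.label)
            d = np.full(5, INF)
            if st is None:
                d[:] = 0.0
            else:
                d[_STATE_INDEX[st]] = 0.0
        else:
            d = np.zeros(5)
            for ch in nd.child_nodes():
                d += m_cost[id(ch)]
        down[id(nd)] = d
        best = d.min()
        m = np.minimum(d, best + 1.0)
        m_cost[id(nd)] = m

    root = tree.seed_node
    score = int(down[id(root)].min())

    # up-pass: U[v][s] = min changes outside the subtree of v given state s
    up: dict[int, np.ndarray] = {id(root): np.zeros(5)}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        base = up[id(nd)]
        children = nd.child_nodes()
        for ch in children:
            # cost at the parent, excluding ch's subtree, per parent state
            other = base.copy()
            for sib in children:
                if sib is not ch:
                    other = other + m_cost[id(sib)]
            best = other.min()
            up[id(ch)] = np.minimum(other, best + 1.0)

    sets: dict[str, set[str]] = {}
    for nd in nodes:
        total = down[id(nd)] + up[id(nd)]
        opt = np.flatnonzero(total == total.min())
        sets[names[id(nd)]] = {ALPHABET[k] for k in opt}
    return score, sets


def reconstruct_sites(tree: dendropy.Tree, columns: list[TipStates]
                      ) -> list[tuple[str, int, set[str]]]:
    """Gap-filter then reconstruct each retained column.

    Returns (site_id, parsimony score, root MPR set) per retained column.
    """
    out = []
    root_name = None
    for col in filter_gap_columns(columns):
        score, sets = fitch_states(tree, col)
        if root_name is None:
            root = tree.seed_node
            root_name = root.label if root.label else "node0"
        out.append((col.site_id, score, sets[root_name]))
    return out


def write_reconstruction(rows: list[tuple[str, int, set[str]]], path) -> None:
    """Per-site TSV: site_id, score, root_state_set (comma-joined)."""
    with open(path, "w") as fh:
        fh.write("site_id\tscore\troot_state_set\n")
        for site_id, score, states in rows:
            fh.write(f"{site_id}\t{score}\t{','.join(sorted(states))}\n")


def read_tip_states(path) -> list[TipStates]:
    """Read per-site tip states TSV: site_id, species, state."""
    by_site: dict[str, dict[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("site_id"):
            raise InputError(f"{path}: expected header site_id\\tspecies\\tstate")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            site, sp, st = line.split("\t")
            if site not in by_site:
                by_site[site] = {}
                order.append(site)
            by_site[site][sp] = st
    return [TipStates(site_id=s, states=by_site[s]) for s in order]
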