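"""Parsimony mapping of sex-chromosome karyotype transitions on a phylogeny.

Tip karyotypes — which Muller elements are sex-linked, and the
heterogamety mode — are placed on a rooted species tree and ancestral
states are reconstructed by unweighted parsimony.  Each element is an
independent binary character (sex-linked or not; partially sex-linked
elements count as sex-linked but stay annotated), heterogamety is a
three-state character (XY / ZW / undifferentiated).  Branches on which a
character changes are the "bold branches" of the karyotype map; per
element the number of independent gains and losses is reported, with
exact min/max ranges over all most-parsimonious reconstructions when the
placement is ambiguous.

The small-parsimony engine is a Sankoff-style dynamic program with unit
costs, which handles polytomies exactly (naive Fitch intersection/union
folding can overcount on multifurcations).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .synthetic import ELEMENTS

HETEROGAMETY_STATES = ("XY", "ZW", "undifferentiated")
_INF = float("inf")


@dataclass(frozen=True)
class KaryotypeState:
    """Sex-linked element set plus heterogamety mode at one tree node."""

    sex_linked_elements: frozenset[str] = frozenset()
    partial_elements: frozenset[str] = frozenset()
    heterogamety: str = "undifferentiated"

    def __post_init__(self) -> None:
        if self.heterogamety not in HETEROGAMETY_STATES:
            raise ValueError(f"unknown heterogamety {self.heterogamety!r}")
        if not self.partial_elements <= self.sex_linked_elements:
            raise ValueError("partial elements must be a subset of sex-linked elements")
        if self.heterogamety == "undifferentiated" and self.sex_linked_elements:
            raise ValueError("undifferentiated karyotypes carry no sex-linked elements")

    @classmethod
    def parse(cls, elements: str, heterogamety: str) -> "KaryotypeState":
        """Parse 'D,F*' style element lists; '*' marks a partial element,
        '-' or empty means none."""
        linked, partial = set(), set()
        text = (elements or "").strip()
        if text not in ("", "-"):
            for tok in text.split(","):
                tok = tok.strip()
                if tok.endswith("*"):
                    tok = tok[:-1]
                    partial.add(tok)
                linked.add(tok)
        unknown = linked - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown Muller elements: {sorted(unknown)}")
        return cls(
            sex_linked_elements=frozenset(linked),
            partial_elements=frozenset(partial),
            heterogamety=heterogamety.strip(),
        )


@dataclass
class CharacterReconstruction:
    """Parsimony result for one character."""

    name: str
    states: tuple  # state alphabet in fixed order
    score: int
    node_states: dict[str, object]  # point (delayed-transformation) reconstruction
    node_state_sets: dict[str, frozenset]  # states attainable in some MPR
    changed_branches: list[tuple[str, object, object]]  # (child node, from, to)
    gains: int = 0  # binary characters only: 0 -> 1 changes in the point reconstruction
    losses: int = 0
    gains_range: tuple[int, int] = (0, 0)  # exact min/max over all MPRs
    losses_range: tuple[int, int] = (0, 0)
    ambiguous: bool = False


@dataclass
class TransitionMap:
    """All characters' reconstructions on one tree."""

    tree: dendropy.Tree
    characters: dict[str, CharacterReconstruction]
    total_changes: int = 0
    partial_annotations: dict[str, frozenset] = field(default_factory=dict)


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick tree, preserving polytomies.

    Tip labels must be unique and present; malformed Newick raises
    ValueError.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise ValueError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None or lab == "" for lab in labels):
        raise ValueError("every tip must carry a label")
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


def read_tip_states(path) -> dict[str, KaryotypeState]:
    """Read states.tsv: species, comma-separated elements ('*' = partial),
    heterogamety."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"species", "elements", "heterogamety"} - set(df.columns)
    if missing:
        raise ValueError(f"states table missing columns: {sorted(missing)}")
    return {
        row["species"]: KaryotypeState.parse(row["elements"], row["heterogamety"])
        for _, row in df.iterrows()
    }


def _node_label(node: dendropy.Node, idx: int) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{idx}"


def _index_tree(tree: dendropy.Tree):
    """Postorder node list with stable labels and child indices."""
    nodes = list(tree.postorder_node_iter())
    labels = {}
    for i, nd in enumerate(nodes):
        labels[id(nd)] = _node_label(nd, i)
    return nodes, labels


def _sankoff_character(
    tree: dendropy.Tree,
    tip_state: dict[str, object],
    states: tuple,
    name: str,
    derived: object | None = None,
) -> CharacterReconstruction:
    """Unit-cost parsimony for one character with exact MPR bookkeeping.

    ``derived`` names the state whose acquisition counts as a "gain" (binary
    characters); gains/losses ranges over all most-parsimonious
    reconstructions come from a tuple DP run alongside the costs.
    """
    nodes, labels = _index_tree(tree)
    n_states = len(states)
    s_index = {s: i for i, s in enumerate(states)}
    up = {}  # id(node) -> cost vector
    # tuple DP for event ranges: (min_gain, max_gain, min_loss, max_loss) per state
    ev = {}

    def _is_gain(sp: int, sc: int) -> int:
        return int(derived is not None and states[sc] == derived and states[sp] != derived)

    def _is_loss(sp: int, sc: int) -> int:
        return int(derived is not None and states[sp] == derived and states[sc] != derived)

    for nd in nodes:
        if nd.is_leaf():
            lab = labels[id(nd)]
            if lab not in tip_state:
                raise ValueError(f"missing tip state for {lab!r}")
            cost = np.full(n_states, _INF)
            cost[s_index[tip_state[lab]]] = 0.0
            up[id(nd)] = cost
            ev[id(nd)] = np.zeros((n_states, 4), dtype=float)
        else:
            cost = np.zeros(n_states)
            events = np.zeros((n_states, 4), dtype=float)
            for child in nd.child_nodes():
                ccost = up[id(child)]
                cev = ev[id(child)]
                for s in range(n_states):
                    cand = ccost + (np.arange(n_states) != s)
                    best = cand.min()
                    cost[s] += best
                    opts = np.flatnonzero(cand == best)
                    gmins = [cev[t, 0] + _is_gain(s, t) for t in opts]
                    gmaxs = [cev[t, 1] + _is_gain(s, t) for t in opts]
                    lmins = [cev[t, 2] + _is_loss(s, t) for t in opts]
                    lmaxs = [cev[t, 3] + _is_loss(s, t) for t in opts]
                    events[s, 0] += min(gmins)
                    events[s, 1] += max(gmaxs)
                    events[s, 2] += min(lmins)
                    events[s, 3] += max(lmaxs)
            up[id(nd)] = cost
            ev[id(nd)] = events

    root = tree.seed_node
    root_cost = up[id(root)]
    score = root_cost.min()
    opt_root = np.flatnonzero(root_cost == score)
    gains_range = (
        int(min(ev[id(root)][s, 0] for s in opt_root)),
        int(max(ev[id(root)][s, 1] for s in opt_root)),
    )
    losses_range = (
        int(min(ev[id(root)][s, 2] for s in opt_root)),
        int(max(ev[id(root)][s, 3] for s in opt_root)),
    )

    # down-pass: cost of the rest of the tree given each node's state,
    # yielding the set of states each node takes in some MPR
    down = {id(root): np.zeros(n_states)}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        parent = nd.parent_node
        pdown = down[id(parent)]
        sib_sum = np.zeros(n_states)
        for sib in parent.child_nodes():
            if sib is nd:
                continue
            ccost = up[id(sib)]
            for t in range(n_states):
                sib_sum[t] += (ccost + (np.arange(n_states) != t)).min()
        dcost = np.full(n_states, _INF)
        for s in range(n_states):
            for t in range(n_states):
                c = pdown[t] + sib_sum[t] + (0.0 if s == t else 1.0)
                if c < dcost[s]:
                    dcost[s] = c
        down[id(nd)] = dcost

    node_state_sets = {}
    for nd in nodes:
        total = up[id(nd)] + down[id(nd)]
        node_state_sets[labels[id(nd)]] = frozenset(
            states[s] for s in np.flatnonzero(total == score)
        )

    # point reconstruction, delaying changes: keep the parent's state
    # whenever it is optimal for the child
    node_states: dict[str, object] = {}
    changed: list[tuple[str, object, object]] = []
    root_state = int(opt_root[0])
    node_states[labels[id(root)]] = states[root_state]
    assigned = {id(root): root_state}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        p = assigned[id(nd.parent_node)]
        cand = up[id(nd)] + (np.arange(n_states) != p)
        opts = np.flatnonzero(cand == cand.min())
        s = int(p) if p in opts else int(opts[0])
        assigned[id(nd)] = s
        node_states[labels[id(nd)]] = states[s]
        if s != p:
            changed.append((labels[id(nd)], states[p], states[s]))

    gains = sum(1 for _, a, b in changed if derived is not None and b == derived)
    losses = sum(1 for _, a, b in changed if derived is not None and a == derived)
    return CharacterReconstruction(
        name=name,
        states=states,
        score=int(score),
        node_states=node_states,
        node_state_sets=node_state_sets,
        changed_branches=changed,
        gains=gains,
        losses=losses,
        gains_range=gains_range,
        losses_range=losses_range,
        ambiguous=(gains_range[0] != gains_range[1]) or (losses_range[0] != losses_range[1]),
    )


def fitch_reconstruct(
    tree: dendropy.Tree, tip_states: dict[str, KaryotypeState]
) -> TransitionMap:
    """Parsimony reconstruction of all karyotype characters.

    Every tip must appear in ``tip_states``; partially sex-linked elements
    are treated as sex-linked for the reconstruction but kept as
    annotations.  ``total_changes`` is the sum over characters of each
    character's minimal change count.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(tip_states)
    if missing:
        raise ValueError(f"missing karyotype states for tips: {sorted(missing)}")

    characters: dict[str, CharacterReconstruction] = {}
    for element in ELEMENTS:
        obs = {t: int(element in tip_states[t].sex_linked_elements) for t in tips}
        characters[f"element_{element}"] = _sankoff_character(
            tree, obs, states=(0, 1), name=f"element_{element}", derived=1
        )
    het_obs = {t: tip_states[t].heterogamety for t in tips}
    characters["heterogamety"] = _sankoff_character(
        tree, het_obs, states=HETEROGAMETY_STATES, name="heterogamety"
    )
    partial = {
        t: tip_states[t].partial_elements for t in tips if tip_states[t].partial_elements
    }
    return TransitionMap(
        tree=tree,
        characters=characters,
        total_changes=sum(c.score for c in characters.values()),
        partial_annotations=partial,
    )


def summarize_transitions(tmap: TransitionMap) -> pd.DataFrame:
    """Per-character gains/losses with MPR ranges and changed-branch lists.

    Point counts come from the delayed-transformation reconstruction; when
    several most-parsimonious reconstructions disagree, the min-max range
    over all of them is reported and ``ambiguous`` is set.
    """
    rows = []
    for name, ch in tmap.characters.items():
        rows.append(
            {
                "character": name,
                "score": ch.score,
                "gains": ch.gains,
                "losses": ch.losses,
                "gains_min": ch.gains_range[0],
                "gains_max": ch.gains_range[1],
                "losses_min": ch.losses_range[0],
                "losses_max": ch.losses_range[1],
                "ambiguous": ch.ambiguous,
                "changed_branches": ";".join(
                    f"{node}:{a}->{b}" for node, a, b in ch.changed_branches
                ),
            }
        )
    return pd.DataFrame(rows)


def annotated_newick(tmap: TransitionMap) -> str:
    """Newick string with per-branch change labels (the bold branches)."""
    changes: dict[str, list[str]] = {}
    for name, ch in tmap.characters.items():
        for node, a, b in ch.changed_branches:
            changes.setdefault(node, []).append(f"{name}:{a}->{b}")
    tree = tmap.tree.clone(depth=1)
    nodes, labels = _index_tree(tree)
    for nd in nodes:
        lab = labels[id(nd)]
        if lab in changes and not nd.is_leaf():
            nd.label = f"{lab}|{'|'.join(changes[lab])}"
        elif lab in changes and nd.is_leaf():
            nd.taxon.label = f"{nd.taxon.label}|{'|'.join(changes[lab])}"
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue().strip()
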