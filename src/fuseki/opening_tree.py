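"""Prefix trees of opening moves with entropy-based pruning.

Each canonicalized game traces a path through the tree of opening
decisions: the root is the empty board, each child edge is one move
(a Korschelt token), and each node counts the games whose opening passes
through it. Trees are built to a fixed depth (7 by default).

For display and for turnover analysis, a tree is pruned by an adaptive
rule: at every decision node, the Shannon entropy H' (natural log) of the
children's relative frequencies is computed and only the ⌈exp(H')⌉ most
common children are kept — i.e. the "effective number" of continuations.
Uniform children are therefore never pruned, while a node dominated by one
continuation keeps only a couple of branches.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import pandas as pd

from .board import point_to_korschelt
from .corpus import GameRecord


@dataclass
class TreeNode:
    label: str | None                 # move token; None for the root
    count: int = 0
    n_terminal: int = 0               # games ending/truncated at this node
    children: dict[str, "TreeNode"] = field(default_factory=dict)

    def check_conservation(self) -> None:
        """A node's count equals its children's counts plus terminals."""
        if self.count != self.n_terminal + sum(c.count for c in self.children.values()):
            raise AssertionError(f"count conservation violated at {self.label!r}")
        for c in self.children.values():
            c.check_conservation()


@dataclass
class OpeningTree:
    root: TreeNode
    depth: int
    era: object | None = None

    @property
    def n_games(self) -> int:
        return self.root.count

    def walk(self) -> Iterator[tuple[tuple[str, ...], TreeNode]]:
        """Yield (prefix, node) pairs in depth-first prefix order."""
        stack: list[tuple[tuple[str, ...], TreeNode]] = [((), self.root)]
        while stack:
            prefix, node = stack.pop()
            yield prefix, node
            for lab in sorted(node.children, reverse=True):
                stack.append((prefix + (lab,), node.children[lab]))

    def level_labels(self, depth: int) -> set[tuple[str, ...]]:
        """All move prefixes of exactly ``depth`` moves present in the tree."""
        return {p for p, _ in self.walk() if len(p) == depth}

    def check_conservation(self) -> None:
        self.root.check_conservation()


def build_tree(games: Sequence[GameRecord], depth: int = 7,
               era: object | None = None) -> OpeningTree:
    """Prefix tree of the first ``depth`` canonical moves of each game.

    Games shorter than ``depth`` contribute along their full prefix and are
    counted as terminating where they end.
    """
    root = TreeNode(label=None)
    for g in games:
        tokens = [point_to_korschelt(p) for p in g.moves[:depth]]
        node = root
        node.count += 1
        for tok in tokens:
            child = node.children.get(tok)
            if child is None:
                child = node.children[tok] = TreeNode(label=tok)
            child.count += 1
            node = child
        node.n_terminal += 1
    return OpeningTree(root=root, depth=depth, era=era)


def keep_budget(child_counts: Sequence[int]) -> int:
    """⌈exp(H')⌉ for the children's relative frequencies (natural log)."""
    total = sum(child_counts)
    if total == 0:
        return 0
    h = -sum((c / total) * math.log(c / total) for c in child_counts if c > 0)
    return math.ceil(math.exp(h) - 1e-12)


def prune_tree(tree: OpeningTree) -> OpeningTree:
    """Keep only the ⌈exp(H')⌉ most common children at each node.

    Ties between equal-count children are broken lexicographically by
    Korschelt label (the smaller label survives). Counts of surviving nodes
    are unchanged; pruned games are reflected in the parent's terminal
    count so the conservation invariant still holds.
    """

    def prune(node: TreeNode) -> TreeNode:
        kids = list(node.children.values())
        if not kids:
            return TreeNode(node.label, node.count, node.n_terminal, {})
        budget = keep_budget([c.count for c in kids])
        ranked = sorted(kids, key=lambda c: (-c.count, c.label))
        survivors = ranked[:budget]
        pruned_games = sum(c.count for c in ranked[budget:])
        new_children = {c.label: prune(c) for c in sorted(
            survivors, key=lambda c: c.label)}
        return TreeNode(node.label, node.count,
                        node.n_terminal + pruned_games, new_children)

    return OpeningTree(root=prune(tree.root), depth=tree.depth, era=tree.era)


def variant_turnover(tree_a: OpeningTree, tree_b: OpeningTree, depth: int
                     ) -> tuple[set, set, set]:
    """(extinct, novel, persisting) depth-level prefixes between two trees."""
    if depth > tree_a.depth or depth > tree_b.depth:
        raise ValueError("turnover depth exceeds a tree's build depth")
    a = tree_a.level_labels(depth)
    b = tree_b.level_labels(depth)
    return a - b, b - a, a & b


# ---------------------------------------------------------------------------
# transpositions and export


def transposition_table(tree: OpeningTree) -> pd.DataFrame:
    """Distinct move orders reaching the same board state.

    Two prefixes of equal length transpose if the sets of points played by
    Black and by White coincide. Returns one row per (state, sequence) for
    states reached by more than one sequence.
    """
    groups: dict[tuple, list[tuple[str, ...]]] = {}
    for prefix, _ in tree.walk():
        if not prefix:
            continue
        black = frozenset(prefix[0::2])
        white = frozenset(prefix[1::2])
        groups.setdefault((len(prefix), black, white), []).append(prefix)
    rows = []
    for state_id, ((_, black, white), seqs) in enumerate(sorted(
            groups.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]), sorted(kv[0][2])))):
        if len(seqs) < 2:
            continue
        for seq in sorted(seqs):
            rows.append({"state": state_id, "depth": len(seq),
                         "sequence": ",".join(seq)})
    return pd.DataFrame(rows, columns=["state", "depth", "sequence"])


def tree_to_dict(tree: OpeningTree) -> dict:
    def node_dict(node: TreeNode) -> dict:
        return {
            "label": node.label,
            "count": node.count,
            "n_terminal": node.n_terminal,
            "children": [node_dict(node.children[k]) for k in sorted(node.children)],
        }

    return {"depth": tree.depth,
            "era": str(tree.era) if tree.era is not None else None,
            "root": node_dict(tree.root)}


def tree_to_json(tree: OpeningTree) -> str:
    return json.dumps(tree_to_dict(tree), indent=1)


def tree_from_dict(payload: dict) -> OpeningTree:
    def node_from(d: dict) -> TreeNode:
        children = {c["label"]: node_from(c) for c in d.get("children", [])}
        return TreeNode(d["label"], d["count"], d.get("n_terminal", 0), children)

    return OpeningTree(root=node_from(payload["root"]), depth=payload["depth"],
                       era=payload.get("era"))


def tree_to_table(tree: OpeningTree) -> pd.DataFrame:
    """Flat (prefix, depth, count) table of the tree."""
    rows = [{"prefix": ",".join(p), "depth": len(p), "count": node.count}
            for p, node in tree.walk() if p]
    return pd.DataFrame(rows, columns=["prefix", "depth", "count"])
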