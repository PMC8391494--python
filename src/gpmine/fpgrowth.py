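"""FP-growth frequent-itemset mining.

Classic FP-tree construction with header-table node links and recursive
conditional-tree growth, specialized only in that items are genotype items
(``variant * 3 + code - 1``): itemsets whose items lie on the same variant
cannot occur in real transactions but are rejected defensively anyway.
Supports are exact transaction counts.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Sequence

__all__ = ["fpgrowth_core"]


class _Node:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item: int, parent: "_Node | None"):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[int, _Node] = {}


def _build_tree(
    weighted_transactions: Iterable[tuple[Sequence[int], int]],
    min_support: int,
) -> tuple[_Node, dict[int, list[_Node]], dict[int, int]]:
    counts: Counter[int] = Counter()
    cached = []
    for items, w in weighted_transactions:
        cached.append((items, w))
        for it in items:
            counts[it] += w
    frequent = {it: c for it, c in counts.items() if c >= min_support}
    # global descending-support order (ties by item code) makes paths overlap
    rank = {
        it: r
        for r, it in enumerate(sorted(frequent, key=lambda i: (-frequent[i], i)))
    }
    root = _Node(-1, None)
    header: dict[int, list[_Node]] = defaultdict(list)
    for items, w in cached:
        path = sorted((it for it in items if it in rank), key=rank.__getitem__)
        node = root
        for it in path:
            child = node.children.get(it)
            if child is None:
                child = _Node(it, node)
                node.children[it] = child
                header[it].append(child)
            child.count += w
            node = child
    return root, header, frequent


def _same_variant(item_a: int, item_b: int) -> bool:
    return item_a // 3 == item_b // 3


def _mine(
    header: dict[int, list[_Node]],
    item_support: dict[int, int],
    suffix: tuple[int, ...],
    min_support: int,
    max_length: int,
    out: dict[frozenset[int], int],
) -> None:
    # grow from least frequent to most frequent item
    for item in sorted(item_support, key=lambda i: (item_support[i], -i), reverse=False):
        support = item_support[item]
        if any(_same_variant(item, s) for s in suffix):
            continue  # defensive: one genotype per variant
        itemset = suffix + (item,)
        out[frozenset(itemset)] = support
        if len(itemset) >= max_length:
            continue
        # conditional pattern base: prefix paths above each occurrence
        base: list[tuple[list[int], int]] = []
        for node in header[item]:
            path: list[int] = []
            parent = node.parent
            while parent is not None and parent.item != -1:
                path.append(parent.item)
                parent = parent.parent
            if path:
                base.append((path, node.count))
        if not base:
            continue
        _, cond_header, cond_support = _build_tree(base, min_support)
        if cond_support:
            _mine(cond_header, cond_support, itemset, min_support,
                  max_length, out)


def fpgrowth_core(
    transactions: Sequence[Sequence[int]],
    min_support: int,
    max_length: int = 2,
) -> dict[frozenset[int], int]:
    """Find all frequent itemsets of size <= max_length.

    Parameters
    ----------
    transactions : sequence of item sequences
        Genotype items as produced by :func:`gpmine.plink.itemize`.
    min_support : int
        Minimal number of transactions containing the itemset (>= 1).
    max_length : int
        Maximal itemset cardinality.

    Returns
    -------
    dict mapping frozenset of items to its exact support count.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    weighted = [(t, 1) for t in transactions]
    _, header, item_support = _build_tree(weighted, min_support)
    out: dict[frozenset[int], int] = {}
    if item_support:
        _mine(header, item_support, (), min_support, max_length, out)
    return out
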