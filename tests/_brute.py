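"""Brute-force oracles for small isomer spaces.

Exhaustively enumerates every valid bond-order assignment for a formula
(feasible only for <= ~5 heavy atoms) and partitions graphs by pairwise
VF2 isomorphism -- deliberately independent of the package's canonical
key, so the two identity notions can cross-check each other.
"""

import itertools
from typing import Dict, List

import networkx as nx

from elucid.chem_graph import VALENCES, MolecularGraph


def enumerate_all_graphs(formula: Dict[str, int]) -> List[MolecularGraph]:
    """Every valid connected graph over the formula (duplicates included)."""
    elements = []
    for el in sorted(formula):
        if el != "H":
            elements += [el] * formula[el]
    n = len(elements)
    h = formula.get("H", 0)
    val = [VALENCES[el] for el in elements]
    target = sum(val) - h
    if target % 2:
        return []
    target //= 2
    pairs = list(itertools.combinations(range(n), 2))
    out = []
    for orders in itertools.product(range(4), repeat=len(pairs)):
        if sum(orders) != target:
            continue
        deg = [0] * n
        adj = {i: {} for i in range(n)}
        for (i, j), o in zip(pairs, orders):
            if o:
                deg[i] += o
                deg[j] += o
                adj[i][j] = o
                adj[j][i] = o
        if any(deg[i] > val[i] for i in range(n)):
            continue
        g = MolecularGraph(list(elements), [val[i] - deg[i] for i in range(n)], adj)
        if g.is_connected():
            out.append(g)
    return out


def _isomorphic(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    return nx.is_isomorphic(
        g1.to_networkx(),
        g2.to_networkx(),
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )


def partition_by_isomorphism(graphs: List[MolecularGraph]) -> List[List[int]]:
    """Partition graph indices into isomorphism classes (pairwise VF2)."""
    classes: List[List[int]] = []
    for idx, g in enumerate(graphs):
        for cls in classes:
            if _isomorphic(g, graphs[cls[0]]):
                cls.append(idx)
                break
        else:
            classes.append([idx])
    return classes


def enumerate_constitutions(formula: Dict[str, int]) -> List[MolecularGraph]:
    """One representative per isomorphism class (brute-force dedup)."""
    graphs = enumerate_all_graphs(formula)
    return [graphs[cls[0]] for cls in partition_by_isomorphism(graphs)]
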