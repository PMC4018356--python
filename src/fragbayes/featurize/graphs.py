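"""Small graph utilities over MoleculeGraph adjacency (no external deps).

Ring counts use the cyclomatic number (equal to the SSSR size for molecular
graphs); ring-bond membership uses bridge detection.
"""

from __future__ import annotations

from fragbayes.chemio import AROMATIC, MoleculeGraph


def n_components(mol: MoleculeGraph) -> int:
    n = mol.n_heavy
    seen = [False] * n
    adj = mol.adjacency()
    comps = 0
    for s in range(n):
        if seen[s]:
            continue
        comps += 1
        stack = [s]
        seen[s] = True
        while stack:
            v = stack.pop()
            for w, _ in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
    return comps


def sssr_count(mol: MoleculeGraph) -> int:
    """Cyclomatic number: bonds - atoms + components."""
    return len(mol.bonds) - mol.n_heavy + n_components(mol)


def aromatic_ring_count(mol: MoleculeGraph) -> int:
    """Number of independent rings in the subgraph of aromatic bonds."""
    arom_bonds = [b for b in mol.bonds if b.order == AROMATIC]
    nodes = {b.a1 for b in arom_bonds} | {b.a2 for b in arom_bonds}
    if not nodes:
        return 0
    # components of the aromatic subgraph
    adj: dict[int, list[int]] = {v: [] for v in nodes}
    for b in arom_bonds:
        adj[b.a1].append(b.a2)
        adj[b.a2].append(b.a1)
    seen = set()
    comps = 0
    for s in nodes:
        if s in seen:
            continue
        comps += 1
        stack = [s]
        seen.add(s)
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
    return len(arom_bonds) - len(nodes) + comps


def bridge_bonds(mol: MoleculeGraph) -> set[int]:
    """Indices (into mol.bonds) of bonds not in any ring (bridges)."""
    n = mol.n_heavy
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for bi, b in enumerate(mol.bonds):
        adj[b.a1].append((b.a2, bi))
        adj[b.a2].append((b.a1, bi))
    disc = [-1] * n
    low = [0] * n
    bridges: set[int] = set()
    timer = 0
    for root in range(n):
        if disc[root] != -1:
            continue
        # iterative DFS (parent edge tracked by bond index)
        stack = [(root, -1, iter(adj[root]))]
        disc[root] = low[root] = timer
        timer += 1
        while stack:
            v, pedge, it = stack[-1]
            advanced = False
            for w, bi in it:
                if bi == pedge:
                    continue
                if disc[w] == -1:
                    disc[w] = low[w] = timer
                    timer += 1
                    stack.append((w, bi, iter(adj[w])))
                    advanced = True
                    break
                low[v] = min(low[v], disc[w])
            if not advanced:
                stack.pop()
                if stack:
                    pv = stack[-1][0]
                    low[pv] = min(low[pv], low[v])
                    if low[v] > disc[pv]:
                        bridges.add(pedge)
    return bridges


def ball(mol: MoleculeGraph, center: int, radius: int) -> tuple[list[int], dict[int, int]]:
    """Atoms within graph distance ``radius`` of ``center`` (BFS order) and distances."""
    adj = mol.adjacency()
    dist = {center: 0}
    order = [center]
    frontier = [center]
    for d in range(1, radius + 1):
        nxt = []
        for v in frontier:
            for w, _ in adj[v]:
                if w not in dist:
                    dist[w] = d
                    order.append(w)
                    nxt.append(w)
        frontier = nxt
        if not frontier:
            break
    return order, dist
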