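"""Canonical labelling of rooted molecular subgraphs.

Produces, for an induced subgraph with a marked center atom, a string that is
invariant under any relabelling of the parent molecule's atoms.  The scheme is
individualization–refinement: Weisfeiler–Lehman colour refinement over atom
invariants (center flag, element, charge, aromaticity, dangling-bond count,
distance from the center), and when the partition is not discrete, every atom
of the first tied cell is individualized in turn and the lexicographically
smallest serialization wins.  Dangling bonds at the fragment boundary appear
as ``~k`` attachment-point markers on the atom tokens.

The serialization lists atom tokens in canonical order followed by the edge
list re-indexed by canonical rank, e.g. ``*C~2;N:a|0-1:1`` — not a SMILES,
but unambiguous and cheap to compare.  (The vendor encoding this stands in
for is unpublished; this is a documented reconstruction.)
"""

from __future__ import annotations

from typing import Sequence

AtomToken = tuple  # (is_center, symbol, charge, aromatic, n_attach)


def token_string(tok: AtomToken) -> str:
    is_center, symbol, charge, aromatic, n_attach = tok
    s = ("*" if is_center else "") + symbol
    if charge:
        s += f"{charge:+d}"
    if aromatic:
        s += ":a"
    if n_attach:
        s += f"~{n_attach}"
    return s


def canonical_fragment_string(
    tokens: Sequence[AtomToken],
    adj: Sequence[Sequence[tuple[int, int]]],
    dists: Sequence[int],
) -> str:
    """Canonical string for a connected rooted fragment.

    ``tokens[i]`` is the atom-token tuple for local atom ``i``; ``adj[i]`` is
    a sequence of (neighbor, bond-order-code); ``dists[i]`` the graph distance
    to the center (an automorphism invariant of the rooted fragment).
    """
    n = len(tokens)
    if n == 1:
        return token_string(tokens[0]) + "|"
    base = sorted(range(n), key=lambda i: (tokens[i], dists[i]))
    colors = [0] * n
    c = 0
    for rank, i in enumerate(base):
        if rank and (tokens[i], dists[i]) != (tokens[base[rank - 1]], dists[base[rank - 1]]):
            c += 1
        colors[i] = c
    return _canon(tokens, adj, colors)


def _refine(colors: list[int], adj) -> list[int]:
    n = len(colors)
    while True:
        sigs = [
            (colors[i], tuple(sorted((o, colors[j]) for j, o in adj[i])))
            for i in range(n)
        ]
        order = sorted(range(n), key=lambda i: sigs[i])
        new = [0] * n
        c = 0
        for rank, i in enumerate(order):
            if rank and sigs[i] != sigs[order[rank - 1]]:
                c += 1
            new[i] = c
        if new == colors:
            return colors
        colors = new


def _canon(tokens, adj, colors) -> str:
    colors = _refine(list(colors), adj)
    cells: dict[int, list[int]] = {}
    for i, c in enumerate(colors):
        cells.setdefault(c, []).append(i)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            target = cells[c]
            break
    if target is None:
        return _serialize(tokens, adj, colors)
    best = None
    for i in target:
        branched = [2 * c for c in colors]
        branched[i] -= 1  # individualize i just below its cell
        s = _canon(tokens, adj, branched)
        if best is None or s < best:
            best = s
    return best


def _serialize(tokens, adj, colors) -> str:
    n = len(tokens)
    order = sorted(range(n), key=lambda i: colors[i])
    rank = [0] * n
    for r, i in enumerate(order):
        rank[i] = r
    atoms_s = ";".join(token_string(tokens[i]) for i in order)
    edges = set()
    for i in range(n):
        for j, o in adj[i]:
            if i < j:
                a, b = sorted((rank[i], rank[j]))
                edges.add((a, b, o))
    bonds_s = ",".join(f"{a}-{b}:{o}" for a, b, o in sorted(edges))
    return atoms_s + "|" + bonds_s
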