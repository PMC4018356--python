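"""Atom-center fragment (ACF) enumeration.

An ACF of level *n* rooted at a heavy atom is the induced subgraph of all
atoms within graph distance *n* of the center, keeping every bond between
two in-reach atoms (ring closures within reach are preserved).  One fragment
is emitted per heavy atom, so occurrence counts at a fixed level always sum
to the heavy-atom count.
"""

from __future__ import annotations

from fragbayes.chemio import MoleculeGraph
from fragbayes.errors import ParameterError
from fragbayes.featurize import graphs
from fragbayes.featurize.canon import canonical_fragment_string
from fragbayes.featurize.featureset import FeatureSet, FragmentKey


def acf_key(mol: MoleculeGraph, center: int, level: int) -> FragmentKey:
    """Canonical key of the level-``level`` ACF rooted at ``center``."""
    atoms_in, dist = graphs.ball(mol, center, level)
    local = {g: i for i, g in enumerate(atoms_in)}
    in_set = set(atoms_in)
    adj_full = mol.adjacency()
    tokens = []
    adj = [[] for _ in atoms_in]
    for g in atoms_in:
        i = local[g]
        n_attach = 0
        for w, order in adj_full[g]:
            if w in in_set:
                adj[i].append((local[w], order))
            else:
                n_attach += 1
        a = mol.atoms[g]
        tokens.append((int(g == center), a.symbol, a.charge, int(a.aromatic), n_attach))
    dists = [dist[g] for g in atoms_in]
    s = canonical_fragment_string(tokens, adj, dists)
    return FragmentKey(family="ACF", level=level, key=s, center_marked=True)


def acf_enumerate(mol: MoleculeGraph, level: int) -> FeatureSet:
    """Enumerate the level-``level`` ACF of every heavy atom."""
    if level < 1:
        raise ParameterError("ACF level must be >= 1")
    fs = FeatureSet(mol.identifier)
    for center in range(mol.n_heavy):
        fs.add(acf_key(mol, center, level))
    return fs


def acf_multilevel(mol: MoleculeGraph, max_level: int) -> FeatureSet:
    """Union (with counts) of ACF levels 1..``max_level``.

    Keys carry their level, so identical shapes reached at different levels
    remain distinct features.
    """
    if not 1 <= max_level <= 6:
        raise ParameterError("max_level must lie in 1..6")
    fs = FeatureSet(mol.identifier)
    for level in range(1, max_level + 1):
        fs.merge(acf_enumerate(mol, level))
    return fs
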