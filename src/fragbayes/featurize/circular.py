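"""Sparse circular (ECFP-style) fingerprints.

Iterative neighborhood identifiers: every heavy atom starts from a hash of
(element, charge, degree, attached hydrogens, aromatic flag); each of
``diameter/2`` rounds rehashes the atom's previous identifier together with
the sorted (bond-order, neighbor-identifier) pairs.  Environments covering an
atom set already emitted by an earlier round (or by a smaller identifier in
the same round) are deduplicated, per the standard ECFP rule.  Identifiers
are kept sparse (no folding); the hash is a fixed 32-bit FNV-1a mix.
"""

from __future__ import annotations

from rdkit import Chem

from fragbayes.chemio import MoleculeGraph
from fragbayes.errors import ParameterError
from fragbayes.featurize.featureset import FeatureSet, FragmentKey

_PT = Chem.GetPeriodicTable()

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193


def _mix(values) -> int:
    """32-bit FNV-1a over a sequence of non-negative ints (4 bytes each)."""
    h = _FNV_OFFSET
    for v in values:
        v &= 0xFFFFFFFF
        for shift in (0, 8, 16, 24):
            h ^= (v >> shift) & 0xFF
            h = (h * _FNV_PRIME) & 0xFFFFFFFF
    return h


def circular_fingerprint(mol: MoleculeGraph, diameter: int) -> FeatureSet:
    """Compute the sparse circular fingerprint of a standardized molecule."""
    if diameter < 0 or diameter % 2:
        raise ParameterError("diameter must be a non-negative even integer")
    n = mol.n_heavy
    adj = mol.adjacency()
    ids = [
        _mix(
            (
                _PT.GetAtomicNumber(a.symbol),
                a.charge + 16,  # keep non-negative
                len(adj[i]),
                a.n_h,
                int(a.aromatic),
            )
        )
        for i, a in enumerate(mol.atoms)
    ]
    balls = [frozenset((i,)) for i in range(n)]
    rounds: list[list[tuple[int, frozenset]]] = [list(zip(ids, balls))]
    for r in range(1, diameter // 2 + 1):
        new_ids = []
        new_balls = []
        for i in range(n):
            pairs = sorted((order, ids[j]) for j, order in adj[i])
            new_ids.append(_mix([r, ids[i]] + [x for p in pairs for x in p]))
            nb = set(balls[i])
            for j, _ in adj[i]:
                nb |= balls[j]
            new_balls.append(frozenset(nb))
        ids, balls = new_ids, new_balls
        rounds.append(list(zip(ids, balls)))
    fs = FeatureSet(mol.identifier)
    seen: set[frozenset] = set()
    for round_items in rounds:
        for ident, env in sorted(round_items, key=lambda t: t[0]):
            if env in seen:
                continue
            seen.add(env)
            fs.add(FragmentKey(family="CIRC", level=diameter, key=f"{ident:08x}"))
    return fs
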