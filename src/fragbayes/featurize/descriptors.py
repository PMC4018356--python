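"""The 13-descriptor panel.

Count descriptors (MW, nHBDon, nHBAcc, N_rot, nRing, nAR, N_plus_O) are
computed natively on the :class:`~fragbayes.chemio.MoleculeGraph`:

* HB donors: N/O atoms bearing at least one hydrogen.
* HB acceptors: N/O atoms, excluding pyrrole-type aromatic nitrogens
  (aromatic N with an H or three heavy neighbours) and amide nitrogens
  (N adjacent to a carbonyl carbon) — the common Lipinski-style convention.
* Rotatable bonds: non-ring single bonds between two non-terminal heavy atoms.
* nRing: SSSR count (cyclomatic number); nAR: aromatic rings.

Continuous surface/partitioning models (AlogP, logD, logS, MPSA, MSA) are
delegated to a pluggable provider; the default provider is backed by RDKit
(Crippen logP, topological PSA, Labute approximate surface area, the Delaney
ESOL regression for logS).  logD (pH 7.4) has no RDKit model and is reported
missing unless a provider supplies it.  MFPSA is always MPSA/MSA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Protocol

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from fragbayes.chemio import DOUBLE, SINGLE, MoleculeGraph
from fragbayes.featurize import graphs

COUNT_DESCRIPTORS = ("MW", "nHBDon", "nHBAcc", "N_rot", "nRing", "nAR", "N_plus_O")
CONTINUOUS_DESCRIPTORS = ("AlogP", "logD", "logS", "MPSA", "MFPSA", "MSA")
DESCRIPTOR_NAMES = COUNT_DESCRIPTORS + CONTINUOUS_DESCRIPTORS

_PT = Chem.GetPeriodicTable()
_H_MASS = 1.008


@dataclass
class DescriptorVector:
    AlogP: float
    logD: float
    logS: float
    MW: float
    nHBDon: int
    nHBAcc: int
    N_rot: int
    nRing: int
    nAR: int
    N_plus_O: int
    MPSA: float
    MFPSA: float
    MSA: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}

    def missing(self) -> list[str]:
        return [n for n in DESCRIPTOR_NAMES if _is_missing(getattr(self, n))]


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


class DescriptorProvider(Protocol):
    """Contract for continuous-descriptor backends.

    ``continuous(mol)`` returns a mapping with any of the keys
    AlogP/logD/logS/MPSA/MSA; absent or ``None`` entries are treated as
    missing and excluded downstream with a warning.
    """

    def continuous(self, mol: MoleculeGraph) -> Mapping[str, float | None]:
        ...


class RDKitDescriptorProvider:
    """Default provider backed by RDKit 2D models."""

    def continuous(self, mol: MoleculeGraph) -> dict[str, float | None]:
        rd = mol.to_rdkit()
        alogp = Crippen.MolLogP(rd)
        mw = Descriptors.MolWt(rd)
        n_rot = Descriptors.NumRotatableBonds(rd)
        aromatic_prop = (
            sum(1 for a in rd.GetAtoms() if a.GetIsAromatic()) / max(rd.GetNumHeavyAtoms(), 1)
        )
        # Delaney ESOL multiple linear regression
        logs = 0.16 - 0.63 * alogp - 0.0062 * mw + 0.066 * n_rot - 0.74 * aromatic_prop
        return {
            "AlogP": alogp,
            "logD": None,  # no pKa model available; reported missing
            "logS": logs,
            "MPSA": Descriptors.TPSA(rd),
            "MSA": Descriptors.LabuteASA(rd),
        }


_DEFAULT_PROVIDER = RDKitDescriptorProvider()


def molecular_weight(mol: MoleculeGraph) -> float:
    return sum(_PT.GetAtomicWeight(a.symbol) + a.n_h * _H_MASS for a in mol.atoms)


def hb_donor_count(mol: MoleculeGraph) -> int:
    return sum(1 for a in mol.atoms if a.symbol in ("N", "O") and a.n_h >= 1)


def hb_acceptor_count(mol: MoleculeGraph) -> int:
    adj = mol.adjacency()
    n = 0
    for i, a in enumerate(mol.atoms):
        if a.symbol not in ("N", "O"):
            continue
        if a.symbol == "N":
            if a.aromatic and (a.n_h >= 1 or len(adj[i]) == 3):
                continue  # pyrrole-type nitrogen donates its lone pair to the ring
            if _is_amide_nitrogen(mol, i):
                continue
        n += 1
    return n


def _is_amide_nitrogen(mol: MoleculeGraph, i: int) -> bool:
    adj = mol.adjacency()
    for j, order in adj[i]:
        if mol.atoms[j].symbol == "C" and order == SINGLE:
            for k, o2 in adj[j]:
                if k != i and mol.atoms[k].symbol == "O" and o2 == DOUBLE:
                    return True
    return False


def rotatable_bond_count(mol: MoleculeGraph) -> int:
    bridges = graphs.bridge_bonds(mol)
    n = 0
    for bi, b in enumerate(mol.bonds):
        if b.order != SINGLE or bi not in bridges:
            continue
        if mol.degree(b.a1) >= 2 and mol.degree(b.a2) >= 2:
            n += 1
    return n


def compute_descriptors(
    mol: MoleculeGraph, provider: DescriptorProvider | None = None
) -> DescriptorVector:
    """Compute the full 13-descriptor panel for a standardized molecule.

    Provider failures leave the affected continuous descriptors as NaN and
    emit a warning; downstream learners drop missing columns.
    """
    provider = provider or _DEFAULT_PROVIDER
    cont: dict[str, float | None] = {}
    try:
        cont = dict(provider.continuous(mol))
    except Exception as exc:  # provider contract: failure = missing
        warnings.warn(f"descriptor provider failed for {mol.identifier or mol.source_smiles}: {exc}")
    nan = float("nan")
    mpsa = cont.get("MPSA")
    msa = cont.get("MSA")
    if _is_missing(mpsa):
        mpsa = nan
    if _is_missing(msa):
        msa = nan
    mfpsa = mpsa / msa if (not math.isnan(mpsa) and not math.isnan(msa) and msa > 0) else nan
    return DescriptorVector(
        AlogP=nan if _is_missing(cont.get("AlogP")) else float(cont["AlogP"]),
        logD=nan if _is_missing(cont.get("logD")) else float(cont["logD"]),
        logS=nan if _is_missing(cont.get("logS")) else float(cont["logS"]),
        MW=molecular_weight(mol),
        nHBDon=hb_donor_count(mol),
        nHBAcc=hb_acceptor_count(mol),
        N_rot=rotatable_bond_count(mol),
        nRing=graphs.sssr_count(mol),
        nAR=graphs.aromatic_ring_count(mol),
        N_plus_O=sum(1 for a in mol.atoms if a.symbol in ("N", "O")),
        MPSA=mpsa,
        MFPSA=mfpsa,
        MSA=msa,
    )
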