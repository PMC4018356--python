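"""Reading, standardizing and labelling compound records.

The module owns the light-weight :class:`MoleculeGraph` used by every
featurizer, the SMILES-table / SDF readers, activity labelling against a
configurable potency cutoff, duplicate collapsing and train/test splitting.
RDKit does the heavy lifting for parsing, sanitization and canonical SMILES;
everything downstream of this module operates on plain graphs.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger

from fragbayes.errors import EmptyLibraryError, ParameterError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: bond-order codes used throughout the package
SINGLE, DOUBLE, TRIPLE, AROMATIC = 1, 2, 3, 4

_BOND_TO_CODE = {
    Chem.BondType.SINGLE: SINGLE,
    Chem.BondType.DOUBLE: DOUBLE,
    Chem.BondType.TRIPLE: TRIPLE,
    Chem.BondType.AROMATIC: AROMATIC,
}
_CODE_TO_BOND = {v: k for k, v in _BOND_TO_CODE.items()}

INHIBITOR = "inhibitor"
NON_INHIBITOR = "non_inhibitor"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class Atom:
    symbol: str
    charge: int = 0
    aromatic: bool = False
    n_h: int = 0  # implicit + explicit hydrogens folded onto the heavy atom


@dataclass(frozen=True)
class Bond:
    a1: int
    a2: int
    order: int  # SINGLE/DOUBLE/TRIPLE/AROMATIC


@dataclass
class MoleculeGraph:
    """Heavy-atom/bond graph with perceived aromaticity."""

    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    identifier: str = ""
    source_smiles: str = ""
    _adj: dict | None = field(default=None, repr=False, compare=False)

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> dict[int, list[tuple[int, int]]]:
        """index -> list of (neighbor index, bond-order code)."""
        if self._adj is None:
            adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(self.atoms))}
            for b in self.bonds:
                adj[b.a1].append((b.a2, b.order))
                adj[b.a2].append((b.a1, b.order))
            self._adj = adj
        return self._adj

    def degree(self, i: int) -> int:
        return len(self.adjacency()[i])

    def permuted(self, perm: Sequence[int]) -> "MoleculeGraph":
        """Relabel atoms so new index ``perm[i]`` holds old atom ``i``."""
        n = len(self.atoms)
        if sorted(perm) != list(range(n)):
            raise ParameterError("perm must be a permutation of atom indices")
        new_atoms = [None] * n
        for old, new in enumerate(perm):
            new_atoms[new] = self.atoms[old]
        new_bonds = tuple(Bond(perm[b.a1], perm[b.a2], b.order) for b in self.bonds)
        return MoleculeGraph(tuple(new_atoms), new_bonds, self.identifier, self.source_smiles)

    def to_rdkit(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.symbol)
            ra.SetFormalCharge(a.charge)
            ra.SetIsAromatic(a.aromatic)
            ra.SetNumExplicitHs(a.n_h)
            ra.SetNoImplicit(True)
            rw.AddAtom(ra)
        for b in self.bonds:
            rw.AddBond(b.a1, b.a2, _CODE_TO_BOND[b.order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


@dataclass
class ActivityRecord:
    compound_id: str
    assay_type: str | None = None  # "Ki" | "IC50"
    value_nM: float | None = None
    label: str = UNLABELED

    def __post_init__(self):
        if self.value_nM is not None and self.value_nM <= 0:
            raise ParameterError(f"value_nM must be positive, got {self.value_nM}")


@dataclass
class DataSplit:
    training_ids: frozenset
    test_ids: frozenset
    seed: int


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_SMILES_TOKEN = re.compile(
    r"Cl|Br|\[[^\]]*\]|[BCNOPSFIbcnops]"  # organic-subset and bracket atoms
    r"|[-=#:/\\~.()]|%\d\d|\d"  # bonds, branches, ring closures
)


def _offending_position(text: str) -> int | None:
    """Best-effort lexical scan for the first token RDKit cannot accept."""
    i = 0
    depth = 0
    while i < len(text):
        m = _SMILES_TOKEN.match(text, i)
        if m is None:
            return i
        tok = m.group(0)
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                return i
        if tok.startswith("[") and not tok.endswith("]"):
            return i
        i = m.end()
    return None  # lexically fine; failure is structural


def mol_to_graph(mol: Chem.Mol, identifier: str = "", source_smiles: str = "") -> MoleculeGraph:
    """Convert an RDKit molecule (explicit Hs removed) to a MoleculeGraph."""
    mol = Chem.RemoveHs(mol)
    atoms = tuple(
        Atom(
            symbol=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            n_h=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_TO_CODE[b.GetBondType()])
        for b in mol.GetBonds()
    )
    if not source_smiles:
        source_smiles = Chem.MolToSmiles(mol)
    return MoleculeGraph(atoms, bonds, identifier, source_smiles)


def parse_smiles(text: str, identifier: str = "") -> MoleculeGraph:
    """Parse a SMILES string into a :class:`MoleculeGraph`.

    Aromaticity is perceived by RDKit; explicit hydrogens are folded into
    per-atom implicit counts.  Raises :class:`SmilesParseError` naming the
    offending token position for lexically malformed input.
    """
    if not text or not text.strip():
        raise SmilesParseError(text, position=0, reason="empty input")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(text, position=_offending_position(text))
    if mol.GetNumHeavyAtoms() < 1:
        raise SmilesParseError(text, reason="no heavy atoms")
    return mol_to_graph(mol, identifier=identifier, source_smiles=text)


def standardize(mol: MoleculeGraph) -> MoleculeGraph:
    """Keep the largest covalent fragment, fold explicit Hs, re-perceive aromaticity."""
    rd = mol.to_rdkit()
    frags = Chem.GetMolFrags(rd, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        # largest by heavy-atom count; ties broken by canonical SMILES for determinism
        rd = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    rd = Chem.RemoveHs(rd)
    Chem.SanitizeMol(rd)
    return mol_to_graph(rd, identifier=mol.identifier)


# ---------------------------------------------------------------------------
# library IO
# ---------------------------------------------------------------------------

_ASSAY_TYPES = {"ki": "Ki", "ic50": "IC50"}


def _normalize_assay(raw: str | None) -> str | None:
    if raw is None:
        return None
    return _ASSAY_TYPES.get(raw.strip().lower())


def read_library(
    path,
    format: str = "smiles_table",
    assay_tag: str = "ASSAY_TYPE",
    value_tag: str = "VALUE_NM",
) -> list[tuple[MoleculeGraph, ActivityRecord]]:
    """Read a compound library from a SMILES table or an SDF file.

    Malformed entries are logged and skipped; a library with zero parseable
    records raises :class:`EmptyLibraryError`.
    """
    path = Path(path)
    if format == "smiles_table":
        records = _read_smiles_table(path)
    elif format == "sdf":
        records = _read_sdf(path, assay_tag, value_tag)
    else:
        raise ParameterError(f"unknown library format {format!r}")
    if not records:
        raise EmptyLibraryError(f"no parseable records in {path}")
    return records


def _read_smiles_table(path: Path) -> list[tuple[MoleculeGraph, ActivityRecord]]:
    out = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            try:
                if len(fields) < 2:
                    raise ValueError("need at least SMILES and ID columns")
                smiles, cid = fields[0], fields[1]
                assay = _normalize_assay(fields[2]) if len(fields) > 2 else None
                value = float(fields[3]) if len(fields) > 3 else None
                graph = parse_smiles(smiles, identifier=cid)
                rec = ActivityRecord(compound_id=cid, assay_type=assay, value_nM=value)
            except (ValueError, SmilesParseError) as exc:
                skipped += 1
                logger.warning("skipping line %d of %s: %s", lineno, path, exc)
                continue
            out.append((graph, rec))
    if skipped:
        logger.warning("%s: skipped %d malformed entries", path, skipped)
    return out


def _read_sdf(path: Path, assay_tag: str, value_tag: str) -> list[tuple[MoleculeGraph, ActivityRecord]]:
    out = []
    skipped = 0
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            logger.warning("skipping unparseable SDF record %d of %s", i, path)
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"SDF{i:05d}"
        assay = _normalize_assay(mol.GetProp(assay_tag)) if mol.HasProp(assay_tag) else None
        value = None
        if mol.HasProp(value_tag):
            try:
                value = float(mol.GetProp(value_tag))
            except ValueError:
                logger.warning("record %s: unreadable %s field", cid, value_tag)
        try:
            rec = ActivityRecord(compound_id=cid, assay_type=assay, value_nM=value)
        except ParameterError as exc:
            skipped += 1
            logger.warning("skipping SDF record %s: %s", cid, exc)
            continue
        out.append((mol_to_graph(mol, identifier=cid), rec))
    if skipped:
        logger.warning("%s: skipped %d malformed entries", path, skipped)
    return out


def write_smiles_table(path, records: Iterable[tuple[str, ActivityRecord]]) -> None:
    """Write (smiles, record) pairs in the package's SMILES-table dialect."""
    with open(path, "w") as fh:
        fh.write("# SMILES ID TYPE VALUE_NM\n")
        for smiles, rec in records:
            assay = rec.assay_type or "IC50"
            value = "" if rec.value_nM is None else f"{rec.value_nM:.6g}"
            fh.write(f"{smiles}\t{rec.compound_id}\t{assay}\t{value}\n")


# ---------------------------------------------------------------------------
# labelling / dedup / splitting
# ---------------------------------------------------------------------------


def label_activity(record: ActivityRecord, cutoff_nM: float) -> str:
    """Label a record: inhibitor iff its value is *strictly below* the cutoff.

    A missing assay value yields :data:`UNLABELED`.
    """
    if cutoff_nM <= 0:
        raise ParameterError("cutoff_nM must be positive")
    if record.value_nM is None:
        return UNLABELED
    return INHIBITOR if record.value_nM < cutoff_nM else NON_INHIBITOR


def apply_labels(
    records: Sequence[tuple[MoleculeGraph, ActivityRecord]], cutoff_nM: float
) -> list[tuple[MoleculeGraph, ActivityRecord]]:
    """Return records with labels recomputed against ``cutoff_nM``."""
    return [
        (g, replace(rec, label=label_activity(rec, cutoff_nM))) for g, rec in records
    ]


def inhibition_index(record: ActivityRecord) -> float:
    """Potency index: molar pXC50 plus an offset of 2 (``-log10(M) + 2``)."""
    if record.value_nM is None or record.value_nM <= 0:
        raise ParameterError("inhibition_index needs a positive assay value")
    return -math.log10(record.value_nM * 1e-9) + 2.0


def collapse_duplicates(
    records: Sequence[tuple[MoleculeGraph, ActivityRecord]]
) -> list[tuple[MoleculeGraph, ActivityRecord]]:
    """Collapse records with identical standardized structure.

    The record with the lowest assay value (most potent evidence) is kept;
    records without values lose to records with values.
    """
    best: dict[str, tuple[MoleculeGraph, ActivityRecord]] = {}
    order: list[str] = []
    for graph, rec in records:
        key = graph.canonical_smiles()
        if key not in best:
            best[key] = (graph, rec)
            order.append(key)
            continue
        incumbent = best[key][1]
        if rec.value_nM is not None and (
            incumbent.value_nM is None or rec.value_nM < incumbent.value_nM
        ):
            best[key] = (graph, rec)
    return [best[k] for k in order]


def split_train_test(records, test_fraction: float, seed: int, labels=None) -> DataSplit:
    """Uniformly random train/test partition, deterministic given ``seed``.

    ``records`` may be compound-id strings, :class:`ActivityRecord` objects or
    (graph, record) tuples.  When ``labels`` is given the split is stratified.
    """
    if not 0 < test_fraction < 1:
        raise ParameterError("test_fraction must lie in (0, 1)")
    ids = [_record_id(r) for r in records]
    if len(ids) < 2:
        raise ParameterError("need at least two records to split")
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate compound ids in split input")
    rng = np.random.default_rng(seed)
    n_test = int(round(len(ids) * test_fraction))
    n_test = min(max(n_test, 1), len(ids) - 1)
    if labels is None:
        perm = rng.permutation(len(ids))
        test_idx = set(perm[:n_test].tolist())
    else:
        labels = list(labels)
        if len(labels) != len(ids):
            raise ParameterError("labels length must match records")
        # proportional allocation per class, remainders by largest fraction
        by_class: dict = {}
        for i, lab in enumerate(labels):
            by_class.setdefault(lab, []).append(i)
        test_idx = set()
        quotas = {c: len(ix) * test_fraction for c, ix in by_class.items()}
        base = {c: int(math.floor(q)) for c, q in quotas.items()}
        rem = n_test - sum(base.values())
        for c in sorted(by_class, key=lambda c: quotas[c] - base[c], reverse=True):
            if rem <= 0:
                break
            base[c] += 1
            rem -= 1
        for c, ix in sorted(by_class.items(), key=lambda kv: str(kv[0])):
            perm = rng.permutation(len(ix))
            for j in perm[: base[c]]:
                test_idx.add(ix[j])
    train = frozenset(ids[i] for i in range(len(ids)) if i not in test_idx)
    test = frozenset(ids[i] for i in test_idx)
    return DataSplit(training_ids=train, test_ids=test, seed=seed)


def _record_id(r) -> str:
    if isinstance(r, str):
        return r
    if isinstance(r, ActivityRecord):
        return r.compound_id
    if isinstance(r, tuple) and len(r) == 2:
        return r[1].compound_id
    if isinstance(r, MoleculeGraph):
        return r.identifier
    raise ParameterError(f"cannot extract a compound id from {type(r)!r}")
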