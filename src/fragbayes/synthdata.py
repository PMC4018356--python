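"""Synthetic labelled compound libraries and published-table fixtures.

The generator assembles valence-respecting molecules by joining curated
SMILES pieces with single bonds.  Class membership is driven by planted
substructures: active compounds carry a nitrogen-in-saturated-ring motif,
inactive compounds a lactam motif, each with a configurable fidelity, so the
learners' ability to recover the planted signal can be tested end to end
without any external data.  Assay values are sampled log-uniformly on the
correct side of the activity cutoff and carry no information beyond the
class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from fragbayes.chemio import ActivityRecord, label_activity
from fragbayes.errors import ParameterError
from fragbayes.evalx import ConfusionCounts

#: planted motifs (favorable: N in a saturated ring; unfavorable: lactam)
ACTIVE_FRAGMENT = "C1CCNCC1"
INACTIVE_FRAGMENT = "O=c1cccc[nH]1"

#: medium-sized pieces keep the number of join operations (and hence the pool
#: of rare junction environments that can pick up spurious class association)
#: small
DEFAULT_VOCABULARY = (
    "c1ccc(-c2ccccc2)cc1",
    "c1ccc2ccccc2c1",
    "C1CCC(C2CCCCC2)CC1",
    "CCCCCCCC",
    "c1ccc(OCc2ccccc2)cc1",
    "CC(C)CC(C)(C)C",
    "c1ccc(Cc2ccccc2)cc1",
)

MW_BAND = (140.0, 700.0)
DEFAULT_CUTOFF_NM = 10_000.0


@dataclass
class PlantedFragment:
    smiles: str
    active: bool  # which class the fragment marks
    fidelity: float  # probability the class's member actually carries it

    def __post_init__(self):
        if not 0.5 < self.fidelity <= 1.0:
            raise ParameterError("fidelity must lie in (0.5, 1]")


@dataclass
class GeneratorConfig:
    n_compounds: int = 500
    active_fraction: float = 0.80
    planted_fragments: tuple[PlantedFragment, ...] = (
        PlantedFragment(ACTIVE_FRAGMENT, active=True, fidelity=0.9),
        PlantedFragment(INACTIVE_FRAGMENT, active=False, fidelity=0.9),
    )
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    cutoff_nM: float = DEFAULT_CUTOFF_NM
    seed: int = 0
    id_prefix: str = "SYN"
    _parsed: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ParameterError("n_compounds must be >= 1")
        if not 0 < self.active_fraction < 1:
            raise ParameterError("active_fraction must lie in (0, 1)")
        if not self.vocabulary:
            raise ParameterError("vocabulary must not be empty")
        actives = [p for p in self.planted_fragments if p.active]
        inactives = [p for p in self.planted_fragments if not p.active]
        if not actives or not inactives:
            raise ParameterError("need planted fragments for both classes")
        for smi in list(self.vocabulary) + [p.smiles for p in self.planted_fragments]:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ParameterError(f"invalid vocabulary SMILES {smi!r}")
            self._parsed[smi] = mol


def _attachable_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]


def _join(
    base: Chem.Mol, piece: Chem.Mol, rng: np.random.Generator, handle: int | None = None
) -> Chem.Mol | None:
    """Bond an H-bearing atom of ``piece`` (``handle`` or random) to a random
    H-bearing atom of ``base``."""
    anchors = _attachable_atoms(base)
    handles = _attachable_atoms(piece)
    if not anchors or not handles:
        return None
    i = int(rng.choice(anchors))
    j = (handle if handle is not None else int(rng.choice(handles))) + base.GetNumAtoms()
    if handle is not None and handle not in handles:
        return None
    combo = Chem.RWMol(Chem.CombineMols(base, piece))
    combo.AddBond(i, j, Chem.BondType.SINGLE)
    for idx in (i, j):
        atom = combo.GetAtomWithIdx(idx)
        if atom.GetNumExplicitHs() > 0:
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _assemble(cfg: GeneratorConfig, planted_smiles: str, rng: np.random.Generator) -> str:
    """Build one molecule containing ``planted_smiles``, MW inside the band.

    A core is grown from vocabulary pieces first; the planted fragment is
    bonded last through its first H-bearing atom, so the fragment's rooted
    environments stay consistent across the library.
    """
    lo, hi = MW_BAND
    planted = cfg._parsed[planted_smiles]
    planted_mw = Descriptors.MolWt(planted)
    handle = _attachable_atoms(planted)[0]
    for _ in range(50):
        core = Chem.Mol(cfg._parsed[cfg.vocabulary[int(rng.integers(len(cfg.vocabulary)))]])
        target = rng.uniform(lo + 110.0, hi - 150.0) - planted_mw
        for _ in range(4):
            if Descriptors.MolWt(core) >= target:
                break
            piece = cfg._parsed[cfg.vocabulary[int(rng.integers(len(cfg.vocabulary)))]]
            joined = _join(core, piece, rng)
            if joined is not None and Descriptors.MolWt(joined) <= hi - planted_mw:
                core = joined
        mol = _join(core, planted, rng, handle=handle)
        if mol is not None and lo <= Descriptors.MolWt(mol) <= hi:
            return Chem.MolToSmiles(mol)
    raise ParameterError("could not assemble a molecule inside the MW band")


def generate_library(cfg: GeneratorConfig) -> list[tuple[str, ActivityRecord]]:
    """Generate a labelled synthetic library, fully deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    active_pool = [p for p in cfg.planted_fragments if p.active]
    inactive_pool = [p for p in cfg.planted_fragments if not p.active]
    out = []
    log_cut = math.log10(cfg.cutoff_nM)
    for i in range(cfg.n_compounds):
        is_active = bool(rng.random() < cfg.active_fraction)
        own = active_pool if is_active else inactive_pool
        other = inactive_pool if is_active else active_pool
        planted = own[int(rng.integers(len(own)))]
        pool = own if rng.random() < planted.fidelity else other
        fragment = pool[int(rng.integers(len(pool)))]
        smiles = _assemble(cfg, fragment.smiles, rng)
        if is_active:
            value = 10.0 ** rng.uniform(-1.0, log_cut - 1e-9)
        else:
            value = 10.0 ** rng.uniform(log_cut, 7.0)
        assay = "Ki" if rng.random() < 0.5 else "IC50"
        rec = ActivityRecord(
            compound_id=f"{cfg.id_prefix}{i:05d}", assay_type=assay, value_nM=float(value)
        )
        rec.label = label_activity(rec, cfg.cutoff_nM)
        out.append((smiles, rec))
    return out


def planted_feature_keys(
    library: list[tuple[str, ActivityRecord]],
    fragment_smiles: str,
    max_level: int,
    sample: int = 200,
) -> set:
    """ACF keys rooted at atoms of the planted substructure across a library.

    Used to verify that top-ranked favorable fragments really derive from the
    planted motif (substituted carriers root slightly different keys than the
    bare fragment).
    """
    from fragbayes.chemio import parse_smiles, standardize
    from fragbayes.featurize.acf import acf_key

    patt = Chem.MolFromSmarts(fragment_smiles)
    keys: set = set()
    for smiles, rec in library[:sample]:
        graph = standardize(parse_smiles(smiles, rec.compound_id))
        rd = graph.to_rdkit()
        for match in rd.GetSubstructMatches(patt):
            for atom in match:
                for level in range(1, max_level + 1):
                    keys.add(acf_key(graph, atom, level))
    return keys


# ---------------------------------------------------------------------------
# published confusion-table fixtures
# ---------------------------------------------------------------------------


def _load_table() -> list[dict]:
    text = resources.files("fragbayes.data").joinpath("confusion_tables.tsv").read_text()
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]


def paper_confusion_fixtures() -> dict[str, ConfusionCounts]:
    """Published confusion counts keyed ``family/model/split``.

    26 table rows, each with a training and a test confusion -> 52 entries.
    """
    out: dict[str, ConfusionCounts] = {}
    for row in _load_table():
        name = f"{row['family']}/{row['model']}/{row['split']}"
        out[name] = ConfusionCounts(
            TP=int(row["TP"]), FN=int(row["FN"]), TN=int(row["TN"]), FP=int(row["FP"])
        )
    return out


def reference_metrics() -> dict[str, dict[str, float]]:
    """Published metric values (3 d.p.) keyed like :func:`paper_confusion_fixtures`."""
    out: dict[str, dict[str, float]] = {}
    for row in _load_table():
        name = f"{row['family']}/{row['model']}/{row['split']}"
        out[name] = {m: float(row[m]) for m in ("SE", "SP", "Q_i", "Q_ni", "C", "AUC")}
    return out
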