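"""Sparse fragment feature sets and their on-disk representation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from fragbayes.errors import ParameterError

#: feature families understood by the learners.  ACF = atom-center fragment,
#: CIRC = circular fingerprint identifier, BIN = binned continuous descriptor,
#: EXT = externally computed feature imported through the adapter.
FAMILIES = ("ACF", "CIRC", "BIN", "EXT")


class FragmentKey(NamedTuple):
    """Canonical identifier of a single feature.

    ``level`` is the ACF level or the fingerprint diameter (bin index for
    BIN features); ``key`` is the canonical string, invariant under atom
    reordering of the input molecule.
    """

    family: str
    level: int
    key: str
    center_marked: bool = False


@dataclass
class FeatureSet:
    """Occurrence counts of fragment features for one compound."""

    compound_id: str
    features: dict[FragmentKey, int] = field(default_factory=dict)

    def add(self, key: FragmentKey, count: int = 1) -> None:
        self.features[key] = self.features.get(key, 0) + count

    def merge(self, other: "FeatureSet") -> "FeatureSet":
        for k, c in other.features.items():
            self.add(k, c)
        return self

    def total_count(self) -> int:
        return sum(self.features.values())

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, key: FragmentKey) -> bool:
        return key in self.features


def write_featuresets(path, featuresets: Iterable[FeatureSet], params: dict | None = None) -> None:
    """Serialize feature sets as a TSV table plus a JSON parameter sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("compound_id\tfamily\tlevel\tcanonical_string\tcount\n")
        for fs in featuresets:
            for key in sorted(fs.features):
                fh.write(
                    f"{fs.compound_id}\t{key.family}\t{key.level}\t{key.key}\t{fs.features[key]}\n"
                )
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(params or {}, fh, indent=2, sort_keys=True)


def read_featuresets(path) -> tuple[list[FeatureSet], dict]:
    """Inverse of :func:`write_featuresets`; reproduces the exact sets."""
    path = Path(path)
    sets: dict[str, FeatureSet] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["compound_id", "family", "level", "canonical_string", "count"]:
            raise ParameterError(f"{path}: not a feature-set table")
        for line in fh:
            cid, family, level, key, count = line.rstrip("\n").split("\t")
            if family not in FAMILIES:
                raise ParameterError(f"{path}: unknown feature family {family!r}")
            if cid not in sets:
                sets[cid] = FeatureSet(cid)
                order.append(cid)
            fk = FragmentKey(family, int(level), key, center_marked=family == "ACF")
            sets[cid].features[fk] = int(count)
    sidecar = path.with_suffix(path.suffix + ".json")
    params = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            params = json.load(fh)
    return [sets[c] for c in order], params
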