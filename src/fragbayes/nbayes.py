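"""Laplacian-corrected naive Bayesian classifier over fragment features.

Per-feature weights are log-ratios of the Laplacian-corrected conditional
active probability to the class prior:

    P_corr(F) = (A_F + P_active * K) / (N_F + K),  K = 1 / P_active

so a feature never seen in training (N_F = 0) returns the prior and carries
weight exactly 0.  A compound's Bayesian score is the sum of the weights of
its distinct features (presence, not multiplicity).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fragbayes.errors import FitError, ParameterError
from fragbayes.featurize.featureset import FeatureSet, FragmentKey

#: default uncertainty zone for Bayesian scores (overlap region of the two
#: class score distributions)
DEFAULT_ZONE_BOUNDS = (-20.0, 0.0)

RELIABLE_INHIBITOR = "reliable_inhibitor"
UNCERTAIN = "uncertain"
RELIABLE_NONINHIBITOR = "reliable_noninhibitor"


def as_binary_labels(labels) -> np.ndarray:
    """Normalize labels to a boolean array (True = inhibitor/active)."""
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab == "inhibitor":
                out.append(True)
            elif lab == "non_inhibitor":
                out.append(False)
            else:
                raise ParameterError(f"cannot interpret label {lab!r}")
        else:
            out.append(bool(lab))
    return np.asarray(out, dtype=bool)


@dataclass
class FeatureStats:
    n_total: int  # N_F: training compounds containing the feature
    n_active: int  # A_F
    weight: float  # w_F


@dataclass
class BayesScore:
    compound_id: str
    score: float
    zone: str


@dataclass
class NBModel:
    prior_active: float
    laplace_k: float
    n_train: int
    table: dict[FragmentKey, FeatureStats]
    feature_config: dict = field(default_factory=dict)
    zone_bounds: tuple[float, float] = DEFAULT_ZONE_BOUNDS

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "prior_active": self.prior_active,
            "laplace_k": self.laplace_k,
            "n_train": self.n_train,
            "zone_bounds": list(self.zone_bounds),
            "feature_config": self.feature_config,
            "features": [
                [list(k), st.n_total, st.n_active, st.weight]
                for k, st in sorted(self.table.items())
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NBModel":
        doc = json.loads(text)
        table = {
            FragmentKey(k[0], int(k[1]), k[2], bool(k[3])): FeatureStats(nt, na, w)
            for k, nt, na, w in doc["features"]
        }
        return cls(
            prior_active=doc["prior_active"],
            laplace_k=doc["laplace_k"],
            n_train=doc["n_train"],
            table=table,
            feature_config=doc.get("feature_config", {}),
            zone_bounds=tuple(doc.get("zone_bounds", DEFAULT_ZONE_BOUNDS)),
        )


def _weight(n_total: int, n_active: int, prior: float, k: float) -> float:
    if n_total == 0:
        return 0.0
    p_corr = (n_active + prior * k) / (n_total + k)
    return math.log(p_corr / prior)


def fit(
    featuresets: Sequence[FeatureSet],
    labels,
    feature_config: dict | None = None,
    prune_singletons: bool = False,
    zone_bounds: tuple[float, float] = DEFAULT_ZONE_BOUNDS,
) -> NBModel:
    """Fit the Laplacian-corrected naive Bayesian model.

    ``prune_singletons`` optionally drops features seen in exactly one
    training compound (a stand-in for the vendor tool's unpublished
    feature-removal rule); the default keeps everything.
    """
    y = as_binary_labels(labels)
    if len(featuresets) != len(y):
        raise ParameterError("featuresets and labels must have equal length")
    n = len(y)
    n_active = int(y.sum())
    if n_active == 0 or n_active == n:
        raise FitError("training data must contain both classes")
    prior = n_active / n
    k = 1.0 / prior
    totals: dict[FragmentKey, int] = {}
    actives: dict[FragmentKey, int] = {}
    for fs, is_active in zip(featuresets, y):
        for key in fs.features:  # presence, not multiplicity
            totals[key] = totals.get(key, 0) + 1
            if is_active:
                actives[key] = actives.get(key, 0) + 1
    table = {}
    for key, n_total in totals.items():
        if prune_singletons and n_total == 1:
            continue
        a = actives.get(key, 0)
        table[key] = FeatureStats(n_total, a, _weight(n_total, a, prior, k))
    return NBModel(
        prior_active=prior,
        laplace_k=k,
        n_train=n,
        table=table,
        feature_config=dict(feature_config or {}),
        zone_bounds=zone_bounds,
    )


def score(model: NBModel, fs: FeatureSet) -> BayesScore:
    """Bayesian score: sum of weights of features present (unseen features add 0)."""
    s = 0.0
    for key in fs.features:
        st = model.table.get(key)
        if st is not None:
            s += st.weight
    lo, hi = model.zone_bounds
    if s >= hi:
        zone = RELIABLE_INHIBITOR
    elif s >= lo:
        zone = UNCERTAIN
    else:
        zone = RELIABLE_NONINHIBITOR
    return BayesScore(compound_id=fs.compound_id, score=s, zone=zone)


def predict(model: NBModel, fs: FeatureSet, threshold: float = 0.0) -> str:
    """Predicted label: inhibitor iff score strictly exceeds ``threshold``."""
    return "inhibitor" if score(model, fs).score > threshold else "non_inhibitor"


def rank_fragments(model: NBModel, top_k: int) -> tuple[list, list]:
    """Top-``top_k`` favorable and unfavorable fragments by Bayesian weight.

    Each entry is ``(key, weight, n_active, n_total)``.  Ties are broken by
    key for determinism.
    """
    if top_k < 1:
        raise ParameterError("top_k must be >= 1")
    if top_k > len(model.table):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(model.table)} available features; returning all"
        )
        top_k = len(model.table)
    entries = [
        (key, st.weight, st.n_active, st.n_total) for key, st in model.table.items()
    ]
    favorable = sorted(entries, key=lambda e: (-e[1], e[0]))[:top_k]
    unfavorable = sorted(entries, key=lambda e: (e[1], e[0]))[:top_k]
    return favorable, unfavorable


# ---------------------------------------------------------------------------
# leave-one-out fast path
# ---------------------------------------------------------------------------


def loo_scores(featuresets: Sequence[FeatureSet], labels) -> list[float]:
    """Leave-one-out Bayesian score of every compound.

    Computed by decrementing the global counts (prior, K and per-feature
    tallies) instead of refitting n models; exactly equivalent to refitting.
    """
    y = as_binary_labels(labels)
    n = len(y)
    if n < 3:
        raise ParameterError("need at least 3 compounds for LOO")
    n_active = int(y.sum())
    if n_active < 2 or n - n_active < 2:
        raise FitError("each class needs >= 2 members for LOO")
    totals: dict[FragmentKey, int] = {}
    actives: dict[FragmentKey, int] = {}
    for fs, is_active in zip(featuresets, y):
        for key in fs.features:
            totals[key] = totals.get(key, 0) + 1
            if is_active:
                actives[key] = actives.get(key, 0) + 1
    out = []
    for fs, is_active in zip(featuresets, y):
        prior = (n_active - int(is_active)) / (n - 1)
        k = 1.0 / prior
        s = 0.0
        for key in fs.features:
            n_total = totals[key] - 1
            a = actives.get(key, 0) - int(is_active)
            s += _weight(n_total, a, prior, k)
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# descriptor binning
# ---------------------------------------------------------------------------


@dataclass
class DescriptorBinner:
    """Equal-frequency binning of continuous descriptors into BIN features.

    Bin edges are learned on training data and frozen; prediction values
    outside the training range clamp to the extreme bins.
    """

    n_bins: int
    edges: dict[str, list[float]] = field(default_factory=dict)  # interior edges

    @classmethod
    def fit(cls, descriptor_rows: Sequence[dict], n_bins: int) -> "DescriptorBinner":
        if n_bins < 1:
            raise ParameterError("n_bins must be >= 1")
        names = sorted({k for row in descriptor_rows for k in row})
        binner = cls(n_bins=n_bins)
        for name in names:
            vals = np.array(
                [row[name] for row in descriptor_rows if name in row and not _nan(row[name])],
                dtype=float,
            )
            if vals.size == 0:
                continue
            qs = np.quantile(np.sort(vals), np.linspace(0, 1, n_bins + 1)[1:-1]).tolist()
            binner.edges[name] = qs
        return binner

    def bin_index(self, name: str, value: float) -> int:
        edges = self.edges[name]
        return int(np.searchsorted(edges, value, side="right"))

    def transform(self, compound_id: str, row: dict) -> FeatureSet:
        fs = FeatureSet(compound_id)
        for name in sorted(self.edges):
            if name not in row or _nan(row[name]):
                continue
            b = self.bin_index(name, row[name])
            fs.add(FragmentKey(family="BIN", level=b, key=name))
        return fs


def _nan(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def bin_descriptors(
    descriptor_rows: Sequence[dict], n_bins: int
) -> DescriptorBinner:
    """Learn equal-frequency bin edges on training descriptor rows."""
    return DescriptorBinner.fit(descriptor_rows, n_bins)
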