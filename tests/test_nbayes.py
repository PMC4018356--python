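import math

import numpy as np
import pytest

from fragbayes import nbayes
from fragbayes.errors import FitError, ParameterError
from fragbayes.featurize.featureset import FeatureSet, FragmentKey


def fk(name, level=1, family="ACF"):
    return FragmentKey(family, level, name, family == "ACF")


def fs(cid, *names):
    out = FeatureSet(cid)
    for n in names:
        out.add(fk(n))
    return out


def balanced_training():
    """4 compounds, P_active = 0.5 (K = 2): feature 'f' in 3 actives + 1 non."""
    sets = [fs("a1", "f"), fs("a2", "f"), fs("a3", "f"), fs("n1", "f")]
    labels = [True, True, True, False]
    # pad with feature-free compounds to keep both classes at prior 0.5
    sets += [fs("a4", "g"), fs("n2"), fs("n3", "g"), fs("n4")]
    labels += [True, False, False, False]
    return sets, labels


class TestFit:
    def test_weight_arithmetic(self):
        sets, labels = balanced_training()
        model = nbayes.fit(sets, labels)
        assert model.prior_active == pytest.approx(0.5)
        assert model.laplace_k == pytest.approx(2.0)
        st = model.table[fk("f")]
        assert (st.n_total, st.n_active) == (4, 3)
        # P_corr = (3+1)/(4+2) = 0.6667, w = ln(1.3333)
        assert st.weight == pytest.approx(0.2877, abs=1e-4)

    def test_high_count_weight(self):
        sets = [fs(f"a{i}", "f") for i in range(98)] + [fs(f"b{i}") for i in range(98)]
        labels = [True] * 98 + [False] * 98
        model = nbayes.fit(sets, labels)
        # P_active=0.5, A=N=98: P_corr=99/100, w=ln(1.98)
        assert model.table[fk("f")].weight == pytest.approx(0.6831, abs=1e-4)

    def test_single_class_errors(self):
        with pytest.raises(FitError):
            nbayes.fit([fs("a", "f"), fs("b", "g")], [True, True])

    def test_feature_in_every_compound_has_zero_weight(self):
        sets = [fs(f"c{i}", "ubiq") for i in range(10)]
        labels = [i < 8 for i in range(10)]
        model = nbayes.fit(sets, labels)
        assert model.table[fk("ubiq")].weight == pytest.approx(0.0, abs=1e-12)

    def test_prune_singletons(self):
        sets, labels = balanced_training()
        sets[0].add(fk("rare"))
        model = nbayes.fit(sets, labels, prune_singletons=True)
        assert fk("rare") not in model.table
        assert fk("f") in model.table


class TestScorePredict:
    def test_empty_featureset_scores_zero(self):
        sets, labels = balanced_training()
        model = nbayes.fit(sets, labels)
        assert nbayes.score(model, FeatureSet("q")).score == 0.0

    def test_unseen_features_neutral(self):
        sets, labels = balanced_training()
        model = nbayes.fit(sets, labels)
        assert nbayes.score(model, fs("q", "zz", "yy")).score == 0.0

    def test_single_feature_additivity(self):
        sets, labels = balanced_training()
        model = nbayes.fit(sets, labels)
        got = nbayes.score(model, fs("q", "f")).score
        assert got == pytest.approx(0.2877, abs=1e-4)

    def test_zones(self):
        sets, labels = balanced_training()
        model = nbayes.fit(sets, labels)
        assert nbayes.score(model, fs("q", "f")).zone == nbayes.RELIABLE_INHIBITOR
        bs = nbayes.BayesScore("x", -25.0, "")
        # zone rule applied through score(): build a model-independent check
        lo, hi = model.zone_bounds
        assert -25.0 < lo
        assert nbayes.score(model, FeatureSet("e")).zone == nbayes.RELIABLE_INHIBITOR

    def test_zone_boundaries(self):
        model = nbayes.NBModel(0.5, 2.0, 4, {fk("neg"): nbayes.FeatureStats(2, 0, -25.0)})
        assert nbayes.score(model, fs("q", "neg")).zone == nbayes.RELIABLE_NONINHIBITOR
        model.table[fk("mid")] = nbayes.FeatureStats(2, 0, -5.0)
        assert nbayes.score(model, fs("q", "mid")).zone == nbayes.UNCERTAIN

    def test_predict_strict_threshold(self):
        model = nbayes.NBModel(0.5, 2.0, 4, {fk("f"): nbayes.FeatureStats(2, 2, 5.0)})
        assert nbayes.predict(model, fs("q", "f")) == "inhibitor"
        assert nbayes.predict(model, FeatureSet("q")) == "non_inhibitor"  # score 0

    def test_threshold_monotonicity(self):
        model = nbayes.NBModel(0.5, 2.0, 4, {fk("f"): nbayes.FeatureStats(2, 1, -3.0)})
        compounds = [fs("a", "f"), FeatureSet("b")]
        at_zero = [nbayes.predict(model, c, 0.0) for c in compounds]
        at_low = [nbayes.predict(model, c, -20.0) for c in compounds]
        for z, l in zip(at_zero, at_low):
            assert not (z == "inhibitor" and l == "non_inhibitor")


class TestRankFragments:
    def test_pure_active_feature_ranks_first(self):
        sets = [fs(f"a{i}", "win", "common") for i in range(10)]
        sets += [fs(f"n{i}", "common") for i in range(5)]
        labels = [True] * 10 + [False] * 5
        model = nbayes.fit(sets, labels)
        favorable, unfavorable = nbayes.rank_fragments(model, 1)
        assert favorable[0][0] == fk("win")
        assert favorable[0][2:] == (10, 10)  # A_F, N_F reported

    def test_topk_and_disjoint(self):
        sets = [fs(f"c{i}", f"x{i}", f"y{i}") for i in range(30)]
        labels = [i < 24 for i in range(30)]
        model = nbayes.fit(sets, labels)
        favorable, unfavorable = nbayes.rank_fragments(model, 20)
        assert len(favorable) == 20 and len(unfavorable) == 20
        assert not {k for k, *_ in favorable[:10]} & {k for k, *_ in unfavorable[:10]}

    def test_topk_exceeding_features_warns(self):
        sets, labels = balanced_training()
        model = nbayes.fit(sets, labels)
        with pytest.warns(UserWarning, match="returning all"):
            favorable, _ = nbayes.rank_fragments(model, 99)
        assert len(favorable) == len(model.table)


class TestPersistence:
    def test_json_roundtrip_bit_identical(self, synthetic_featureset_bundle):
        b = synthetic_featureset_bundle
        model = nbayes.fit(b["featuresets"][:100], b["labels"][:100])
        clone = nbayes.NBModel.from_json(model.to_json())
        for fsx in b["featuresets"][100:140]:
            assert nbayes.score(clone, fsx).score == nbayes.score(model, fsx).score


class TestLOO:
    def test_fast_path_equals_refits(self, rng):
        names = [f"f{i}" for i in range(12)]
        sets = []
        labels = []
        for i in range(24):
            chosen = rng.choice(names, size=4, replace=False)
            sets.append(fs(f"c{i}", *chosen))
            labels.append(bool(rng.random() < 0.6))
        # ensure both classes have >= 2 members
        labels[0] = labels[1] = True
        labels[2] = labels[3] = False
        fast = nbayes.loo_scores(sets, labels)
        for i in range(24):
            model = nbayes.fit(sets[:i] + sets[i + 1 :], labels[:i] + labels[i + 1 :])
            assert fast[i] == pytest.approx(
                nbayes.score(model, sets[i]).score, abs=1e-9
            )

    def test_unique_features_score_zero(self):
        sets = [fs("u", "only_here"), fs("a", "f"), fs("b", "f"), fs("c", "g"), fs("d", "g")]
        labels = [True, True, False, True, False]
        scores = nbayes.loo_scores(sets, labels)
        assert scores[0] == 0.0


class TestBinning:
    def test_equal_frequency_sizes(self, rng):
        vals = rng.normal(size=100)
        rows = [{"MW": float(v)} for v in vals]
        binner = nbayes.bin_descriptors(rows, 10)
        counts = np.zeros(10, dtype=int)
        for v in vals:
            counts[binner.bin_index("MW", float(v))] += 1
        assert counts.tolist() == [10] * 10

    def test_out_of_range_clamps(self, rng):
        rows = [{"MW": float(v)} for v in rng.uniform(100, 200, size=50)]
        binner = nbayes.bin_descriptors(rows, 5)
        assert binner.bin_index("MW", 0.0) == 0
        assert binner.bin_index("MW", 1e6) == 4

    def test_shuffle_invariant_edges(self, rng):
        vals = rng.normal(size=80).tolist()
        b1 = nbayes.bin_descriptors([{"x": v} for v in vals], 4)
        rng.shuffle(vals)
        b2 = nbayes.bin_descriptors([{"x": v} for v in vals], 4)
        assert b1.edges == b2.edges

    def test_constant_descriptor_zero_weight(self):
        rows = [{"k": 1.0} for _ in range(10)]
        binner = nbayes.bin_descriptors(rows, 5)
        sets = [binner.transform(f"c{i}", rows[i]) for i in range(10)]
        labels = [i < 8 for i in range(10)]
        model = nbayes.fit(sets, labels)
        (st,) = model.table.values()
        assert st.weight == pytest.approx(0.0, abs=1e-12)

    def test_transform_skips_missing(self):
        binner = nbayes.bin_descriptors([{"x": 1.0}, {"x": 2.0}, {"x": 3.0}], 2)
        out = binner.transform("c", {"x": float("nan")})
        assert len(out) == 0
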