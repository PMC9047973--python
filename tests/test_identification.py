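"""Gallery/probe ranking, closed/open-set metrics, database growth."""

import numpy as np
import pytest

from sealface.identification import (Gallery, OpenSetMetrics, ProbeResult,
                                     closed_set_accuracy, compare_models,
                                     cross_validate, enroll_or_merge,
                                     individual_similarity, open_set_evaluate,
                                     pair_similarity, rank_candidates,
                                     split_identity_folds)


def unit(*values, dim=8):
    v = np.zeros(dim)
    v[:len(values)] = values
    return v / np.linalg.norm(v)


class TestPairSimilarity:
    def test_self_similarity_one(self):
        v = unit(1, 2, 3)
        assert pair_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_zero(self):
        assert pair_similarity(unit(1), unit(0, 1)) == pytest.approx(0.0)

    def test_hand_dot_product(self):
        assert pair_similarity(unit(1), unit(0.6, 0.8)) == pytest.approx(0.6)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pair_similarity(np.array([np.nan, 0.0]), np.array([1.0, 0.0]))


class TestIndividualSimilarity:
    def test_identical_folders(self):
        v = unit(1, 1)
        assert individual_similarity([v], [v]) == pytest.approx(1.0)

    def test_mean_of_pairwise(self):
        probe = [unit(1)]
        gallery = [unit(0.4, np.sqrt(1 - 0.16)), unit(0.8, 0.6)]
        assert individual_similarity(probe, gallery) == pytest.approx(0.6)

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        probe = [unit(*rng.normal(size=4)) for _ in range(3)]
        gallery = [unit(*rng.normal(size=4)) for _ in range(4)]
        a = individual_similarity(probe, gallery)
        b = individual_similarity(probe[::-1], gallery[::-1])
        assert a == pytest.approx(b)

    def test_max_aggregation(self):
        probe = [unit(1)]
        gallery = [unit(0.4, np.sqrt(1 - 0.16)), unit(0.8, 0.6)]
        assert individual_similarity(probe, gallery, "max") == pytest.approx(0.8)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            individual_similarity(np.empty((0, 4)), [unit(1)])


def make_gallery(vectors):
    g = Gallery()
    for gid, vecs in vectors.items():
        g.enroll(gid, np.atleast_2d(vecs))
    return g


class TestRankCandidates:
    def test_singleton_gallery(self):
        g = make_gallery({"a": unit(1)})
        result = rank_candidates([unit(1)], g)
        assert result.ranked == [("a", pytest.approx(1.0))]

    def test_descending_order(self):
        g = make_gallery({"lo": unit(0.2, np.sqrt(1 - 0.04)),
                          "hi": unit(0.9, np.sqrt(1 - 0.81)),
                          "mid": unit(0.5, np.sqrt(0.75))})
        result = rank_candidates([unit(1)], g, top_k=3)
        assert [gid for gid, _ in result.ranked] == ["hi", "mid", "lo"]

    def test_tie_broken_by_ascending_id(self):
        v = unit(1, 1)
        g = make_gallery({"b": v, "a": v})
        result = rank_candidates([v], g, top_k=2)
        assert [gid for gid, _ in result.ranked] == ["a", "b"]

    def test_empty_gallery_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates([unit(1)], Gallery())


class TestClosedSetAccuracy:
    def _result(self, truth, ranked_ids):
        return ProbeResult(probe_id="p", truth=truth,
                           ranked=[(g, 1.0 - 0.1 * i)
                                   for i, g in enumerate(ranked_ids)])

    def test_all_rank_one(self):
        results = [self._result("a", ["a", "b"]),
                   self._result("b", ["b", "a"])]
        assert closed_set_accuracy(results, 1) == 1.0

    def test_ranks_1_2_6(self):
        ids = [f"g{i}" for i in range(7)]
        results = [self._result("g0", ids),
                   self._result("g1", ids),
                   self._result("g5", ids)]
        assert closed_set_accuracy(results, 1) == pytest.approx(1 / 3)
        assert closed_set_accuracy(results, 5) == pytest.approx(2 / 3)

    def test_k_at_gallery_size(self):
        ids = ["a", "b", "c"]
        results = [self._result(t, ids) for t in ids]
        assert closed_set_accuracy(results, 3) == 1.0

    def test_non_decreasing_in_k(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(6)]
        results = [self._result(str(rng.choice(ids)),
                                list(rng.permutation(ids)))
                   for _ in range(20)]
        accs = [closed_set_accuracy(results, k) for k in range(1, 7)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))

    def test_imposter_probe_rejected(self):
        with pytest.raises(ValueError):
            closed_set_accuracy([self._result("imposter", ["a"])], 1)


def open_set_oracle(results, threshold, k):
    """Independent enumeration of the open-set confusion counts."""
    tp = fn = fp = tn = 0
    for r in results:
        best = r.ranked[0][1]
        if r.truth == "imposter":
            if best >= threshold:
                fp += 1
            else:
                tn += 1
        else:
            in_top = any(gid == r.truth for gid, _ in r.ranked[:k])
            if best >= threshold and in_top:
                tp += 1
            else:
                fn += 1
    return tp, fp, fn, tn


class TestOpenSetEvaluate:
    def test_hand_enumerated_example(self):
        results = [
            ProbeResult("g1", [("a", 0.8), ("b", 0.1)], truth="a"),
            ProbeResult("g2", [("b", 0.3), ("a", 0.2)], truth="b"),
            ProbeResult("i1", [("a", 0.6), ("b", 0.5)], truth="imposter"),
            ProbeResult("i2", [("b", 0.2), ("a", 0.1)], truth="imposter"),
        ]
        m = open_set_evaluate(results, threshold=0.5, k=1)
        assert m.counts == {"TP": 1, "FP": 1, "FN": 1, "TN": 1}
        assert m.TPR == m.FPR == m.accuracy == m.precision == m.f_score == 0.5

    def test_infinite_threshold_accuracy_is_baseline(self):
        results = [
            ProbeResult("g", [("a", 0.9)], truth="a"),
            ProbeResult("i", [("a", 0.9)], truth="imposter"),
            ProbeResult("i2", [("a", 0.1)], truth="imposter"),
        ]
        m = open_set_evaluate(results, threshold=np.inf, k=1)
        assert m.accuracy == m.baseline == pytest.approx(2 / 3)

    def test_rate_identities_hold(self):
        rng = np.random.default_rng(5)
        gallery_ids = ["a", "b", "c"]
        for trial in range(30):
            results = []
            for p in range(int(rng.integers(2, 10))):
                scores = sorted(rng.uniform(-1, 1, 3))[::-1]
                ranked = list(zip(gallery_ids, scores))
                truth = ("imposter" if rng.random() < 0.4
                         else str(rng.choice(gallery_ids)))
                results.append(ProbeResult(f"p{p}", ranked, truth=truth))
            thr = float(rng.uniform(-1, 1))
            m = open_set_evaluate(results, thr, k=2)
            if not np.isnan(m.TPR):
                assert m.TPR + m.FNR == pytest.approx(1.0)
            if not np.isnan(m.FPR):
                assert m.FPR + m.TNR == pytest.approx(1.0)
            tp, fp, fn, tn = open_set_oracle(results, thr, 2)
            assert m.counts == {"TP": tp, "FP": fp, "FN": fn, "TN": tn}

    def test_missing_probe_class_flagged_nan(self, caplog):
        results = [ProbeResult("g", [("a", 0.9)], truth="a")]
        with caplog.at_level("WARNING"):
            m = open_set_evaluate(results, 0.5, k=1)
        assert np.isnan(m.FPR) and np.isnan(m.TNR)
        assert m.TPR == 1.0


class TestEnrollOrMerge:
    def test_empty_gallery_creates_first_id(self):
        gallery, decision = enroll_or_merge(Gallery(), [unit(1)])
        assert decision["decision"] == "new"
        assert decision["identity"] == "000"

    def test_identical_probe_merges(self):
        v = unit(1, 2)
        gallery = make_gallery({"000": v})
        gallery.id_counter = 1
        gallery, decision = enroll_or_merge(gallery, [v], threshold=0.5)
        assert decision["decision"] == "merge"
        assert decision["identity"] == "000"
        assert len(gallery.entries["000"]) == 2

    def test_boundary_score_merges(self):
        # cosine exactly at threshold: the >= rule merges
        a = unit(1)
        b = unit(0.5, np.sqrt(0.75))
        gallery = make_gallery({"000": a})
        gallery.id_counter = 1
        _, decision = enroll_or_merge(gallery, [b], threshold=0.5)
        assert decision["decision"] == "merge"

    def test_low_score_enrolls_new_id(self):
        gallery = make_gallery({"000": unit(1)})
        gallery.id_counter = 1
        gallery, decision = enroll_or_merge(gallery, [unit(0, 1)],
                                            threshold=0.5)
        assert decision["decision"] == "new"
        assert decision["identity"] == "001"


def fake_embedder(train_chips, seed):
    """Deterministic stand-in: one orthogonal direction per identity,
    chips of an identity embed near that direction."""
    ids = sorted({c.identity for chips in train_chips.values() for c in chips}
                 | set(train_chips))

    def embed(chips):
        out = []
        for c in chips:
            rng = np.random.default_rng(
                abs(hash(c.identity)) % (2 ** 31))
            base = np.zeros(512)
            base[rng.integers(0, 512)] = 1.0
            noise = np.random.default_rng(
                c.pixels.sum() % (2 ** 31)).normal(0, 0.05, 512)
            v = base + noise
            out.append(v / np.linalg.norm(v))
        return np.array(out)

    return embed


@pytest.fixture(scope="module")
def chips():
    from conftest import make_chip_set
    return make_chip_set(8, 6, seed=77)


class TestCrossValidate:

    def test_split_contract(self, chips):
        folds, smalls = split_identity_folds(chips, 5, seed=1)
        assert smalls == {}
        for fold in folds:
            assert set(fold) == set(chips)
            assert all(len(v) >= 1 for v in fold.values())
        for identity in chips:
            sections = [c for fold in folds for c in fold[identity]]
            assert len(sections) == 6
            assert len({id(c) for c in sections}) == 6  # disjoint

    def test_photo_filter_pools_small_identities(self, chips):
        mixed = dict(chips)
        mixed["small"] = chips["000"][:2]
        folds, smalls = split_identity_folds(mixed, 5, seed=1)
        assert "small" in smalls and "small" not in folds[0]

    def test_closed_protocol_metrics(self, chips):
        cv = cross_validate(chips, k_folds=3, protocol="closed", seed=2,
                            train_fn=fake_embedder)
        assert len(cv["folds"]) == 3
        for row in cv["folds"]:
            assert row["rank5"] >= row["rank1"]
        assert set(cv["mean"]) == {"rank1", "rank5"}
        assert cv["sd"]["rank1"] >= 0

    def test_open_protocol_includes_imposters(self, chips):
        mixed = dict(chips)
        mixed["zz_stray"] = chips["000"][:2]
        cv = cross_validate(mixed, k_folds=3, protocol="open", seed=2,
                            train_fn=fake_embedder, threshold=0.5)
        row = cv["folds"][0]
        assert 0.0 <= row["rank1_TPR"] <= 1.0
        assert row["rank1_TPR"] + row["rank1_FNR"] == pytest.approx(1.0)
        assert row["rank1_FPR"] + row["rank1_TNR"] == pytest.approx(1.0)

    def test_no_qualifying_identity_rejected(self, chips):
        small = {k: v[:2] for k, v in chips.items()}
        with pytest.raises(ValueError):
            cross_validate(small, k_folds=5, train_fn=fake_embedder)


class TestCompareModels:
    def _metrics(self, values, rank=1):
        names = ("TPR", "FPR", "FNR", "TNR", "baseline", "accuracy",
                 "precision", "f_score")
        return OpenSetMetrics(**dict(zip(names, values)), rank=rank)

    def test_equal_tables_zero_difference(self):
        m = self._metrics([0.5] * 8)
        assert all(v == 0.0 for v in compare_models(m, m).values())

    def test_published_rank1_differences(self):
        # difference row of the published open-set comparison, rank 1
        ours = self._metrics([0.678, 0.032, 0.322, 0.968, 0.892, 0.945,
                              0.656, 0.663])
        baseline = self._metrics([0.251, 0.057, 0.749, 0.943, 0.868, 0.888,
                                  0.285, 0.259])
        diff = compare_models(ours, baseline)
        printed = {"TPR": 0.427, "FPR": -0.025, "FNR": -0.427, "TNR": 0.025,
                   "baseline": 0.023, "accuracy": 0.057, "precision": 0.371,
                   "f_score": 0.405}
        for key, value in printed.items():
            assert diff[key] == pytest.approx(value, abs=1.5e-3)

    def test_mismatched_ranks_rejected(self):
        with pytest.raises(ValueError):
            compare_models(self._metrics([0.5] * 8, rank=1),
                           self._metrics([0.5] * 8, rank=5))
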