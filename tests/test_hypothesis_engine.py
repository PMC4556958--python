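"""Common-pharmacophore generation, scoring, and filtering."""

import math
from itertools import combinations

import numpy as np
import pytest

from combipharm import (
    FeaturePoint,
    GenerationParams,
    PharmacophoreHypothesis,
    enumerate_candidate_hypotheses,
    filter_hypotheses,
    hypotheses_from_json,
    hypotheses_to_json,
    match_molecule,
    selectivity_score,
    survival_inactive_score,
    survival_score,
)
from combipharm.hypothesis_engine import HypothesisScore, score_hypothesis

from conftest import feature_cloud, random_cloud, triangle_points


class TestHypothesisType:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            PharmacophoreHypothesis("X1", ("A", "A", "A"), np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]]), 1.0)
        with pytest.raises(ValueError, match="triangle"):
            PharmacophoreHypothesis("X1", ("A", "A", "A"), np.array([[0, 1, 9], [1, 0, 1], [9, 1, 0]]), 1.0)
        with pytest.raises(ValueError, match="3 or 4"):
            PharmacophoreHypothesis("X1", ("A", "A"), np.zeros((2, 2)), 1.0)

    def test_json_round_trip_exact(self, tmp_path, hhr_hypothesis):
        path = tmp_path / "hyps.json"
        hypotheses_to_json([hhr_hypothesis], path)
        (back,) = hypotheses_from_json(path)
        assert back.hyp_id == hhr_hypothesis.hyp_id
        assert back.sites == hhr_hypothesis.sites
        np.testing.assert_array_equal(back.distances, hhr_hypothesis.distances)
        assert back.tol == hhr_hypothesis.tol

    def test_json_schema_validated(self, tmp_path):
        (tmp_path / "bad.json").write_text('[{"hyp_id": "X"}]')
        with pytest.raises(ValueError, match="missing fields"):
            hypotheses_from_json(tmp_path / "bad.json")


class TestGeneration:
    def test_single_tuple_gives_single_hypothesis(self):
        rec = feature_cloud("a1", "active", triangle_points(("H", "H", "R"), 3, 4, 5))
        (hyp,) = enumerate_candidate_hypotheses([rec], {3}, GenerationParams(min_actives=1))
        assert hyp.hyp_id == "HHR1"
        assert sorted(hyp.distances[np.triu_indices(3, 1)]) == pytest.approx([3, 4, 5])

    def test_disjoint_vocabularies_give_nothing(self):
        a = feature_cloud("a1", "active", triangle_points(("A", "A", "A"), 3, 4, 5))
        b = feature_cloud("a2", "active", triangle_points(("H", "H", "H"), 3, 4, 5))
        assert enumerate_candidate_hypotheses([a, b], {3}, GenerationParams(min_actives=2)) == []

    def test_invalid_k_rejected(self):
        rec = feature_cloud("a1", "active", triangle_points(("H", "H", "R"), 3, 4, 5))
        with pytest.raises(ValueError, match="subset"):
            enumerate_candidate_hypotheses([rec], {2, 3})

    def test_featureless_active_excluded_with_warning(self):
        ok = feature_cloud("a1", "active", triangle_points(("H", "H", "R"), 3, 4, 5))
        empty = feature_cloud("a2", "active", [FeaturePoint("A", (0, 0, 0))])
        empty.features = {0: []}
        with pytest.warns(UserWarning, match="a2"):
            hyps = enumerate_candidate_hypotheses([ok, empty], {3}, GenerationParams(min_actives=1))
        assert len(hyps) == 1

    @staticmethod
    def _planted_actives(rng, n=5, noise=0.0, decoys=3):
        records = []
        for i in range(n):
            pts = triangle_points(("H", "H", "R"), 3, 4, 5)
            jitter = [
                FeaturePoint(p.ftype, tuple(p.xyz + rng.normal(0, noise, 3))) for p in pts
            ]
            records.append(feature_cloud(f"a{i}", "active", jitter + random_cloud(rng, decoys)))
        return records

    def test_planted_triangle_recovered_against_brute_force(self):
        rng = np.random.default_rng(3)
        actives = self._planted_actives(rng)
        params = GenerationParams(min_actives=5, bin_width=1.0)
        hyps = enumerate_candidate_hypotheses(actives, {3}, params)
        target = np.array([3.0, 4.0, 5.0])
        found = [
            h for h in hyps
            if "".join(sorted(h.sites)) == "HHR"
            and np.abs(np.sort(h.distances[np.triu_indices(3, 1)]) - target).max() <= params.bin_width
        ]
        assert found, "planted HHR triangle not recovered"
        # oracle: brute-force count of actives owning an HHR triple at (3,4,5)
        n_support = 0
        for rec in actives:
            ok = False
            for combo in combinations(rec.features[0], 3):
                types = sorted(f.ftype for f in combo)
                if types != ["H", "H", "R"]:
                    continue
                pos = np.array([f.xyz for f in combo])
                d = np.sort(
                    [np.linalg.norm(pos[i] - pos[j]) for i in range(3) for j in range(i + 1, 3)]
                )
                if np.abs(d - target).max() <= params.bin_width:
                    ok = True
            n_support += ok
        assert n_support == 5

    def test_emitted_hypotheses_matched_by_min_actives(self):
        rng = np.random.default_rng(9)
        actives = self._planted_actives(rng, n=6, noise=0.1, decoys=4)
        hyps = enumerate_candidate_hypotheses(actives, {3}, GenerationParams(min_actives=4))
        assert hyps
        for hyp in hyps:
            n = sum(1 for rec in actives if match_molecule(rec, hyp).matched)
            assert n >= 4

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        actives = self._planted_actives(rng, n=5, noise=0.1, decoys=4)
        params = GenerationParams(min_actives=3)
        h1 = enumerate_candidate_hypotheses(actives, {3, 4}, params)
        h2 = enumerate_candidate_hypotheses(actives[::-1], {3, 4}, params)
        key = lambda hs: sorted((h.hyp_id, h.distances.tolist()) for h in hs)
        assert key(h1) == key(h2)


class TestScores:
    @staticmethod
    def _match_first_n(n):
        """A fake matcher flagging records whose numeric suffix is < n."""

        class R:
            def __init__(self, m):
                self.matched = m

        return lambda rec, hyp: R(int(rec.mol_id[1:]) < n)

    def _records(self, prefix, n):
        return [
            feature_cloud(f"{prefix}{i}", "active", [FeaturePoint("A", (0, 0, 0))])
            for i in range(n)
        ]

    def test_survival_bounds_and_fraction(self, hhr_hypothesis):
        recs = self._records("a", 10)
        assert survival_score(hhr_hypothesis, recs, self._match_first_n(10)) == 1.0
        assert survival_score(hhr_hypothesis, recs, self._match_first_n(0)) == 0.0
        assert survival_score(hhr_hypothesis, recs, self._match_first_n(5)) == 0.5
        with pytest.raises(ValueError):
            survival_score(hhr_hypothesis, [], self._match_first_n(1))

    def test_survival_inactive_arithmetic(self, hhr_hypothesis):
        act, inact = self._records("a", 10), self._records("i", 10)
        fn = self._match_first_n
        assert survival_inactive_score(hhr_hypothesis, act, inact, 1.0, fn(10)) == pytest.approx(0.0)
        # f_active=0.5, f_inactive=0.2, lambda=1 -> 0.3
        class Sel:
            def __call__(self, rec, hyp):
                class R:
                    pass
                r = R()
                n = int(rec.mol_id[1:])
                r.matched = (rec.mol_id[0] == "a" and n < 5) or (rec.mol_id[0] == "i" and n < 2)
                return r
        assert survival_inactive_score(hhr_hypothesis, act, inact, 1.0, Sel()) == pytest.approx(0.3)
        # lambda=0 -> identical to survival for any matcher
        assert survival_inactive_score(hhr_hypothesis, act, inact, 0.0, Sel()) == pytest.approx(0.5)

    def test_survival_inactive_monotone_in_lambda(self, hhr_hypothesis):
        act, inact = self._records("a", 10), self._records("i", 10)
        class Sel:
            def __call__(self, rec, hyp):
                class R:
                    matched = True
                return R()
        vals = [
            survival_inactive_score(hhr_hypothesis, act, inact, lam, Sel())
            for lam in (0.0, 0.5, 1.0, 2.0)
        ]
        assert vals == sorted(vals, reverse=True)

    def test_empty_inactives_warns_and_returns_survival(self, hhr_hypothesis):
        act = self._records("a", 4)
        with pytest.warns(UserWarning):
            v = survival_inactive_score(hhr_hypothesis, act, [], 1.0, self._match_first_n(4))
        assert v == 1.0

    def test_selectivity_pseudocount_arithmetic(self, hhr_hypothesis):
        # all match -> 0; N=99 none match -> 2; N=999, 9 match -> 2
        recs = self._records("a", 99)
        assert selectivity_score(hhr_hypothesis, recs, self._match_first_n(99)) == pytest.approx(0.0)
        assert selectivity_score(hhr_hypothesis, recs, self._match_first_n(0)) == pytest.approx(2.0)
        recs = self._records("a", 999)
        assert selectivity_score(hhr_hypothesis, recs, self._match_first_n(9)) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            selectivity_score(hhr_hypothesis, [], self._match_first_n(0))

    def test_selectivity_strictly_decreasing_in_matches(self, hhr_hypothesis):
        recs = self._records("a", 50)
        vals = [
            selectivity_score(hhr_hypothesis, recs, self._match_first_n(n)) for n in range(0, 51, 10)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestFilter:
    def _mk(self, hyp_id, si, sel, n_inact):
        hyp = PharmacophoreHypothesis(
            hyp_id, ("A", "A", "A"), np.array([[0.0, 3, 3], [3, 0, 3], [3, 3, 0]]), 1.0
        )
        return hyp, HypothesisScore(
            survival=1.0, survival_inactive=si, selectivity=sel,
            n_active_matched=5, n_inactive_matched=n_inact,
        )

    def test_pass_through(self):
        scored = [self._mk(f"AAA{i}", 0.5, 1.0, i) for i in range(5)]
        out = filter_hypotheses(scored, -math.inf, -math.inf, inactive_match_top_k=10)
        assert [h.hyp_id for h in out] == [f"AAA{i}" for i in range(5)]

    def test_top_k_by_fewest_inactive_matches(self):
        scored = [self._mk(f"AAA{i}", 0.5, 1.0, n) for i, n in enumerate([0, 1, 2, 3, 4])]
        out = filter_hypotheses(scored, -math.inf, -math.inf, inactive_match_top_k=2)
        assert [h.hyp_id for h in out] == ["AAA0", "AAA1"]

    def test_score_thresholds(self):
        scored = [self._mk("AAA1", 0.8, 2.0, 0), self._mk("AAA2", 0.1, 2.0, 0), self._mk("AAA3", 0.8, 0.5, 0)]
        out = filter_hypotheses(scored, survival_inactive_min=0.5, selectivity_min=1.0, inactive_match_top_k=5)
        assert [h.hyp_id for h in out] == ["AAA1"]

    def test_tie_break_matches_exhaustive_stable_sort(self):
        scored = [
            self._mk("AAA3", 0.5, 1.0, 2),
            self._mk("AAA1", 0.9, 1.0, 2),
            self._mk("AAA2", 0.9, 1.0, 2),
            self._mk("AAA4", 0.9, 1.0, 1),
        ]
        out = filter_hypotheses(scored, -math.inf, -math.inf, inactive_match_top_k=2)
        expected = sorted(scored, key=lambda hs: (hs[1].n_inactive_matched, -hs[1].survival_inactive, hs[0].hyp_id))[:2]
        assert [h.hyp_id for h in out] == sorted(h.hyp_id for h, _ in expected)

    def test_top_k_validation(self):
        with pytest.raises(ValueError):
            filter_hypotheses([], inactive_match_top_k=0)


def test_score_hypothesis_consistency(hhr_hypothesis, hhr_cloud):
    """Composite scorer agrees with the individual scoring functions."""
    act = [feature_cloud(f"a{i}", "active", hhr_cloud) for i in range(4)]
    inact = [feature_cloud(f"i{i}", "inactive", random_cloud(np.random.default_rng(0), 3)) for i in range(6)]
    s = score_hypothesis(hhr_hypothesis, act, inact, match_molecule)
    assert s.survival == survival_score(hhr_hypothesis, act, match_molecule)
    assert s.survival_inactive == pytest.approx(
        survival_inactive_score(hhr_hypothesis, act, inact, 1.0, match_molecule)
    )
    assert s.selectivity == pytest.approx(
        selectivity_score(hhr_hypothesis, act + inact, match_molecule)
    )
    assert s.n_active_matched == 4
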