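"""Target-diagnosis attribution attack and baselines."""

import numpy as np
import pytest

from embaudit import (
    Corpus,
    DiagnosisEntry,
    GroundTruth,
    majority_baseline,
    predict_diagnoses,
    score_attack,
    select_target_diagnoses,
)
from embaudit.attack import evaluation_set, phrase_occurrences, run_attack_trials
from embaudit.embeddings import vec_distance
from conftest import make_model


def make_truth(patient_diagnoses, names=None, retained=None):
    names = names or {pid: (f"fn{pid}", f"ln{pid}") for pid in patient_diagnoses}
    retained = set(retained if retained is not None else patient_diagnoses)
    return GroundTruth(
        retained_full_names={tuple(sorted(names[p])) for p in retained},
        patient_diagnoses={p: frozenset(d) for p, d in patient_diagnoses.items()},
        retained_name_tokens={t for p in retained for t in names[p]},
        patient_names=names,
        retained_patient_ids=retained,
    )


class TestPhraseCounting:
    def test_counts_contiguous_occurrences(self):
        corpus = Corpus.from_notes([
            ("p0", ["colon", "screening", "x", "colon", "screening"]),
            ("p1", ["screening", "colon"]),
        ])
        assert phrase_occurrences(corpus, ["colon", "screening"]) == 2
        assert phrase_occurrences(corpus, ["colon"]) == 3
        assert phrase_occurrences(corpus, ["screening", "colon"]) == 1


class TestTargetSelection:
    CATALOGUE = [DiagnosisEntry("a", ("aa",)), DiagnosisEntry("b", ("bb",)),
                 DiagnosisEntry("c", ("cc",))]

    def test_min_count_filter(self):
        counts = {"a": 12, "b": 9, "c": 30}
        got = select_target_diagnoses(
            self.CATALOGUE, None, 2, min_count=10, seed=0, precomputed_counts=counts
        )
        assert sorted(got) == ["a", "c"]

    def test_whole_catalogue_at_zero_min_count(self):
        counts = {"a": 0, "b": 0, "c": 0}
        got = select_target_diagnoses(
            self.CATALOGUE, None, 3, min_count=0, seed=1, precomputed_counts=counts
        )
        assert sorted(got) == ["a", "b", "c"]

    def test_deterministic(self):
        corpus = Corpus.from_notes([("p", ["aa", "bb", "cc"] * 5)])
        a = select_target_diagnoses(self.CATALOGUE, corpus, 2, min_count=1, seed=42)
        b = select_target_diagnoses(self.CATALOGUE, corpus, 2, min_count=1, seed=42)
        assert a == b

    def test_shortfall_error_names_counts(self):
        counts = {"a": 1, "b": 1, "c": 30}
        with pytest.raises(ValueError, match="min_count"):
            select_target_diagnoses(
                self.CATALOGUE, None, 2, min_count=10, seed=0, precomputed_counts=counts
            )


class TestPrediction:
    def _model(self):
        return make_model({
            "fn": [0.0, 0.0], "ln": [0.0, 0.0],
            "aa": [1.0, 0.0], "bb": [2.0, 0.0], "cc": [3.0, 0.0], "dd": [2.0, 0.0],
        })

    CAT = {"a": ("aa",), "b": ("bb",), "c": ("cc",), "d": ("dd",)}

    def test_matches_brute_force_sort(self):
        model = self._model()
        got = predict_diagnoses(model, ("fn", "ln"), ["a", "b", "c", "d"], self.CAT,
                                k=4, metric="cityblock", direction="farthest")
        name_vec = np.zeros(2)
        dist = {t: vec_distance(name_vec, model.vector(self.CAT[t][0]), "cityblock")
                for t in "abcd"}
        expected = sorted("abcd", key=lambda t: (-dist[t], t))
        assert got == expected
        assert got == ["c", "b", "d", "a"]  # tie b/d broken lexicographically

    def test_nearest_direction(self):
        got = predict_diagnoses(self._model(), ("fn", "ln"), ["a", "b", "c", "d"],
                                self.CAT, k=2, metric="cityblock", direction="nearest")
        assert got == ["a", "b"]

    def test_k_cannot_exceed_targets(self):
        with pytest.raises(ValueError):
            predict_diagnoses(self._model(), ("fn",), ["a"], self.CAT, k=2)


class TestScoring:
    def test_hand_counted_accuracy(self):
        truth = make_truth({"p1": {"a"}, "p2": {"b"}, "p3": {"c"}})
        preds = {"p1": ["a", "b"], "p2": ["c", "a"], "p3": ["b", "c"]}
        targets = ["a", "b", "c"]
        assert score_attack(preds, truth, targets, 1) == pytest.approx(1 / 3)
        assert score_attack(preds, truth, targets, 2) == pytest.approx(2 / 3)

    def test_never_correct_is_zero(self):
        truth = make_truth({"p1": {"a"}, "p2": {"a"}})
        preds = {"p1": ["b"], "p2": ["b"]}
        assert score_attack(preds, truth, ["a", "b"], 1) == 0.0

    def test_full_prediction_list_scores_one(self):
        truth = make_truth({"p1": {"a"}, "p2": {"b"}})
        preds = {"p1": ["a", "b"], "p2": ["a", "b"]}
        assert score_attack(preds, truth, ["a", "b"], 2) == 1.0

    def test_empty_evaluation_set_errors(self):
        truth = make_truth({"p1": {"a"}})
        with pytest.raises(ValueError, match="empty"):
            score_attack({}, truth, ["a"], 1)


class TestMajorityBaseline:
    def test_degenerate_single_target(self):
        truth = make_truth({f"p{i}": {"a"} for i in range(4)})
        pids = evaluation_set(truth, ["a"])
        assert majority_baseline(["a"], truth, pids, 1) == 1.0

    def test_hand_counted_five_ninths(self):
        billing = {}
        for i in range(5):
            billing[f"pa{i}"] = {"a"}
        for i in range(3):
            billing[f"pb{i}"] = {"b"}
        billing["pc0"] = {"c"}
        truth = make_truth(billing)
        pids = evaluation_set(truth, ["a", "b", "c"])
        assert len(pids) == 9
        assert majority_baseline(["a", "b", "c"], truth, pids, 1) == pytest.approx(5 / 9)

    def test_covers_all_targets_at_full_n(self):
        truth = make_truth({"p1": {"a"}, "p2": {"c"}})
        pids = evaluation_set(truth, ["a", "b", "c"])
        assert majority_baseline(["a", "b", "c"], truth, pids, 3) == 1.0


class TestTrials:
    def _random_setup(self, n_patients=60, n_diag=12, seed=0):
        rng = np.random.default_rng(seed)
        catalogue = [DiagnosisEntry(f"d{i:02d}", (f"diag{i:02d}",)) for i in range(n_diag)]
        vocab = {e.description_tokens[0]: rng.normal(size=6) for e in catalogue}
        billing, names = {}, {}
        for i in range(n_patients):
            pid = f"p{i:03d}"
            names[pid] = (f"fn{i:03d}", f"ln{i:03d}")
            vocab[names[pid][0]] = rng.normal(size=6)
            vocab[names[pid][1]] = rng.normal(size=6)
            billed = rng.choice(n_diag, size=2, replace=False)
            billing[pid] = {f"d{j:02d}" for j in billed}
        model = make_model(vocab)
        truth = make_truth(billing, names=names)
        counts = {e.diagnosis_id: 99 for e in catalogue}
        return model, truth, catalogue, counts

    def test_reproducible_with_fixed_seed(self):
        model, truth, catalogue, counts = self._random_setup()
        kw = dict(n_trials=5, n_targets=4, min_count=0, k=2, seed=11,
                  count_mode="patients")
        a = run_attack_trials(model, truth, catalogue, None, **kw)
        b = run_attack_trials(model, truth, catalogue, None, **kw)
        assert a["beat_rate_a1"] == b["beat_rate_a1"]
        assert [t.target_ids for t in a["trials"]] == [t.target_ids for t in b["trials"]]

    def test_accuracy_ordering_invariants(self):
        model, truth, catalogue, _ = self._random_setup(seed=3)
        out = run_attack_trials(model, truth, catalogue, None, n_trials=20,
                                n_targets=6, min_count=0, k=5, seed=2,
                                count_mode="patients", include_random=True)
        for t in out["trials"]:
            assert t.a_at_1 <= t.a_at_5
            assert t.baseline_a1 <= t.baseline_a5
            for v in (t.a_at_1, t.a_at_5, t.baseline_a1, t.baseline_a5):
                assert 0.0 <= v <= 1.0
        assert 0.0 <= out["beat_rate_a1"] <= 1.0

    def test_random_embedding_attack_is_chance_level(self):
        """On random vectors the distance attack should behave like the
        random-ranking attacker (paired beat rates within 3 SE)."""
        model, truth, catalogue, _ = self._random_setup(n_patients=80, seed=5)
        out = run_attack_trials(model, truth, catalogue, None, n_trials=150,
                                n_targets=6, min_count=0, k=5, seed=7,
                                count_mode="patients", include_random=True)
        diff = out["beat_rate_a5"] - out["random_beat_rate_a5"]
        se = np.sqrt(2 * 0.25 / 150)  # conservative paired-binomial bound
        assert abs(diff) <= 3 * se
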