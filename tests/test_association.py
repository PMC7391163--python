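"""In/out distance statistics: means, Wilcoxon, Holm, permutation p-values."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from embaudit import (
    DiagnosisEntry,
    InOutResult,
    OOVError,
    PatientRecord,
    holm_bonferroni,
    in_out_distances,
    patient_empirical_pvalue,
    wilcoxon_signed_rank,
)
from embaudit.association import compute_in_out, frequency_threshold_curve
from embaudit.embeddings import vec_distance
from conftest import make_model


def _setup(n_diag=5, billed=("d0", "d1"), seed=0, dim=4):
    rng = np.random.default_rng(seed)
    vocab = {"first": rng.normal(size=dim), "last": rng.normal(size=dim)}
    catalogue = []
    for i in range(n_diag):
        tok = f"diag{i}"
        vocab[tok] = rng.normal(size=dim)
        catalogue.append(DiagnosisEntry(f"d{i}", (tok,)))
    model = make_model(vocab)
    record = PatientRecord("p0", ("first", "last"), frozenset(billed), retained=True)
    return model, record, catalogue


class TestInOut:
    def test_singleton_groups(self):
        model, record, catalogue = _setup(n_diag=2, billed=("d0",))
        res = in_out_distances(model, record, catalogue, "cityblock")
        name_vec = (model.vector("first") + model.vector("last")) / 2
        assert res.in_group == pytest.approx(
            vec_distance(name_vec, model.vector("diag0"), "cityblock")
        )
        assert res.out_group == pytest.approx(
            vec_distance(name_vec, model.vector("diag1"), "cityblock")
        )
        assert res.n_in == res.n_out == 1

    def test_matches_brute_force_means(self):
        model, record, catalogue = _setup(n_diag=5, billed=("d1", "d3"), seed=3)
        res = in_out_distances(model, record, catalogue, "cosine")
        name_vec = (model.vector("first") + model.vector("last")) / 2
        d = {e.diagnosis_id: vec_distance(name_vec, model.vector(e.description_tokens[0]), "cosine")
             for e in catalogue}
        assert res.in_group == pytest.approx((d["d1"] + d["d3"]) / 2)
        assert res.out_group == pytest.approx((d["d0"] + d["d2"] + d["d4"]) / 3)
        assert res.diff == res.in_group - res.out_group
        assert res.n_in + res.n_out == len(catalogue)

    def test_identical_diagnosis_vectors_give_zero_diff(self):
        vocab = {"first": [1.0, 2.0], "last": [3.0, 0.0], "same": [5.0, 5.0]}
        model = make_model(vocab)
        catalogue = [DiagnosisEntry(f"d{i}", ("same",)) for i in range(4)]
        record = PatientRecord("p0", ("first", "last"), frozenset({"d0"}), retained=True)
        res = in_out_distances(model, record, catalogue, "cityblock")
        assert res.diff == pytest.approx(0.0)

    def test_oov_name_raises_and_batch_skips(self):
        model, record, catalogue = _setup()
        ghost = PatientRecord("p1", ("first", "ghost"), frozenset({"d0"}), retained=True)
        with pytest.raises(OOVError):
            in_out_distances(model, ghost, catalogue)
        results, excluded = compute_in_out(model, [record, ghost], catalogue)
        assert [r.patient_id for r in results] == ["p0"]
        assert excluded["oov_name"] == 1

    def test_oov_diagnoses_dropped_from_both_groups(self):
        model, record, catalogue = _setup(n_diag=4, billed=("d0", "d2"))
        catalogue = catalogue + [DiagnosisEntry("d9", ("missingtok",))]
        res = in_out_distances(model, record, catalogue, "cityblock")
        assert res.n_in + res.n_out == 4

    def test_degenerate_partition_raises(self):
        model, record, catalogue = _setup(n_diag=2, billed=("d0", "d1"))
        with pytest.raises(ValueError, match="degenerate"):
            in_out_distances(model, record, catalogue)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            InOutResult("p", 1.0, 2.0, 0.5, 1, 1)  # diff wrong
        with pytest.raises(ValueError):
            InOutResult("p", 1.0, 2.0, -1.0, 0, 1)  # empty group


class TestThresholdCurve:
    def _results(self, diffs):
        return [InOutResult(f"p{i}", d, 0.0, d, 1, 1) for i, d in enumerate(diffs)]

    def _records(self, names):
        return [
            PatientRecord(f"p{i}", nm, frozenset({"d0"}), retained=True)
            for i, nm in enumerate(names)
        ]

    def test_mixed_frequency_name_included_below_200(self):
        # component counts 201 and 2 average to 101.5, below 200 but not 100
        results = self._results([4.0])
        records = self._records([("james", "qwerty")])
        counts = {"james": 201, "qwerty": 2}
        curve = frequency_threshold_curve(results, records, counts, [100, 200])
        assert 200.0 in curve and 100.0 not in curve
        assert curve[200.0] == pytest.approx(4.0)

    def test_mean_of_bucket(self):
        results = self._results([4.0, 6.0])
        records = self._records([("a", "b"), ("c", "d")])
        counts = {"a": 1, "b": 1, "c": 2, "d": 2}
        curve = frequency_threshold_curve(results, records, counts, [10])
        assert curve[10.0] == pytest.approx(5.0)

    def test_empty_bucket_absent(self):
        results = self._results([1.0])
        records = self._records([("a", "b")])
        curve = frequency_threshold_curve(results, records, {"a": 50, "b": 50}, [10])
        assert curve == {}


def exact_wilcoxon_p(diffs):
    """Sign-enumeration oracle for the two-sided signed-rank test."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = ranks[diffs > 0].sum()
    mean = n * (n + 1) / 4
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append((ranks * np.array(signs)).sum())
    stats = np.asarray(stats)
    p = np.mean(np.abs(stats - mean) >= abs(w_obs - mean) - 1e-12)
    return p


class TestWilcoxon:
    def test_three_positive_differences_exact(self):
        out = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert out.p_value == pytest.approx(0.25)
        assert out.p_value == pytest.approx(exact_wilcoxon_p([1, 2, 3]))

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        out = wilcoxon_signed_rank(x, y)
        assert out.p_value == pytest.approx(exact_wilcoxon_p(x - y), abs=1e-12)

    def test_large_n_matches_normal_approximation_formula(self):
        """Hand-coded tie-corrected normal approximation, n=50."""
        rng = np.random.default_rng(8)
        x = rng.normal(loc=0.3, size=50)
        y = rng.normal(size=50)
        d = x - y
        absd = np.abs(d)
        ranks = np.argsort(np.argsort(absd)) + 1.0
        w_plus = ranks[d > 0].sum()
        n = len(d)
        mean = n * (n + 1) / 4
        var = n * (n + 1) * (2 * n + 1) / 24
        from scipy.stats import norm
        z = (w_plus - mean) / np.sqrt(var)
        p_ref = 2 * norm.sf(abs(z))
        out = wilcoxon_signed_rank(x, y)
        assert out.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_zero_differences_dropped(self):
        out = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 9.0],
                                   [1.0, 1.0, 1.0, 1.0, 1.0, 9.0])
        assert out.p_value == pytest.approx(exact_wilcoxon_p([0, 1, 2, 3, 4]))

    def test_all_zero_raises(self):
        x = [1.0] * 6
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, x)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [0, 0])


def holm_oracle(p, alpha):
    """Iterative-removal oracle, formulated independently of the step-down
    loop: repeatedly reject the smallest remaining p against alpha / m_rem."""
    p = list(p)
    rejected = [False] * len(p)
    remaining = list(range(len(p)))
    while remaining:
        i = min(remaining, key=lambda j: p[j])
        if p[i] <= alpha / len(remaining):
            rejected[i] = True
            remaining.remove(i)
        else:
            break
    return rejected


class TestHolm:
    def test_single_p_reduces_to_plain_test(self):
        assert holm_bonferroni([0.04], 0.05) == [True]
        assert holm_bonferroni([0.06], 0.05) == [False]

    def test_stepdown_example(self):
        # 0.01 <= 0.05/3 rejects; 0.03 > 0.05/2 stops the procedure
        assert holm_bonferroni([0.01, 0.04, 0.03], 0.05) == [True, False, False]

    def test_all_ones_no_rejections(self):
        assert holm_bonferroni([1.0, 1.0, 1.0], 0.05) == [False] * 3

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8),
           st.floats(0.01, 0.2))
    @settings(max_examples=300, deadline=None)
    def test_nested_between_bonferroni_and_uncorrected(self, p, alpha):
        m = len(p)
        holm = holm_bonferroni(p, alpha)
        bonf = [pi <= alpha / m for pi in p]
        raw = [pi <= alpha for pi in p]
        assert all(h for h, b in zip(holm, bonf) if b)  # superset of Bonferroni
        assert all(r for h, r in zip(holm, raw) if h)  # subset of uncorrected

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    @settings(max_examples=300, deadline=None)
    def test_matches_statsmodels_and_oracle(self, p):
        got = holm_bonferroni(p, 0.05)
        assert got == list(multipletests(p, alpha=0.05, method="holm")[0])
        assert got == holm_oracle(p, 0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            holm_bonferroni([1.5], 0.05)
        with pytest.raises(ValueError):
            holm_bonferroni([0.5], 0.0)


class TestEmpiricalPvalue:
    def test_minimum_attainable_p(self):
        model, record, catalogue = _setup(n_diag=6, billed=("d0",), seed=2)
        p = patient_empirical_pvalue(model, record, catalogue, n_perm=50, seed=0)
        assert p >= 1 / 51

    def test_sampled_close_to_exhaustive(self):
        """Exhaustive oracle over all C(6,2)=15 pseudo in-groups."""
        model, record, catalogue = _setup(n_diag=6, billed=("d0", "d3"), seed=4)
        name_vec = (model.vector("first") + model.vector("last")) / 2
        d = np.array([
            vec_distance(name_vec, model.vector(e.description_tokens[0]), "cityblock")
            for e in catalogue
        ])
        obs = abs(d[[0, 3]].mean() - np.delete(d, [0, 3]).mean())
        perms = []
        for combo in itertools.combinations(range(6), 2):
            rest = [i for i in range(6) if i not in combo]
            perms.append(abs(d[list(combo)].mean() - d[rest].mean()))
        exact = np.mean([x >= obs - 1e-12 for x in perms])
        sampled = patient_empirical_pvalue(
            model, record, catalogue, "cityblock", n_perm=2000, seed=9
        )
        assert sampled == pytest.approx(exact, abs=0.05)

    def test_population_scheme_requires_pool(self):
        model, record, catalogue = _setup()
        with pytest.raises(ValueError):
            patient_empirical_pvalue(model, record, catalogue, scheme="population")
        p = patient_empirical_pvalue(
            model, record, catalogue, scheme="population",
            pool=np.linspace(0.1, 3.0, 40), n_perm=200, seed=1,
        )
        assert 0 < p <= 1

    def test_deterministic_under_seed(self):
        model, record, catalogue = _setup(seed=6)
        a = patient_empirical_pvalue(model, record, catalogue, n_perm=100, seed=5)
        b = patient_empirical_pvalue(model, record, catalogue, n_perm=100, seed=5)
        assert a == b
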