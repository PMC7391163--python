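"""Frozen leakage-audit study conditions and their runners.

This module pins one set of study conditions — an 800-patient associative
corpus whose de-identifier leaves roughly 60 full names in the text, and a
200-patient null corpus with no name-diagnosis association — and runs the
three audit experiments against them.  The same runners back both the test
suite and ``scripts/acceptance.py``, so every reported number is recomputed
from scratch.

Problem sizes are deliberately desk-scale (tens of thousands of tokens, one
CPU, minutes): large enough for the leakage channels to be measurable,
small enough to re-run routinely.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .association import (
    compute_in_out,
    patient_empirical_pvalue,
    wilcoxon_signed_rank,
)
from .attack import run_attack_trials
from .corpus import Corpus, DiagnosisEntry, GeneratorConfig, GroundTruth, PatientRecord, deidentify, generate_corpus
from .embeddings import EmbeddingModel, GloVe, Word2Vec
from .reconstruction import evaluate_reconstruction, rank_candidate_pairs

__all__ = [
    "associative_config",
    "null_config",
    "make_study_corpus",
    "train_study_model",
    "reconstruction_study",
    "association_study",
    "null_population_study",
    "null_patient_level_study",
    "attack_study",
]

#: number of full-name mentions the de-identifier should leave behind
TARGET_SURVIVORS = 60
STUDY_DIM = 50
STUDY_WINDOWS = (1, 3, 5, 9)


def associative_config(seed: int) -> GeneratorConfig:
    """800 patients, strong note-level name-diagnosis association."""
    return GeneratorConfig(
        n_patients=800,
        name_pool_first=120,
        name_pool_last=160,
        n_diagnoses=40,
        notes_per_patient_range=(2, 4),
        note_len_range=(10, 25),
        background_vocab_size=1200,
        association_prob=0.9,
        seed=seed,
    )


def null_config(seed: int) -> GeneratorConfig:
    """200 patients, diagnoses mentioned independently of billing."""
    return GeneratorConfig(
        n_patients=200,
        name_pool_first=60,
        name_pool_last=90,
        n_diagnoses=40,
        notes_per_patient_range=(2, 4),
        note_len_range=(10, 25),
        background_vocab_size=600,
        association_prob=0.0,
        seed=seed,
    )


def make_study_corpus(
    seed: int, associative: bool = True, removal: bool = True
) -> tuple[Corpus, list[PatientRecord], list[DiagnosisEntry], GroundTruth]:
    """Generate, then de-identify, one study corpus.

    For the associative corpus the removal fraction is set so that exactly
    ``TARGET_SURVIVORS`` full-name mentions survive; the null corpus keeps
    all names (removal 0) so that every patient is evaluable in the
    calibration checks.
    """
    cfg = associative_config(seed) if associative else null_config(seed)
    corpus, records, catalogue = generate_corpus(cfg)
    if removal and associative:
        fraction = 1.0 - TARGET_SURVIVORS / len(corpus.notes)
    else:
        fraction = 0.0
    deid, truth = deidentify(corpus, records, "remove", fraction, seed=seed + 1)
    return deid, records, catalogue, truth


def train_study_model(
    corpus: Corpus, algorithm: str, window: int, seed: int
) -> EmbeddingModel:
    if algorithm == "glove":
        est = GloVe(dim=STUDY_DIM, window=window, seed=seed)
    else:
        est = Word2Vec(algorithm=algorithm, dim=STUDY_DIM, window=window, seed=seed)
    return est.fit(corpus).to_model()


def reconstruction_study(
    models: dict[tuple[str, int], EmbeddingModel],
    truth: GroundTruth,
    k: int = TARGET_SURVIVORS,
    metric: str = "cosine",
) -> dict:
    """Name reconstruction at k for each (algorithm, window) model.

    Reports, per model, the true-pair count among the top-k ranked pairs,
    the chance level K / C(T, 2) for K true names over T surviving tokens,
    and a one-sided binomial p-value against chance.
    """
    K = len(truth.retained_full_names)
    T = len(truth.retained_name_tokens)
    chance = K / (T * (T - 1) / 2)
    out: dict = {"k": k, "n_names": K, "n_tokens": T, "chance": chance, "models": {}}
    for (algo, window), model in models.items():
        pairs = rank_candidate_pairs(model, truth.retained_name_tokens, metric)
        n_true, fraction = evaluate_reconstruction(pairs, truth, k)
        out["models"][(algo, window)] = {
            "n_true": n_true,
            "fraction": fraction,
            "binom_p": float(stats.binom.sf(n_true - 1, k, chance)),
        }
    return out


def association_study(
    model: EmbeddingModel,
    records: list[PatientRecord],
    catalogue: list[DiagnosisEntry],
    metric: str = "cityblock",
    retained_only: bool = True,
) -> dict:
    """Population-level in/out contrast for one model."""
    results, excluded = compute_in_out(model, records, catalogue, metric, retained_only)
    outcome = wilcoxon_signed_rank(
        [r.in_group for r in results], [r.out_group for r in results]
    )
    return {
        "n_patients": len(results),
        "mean_diff": float(np.mean([r.diff for r in results])),
        "statistic": outcome.statistic,
        "p_value": outcome.p_value,
        "excluded": excluded,
        "results": results,
    }


def null_population_study(
    n_seeds: int = 20, base_seed: int = 1000, matched_size: int = TARGET_SURVIVORS
) -> dict:
    """Wilcoxon p across independently generated null corpora.

    Each seed generates a fresh null corpus, trains a Skipgram window-5
    model, and tests the population in/out contrast twice: over all
    patients, and over a random subsample of ``matched_size`` patients
    (the cohort size the associative study operates at).  The full-sample
    test has more power against the imbalanced-group skew artifact (see
    the methods note), so its rejection rate under the null exceeds the
    matched-sample one.
    """
    p_values, p_matched = [], []
    for i in range(n_seeds):
        seed = base_seed + 10 * i
        deid, records, catalogue, _truth = make_study_corpus(seed, associative=False)
        model = train_study_model(deid, "skipgram", 5, seed=seed + 2)
        res = association_study(model, records, catalogue, retained_only=False)
        p_values.append(res["p_value"])
        rng = np.random.default_rng(seed + 5)
        sub = rng.choice(len(res["results"]), size=min(matched_size, len(res["results"])),
                         replace=False)
        sub_results = [res["results"][j] for j in sub]
        outcome = wilcoxon_signed_rank(
            [r.in_group for r in sub_results], [r.out_group for r in sub_results]
        )
        p_matched.append(outcome.p_value)
    return {
        "p_values": p_values,
        "n_above_05": int(sum(p > 0.05 for p in p_values)),
        "p_values_matched": p_matched,
        "n_above_05_matched": int(sum(p > 0.05 for p in p_matched)),
        "matched_size": matched_size,
        "n_seeds": n_seeds,
    }


def null_patient_level_study(
    seed: int = 1000, n_perm: int = 200, alpha: float = 0.05
) -> dict:
    """Per-patient empirical p-values on one null corpus.

    Under no association the p-values should be approximately uniform, so
    the fraction below alpha estimates the test's false-positive rate.
    """
    deid, records, catalogue, _truth = make_study_corpus(seed, associative=False)
    model = train_study_model(deid, "skipgram", 5, seed=seed + 2)
    p_values = [
        patient_empirical_pvalue(
            model, rec, catalogue, "cityblock", n_perm=n_perm, seed=seed + 7 + i
        )
        for i, rec in enumerate(records)
    ]
    return {
        "p_values": p_values,
        "fraction_below_alpha": float(np.mean([p < alpha for p in p_values])),
        "n_patients": len(p_values),
        "n_perm": n_perm,
    }


def attack_study(
    model: EmbeddingModel,
    truth: GroundTruth,
    catalogue: list[DiagnosisEntry],
    corpus: Corpus,
    n_trials: int = 200,
    n_targets: int = 10,
    seed: int = 0,
    direction: str = "farthest",
) -> dict:
    """Randomized-target attack trials with a random-ranking null attacker.

    The paired sign test compares the attack's A@5 with the random ranker's
    A@5 trial by trial.
    """
    summary = run_attack_trials(
        model,
        truth,
        catalogue,
        corpus,
        n_trials=n_trials,
        n_targets=n_targets,
        min_count=10,
        k=5,
        metric="cityblock",
        seed=seed,
        direction=direction,
        include_random=True,
    )
    deltas = [t.a_at_5 - t.random_a5 for t in summary["trials"]]
    pos = sum(1 for d in deltas if d > 0)
    neg = sum(1 for d in deltas if d < 0)
    sign_p = (
        float(stats.binomtest(pos, pos + neg, alternative="greater").pvalue)
        if pos + neg > 0
        else 1.0
    )
    summary = {k: v for k, v in summary.items() if k != "trials"}
    summary.update({"sign_pos": pos, "sign_neg": neg, "sign_p": sign_p})
    return summary
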