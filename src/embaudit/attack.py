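"""Attack simulation: assigning target diagnoses to reconstructed names.

The simulated adversary holds only the released embedding model and a list
of surviving full names.  For a chosen set of target diagnoses, each name is
assigned the *k* targets **farthest** from its name vector (exploiting the
observation that billed diagnoses sit farther from the name than non-billed
ones); Top-1 and Top-5 accuracies are scored against ground truth and
compared with a majority baseline that always predicts the targets billed to
the most patients.  Randomized trials over fresh target sets measure how
often the attack strictly beats the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus, DiagnosisEntry, GroundTruth
from .embeddings import EmbeddingModel, distances_from, phrase_vector

__all__ = [
    "AttackTrial",
    "PRESET_TARGETS",
    "phrase_occurrences",
    "select_target_diagnoses",
    "predict_diagnoses",
    "evaluation_set",
    "score_attack",
    "majority_baseline",
    "run_attack_trials",
]

logger = logging.getLogger(__name__)

#: demonstration target list for free-text corpora (descriptions, not ids)
PRESET_TARGETS: tuple[tuple[str, ...], ...] = (
    ("constipation",),
    ("diarrhea",),
    ("vaginitis",),
    ("sexual", "dysfunction"),
    ("urinary", "infection"),
    ("herpes", "genitalis"),
    ("dementia",),
    ("anorexia",),
    ("alcoholism",),
    ("threatened", "abortion"),
    ("aids",),
)


@dataclass
class AttackTrial:
    target_ids: tuple[str, ...]
    per_name_predictions: dict[str, list[str]]
    a_at_1: float
    a_at_5: float
    baseline_a1: float
    baseline_a5: float
    random_a1: float | None = None
    random_a5: float | None = None

    def __post_init__(self) -> None:
        if self.a_at_1 > self.a_at_5 + 1e-12:
            raise ValueError("A@1 cannot exceed A@5")


def phrase_occurrences(corpus: Corpus, phrase: Sequence[str]) -> int:
    """Occurrences of the contiguous token sequence across all notes."""
    phrase = list(phrase)
    m = len(phrase)
    count = 0
    for _pid, toks in corpus.notes:
        for i in range(len(toks) - m + 1):
            if toks[i : i + m] == phrase:
                count += 1
    return count


def select_target_diagnoses(
    catalogue: Sequence[DiagnosisEntry],
    corpus: Corpus | None,
    n: int,
    min_count: int = 10,
    seed: int = 0,
    count_mode: str = "phrase",
    patient_diagnoses: Mapping[str, frozenset[str]] | None = None,
    precomputed_counts: Mapping[str, int] | None = None,
) -> list[str]:
    """Uniform sample (without replacement) of eligible target diagnoses.

    Eligibility: the full description phrase occurs at least ``min_count``
    times in the corpus (``count_mode="phrase"``), or at least ``min_count``
    patients are billed the code (``count_mode="patients"``).
    """
    if precomputed_counts is not None:
        counts = {e.diagnosis_id: precomputed_counts[e.diagnosis_id] for e in catalogue}
    elif count_mode == "phrase":
        if corpus is None:
            raise ValueError("phrase counting requires the corpus")
        counts = {
            e.diagnosis_id: phrase_occurrences(corpus, e.description_tokens)
            for e in catalogue
        }
    elif count_mode == "patients":
        if patient_diagnoses is None:
            raise ValueError("patient counting requires the patient->diagnoses map")
        counts = {
            e.diagnosis_id: sum(
                1 for ids in patient_diagnoses.values() if e.diagnosis_id in ids
            )
            for e in catalogue
        }
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")

    eligible = sorted(did for did, c in counts.items() if c >= min_count)
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} diagnoses meet min_count={min_count}, need {n}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(pick.tolist())]


def predict_diagnoses(
    model: EmbeddingModel,
    name_tokens: Sequence[str],
    targets: Sequence[str],
    catalogue: Sequence[DiagnosisEntry] | Mapping[str, Sequence[str]],
    k: int = 5,
    metric: str = "cityblock",
    direction: str = "farthest",
) -> list[str]:
    """The ``k`` targets farthest from (or nearest to) the name vector.

    Ranked farthest-first by default; ties broken lexicographically by
    diagnosis id for determinism.
    """
    if k > len(targets):
        raise ValueError(f"k={k} exceeds {len(targets)} targets")
    if direction not in ("farthest", "nearest"):
        raise ValueError(f"direction must be farthest or nearest, got {direction!r}")
    desc = (
        {e.diagnosis_id: e.description_tokens for e in catalogue}
        if not isinstance(catalogue, Mapping)
        else catalogue
    )
    name_vec = phrase_vector(model, name_tokens)
    tids = sorted(targets)
    vecs = np.asarray([phrase_vector(model, desc[t]) for t in tids])
    d = distances_from(name_vec, vecs, metric)
    keyed = sorted(zip(d, tids), key=lambda x: (-x[0], x[1]) if direction == "farthest" else (x[0], x[1]))
    return [t for _d, t in keyed[:k]]


def evaluation_set(truth: GroundTruth, targets: Sequence[str]) -> list[str]:
    """Retained patients holding at least one target diagnosis."""
    tset = set(targets)
    return sorted(
        pid
        for pid in truth.retained_patient_ids
        if truth.patient_diagnoses[pid] & tset
    )


def _hits(
    predictions: Mapping[str, Sequence[str]],
    truth: GroundTruth,
    targets: Sequence[str],
    n: int,
) -> float:
    tset = set(targets)
    if not predictions:
        raise ValueError("empty evaluation set: no names to score")
    hit = sum(
        1
        for pid, ranked in predictions.items()
        if set(ranked[:n]) & (truth.patient_diagnoses[pid] & tset)
    )
    return hit / len(predictions)


def score_attack(
    predictions: Mapping[str, Sequence[str]],
    truth: GroundTruth,
    targets: Sequence[str],
    n: int,
) -> float:
    """Top-n accuracy: fraction of evaluated names whose billed target
    diagnosis appears among the first ``n`` predictions."""
    return _hits(predictions, truth, targets, n)


def majority_baseline(
    targets: Sequence[str],
    truth: GroundTruth,
    eval_pids: Sequence[str],
    n: int,
) -> float:
    """Predict for every name the ``n`` targets billed to the most patients
    (ties lexicographic); scored identically to the attack."""
    if not eval_pids:
        raise ValueError("empty evaluation set: no names to score")
    freq = {
        t: sum(1 for ids in truth.patient_diagnoses.values() if t in ids)
        for t in targets
    }
    ranked = [t for t in sorted(targets, key=lambda t: (-freq[t], t))]
    predictions = {pid: ranked for pid in eval_pids}
    return _hits(predictions, truth, targets, n)


def run_attack_trials(
    model: EmbeddingModel,
    truth: GroundTruth,
    catalogue: Sequence[DiagnosisEntry],
    corpus: Corpus | None = None,
    n_trials: int = 1000,
    n_targets: int = 30,
    min_count: int = 10,
    k: int = 5,
    metric: str = "cityblock",
    seed: int = 0,
    direction: str = "farthest",
    include_random: bool = False,
    count_mode: str = "phrase",
) -> dict:
    """Repeat the attack over fresh random target sets; summarize beat rates.

    ``beat`` means the attack's accuracy strictly exceeds the majority
    baseline's.  Trials whose evaluation set is empty are resampled (the
    count is reported).  With ``include_random=True`` a random-ranking
    attacker is scored on the same trials for null comparison.
    """
    rng = np.random.default_rng(seed)
    desc = {e.diagnosis_id: e.description_tokens for e in catalogue}
    if count_mode == "phrase":
        counts = {
            e.diagnosis_id: phrase_occurrences(corpus, e.description_tokens)
            for e in catalogue
        }
    else:
        counts = {
            e.diagnosis_id: sum(
                1 for ids in truth.patient_diagnoses.values() if e.diagnosis_id in ids
            )
            for e in catalogue
        }

    # names scorable at all: retained patients whose name resolves in vocab
    names = {}
    for pid in sorted(truth.retained_patient_ids):
        nm = truth.patient_names[pid]
        if all(t in model for t in nm):
            names[pid] = nm
        else:
            logger.info("skipping retained patient %s: name token out of vocabulary", pid)

    trials: list[AttackTrial] = []
    resampled = 0
    attempts = 0
    max_attempts = 50 * n_trials + 100
    while len(trials) < n_trials and attempts < max_attempts:
        attempts += 1
        trial_seed = int(rng.integers(0, 2**31 - 1))
        targets = select_target_diagnoses(
            catalogue, corpus, n_targets, min_count=min_count, seed=trial_seed,
            count_mode=count_mode, patient_diagnoses=truth.patient_diagnoses,
            precomputed_counts=counts,
        )
        eval_pids = [pid for pid in evaluation_set(truth, targets) if pid in names]
        if not eval_pids:
            resampled += 1
            continue
        preds = {
            pid: predict_diagnoses(model, names[pid], targets, desc, k=k,
                                   metric=metric, direction=direction)
            for pid in eval_pids
        }
        a1 = score_attack(preds, truth, targets, 1)
        a5 = score_attack(preds, truth, targets, min(5, k))
        b1 = majority_baseline(targets, truth, eval_pids, 1)
        b5 = majority_baseline(targets, truth, eval_pids, min(5, k))
        trial = AttackTrial(tuple(targets), preds, a1, a5, b1, b5)
        if include_random:
            rpreds = {}
            for pid in eval_pids:
                perm = rng.permutation(len(targets))
                rpreds[pid] = [targets[i] for i in perm[:k]]
            trial.random_a1 = score_attack(rpreds, truth, targets, 1)
            trial.random_a5 = score_attack(rpreds, truth, targets, min(5, k))
        trials.append(trial)
    if len(trials) < n_trials:
        raise ValueError(
            f"could not assemble {n_trials} non-empty trials "
            f"({resampled} resampled, {attempts} attempts)"
        )

    summary = {
        "n_trials": n_trials,
        "resampled": resampled,
        "beat_rate_a1": float(np.mean([t.a_at_1 > t.baseline_a1 for t in trials])),
        "beat_rate_a5": float(np.mean([t.a_at_5 > t.baseline_a5 for t in trials])),
        "mean_a1": float(np.mean([t.a_at_1 for t in trials])),
        "mean_a5": float(np.mean([t.a_at_5 for t in trials])),
        "mean_baseline_a1": float(np.mean([t.baseline_a1 for t in trials])),
        "mean_baseline_a5": float(np.mean([t.baseline_a5 for t in trials])),
        "trials": trials,
    }
    if include_random:
        summary["random_beat_rate_a1"] = float(
            np.mean([t.random_a1 > t.baseline_a1 for t in trials])
        )
        summary["random_beat_rate_a5"] = float(
            np.mean([t.random_a5 > t.baseline_a5 for t in trials])
        )
        summary["mean_random_a1"] = float(np.mean([t.random_a1 for t in trials]))
        summary["mean_random_a5"] = float(np.mean([t.random_a5 for t in trials]))
    return summary
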