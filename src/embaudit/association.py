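"""In-group / out-group diagnosis distances and their statistical tests.

For each patient, the *name vector* (mean of the name-token vectors) is
compared against every diagnosis description vector in the catalogue.  The
mean distance to the patient's own billed diagnoses is the **in-group**, the
mean distance to all other diagnoses the **out-group**; a systematic
difference between them means the embedding betrays who was billed what.

Population level: a two-sided Wilcoxon signed-rank test on the paired
(in, out) values across patients, with Holm-Bonferroni correction across
the swept model configurations.  Patient level: an empirical permutation
p-value per patient — pseudo in-groups of the same size are resampled from
the patient's own distance multiset (or, optionally, from the population
distance pool) and the observed |in - out| is ranked among them with +1
smoothing, so the smallest attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus import DiagnosisEntry, PatientRecord
from .embeddings import EmbeddingModel, OOVError, distances_from, phrase_vector

__all__ = [
    "InOutResult",
    "TestOutcome",
    "in_out_distances",
    "compute_in_out",
    "frequency_threshold_curve",
    "wilcoxon_signed_rank",
    "holm_bonferroni",
    "patient_empirical_pvalue",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InOutResult:
    patient_id: str
    in_group: float
    out_group: float
    diff: float
    n_in: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_in < 1 or self.n_out < 1:
            raise ValueError("both groups must be nonempty")
        if self.diff != self.in_group - self.out_group:
            raise ValueError("diff must equal in_group - out_group exactly")


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    p_value: float
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _usable_distances(
    model: EmbeddingModel,
    record: PatientRecord,
    catalogue: Sequence[DiagnosisEntry],
    metric: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Distances from the name vector to each usable catalogue entry.

    Returns ``(distances, is_in_group)``; raises :class:`OOVError` if a name
    token is missing.  Diagnoses with out-of-vocabulary description tokens
    are dropped from both groups.
    """
    name_vec = phrase_vector(model, record.name_tokens)
    vecs, is_in = [], []
    for entry in catalogue:
        try:
            vecs.append(phrase_vector(model, entry.description_tokens))
        except OOVError:
            logger.debug("dropping diagnosis %s (OOV description)", entry.diagnosis_id)
            continue
        is_in.append(entry.diagnosis_id in record.diagnosis_ids)
    if not vecs:
        return np.empty(0), np.empty(0, dtype=bool)
    d = distances_from(name_vec, np.asarray(vecs), metric)
    return d, np.asarray(is_in, dtype=bool)


def in_out_distances(
    model: EmbeddingModel,
    record: PatientRecord,
    catalogue: Sequence[DiagnosisEntry],
    metric: str = "cityblock",
) -> InOutResult:
    """Unweighted mean distances to billed vs non-billed diagnoses."""
    d, is_in = _usable_distances(model, record, catalogue, metric)
    n_in, n_out = int(is_in.sum()), int((~is_in).sum()) if len(d) else 0
    if len(d) == 0 or n_in == 0 or n_out == 0:
        raise ValueError(
            f"patient {record.patient_id}: in/out partition degenerate "
            f"(n_in={n_in}, n_out={n_out})"
        )
    in_group = float(d[is_in].mean())
    out_group = float(d[~is_in].mean())
    return InOutResult(record.patient_id, in_group, out_group,
                       in_group - out_group, n_in, n_out)


def compute_in_out(
    model: EmbeddingModel,
    records: Sequence[PatientRecord],
    catalogue: Sequence[DiagnosisEntry],
    metric: str = "cityblock",
    retained_only: bool = True,
) -> tuple[list[InOutResult], dict[str, int]]:
    """Batch in/out computation; patients that cannot be scored are skipped.

    Returns the results plus exclusion counts (OOV names, degenerate
    partitions, not-retained patients).
    """
    results: list[InOutResult] = []
    excluded = {"oov_name": 0, "degenerate": 0, "not_retained": 0}
    for r in records:
        if retained_only and not r.retained:
            excluded["not_retained"] += 1
            continue
        try:
            results.append(in_out_distances(model, r, catalogue, metric))
        except OOVError as e:
            logger.info("skipping patient %s: %s", r.patient_id, e)
            excluded["oov_name"] += 1
        except ValueError:
            excluded["degenerate"] += 1
    return results, excluded


def frequency_threshold_curve(
    results: Sequence[InOutResult],
    records: Sequence[PatientRecord],
    counts: Mapping[str, int],
    thresholds: Sequence[float],
) -> dict[float, float]:
    """Mean in-out difference over names rarer than each threshold.

    A name is below threshold ``t`` if the *average* corpus count of its
    component tokens is below ``t`` (tokens counted 201 and 2 times average
    to 101.5, hence fall below a threshold of 200).  Thresholds whose bucket
    holds no patients are absent from the result, not zero.
    """
    name_by_pid = {r.patient_id: r.name_tokens for r in records}
    mean_counts = {
        res.patient_id: float(
            np.mean([counts.get(t, 0) for t in name_by_pid[res.patient_id]])
        )
        for res in results
    }
    curve: dict[float, float] = {}
    for t in thresholds:
        diffs = [res.diff for res in results if mean_counts[res.patient_id] < t]
        if diffs:
            curve[float(t)] = float(np.mean(diffs))
    return curve


def wilcoxon_signed_rank(
    in_values: Sequence[float], out_values: Sequence[float]
) -> TestOutcome:
    """Two-sided paired Wilcoxon signed-rank test on (in, out) pairs.

    Zero differences are discarded before ranking (``wilcox`` convention).
    The exact null distribution is used for n <= 25 without tied
    |differences|; otherwise the normal approximation with tie correction.
    All differences zero is degenerate and raises.
    """
    x = np.asarray(in_values, dtype=np.float64)
    y = np.asarray(out_values, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("in_values and out_values must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    d = d[d != 0.0]
    if len(d) == 0:
        raise ValueError("all differences are zero: test undefined")
    absd = np.abs(d)
    no_ties = len(np.unique(absd)) == len(absd)
    method = "exact" if (len(d) <= 25 and no_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False,
                         alternative="two-sided", method=method)
    return TestOutcome(statistic=float(res.statistic), p_value=float(res.pvalue))


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Holm's step-down rejections, returned in input order.

    Sort ascending and reject p_(i) while p_(i) <= alpha / (m - i + 1)
    (1-based i), stopping at the first failure.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):  # i is 0-based
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject.tolist()


def patient_empirical_pvalue(
    model: EmbeddingModel,
    record: PatientRecord,
    catalogue: Sequence[DiagnosisEntry],
    metric: str = "cityblock",
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "within",
    pool: np.ndarray | None = None,
) -> float:
    """Empirical two-sided p-value for one patient's |in - out| difference.

    Each permutation draws a pseudo in-group of size ``n_in`` — from the
    patient's own distance multiset (``scheme="within"``, the default) or
    from a supplied population distance ``pool`` (``scheme="population"``) —
    and recomputes |mean(in) - mean(out)|.  Smoothed rank:
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d, is_in = _usable_distances(model, record, catalogue, metric)
    n_in, n_out = int(is_in.sum()), int(len(d) - is_in.sum())
    if n_in == 0 or n_out == 0:
        raise ValueError(f"patient {record.patient_id} has a degenerate partition")
    observed = abs(d[is_in].mean() - d[~is_in].mean())

    rng = np.random.default_rng(seed)
    if scheme == "within":
        total = d.sum()
        n = len(d)
        # vectorized subset draws: argsort of uniforms = random permutations
        idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_in]
        in_sums = d[idx].sum(axis=1)
        perm = np.abs(in_sums / n_in - (total - in_sums) / n_out)
    elif scheme == "population":
        if pool is None:
            raise ValueError("population scheme requires a distance pool")
        pool = np.asarray(pool, dtype=np.float64)
        ins = pool[rng.integers(0, len(pool), size=(n_perm, n_in))].mean(axis=1)
        outs = pool[rng.integers(0, len(pool), size=(n_perm, n_out))].mean(axis=1)
        perm = np.abs(ins - outs)
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return float((1 + int((perm >= observed).sum())) / (1 + n_perm))
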