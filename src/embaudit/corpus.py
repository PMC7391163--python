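"""Synthetic clinical-note corpora with planted names and diagnoses.

Real consultation-note corpora that link patient names to billing diagnoses
are private and cannot be shipped, so every downstream stage of the audit
(embedding training, name reconstruction, diagnosis association, attack
simulation) is exercised against corpora generated here.  A generated corpus
emulates the features the attacks exploit:

* semistructured notes opening with a ``name <first> <last>`` header;
* two-token patient names drawn from skewed (Zipf-like) first/last pools, so
  name tokens are shared across patients the way common surnames are;
* a catalogue of diagnoses with 1-3 token descriptions (``colon screening``)
  that co-occur with the notes of patients billed those codes;
* background clinical filler drawn from a unigram distribution; and
* an imperfect de-identifier that deletes (or tags, or replaces) a configured
  fraction of full-name mentions, leaving the remainder in the text.

Ground truth (which full names survived, who is billed what) is emitted next
to the corpus so that attack performance can be scored exactly.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "GeneratorConfig",
    "PatientRecord",
    "DiagnosisEntry",
    "Corpus",
    "GroundTruth",
    "normalize_text",
    "generate_corpus",
    "deidentify",
    "write_corpus",
    "read_corpus",
]

#: literal token that opens every note header, as in ``name john smith``
HEADER_TOKEN = "name"
#: token substituted for a detected name in ``tag`` mode
TAG_TOKEN = "xxnamexx"

_NON_ALPHA = re.compile(r"[^a-z\s]")


def normalize_text(raw: str) -> list[str]:
    """Lowercase, delete punctuation and digits, split on whitespace.

    No lemmatization or any further processing is applied; an empty input
    yields an empty token list.
    """
    return _NON_ALPHA.sub("", raw.lower()).split()


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    ``association_prob`` is the probability that a note mentions one of its
    patient's own billed diagnoses; otherwise a random catalogue diagnosis
    (drawn from the billing-frequency distribution) is mentioned instead, so
    that at ``association_prob=0`` the diagnosis tokens are present but
    statistically independent of the names (the null corpus used for
    calibration checks).  ``diag_freq_exponent`` is the Zipf exponent of the
    billing-code popularity distribution: real billing frequencies are
    heavy-tailed (a screening code is billed orders of magnitude more often
    than a rare condition), and that skew is what differentiates common from
    rare diagnoses in the embedding geometry.
    """

    n_patients: int = 200
    name_pool_first: int = 80
    name_pool_last: int = 120
    name_freq_exponent: float = 1.0
    n_diagnoses: int = 40
    diag_freq_exponent: float = 0.0
    desc_len_range: tuple[int, int] = (1, 3)
    diagnoses_per_patient_range: tuple[int, int] = (1, 3)
    notes_per_patient_range: tuple[int, int] = (2, 4)
    note_len_range: tuple[int, int] = (10, 25)
    background_vocab_size: int = 1200
    association_prob: float = 0.9
    removal_fraction: float = 0.99
    deid_mode: str = "remove"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_patients",
            "name_pool_first",
            "name_pool_last",
            "n_diagnoses",
            "background_vocab_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        lo, hi = self.desc_len_range
        if not (1 <= lo <= hi <= 3):
            raise ValueError(f"desc_len_range must lie within [1, 3], got {self.desc_len_range}")
        for name in ("diagnoses_per_patient_range", "notes_per_patient_range", "note_len_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a nonempty positive range, got {(lo, hi)}")
        if not 0.0 <= self.association_prob <= 1.0:
            raise ValueError("association_prob must lie in [0, 1]")
        if not 0.0 <= self.removal_fraction <= 1.0:
            raise ValueError("removal_fraction must lie in [0, 1]")
        if self.deid_mode not in ("remove", "tag", "replace"):
            raise ValueError(f"deid_mode must be remove/tag/replace, got {self.deid_mode!r}")
        if self.name_pool_first * self.name_pool_last < self.n_patients:
            raise ValueError(
                "name pools cannot supply distinct full names for "
                f"{self.n_patients} patients "
                f"({self.name_pool_first} x {self.name_pool_last} combinations)"
            )
        dlo, _ = self.diagnoses_per_patient_range
        if self.n_diagnoses < self.diagnoses_per_patient_range[1] + 1:
            # every patient needs a nonempty out-group
            raise ValueError("n_diagnoses must exceed diagnoses_per_patient_range[1]")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in (
            "desc_len_range",
            "diagnoses_per_patient_range",
            "notes_per_patient_range",
            "note_len_range",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PatientRecord:
    patient_id: str
    name_tokens: tuple[str, str]
    diagnosis_ids: frozenset[str]
    retained: bool | None = None  # set by :func:`deidentify`

    def __post_init__(self) -> None:
        if not self.name_tokens:
            raise ValueError("name_tokens must be nonempty")
        if not self.diagnosis_ids:
            raise ValueError("diagnosis_ids must be nonempty")


@dataclass(frozen=True)
class DiagnosisEntry:
    diagnosis_id: str
    description_tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.description_tokens) <= 3:
            raise ValueError("description_tokens length must lie in [1, 3]")


@dataclass
class Corpus:
    """Token sequences per note plus a consistent token count table."""

    notes: list[tuple[str, list[str]]]
    token_counts: Counter = field(default_factory=Counter)

    @classmethod
    def from_notes(cls, notes: Iterable[tuple[str, Sequence[str]]]) -> "Corpus":
        notes = [(pid, list(toks)) for pid, toks in notes]
        counts = Counter(tok for _, toks in notes for tok in toks)
        return cls(notes=notes, token_counts=counts)

    def recount(self) -> Counter:
        return Counter(tok for _, toks in self.notes for tok in toks)

    def sentences(self) -> list[list[str]]:
        return [toks for _, toks in self.notes]

    def __len__(self) -> int:
        return len(self.notes)


@dataclass
class GroundTruth:
    """What the de-identifier left behind, for scoring attacks.

    ``retained_full_names`` holds unordered (lexicographically sorted) token
    pairs of the full-name mentions that survived de-identification.
    """

    retained_full_names: set[tuple[str, str]]
    patient_diagnoses: dict[str, frozenset[str]]
    retained_name_tokens: set[str]
    patient_names: dict[str, tuple[str, str]]
    retained_patient_ids: set[str]

    def to_json(self, path: str | Path, catalogue: Sequence[DiagnosisEntry]) -> None:
        payload = {
            "names": sorted([list(p) for p in self.retained_full_names]),
            "diagnoses": {pid: sorted(ids) for pid, ids in sorted(self.patient_diagnoses.items())},
            "catalogue": {e.diagnosis_id: list(e.description_tokens) for e in catalogue},
            "patient_names": {pid: list(nm) for pid, nm in sorted(self.patient_names.items())},
            "retained_patients": sorted(self.retained_patient_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> tuple["GroundTruth", list[DiagnosisEntry]]:
        payload = json.loads(Path(path).read_text())
        truth = cls(
            retained_full_names={tuple(p) for p in payload["names"]},
            patient_diagnoses={
                pid: frozenset(ids) for pid, ids in payload["diagnoses"].items()
            },
            retained_name_tokens={t for p in payload["names"] for t in p},
            patient_names={pid: tuple(nm) for pid, nm in payload["patient_names"].items()},
            retained_patient_ids=set(payload["retained_patients"]),
        )
        catalogue = [
            DiagnosisEntry(did, tuple(desc)) for did, desc in sorted(payload["catalogue"].items())
        ]
        return truth, catalogue


# ---------------------------------------------------------------------------
# token pools


def _make_tokens(rng: np.random.Generator, n: int, taken: set[str], prefix_len=(4, 8)) -> list[str]:
    """Draw ``n`` distinct lowercase pseudo-words not present in ``taken``."""
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(prefix_len[0], prefix_len[1] + 1))
        word = "".join(letters[rng.integers(0, 26, size=length)])
        if word not in taken:
            taken.add(word)
            out.append(word)
    return out


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


# ---------------------------------------------------------------------------
# generation


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[Corpus, list[PatientRecord], list[DiagnosisEntry]]:
    """Generate a raw (not yet de-identified) corpus with planted structure.

    Every note starts with the header ``name <first> <last>``; the body is
    background filler with one diagnosis description spliced in at a random
    position (the patient's own with probability ``association_prob``, a
    random catalogue entry otherwise).  Fixed seed implies byte-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    taken = {HEADER_TOKEN, TAG_TOKEN}

    first_pool = _make_tokens(rng, config.name_pool_first, taken)
    last_pool = _make_tokens(rng, config.name_pool_last, taken)
    diag_vocab = _make_tokens(rng, max(8, int(1.5 * config.n_diagnoses)), taken)
    background = _make_tokens(rng, config.background_vocab_size, taken)

    w_first = _zipf_weights(config.name_pool_first, config.name_freq_exponent)
    w_last = _zipf_weights(config.name_pool_last, config.name_freq_exponent)
    w_bg = _zipf_weights(config.background_vocab_size, 1.0)

    # distinct full names per patient; tokens may still be shared across names
    names: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for _ in range(config.n_patients):
        for _attempt in range(10_000):
            nm = (
                first_pool[int(rng.choice(config.name_pool_first, p=w_first))],
                last_pool[int(rng.choice(config.name_pool_last, p=w_last))],
            )
            if nm not in seen:
                break
        else:  # pragma: no cover - heavy-collision fallback, still deterministic
            free = [
                (f, l) for f in first_pool for l in last_pool if (f, l) not in seen
            ]
            nm = free[int(rng.integers(0, len(free)))]
        seen.add(nm)
        names.append(nm)

    catalogue: list[DiagnosisEntry] = []
    seen_desc: set[tuple[str, ...]] = set()
    dlo, dhi = config.desc_len_range
    for i in range(config.n_diagnoses):
        for _attempt in range(10_000):
            length = int(rng.integers(dlo, dhi + 1))
            desc = tuple(
                diag_vocab[j] for j in rng.integers(0, len(diag_vocab), size=length)
            )
            if desc not in seen_desc and len(set(desc)) == len(desc):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw distinct diagnosis descriptions")
        seen_desc.add(desc)
        catalogue.append(DiagnosisEntry(f"d{i:03d}", desc))

    records: list[PatientRecord] = []
    notes: list[tuple[str, list[str]]] = []
    nd_lo, nd_hi = config.diagnoses_per_patient_range
    nn_lo, nn_hi = config.notes_per_patient_range
    bl_lo, bl_hi = config.note_len_range
    diag_ids = [e.diagnosis_id for e in catalogue]
    desc_by_id = {e.diagnosis_id: e.description_tokens for e in catalogue}

    w_diag = _zipf_weights(config.n_diagnoses, config.diag_freq_exponent)

    for p, nm in enumerate(names):
        pid = f"p{p:05d}"
        n_diag = int(rng.integers(nd_lo, nd_hi + 1))
        billed = sorted(
            diag_ids[j]
            for j in rng.choice(config.n_diagnoses, size=n_diag, replace=False, p=w_diag)
        )
        records.append(PatientRecord(pid, nm, frozenset(billed)))
        for _ in range(int(rng.integers(nn_lo, nn_hi + 1))):
            body_len = int(rng.integers(bl_lo, bl_hi + 1))
            body = [
                background[j]
                for j in rng.choice(config.background_vocab_size, size=body_len, p=w_bg)
            ]
            if rng.random() < config.association_prob:
                mention = billed[int(rng.integers(0, len(billed)))]
            else:
                mention = diag_ids[int(rng.choice(config.n_diagnoses, p=w_diag))]
            pos = int(rng.integers(0, body_len + 1))
            body[pos:pos] = list(desc_by_id[mention])
            notes.append((pid, [HEADER_TOKEN, nm[0], nm[1]] + body))

    return Corpus.from_notes(notes), records, catalogue


# ---------------------------------------------------------------------------
# de-identification


def _locate_mentions(corpus: Corpus) -> list[int]:
    """Indices of notes whose header carries a full-name mention."""
    return [
        i
        for i, (_pid, toks) in enumerate(corpus.notes)
        if len(toks) >= 3 and toks[0] == HEADER_TOKEN
    ]


def deidentify(
    corpus: Corpus,
    records: list[PatientRecord],
    mode: str = "remove",
    removal_fraction: float = 0.99,
    seed: int = 0,
) -> tuple[Corpus, GroundTruth]:
    """Apply an imperfect de-identifier to the planted full-name mentions.

    Exactly ``round(removal_fraction * N)`` of the ``N`` full-name mentions
    (both tokens of a mention together) are hit, chosen uniformly at random,
    emulating a PHI search with recall ``removal_fraction``.  Hit mentions are
    deleted (``remove``), collapsed to a single tag token (``tag``), or
    substituted with another randomly chosen name from the patient pool
    (``replace``).  ``records`` have their ``retained`` flag set in place;
    the returned :class:`GroundTruth` lists the surviving full names.
    """
    if not 0.0 <= removal_fraction <= 1.0:
        raise ValueError("removal_fraction must lie in [0, 1]")
    if mode not in ("remove", "tag", "replace"):
        raise ValueError(f"unknown de-identification mode {mode!r}")

    rng = np.random.default_rng(seed)
    mentions = _locate_mentions(corpus)
    mention_set = set(mentions)
    n_hit = round(removal_fraction * len(mentions))
    hit = set(np.asarray(mentions)[rng.permutation(len(mentions))[:n_hit]].tolist())

    by_pid = {r.patient_id: r for r in records}
    pool = [r.name_tokens for r in records]
    new_notes: list[tuple[str, list[str]]] = []
    surviving_pids: set[str] = set()
    retained_names: set[tuple[str, str]] = set()

    for i, (pid, toks) in enumerate(corpus.notes):
        toks = list(toks)
        if i in hit:
            if mode == "remove":
                toks = [toks[0]] + toks[3:]
            elif mode == "tag":
                toks = [toks[0], TAG_TOKEN] + toks[3:]
            else:  # replace
                own = by_pid[pid].name_tokens
                for _attempt in range(10_000):
                    fake = pool[int(rng.integers(0, len(pool)))]
                    if fake != own or len(pool) == 1:
                        break
                toks[1:3] = list(fake)
        elif i in mention_set:
            surviving_pids.add(pid)
            nm = by_pid[pid].name_tokens
            retained_names.add(tuple(sorted(nm)))
        new_notes.append((pid, toks))

    for r in records:
        r.retained = r.patient_id in surviving_pids

    truth = GroundTruth(
        retained_full_names=retained_names,
        patient_diagnoses={r.patient_id: r.diagnosis_ids for r in records},
        retained_name_tokens={t for p in retained_names for t in p},
        patient_names={r.patient_id: r.name_tokens for r in records},
        retained_patient_ids=surviving_pids,
    )
    return Corpus.from_notes(new_notes), truth


# ---------------------------------------------------------------------------
# plain-text IO


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """One note per line, space-separated tokens, UTF-8."""
    with open(path, "w") as fh:
        for _pid, toks in corpus.notes:
            fh.write(" ".join(toks) + "\n")


def read_corpus(path: str | Path, normalize: bool = False) -> Corpus:
    """Read a one-note-per-line text file; optionally normalize each line."""
    notes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            toks = normalize_text(line) if normalize else line.split()
            if toks:
                notes.append((f"n{i:06d}", toks))
    return Corpus.from_notes(notes)
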