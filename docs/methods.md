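# Methods

`embaudit` measures how much patient-identifying signal survives in word
embeddings trained on clinical notes that were de-identified by PHI
(personal health information) *removal*. Because corpora that link real
patient names to billing diagnoses cannot be shared, the package audits the
phenomenon end to end on synthetic corpora with known ground truth: it
plants names and diagnoses, removes most name mentions the way an imperfect
PHI detector would, trains embeddings, and then attacks them.

## Threat model

The adversary holds only a released embedding table (token → dense vector)
and a list of name tokens that survived de-identification. No perfect PHI
detector exists, so some name tokens always remain in the training text and
therefore in the vocabulary; the audit assumes the adversary can spot them,
which isolates what the *embedding geometry* leaks from the separate
problem of finding the tokens. Three leakage channels are measured:

1. **Name reconstruction.** The two tokens of one person's name occur in
   the same contexts, so their vectors end up close. All C(T,2) unordered
   pairs of the T surviving tokens are ranked by distance, ascending; the
   fraction of the first *k* pairs that are true names measures leakage.
   Without ground truth the attacker expects ⌊T/2⌋ names (two tokens per
   name, no sharing), so *k* defaults to that estimate. Chance level for K
   true names is K / C(T,2); significance is a one-sided binomial test.
2. **Name–diagnosis association.** For patient *p* with name vector
   **n**_p (mean of the component token vectors), the *in-group* is the
   mean distance from **n**_p to the description vectors of p's billed
   diagnoses, the *out-group* the mean distance to all other catalogue
   diagnoses, and diff = in − out. Population level: two-sided Wilcoxon
   signed-rank over patients' (in, out) pairs, Holm–Bonferroni-corrected
   across the swept models. Patient level: an empirical permutation
   p-value — pseudo in-groups of the same size n_in are drawn from the
   patient's own distance multiset (optionally from a population pool) and
   |diff| is ranked with +1 smoothing, p = (1 + #{perm ≥ obs}) / (1 + N);
   the smallest attainable p is therefore 1/(N+1), which bounds how many
   patients can survive a Holm correction across hundreds of patients —
   uncorrected and Holm counts are both reported for that reason.
3. **Attack simulation.** For a random set of target diagnoses (each
   description phrase must occur ≥ 10 times in the corpus), every surviving
   name is assigned the k = 5 targets *farthest* from its name vector —
   the direction the source threat model prescribes — and Top-1/Top-5
   accuracy is scored against a majority baseline that always predicts the
   most-billed targets. Trials are repeated with fresh target sets; the
   headline number is how often the attack strictly beats the baseline,
   compared with a random-ranking attacker via a paired sign test.

## Synthetic corpus model

Each note is `name <first> <last>` followed by a body of background filler
with one diagnosis description (1–3 tokens) spliced in at a random
position. Key knobs (defaults in parentheses):

- `n_patients` (200); names are two tokens drawn from skewed first/last
  pools (Zipf exponent 1.0), so common name tokens are shared across
  patients while full names stay distinct.
- `association_prob` (0.9): probability the mentioned diagnosis is one of
  the patient's own billed codes; otherwise a random catalogue code is
  mentioned. At 0 the mention stream is independent of billing — the null
  corpus used for calibration.
- `diag_freq_exponent` (0.0): Zipf exponent of billing-code popularity.
  See "frequency artifact" below for why the default is uniform.
- `removal_fraction` (0.99) and `deid_mode` (`remove`/`tag`/`replace`):
  exactly round(f·N) of the N full-name mentions are hit (both tokens
  together), chosen uniformly — detection recall is 1−f by construction
  and survivor counts are deterministic. `remove` deletes the tokens,
  `tag` collapses them to one tag token, `replace` substitutes another
  pool name.
- note shape: 2–4 notes per patient, 10–25 body tokens, 1 200 background
  types with Zipf unigram frequencies; diagnoses per patient 1–3 from a
  40-code catalogue.

What the generator does **not** emulate: clinical grammar or section
structure, name mentions outside the header, correlated detector failures
(a real dictionary-based de-identifier misses the same name everywhere,
concentrating survivors on few names), co-morbidity structure, and corpus
scale (a real released embedding is trained on orders of magnitude more
text). Passing audits here show the pipeline extracts planted structure
from distributional geometry; absolute leakage rates on real corpora will
differ.

## Embedding trainers

CBOW, Skipgram (negative sampling) and GloVe are implemented in vectorized
numpy. Training follows the standard recipes — unigram^0.75 noise
distribution with 5 negatives and a linearly decaying learning rate for
the word2vec family; 1/distance-weighted co-occurrence accumulation,
f(x) = min(1, (x/x_max)^α) weighting (α = 0.75, x_max = 10) and AdaGrad
for GloVe — with two deliberate choices:

- **Scatter-averaged minibatches.** Within a batch, gradient contributions
  that hit the same embedding row are averaged, not summed. Summing
  multiplies the effective step of very frequent tokens (the `name` header
  token sits in ~5 % of all pairs) by their within-batch multiplicity and
  training diverges.
- **Aggressive small-corpus schedules.** Defaults are lr 0.1/30 epochs
  (Skipgram), 0.2/30 (CBOW — it spreads each update across the whole
  context window, so it takes larger steps, as the classic trainers also
  do), and 150 epochs (GloVe). Desk-scale corpora (~50 k tokens) give a
  surviving name token only a handful of positive updates; the classic
  billion-token defaults (0.025, 5 epochs) leave such vectors at their
  random initialization and the audit would measure nothing but noise.
- Determinism: single-threaded, one RNG per fit; identical seed ⇒
  identical vectors. No per-position window shrinking, no frequent-word
  subsampling.

Cosine distance is 1 − cosine similarity (range [0, 2]; zero vectors are
an explicit error, never NaN); cityblock is Σ|uᵢ−vᵢ|. Reconstruction
defaults to cosine, association and attack to cityblock, whose sensitivity
to vector magnitude (which grows with token frequency) makes it the more
revealing metric for this task.

## Statistical choices

- Wilcoxon: zeros discarded before ranking; exact null for n ≤ 25 without
  tied |differences|, else normal approximation with tie correction
  (delegated to scipy, cross-checked in the tests against a
  sign-enumeration oracle and a hand-coded approximation formula). The
  minimum is 3 pairs, the smallest n with a two-sided exact p below 1.
- Holm–Bonferroni: step-down implemented directly (sort ascending, reject
  while p(i) ≤ α/(m−i+1)), returned in input order; population-level
  correction spans the swept model grid, patient-level correction spans
  patients within one model.
- Patient permutations are two-sided on |diff|: the audit must not assume
  the direction of the effect (see below).
- Ranking ties (candidate pairs, predicted targets) break
  lexicographically, so every ranking is deterministic.
- Patients whose name tokens are out of vocabulary are skipped and
  counted; diagnoses with out-of-vocabulary description tokens are dropped
  from both groups; a patient with an empty in- or out-group is excluded.

## The sign of the in/out difference and the frequency artifact

On associative synthetic corpora the in-group is systematically *closer*
than the out-group (negative diff): co-occurrence produces proximity, as
the distributional hypothesis predicts. The original observation this
audit emulates reported the opposite, unexplained sign on real notes.
The generator reproduces that inverted sign only when billing popularity
is Zipf-skewed (`diag_freq_exponent` ≈ 1): billed sets then
over-represent common codes, frequent tokens carry larger norms, and
cityblock distances grow with norm — so in-groups sit farther *even on
null corpora with no name–diagnosis association at all*. Because that is
a frequency-composition artifact rather than patient-specific leakage —
it destroys the null calibration the audit depends on — the default is
uniform billing, the population test stays calibrated, and the artifact is
exposed as a configurable property instead. Consequence: the attack's
farthest-first convention, inherited from the source threat model, points
the wrong way on calibrated synthetic corpora; `direction="nearest"` is
provided and is the setting under which the attack demonstrably extracts
the association signal. `scripts/acceptance.py` reports both directions.

## Calibration of the population test under group imbalance

A second, subtler property matters when interpreting the population
Wilcoxon. Patients are billed only 1–3 of the 40 catalogue codes, so each
null diff is the mean of a small random subset minus the mean of its large
complement: mean-zero, but *skewed* whenever a few diagnosis vectors sit
far from the name cloud — and that skew is shared across patients, because
everyone is scored against the same trained vectors. The signed-rank test
is sensitive to the pseudomedian, not the mean, so its null rejection rate
rises above the nominal level as more patients are scored (resimulating
random billing on fixed trained geometry shows per-corpus rejection
probabilities from ~4 % up to ~40 % for unlucky geometries at 200 scored
patients, while balanced in/out groups on the same geometries are
calibrated). Practical consequence: calibrate and interpret the population
test at the cohort size the audit actually operates on (the ~60 retained
patients), not on inflated cohorts; `null_population_study` reports both
the full-sample and the matched-size p-values for exactly this reason.

## Frozen study conditions

The acceptance studies (same code path in `tests/test_acceptance.py` and
`scripts/acceptance.py`) pin: an associative corpus of 800 patients
(association 0.9, removal fraction set so 60 full-name mentions survive,
~53 k tokens), Skipgram/CBOW/GloVe at windows {1, 3, 5, 9}, dimension 50;
reconstruction at k = 60 against chance K/C(T,2); a 20-seed null ensemble
of 200-patient corpora (association 0, no removal) for population
calibration plus one 200-patient/200-permutation run for patient-level
calibration; and 200 attack trials of 10 targets with the
random-ranking-attacker sign test. These sizes keep a full audit within
minutes on one CPU while leaving the leakage signals many standard errors
from chance.

## Known limitations

- The trainers are reference implementations for auditability, not speed;
  they are single-threaded by design (reproducibility) and unsuitable for
  100 M-token corpora.
- The empirical-p floor 1/(N+1) makes family-wise-corrected patient counts
  at N = 200–1000 permutations structurally small; interpret the
  uncorrected count as a rate against the null calibration instead.
- Greedy (token-consuming) pairing, the population permutation pool, the
  patient-count target filter and the nearest attack direction are
  provided as sensitivity flags; the defaults follow the conventions of
  the source threat model.
- With very small catalogues the permutation grid is coarse; p-values are
  then conservative by construction.
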