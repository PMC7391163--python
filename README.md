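# embaudit

**Privacy-leakage audit for word embeddings trained on de-identified
clinical text.**

Clinical notes are commonly "anonymized" by *PHI removal*: a search
algorithm finds personal health information (names, dates, identifiers)
and deletes it. No detector has perfect recall, so some name tokens always
survive — and when word embeddings (CBOW, Skipgram, GloVe) are trained on
the cleaned text and released, the surviving names are still in the
vocabulary, embedded in the geometry of everything that co-occurred with
them. `embaudit` quantifies what that geometry gives away. It is aimed at
data custodians deciding whether an embedding table is safe to release,
and at researchers studying text de-identification.

The package audits three leakage channels against corpora with known
ground truth (a built-in generator plants names and diagnoses in
clinical-note-like synthetic text, then de-identifies it imperfectly):

1. **Name reconstruction** — rank all unordered pairs of surviving name
   tokens by vector distance; true first/last pairs concentrate at the
   top. Scored as the fraction of true names in the first *k* pairs
   against the chance level K/C(T,2).
2. **Name–diagnosis association** — for each patient, compare the mean
   distance from the name vector **n**_p to billed-diagnosis vectors
   (*in-group*) versus all other diagnoses (*out-group*); tested with a
   Wilcoxon signed-rank across patients (Holm–Bonferroni corrected) and
   with per-patient permutation p-values, p = (1 + #{perm ≥ obs})/(1 + N).
3. **Attack simulation** — assign each surviving name the *k* target
   diagnoses farthest from it and score Top-1/Top-5 accuracy against a
   majority baseline over randomized target sets.

All embedding trainers are deterministic, pure-numpy, scikit-learn-style
estimators (`Word2Vec`, `GloVe`: `fit`/`transform`, fitted
`vocabulary_`/`vectors_`), and models round-trip through the standard
word2vec text format.

## Worked example

```python
from embaudit import (GeneratorConfig, generate_corpus, deidentify,
                      Word2Vec, rank_candidate_pairs, evaluate_reconstruction,
                      expected_name_count)
from embaudit.association import compute_in_out, wilcoxon_signed_rank

cfg = GeneratorConfig(n_patients=800, name_pool_first=120, name_pool_last=160,
                      n_diagnoses=40, note_len_range=(10, 25),
                      background_vocab_size=1200, association_prob=0.9, seed=7)
corpus, records, catalogue = generate_corpus(cfg)
deid, truth = deidentify(corpus, records, "remove",
                         removal_fraction=1 - 60 / len(corpus.notes), seed=8)
print(f"{len(truth.retained_full_names)} full names "
      f"({len(truth.retained_name_tokens)} tokens) survive de-identification")

model = Word2Vec(algorithm="skipgram", dim=50, window=5, seed=1).fit(deid).to_model()

k = expected_name_count(len(truth.retained_name_tokens))
pairs = rank_candidate_pairs(model, truth.retained_name_tokens, metric="cosine")
n_true, frac = evaluate_reconstruction(pairs, truth, k=k)
print(f"reconstruction: {n_true}/{k} of the top-ranked pairs are true names "
      f"({100 * frac:.1f}%)")

results, _ = compute_in_out(model, records, catalogue, metric="cityblock")
test = wilcoxon_signed_rank([r.in_group for r in results],
                            [r.out_group for r in results])
print(f"association: Wilcoxon p = {test.p_value:.2g} over {len(results)} patients")
```

Output:

```
59 full names (78 tokens) survive de-identification
reconstruction: 30/39 of the top-ranked pairs are true names (76.9%)
association: Wilcoxon p = 0.0019 over 59 patients
```

Read: the de-identifier deleted 97.5 % of name mentions, yet three quarters
of the attacker's top-ranked token pairs are real patient names
(chance would be ~2 %), and billed diagnoses sit at systematically
different distances from their patients' names than non-billed ones — the
embedding betrays both who is in the corpus and what they were billed.

## Full pipeline and CLI

```bash
embaudit run --config examples/audit_config.yaml   # generate → deidentify → sweep → report
embaudit train --corpus corpus.txt --algorithm glove --window 9 --out glove.txt
embaudit reconstruct --model glove.txt --tokens tokens.txt --metric cosine \
    --k 600 --out pairs.csv
embaudit associate --model glove.txt --truth ground_truth.json --nperm 1000 \
    --out assoc.json
embaudit attack --model glove.txt --truth ground_truth.json --corpus corpus.txt \
    --n-targets 30 --min-count 10 --trials 1000 --out attack.json
```

`embaudit run` leaves a self-contained run directory (corpora, ground
truth, every swept model in word2vec text format, per-experiment JSON, a
Markdown report with one table row per context window and one column per
algorithm).

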