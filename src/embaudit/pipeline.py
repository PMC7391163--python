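"""End-to-end audit pipeline: generate -> de-identify -> sweep -> experiments.

``run_pipeline`` drives the whole audit from one YAML config and leaves a
self-contained run directory behind: corpora, ground truth, every swept
embedding model in word2vec text format, per-experiment JSON results, a log
with all derived seeds, and a rendered Markdown report whose tables have one
row per context window and one column per algorithm.

Every stage derives its own seed deterministically from the master seed, so
a stage can be re-run (or resumed: existing artifacts are reused) in
isolation without disturbing the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import frequency_threshold_curve, holm_bonferroni, patient_empirical_pvalue
from .attack import run_attack_trials
from .corpus import (
    GeneratorConfig,
    GroundTruth,
    PatientRecord,
    deidentify,
    generate_corpus,
    write_corpus,
)
from .embeddings import EmbeddingModel, Hyperparams, load_word2vec_format, train_embedding
from .reconstruction import evaluate_reconstruction, expected_name_count, rank_candidate_pairs
from .study import association_study

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "render_report", "stage_seed"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "corpus": {},
    "deidentify": {"mode": "remove", "removal_fraction": 0.99},
    "sweep": {
        "algorithms": ["skipgram", "cbow", "glove"],
        "windows": [1, 3, 5, 7, 9],
        "dim": 100,
        "min_count": 1,
        "epochs": None,
    },
    "experiments": {
        "reconstruction_metric": "cosine",
        "association_metric": "cityblock",
        "k": None,  # default: expected_name_count of the surviving tokens
        "thresholds": [2, 5, 10, 25, 50, 100, 200],
        "n_perm": 1000,
        "alpha": 0.05,
        "attack": {
            "n_trials": 100,
            "n_targets": 10,
            "min_count": 10,
            "k": 5,
            "direction": "farthest",
        },
    },
}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def _records_from_truth(truth: GroundTruth) -> list[PatientRecord]:
    return [
        PatientRecord(
            pid,
            truth.patient_names[pid],
            truth.patient_diagnoses[pid],
            retained=pid in truth.retained_patient_ids,
        )
        for pid in sorted(truth.patient_names)
    ]


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> Path:
    """Run (or resume) the full audit; returns the run directory."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, config)
    master = int(cfg["seed"])

    if out_dir is None:
        out_dir = cfg.get("run_dir") or time.strftime("runs/audit_%Y%m%d_%H%M%S")
    run = Path(out_dir)
    (run / "models").mkdir(parents=True, exist_ok=True)
    (run / "results").mkdir(exist_ok=True)

    handler = logging.FileHandler(run / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("embaudit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_stages(cfg, run, master)
    finally:
        root.removeHandler(handler)


def _run_stages(cfg: dict, run: Path, master: int) -> Path:
    logger.info("embaudit %s | numpy %s | master seed %d", __version__, np.__version__, master)

    # --- stage: generate ------------------------------------------------
    gen_cfg = GeneratorConfig.from_dict(
        {**cfg["corpus"], "seed": cfg["corpus"].get("seed", stage_seed(master, "generate"))}
    )
    raw_path = run / "corpus_raw.txt"
    corpus, records, catalogue = generate_corpus(gen_cfg)
    if not raw_path.exists():
        write_corpus(corpus, raw_path)
        logger.info("generate: %d notes, %d tokens", len(corpus), sum(corpus.token_counts.values()))

    # --- stage: deidentify ----------------------------------------------
    deid_path, truth_path = run / "corpus.txt", run / "ground_truth.json"
    deid, truth = deidentify(
        corpus,
        records,
        mode=cfg["deidentify"].get("mode", gen_cfg.deid_mode),
        removal_fraction=cfg["deidentify"].get("removal_fraction", gen_cfg.removal_fraction),
        seed=stage_seed(master, "deidentify"),
    )
    if not deid_path.exists():
        write_corpus(deid, deid_path)
        truth.to_json(truth_path, catalogue)
        logger.info(
            "deidentify: %d full names (%d tokens) survive",
            len(truth.retained_full_names),
            len(truth.retained_name_tokens),
        )

    # --- stage: train sweep ---------------------------------------------
    sweep = cfg["sweep"]
    models: dict[tuple[str, int], EmbeddingModel] = {}
    for algo in sweep["algorithms"]:
        for window in sweep["windows"]:
            name = f"{algo}_w{window}"
            path = run / "models" / f"{name}.txt"
            if path.exists():
                models[(algo, window)] = load_word2vec_format(path)
                logger.info("train: reusing %s", path)
                continue
            hp = Hyperparams(
                algorithm=algo,
                window=window,
                dim=sweep["dim"],
                min_count=sweep["min_count"],
                epochs=sweep["epochs"],
                seed=stage_seed(master, f"train:{name}"),
            )
            t0 = time.time()
            models[(algo, window)] = train_embedding(deid, hp)
            models[(algo, window)].save(path)
            logger.info("train: %s in %.1fs", name, time.time() - t0)
    logger.info("sweep: %d models", len(models))

    exp = cfg["experiments"]
    # --- stage: reconstruction ------------------------------------------
    rec_path = run / "results" / "reconstruction.json"
    if not rec_path.exists():
        tokens = truth.retained_name_tokens
        k = exp["k"] or max(1, expected_name_count(len(tokens)))
        rec = {"k": k, "n_tokens": len(tokens), "n_names": len(truth.retained_full_names), "models": {}}
        for (algo, window), model in models.items():
            pairs = rank_candidate_pairs(model, tokens, exp["reconstruction_metric"])
            kk = min(k, len(pairs))
            n_true, fraction = evaluate_reconstruction(pairs, truth, kk)
            rec["models"][f"{algo}_w{window}"] = {
                "algorithm": algo, "window": window,
                "n_true": n_true, "fraction": fraction, "k": kk,
            }
        rec_path.write_text(json.dumps(rec, indent=1))
        logger.info("reconstruction: done")

    # --- stage: association ---------------------------------------------
    assoc_path = run / "results" / "association.json"
    if not assoc_path.exists():
        out: dict = {"alpha": exp["alpha"], "n_perm": exp["n_perm"], "models": {}}
        recs = _records_from_truth(truth)
        for (algo, window), model in models.items():
            res = association_study(
                model, recs, catalogue, exp["association_metric"], retained_only=True
            )
            curve = frequency_threshold_curve(
                res["results"], recs, deid.token_counts, exp["thresholds"]
            )
            by_pid = {x.patient_id: x for x in recs}
            pvals = []
            scored = []
            for i, r in enumerate(res["results"]):
                rec_obj = by_pid[r.patient_id]
                pvals.append(
                    patient_empirical_pvalue(
                        model, rec_obj, catalogue, exp["association_metric"],
                        n_perm=exp["n_perm"],
                        seed=stage_seed(master, f"perm:{algo}:{window}:{i}"),
                    )
                )
                scored.append(r.patient_id)
            holm = holm_bonferroni(pvals, exp["alpha"]) if pvals else []
            out["models"][f"{algo}_w{window}"] = {
                "algorithm": algo, "window": window,
                "n_patients": res["n_patients"],
                "mean_diff": res["mean_diff"],
                "wilcoxon_statistic": res["statistic"],
                "wilcoxon_p": res["p_value"],
                "excluded": res["excluded"],
                "threshold_curve": {str(t): v for t, v in curve.items()},
                "patient_p_values": dict(zip(scored, pvals)),
                "n_significant_uncorrected": int(sum(p < exp["alpha"] for p in pvals)),
                "n_significant_holm": int(sum(holm)),
            }
        # Holm across the swept configurations at the population level
        names = list(out["models"])
        pop_p = [out["models"][n]["wilcoxon_p"] for n in names]
        for name, sig in zip(names, holm_bonferroni(pop_p, exp["alpha"])):
            out["models"][name]["wilcoxon_significant_holm"] = bool(sig)
        assoc_path.write_text(json.dumps(out, indent=1))
        logger.info("association: done")

    # --- stage: attack ---------------------------------------------------
    attack_path = run / "results" / "attack.json"
    if not attack_path.exists():
        acfg = exp["attack"]
        out = {"config": acfg, "models": {}}
        for (algo, window), model in models.items():
            summary = run_attack_trials(
                model, truth, catalogue, deid,
                n_trials=acfg["n_trials"], n_targets=acfg["n_targets"],
                min_count=acfg["min_count"], k=acfg["k"],
                metric=exp["association_metric"],
                seed=stage_seed(master, f"attack:{algo}:{window}"),
                direction=acfg.get("direction", "farthest"),
            )
            summary.pop("trials")
            out["models"][f"{algo}_w{window}"] = {
                "algorithm": algo, "window": window, **summary
            }
        attack_path.write_text(json.dumps(out, indent=1))
        logger.info("attack: done")

    (run / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    (run / "report.md").write_text(render_report(run))
    logger.info("report rendered")
    return run


# ---------------------------------------------------------------------------
# reporting


def _load(run: Path, rel: str) -> dict:
    path = run / rel
    if not path.exists():
        raise FileNotFoundError(f"missing run artifact: {path}")
    return json.loads(path.read_text())


def _table(models: dict, value) -> str:
    rows = sorted({m["window"] for m in models.values()})
    cols = sorted({m["algorithm"] for m in models.values()})
    df = pd.DataFrame(index=rows, columns=cols, dtype=object)
    for m in models.values():
        df.loc[m["window"], m["algorithm"]] = value(m)
    df.index.name = "window"
    return df.to_markdown()


def render_report(run_dir: str | Path) -> str:
    """Markdown summary of one run: four tables plus the threshold curve."""
    run = Path(run_dir)
    rec = _load(run, "results/reconstruction.json")
    assoc = _load(run, "results/association.json")
    attack = _load(run, "results/attack.json")

    lines = ["# Embedding privacy audit report", ""]
    lines += [
        f"Run directory: `{run}`",
        "",
        "## Name reconstruction",
        "",
        f"True names among the first k={rec['k']} candidate pairs "
        f"({rec['n_names']} surviving names, {rec['n_tokens']} tokens); "
        "cells are `n_true (percent)`.",
        "",
        _table(rec["models"], lambda m: f"{m['n_true']} ({100 * m['fraction']:.1f}%)"),
        "",
        "## Population-level association (in-group minus out-group)",
        "",
        "Cells are `mean diff / Wilcoxon p`; `*` marks significance after "
        "Holm correction across the sweep.",
        "",
        _table(
            assoc["models"],
            lambda m: f"{m['mean_diff']:+.3f} / p={m['wilcoxon_p']:.2g}"
            + ("*" if m.get("wilcoxon_significant_holm") else ""),
        ),
        "",
        "## Patient-level association",
        "",
        f"Patients with empirical p < {assoc['alpha']} "
        f"({assoc['n_perm']} permutations); cells are `uncorrected (Holm)` "
        "out of the scored patients.",
        "",
        _table(
            assoc["models"],
            lambda m: f"{m['n_significant_uncorrected']} ({m['n_significant_holm']}) / {m['n_patients']}",
        ),
        "",
        "## Attack beat rates",
        "",
        f"Fraction of {attack['config']['n_trials']} random "
        f"{attack['config']['n_targets']}-target trials in which the "
        f"{attack['config'].get('direction', 'farthest')}-{attack['config']['k']} "
        "attack strictly beats the majority baseline; cells are `A@1, A@5`.",
        "",
        _table(
            attack["models"],
            lambda m: f"{m['beat_rate_a1']:.2f}, {m['beat_rate_a5']:.2f}",
        ),
        "",
        "## Name-frequency threshold curve",
        "",
    ]
    for name, m in sorted(assoc["models"].items()):
        curve = ", ".join(f"<{t}: {v:+.3f}" for t, v in sorted(
            m["threshold_curve"].items(), key=lambda kv: float(kv[0])
        ))
        lines.append(f"- `{name}`: {curve or 'no bucket occupied'}")
    excl = {name: m["excluded"] for name, m in sorted(assoc["models"].items())}
    lines += ["", "## Exclusions", "", "```json", json.dumps(excl, indent=1), "```", ""]
    return "\n".join(lines)
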