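"""Config-driven end-to-end experiment runner.

Reproduces the four-part workflow on synthetic corpora: (A) backend and
prompt-template selection by effective response rate then selection
accuracy; (B) prompt improvement — five-shot strategy comparison and
error-analysis-based instructions; (C) evaluation of the prompted model, the
two locally trained baselines, and their majority-vote ensemble on the test
analog, with bootstrap CIs and paired tests; (D) keyword interpretation and
error-overlap analysis.  Every artefact is written into a run directory
together with a manifest (config, seeds, version) that makes each number
recomputable from configuration alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .baselines import AttentionNetConfig, predict_labels, train_attention_net, train_boosted_trees
from .corpus import Corpus, load_default_lexicon, keyword_filter, write_corpus
from .ensemble import PredictionSet, majority_vote
from .error_analysis import error_sets, mutual_error_fraction, overlap_counts, plot_venn
from .evaluation import bootstrap_cis, compute_metrics, confusion_matrix, paired_metric_test
from .fewshot import (
    DynamicKnnExamples,
    ExamplePool,
    StaticExamples,
    TfidfEmbeddingProvider,
    select_kmeans_centers,
    select_random,
    select_targeted,
)
from .interpretation import (
    attention_keywords,
    gain_keywords,
    llm_keywords,
    merge_keyword_report,
    render_keyword_table,
)
from .prompting import (
    ScriptedBackend,
    ScriptedBackendConfig,
    build_error_instructions,
    classify_sections,
    default_templates,
    selection_accuracy,
    template_selection_report,
)

__all__ = ["ExperimentConfig", "run_experiment", "render_report"]

logger = logging.getLogger("cognote.pipeline")


@dataclass
class ExperimentConfig:
    """Study conditions for one synthetic end-to-end run."""

    seed: int = 0
    n_dataset_i: int = 4949
    n_dataset_ii: int = 1996
    i_s_size: int = 200  # template-selection subset, disjoint from the example pool
    probe_size: int = 10  # sections probed for effective response rate
    patient_split: bool = False  # make I-S / I-A disjoint by patient, not just section
    fewshot_k: int = 5
    fewshot_strategies: tuple[str, ...] = ("random", "targeted", "kmeans", "knn_dynamic")
    # Scripted-LLM error profile: modest uniform noise plus category-specific
    # confusion (negation / uncertainty), the classic LLM failure modes that
    # error-analysis-based instructions then suppress.
    llm_flip_rate: float = 0.03
    llm_category_flips: dict = field(
        default_factory=lambda: {"negated": 0.5, "uncertain": 0.35}
    )
    llm_format_break_rate: float = 0.0
    llm_mute_rate: float = 0.0
    net_epochs: int = 8
    net_max_len: int = 256
    bootstrap_B: int = 1000
    patient_bootstrap: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fewshot_strategies" in data:
            data["fewshot_strategies"] = tuple(data["fewshot_strategies"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fewshot_strategies"] = list(self.fewshot_strategies)
        return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n", encoding="utf-8")


def _split_i(corpus: Corpus, size: int, seed: int, by_patient: bool) -> tuple[Corpus, Corpus]:
    """Split the development corpus into selection (I-S) and pool (I-A)."""
    rng = np.random.default_rng(seed)
    if by_patient:
        patients = sorted({s.patient_id for s in corpus.sections})
        order = rng.permutation(len(patients))
        chosen_patients: set[str] = set()
        chosen_count = 0
        for i in order:
            chosen_patients.add(patients[i])
            chosen_count = sum(1 for s in corpus.sections if s.patient_id in chosen_patients)
            if chosen_count >= size:
                break
        sel_ids = [s.section_id for s in corpus.sections if s.patient_id in chosen_patients]
    else:
        idx = rng.choice(len(corpus), size=size, replace=False)
        sel_ids = [corpus.sections[int(i)].section_id for i in idx]
    sel = corpus.subset(sel_ids, name="dataset-I-S-analog")
    rest = corpus.subset(
        [sid for sid in corpus.section_ids if sid not in set(sel_ids)],
        name="dataset-I-A-analog",
    )
    return sel, rest


def _characteristics_row(corpus: Corpus) -> dict:
    lengths = np.array([len(s.text) for s in corpus.sections])
    return {
        "dataset": corpus.name,
        "n_sections": len(corpus),
        "n_patients": len({s.patient_id for s in corpus.sections}),
        "mean_length": round(float(lengths.mean()), 1),
        "min_length": int(lengths.min()),
        "max_length": int(lengths.max()),
        "positive_rate_pct": round(100 * corpus.positive_rate, 1),
    }


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure aborts with the stage name while partial artefacts
    persist on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "init"
    stages_done: list[str] = []
    bank = synthetic.load_default_phrase_bank()
    lexicon = load_default_lexicon()
    try:
        # -- generate ------------------------------------------------------
        stage = "generate"
        cfg_i = synthetic.dataset_i_config(seed=config.seed, n_sections=config.n_dataset_i)
        cfg_ii = synthetic.dataset_ii_config(seed=config.seed + 1, n_sections=config.n_dataset_ii)
        corpus_i = synthetic.generate_corpus(cfg_i, bank)
        corpus_ii = synthetic.generate_corpus(cfg_ii, bank)
        write_corpus(corpus_i, outdir / "dataset_i.jsonl")
        write_corpus(corpus_ii, outdir / "dataset_ii.jsonl")
        i_s, i_a = _split_i(corpus_i, config.i_s_size, config.seed + 2, config.patient_split)
        write_corpus(i_s, outdir / "dataset_i_s.jsonl")
        write_corpus(i_a, outdir / "dataset_i_a.jsonl")
        chars = pd.DataFrame(
            [_characteristics_row(c) for c in (corpus_i, i_a, i_s, corpus_ii)]
        )
        chars.to_csv(outdir / "dataset_characteristics.csv", index=False)
        stages_done.append(stage)

        # -- filter --------------------------------------------------------
        stage = "filter"
        filtered, kept = keyword_filter(corpus_i, lexicon)
        _write_json(
            outdir / "filter_report.json",
            {
                "input_sections": len(corpus_i),
                "retained_sections": kept,
                "retained_positives": sum(filtered.labels),
                "input_positives": sum(corpus_i.labels),
            },
        )
        stages_done.append(stage)

        # -- template/backend selection -------------------------------------
        stage = "select_template"
        rng = np.random.default_rng(config.seed + 3)
        probe_ids = [
            corpus_i.sections[int(i)].section_id
            for i in rng.choice(len(corpus_i), size=config.probe_size, replace=False)
        ]
        probe = corpus_i.subset(probe_ids, name="probe")
        templates = default_templates()
        main_profile = ScriptedBackendConfig(
            lexicon=lexicon,
            phrase_bank=bank,
            flip_rate_overall=config.llm_flip_rate,
            per_category_flip=dict(config.llm_category_flips),
            format_break_rate=config.llm_format_break_rate,
            mute_rate=config.llm_mute_rate,
            seed=config.seed + 10,
        )
        backends = {
            "scripted-a": ScriptedBackend(main_profile, name="scripted-a"),
            # A weaker alternative: frequent refusals and heavier noise.
            "scripted-b": ScriptedBackend(
                ScriptedBackendConfig(
                    lexicon=lexicon,
                    phrase_bank=bank,
                    flip_rate_overall=0.25,
                    mute_rate=0.2,
                    seed=config.seed + 11,
                ),
                name="scripted-b",
            ),
        }
        selection_rows = []
        for bname, backend in backends.items():
            report = template_selection_report(backend, templates, probe, i_s)
            report.insert(0, "backend", bname)
            selection_rows.append(report)
        selection = pd.concat(selection_rows, ignore_index=True).sort_values(
            ["effective_response_rate", "accuracy", "backend", "template_id"],
            ascending=[False, False, True, True],
            kind="stable",
        )
        selection.to_csv(outdir / "template_selection.csv", index=False)
        best_backend = backends[selection.iloc[0]["backend"]]
        best_template = templates[selection.iloc[0]["template_id"]]
        zero_shot_acc = float(selection.iloc[0]["accuracy"])
        stages_done.append(stage)

        # -- few-shot comparison --------------------------------------------
        stage = "fewshot"
        provider = TfidfEmbeddingProvider([s.text for s in i_a.sections])
        pool = ExamplePool.from_corpus(i_a)
        fewshot_rows = [{"strategy": "zero_shot", "accuracy": zero_shot_acc}]
        strategies = {}
        if "random" in config.fewshot_strategies:
            strategies["random"] = StaticExamples.from_sections(
                select_random(pool, config.fewshot_k, config.seed + 20)
            )
        if "targeted" in config.fewshot_strategies:
            prior, _ = classify_sections(best_backend, best_template, i_a)
            strategies["targeted"] = StaticExamples.from_sections(
                select_targeted(pool, prior, config.fewshot_k, config.seed + 21)
            )
        if "kmeans" in config.fewshot_strategies:
            strategies["kmeans"] = StaticExamples.from_sections(
                select_kmeans_centers(pool, config.fewshot_k, provider, config.seed + 22)
            )
        if "knn_dynamic" in config.fewshot_strategies:
            strategies["knn_dynamic"] = DynamicKnnExamples(pool, provider, config.fewshot_k)
        for sname, strategy in strategies.items():
            preds, _ = classify_sections(best_backend, best_template, i_s, fewshot=strategy)
            fewshot_rows.append({"strategy": sname, "accuracy": selection_accuracy(preds, i_s)})
        fewshot_report = pd.DataFrame(fewshot_rows)
        fewshot_report.to_csv(outdir / "fewshot_report.csv", index=False)
        stages_done.append(stage)

        # -- error-analysis-based instructions -------------------------------
        stage = "error_instructions"
        base_preds, _ = classify_sections(best_backend, best_template, i_s)
        errors = [
            (s, s.label, base_preds.predictions[s.section_id])
            for s in i_s.sections
            if base_preds.predictions[s.section_id] != s.label
        ]
        if errors:
            instructions = build_error_instructions(errors, phrase_bank=bank)
        else:
            instructions = None
        (outdir / "error_instructions.txt").write_text(
            (instructions or "(no errors observed)") + "\n", encoding="utf-8"
        )
        instructed_acc = None
        if instructions:
            inst_preds, _ = classify_sections(
                best_backend, best_template, i_s, error_instructions=instructions
            )
            instructed_acc = selection_accuracy(inst_preds, i_s)
        candidates = {row["strategy"]: row["accuracy"] for row in fewshot_rows}
        if instructed_acc is not None:
            candidates["error_instructions"] = instructed_acc
        final_strategy = max(candidates, key=lambda k: (candidates[k], k == "error_instructions"))
        _write_json(
            outdir / "prompt_improvement.json",
            {"candidates": candidates, "chosen": final_strategy},
        )
        stages_done.append(stage)

        # -- baselines --------------------------------------------------------
        stage = "train_baselines"
        trees = train_boosted_trees(corpus_i, seed=config.seed + 30)
        trees.cv_results.to_csv(outdir / "trees_cv_results.csv", index=False)
        net = train_attention_net(
            corpus_i,
            AttentionNetConfig(epochs=config.net_epochs, max_len=config.net_max_len),
            seed=config.seed + 31,
        )
        stages_done.append(stage)

        # -- classify the test analog ----------------------------------------
        stage = "classify_test"
        fewshot = strategies.get(final_strategy)
        llm_preds, llm_log = classify_sections(
            best_backend,
            best_template,
            corpus_ii,
            fewshot=fewshot,
            error_instructions=instructions if final_strategy == "error_instructions" else None,
            model_name="llm",
        )
        with open(outdir / "llm_verdicts.jsonl", "w", encoding="utf-8") as fh:
            for rec in llm_log:
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
        trees_preds = predict_labels(trees, corpus_ii, model_name="boosted_trees")
        net_preds = predict_labels(net, corpus_ii, model_name="attention_net")
        ens_preds = majority_vote([llm_preds, net_preds, trees_preds])
        for p in (llm_preds, trees_preds, net_preds, ens_preds):
            p.to_csv(outdir / f"predictions_{p.model_name}.csv")
        stages_done.append(stage)

        # -- evaluation -------------------------------------------------------
        stage = "evaluate"
        metrics = {}
        for p in (llm_preds, net_preds, trees_preds, ens_preds):
            report = bootstrap_cis(
                p,
                corpus_ii,
                B=config.bootstrap_B,
                seed=config.seed + 40,
                by_patient=config.patient_bootstrap,
            )
            metrics[p.model_name] = report.as_dict()
        tests = {
            p.model_name: {
                m: {"t": t, "p": pv}
                for m, (t, pv) in paired_metric_test(
                    ens_preds, p, corpus_ii, B=config.bootstrap_B, seed=config.seed + 41
                ).items()
            }
            for p in (llm_preds, net_preds, trees_preds)
        }
        _write_json(outdir / "metrics.json", {"metrics": metrics, "paired_vs_ensemble": tests})
        stages_done.append(stage)

        # -- interpretation ---------------------------------------------------
        stage = "interpret"
        tables = [
            llm_keywords(llm_log),
            attention_keywords(net, corpus_ii),
            gain_keywords(trees),
        ]
        report = merge_keyword_report(tables, lexicon)
        report.to_csv(outdir / "keywords.tsv", sep="\t", index=False)
        (outdir / "keyword_table.txt").write_text(
            render_keyword_table(report) + "\n", encoding="utf-8"
        )
        stages_done.append(stage)

        # -- error overlap ----------------------------------------------------
        stage = "overlap"
        sets = error_sets([llm_preds, net_preds, trees_preds], corpus_ii)
        counts = overlap_counts(sets)
        _write_json(
            outdir / "overlap.json",
            {
                "models": list(sets),
                "counts": asdict(counts),
                "mutual_error_pct": mutual_error_fraction(counts),
            },
        )
        plot_venn(counts, labels=list(sets), path=outdir / "venn.svg")
        stages_done.append(stage)

        # -- manifest ---------------------------------------------------------
        stage = "manifest"
        cfg_dict = config.to_dict()
        cfg_hash = hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode("utf-8")
        ).hexdigest()
        try:
            pkg_version = _pkg_version("cognote")
        except Exception:  # pragma: no cover
            pkg_version = "unknown"
        _write_json(
            outdir / "manifest.json",
            {
                "config": cfg_dict,
                "config_sha256": cfg_hash,
                "package_version": pkg_version,
                "stages": stages_done + [stage],
                "chosen_backend": best_backend.name,
                "chosen_template": best_template.template_id,
                "final_prompt_strategy": final_strategy,
            },
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


_REPORT_ARTIFACTS = {
    "dataset_characteristics.csv": "dataset characteristics table",
    "metrics.json": "metrics table",
    "keyword_table.txt": "keyword table",
    "overlap.json": "overlap summary",
}


def _format_metrics_table(metrics: dict) -> str:
    header = f"{'model':<16}" + "".join(
        f"{m:>24}" for m in ("precision", "recall", "f1", "specificity", "npv", "accuracy")
    )
    lines = [header, "-" * len(header)]
    for model, rep in metrics.items():
        cells = []
        for m in ("precision", "recall", "f1", "specificity", "npv", "accuracy"):
            v = rep.get(m)
            ci = rep.get("cis", {}).get(m)
            if v is None:
                cells.append(f"{'undefined':>24}")
            elif ci:
                cells.append(f"{100 * v:9.1f}% [{100 * ci[0]:5.1f}-{100 * ci[1]:5.1f}%]")
            else:
                cells.append(f"{100 * v:23.1f}%")
        lines.append(f"{model:<16}" + "".join(cells))
    return "\n".join(lines)


def render_report(run_dir: str | Path) -> str:
    """Assemble the human-readable run report; write it as report.txt.

    Raises ``FileNotFoundError`` listing every missing artefact by name.
    """
    run_dir = Path(run_dir)
    missing = [name for name in _REPORT_ARTIFACTS if not (run_dir / name).exists()]
    if missing:
        raise FileNotFoundError(f"missing artefacts in {run_dir}: {missing}")
    parts = []
    chars = pd.read_csv(run_dir / "dataset_characteristics.csv")
    parts.append("## Dataset characteristics\n" + chars.to_string(index=False))
    payload = json.loads((run_dir / "metrics.json").read_text())
    parts.append("## Model evaluation\n" + _format_metrics_table(payload["metrics"]))
    parts.append("## Keywords\n" + (run_dir / "keyword_table.txt").read_text().rstrip())
    ov = json.loads((run_dir / "overlap.json").read_text())
    c = ov["counts"]
    parts.append(
        "## Error overlap\n"
        f"models: {', '.join(ov['models'])}\n"
        f"per-model errors: {c['a']}, {c['b']}, {c['c']}\n"
        f"pairwise overlaps (incl. triple): {c['ab']}, {c['ac']}, {c['bc']}\n"
        f"triple overlap: {c['abc']}; union: {c['union']}\n"
        f"mutual error fraction: {ov['mutual_error_pct']}%"
    )
    report = "\n\n".join(parts) + "\n"
    (run_dir / "report.txt").write_text(report, encoding="utf-8")
    return report
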