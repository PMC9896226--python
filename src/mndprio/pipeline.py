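"""Pipeline orchestration: validate → longlist → score → rank → preclinical → shortlist.

:func:`run_pipeline` is a pure function of the corpus files and the run
configuration: repeated runs write identical outputs.  It produces
``ranking.csv`` (the ranked drug scores), ``summary.csv`` (per-disease
publication/participant counts), ``preclinical.csv`` and
``preclinical_summary.csv`` (study-level LogMSR and per-drug aggregates),
``decisions.csv`` (shortlisting audit, when inputs are supplied),
``report.md`` (human-readable ranked list and survival table) and
``manifest.json`` (config echo, record counts and stage timings).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .eligibility import longlist_table
from .io import load_corpus, validate_corpus
from .preclinical import study_table, summary_table
from .prioritize import disease_summary, rank_corpus, round_half_up
from .records import Corpus
from .scoring import score_corpus
from .shortlist import decisions_table, read_shortlist_inputs, run_round

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("mndprio")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    corpus_dir: str
    out_dir: str
    shortlist_inputs: str | None = None
    shortlist_round: int = 1
    score_digits: int = 2
    logmsr_digits: int = 4
    tie_break: str = "alphabetical"
    supportive_min_positive: int = 1
    seed: int | None = None  # only used by the simulate subcommand

    def __post_init__(self) -> None:
        if self.score_digits < 0 or self.logmsr_digits < 0:
            raise ValueError("rounding digits must be ≥ 0")
        if self.tie_break != "alphabetical":
            raise ValueError(f"unknown tie-break rule {self.tie_break!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a JSON or YAML config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _report(ranking: pd.DataFrame, pre: pd.DataFrame, digits: int, logmsr_digits: int) -> str:
    lines = ["# Drug prioritisation report", "", "## Ranked interventions", ""]
    cols = ["rank", "intervention", "n_publications", "quality", "efficacy",
            "safety", "study_size", "drug_score"]
    lines.append("| " + " | ".join(cols) + " |")
    lines.append("|" + "---|" * len(cols))
    for _, row in ranking.iterrows():
        cells = [
            str(int(row["rank"])),
            str(row["intervention"]),
            str(int(row["n_publications"])),
            *(f"{round_half_up(row[c], digits):g}" for c in
              ("quality", "efficacy", "safety", "study_size", "drug_score")),
        ]
        lines.append("| " + " | ".join(cells) + " |")
    lines += ["", "## Preclinical survival studies", ""]
    pcols = ["study_id", "drug", "n_animals", "median_survival_treated",
             "median_survival_control", "logmsr"]
    lines.append("| " + " | ".join(pcols) + " |")
    lines.append("|" + "---|" * len(pcols))
    for _, row in pre.iterrows():
        lines.append(
            "| " + " | ".join(
                [str(row["study_id"]), str(row["drug"]), str(int(row["n_animals"])),
                 f"{row['median_survival_treated']:g}",
                 f"{row['median_survival_control']:g}",
                 f"{row['logmsr']:.{logmsr_digits}f}"]
            ) + " |"
        )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, corpus: Corpus | None = None) -> dict[str, Path]:
    """Run every stage in order and write the report bundle.

    Any stage failure raises :class:`PipelineError` naming the stage.
    Returns the mapping of output names to written paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, Path] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                logger.info("stage %s: done in %.3fs", name, timings[name])

        return _Timer()

    with stage("load"):
        if corpus is None:
            corpus = load_corpus(config.corpus_dir, strict=False)

    with stage("validate"):
        issues = validate_corpus(corpus)
        if issues:
            raise PipelineError(
                "validate", f"{len(issues)} issue(s): " + "; ".join(str(i) for i in issues[:10])
            )

    with stage("longlist"):
        ll = longlist_table(corpus)
        eligible = list(ll.loc[ll["eligible"], "drug"])
        outputs["longlist"] = out / "longlist.csv"
        ll.to_csv(outputs["longlist"], index=False, lineterminator="\n")

    with stage("score"):
        scores = score_corpus(corpus)
        outputs["scores"] = out / "scores.csv"
        scores.to_csv(outputs["scores"], lineterminator="\n")

    with stage("rank"):
        ranking = rank_corpus(corpus, drugs=eligible, scores=scores)
        report_ranking = ranking.copy()
        for col in ("quality", "efficacy", "safety", "study_size", "drug_score"):
            report_ranking[col] = [
                round_half_up(v, config.score_digits) for v in report_ranking[col]
            ]
        outputs["ranking"] = out / "ranking.csv"
        report_ranking.to_csv(outputs["ranking"], index=False, lineterminator="\n")

    with stage("summary"):
        summary = disease_summary(corpus, drugs=eligible)
        outputs["summary"] = out / "summary.csv"
        summary.to_csv(outputs["summary"], index=False, lineterminator="\n")

    with stage("preclinical"):
        pre = study_table(corpus, digits=config.logmsr_digits)
        outputs["preclinical"] = out / "preclinical.csv"
        pre.to_csv(outputs["preclinical"], index=False, lineterminator="\n")
        pre_summary = summary_table(corpus, min_positive=config.supportive_min_positive)
        outputs["preclinical_summary"] = out / "preclinical_summary.csv"
        pre_summary.to_csv(outputs["preclinical_summary"], index=False, lineterminator="\n")

    if config.shortlist_inputs:
        with stage("shortlist"):
            inputs = read_shortlist_inputs(config.shortlist_inputs)
            decisions, _ = run_round(inputs, round_id=config.shortlist_round)
            outputs["decisions"] = out / "decisions.csv"
            decisions_table(decisions).to_csv(
                outputs["decisions"], index=False, lineterminator="\n"
            )

    with stage("report"):
        outputs["report"] = out / "report.md"
        outputs["report"].write_text(
            _report(ranking, pre, config.score_digits, config.logmsr_digits)
        )
        manifest = {
            "package_version": __version__,
            "config": asdict(config),
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True).encode()
            ).hexdigest(),
            "record_counts": {
                "publications": int(len(corpus.publications)),
                "outcomes": int(len(corpus.outcomes)),
                "quality": int(len(corpus.quality)),
                "preclinical": int(len(corpus.preclinical)),
                "longlisted_drugs": len(eligible),
            },
            "stage_timings_s": timings,
        }
        outputs["manifest"] = out / "manifest.json"
        outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return outputs
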