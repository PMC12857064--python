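"""End-to-end pipeline: ingest -> dedup -> flag -> filter -> score -> report.

Stage order mirrors the standard spontaneous-report cleaning flow: raw
tables, deduplication (one record per case), reporter filter, target
event selection, drug-name consolidation, minimum-case filter,
four-algorithm scoring, criteria evaluation and ranking, then the
onset and covariate analyses.  Every run writes a JSON manifest with
input checksums, the record counts surviving each stage, a config echo
and package versions; identical config and seed give identical outputs
(timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .dispro import contingency_by_drug, results_frame
from .io import (
    FaersTables,
    deduplicate,
    filter_reporters,
    harmonize,
    read_tables,
)
from .onset import (
    AnalysisError,
    anova_classes,
    build_covariate_rows,
    compute_onsets,
    cumulative_onset_curve,
    fit_logistic,
    summarize_onsets,
)
from .signals import (
    SIGNALS_COLUMN_ORDER,
    SignalCriteria,
    apply_min_case_filter,
    evaluate,
    rank_and_annotate,
)
from .synthetic import SyntheticConfig, generate
from .terms import DrugSynonymTable, TermSet, flag_target_events, normalize_drugs

logger = logging.getLogger(__name__)

__all__ = ["InputPaths", "OnsetOptions", "LogisticOptions", "RunConfig", "RunResult", "run"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and suggests a remedy."""


class InputPaths(BaseModel):
    demo: Path
    drug: Path
    reac: Path
    ther: Path
    delimiter: str = "$"


class OnsetOptions(BaseModel):
    enabled: bool = True
    group: str = "drug_class"


class LogisticOptions(BaseModel):
    enabled: bool = False
    top_k: int = Field(ge=1, default=20)


class RunConfig(BaseModel):
    """Declarative configuration of one pipeline run (YAML-loadable)."""

    inputs: InputPaths | None = None
    synthetic: SyntheticConfig | None = None
    allowed_reporters: list[str] = Field(
        default_factory=lambda: ["physician", "pharmacist", "other-health-professional"]
    )
    smq_terms: Path | None = None
    drug_synonyms: Path | None = None
    criteria: SignalCriteria = Field(default_factory=SignalCriteria)
    onset: OnsetOptions = Field(default_factory=OnsetOptions)
    logistic: LogisticOptions = Field(default_factory=LogisticOptions)
    sort_by: str = "ror"
    output_dir: Path = Path("pvsignals-out")
    seed: int | None = None

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'inputs' or 'synthetic' must be configured")
        if self.inputs is not None:
            if self.smq_terms is None:
                raise ValueError("'smq_terms' path is required when reading input tables")
            if self.drug_synonyms is None:
                raise ValueError("'drug_synonyms' path is required when reading input tables")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


@dataclass
class RunResult:
    output_dir: Path
    manifest: dict
    signals: pd.DataFrame


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; returns the manifest and ranked signals."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pvsignals")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    counts: dict[str, int] = {}
    checksums: dict[str, str] = {}
    try:
        # ---- stage: acquire tables -------------------------------------
        if config.synthetic is not None:
            syn_cfg = config.synthetic
            if config.seed is not None:
                syn_cfg = syn_cfg.model_copy(update={"seed": config.seed})
            data = generate(syn_cfg)
            tables = data.tables
            table_paths = data.write(outdir / "tables")
            terms = (
                TermSet.from_file(config.smq_terms)
                if config.smq_terms is not None
                else TermSet.from_terms(
                    "synthetic-target-smq", "narrow",
                    [e.pt for e in syn_cfg.event_vocab if e.smq_narrow],
                )
            )
            synonyms = (
                DrugSynonymTable.from_file(config.drug_synonyms)
                if config.drug_synonyms is not None
                else DrugSynonymTable.from_vocab(syn_cfg.drug_vocab)
            )
            synonyms.to_frame().to_csv(outdir / "drug_synonyms.tsv", sep="\t", index=False)
            pd.DataFrame({"smq": terms.name, "scope": terms.scope, "pt": sorted(terms.terms)}).to_csv(
                outdir / "smq_terms.tsv", sep="\t", index=False
            )
            for name, p in table_paths.items():
                if isinstance(p, Path) and p.is_file():
                    checksums[name] = _sha256(p)
        else:
            paths = config.inputs
            tables = read_tables(
                paths.demo, paths.drug, paths.reac, paths.ther, delimiter=paths.delimiter
            )
            terms = TermSet.from_file(config.smq_terms)
            synonyms = DrugSynonymTable.from_file(config.drug_synonyms)
            for name in ("demo", "drug", "reac", "ther"):
                checksums[name] = _sha256(Path(getattr(paths, name)))
        counts["raw_records"] = len(tables.demo)
        counts["malformed_rows"] = int(sum(tables.malformed.values()))

        # ---- stage: harmonize + dedup + reporter filter ----------------
        reports, exposures, events = harmonize(tables)
        deduped = deduplicate(reports)
        counts["deduplicated"] = len(deduped)
        kept = filter_reporters(deduped, config.allowed_reporters)
        counts["after_reporter_filter"] = len(kept)
        kept_ids = set(kept["record_id"])
        exposures = exposures.loc[exposures["record_id"].isin(kept_ids)]
        events = events.loc[events["record_id"].isin(kept_ids)]

        # ---- stage: event flagging + drug consolidation ----------------
        flagged = flag_target_events(events, terms)
        counts["flagged_reports"] = len(flagged)
        exposures, n_unmapped = normalize_drugs(exposures, synonyms)
        counts["unmapped_drug_mentions"] = n_unmapped

        # ---- stage: contingency + min-case filter + scoring ------------
        tables_2x2 = contingency_by_drug(
            exposures, flagged, n_reports=len(kept)
        )
        counts["pairs_total"] = len(tables_2x2)
        tables_2x2, n_removed = apply_min_case_filter(tables_2x2, config.criteria.min_cases)
        counts["pairs_tested"] = len(tables_2x2)
        counts["pairs_below_min_cases"] = n_removed

        scored = results_frame(tables_2x2)
        evaluated = evaluate(scored, config.criteria)
        ranked = rank_and_annotate(
            evaluated, classes=dict(synonyms.classes), sort_by=config.sort_by
        )
        counts["positives"] = int(ranked["positive"].sum())

        out_signals = ranked.reset_index()[
            [c for c in SIGNALS_COLUMN_ORDER if c in ranked.reset_index().columns]
        ]
        out_signals.to_csv(outdir / "signals.csv", index=False)
        forest = ranked.loc[:, ["ror", "ror_ci_low", "ror_ci_high"]].reset_index()
        forest.to_csv(outdir / "forest.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(
            f"scoring stages failed ({exc}); check table dialect, term and synonym files"
        ) from exc

    anova: dict | None = None
    try:
        # ---- stage: onset analysis -------------------------------------
        if config.onset.enabled:
            onsets, onset_tally = compute_onsets(exposures, kept, flagged)
            counts["onset_records"] = len(onsets)
            counts.update({f"onset_excluded_{k}": v for k, v in onset_tally.items()})
            summarize_onsets(onsets, group=config.onset.group).to_csv(
                outdir / "onset_summary.csv"
            )
            cumulative_onset_curve(onsets, group=config.onset.group).to_csv(
                outdir / "onset_curve.csv", index=False
            )
            try:
                anova = anova_classes(onsets, group=config.onset.group)
            except AnalysisError as exc:
                logger.info("ANOVA skipped: %s", exc)

        # ---- stage: covariate model ------------------------------------
        if config.logistic.enabled:
            top = (
                ranked.loc[ranked["positive"]]
                .sort_values("a", ascending=False, kind="mergesort")
                .index[: config.logistic.top_k]
                .tolist()
            )
            if top:
                rows = build_covariate_rows(kept, exposures, flagged, top)
                try:
                    fit_logistic(rows).to_csv(outdir / "logistic.csv")
                except AnalysisError as exc:
                    logger.info("logistic model skipped: %s", exc)
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(
            f"onset/covariate stage failed ({exc}); disable it in the config to bypass"
        ) from exc

    import numpy as _np
    import scipy as _scipy

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed if config.seed is not None else (
            config.synthetic.seed if config.synthetic else None
        ),
        "input_checksums": checksums,
        "stage_counts": counts,
        "anova": anova,
        "versions": {
            "pvsignals": __version__,
            "pandas": pd.__version__,
            "numpy": _np.__version__,
            "scipy": _scipy.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    root.removeHandler(handler)
    handler.close()
    return RunResult(output_dir=outdir, manifest=manifest, signals=ranked)
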