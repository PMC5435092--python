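"""End-to-end pipeline: read → quality filter → episodes → prevalence →
co-occurrence → remission, with a run log and diff-clean outputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import comorbidity as com
from . import episodes as eng
from . import prevalence as prev
from .config import PipelineConfig
from .definitions import default_definitions, load_definitions
from .errors import PipelineStageError
from .io import read_dataset
from .quality import attrition_report, select_children


@dataclass
class RunLog:
    """One summary record per pipeline stage."""

    config_hash: str
    records: list[dict] = field(default_factory=list)

    def add(self, stage: str, rows_in: int, rows_out: int) -> None:
        self.records.append(
            {
                "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
                "stage": stage,
                "rows_in": rows_in,
                "rows_out": rows_out,
                "config_hash": self.config_hash,
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


def _config_hash(config: PipelineConfig) -> str:
    blob = config.model_dump_json().encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns the manifest of written outputs.

    Any stage failure is re-raised as :class:`PipelineStageError` with
    the stage name attached.  Outputs are written with fixed precision
    so identical runs produce identical bytes.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog(_config_hash(config))
    manifest: dict[str, Path] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and propagate
            raise PipelineStageError(name, exc) from exc

    dataset = stage("read", read_dataset, config.input_dir)
    log.add("read", 0, sum(len(t) for t in dataset.tables().values()))

    selection = stage(
        "filter",
        select_children,
        dataset,
        config.study_window,
        config.min_followup_days,
        config.strict_quality,
    )
    log.add("filter", len(dataset.patients), selection.final_count)
    attrition = attrition_report(selection)
    path = out_dir / "attrition.csv"
    attrition.to_csv(path, index=False, float_format="%.1f")
    manifest["attrition"] = path

    definitions = (
        load_definitions(config.definitions_path)
        if config.definitions_path
        else default_definitions()
    )
    validated = stage(
        "episodes",
        eng.validate_episodes,
        dataset,
        selection.included_ids,
        config.strategies,
        definitions,
        config.study_window,
        strict_contacts=config.strict_contacts,
        rx_window_days=config.rx_window_days,
    )
    log.add("episodes", len(dataset.episodes), len(validated))
    vout = validated.copy()
    for col in ("effective_start", "effective_end"):
        vout[col] = pd.to_datetime(vout[col]).dt.strftime("%Y-%m-%d")
    path = out_dir / "validated_episodes.csv"
    # header flag documents the permissive missing-closing-date reading
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# open episodes (no recorded closing date) run to follow-up end\n")
        vout.to_csv(fh, index=False)
    manifest["validated_episodes"] = path

    cohort_patients = dataset.patients[
        dataset.patients["patient_id"].isin(selection.included_ids)
    ]
    tables = []
    for strategy in config.strategies:
        tables.append(
            stage(
                "prevalence",
                prev.point_prevalence,
                cohort_patients,
                validated,
                strategy,
                config.study_window,
                config.pool_years,
            )
        )
    prevalence = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    log.add("prevalence", len(validated), len(prevalence))
    path = out_dir / "prevalence.csv"
    prevalence.to_csv(path, index=False, float_format="%.2f")
    manifest["prevalence"] = path

    if 2 in config.strategies:
        statuses = stage("comorbidity", com.period_case_status, validated, 2)
        full = {
            pid: statuses.get(pid, frozenset()) for pid in selection.included_ids
        }
        venn = com.venn_counts(full)
        stats = com.cooccurrence_stats(venn)
        rows = [{"metric": k, "value": v} for k, v in venn.as_dict().items()]
        rows += [
            {"metric": f"marginal_{d}", "value": venn.marginal(d)}
            for d in ("eczema", "asthma", "rhinitis")
        ]
        rows += [
            {"metric": "observed_triad_proportion", "value": round(stats.observed_triad, 6)},
            {"metric": "expected_triad_proportion", "value": round(stats.expected_triad, 6)},
            {"metric": "fold_enrichment", "value": round(stats.fold, 2)},
            {"metric": "fold_enrichment_rounded", "value": stats.fold_rounded},
        ]
        path = out_dir / "comorbidity.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        manifest["comorbidity"] = path
        log.add("comorbidity", selection.final_count, len(rows))

    if 2 in config.strategies and 4 in config.strategies and len(prevalence):
        s2 = prevalence[prevalence["strategy"] == 2]
        s4 = prevalence[prevalence["strategy"] == 4]
        remission = com.remission_table(s2, s4, config.remission_ages)
        path = out_dir / "remission.csv"
        remission.to_csv(path, index=False, float_format="%.1f")
        manifest["remission"] = path
        log.add("remission", len(s2), len(remission))

    log_path = out_dir / "runlog.jsonl"
    log.write(log_path)
    manifest["runlog"] = log_path
    return manifest
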