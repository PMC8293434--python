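"""End-to-end orchestration: read -> filter -> enrich -> score -> phospho-classify.

One YAML config drives a run.  Outputs are deterministic (scores sorted by
score descending then accession; categories and quadrants from fixed
thresholds) so re-running an identical config on identical inputs produces
byte-identical result tables.

Config schema (all thresholds optional, defaults shown)::

    experiments:                 # pull-down experiments for enrichment scoring
      - label: exp1
        protein_groups: exp1.tsv
        dialect: {...}           # optional ProteinGroupDialect overrides
    psm:                         # optional: spectral-count differential analysis
      path: psm.tsv
      bait_id: E9Q401
      dialect: {...}             # optional PsmDialect overrides
    bait_id: E9Q401
    thresholds:
      floor: 50000.0             # background intensity imputed for zeros
      cutoff: 1.5                # enrichment ratio cutoff
      min_unique: 3              # unique peptides (LFQ path)
      min_psm: 5                 # max-over-conditions PSM (spectral path)
      min_peptides: 2
      quadrant_threshold: 1.0
      min_score_quadrant: 2      # quadrant analysis restricted to score >= this
      pseudo: 0.0
    normalization: wt_bait       # or per_sample_bait
    outdir: results/
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .enrichment_scoring import (
    DEFAULT_CUTOFF,
    DEFAULT_FLOOR,
    EnrichmentRecord,
    ScoreRecord,
    score_experiments,
)
from .errors import ConfigurationError, DataError
from .phospho_differential import PhosphoRecord, phospho_analysis
from .qc_filtering import (
    DEFAULT_IG_PATTERNS,
    DEFAULT_KERATIN_PATTERNS,
    FilterReport,
    filter_flags,
    filter_ig_keratin,
    filter_min_unique_peptides,
    filter_psm_threshold,
)
from .tables_io import (
    ProteinGroupDialect,
    PsmDialect,
    read_protein_groups,
    read_psm_table,
    write_results,
)

logger = logging.getLogger("ryr2apms")

__all__ = ["RunConfig", "SummaryCounts", "Thresholds", "run_pipeline", "summarize_counts"]


@dataclass
class Thresholds:
    floor: float = DEFAULT_FLOOR
    cutoff: float = DEFAULT_CUTOFF
    min_unique: int = 3
    min_psm: int = 5
    min_peptides: int = 2
    quadrant_threshold: float = 1.0
    min_score_quadrant: int = 2
    pseudo: float = 0.0


@dataclass
class ExperimentInput:
    label: str
    protein_groups: str
    dialect: ProteinGroupDialect = field(default_factory=ProteinGroupDialect)


@dataclass
class PsmInput:
    path: str
    bait_id: str
    dialect: PsmDialect = field(default_factory=PsmDialect)


@dataclass
class RunConfig:
    experiments: list[ExperimentInput] = field(default_factory=list)
    psm: PsmInput | None = None
    bait_id: str = ""
    thresholds: Thresholds = field(default_factory=Thresholds)
    normalization: str = "wt_bait"
    ig_patterns: tuple[str, ...] = DEFAULT_IG_PATTERNS
    keratin_patterns: tuple[str, ...] = DEFAULT_KERATIN_PATTERNS
    outdir: str = "results"
    seed: int | None = None

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        experiments = []
        for entry in data.pop("experiments", []) or []:
            entry = dict(entry)
            dialect = ProteinGroupDialect.from_dict(entry.pop("dialect", {}) or {})
            experiments.append(ExperimentInput(dialect=dialect, **entry))
        psm_raw = data.pop("psm", None)
        psm = None
        if psm_raw:
            psm_raw = dict(psm_raw)
            psm_dialect = PsmDialect.from_dict(psm_raw.pop("dialect", {}) or {})
            psm = PsmInput(dialect=psm_dialect, **psm_raw)
        thresholds = Thresholds(**(data.pop("thresholds", {}) or {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(experiments=experiments, psm=psm, thresholds=thresholds, **data)
        if cfg.normalization not in ("wt_bait", "per_sample_bait"):
            raise ConfigurationError(
                f"unknown normalization mode {cfg.normalization!r}"
            )
        if not cfg.bait_id and cfg.psm is not None:
            cfg.bait_id = cfg.psm.bait_id
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigurationError(f"config root must be a mapping: {path}")
        return cls.from_dict(raw)


@dataclass(frozen=True)
class SummaryCounts:
    """Headline tallies of one run (bait excluded everywhere)."""

    n_identified: int
    n_both_enriched: int
    n_igg_only: int
    n_beads_only: int
    n_scored: int
    per_score: dict[str, int]        # keys "1".."6"
    n_high_confidence: int
    n_quadrant: dict[str, int]

    def check(self) -> None:
        if sum(self.per_score.values()) != self.n_scored:
            raise DataError("per-score counts do not sum to n_scored")
        high = sum(v for k, v in self.per_score.items() if int(k) >= 3)
        if high != self.n_high_confidence:
            raise DataError("high-confidence count inconsistent with per-score counts")


def summarize_counts(
    scores: Sequence[ScoreRecord],
    primary_enrichment: Sequence[EnrichmentRecord],
    phospho: Sequence[PhosphoRecord],
    bait_id: str = "",
) -> SummaryCounts:
    """Tally the run's headline counts.

    Enrichment-category counts are taken from the designated primary
    experiment; ``n_scored`` counts proteins with score >= 1 across all
    experiments; quadrant counts cover records with a defined quadrant.
    The bait never contributes to any count.
    """
    cats = [r.category for r in primary_enrichment if r.protein_id != bait_id]
    nonzero = [s for s in scores if s.protein_id != bait_id and s.score > 0]
    per_score = {str(k): 0 for k in range(1, 7)}
    for s in nonzero:
        per_score[str(s.score)] += 1
    quadrant_counts: dict[str, int] = {}
    for rec in phospho:
        if rec.protein_id == bait_id or not rec.quadrant:
            continue
        quadrant_counts[rec.quadrant] = quadrant_counts.get(rec.quadrant, 0) + 1
    summary = SummaryCounts(
        n_identified=len(cats),
        n_both_enriched=cats.count("both_enriched"),
        n_igg_only=cats.count("igg_only"),
        n_beads_only=cats.count("beads_only"),
        n_scored=len(nonzero),
        per_score=per_score,
        n_high_confidence=sum(1 for s in nonzero if s.score >= 3),
        n_quadrant=quadrant_counts,
    )
    summary.check()
    return summary


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _qc_protein_groups(table, config: RunConfig, label: str):
    reports = []
    for name, fn in (
        ("flags", filter_flags),
        ("ig_keratin", lambda t: filter_ig_keratin(
            t, config.ig_patterns, config.keratin_patterns)),
        ("min_unique_peptides", lambda t: filter_min_unique_peptides(
            t, config.thresholds.min_unique)),
    ):
        table, report = fn(table)
        logger.info("%s/%s: removed %d, kept %d", label, report.rule_name,
                    len(report.removed_ids), report.kept_count)
        reports.append((label, report))
    return table, reports


def run_pipeline(config: RunConfig) -> SummaryCounts:
    """Execute the full pipeline and write all result files to ``config.outdir``.

    Outputs: ``enrichment.tsv`` (per-experiment classified ratios),
    ``scores.tsv``, ``phospho.tsv``, ``summary.json``, ``manifest.json``,
    ``audit_filters.tsv``.  On any stage error, files written so far are
    removed before the exception propagates.
    """
    if not config.experiments and config.psm is None:
        raise ConfigurationError("config names neither experiments nor a PSM table")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        audit: list[tuple[str, FilterReport]] = []

        # --- LFQ path: read, QC, enrich, score --------------------------------
        filtered = []
        for exp in config.experiments:
            table = read_protein_groups(exp.protein_groups, exp.dialect)
            table, reports = _qc_protein_groups(table, config, exp.label)
            audit.extend(reports)
            filtered.append((exp.label, table))

        per_exp: dict[str, list[EnrichmentRecord]] = {}
        scores: list[ScoreRecord] = []
        if filtered:
            per_exp, scores = score_experiments(
                filtered,
                bait_id=config.bait_id,
                floor=config.thresholds.floor,
                cutoff=config.thresholds.cutoff,
            )
            frames = []
            for label, records in per_exp.items():
                frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
                frame.insert(0, "experiment", label)
                frame["imputed_channels"] = frame["imputed_channels"].map(
                    lambda t: json.dumps(list(t)))
                frames.append(frame)
            pd.concat(frames, ignore_index=True).to_csv(
                _out("enrichment.tsv"), sep="\t", index=False)
            write_results(scores, _out("scores.tsv"), record_cls=ScoreRecord)

        # --- spectral-count path: QC, normalize, quadrants --------------------
        phospho: list[PhosphoRecord] = []
        if config.psm is not None:
            psm_table = read_psm_table(
                config.psm.path, config.psm.dialect, bait_id=config.psm.bait_id)
            psm_table, report = filter_psm_threshold(
                psm_table, config.thresholds.min_psm, config.thresholds.min_peptides)
            audit.append(("psm", report))
            records = phospho_analysis(
                psm_table,
                mode=config.normalization,
                pseudo=config.thresholds.pseudo,
                threshold=config.thresholds.quadrant_threshold,
            )
            if scores:
                eligible = {s.protein_id for s in scores
                            if s.score >= config.thresholds.min_score_quadrant}
                records = [r for r in records if r.protein_id in eligible]
            phospho = sorted(records, key=lambda r: r.protein_id)
            write_results(phospho, _out("phospho.tsv"), record_cls=PhosphoRecord)

        # --- summaries and manifests ------------------------------------------
        primary = per_exp[config.experiments[0].label] if per_exp else []
        summary = summarize_counts(scores, primary, phospho, bait_id=config.bait_id)
        with open(_out("summary.json"), "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(summary), fh, indent=1)
            fh.write("\n")

        audit_rows = [
            {"experiment": label, "rule_name": rep.rule_name,
             "n_removed": len(rep.removed_ids), "kept_count": rep.kept_count,
             "removed_ids": json.dumps(list(rep.removed_ids))}
            for label, rep in audit
        ]
        pd.DataFrame(
            audit_rows,
            columns=["experiment", "rule_name", "n_removed", "kept_count", "removed_ids"],
        ).to_csv(_out("audit_filters.tsv"), sep="\t", index=False)

        manifest = {
            "package_version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "seed": config.seed,
            "config": _config_echo(config),
        }
        with open(_out("manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
            fh.write("\n")
        return summary
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["ig_patterns"] = list(config.ig_patterns)
    echo["keratin_patterns"] = list(config.keratin_patterns)
    return echo
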