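"""End-to-end orchestration: extract -> triangulate -> validate -> QA -> analyze.

Each stage persists its intermediate as a flat table or JSON/CSV so any
stage can be inspected or rerun independently, and a manifest records the
record/user counts at every stage boundary (the filtration funnel).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from tweetregion import defaults
from tweetregion.analytics import (
    CombinedTotals,
    EventWindowSpec,
    HourlySeries,
    METRICS,
    WindowSummary,
    combined_totals,
    fold_change,
    hourly_series,
    split_windows,
    window_summary,
)
from tweetregion.extraction import (
    apply_ruleset,
    compile_ruleset,
    purge_homonyms,
)
from tweetregion.ingest import (
    read_activity_stream,
    write_flat_table,
)
from tweetregion.triangulation import (
    CriterionCounts,
    RegionalCriterion,
    classify_users,
    criterion_counts,
    default_criteria,
    exclusive_share,
    timezone_table,
)
from tweetregion.validation import (
    QASample,
    ValidationReport,
    draw_sample,
    gps_validation_report,
    load_region_polygons,
    required_sample_size,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, window geometry, sampling settings, and toggles for one run."""

    corpus_path: str | Path
    output_dir: str | Path
    polygons_path: str | Path | None = None  # defaults to the shipped fixtures
    ruleset: Mapping | None = None  # term-list config; defaults shipped
    criteria: Sequence[RegionalCriterion] | None = None
    exclusions: Sequence[str] = defaults.DEFAULT_EXCLUSION_PLACES
    window: EventWindowSpec = field(default_factory=EventWindowSpec)
    confidence: float = 0.99
    moe: float = 0.03
    seed: int = 0
    qa_sample_override: int | None = None
    rt_heuristic: bool = False
    substring_compat: bool = False


@dataclass
class RunReport:
    """All computed outputs of one pipeline run plus the stage manifest."""

    manifest: dict
    assignments: list
    counts: CriterionCounts
    exclusive_shares: dict[str, float] | None
    timezones: dict
    validation: ValidationReport | None
    pre_summary: WindowSummary
    post_summary: WindowSummary
    combined: CombinedTotals
    fold_changes: dict[str, float | None]
    series: dict[str, HourlySeries]
    qa_sample: QASample | None


def _write_csv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full filtration-and-analysis flow over one corpus.

    Stage order: ingest, first-pass rule extraction, homonym purge,
    triangulation, GPS validation, QA sampling, event-window analytics.
    Every intermediate is persisted under ``config.output_dir``; the
    returned report carries the in-memory results and a manifest of stage
    counts (monotonically non-increasing through filtration).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # no wall-clock fields: reruns with the same config are byte-identical
    manifest: dict = {"stages": []}
    log_lines: list[str] = []

    def stage(name: str, count: int, unit: str = "tweets") -> None:
        # two funnels share the manifest: tweet counts and user counts are
        # each monotonically non-increasing through filtration
        manifest["stages"].append({"stage": name, "count": count, "unit": unit})
        line = f"{name}: {count} {unit}"
        log_lines.append(line)
        logger.info("%s", line)

    def _run(name, fn):
        try:
            return fn()
        except Exception as exc:  # persist partial outputs, then abort
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(name, exc) from exc

    # --- ingest -------------------------------------------------------------
    def _ingest():
        errs: list = []
        recs = read_activity_stream(
            config.corpus_path,
            rt_heuristic=config.rt_heuristic,
            errors="skip",
            error_log=errs,
        )
        return recs, errs

    records, errs = _run("ingest", _ingest)
    stage("ingested", len(records))

    polygons = _run(
        "polygons",
        lambda: load_region_polygons(
            config.polygons_path
            if config.polygons_path is not None
            else defaults.region_polygons_path()
        ),
    )

    # --- extraction + purge ---------------------------------------------------
    ruleset_cfg = config.ruleset or {
        "keywords": defaults.DEFAULT_KEYWORDS,
        "hashtags": defaults.DEFAULT_HASHTAGS,
        "bio_location_terms": defaults.STATE_CITY_TERMS
        + defaults.UNIVERSITY_TERMS
        + defaults.CHANT_TERMS
        + defaults.STATE_ABBREV_TERMS,
        "news_handles": defaults.DEFAULT_NEWS_HANDLES,
        "gps_region": "MS+AL",
    }
    ruleset = _run("compile_rules", lambda: compile_ruleset(ruleset_cfg))
    extraction = _run(
        "extract",
        lambda: apply_ruleset(
            records, ruleset, polygons, substring=config.substring_compat
        ),
    )
    stage("extracted", len(extraction.matched))
    extraction = _run(
        "purge", lambda: purge_homonyms(extraction, config.exclusions, polygons)
    )
    stage("purged", len(extraction.matched))
    write_flat_table(extraction.matched, out / "extracted.tsv")

    # --- triangulation --------------------------------------------------------
    criteria = (
        list(config.criteria) if config.criteria is not None else default_criteria()
    )
    assignments = _run(
        "triangulate",
        lambda: classify_users(
            extraction.matched, criteria, substring=config.substring_compat
        ),
    )
    regional = [a for a in assignments if a.is_regional]
    stage("users_seen", len(assignments), unit="users")
    stage("regional_users", len(regional), unit="users")
    _write_csv(
        out / "assignments.csv",
        ["user_id", "is_regional", "matched_rows"],
        [
            (a.user_id, a.is_regional, ";".join(sorted(a.matched_rows)))
            for a in assignments
        ],
    )
    counts = criterion_counts(assignments, criteria)
    _write_csv(
        out / "criterion_counts.csv",
        ["row_label", "category", "inclusive_users", "exclusive_users"],
        [
            (label, row["category"], row["inclusive_users"], row["exclusive_users"])
            for label, row in counts.rows.items()
        ],
    )
    shares = exclusive_share(counts) if counts.total_regional else None

    regional_records = [
        r
        for r in extraction.matched
        if r.user_id in {a.user_id for a in regional}
    ]
    stage("regional_tweets", len(regional_records))

    tz = timezone_table(regional, regional_records)
    _write_csv(
        out / "timezones.csv",
        ["time_zone", "users"],
        sorted(
            ((z if z is not None else "null", n) for z, n in tz.items()),
            key=lambda kv: -kv[1],
        ),
    )

    # --- GPS validation -------------------------------------------------------
    loc_criteria = [c for c in criteria if c.category == "location"]
    validation = (
        _run(
            "validate",
            lambda: gps_validation_report(
                regional, regional_records, polygons, loc_criteria
            ),
        )
        if regional
        else None
    )
    if validation is not None:
        (out / "validation.json").write_text(json.dumps(asdict(validation), indent=2))

    # --- QA sampling ----------------------------------------------------------
    qa_sample = None
    if regional:
        pop = len(regional)
        n = (
            config.qa_sample_override
            if config.qa_sample_override is not None
            else required_sample_size(pop, config.confidence, config.moe)
        )
        n = min(n, pop)
        qa_sample = _run(
            "qa_sample",
            lambda: draw_sample(
                sorted(a.user_id for a in regional), n, config.seed, "regional"
            ),
        )
        _write_csv(
            out / "qa_sample.csv", ["user_id"], [(u,) for u in qa_sample.sampled_user_ids]
        )

    # --- event-window analytics ----------------------------------------------
    pre, post, outside = split_windows(regional_records, config.window)
    pre_summary = window_summary(pre, config.window.event_time)
    post_summary = window_summary(post, config.window.event_time)
    combined = combined_totals(pre_summary, post_summary)
    folds = {}
    for name in ("tweets", "retweets", "hashtag_tweets", "gps_tweets", "users"):
        pre_v, post_v = getattr(pre_summary, name), getattr(post_summary, name)
        folds[name] = fold_change(pre_v, post_v) if pre_v else None
    series = {
        m: hourly_series(regional_records, config.window, m) for m in METRICS
    }
    for m, s in series.items():
        _write_csv(
            out / f"hourly_{m}.csv",
            ["hour_offset", "count"],
            list(zip(s.hour_offsets, s.counts)),
        )
    (out / "windows.json").write_text(
        json.dumps(
            {
                "pre": asdict(pre_summary),
                "post": asdict(post_summary),
                "combined": asdict(combined),
                "fold_changes": folds,
            },
            indent=2,
        )
    )

    manifest["ingest_errors"] = len(errs)
    manifest["purged_count"] = extraction.purged_count
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return RunReport(
        manifest=manifest,
        assignments=assignments,
        counts=counts,
        exclusive_shares=shares,
        timezones=tz,
        validation=validation,
        pre_summary=pre_summary,
        post_summary=post_summary,
        combined=combined,
        fold_changes=folds,
        series=series,
        qa_sample=qa_sample,
    )
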