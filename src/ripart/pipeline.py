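"""End-to-end pipeline: screen -> clean -> segment -> verify -> estimate.

Ties the stages into one reproducible run driven by a RunConfig (YAML or
JSON): read the cohort CSV, apply laboratory exclusion, clean each
(analyte, age-bin) sample with the Dixon test, build the ordered percentile
matrix, run Fisher segmentation with the f(k) class-count rule, verify and
merge candidate cuts with the Harris-Boyd Z criterion, test for sex
differences inside each final range, and emit the reference-interval table.

Every artifact is plain text with deterministic ordering and formatting, so
identical (config, seed) runs produce byte-identical bundles; the run log
records seed, versions and every decision (outliers removed, merges, sex
splits) without timestamps.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .intervals import ReferenceInterval, build_ri_table
from .partition import MergeOutcome, SexSplitResult, merge_adjacent, sex_split_test
from .preprocess import (
    AGE_BINS,
    OrderedSampleMatrix,
    build_matrix,
    dixon_outlier_removal,
    nondimensionalize,
)
from .screening import ExclusionCriteria, SubjectRecord, apply_exclusion, read_cohort
from .segmentation import SegmentationResult, optimal_segmentation

__all__ = [
    "RunConfig",
    "AnalyteResult",
    "PipelineResult",
    "load_run_config",
    "clean_analyte",
    "segment_analyte",
    "candidate_ranges",
    "run_pipeline",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    input: str
    analytes: tuple[str, ...]
    outdir: str
    mode: str = "percentile"      # "percentile" | "summary"
    k_max: int = 6
    tolerance: float = 0.05
    exclusion: bool = True
    sex_test: bool = True
    seed: int = 0
    detection_limit: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if not (0.0 < self.tolerance < 1.0):
            raise ValueError("tolerance must be in (0, 1)")
        if self.mode not in ("percentile", "summary"):
            raise ValueError(f"unknown mode {self.mode!r}")


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return RunConfig(
        input=data["input"],
        analytes=tuple(data["analytes"]),
        outdir=data["outdir"],
        mode=data.get("mode", "percentile"),
        k_max=int(data.get("k_max", 6)),
        tolerance=float(data.get("tolerance", 0.05)),
        exclusion=bool(data.get("exclusion", True)),
        sex_test=bool(data.get("sex_test", True)),
        seed=int(data.get("seed", 0)),
        detection_limit=dict(data.get("detection_limit", {})),
    )


def clean_analyte(
    records: Sequence[SubjectRecord], analyte: str
) -> tuple[list[SubjectRecord], dict[int, int]]:
    """Dixon-clean one analyte per age bin.

    Returns the records that survive for this analyte (records whose value
    was deleted in their bin are dropped from this analyte's analysis, not
    from the cohort) and the per-bin removal counts.
    """
    removed_per_bin: dict[int, int] = {}
    kept: list[SubjectRecord] = []
    by_bin: dict[int, list[SubjectRecord]] = {age: [] for age in AGE_BINS}
    for rec in records:
        if analyte in rec.analytes and rec.age_years in by_bin:
            by_bin[rec.age_years].append(rec)
    for age in AGE_BINS:
        recs = by_bin[age]
        if len(recs) < 3:
            kept.extend(recs)
            continue
        values = np.asarray([r.analytes[analyte] for r in recs])
        result = dixon_outlier_removal(values)
        removed_per_bin[age] = int(result.removed.size)
        budget = Counter(result.removed.tolist())
        for rec, value in zip(recs, values):
            if budget.get(value, 0) > 0:
                budget[value] -= 1
            else:
                kept.append(rec)
    return kept, removed_per_bin


def candidate_ranges(seg: SegmentationResult, k: int | None = None) -> list[tuple[int, int]]:
    """Translate cut indices at k (default the selected k_opt) into
    half-open age ranges tiling [1, 18)."""
    if k is None:
        k = seg.k_opt
    if k <= 1:
        return [(seg.row_labels[0], seg.row_labels[-1] + 1)]
    starts = [seg.row_labels[0], *seg.boundary_labels(k)]
    ends = [*starts[1:], seg.row_labels[-1] + 1]
    return list(zip(starts, ends))


def segment_analyte(
    records: Sequence[SubjectRecord],
    analyte: str,
    k_max: int = 6,
    tolerance: float = 0.05,
) -> tuple[OrderedSampleMatrix, SegmentationResult]:
    """Percentile matrix + Fisher segmentation for one analyte."""
    matrix = nondimensionalize(build_matrix(records, analyte, "percentile"))
    seg = optimal_segmentation(matrix, k_max=k_max, tolerance=tolerance)
    return matrix, seg


@dataclass(frozen=True)
class AnalyteResult:
    analyte: str
    outliers_removed: dict[int, int]
    segmentation: SegmentationResult
    candidates: tuple[tuple[int, int], ...]
    merge: MergeOutcome | None
    sex: tuple[SexSplitResult, ...]
    final: tuple[tuple[int, int, bool], ...]  # (age_lo, age_hi, sex_specific)


@dataclass(frozen=True)
class PipelineResult:
    config: RunConfig
    n_input: int
    n_kept: int
    exclusion_counts: dict[str, int]
    analytes: dict[str, AnalyteResult]
    ri_table: list[ReferenceInterval]
    summary_partitions: dict[str, tuple[tuple[int, int], ...]]
    artifacts: dict[str, str]
    log_lines: list[str]


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def _write_curves(path: Path, seg: SegmentationResult) -> None:
    lines = ["k\tbstar\tf"]
    bstar = seg.bstar_row
    for idx, k in enumerate(range(1, seg.k_max + 1)):
        f_val = "" if k < 2 else _fmt(seg.fk[k])
        lines.append(f"{k}\t{_fmt(bstar[idx])}\t{f_val}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_ri_csv(path: Path, table: Sequence[ReferenceInterval]) -> None:
    lines = ["analyte,age_lo,age_hi,sex,n,ll,ul,ci_ll_lo,ci_ll_hi,ci_ul_lo,ci_ul_hi,censored"]
    for row in table:
        lines.append(
            ",".join(
                [
                    row.analyte, str(row.age_lo), str(row.age_hi), row.sex,
                    str(row.n), _fmt(row.ll), _fmt(row.ul),
                    _fmt(row.ci_ll[0]), _fmt(row.ci_ll[1]),
                    _fmt(row.ci_ul[0]), _fmt(row.ci_ul[1]),
                    "1" if row.censored else "0",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(
    config: RunConfig,
    records: Sequence[SubjectRecord] | None = None,
) -> PipelineResult:
    """Execute the full pipeline and write the artifact bundle.

    ``records`` may be supplied directly (e.g. freshly generated), in which
    case ``config.input`` is not read.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"ripart {__version__}",
        f"seed {config.seed}",
        f"mode {config.mode}",
        f"k_max {config.k_max} tolerance {_fmt(config.tolerance)}",
    ]

    if records is None:
        read = read_cohort(config.input)
        records = read.records
        for err in read.errors:
            log.append(f"input: rejected row {err.row}: {err.reason}")
    records = list(records)
    n_input = len(records)

    exclusion_counts: dict[str, int] = {}
    if config.exclusion:
        kept, excluded = apply_exclusion(records, ExclusionCriteria())
        for _, reasons in excluded:
            for reason in reasons:
                exclusion_counts[reason] = exclusion_counts.get(reason, 0) + 1
        records = kept
        log.append(f"screening: kept {len(records)}/{n_input}")
        for reason in sorted(exclusion_counts):
            log.append(f"screening: excluded {exclusion_counts[reason]} by {reason}")
    else:
        log.append("screening: disabled")

    artifacts: dict[str, str] = {}

    # cohort summary
    counts = Counter((rec.age_years, rec.sex) for rec in records)
    summary_path = outdir / "cohort_summary.csv"
    lines = ["age_years,sex,n"]
    for age in AGE_BINS:
        for sex in ("M", "F"):
            lines.append(f"{age},{sex},{counts.get((age, sex), 0)}")
    summary_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    artifacts["cohort_summary"] = str(summary_path)

    analyte_results: dict[str, AnalyteResult] = {}
    ri_table: list[ReferenceInterval] = []
    summary_partitions: dict[str, tuple[tuple[int, int], ...]] = {}

    if config.mode == "summary":
        # combined panel: per-age central-tendency 17 x len(panel) matrix,
        # segmented pooled and per sex
        for label, subset in (
            ("M+F", records),
            ("M", [r for r in records if r.sex == "M"]),
            ("F", [r for r in records if r.sex == "F"]),
        ):
            matrix = nondimensionalize(build_matrix(subset, list(config.analytes), "summary"))
            seg = optimal_segmentation(matrix, k_max=config.k_max, tolerance=config.tolerance)
            ranges = tuple(candidate_ranges(seg))
            summary_partitions[label] = ranges
            log.append(
                f"summary[{label}]: k_opt {seg.k_opt} ranges "
                + " ".join(f"{lo}-<{hi}" for lo, hi in ranges)
            )
            curves_path = outdir / f"curves_summary_{label.replace('+', '')}.tsv"
            _write_curves(curves_path, seg)
            artifacts[f"curves_summary_{label}"] = str(curves_path)
        payload = {
            label: [list(r) for r in ranges]
            for label, ranges in summary_partitions.items()
        }
        part_path = outdir / "partition_summary.json"
        part_path.write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        artifacts["partition_summary"] = str(part_path)
    else:
        partitions_payload: dict[str, dict] = {}
        final_map: dict[str, tuple[tuple[int, int, bool], ...]] = {}
        for analyte in config.analytes:
            cleaned, removed = clean_analyte(records, analyte)
            total_removed = sum(removed.values())
            log.append(f"{analyte}: Dixon removed {total_removed} value(s)")
            matrix, seg = segment_analyte(
                cleaned, analyte, k_max=config.k_max, tolerance=config.tolerance
            )
            cands = tuple(candidate_ranges(seg))
            log.append(
                f"{analyte}: k_opt {seg.k_opt} candidates "
                + " ".join(f"{lo}-<{hi}" for lo, hi in cands)
            )
            merge = merge_adjacent(cands, cleaned, analyte)
            if merge.ranges != cands:
                log.append(
                    f"{analyte}: merged to " + " ".join(f"{lo}-<{hi}" for lo, hi in merge.ranges)
                )
            if config.sex_test:
                sex_results = tuple(sex_split_test(cleaned, merge.ranges, analyte))
            else:
                sex_results = tuple()
            split_flags = {
                (r.age_lo, r.age_hi): r.sex_specific for r in sex_results
            }
            final = tuple(
                (lo, hi, split_flags.get((lo, hi), False)) for lo, hi in merge.ranges
            )
            for r in sex_results:
                if r.sex_specific:
                    log.append(f"{analyte}: sex split in {r.age_lo}-<{r.age_hi}")
            final_map[analyte] = final
            analyte_results[analyte] = AnalyteResult(
                analyte=analyte,
                outliers_removed=removed,
                segmentation=seg,
                candidates=cands,
                merge=merge,
                sex=sex_results,
                final=final,
            )
            curves_path = outdir / f"curves_{analyte}.tsv"
            _write_curves(curves_path, seg)
            artifacts[f"curves_{analyte}"] = str(curves_path)
            partitions_payload[analyte] = {
                "k_opt": seg.k_opt,
                "bstar": [_fmt(b) for b in seg.bstar_row],
                "f": {str(k): _fmt(v) for k, v in seg.fk.items()},
                "candidates": [list(c) for c in cands],
                "final": [[lo, hi, bool(flag)] for lo, hi, flag in final],
            }

            # RIs per analyte, using the cleaned records for that analyte
            ri_table.extend(
                build_ri_table(
                    cleaned,
                    {analyte: final},
                    detection_limits=config.detection_limit,
                    seed=config.seed,
                )
            )

        part_path = outdir / "partition.json"
        part_path.write_text(
            json.dumps(partitions_payload, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        artifacts["partition"] = str(part_path)

        ri_path = outdir / "ri_table.csv"
        _write_ri_csv(ri_path, ri_table)
        artifacts["ri_table"] = str(ri_path)

    log_path = outdir / "run.log"
    log_path.write_text("\n".join(log) + "\n", encoding="utf-8")
    artifacts["log"] = str(log_path)

    return PipelineResult(
        config=config,
        n_input=n_input,
        n_kept=len(records),
        exclusion_counts=exclusion_counts,
        analytes=analyte_results,
        ri_table=ri_table,
        summary_partitions=summary_partitions,
        artifacts=artifacts,
        log_lines=log,
    )
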