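"""Time-course aggregation, two-sample testing, and the batch pipeline.

Per-cell co-localization results are grouped by (time point, label pair,
direction); each group is summarized as mean ± SEM over cells, with
undefined (empty-denominator) results excluded and the exclusions logged.
Group comparisons use a two-tailed two-sample t-test — pooled-variance
("student") by default, Welch as an option.  No multiple-testing correction
is applied by default; per-comparison significance stars mirror the usual
figure-legend convention (* 0.05, ** 0.01, *** 0.001).

``run_pipeline`` drives the whole chain over a manifest of stacks: load →
slab-project → DoG-filter → threshold → binarize → overlap (+ rotation
null) → summarize, writing a tidy per-cell CSV, a summary CSV, a run log
with every effective parameter, and a config snapshot.  With fixed config
and inputs the outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .colocalization import ColocResult, ThresholdConfig, cell_coloc
from .errors import DegenerateInputError, ParameterError, ValidationError
from .image_io import annotation_overrides, load_stack, read_annotations
from .vesicle_filter import DOGParams

__all__ = [
    "TimeCourseSummary",
    "results_to_frame",
    "summarize_timecourse",
    "compare_pairs",
    "significance_stars",
    "run_pipeline",
]

logger = logging.getLogger("vesicoloc")

PER_CELL_COLUMNS = [
    "cell_id",
    "condition",
    "time_min",
    "label_A",
    "label_B",
    "direction",
    "numerator_px",
    "denominator_px",
    "percent",
    "null_percent",
    "threshold_A",
    "threshold_B",
    "n_slabs",
    "partial_slab",
]


@dataclass
class TimeCourseSummary:
    """Per-timepoint aggregation plus pairwise comparisons.

    ``table`` has one row per (time_min, label_A, label_B, direction) with
    n_cells, mean_percent, sem_percent (NaN when n_cells < 2);
    ``comparisons`` holds t-test rows when requested.
    """

    table: pd.DataFrame
    comparisons: pd.DataFrame
    n_excluded: int = 0


def results_to_frame(results: Iterable[ColocResult]) -> pd.DataFrame:
    """Flatten ColocResults into the tidy per-cell table."""
    rows = []
    for r in results:
        thr = dict(r.thresholds)
        rows.append(
            {
                "cell_id": r.cell_id,
                "condition": r.condition,
                "time_min": r.time_min,
                "label_A": r.label_A,
                "label_B": r.label_B,
                "direction": r.direction,
                "numerator_px": r.numerator_px,
                "denominator_px": r.denominator_px,
                "percent": r.percent if r.defined else np.nan,
                "null_percent": r.null_percent if r.null_defined else np.nan,
                "threshold_A": thr.get(r.label_A, np.nan),
                "threshold_B": thr.get(r.label_B, np.nan),
                "n_slabs": len(r.per_slab) if r.per_slab else 1,
                "partial_slab": r.partial_slab,
            }
        )
    return pd.DataFrame(rows, columns=PER_CELL_COLUMNS)


def summarize_timecourse(
    results: Iterable[ColocResult] | pd.DataFrame,
) -> TimeCourseSummary:
    """Group per-cell percents by (time, pair, direction): mean, SEM, n.

    Undefined percents (empty normalizing channel) are excluded from n and
    logged; SEM = sample SD / √n, reported only for n ≥ 2.
    """
    frame = (
        results
        if isinstance(results, pd.DataFrame)
        else results_to_frame(list(results))
    )
    if frame.empty:
        raise DegenerateInputError("no results to summarize")
    defined = frame.dropna(subset=["percent"])
    n_excluded = len(frame) - len(defined)
    if n_excluded:
        logger.info("summarize_timecourse: excluded %d undefined results", n_excluded)
    if defined.empty:
        raise DegenerateInputError("all results have undefined percent")

    def agg(group: pd.DataFrame) -> pd.Series:
        vals = group["percent"].to_numpy(dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        return pd.Series(
            {
                "n_cells": n,
                "mean_percent": float(np.mean(vals)),
                "sem_percent": sem,
                "mean_null_percent": float(np.nanmean(group["null_percent"]))
                if group["null_percent"].notna().any()
                else np.nan,
            }
        )

    table = (
        defined.groupby(["time_min", "label_A", "label_B", "direction"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    table["n_cells"] = table["n_cells"].astype(int)
    return TimeCourseSummary(
        table=table, comparisons=pd.DataFrame(), n_excluded=n_excluded
    )


def compare_pairs(
    group1: Sequence[float],
    group2: Sequence[float],
    variant: str = "student",
) -> tuple[float, float]:
    """Two-tailed two-sample t-test between two groups of per-cell percents.

    ``"student"`` pools variances (classical Student's t); ``"welch"`` does
    not assume equal variances.  Returns ``(t, p)``.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if len(g1) < 2 or len(g2) < 2:
        raise DegenerateInputError(
            f"each group needs >= 2 defined values (got {len(g1)}, {len(g2)})"
        )
    if variant not in ("student", "welch"):
        raise ParameterError(f"variant must be 'student' or 'welch', got {variant!r}")
    t, p = stats.ttest_ind(g1, g2, equal_var=(variant == "student"))
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Figure-legend stars: *** <0.001, ** <0.01, * <0.05, '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _compare_label_pairs(
    frame: pd.DataFrame, variant: str
) -> pd.DataFrame:
    """All pairwise t-tests between label pairs sharing a time point."""
    rows = []
    defined = frame.dropna(subset=["percent"])
    for (t_min, direction), sub in defined.groupby(["time_min", "direction"]):
        pairs = sorted(sub.groupby(["label_A", "label_B"]).groups)
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                v1 = sub[(sub.label_A == pairs[i][0]) & (sub.label_B == pairs[i][1])][
                    "percent"
                ]
                v2 = sub[(sub.label_A == pairs[j][0]) & (sub.label_B == pairs[j][1])][
                    "percent"
                ]
                if len(v1) < 2 or len(v2) < 2:
                    continue
                t, p = compare_pairs(v1, v2, variant)
                rows.append(
                    {
                        "time_min": t_min,
                        "direction": direction,
                        "pair1": f"{pairs[i][0]}|{pairs[i][1]}",
                        "pair2": f"{pairs[j][0]}|{pairs[j][1]}",
                        "t_statistic": t,
                        "p_value": p,
                        "stars": significance_stars(p),
                        "variant": variant,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "time_min",
            "direction",
            "pair1",
            "pair2",
            "t_statistic",
            "p_value",
            "stars",
            "variant",
        ],
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything run_pipeline needs, loadable from YAML."""

    dog: DOGParams = DOGParams()
    thresholds: ThresholdConfig = ThresholdConfig()
    slab_nm: float = 500.0
    direction: str = "B_with_A"
    threshold_scope: str = "stack"
    pairs: tuple[tuple[str, str], ...] = ()
    test_variant: str = "student"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        dog = DOGParams(**raw.get("dog", {}))
        thr_raw = dict(raw.get("threshold", {}))
        thresholds = ThresholdConfig(
            method=thr_raw.get("method", "otsu-positive"),
            quantile_q=thr_raw.get("quantile_q"),
            values=thr_raw.get("values", {}),
        )
        return cls(
            dog=dog,
            thresholds=thresholds,
            slab_nm=float(raw.get("slab_nm", 500.0)),
            direction=raw.get("direction", "B_with_A"),
            threshold_scope=raw.get("threshold_scope", "stack"),
            pairs=tuple(tuple(p) for p in raw.get("pairs", [])),
            test_variant=raw.get("test_variant", "student"),
        )

    def snapshot(self) -> dict:
        return {
            "dog": dataclasses.asdict(self.dog),
            "threshold": {
                "method": self.thresholds.method,
                "quantile_q": self.thresholds.quantile_q,
                "values": dict(self.thresholds.values),
            },
            "slab_nm": self.slab_nm,
            "direction": self.direction,
            "threshold_scope": self.threshold_scope,
            "pairs": [list(p) for p in self.pairs],
            "test_variant": self.test_variant,
        }


def run_pipeline(
    manifest: str | Path | pd.DataFrame,
    out_dir: str | Path,
    config: PipelineConfig | str | Path | None = None,
) -> Path:
    """Run the full analysis over a manifest of stacks.

    *manifest* is a CSV (or DataFrame) with a ``file`` column plus optional
    annotation columns (``time_min``, ``condition``, ``cell_id``,
    ``pixel_size_nm``, ``z_spacing_nm``, ``channel_labels``).  Analyzed
    label pairs come from ``config.pairs``, defaulting to all ordered pairs
    of the first stack's channels.

    Writes ``per_cell.csv``, ``summary.csv``, ``comparisons.csv``,
    ``run.log`` and ``config_snapshot.json`` under *out_dir* and returns it.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        manifest = read_annotations(manifest).reset_index()
    if manifest.empty:
        raise ValidationError("empty manifest: nothing to analyze")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config: {json.dumps(config.snapshot(), sort_keys=True)}"]

    results: list[ColocResult] = []
    for _, row in manifest.iterrows():
        path = row["file"]
        try:
            stack = load_stack(path, annotation_overrides(row))
        except Exception as exc:
            raise type(exc)(f"stage=load file={path}: {exc}") from exc
        pairs = config.pairs or tuple(
            (a, b)
            for a in stack.channel_labels
            for b in stack.channel_labels
            if a != b
        )
        for label_A, label_B in pairs:
            try:
                res = cell_coloc(
                    stack,
                    label_A,
                    label_B,
                    params=config.dog,
                    thresholds=config.thresholds,
                    slab_nm=config.slab_nm,
                    direction=config.direction,
                    threshold_scope=config.threshold_scope,
                )
            except Exception as exc:
                raise type(exc)(
                    f"stage=coloc file={path} pair={label_A}|{label_B}: {exc}"
                ) from exc
            results.append(res)
            log_lines.append(
                f"coloc file={path} pair={label_A}|{label_B} "
                f"thresholds={res.thresholds} percent={res.percent} "
                f"null={res.null_percent}"
            )

    per_cell = results_to_frame(results)
    summary = summarize_timecourse(per_cell)
    comparisons = _compare_label_pairs(per_cell, config.test_variant)

    per_cell.to_csv(out_dir / "per_cell.csv", index=False, float_format="%.10g")
    summary.table.to_csv(out_dir / "summary.csv", index=False, float_format="%.10g")
    comparisons.to_csv(out_dir / "comparisons.csv", index=False, float_format="%.10g")
    (out_dir / "config_snapshot.json").write_text(
        json.dumps(config.snapshot(), indent=2, sort_keys=True) + "\n"
    )
    log_lines.append(f"excluded_undefined={summary.n_excluded}")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return out_dir
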