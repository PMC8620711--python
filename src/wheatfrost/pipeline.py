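"""Batch pipeline: image directory + layout config -> phenotype report.

Discovers plot photos, maps filenames to plot identities, segments each
image, extracts coverage / grade / withered fraction, aggregates to plot and
variety x treatment level, and summarizes which nitrogen treatment ranks
lowest or highest per variety.  Per-image failures are logged and isolated —
one corrupt file must not kill a field batch.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiment import ExperimentLayout, PlotID, load_layout
from .indices import read_rgb
from .phenotypes import (
    WitheredThresholds,
    aggregate_plot,
    coverage,
    grade,
    treatment_ranking_summary,
    withered_extract,
)
from .segmentation import SegmentationParams, segment

__all__ = ["RunConfig", "RunReport", "run", "summarize", "parse_image_name"]

logger = logging.getLogger("wheatfrost")

_NAME_RE = re.compile(r"^(?P<variety>.+)_(?P<treatment>[^_]+)_(?P<rep>\d+)_(?P<k>\d+)$")

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class RunConfig:
    """Everything a batch run needs; serializable to/from YAML."""

    input_dir: str
    output_dir: str | None = None
    layout_file: str | None = None
    min_object_px: int = 16
    fill_holes: bool = True
    index_kind: str = "ExV"
    withered: WitheredThresholds = field(default_factory=WitheredThresholds)
    grade_mapping: str = "severity"
    aggregation: str = "plot"  # image | plot | variety_treatment
    log_level: str = "INFO"
    seed: int = 0

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            index_kind=self.index_kind,
            min_object_px=self.min_object_px,
            fill_holes=self.fill_holes,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "withered" in d and isinstance(d["withered"], dict):
            d["withered"] = WitheredThresholds(**d["withered"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        if not isinstance(cfg, dict):
            raise ValueError(f"run config {path} did not parse to a mapping")
        return cls.from_dict(cfg)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunReport:
    images: pd.DataFrame          # one row per processed image
    plots: pd.DataFrame           # one row per plot
    groups: pd.DataFrame          # variety x treatment means
    ranking: dict | None          # treatment_ranking_summary output
    failed: list[dict]            # per-file failure records
    config: RunConfig

    @property
    def n_processed(self) -> int:
        return len(self.images)

    @property
    def n_failed(self) -> int:
        return len(self.failed)


def parse_image_name(name: str) -> tuple[PlotID, int]:
    """Parse ``{variety}_{treatment}_{replicate}_{k}`` from a file stem.

    The variety part may itself contain underscores; the last three
    underscore-separated fields are treatment, replicate and image index.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(
            f"filename {name!r} does not match "
            "'{variety}_{treatment}_{replicate}_{imageindex}'"
        )
    return (
        PlotID(m["variety"], m["treatment"], int(m["rep"])),
        int(m["k"]),
    )


def _discover(input_dir: Path) -> list[Path]:
    return sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file()
    )


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline over a directory of plot images.

    Deterministic for fixed inputs and config.  Images whose filenames do
    not parse, or that fail to decode/segment, are recorded under
    ``report.failed`` and excluded from aggregates.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory {input_dir} does not exist")
    files = _discover(input_dir)
    if not files:
        raise FileNotFoundError(f"no images found in {input_dir}")

    seg_params = config.segmentation_params()
    rows: list[dict] = []
    failed: list[dict] = []
    for path in files:
        try:
            plot, k = parse_image_name(path.stem)
        except ValueError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            failed.append({"image": path.name, "error": str(exc)})
            continue
        try:
            img = read_rgb(path)
            seg = segment(img, seg_params)
            cov = coverage(seg.mask)
            g = grade(cov, mapping=config.grade_mapping)
            wres = withered_extract(img, thresholds=config.withered)
        except Exception as exc:  # isolate per-image failures
            logger.warning("failed on %s: %s", path.name, exc)
            failed.append({"image": path.name, "error": str(exc)})
            continue
        logger.debug("%s: otsu_t=%d coverage=%.2f%%", path.name, seg.otsu_t, cov.coverage_pct)
        rows.append(
            {
                "image": path.name,
                "plot_id": str(plot),
                "variety": plot.variety,
                "treatment": plot.treatment_label,
                "replicate": plot.replicate,
                "image_index": k,
                "otsu_t": seg.otsu_t,
                "threshold": seg.threshold,
                "coverage_pct": cov.coverage_pct,
                "grade": g.grade,
                "grade_label": g.label,
                "withered_fraction": wres.withered_fraction,
            }
        )
    if not rows:
        raise RuntimeError("every discovered image failed; nothing to report")

    images = pd.DataFrame(rows)

    plot_rows = []
    for plot_id, sub in images.groupby("plot_id", sort=True):
        mean_cov, g = aggregate_plot(
            list(sub["coverage_pct"]), mapping=config.grade_mapping
        )
        plot_rows.append(
            {
                "plot_id": plot_id,
                "variety": sub["variety"].iloc[0],
                "treatment": sub["treatment"].iloc[0],
                "replicate": sub["replicate"].iloc[0],
                "n_images": len(sub),
                "mean_coverage_pct": mean_cov,
                "grade": g.grade,
                "grade_label": g.label,
                "mean_withered_fraction": float(sub["withered_fraction"].mean()),
                "otsu_thresholds": ";".join(str(t) for t in sub["otsu_t"]),
            }
        )
    plots = pd.DataFrame(plot_rows)

    groups = (
        plots.groupby(["variety", "treatment"], sort=True)
        .agg(
            mean_coverage_pct=("mean_coverage_pct", "mean"),
            sd_coverage_pct=("mean_coverage_pct", "std"),
            mean_withered_fraction=("mean_withered_fraction", "mean"),
            n_plots=("plot_id", "count"),
        )
        .reset_index()
    )

    ranking = None
    table = groups.pivot(index="variety", columns="treatment", values="mean_coverage_pct")
    if not table.isna().any().any() and table.shape[1] > 1:
        ranking = treatment_ranking_summary(table)
    elif table.isna().any().any():
        logger.warning(
            "incomplete variety x treatment table; treatment ranking skipped"
        )

    report = RunReport(
        images=images, plots=plots, groups=groups, ranking=ranking,
        failed=failed, config=config,
    )
    if config.output_dir:
        _write_outputs(report, Path(config.output_dir))
    return report


def _write_outputs(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.images.to_csv(out_dir / "images.csv", index=False)
    report.plots.to_csv(out_dir / "plots.csv", index=False)
    report.groups.to_csv(out_dir / "groups.csv", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summarize(report), fh, indent=2)
    if report.failed:
        pd.DataFrame(report.failed).to_csv(out_dir / "failed.csv", index=False)


def summarize(report: RunReport) -> dict:
    """Compact summary: grade counts, coverage quartiles, treatment ranking."""
    if report.n_processed == 0:
        raise ValueError("cannot summarize an empty report")
    grade_counts = {
        int(g): int(n) for g, n in report.plots["grade"].value_counts().items()
    }
    quartiles = {}
    for treatment, sub in report.plots.groupby("treatment", sort=True):
        q = np.percentile(sub["mean_coverage_pct"], [0, 25, 50, 75, 100])
        quartiles[str(treatment)] = {
            "min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4]),
        }
    return {
        "n_images_processed": report.n_processed,
        "n_images_failed": report.n_failed,
        "n_plots": int(len(report.plots)),
        "grade_counts": grade_counts,
        "coverage_quartiles_by_treatment": quartiles,
        "treatment_ranking": report.ranking,
    }
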