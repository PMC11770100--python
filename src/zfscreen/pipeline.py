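"""Batch orchestration: analyze many recordings grouped by condition,
summarize per group as mean ± s.e.m., and serialize reports deterministically.

A batch is described by a manifest of (video path, condition label, nominal
concentration) rows sharing one analysis configuration. Videos that fail
analysis are logged and excluded with a recorded reason rather than aborting
the batch; the run errors only when nothing could be analyzed. Outputs carry
a config snapshot and the package version but no timestamps, so identical
inputs give byte-identical files.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cardio import CardiacConfig, CardiacReport, analyze
from .core import VideoStack, ZfscreenError, read_video

logger = logging.getLogger("zfscreen")

__all__ = [
    "ExperimentItem",
    "Experiment",
    "GroupSummary",
    "ExperimentResult",
    "load_manifest",
    "run_experiment",
    "write_report",
]


@dataclass(frozen=True)
class ExperimentItem:
    video: "str | Path | VideoStack"
    condition: str
    concentration: float = 0.0  # µM, nominal

    def __post_init__(self) -> None:
        if not self.condition:
            raise ValueError("condition label must be non-empty")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    @property
    def name(self) -> str:
        if isinstance(self.video, (str, Path)):
            return Path(self.video).stem
        return f"{self.condition}_{self.concentration:g}"


@dataclass(frozen=True)
class Experiment:
    """A batch of recordings analyzed with one shared configuration."""

    items: tuple[ExperimentItem, ...]
    frame_rate: float = 35.0  # frames/s, for videos loaded from disk
    pixel_size: float = 1.0  # µm/px
    config: CardiacConfig = field(default_factory=CardiacConfig)
    seed: int = 0


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive per-condition summary: n, mean and s.e.m. of each index."""

    condition: str
    n: int
    hr_mean: float
    hr_sem: float | None
    fac_mean: float
    fac_sem: float | None
    sv_mean: float
    sv_sem: float | None
    co_mean: float
    co_sem: float | None


@dataclass(frozen=True)
class ExperimentResult:
    reports: tuple[tuple[ExperimentItem, CardiacReport], ...]
    summaries: tuple[GroupSummary, ...]
    failures: tuple[tuple[ExperimentItem, str], ...] = ()


def _sem(values: np.ndarray) -> float | None:
    """Standard error of the mean, sd(ddof=1)/√n; undefined for n = 1."""
    if values.size < 2:
        return None
    return float(values.std(ddof=1) / np.sqrt(values.size))


def load_manifest(
    path: "str | Path",
    frame_rate: float,
    pixel_size: float = 1.0,
    config: CardiacConfig | None = None,
    seed: int = 0,
) -> Experiment:
    """Read an experiment manifest CSV (path, condition, concentration_uM).

    Relative video paths are resolved against the manifest's directory.
    """
    path = Path(path)
    items = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            video = Path(row["path"])
            if not video.is_absolute():
                video = path.parent / video
            items.append(
                ExperimentItem(
                    video=video,
                    condition=row["condition"],
                    concentration=float(row.get("concentration_uM", 0) or 0),
                )
            )
    return Experiment(
        items=tuple(items),
        frame_rate=frame_rate,
        pixel_size=pixel_size,
        config=config or CardiacConfig(),
        seed=seed,
    )


def run_experiment(exp: Experiment) -> ExperimentResult:
    """Analyze every recording in the batch and summarize per condition.

    Failures (unreadable or unanalyzable videos) are logged and recorded with
    their reason; raises only when no video could be analyzed.
    """
    reports: list[tuple[ExperimentItem, CardiacReport]] = []
    failures: list[tuple[ExperimentItem, str]] = []
    for item in exp.items:
        try:
            if isinstance(item.video, VideoStack):
                video = item.video
            else:
                video = read_video(item.video, frame_rate=exp.frame_rate, pixel_size=exp.pixel_size)
            reports.append((item, analyze(video, exp.config)))
            logger.info("analyzed %s (%s)", item.name, item.condition)
        except Exception as exc:  # noqa: BLE001 — skip-and-log failure policy
            logger.warning("failed %s (%s): %s", item.name, item.condition, exc)
            failures.append((item, f"{type(exc).__name__}: {exc}"))
    if not reports:
        raise ZfscreenError("no video could be analyzed; every item failed")

    conditions: dict[str, list[CardiacReport]] = {}
    for item, report in reports:
        conditions.setdefault(item.condition, []).append(report)
    summaries = []
    for condition in sorted(conditions):
        group = conditions[condition]
        hr = np.array([r.hr for r in group])
        fac_ = np.array([r.fac for r in group])
        sv = np.array([r.sv for r in group])
        co = np.array([r.co for r in group])
        summaries.append(
            GroupSummary(
                condition=condition,
                n=len(group),
                hr_mean=float(hr.mean()),
                hr_sem=_sem(hr),
                fac_mean=float(fac_.mean()),
                fac_sem=_sem(fac_),
                sv_mean=float(sv.mean()),
                sv_sem=_sem(sv),
                co_mean=float(co.mean()),
                co_sem=_sem(co),
            )
        )
    return ExperimentResult(
        reports=tuple(reports), summaries=tuple(summaries), failures=tuple(failures)
    )


def write_report(
    result: ExperimentResult,
    out_dir: "str | Path",
    config: CardiacConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Serialize a batch result: per-video JSON, per-cycle CSV, summary CSV,
    and a provenance snapshot (config + package version, no timestamps).

    Returns the list of files written. Field order is fixed so repeat runs on
    identical inputs produce byte-identical files.
    """
    if not result.reports:
        raise ValueError("nothing to write: empty report list")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for idx, (item, report) in enumerate(result.reports):
        payload = {
            "video": item.name,
            "condition": item.condition,
            "concentration_uM": item.concentration,
            **report.to_dict(),
        }
        # index prefix keeps names unique for in-memory items sharing a label
        p = out / f"{idx:03d}_{item.name}.json"
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")
        written.append(p)

    cycles_path = out / "cycles.csv"
    with open(cycles_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["video", "condition", "cycle", "ld_d_um", "ld_s_um", "sd_d_um", "sd_s_um",
             "eda_um2", "esa_um2", "edv_nl", "esv_nl", "start_frame", "end_frame"]
        )
        for item, report in result.reports:
            for k, c in enumerate(report.cycles):
                writer.writerow(
                    [item.name, item.condition, k,
                     f"{c.ld_d:.6f}", f"{c.ld_s:.6f}", f"{c.sd_d:.6f}", f"{c.sd_s:.6f}",
                     f"{c.eda:.6f}", f"{c.esa:.6f}", f"{c.edv:.8f}", f"{c.esv:.8f}",
                     c.start_frame, c.end_frame]
                )
    written.append(cycles_path)

    summary_path = out / "summary.csv"
    with open(summary_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["condition", "n", "hr_mean", "hr_sem", "fac_mean", "fac_sem",
             "sv_mean", "sv_sem", "co_mean", "co_sem"]
        )
        for s in result.summaries:
            fmt = lambda v: "" if v is None else f"{v:.6f}"  # noqa: E731
            writer.writerow(
                [s.condition, s.n, fmt(s.hr_mean), fmt(s.hr_sem), fmt(s.fac_mean),
                 fmt(s.fac_sem), fmt(s.sv_mean), fmt(s.sv_sem), fmt(s.co_mean), fmt(s.co_sem)]
            )
    written.append(summary_path)

    prov = {
        "package": "zfscreen",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config) if config is not None else None,
        "failures": [
            {"video": item.name, "condition": item.condition, "reason": reason}
            for item, reason in result.failures
        ],
    }
    prov_path = out / "run_config.json"
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=2)
        fh.write("\n")
    written.append(prov_path)
    return written
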