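"""End-to-end orchestration: simulate phantom experiments, analyze manifests.

A run manifest is a CSV listing one sample per row (image path, sound and
lesion rectangles, acid-etching duration, exclusion flag) plus a JSON
sidecar with the global parameters (analysis window, central fraction,
channel policy, declared duration groups). Plain text throughout, so
manifests are diffable and fixtures can live in a repository.

``run_analysis`` produces, under the output directory: ``samples.csv`` (one
row per measured sample), ``group_summary.csv`` / ``group_summary.json``,
``report.json`` / ``report.txt`` (statistical battery), per-sample LASCA map
exports and false-color renderings, and ``run.log`` recording the package
version, every effective parameter, and every output path.

Exit-code convention used by the CLI: 0 success, 2 partial (some samples
failed but the run completed), 1 fatal.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConsistencyError, LascaError, ParameterError, RunError
from .imaging import IntensityImage, RegionSpec, load_image, render_false_color
from .lasca import DEFAULT_WINDOW, average_image, lasca_map
from .metrics import (
    DEFAULT_CENTRAL_FRACTION,
    DEFAULT_MIN_CELLS,
    SampleMeasurement,
    measure_sample,
    measurements_to_rows,
    summarize_group,
)
from .stats import statistical_report, write_report
from .synthetic import PhantomConfig, write_phantom

__all__ = [
    "ManifestEntry",
    "RunManifest",
    "RunResult",
    "run_analysis",
    "run_simulation",
    "read_manifest",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_MANIFEST_COLUMNS = [
    "sample_id", "image",
    "sound_top", "sound_left", "sound_bottom", "sound_right",
    "lesion_top", "lesion_left", "lesion_bottom", "lesion_right",
    "duration_min", "excluded",
]


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    image_path: str
    sound: RegionSpec
    lesion: RegionSpec
    duration_min: float
    excluded: bool = False


@dataclass(frozen=True)
class RunManifest:
    """All inputs of one analysis run."""

    entries: List[ManifestEntry]
    window: int = DEFAULT_WINDOW
    central_fraction: float = DEFAULT_CENTRAL_FRACTION
    channel_policy: str = "red"
    min_cells: int = DEFAULT_MIN_CELLS
    groups: Optional[List[float]] = None  # declared duration set

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("sample_ids in a manifest must be unique")
        declared = self.groups if self.groups is not None else sorted(
            {e.duration_min for e in self.entries}
        )
        object.__setattr__(self, "groups", list(declared))
        for e in self.entries:
            if e.duration_min not in self.groups:
                raise ConsistencyError(
                    f"{e.sample_id}: duration {e.duration_min} not in declared groups {self.groups}"
                )


def write_manifest(manifest: RunManifest, csv_path: Union[str, Path]) -> None:
    csv_path = Path(csv_path)
    with csv_path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_MANIFEST_COLUMNS)
        for e in manifest.entries:
            writer.writerow([
                e.sample_id, e.image_path,
                e.sound.top, e.sound.left, e.sound.bottom, e.sound.right,
                e.lesion.top, e.lesion.left, e.lesion.bottom, e.lesion.right,
                e.duration_min, int(e.excluded),
            ])
    sidecar = {
        "window": manifest.window,
        "central_fraction": manifest.central_fraction,
        "channel_policy": manifest.channel_policy,
        "min_cells": manifest.min_cells,
        "groups": manifest.groups,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_manifest(csv_path: Union[str, Path]) -> RunManifest:
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    params = json.loads(sidecar_path.read_text()) if sidecar_path.is_file() else {}
    entries: List[ManifestEntry] = []
    with csv_path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(ManifestEntry(
                sample_id=row["sample_id"],
                image_path=row["image"],
                sound=RegionSpec("sound", int(row["sound_top"]), int(row["sound_left"]),
                                 int(row["sound_bottom"]), int(row["sound_right"])),
                lesion=RegionSpec("lesion", int(row["lesion_top"]), int(row["lesion_left"]),
                                  int(row["lesion_bottom"]), int(row["lesion_right"])),
                duration_min=float(row["duration_min"]),
                excluded=bool(int(row["excluded"])),
            ))
    return RunManifest(
        entries=entries,
        window=int(params.get("window", DEFAULT_WINDOW)),
        central_fraction=float(params.get("central_fraction", DEFAULT_CENTRAL_FRACTION)),
        channel_policy=str(params.get("channel_policy", "red")),
        min_cells=int(params.get("min_cells", DEFAULT_MIN_CELLS)),
        groups=params.get("groups"),
    )


@dataclass
class RunResult:
    measurements: List[SampleMeasurement]
    failures: Dict[str, str]
    report: dict
    out_dir: Path

    @property
    def exit_code(self) -> int:
        return 2 if self.failures else 0


def _resolve_image(entry: ManifestEntry, manifest_dir: Optional[Path]) -> Path:
    p = Path(entry.image_path)
    if not p.is_absolute() and manifest_dir is not None:
        p = manifest_dir / p
    return p


def run_analysis(
    manifest: RunManifest,
    out_dir: Union[str, Path],
    manifest_dir: Union[str, Path, None] = None,
    render_maps: bool = True,
) -> RunResult:
    """Measure every non-excluded sample, summarize groups, run the
    statistical battery, and write the full result bundle to ``out_dir``.

    A sample whose image is missing or unmeasurable is recorded as a failure
    and the run continues; a declared group left empty after exclusions and
    failures aborts the run with :class:`~lascakit.errors.RunError`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_dir = Path(manifest_dir) if manifest_dir is not None else None
    log_lines: List[str] = [
        f"lascakit {__version__}",
        f"window={manifest.window} central_fraction={manifest.central_fraction} "
        f"channel_policy={manifest.channel_policy} min_cells={manifest.min_cells}",
        f"groups={manifest.groups}",
    ]

    active = [e for e in manifest.entries if not e.excluded]
    for e in manifest.entries:
        if e.excluded:
            log_lines.append(f"excluded: {e.sample_id}")
    if not active:
        raise RunError("all samples are excluded")

    measurements: List[SampleMeasurement] = []
    failures: Dict[str, str] = {}
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    for entry in active:
        path = _resolve_image(entry, manifest_dir)
        try:
            image = load_image(path, manifest.channel_policy)
            m = measure_sample(
                image, entry.sound, entry.lesion,
                window=manifest.window, fraction=manifest.central_fraction,
                sample_id=entry.sample_id, group_duration=entry.duration_min,
                min_cells=manifest.min_cells,
            )
            measurements.append(m)
            lmap = lasca_map(image, manifest.window)
            csv_path = maps_dir / f"{entry.sample_id}_lasca.csv"
            lmap.to_csv(csv_path)
            log_lines.append(f"wrote {csv_path}")
            log_lines.append(f"wrote {csv_path.with_suffix('.json')}")
            if render_maps:
                png = maps_dir / f"{entry.sample_id}_lasca.png"
                render_false_color(lmap.contrast, png, valid=lmap.valid)
                avg_png = maps_dir / f"{entry.sample_id}_mean.png"
                render_false_color(average_image(image, manifest.window), avg_png)
                log_lines += [f"wrote {png}", f"wrote {avg_png}"]
            log_lines.append(
                f"measured {entry.sample_id}: CR={m.contrast_ratio:.4f} "
                f"(c_sound={m.c_sound:.4f}, c_lesion={m.c_lesion:.4f})"
            )
        except (LascaError, OSError) as exc:
            failures[entry.sample_id] = str(exc)
            log_lines.append(f"FAILED {entry.sample_id}: {exc}")

    by_group: Dict[float, List[SampleMeasurement]] = {g: [] for g in manifest.groups}
    for m in measurements:
        by_group[m.group_duration].append(m)
    empty = [g for g, ms in by_group.items() if not ms]
    if empty:
        raise RunError(f"groups {empty} have no measurable samples")

    samples_csv = out_dir / "samples.csv"
    pd.DataFrame(measurements_to_rows(measurements)).to_csv(samples_csv, index=False)
    log_lines.append(f"wrote {samples_csv}")

    summaries = [summarize_group(ms, g) for g, ms in sorted(by_group.items())]
    summary_rows = [
        {"duration_min": s.duration, "n": s.n, "mean_cr": s.mean_cr, "sd_cr": s.sd_cr}
        for s in summaries
    ]
    summary_csv = out_dir / "group_summary.csv"
    pd.DataFrame(summary_rows).to_csv(summary_csv, index=False)
    (out_dir / "group_summary.json").write_text(json.dumps(summary_rows, indent=2) + "\n")
    log_lines += [f"wrote {summary_csv}", f"wrote {out_dir / 'group_summary.json'}"]

    durations = sorted(by_group)
    report = statistical_report(
        durations, [[m.contrast_ratio for m in by_group[g]] for g in durations]
    )
    write_report(report, out_dir / "report.json", out_dir / "report.txt")
    log_lines += [f"wrote {out_dir / 'report.json'}", f"wrote {out_dir / 'report.txt'}"]

    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return RunResult(measurements=measurements, failures=failures, report=report, out_dir=out_dir)


def run_simulation(
    configs: Sequence[PhantomConfig],
    durations: Sequence[float],
    out_dir: Union[str, Path],
) -> Path:
    """Write a phantom per config (16-bit TIFF + sidecar) and an auto-generated
    manifest consumable by :func:`run_analysis`. Returns the manifest path.

    ``durations[i]`` labels phantom i's duration group. Invalid configs are
    skipped and reported via :class:`~lascakit.errors.RunError` containing
    the full skip list.
    """
    if len(configs) == 0:
        raise ParameterError("empty config set")
    if len(durations) != len(configs):
        raise ParameterError("one duration per config required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: List[ManifestEntry] = []
    skipped: List[str] = []
    for i, (config, dur) in enumerate(zip(configs, durations)):
        sample_id = f"phantom_{i:03d}"
        tiff = out_dir / f"{sample_id}.tiff"
        try:
            lesion, sound = write_phantom(config, tiff)
        except LascaError as exc:
            skipped.append(f"{sample_id}: {exc}")
            continue
        entries.append(ManifestEntry(
            sample_id=sample_id, image_path=tiff.name,
            sound=sound, lesion=lesion, duration_min=float(dur),
        ))
    manifest = RunManifest(entries=entries, channel_policy="single")
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    if skipped:
        raise RunError("invalid configs skipped: " + "; ".join(skipped))
    return manifest_path


def graded_experiment_configs(
    master_seed: int = 0,
    samples_per_group: int = 8,
    height: int = 700,
    width: int = 700,
    grain: float = 1.5,
) -> tuple[List[PhantomConfig], List[float]]:
    """The default 4-group phantom experiment.

    Four acid-etching duration groups (10/20/30/40 min), ``samples_per_group``
    phantoms each. Erosion severity is graded through the pattern-sum pairs
    (N_sound, N_lesion) = (3,2), (5,3), (8,3), (16,5), whose analytic
    contrast ratios 1 - sqrt(N_lesion/N_sound) = 0.183, 0.225, 0.388, 0.441
    mirror the graded response of an in-vitro erosion model. Per-phantom
    seeds are spawned deterministically from ``master_seed``.
    """
    group_params = [
        (10.0, 3, 2, 120.0, 95.0),
        (20.0, 5, 3, 120.0, 90.0),
        (30.0, 8, 3, 120.0, 85.0),
        (40.0, 16, 5, 120.0, 80.0),
    ]
    seeds = np.random.SeedSequence(master_seed).generate_state(
        4 * samples_per_group, dtype=np.uint32
    ) % (2**31)
    configs: List[PhantomConfig] = []
    durations: List[float] = []
    idx = 0
    for dur, ns, nl, ms, ml in group_params:
        for _ in range(samples_per_group):
            configs.append(PhantomConfig(
                height=height, width=width, grain=grain,
                mean_sound=ms, mean_lesion=ml,
                n_sum_sound=ns, n_sum_lesion=nl,
                boundary_col=width // 2, seed=int(seeds[idx]),
            ))
            durations.append(dur)
            idx += 1
    return configs, durations
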