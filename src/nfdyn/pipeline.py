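"""Pipeline orchestration: configuration, staging, seeds, reproducibility.

A full run goes simulate → segment → track → trace → features → summarize →
compare, persisting standard-format intermediates (TIFF / CSV / JSON) at
every stage boundary so any stage can be re-run from the previous one's
output, or replaced by a third-party tool.  One global seed expands into
per-condition, per-movie seeds through a CRC of the condition key, so adding
conditions never shifts the random streams of existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import features as feat
from . import population as pop
from .response_model import PreparationPreset, default_presets, load_presets
from .segment import (
    LabelStack,
    SegmentationConfig,
    link_tracks,
    ring_stack,
    segment_stack,
    tracks_to_df,
    Track,
)
from .simulate import (
    ImagingConfig,
    Movie,
    read_movie,
    simulate_condition,
    write_ground_truth,
    write_movie,
)

__all__ = [
    "PipelineConfig",
    "StageError",
    "condition_seed",
    "validate_config",
    "analyze_movie",
    "summarize_condition",
    "run_full",
]

log = logging.getLogger(__name__)

#: Nine-decade default concentration grid, µg/mL.
DEFAULT_CONCENTRATIONS = (5e-7, 5e-6, 5e-5, 5e-4, 5e-3, 5e-2, 0.5, 5.0, 50.0)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    presets: tuple[str, ...] = ("Sigma", "EB", "UP")
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    stnfr_arm: bool = False
    cells_per_movie: int = 60
    movies_per_condition: int = 3
    seed: int = 0
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: feat.FeatureConfig = field(default_factory=feat.FeatureConfig)
    grid_max: float = 595.0
    preset_file: str | None = None

    def preset_objects(self) -> dict[str, PreparationPreset]:
        table = load_presets(self.preset_file) if self.preset_file else default_presets()
        return {name: table[name] for name in self.presets}

    def grid(self) -> np.ndarray:
        return pop.default_grid(self.grid_max, self.imaging.dt)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        violations = validate_config(raw)
        if violations:
            lines = "; ".join(f"{v['field']}: {v['message']}" for v in violations)
            raise ValueError(f"invalid configuration: {lines}")
        kwargs = dict(raw)
        for key, sub in (
            ("imaging", ImagingConfig),
            ("segmentation", SegmentationConfig),
            ("features", feat.FeatureConfig),
        ):
            if key in kwargs:
                kwargs[key] = sub(**kwargs[key])
        for key in ("presets", "concentrations"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["imaging"]["nucleus_semi_axes"] = list(d["imaging"]["nucleus_semi_axes"])
        d["presets"] = list(self.presets)
        d["concentrations"] = list(self.concentrations)
        return d


def validate_config(raw: dict) -> list[dict]:
    """Schema/range/preset checks on a raw config mapping.

    Returns a machine-readable list of violations (empty when valid).
    """
    violations: list[dict] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            violations.append({"field": key, "message": "unknown configuration field"})

    available = sorted(default_presets())
    for name in raw.get("presets", ()):
        if name not in available:
            violations.append(
                {
                    "field": "presets",
                    "message": f"unknown preset {name!r}; available: {available}",
                }
            )
    concs = raw.get("concentrations", DEFAULT_CONCENTRATIONS)
    if len(concs) == 0:
        violations.append(
            {"field": "concentrations", "message": "concentration grid is empty"}
        )
    for c in concs:
        if not np.isfinite(c) or c < 0:
            violations.append(
                {"field": "concentrations", "message": f"invalid concentration {c!r}"}
            )
    for key, lo in (("cells_per_movie", 1), ("movies_per_condition", 1)):
        if key in raw and raw[key] < lo:
            violations.append({"field": key, "message": f"must be >= {lo}"})
    for key, sub in (
        ("imaging", ImagingConfig),
        ("segmentation", SegmentationConfig),
        ("features", feat.FeatureConfig),
    ):
        if key in raw:
            try:
                sub(**raw[key])
            except (TypeError, ValueError) as exc:
                violations.append({"field": key, "message": str(exc)})
    return violations


def condition_seed(
    global_seed: int, preset: str, conc: float, stnfr: bool, movie_index: int
) -> int:
    """Per-movie seed: CRC32 of the condition key mixed with the global seed.

    Key-based (not order-based), so adding presets or concentrations leaves
    the seeds of existing conditions unchanged.
    """
    key = f"{preset}|{conc:.10g}|{int(bool(stnfr))}|{movie_index}"
    crc = zlib.crc32(key.encode())
    ss = np.random.SeedSequence([int(global_seed), crc])
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


# ---------------------------------------------------------------------------
# In-memory single-movie analysis (segment -> track -> trace -> features)


def analyze_movie(
    movie: Movie,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    feat_cfg: feat.FeatureConfig = feat.FeatureConfig(),
) -> tuple[LabelStack, list[Track], list[feat.Trace], pd.DataFrame]:
    """Run the measurement pipeline on one movie.

    Returns the label stack, tracks, per-cell traces, and the feature table.
    Cells whose trace cannot be normalized (no pre-stimulus cytoplasm) are
    excluded with a logged reason.
    """
    stack = segment_stack(movie.nuclear, seg_cfg)
    rings = ring_stack(stack, seg_cfg.ring_inner, seg_cfg.ring_outer)
    tracks = link_tracks(stack, seg_cfg.max_displacement, seg_cfg.max_gap)
    traces = []
    for track in tracks:
        try:
            traces.append(
                feat.extract_trace(
                    movie.reporter,
                    track,
                    stack.labels,
                    rings,
                    movie.stim_frame,
                    movie.dt,
                    background=feat_cfg.background,
                )
            )
        except feat.TraceExtractionError as exc:
            log.info("excluded: %s", exc)
    table = feat.features_table(traces, feat_cfg)
    return stack, tracks, traces, table


def summarize_condition(
    preparation: str,
    concentration: float,
    stnfr: bool,
    traces: list[feat.Trace],
    table: pd.DataFrame,
    grid: np.ndarray,
) -> pop.ConditionSummary:
    """Aggregate one condition's traces and features into a summary."""
    active_ids = set(table.loc[table["active"], "track_id"])
    active_traces = [t for t in traces if t.track_id in active_ids]
    course = pop.average_time_course(active_traces, grid)
    act = table[table["active"]]
    means, sds = {}, {}
    for col in ("peak_amp", "time_to_peak", "peak_width"):
        vals = act[col].to_numpy(dtype=float)
        if col == "peak_width":
            vals = act.loc[~act["width_censored"], col].to_numpy(dtype=float)
        means[col] = float(np.mean(vals)) if len(vals) else float("nan")
        sds[col] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return pop.ConditionSummary(
        preparation=preparation,
        concentration=concentration,
        stnfr=stnfr,
        n_total=len(table),
        n_active=len(act),
        grid=grid,
        average_course=course,
        feature_means=means,
        feature_sds=sds,
    )


# ---------------------------------------------------------------------------
# Staged on-disk run


def _conditions(config: PipelineConfig):
    arms = (False, True) if config.stnfr_arm else (False,)
    for preset in config.presets:
        for conc in config.concentrations:
            for stnfr in arms:
                yield preset, conc, stnfr


def _tag(preset: str, conc: float, stnfr: bool, movie_index: int) -> str:
    arm = "stnfr" if stnfr else "ctrl"
    return f"{preset}_{conc:.10g}_{arm}_m{movie_index}"


def run_full(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage, persisting intermediates under ``out_dir``.

    Stages skip work whose outputs already exist, so deleting one stage's
    files and re-running recomputes exactly that stage from the persisted
    intermediates of the one before.
    """
    out = Path(out_dir)
    manifest: dict = {"completed": []}
    manifest_path = out / "manifest.json"
    for d in ("movies", "labels", "tracks", "traces", "features", "summaries", "compare"):
        (out / d).mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    stages = [
        ("simulate", _stage_simulate),
        ("segment", _stage_segment),
        ("track", _stage_track),
        ("trace", _stage_trace),
        ("features", _stage_features),
        ("summarize", _stage_summarize),
        ("compare", _stage_compare),
    ]
    for name, fn in stages:
        try:
            fn(config, out)
        except Exception as exc:  # noqa: BLE001 - stage-named rewrap
            manifest["failed"] = name
            manifest_path.write_text(json.dumps(manifest, indent=2))
            raise StageError(name, str(exc)) from exc
        manifest["completed"].append(name)
        log.info("stage %s done", name)
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out


def _movie_jobs(config: PipelineConfig):
    for preset, conc, stnfr in _conditions(config):
        for m in range(config.movies_per_condition):
            yield preset, conc, stnfr, m, _tag(preset, conc, stnfr, m)


def _stage_simulate(config: PipelineConfig, out: Path) -> None:
    presets = config.preset_objects()
    for preset, conc, stnfr, m, tag in _movie_jobs(config):
        path = out / "movies" / f"{tag}.tif"
        if path.exists():
            continue
        seed = condition_seed(config.seed, preset, conc, stnfr, m)
        movie, truth = simulate_condition(
            presets[preset], conc, stnfr, config.cells_per_movie, config.imaging, seed
        )
        write_movie(movie, path)
        write_ground_truth(truth, out / "movies" / tag)


def _stage_segment(config: PipelineConfig, out: Path) -> None:
    for *_, tag in _movie_jobs(config):
        path = out / "labels" / f"{tag}.tif"
        if path.exists():
            continue
        movie = read_movie(out / "movies" / f"{tag}.tif")
        stack = segment_stack(movie.nuclear, config.segmentation)
        tifffile.imwrite(path, stack.labels.astype(np.uint16))
        stack.regions.to_csv(out / "labels" / f"{tag}.regions.csv", index=False)


def _load_label_stack(out: Path, tag: str) -> LabelStack:
    labels = tifffile.imread(out / "labels" / f"{tag}.tif").astype(np.int32)
    if labels.ndim == 2:
        labels = labels[None]
    regions = pd.read_csv(out / "labels" / f"{tag}.regions.csv")
    return LabelStack(labels=labels, regions=regions)


def _stage_track(config: PipelineConfig, out: Path) -> None:
    for *_, tag in _movie_jobs(config):
        path = out / "tracks" / f"{tag}.csv"
        if path.exists():
            continue
        stack = _load_label_stack(out, tag)
        tracks = link_tracks(
            stack, config.segmentation.max_displacement, config.segmentation.max_gap
        )
        tracks_to_df(tracks).to_csv(path, index=False)


def _tracks_from_df(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, grp in df.groupby("track_id"):
        t = Track(track_id=int(tid))
        for row in grp.sort_values("frame").itertuples():
            t.rows.append((int(row.frame), int(row.label), float(row.row), float(row.col)))
        tracks.append(t)
    return tracks


def _stage_trace(config: PipelineConfig, out: Path) -> None:
    for *_, tag in _movie_jobs(config):
        path = out / "traces" / f"{tag}.csv"
        if path.exists():
            continue
        movie = read_movie(out / "movies" / f"{tag}.tif")
        stack = _load_label_stack(out, tag)
        rings = ring_stack(stack, config.segmentation.ring_inner, config.segmentation.ring_outer)
        tracks = _tracks_from_df(pd.read_csv(out / "tracks" / f"{tag}.csv"))
        traces = []
        for track in tracks:
            try:
                traces.append(
                    feat.extract_trace(
                        movie.reporter,
                        track,
                        stack.labels,
                        rings,
                        movie.stim_frame,
                        movie.dt,
                        background=config.features.background,
                    )
                )
            except feat.TraceExtractionError as exc:
                log.info("excluded: %s", exc)
        feat.traces_table(traces).to_csv(path, index=False)


def _traces_from_df(df: pd.DataFrame) -> list[feat.Trace]:
    traces = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("time_min")
        traces.append(
            feat.Trace(
                track_id=int(tid),
                time=grp["time_min"].to_numpy(dtype=float),
                values=grp["intensity"].to_numpy(dtype=float),
                valid=grp["valid"].to_numpy(dtype=bool),
            )
        )
    return traces


def _stage_features(config: PipelineConfig, out: Path) -> None:
    for *_, tag in _movie_jobs(config):
        path = out / "features" / f"{tag}.csv"
        if path.exists():
            continue
        traces = _traces_from_df(pd.read_csv(out / "traces" / f"{tag}.csv"))
        feat.features_table(traces, config.features).to_csv(path, index=False)


def _stage_summarize(config: PipelineConfig, out: Path) -> None:
    summary_path = out / "summaries" / "summary.csv"
    courses_path = out / "summaries" / "courses.csv"
    if summary_path.exists() and courses_path.exists():
        return
    grid = config.grid()
    rows = []
    courses: dict[str, np.ndarray] = {}
    for preset, conc, stnfr in _conditions(config):
        traces: list[feat.Trace] = []
        tables = []
        for m in range(config.movies_per_condition):
            tag = _tag(preset, conc, stnfr, m)
            movie_traces = _traces_from_df(pd.read_csv(out / "traces" / f"{tag}.csv"))
            # offset track ids so cells from different movies stay distinct
            offset = 100000 * m
            for t in movie_traces:
                traces.append(
                    feat.Trace(
                        track_id=t.track_id + offset,
                        time=t.time,
                        values=t.values,
                        valid=t.valid,
                    )
                )
            table = pd.read_csv(out / "features" / f"{tag}.csv")
            table["track_id"] += offset
            tables.append(table)
        table = pd.concat(tables, ignore_index=True)
        summary = summarize_condition(preset, conc, stnfr, traces, table, grid)
        rows.append(
            {
                "preparation": preset,
                "concentration": conc,
                "stnfr": stnfr,
                "n_total": summary.n_total,
                "n_active": summary.n_active,
                "fraction_active": summary.fraction_active,
                **{f"mean_{k}": v for k, v in summary.feature_means.items()},
                **{f"sd_{k}": v for k, v in summary.feature_sds.items()},
            }
        )
        if not summary.empty:
            courses[summary.label] = summary.average_course
    pd.DataFrame(rows).to_csv(summary_path, index=False)
    courses_df = pd.DataFrame({"time_min": grid, **courses})
    courses_df.to_csv(courses_path, index=False)


def _stage_compare(config: PipelineConfig, out: Path) -> None:
    sim_path = out / "compare" / "similarity.csv"
    if not sim_path.exists():
        courses = pd.read_csv(out / "summaries" / "courses.csv")
        summary = pd.read_csv(out / "summaries" / "summary.csv")
        grid = courses["time_min"].to_numpy()
        summaries = []
        for row in summary.itertuples():
            s = pop.ConditionSummary(
                preparation=row.preparation,
                concentration=row.concentration,
                stnfr=bool(row.stnfr),
                n_total=int(row.n_total),
                n_active=int(row.n_active),
                grid=grid,
                average_course=None,
            )
            if s.label in courses.columns:
                s.average_course = courses[s.label].to_numpy()
            summaries.append(s)
        control = [s for s in summaries if not s.stnfr and not s.empty]
        if control:
            mat = pop.similarity_matrix(control)
            pd.DataFrame(mat.distances, index=mat.labels, columns=mat.labels).to_csv(
                sim_path
            )
        if any(s.stnfr for s in summaries):
            effects = []
            by_key = {(s.preparation, s.concentration, s.stnfr): s for s in summaries}
            for (prep, conc, stnfr), s in by_key.items():
                if stnfr:
                    continue
                blocked = by_key.get((prep, conc, True))
                if blocked is None:
                    continue
                eff = pop.receptor_effect(s, blocked)
                effects.append(
                    {
                        "preparation": eff.preparation,
                        "concentration": eff.concentration,
                        "cosine_distance": eff.distance,
                        "n_active_control": eff.n_active_control,
                        "n_active_stnfr": eff.n_active_stnfr,
                        "defensible": eff.defensible,
                    }
                )
            pd.DataFrame(effects).to_csv(out / "compare" / "receptor_effect.csv", index=False)
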