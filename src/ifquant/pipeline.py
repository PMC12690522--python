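"""End-to-end orchestration: simulate -> segment -> quantify -> compare.

A run is described by a :class:`RunConfig` (built from a YAML mapping),
executed stage by stage with structured logging, and summarized in a
:class:`RunManifest` listing every output file with its SHA-256 checksum.
Re-running an identical config reproduces byte-identical tables.

All outputs are plain CSV/JSON with documented headers so results are
diffable. Floats in exported tables are formatted at 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import align_growth, km_estimate, mann_whitney
from .errors import ConfigError, StageError
from .image import write_mip
from .quantify import (MarkerThresholds, baseline_normalize, classify_markers,
                       measure_objects, size_filter, summarize,
                       thresholds_from_preset)
from .segmentation import segment_nuclei
from .synthetic import (MarkerSpec, SceneParams, SyntheticCohortParams,
                        generate_growth_tables, generate_scene,
                        generate_survival_table)

log = logging.getLogger("ifquant")

CSV_FLOAT_FORMAT = "%.6g"


def write_csv(df: pd.DataFrame, path) -> None:
    """Export a table with the run-wide float format (6 significant digits)."""
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Full description of one reproducible run (see README for the YAML form)."""

    output_dir: Path
    seed: int = 0
    nuclear_channel: str = "Hoechst"
    markers: list[MarkerSpec] = field(default_factory=list)  # empty -> scene defaults
    scene: dict = field(default_factory=dict)          # SceneParams overrides
    genotypes: dict[str, dict] = field(default_factory=lambda: {"Ctrl": {}})
    samples_per_genotype: int = 3
    images_per_sample: int = 5
    thresholds: MarkerThresholds = None
    size_bounds: tuple[float, float] = (5.0, 60.0)
    baseline_fraction: float = 0.10
    smoothing_scale: float = 0.5
    min_seed_distance: float = 2.5
    survival: dict | None = None                       # SyntheticCohortParams overrides
    growth: dict | None = None
    compare_metric: str | None = None
    alpha: float = 0.05
    save_images: bool = False

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        markers = [MarkerSpec(**m) if isinstance(m, dict) else MarkerSpec(
            channel=m, positive_fraction_tumor=1.0, positive_fraction_stroma=0.0)
            for m in cfg.pop("markers", [])]
        thr = cfg.pop("thresholds", "tracer_pair2")
        thresholds = (thresholds_from_preset(thr) if isinstance(thr, str)
                      else MarkerThresholds.from_dict(thr))
        return cls(output_dir=Path(cfg.pop("output_dir", "ifquant-run")),
                   markers=markers, thresholds=thresholds,
                   size_bounds=tuple(cfg.pop("size_bounds", (5.0, 60.0))),
                   **cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    @property
    def effective_markers(self) -> list[MarkerSpec]:
        from .synthetic import default_markers
        return list(self.markers) if self.markers else default_markers()

    def validate(self) -> None:
        if self.thresholds is None:
            raise ConfigError("no marker thresholds configured")
        channel_names = ({self.nuclear_channel}
                         | {m.channel for m in self.effective_markers})
        for name, thr in self.thresholds:
            if thr.channel not in channel_names:
                raise ConfigError(
                    f"threshold {name!r} references unknown channel {thr.channel!r}; "
                    f"known channels: {sorted(channel_names)}")
        if self.samples_per_genotype < 1 or self.images_per_sample < 1:
            raise ConfigError("samples_per_genotype and images_per_sample must be >= 1")
        if not self.genotypes:
            raise ConfigError("at least one genotype required")
        # scene overrides must be valid before any image work
        self._scene_params("__validate__", 0).validate()

    def _scene_params(self, genotype: str, seed: int) -> SceneParams:
        overrides = dict(self.scene)
        overrides.update(self.genotypes.get(genotype, {}) or {})
        if "image_shape" in overrides:
            overrides["image_shape"] = tuple(overrides["image_shape"])
        if "nucleus_area_range" in overrides:
            overrides["nucleus_area_range"] = tuple(overrides["nucleus_area_range"])
        kwargs = dict(nuclear_channel=self.nuclear_channel, seed=seed, **overrides)
        if self.markers:
            kwargs["markers"] = list(self.markers)
        return SceneParams(**kwargs)


@dataclass
class RunManifest:
    """Record of one run: config echo, software version, outputs, warnings."""

    config: dict
    version: str
    completed_stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    segmentation_reports: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)

    def write(self, path: Path) -> None:
        path.write_text(self.to_json())


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["output_dir"] = str(d["output_dir"])
    d["thresholds"] = {k: dataclasses.asdict(v) for k, v in config.thresholds}
    return d


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order; abort on the first stage error.

    Stage errors are re-raised as :class:`StageError` with stage identity,
    after the manifest (recording completed stages) is written to
    ``output_dir/manifest.json``.
    """
    manifest = RunManifest(config={}, version=__version__)
    out = config.output_dir

    def finish_stage(name: str) -> None:
        manifest.completed_stages.append(name)

    def record(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out))] = _sha256(path)

    try:
        config.validate()
        manifest.config = _config_echo(config)
        out.mkdir(parents=True, exist_ok=True)
        finish_stage("validate")

        rng = np.random.default_rng(np.random.SeedSequence(config.seed))

        # ---------------- simulate + segment + measure ----------------
        records_all = []
        meta_rows = []
        channels = [config.nuclear_channel] + [m.channel for m in config.effective_markers]
        truth_rows = []
        for genotype in config.genotypes:
            for s in range(config.samples_per_genotype):
                sample_id = f"{genotype}-s{s}"
                for i in range(config.images_per_sample):
                    scene_seed = int(rng.integers(0, 2**31 - 1))
                    params = config._scene_params(genotype, scene_seed)
                    image, truth = generate_scene(params)
                    image.image_id = f"{sample_id}-img{i}"
                    meta_rows.append((image.image_id, sample_id, genotype))
                    for ch, frac in truth.clipped_fraction.items():
                        if frac > 0:
                            manifest.warnings.append(
                                f"{image.image_id}: {frac:.2%} saturated pixels in {ch}")
                    if config.save_images:
                        img_path = out / "images" / f"{image.image_id}.tif"
                        img_path.parent.mkdir(exist_ok=True)
                        write_mip(img_path, image)
                        record(img_path)
                    t = truth.cells.copy()
                    t.insert(0, "image_id", image.image_id)
                    t["genotype"] = genotype
                    truth_rows.append(t)

                    labels, report = segment_nuclei(
                        image, config.nuclear_channel,
                        smoothing_scale=config.smoothing_scale,
                        min_seed_distance=config.min_seed_distance)
                    manifest.segmentation_reports.append(report)
                    records_all.append(measure_objects(labels, image))
                    log.info("segment %s: %d objects, threshold %.3f",
                             image.image_id, report["n_objects"], report["threshold"])
        records = pd.concat(records_all, ignore_index=True)
        image_meta = pd.DataFrame(meta_rows, columns=["image_id", "sample_id", "genotype"])
        truth_table = pd.concat(truth_rows, ignore_index=True)
        truth_path = out / "ground_truth.csv"
        write_csv(truth_table, truth_path)
        record(truth_path)
        finish_stage("simulate-segment-measure")

        # ---------------- quantify ----------------
        n_raw = len(records)
        filtered, n_dropped = size_filter(records, *config.size_bounds)
        log.info("size filter [%g, %g] um^2: %d raw -> %d kept, %d dropped",
                 *config.size_bounds, n_raw, len(filtered), n_dropped)
        normalized, baselines = baseline_normalize(
            filtered, [m.channel for m in config.effective_markers],
            baseline_fraction=config.baseline_fraction)
        classified = classify_markers(normalized, config.thresholds)
        nuclei_path = out / "nuclei.csv"
        write_csv(classified, nuclei_path)
        record(nuclei_path)
        baselines_path = out / "baselines.csv"
        write_csv(baselines, baselines_path)
        record(baselines_path)
        finish_stage("quantify")

        # ---------------- summarize ----------------
        marker_names = [name for name, _ in config.thresholds]
        conjunctions = [tuple(marker_names[:2])] if len(marker_names) >= 2 else []
        per_image, per_sample, per_genotype = summarize(
            classified, image_meta, marker_names, conjunctions)
        for name, df in (("per_image", per_image), ("per_sample", per_sample),
                         ("per_genotype", per_genotype)):
            p = out / f"summary_{name}.csv"
            write_csv(df, p)
            record(p)
        n_empty = int(per_image["empty"].sum())
        if n_empty:
            manifest.warnings.append(f"{n_empty} images empty after filtering")
        log.info("summaries: %d images (%d empty), %d samples, %d genotypes",
                 len(per_image), n_empty, len(per_sample), len(per_genotype))
        finish_stage("summarize")

        # ---------------- compare ----------------
        metric = config.compare_metric or (f"prop_{marker_names[0]}" if marker_names else None)
        if metric and len(config.genotypes) >= 2:
            genos = list(config.genotypes)
            comp_rows = []
            for a_i in range(len(genos)):
                for b_i in range(a_i + 1, len(genos)):
                    a, b = genos[a_i], genos[b_i]
                    xa = per_sample.loc[per_sample["genotype"] == a, metric]
                    xb = per_sample.loc[per_sample["genotype"] == b, metric]
                    cmp_ = mann_whitney(xa, xb, alpha=config.alpha)
                    comp_rows.append({"group1": a, "group2": b, "metric": metric,
                                      "n1": cmp_.n1, "n2": cmp_.n2, "U": cmp_.u,
                                      "p": cmp_.p, "method": cmp_.method,
                                      "significant": cmp_.significant})
            comp_path = out / "comparisons.csv"
            write_csv(pd.DataFrame(comp_rows), comp_path)
            record(comp_path)
        finish_stage("compare")

        # ---------------- cohort survival / growth ----------------
        if config.survival is not None:
            km_frames = []
            surv_frames = []
            for genotype in config.genotypes:
                params = SyntheticCohortParams(
                    group=genotype, seed=int(rng.integers(0, 2**31 - 1)),
                    **(config.survival or {}))
                table = generate_survival_table(params)
                surv_frames.append(table)
                curve = km_estimate(table)
                f = curve.to_frame()
                f.insert(0, "group", genotype)
                f["median"] = curve.median if curve.median is not None else np.nan
                km_frames.append(f)
                log.info("KM %s: n=%d, median=%s", genotype, curve.n_total, curve.median)
            for name, df in (("survival", pd.concat(surv_frames, ignore_index=True)),
                             ("km", pd.concat(km_frames, ignore_index=True))):
                p = out / f"{name}.csv"
                write_csv(df, p)
                record(p)
            finish_stage("survival")

        if config.growth is not None:
            growth_cfg = dict(config.growth)
            rates = growth_cfg.pop("growth_rate", 0.08)
            frames = []
            for genotype in config.genotypes:
                rate = rates.get(genotype, 0.08) if isinstance(rates, dict) else rates
                params = SyntheticCohortParams(
                    group=genotype, growth_rate=rate,
                    seed=int(rng.integers(0, 2**31 - 1)), **growth_cfg)
                frames.append(generate_growth_tables(params))
            growth_table = pd.concat(frames, ignore_index=True)
            aligned, excluded = align_growth(growth_table)
            for a in excluded:
                manifest.warnings.append(f"growth series {a}: no post-induction measurements")
            for name, df in (("growth", growth_table), ("growth_aligned", aligned)):
                p = out / f"{name}.csv"
                write_csv(df, p)
                record(p)
            finish_stage("growth")

    except Exception as exc:  # record progress, then surface stage identity
        stage = {0: "validate"}.get(len(manifest.completed_stages),
                                    f"after:{manifest.completed_stages[-1]}"
                                    if manifest.completed_stages else "validate")
        manifest.failed_stage = stage
        if out.exists():
            manifest.write(out / "manifest.json")
        if isinstance(exc, ConfigError):
            raise
        raise StageError(stage, exc) from exc

    manifest.write(out / "manifest.json")
    return manifest
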