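"""Configuration, orchestration and end-to-end runs.

A single YAML config drives simulation -> measurement -> statistics.  One
global seed is fanned out to per-stage substreams keyed by stable stage
names, so adding or reordering stages never perturbs another stage's
draws.  Every run writes a manifest with a config hash for provenance,
and all tabular outputs are CSV with units in the column names.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fundusgeom import fundus_pipeline as fp
from fundusgeom import geometry, stats, synthgen

__all__ = [
    "RunConfig",
    "StudyReport",
    "ConfigError",
    "validate_config",
    "stage_seed",
    "run_pipeline",
    "measure_image",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class MeasureParams:
    spur_len_px: float = 5.0
    probe_len_px: float = 16.0
    zone_lo_dd: float = 1.0
    zone_hi_dd: float = 1.5
    zone_from_margin: bool = False
    min_sections: int = 10
    backend: str = "truth"  # vessel segmentation backend name


@dataclass
class RunConfig:
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate", "measure", "stats"])
    out_dir: str = "fundusgeom_run"
    n_images: int = 5
    tree: synthgen.VesselTreeSpec = field(default_factory=synthgen.VesselTreeSpec)
    cohort: synthgen.CohortSpec = field(default_factory=synthgen.CohortSpec)
    measure: MeasureParams = field(default_factory=MeasureParams)
    noise_sd: float = 4.0
    av_contrast: float = 30.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.measure.zone_lo_dd < self.measure.zone_hi_dd):
            raise ConfigError(
                "zone bounds must satisfy 0 < zone_lo_dd < zone_hi_dd, got "
                f"{self.measure.zone_lo_dd} / {self.measure.zone_hi_dd}"
            )
        unknown = [s for s in self.stages if s not in ("simulate", "measure", "stats")]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        if self.n_images < 0:
            raise ConfigError("n_images must be >= 0")


def _known_fields(cls) -> dict[str, type]:
    return {f.name: f for f in dataclasses.fields(cls)}


def _build_dataclass(cls, data: dict, path: str):
    fields = _known_fields(cls)
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            hint = difflib.get_close_matches(key, fields, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {path}{key!r}{suffix}")
        ftype = fields[key].type
        if isinstance(value, dict) and key in ("tree", "cohort", "measure"):
            sub_cls = {"tree": synthgen.VesselTreeSpec,
                       "cohort": synthgen.CohortSpec,
                       "measure": MeasureParams}[key]
            value = _build_dataclass(sub_cls, value, path=f"{path}{key}.")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


def validate_config(source) -> RunConfig:
    """Load and validate a YAML config (path, mapping, or YAML string).

    Missing keys take documented defaults; unknown keys are rejected with
    a nearest-match suggestion.
    """
    if isinstance(source, RunConfig):
        cfg = source
    else:
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = yaml.safe_load(Path(source).read_text()) or {}
        elif isinstance(source, str):
            data = yaml.safe_load(source) or {}
        elif isinstance(source, dict):
            data = source
        else:
            raise ConfigError(f"cannot read config from {source!r}")
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        cfg = _build_dataclass(RunConfig, data, path="")
    cfg.validate()
    cfg.tree.validate()
    cfg.cohort.validate()
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream seed (independent of stage order)."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _canon(obj):
    if isinstance(obj, dict):
        return sorted((str(k), _canon(v)) for k, v in obj.items())
    if isinstance(obj, (list, tuple)):
        return [_canon(v) for v in obj]
    return str(obj)


def config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (execution details such as
    output paths and log level do not change what is computed)."""
    d = dataclasses.asdict(cfg)
    d.pop("out_dir", None)
    d.pop("log_level", None)
    canon = json.dumps(_canon(d))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    config_hash: str
    seed: int
    stages_run: list[str]
    stages_failed: list[str]
    manifest: dict[str, str]  # artifact name -> path
    summary: dict

    def ok(self) -> bool:
        return not self.stages_failed


def measure_image(
    image: np.ndarray,
    params: MeasureParams,
    truth_mask: np.ndarray | None = None,
    laterality: str = "OD",
    disc=None,
):
    """Measure one fundus image end to end.

    Preprocess, segment (with the configured backend), A/V-classify,
    detect the disc (unless a reference ``disc`` is supplied), extract
    the centerline graph, measure diameters, summarize annulus calibers
    and bifurcation angles.  Returns a dict of results.
    """
    pre = fp.preprocess(image)
    mask = fp.segment_vessels(pre, backend=params.backend, truth_mask=truth_mask)
    clg = geometry.extract_centerline(mask, spur_len=params.spur_len_px)
    av = fp.classify_arteries_veins(pre, mask, clg)
    geometry.label_edges(clg, av.labels)
    if disc is None:
        disc = fp.locate_and_segment_disc(pre)
    profile = geometry.measure_diameters(mask, clg)
    summary = geometry.annulus_calibers(
        profile, disc, zone=(params.zone_lo_dd, params.zone_hi_dd),
        zone_from_margin=params.zone_from_margin, min_sections=params.min_sections,
    )
    angles = geometry.bifurcation_angles(
        clg, disc=disc, laterality=laterality, profile=profile,
        probe_len=params.probe_len_px,
    )
    return {
        "pre": pre,
        "mask": mask,
        "av": av,
        "graph": clg,
        "disc": disc,
        "profile": profile,
        "calibers": summary,
        "angles": angles,
        "quadrant_means": geometry.quadrant_angle_means(angles),
    }


def run_pipeline(config) -> StudyReport:
    """Run the configured stages; deterministic for a fixed seed.

    A stage failure marks the stage failed, skips downstream stages, and
    leaves the report with ``ok() == False``.
    """
    cfg = validate_config(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    manifest: dict[str, str] = {}
    summary: dict = {"config_hash": chash, "seed": cfg.seed}
    run_order = [s for s in ("simulate", "measure", "stats") if s in cfg.stages]
    stages_run: list[str] = []
    stages_failed: list[str] = []
    images = []

    for stage in run_order:
        if stages_failed:
            log.warning("skipping stage %s after failure", stage)
            continue
        try:
            if stage == "simulate":
                sseed = stage_seed(cfg.seed, "simulate")
                img_dir = out / "images"
                img_dir.mkdir(exist_ok=True)
                for i in range(cfg.n_images):
                    spec = dataclasses.replace(cfg.tree, seed=sseed + i)
                    truth = synthgen.generate_vessel_tree(spec)
                    img, vm, avm, dm = synthgen.render_fundus(
                        truth, noise_sd=cfg.noise_sd, av_contrast=cfg.av_contrast,
                        noise_seed=sseed + i,
                    )
                    images.append((truth, img, vm, avm))
                    from PIL import Image

                    Image.fromarray(img.astype(np.uint8)).save(img_dir / f"img_{i:03d}.png")
                    truth_json = {
                        "disc_center": list(truth.disc_center),
                        "disc_diameter_px": truth.disc_diameter_px,
                        "n_segments": len(truth.segments),
                        "bifurcation_angles_deg": [b.angle_deg for b in truth.bifurcations],
                        "config_hash": chash,
                    }
                    (img_dir / f"img_{i:03d}_truth.json").write_text(
                        json.dumps(truth_json, indent=1))
                manifest["images"] = str(img_dir)
                cspec = dataclasses.replace(
                    cfg.cohort, seed=stage_seed(cfg.seed, "simulate-cohort"))
                cohort = synthgen.generate_cohort(cspec)
                (out / "cohort.csv").write_text(cohort.to_csv())
                manifest["cohort"] = str(out / "cohort.csv")
                summary["n_images"] = cfg.n_images
                summary["n_eyes"] = int(len(cohort.df))
            elif stage == "measure":
                rows = []
                for i, (truth, img, vm, avm) in enumerate(images):
                    res = measure_image(img, cfg.measure, truth_mask=vm)
                    cal = res["calibers"]
                    rows.append({
                        "image": i,
                        "dd_px": res["disc"].dd,
                        "rel_arteriolar_caliber": cal.rel_arteriolar,
                        "rel_venular_caliber": cal.rel_venular,
                        "avr": cal.avr,
                        "n_bifurcations": len(res["angles"]),
                        "mean_angle_deg": (
                            float(np.mean([a.angle_deg for a in res["angles"]]))
                            if res["angles"] else np.nan),
                    })
                meas = pd.DataFrame(rows)
                meas.to_csv(out / "measurements.csv", index=False)
                manifest["measurements"] = str(out / "measurements.csv")
                summary["measurement_means"] = (
                    meas.drop(columns=["image"]).mean(numeric_only=True).to_dict())
            elif stage == "stats":
                cohort_path = out / "cohort.csv"
                df = pd.read_csv(cohort_path)
                tables = stats.build_comparison_report(df)
                tables.table1.to_csv(out / "table1.csv", index=False)
                tables.table2.to_csv(out / "table2.csv", index=False)
                models = {
                    "crvo_vs_brvo": {
                        m: [dataclasses.asdict(t) for t in r.terms]
                        for m, r in tables.model_crvo_vs_brvo.items()
                    },
                    "affected_vs_fellow": {
                        m: [dataclasses.asdict(t) for t in r.terms]
                        for m, r in tables.model_affected_vs_fellow.items()
                    },
                }
                (out / "logistic_models.json").write_text(json.dumps(models, indent=1))
                manifest["table1"] = str(out / "table1.csv")
                manifest["table2"] = str(out / "table2.csv")
                manifest["logistic_models"] = str(out / "logistic_models.json")
                summary["crvo_venular_or"] = (
                    tables.model_crvo_vs_brvo["rel_venular_caliber"]
                    .term("rel_venular_caliber").odds_ratio)
            stages_run.append(stage)
        except Exception:
            log.exception("stage %s failed", stage)
            stages_failed.append(stage)

    report = StudyReport(
        config_hash=chash, seed=cfg.seed, stages_run=stages_run,
        stages_failed=stages_failed, manifest=manifest, summary=summary,
    )
    (out / "report.json").write_text(json.dumps({
        "config_hash": chash, "seed": cfg.seed, "stages_run": stages_run,
        "stages_failed": stages_failed, "manifest": manifest,
        "summary": _jsonable(summary),
    }, indent=1, sort_keys=True))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
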