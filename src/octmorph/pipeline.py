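"""End-to-end pipeline: simulate -> segment -> measure -> stats -> diagnose.

The pipeline samples a two-eye parameter cohort from the published group
summaries, renders an ONH and a fovea B-scan per eye from its sampled
parameters, segments and measures the scans, and runs the statistical
layer (group comparison table, percent-of-control table) and the
fixed-threshold diagnostic table on the *measured* parameters. Outputs are
deterministic CSVs plus a JSON run manifest with configuration, versions
and file checksums.
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

from . import reference
from .diagnose import DiagRule, diagnostic_table
from .fovea import measure_fovea
from .onh import OnhMeasureConfig, measure_onh
from .scan import ScanMeta
from .segment import elm_detectability, segment_fovea_layers, segment_onh
from .stats import group_table, percent_table
from .synth import (NoiseModel, fovea_geometry_from_row, generate_fovea_bscan,
                    generate_onh_bscan, onh_geometry_from_row, sample_cohort)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Configuration for one simulated study run."""

    n_case: int = 20
    n_control: int = 20
    unilateral_fraction: float = 0.65
    seed: int = 0
    offset_um: float = 150.0
    rnfl_from: str = "centre"
    rnfl_eccentricity_deg: float = 6.0
    um_per_degree: float = 292.0
    elm_threshold: float = 1.2
    alpha: float = 0.05
    bonferroni_m: int | None = None
    control_eyes: str = "one"
    speckle_scale: float = 0.5
    additive_sigma: float = 0.02
    blur_sigma_px: float = 1.0
    render_scans: bool = True
    elm_present_in_cases: bool = False

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one participant per group")
        if self.um_per_degree <= 0 or self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("invalid calibration or alpha")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def measure_eye(row, config: PipelineConfig, noise_seed: int) -> dict:
    """Render, segment and measure both scans for one cohort row."""
    meta_onh = ScanMeta(um_per_degree=config.um_per_degree, scan_kind="onh")
    meta_fov = ScanMeta(um_per_degree=config.um_per_degree, scan_kind="fovea")
    noise = NoiseModel(config.speckle_scale, config.additive_sigma,
                       config.blur_sigma_px, seed=noise_seed)
    out: dict = {}

    scan, _ = generate_onh_bscan(onh_geometry_from_row(row), meta_onh, noise,
                                 offset_um=config.offset_um)
    b = segment_onh(scan)
    params = measure_onh(b, meta_onh, OnhMeasureConfig(
        config.offset_um, config.rnfl_from, config.rnfl_eccentricity_deg))
    out.update({k: v for k, v in params.to_dict().items() if k != "no_cup"})

    affected_case = bool(row["group"] == "case" and row["affected"])
    elm_present = config.elm_present_in_cases if affected_case else True
    fscan, _ = generate_fovea_bscan(
        fovea_geometry_from_row(row, elm_present=elm_present),
        meta_fov, dataclasses.replace(noise, seed=noise_seed + 1))
    fb = segment_fovea_layers(fscan)
    elm = elm_detectability(fscan, fb, threshold=config.elm_threshold)
    fparams = measure_fovea(fb, meta_fov, elm)
    out["foveal_pit_width_deg"] = fparams.pit_width_deg
    out["foveal_pit_depth_um"] = fparams.pit_depth_um
    out["elm_detected"] = fparams.elm_detected
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write the report bundle.

    Writes the sampled cohort, the measured cohort (when scans are
    rendered), a group-comparison table, a percent-of-control table, a
    diagnostic-accuracy table and a JSON manifest; returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        cohort = sample_cohort(reference.PCG, reference.PCG_CONTROL,
                               config.n_case, config.n_control,
                               config.unilateral_fraction, seed=config.seed)
        cohort_path = outdir / "cohort_sampled.csv"
        _write_csv(cohort, cohort_path)

        analysis = cohort
        if config.render_scans:
            stage = "segment/measure"
            measured_rows = []
            for i, (_, row) in enumerate(cohort.iterrows()):
                try:
                    m = measure_eye(row, config, noise_seed=config.seed * 100003 + i)
                except Exception as exc:   # noqa: BLE001 - aborts with context
                    raise RuntimeError(
                        f"stage {stage} failed for {row['participant_id']} "
                        f"{row['eye']}: {exc}") from exc
                rec = {k: row[k] for k in ("participant_id", "group", "eye",
                                           "age_years", "affected")}
                rec.update(m)
                measured_rows.append(rec)
            analysis = pd.DataFrame(measured_rows)
            _write_csv(analysis, outdir / "cohort_measured.csv")

        stage = "stats"
        params = [p for p in reference.ONH_PARAMS + reference.FOVEA_PARAMS
                  if p in analysis.columns]
        t2 = group_table(analysis, params, bonferroni_m=config.bonferroni_m)
        _write_csv(t2, outdir / "group_comparison.csv")
        t2c = percent_table(analysis, params)
        _write_csv(t2c, outdir / "percent_of_control.csv")

        stage = "diagnose"
        rules = [DiagRule(p, t, d) for p, t, d in reference.FIXED_RULES
                 if p in analysis.columns]
        t3 = diagnostic_table(analysis, rules, control_eyes=config.control_eyes)
        _write_csv(t3, outdir / "diagnostic_accuracy.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    import octmorph
    files = sorted(p.name for p in outdir.glob("*.csv"))
    manifest = {
        "config": dataclasses.asdict(config),
        "versions": {"octmorph": octmorph.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "outputs": {name: _sha256(outdir / name) for name in files},
        "n_eyes": int(len(cohort)),
        "n_affected_eyes": int(cohort["affected"].sum()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
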