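"""Validated run configuration and the multi-stage pipeline driver.

A :class:`RunConfig` (YAML or JSON on disk) lists stages to execute in
order; unknown keys are rejected at load time so a typo cannot silently
fall back to a default.  :func:`run_pipeline` executes the stages, writes
their outputs under ``output_dir`` and finishes with a ``manifest.json``
recording the tool version, a hash of the canonical config, the seed, and
per-stage record counts — the same config and inputs reproduce the same
manifest except for the timestamp.

Also hosts :func:`synthetic_phase_grid_experiment`, the end-to-end
simulate → quantify → classify loop used to validate threshold recovery on
a concentration grid with a known droplet onset.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Annotated, Literal, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .imaging import ROISpec, index_of_dispersion, quantify_image, tile_rois
from .io import (
    PEAK_COLUMNS,
    VESICLE_COLUMNS,
    read_image,
    read_table,
    write_image,
    write_table,
)
from .nmr import PeakTable, intensity_ratio_profile, pre_profile
from .phases import PhaseCondition, build_phase_diagram
from .vesicles import VesicleSet, radius_stats, surface_gaps

logger = logging.getLogger("condensate_metrics")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateImageStage(_StrictModel):
    kind: Literal["simulate_image"] = "simulate_image"
    output: str = "synthetic_image.tif"
    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 481.5
    n_droplets: int = 5
    droplet_radius_px: tuple[float, float] = (12.0, 2.0)
    partition_true: float = 10.0
    background_level: float = 50.0
    psf_sigma_px: float = 1.0
    noise_model: str = "poisson"


class SimulateVesiclesStage(_StrictModel):
    kind: Literal["simulate_vesicles"] = "simulate_vesicles"
    output: str = "synthetic_vesicles.csv"
    n_vesicles: int = 500
    radius_mean_nm: float = 9.10
    radius_sd_nm: float = 1.0
    region_radius_nm: float = 180.0


class QuantifyStage(_StrictModel):
    kind: Literal["quantify"] = "quantify"
    image: str
    pixel_size_nm: float | None = None
    roi_side_um: float = 61.63
    min_area_px: int = 4
    circularity: tuple[float, float] = (0.1, 1.0)
    output_prefix: str = "quantify"


class VesicleStatsStage(_StrictModel):
    kind: Literal["vesicle_stats"] = "vesicle_stats"
    coords: str
    mode: Literal["nearest_neighbour", "all_pairs"] = "nearest_neighbour"
    cutoff_nm: float = 20.0
    output_prefix: str = "vesicle"


class NmrRatioStage(_StrictModel):
    kind: Literal["nmr_ratio"] = "nmr_ratio"
    numerator: str
    denominator: str
    noise_multiple: float = 3.0
    output: str = "intensity_ratio.csv"


class NmrPreStage(_StrictModel):
    kind: Literal["nmr_pre"] = "nmr_pre"
    para: str
    dia: str
    delta_t_s: float = 0.007
    output: str = "pre_rates.csv"


Stage = Annotated[
    Union[
        SimulateImageStage,
        SimulateVesiclesStage,
        QuantifyStage,
        VesicleStatsStage,
        NmrRatioStage,
        NmrPreStage,
    ],
    Field(discriminator="kind"),
]


class RunConfig(_StrictModel):
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "condensate_metrics_out"
    stages: list[Stage] = Field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True),
            encoding="utf-8",
        )
        return path

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage execution
# ---------------------------------------------------------------------------

def _run_stage(stage: Stage, out_dir: Path, seed: int) -> tuple[list[Path], int]:
    """Execute one stage; returns (output paths, record count)."""
    from . import synthetic  # local import: synthetic depends on the analysers

    if isinstance(stage, SimulateImageStage):
        params = synthetic.DropletImageParams(
            image_size_px=stage.image_size_px,
            pixel_size_nm=stage.pixel_size_nm,
            n_droplets=stage.n_droplets,
            droplet_radius_px=stage.droplet_radius_px,
            partition_true=stage.partition_true,
            background_level=stage.background_level,
            psf_sigma_px=stage.psf_sigma_px,
            noise_model=stage.noise_model,
            seed=seed,
        )
        image, _, truth = synthetic.gen_droplet_image(params)
        img_path = write_image(out_dir / stage.output, image)
        truth_path = write_table(out_dir / (Path(stage.output).stem + "_truth.csv"), truth)
        return [img_path, truth_path], len(truth)

    if isinstance(stage, SimulateVesiclesStage):
        params = synthetic.VesiclePackingParams(
            n_vesicles=stage.n_vesicles,
            radius_mean_nm=stage.radius_mean_nm,
            radius_sd_nm=stage.radius_sd_nm,
            region_radius_nm=stage.region_radius_nm,
            seed=seed,
        )
        vs = synthetic.gen_vesicle_packing(params)
        path = write_table(out_dir / stage.output, vs.to_table())
        return [path], len(vs)

    if isinstance(stage, QuantifyStage):
        image = read_image(stage.image, pixel_size_nm=stage.pixel_size_nm)
        spec = ROISpec(side_um=stage.roi_side_um, pixel_size_nm=image.pixel_size_nm)
        result = quantify_image(
            image, roi_spec=spec, min_area_px=stage.min_area_px,
            circularity_range=stage.circularity,
        )
        droplet_path = write_table(
            out_dir / f"{stage.output_prefix}_droplets.csv", result["droplets"].table
        )
        roi_path = write_table(
            out_dir / f"{stage.output_prefix}_rois.csv", result["roi_table"]
        )
        summary = {
            "threshold": result["threshold"],
            "n_droplets": result["droplets"].n_droplets,
        }
        if result["partition"] is not None:
            p, inside, outside = result["partition"]
            summary.update(partition=p, inside_mean=inside, outside_mean=outside)
        summary_path = out_dir / f"{stage.output_prefix}_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
        return [droplet_path, roi_path, summary_path], result["droplets"].n_droplets

    if isinstance(stage, VesicleStatsStage):
        table = read_table(stage.coords, required=VESICLE_COLUMNS)
        vs = VesicleSet.from_table(table)
        stats = surface_gaps(vs, mode=stage.mode, cutoff_nm=stage.cutoff_nm)
        mean_r, sem_r, n_r, hist = radius_stats(vs)
        gap_path = write_table(
            out_dir / f"{stage.output_prefix}_gaps.csv",
            pd.DataFrame({"gap_nm": stats.gaps_nm}),
        )
        hist_path = write_table(out_dir / f"{stage.output_prefix}_radius_hist.csv", hist)
        stats_path = out_dir / f"{stage.output_prefix}_stats.json"
        stats_path.write_text(
            json.dumps(
                {
                    "gap_mean_nm": stats.mean_nm,
                    "gap_sem_nm": stats.sem_nm,
                    "gap_n": stats.n,
                    "gap_mode": stats.mode,
                    "n_overlapping": stats.n_negative,
                    "radius_mean_nm": mean_r,
                    "radius_sem_nm": sem_r,
                    "radius_n": n_r,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )
        return [gap_path, hist_path, stats_path], stats.n

    if isinstance(stage, NmrRatioStage):
        num = PeakTable(read_table(stage.numerator, required=PEAK_COLUMNS, sep="\t"))
        den = PeakTable(read_table(stage.denominator, required=PEAK_COLUMNS, sep="\t"))
        profile = intensity_ratio_profile(num, den, noise_multiple=stage.noise_multiple)
        path = write_table(out_dir / stage.output, profile)
        return [path], len(profile)

    if isinstance(stage, NmrPreStage):
        para = PeakTable(read_table(stage.para, required=PEAK_COLUMNS, sep="\t"))
        dia = PeakTable(read_table(stage.dia, required=PEAK_COLUMNS, sep="\t"))
        profile = pre_profile(para, dia, delta_t_s=stage.delta_t_s)
        path = write_table(out_dir / stage.output, profile)
        return [path], len(profile)

    raise ValueError(f"unknown stage {stage!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write a manifest.

    Returns the manifest dict.  On stage failure the partially written
    outputs of that stage are renamed with a ``.partial`` suffix and the
    exception propagates.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "condensate-metrics",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "stages": [],
    }
    for i, stage in enumerate(config.stages):
        logger.info("stage %d: %s", i, stage.kind)
        stage_dir = out_dir / f".stage{i}.tmp"
        stage_dir.mkdir(exist_ok=True)
        try:
            outputs, n_records = _run_stage(stage, stage_dir, config.seed)
        except Exception:
            # keep whatever the stage managed to write, marked as partial
            for produced in sorted(stage_dir.iterdir()):
                produced.rename(out_dir / (produced.name + ".partial"))
            stage_dir.rmdir()
            raise
        final_paths = []
        for produced in sorted(stage_dir.iterdir()):
            target = out_dir / produced.name
            produced.rename(target)
            final_paths.append(target)
        stage_dir.rmdir()
        outputs = [out_dir / p.name for p in outputs]
        manifest["stages"].append(
            {
                "kind": stage.kind,
                "outputs": [p.name for p in outputs],
                "n_records": n_records,
            }
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# End-to-end synthetic phase grid
# ---------------------------------------------------------------------------

def synthetic_phase_grid_experiment(
    concentrations_uM: list[float],
    onset_uM: float,
    seed: int = 0,
    image_size_px: tuple[int, int] = (256, 256),
    roi_side_px: int = 64,
    n_droplets: int = 12,
    partition_true: float = 10.0,
) -> tuple[list[PhaseCondition], float | None]:
    """Simulate a concentration grid and recover the phase threshold.

    Conditions at or above ``onset_uM`` get droplet images, those below get
    droplet-free images with the same background and shot noise; every
    image is tiled into ROIs whose index of dispersion feeds the
    classifier.  The reference (no-droplet control) is an extra image at
    zero protein.  Returns the labelled conditions and the recovered
    threshold concentration.

    ``n_droplets`` must be large enough that most ROI tiles contain droplet
    signal — the classifier compares the *median* ROI index of dispersion
    against the reference cutoff, so a sparse field whose droplets touch
    fewer than half the tiles reads as dispersed.
    """
    from .synthetic import DropletImageParams, gen_droplet_image

    pixel_size_nm = 481.5
    spec = ROISpec(side_um=roi_side_px * pixel_size_nm / 1000.0, pixel_size_nm=pixel_size_nm)

    def iod_samples(conc_index: int, with_droplets: bool, offset: int = 0) -> list[float]:
        params = DropletImageParams(
            image_size_px=image_size_px,
            pixel_size_nm=pixel_size_nm,
            n_droplets=n_droplets if with_droplets else 0,
            partition_true=partition_true,
            noise_model="poisson",
            seed=(seed * 1009 + conc_index * 13 + offset) % (2**31),
        )
        image, _, _ = gen_droplet_image(params)
        return [index_of_dispersion(block) for block, _ in tile_rois(image, spec)]

    reference = iod_samples(-1, with_droplets=False, offset=7919)
    conditions = []
    for i, conc in enumerate(sorted(concentrations_uM)):
        cond = PhaseCondition(
            slp65_uM=conc, cin85_uM=conc, lipid_mM=1.0,
            iod_samples=iod_samples(i, with_droplets=conc >= onset_uM),
        )
        conditions.append(cond)
    diagram = build_phase_diagram(conditions, reference, axis="slp65_uM")
    return diagram.conditions, diagram.threshold
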