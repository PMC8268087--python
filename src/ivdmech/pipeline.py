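"""End-to-end pipeline: simulate -> fit -> statistics, and orient -> tables.

The pipeline is driven by a :class:`PipelineConfig` (loadable from YAML) and
is fully regenerable from config + seed: a machine-readable manifest with
the config hash, seed and package versions is written next to the outputs.
Failures on individual curves or images are logged and counted; the run
continues over the remaining items.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_stats import compare_groups, exclude_outliers
from .indentation import check_validity, detect_contact, fit_sls
from .io import _jsonable, fits_to_frame, read_indent_csv, write_indent_csv, write_image
from .orientation import (
    apply_masks,
    circular_summary,
    group_orientation_table,
    orientation_field,
    split_quadrants,
)
from .synthetic import (
    FiberImageSpec,
    generate_cohort,
    generate_fiber_image,
    ts24_cohort_spec,
)

logger = logging.getLogger("ivdmech")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-cohort analysis run.

    Loadable from YAML via :meth:`from_yaml`; unknown keys are rejected so
    typos fail loudly.
    """

    output_dir: str = "ivdmech-output"
    curves_dir: str | None = None  # read existing curves instead of simulating
    seed: int = 0
    # simulation
    simulate: bool = True
    n_specimens: int = 3
    n_indents: int = 6
    noise_sd_uN: float = 0.002
    # indentation analysis
    tip_radius_um: float = 42.0
    poisson_ratio: float = 0.5
    abs_threshold_uN: float = 0.003
    rel_threshold: float = 0.005
    section_thickness_um: float = 25.0
    # orientation analysis
    orient: bool = True
    window_sigma_px: float = 10.0
    intensity_frac: float = 0.05
    coherency_min: float = 0.05
    n_bins: int = 36
    image_size_px: int = 256
    n_fibers: int = 120
    n_images_per_group: int = 3
    quadrant_angles: dict[str, Any] = field(
        default_factory=lambda: {
            "control": {
                "cranial-dorsal": [93.0, 3.0],
                "caudal-dorsal": [90.0, 3.4],
                "cranial-ventral": [104.0, 10.0],
                "caudal-ventral": [87.0, 10.0],
            },
            "mdg": {
                "cranial-dorsal": [95.0, 10.0],
                "caudal-dorsal": [107.0, 10.0],
                "cranial-ventral": [129.0, 10.0],
                "caudal-ventral": [7.0, 10.0],
            },
        }
    )
    # statistics
    outlier_k: float = 3.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        for name in ("abs_threshold_uN", "window_sigma_px", "outlier_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis written to different directories hashes identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        payload.pop("curves_dir")
        return hashlib.sha256(
            json.dumps(_jsonable(payload), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Outputs of one pipeline run."""

    fit_table: pd.DataFrame | None
    comparison_table: pd.DataFrame | None
    orientation_table: pd.DataFrame | None
    n_failures: int
    manifest: dict[str, Any]


def _analyse_curves(records, config: PipelineConfig, outdir: Path):
    rows, failures = [], 0
    validity = check_validity(
        2.0, config.tip_radius_um, config.section_thickness_um
    )
    for i, record in enumerate(records):
        label = record.metadata.get("specimen", f"curve-{i}")
        try:
            contact = detect_contact(
                record,
                abs_threshold=config.abs_threshold_uN,
                rel_threshold=config.rel_threshold,
            )
            fit = fit_sls(record, contact)
            rows.append((record, fit))
            logger.info(
                "fit %s/%s: E_ins=%.2f kPa f=%.3f converged=%s",
                label,
                record.metadata.get("structure", "?"),
                fit.E_ins,
                fit.f,
                fit.converged,
            )
        except Exception as exc:  # noqa: BLE001 - per-item fault tolerance
            failures += 1
            logger.warning("fit failed for %s: %s", label, exc)
    table = fits_to_frame(rows)
    if not table.empty:
        table["strain_ok"] = validity.strain_ok
        table["substrate_ok"] = validity.substrate_ok
        table.to_csv(outdir / "fit_table.csv", index=False)
    return table, failures


def _compare(table: pd.DataFrame, config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    out_rows = []
    for metric, col in (("E_ins", "E_ins_kPa"), ("f", "f")):
        obs = table.rename(columns={col: "value"})[
            ["value", "group", "specimen", "structure", "level", "stage"]
        ]
        kept, excluded = exclude_outliers(obs, k=config.outlier_k)
        for (structure, level, stage), sub in kept.groupby(
            ["structure", "level", "stage"], sort=False
        ):
            cmp_res = compare_groups(sub, n_excluded=len(excluded))
            row = {
                "stage": stage,
                "structure": structure,
                "level": level,
                "metric": metric,
                "F": cmp_res.F,
                "df1": cmp_res.df1,
                "df2": cmp_res.df2,
                "p": cmp_res.p,
                "n_excluded": cmp_res.n_excluded,
            }
            for g in cmp_res.group_means:
                row[f"mean_{g}"] = cmp_res.group_means[g]
                row[f"sd_{g}"] = cmp_res.group_sds[g]
            out_rows.append(row)
    out = pd.DataFrame(out_rows)
    out.to_csv(outdir / "group_comparison.csv", index=False)
    return out


def _orient_images(config: PipelineConfig, outdir: Path, rng: np.random.Generator):
    rows, failures = [], 0
    for group, quadrants in config.quadrant_angles.items():
        for i_img in range(config.n_images_per_group):
            sample = f"{group}-{i_img + 1}"
            try:
                phantom = generate_fiber_image(
                    FiberImageSpec(
                        width=config.image_size_px,
                        height=config.image_size_px,
                        n_fibers=config.n_fibers,
                        quadrant_angles={
                            k: tuple(v) for k, v in quadrants.items()
                        },
                        noise_sd=0.02,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
                write_image(phantom.image, outdir / "images" / f"{sample}.tif")
                fld = orientation_field(
                    phantom.image, window_sigma_px=config.window_sigma_px
                )
                fld = apply_masks(
                    phantom.image,
                    fld,
                    intensity_frac=config.intensity_frac,
                    coherency_min=config.coherency_min,
                )
                part = split_quadrants(
                    (0, phantom.image.shape[0], 0, phantom.image.shape[1])
                )
                for region, (rows_sl, cols_sl) in part.regions.items():
                    thetas = fld.theta[rows_sl, cols_sl][fld.valid_mask[rows_sl, cols_sl]]
                    summary = circular_summary(thetas, n_bins=config.n_bins)
                    rows.append(
                        {
                            "stage": "TS24",
                            "group": group,
                            "sample": sample,
                            "region": region,
                            "circular_mean": summary.circular_mean,
                            "circular_dispersion": summary.circular_dispersion,
                            "n_pixels": summary.n_pixels,
                            "predominant": summary.predominant_flag,
                        }
                    )
                logger.info("orientation done for %s", sample)
            except Exception as exc:  # noqa: BLE001
                failures += 1
                logger.warning("orientation failed for %s: %s", sample, exc)
    per_sample = pd.DataFrame(rows)
    if not per_sample.empty:
        per_sample.to_csv(outdir / "orientation_per_sample.csv", index=False)
        table = group_orientation_table(per_sample)
        table.to_csv(outdir / "orientation_table.csv", index=False)
    else:
        table = per_sample
    return table, failures


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured pipeline and write all outputs.

    Stages: simulate (optional) -> contact/fit -> validity flags -> outlier
    exclusion -> group comparison; and phantom generation -> orientation
    field -> masks -> quadrant summaries -> group orientation table.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_failures = 0

    fit_table = comparison = None
    if config.curves_dir:
        records = []
        for path in sorted(Path(config.curves_dir).glob("*.csv")):
            try:
                records.append(read_indent_csv(path))
            except Exception as exc:  # noqa: BLE001
                n_failures += 1
                logger.warning("could not read %s: %s", path.name, exc)
    elif config.simulate:
        cohort = ts24_cohort_spec(
            n_specimens=config.n_specimens,
            n_indents_per_structure=config.n_indents,
            noise_sd=config.noise_sd_uN,
            tip_radius=config.tip_radius_um,
            poisson_ratio=config.poisson_ratio,
        )
        records = generate_cohort(cohort, seed=int(rng.integers(0, 2**31 - 1)))
        curve_dir = outdir / "curves"
        for j, rec in enumerate(records):
            write_indent_csv(rec, curve_dir / f"indent_{j:03d}.csv")
    else:
        records = []

    if records:
        fit_table, fails = _analyse_curves(records, config, outdir)
        n_failures += fails
        if fit_table is not None and not fit_table.empty:
            comparison = _compare(fit_table, config, outdir)

    orientation_table = None
    if config.orient:
        orientation_table, fails = _orient_images(config, outdir, rng)
        n_failures += fails

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_failures": n_failures,
        "config": _jsonable(dataclasses.asdict(config)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        fit_table=fit_table,
        comparison_table=comparison,
        orientation_table=orientation_table,
        n_failures=n_failures,
        manifest=manifest,
    )
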