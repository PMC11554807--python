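"""Formats, run configuration, and the end-to-end pipelines.

Images travel as multi-page TIFF (one page per channel) with a JSON sidecar
recording channel roles and pixel size; plate layouts and ground truth are
JSON; all tabular results are CSV.  ``run_potency`` and ``run_tissue`` tie
the synthetic generator, segmentation, scoring/profiling and tissue stages
into deterministic, auditable runs: given the same config and seed they
produce byte-identical result files, and every run writes its resolved
configuration next to its outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field

from . import profiling, scoring, segmentation, tissue
from .synthetic import (
    CHANNEL_ROLES,
    FieldImage,
    FieldSpec,
    PlateLayoutSpec,
    SyntheticPlate,
    default_dose_response,
    default_potency_layout,
    generate_plate,
    generate_tissue_field,
)

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


def write_field(field: FieldImage, path: str | Path) -> Path:
    """Write a field as multi-page TIFF plus a ``<path>.json`` sidecar."""
    path = Path(path)
    roles = sorted(field.channels)
    tifffile.imwrite(
        path,
        np.stack([field.channels[r].astype(np.float32) for r in roles]),
        photometric="minisblack",
    )
    sidecar = {
        "channel_roles": roles,
        "pixel_size_um": field.pixel_size_um,
        "well_id": field.well_id,
        "site_index": field.site_index,
    }
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return sidecar_path


def read_field(
    path: str | Path,
    sidecar: str | Path | None = None,
    default_pixel_size_um: float | None = None,
    require: tuple[str, ...] | None = None,
) -> FieldImage:
    """Read a field TIFF; the sidecar's pixel size takes precedence over
    ``default_pixel_size_um``.  ``require`` lists channel roles that must be
    present (a missing one raises a named error)."""
    path = Path(path)
    sidecar_path = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"channel-role sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    roles = meta["channel_roles"]
    unknown = set(roles) - set(CHANNEL_ROLES)
    if unknown:
        raise ValueError(
            f"unknown channel roles {sorted(unknown)} in {sidecar_path}; "
            f"expected roles among {CHANNEL_ROLES}"
        )
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if len(roles) != pages.shape[0]:
        raise ValueError(
            f"{path}: sidecar lists {len(roles)} channels but TIFF has {pages.shape[0]} pages"
        )
    if require:
        missing = [r for r in require if r not in roles]
        if missing:
            raise ValueError(
                f"{path} is missing required channel(s) {missing}; present: {roles}"
            )
    pixel_size = meta.get("pixel_size_um", default_pixel_size_um)
    if pixel_size is None:
        raise ValueError(f"{sidecar_path} has no pixel_size_um and no default given")
    return FieldImage(
        channels={r: pages[i].astype(np.float64) for i, r in enumerate(roles)},
        pixel_size_um=float(pixel_size),
        well_id=meta.get("well_id", ""),
        site_index=int(meta.get("site_index", 0)),
    )


class DoseEntry(BaseModel):
    moi: float = Field(gt=0)
    cargo_inside_fraction: float = Field(ge=0, le=1)
    expected_cells_per_site: float = Field(gt=0)


class ThresholdConfig(BaseModel):
    k: dict[str, float] = Field(default_factory=dict)
    background_window_px: int = Field(segmentation.DEFAULT_BACKGROUND_WINDOW_PX, ge=3)
    scale_floor: float = Field(segmentation.DEFAULT_SCALE_FLOOR, gt=0)


class RunConfig(BaseModel):
    """Validated configuration of a potency run (synthetic plate mode)."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    seed: int = 0
    output_dir: str = "results"
    layout: PlateLayoutSpec
    ko_field: FieldSpec
    wt_field: FieldSpec
    dose_response: list[DoseEntry] = Field(default_factory=list)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    log_level: str = "INFO"


def default_run_config(
    seed: int = 0,
    output_dir: str = "results",
    mois: list[float] | None = None,
    wells_per_moi: int = 2,
    n_sites: int = 1,
) -> RunConfig:
    """The default synthetic potency run: the standard control layout, the
    KO-like and WT-like field conditions, and the default dose table."""
    table = default_dose_response()
    mois = sorted(mois if mois is not None else table)
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        layout=default_potency_layout(mois, wells_per_moi=wells_per_moi, n_sites=n_sites),
        ko_field=FieldSpec(cargo_inside_fraction=0.84),
        wt_field=FieldSpec(cargo_inside_fraction=0.70),
        dose_response=[
            DoseEntry(
                moi=m,
                cargo_inside_fraction=table[m][0],
                expected_cells_per_site=table[m][1],
            )
            for m in mois
        ],
    )


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.model_validate_json(Path(path).read_text())


def segment_field(
    field: FieldImage, thresholds: ThresholdConfig | None = None
) -> tuple[
    segmentation.LabelledCells,
    segmentation.MaskSet,
    segmentation.CompartmentAssignment,
    np.ndarray,
    np.ndarray,
]:
    """Segment one field and measure its per-cell cargo split."""
    thresholds = thresholds or ThresholdConfig()
    masks = segmentation.build_masks(
        field,
        k=thresholds.k,
        background_window_px=thresholds.background_window_px,
        scale_floor=thresholds.scale_floor,
    )
    cells = segmentation.define_cells(masks.nucleus_mask, masks.cellbody_mask)
    assignment = segmentation.assign_compartments(cells, masks.tgn_mask, masks.cargo_mask)
    fu_in, fu_out = segmentation.measure_cargo(
        field.channels["cargo"], assignment, background=masks.backgrounds["cargo"]
    )
    return cells, masks, assignment, fu_in, fu_out


def plate_cell_records(
    plate: SyntheticPlate, thresholds: ThresholdConfig | None = None
) -> dict[str, list[scoring.CellRecord]]:
    """Segment every field of a plate into CellRecords grouped by well."""
    by_well: dict[str, list[scoring.CellRecord]] = {
        w.well_id: [] for w in plate.layout.wells
    }
    for (well_id, site), (field, _truth) in sorted(plate.fields.items()):
        cells, _masks, _assignment, fu_in, fu_out = segment_field(field, thresholds)
        for label in range(1, cells.n_cells + 1):
            by_well[well_id].append(
                scoring.CellRecord(
                    cell_id=label,
                    well_id=well_id,
                    site_index=site,
                    fu_inside=float(fu_in[label - 1]),
                    fu_outside=float(fu_out[label - 1]),
                )
            )
    return by_well


def _write_resolved_config(config: BaseModel, out_dir: Path) -> None:
    (out_dir / "resolved_config.json").write_text(config.model_dump_json(indent=1))


def run_potency(
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate, segment and score a plate; write per-cell, per-well and
    per-MOI CSVs under ``config.output_dir``.

    Returns ``(potency_table, well_summaries, cell_records)``.  Raises before
    any image work when the layout lacks KO or WT control wells.
    """
    logging.basicConfig(level=config.log_level)
    roles = {w.well_id: w.role for w in config.layout.wells}
    if "KO_untreated" not in roles.values() or "WT_untreated" not in roles.values():
        raise scoring.DegenerateControlsError(
            "plate layout must contain KO_untreated and WT_untreated control wells"
        )
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    dose = {
        d.moi: (d.cargo_inside_fraction, d.expected_cells_per_site)
        for d in config.dose_response
    }
    plate = generate_plate(
        config.layout, config.ko_field, config.wt_field, dose, seed=config.seed
    )
    by_well = plate_cell_records(plate, config.thresholds)
    mois = {w.well_id: w.moi for w in config.layout.wells}
    well_df = scoring.score_plate(by_well, roles, mois)
    pot_df = scoring.potency_table(well_df)

    cell_rows = [
        {
            "well_id": c.well_id,
            "site_index": c.site_index,
            "cell_id": c.cell_id,
            "fu_inside": c.fu_inside,
            "fu_outside": c.fu_outside,
            "ratio": c.ratio,
        }
        for recs in by_well.values()
        for c in recs
    ]
    cell_df = pd.DataFrame(
        cell_rows,
        columns=["well_id", "site_index", "cell_id", "fu_inside", "fu_outside", "ratio"],
    ).sort_values(["well_id", "site_index", "cell_id"], kind="mergesort", ignore_index=True)

    cell_df.to_csv(out_dir / "cells.csv", index=False)
    well_df.to_csv(out_dir / "wells.csv", index=False)
    pot_df.to_csv(out_dir / "potency.csv", index=False)
    _write_resolved_config(config, out_dir)
    logger.info(
        "potency run: %d wells, %d cells, %d MOI rows",
        len(well_df), len(cell_df), len(pot_df),
    )
    return pot_df, well_df, cell_df


def run_profile(config: RunConfig) -> pd.DataFrame:
    """KO-normalized feature Z-score profile per condition (control roles and
    each MOI), written to ``profile.csv``."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dose = {
        d.moi: (d.cargo_inside_fraction, d.expected_cells_per_site)
        for d in config.dose_response
    }
    plate = generate_plate(
        config.layout, config.ko_field, config.wt_field, dose, seed=config.seed
    )
    frames = []
    for (_well_id, _site), (field, _truth) in sorted(plate.fields.items()):
        cells, masks, assignment, fu_in, fu_out = segment_field(field, config.thresholds)
        frames.append(
            profiling.extract_field_features(
                field, cells, masks, assignment, fu_in, fu_out
            )
        )
    feats = pd.concat(frames, ignore_index=True)
    per_well = profiling.per_well_feature_means(feats)

    roles = {w.well_id: w.role for w in config.layout.wells}
    mois = {w.well_id: w.moi for w in config.layout.wells}
    ko_wells = [w for w, r in roles.items() if r == "KO_untreated"]
    wt_wells = [w for w, r in roles.items() if r == "WT_untreated"]
    ko_table = per_well.loc[[w for w in ko_wells if w in per_well.index]]

    tables: dict[str, pd.DataFrame] = {"KO_untreated": ko_table}
    tables["WT_untreated"] = per_well.loc[[w for w in wt_wells if w in per_well.index]]
    treated_mois = sorted({mois[w] for w, r in roles.items() if r == "treated"})
    order = ["KO_untreated", "WT_untreated"]
    for moi in treated_mois:
        name = f"MOI_{moi:g}"
        members = [w for w, r in roles.items() if r == "treated" and mois[w] == moi]
        tables[name] = per_well.loc[[w for w in members if w in per_well.index]]
        order.append(name)
    profile = profiling.zscore_profile(tables, ko_table, condition_order=order)
    profile.to_csv(out_dir / "profile.csv", index_label="condition")
    return profile


class TissueGroupConfig(BaseModel):
    name: str
    enrichment: float = Field(gt=0)
    n_images: int = Field(3, gt=0)
    n_cells: int = Field(6, ge=0)
    spheroid_areas_um2: list[float] = Field(default_factory=list)


class TissueRunConfig(BaseModel):
    """Configuration of a synthetic tissue quantification run."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    seed: int = 0
    output_dir: str = "results_tissue"
    groups: list[TissueGroupConfig]
    wt_group: str = "WT"
    region_profile: str = "cortex"
    noise_sd: float = 0.5
    spheroid_threshold_um2: float = tissue.SPHEROID_AREA_THRESHOLD_UM2
    log_level: str = "INFO"


def run_tissue(config: TissueRunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate tissue fields per group, quantify perinuclear accumulation
    and spheroids, and write ``perinuclear.csv``, ``fold_change.csv`` and
    ``spheroids.csv``.

    Returns ``(perinuclear_df, fold_change_df, spheroid_df)``.
    """
    logging.basicConfig(level=config.log_level)
    if config.wt_group not in {g.name for g in config.groups}:
        raise ValueError(
            f"wt_group {config.wt_group!r} not among groups "
            f"{sorted(g.name for g in config.groups)}"
        )
    profile = tissue.get_region_profile(config.region_profile)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    peri_rows, sph_rows = [], []
    per_image_means: dict[str, list[float]] = {}
    for gi, group in enumerate(config.groups):
        per_image_means[group.name] = []
        for img_i in range(group.n_images):
            seed = (config.seed * 1009 + gi * 131 + img_i) & 0x7FFFFFFF
            field, truth = generate_tissue_field(
                n_cells=group.n_cells,
                enrichment=group.enrichment,
                spheroid_areas_um2=group.spheroid_areas_um2,
                noise_sd=config.noise_sd,
                seed=seed,
            )
            annuli = tissue.perinuclear_region(
                truth.nucleus_labels, profile, field.pixel_size_um
            )
            result = tissue.perinuclear_intensity(
                field.channels["cargo"], annuli, profile,
                exclude_mask=truth.nucleus_labels > 0,
            )
            per_image_means[group.name].append(result.per_image_mean)
            for ci, v in enumerate(result.per_cell):
                peri_rows.append(
                    {
                        "group": group.name,
                        "image_index": img_i,
                        "cell_id": ci + 1,
                        "normalized_intensity": v,
                        "region_profile": profile.region_profile,
                    }
                )
            sph = tissue.detect_spheroids(
                field.channels["calbindin"],
                field.pixel_size_um,
                threshold_um2=config.spheroid_threshold_um2,
            )
            sph_rows.append(
                {
                    "group": group.name,
                    "image_index": img_i,
                    "spheroid_count": sph.count,
                    "areas_um2": ";".join(f"{a:.3f}" for a in sph.areas_um2),
                    "threshold_um2": sph.threshold_um2,
                }
            )

    folds = tissue.group_fold_change(per_image_means, config.wt_group)
    peri_df = pd.DataFrame(peri_rows)
    fold_df = pd.DataFrame(
        {
            "group": list(folds),
            "mean_normalized_intensity": [
                float(np.mean(per_image_means[g])) for g in folds
            ],
            "fold_change_vs_wt": [folds[g] for g in folds],
        }
    )
    sph_df = pd.DataFrame(sph_rows)
    peri_df.to_csv(out_dir / "perinuclear.csv", index=False)
    fold_df.to_csv(out_dir / "fold_change.csv", index=False)
    sph_df.to_csv(out_dir / "spheroids.csv", index=False)
    _write_resolved_config(config, out_dir)
    return peri_df, fold_df, sph_df
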