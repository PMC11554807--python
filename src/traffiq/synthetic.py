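"""Seeded synthetic microscopy fields with exact ground truth.

Every downstream stage of the pipeline (segmentation, scoring, profiling,
tissue quantification) is exercised against images generated here, for which
the true cell geometry, the true inside/outside-TGN cargo split, and the true
planted object areas are known exactly.

Cells are idealized as non-overlapping disks with a nested nuclear disk and a
trans-Golgi (TGN) disk tucked against the nucleus, all inside the cell body.
Cargo fluorescence (ATG9A) is apportioned between the TGN footprint and the
rest of the cell body so that the planted inside fraction is exact before
noise.  Noise is additive Gaussian on a constant background.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

DEFAULT_PIXEL_SIZE_UM = 0.325
"""Default sampling, µm per pixel (typical 40x high-content objective)."""

CHANNEL_ROLES = ("nucleus", "cell_body", "tgn", "cargo", "calbindin")


class PlacementError(ValueError):
    """Raised when the requested cells/objects cannot be placed in the field."""


class FieldSpec(BaseModel):
    """Generative parameters for one cultured-cell field.

    ``cargo_inside_fraction`` is the fraction of each cell's total cargo
    fluorescence placed within the TGN footprint: high values emulate the
    knockout phenotype (cargo trapped at the TGN), low values the wild type.
    """

    field_width_px: int = Field(320, gt=0)
    field_height_px: int = Field(320, gt=0)
    pixel_size_um: float = Field(DEFAULT_PIXEL_SIZE_UM, gt=0)
    n_cells: int = Field(6, ge=0)
    cargo_inside_fraction: float = Field(..., ge=0.0, le=1.0)
    cell_radius_um: float = Field(8.0, gt=0)
    nucleus_radius_um: float = Field(3.5, gt=0)
    tgn_radius_um: float = Field(2.5, gt=0)
    background_level: float = Field(20.0, ge=0)
    noise_sd: float = Field(0.5, ge=0)
    cargo_total_fu: float = Field(20000.0, gt=0)
    nucleus_intensity: float = Field(150.0, gt=0)
    cellbody_intensity: float = Field(60.0, gt=0)
    tgn_intensity: float = Field(120.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "FieldSpec":
        if not self.nucleus_radius_um < self.cell_radius_um:
            raise ValueError("nucleus_radius_um must be smaller than cell_radius_um")
        # TGN disk sits tangent to the nucleus centre offset; it must stay
        # inside the cell body so compartment masks nest properly.
        if self.nucleus_radius_um + self.tgn_radius_um > self.cell_radius_um:
            raise ValueError(
                "TGN footprint does not fit inside the cell: require "
                "nucleus_radius_um + tgn_radius_um <= cell_radius_um"
            )
        return self


class WellSpec(BaseModel):
    well_id: str
    role: Literal["KO_untreated", "WT_untreated", "treated"]
    moi: float = Field(0.0, ge=0)
    n_sites: int = Field(1, gt=0)

    @model_validator(mode="after")
    def _check_moi(self) -> "WellSpec":
        if self.role == "treated" and self.moi <= 0:
            raise ValueError(f"treated well {self.well_id!r} must have moi > 0")
        if self.role != "treated" and self.moi != 0:
            raise ValueError(f"untreated well {self.well_id!r} must have moi = 0")
        return self


class PlateLayoutSpec(BaseModel):
    """Which wells a plate carries and how sites are acquired within a well."""

    wells: list[WellSpec]
    grid_n: int = Field(5, gt=0)
    site_spacing_um: float = Field(330.0, gt=0)
    omit_centre: bool = True

    @model_validator(mode="after")
    def _check_unique(self) -> "PlateLayoutSpec":
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well_ids must be unique")
        return self

    def wells_with_role(self, role: str) -> list[WellSpec]:
        return [w for w in self.wells if w.role == role]


@dataclass
class GroundTruth:
    """Exact planted truth for one field.

    Label images use 0 for background and ``i+1`` for cell ``i`` (the index
    into ``cell_centres``).  ``inside_fu[i] + outside_fu[i]`` equals cell
    ``i``'s total planted cargo fluorescence exactly (pre-noise).
    """

    cell_centres: list[tuple[float, float]]
    nucleus_labels: np.ndarray
    body_labels: np.ndarray
    tgn_labels: np.ndarray
    inside_fu: np.ndarray
    outside_fu: np.ndarray
    enrichment: np.ndarray | None = None
    spheroid_areas_um2: list[float] = dc_field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_centres)

    def body_mask(self, i: int) -> np.ndarray:
        return self.body_labels == i + 1

    def nucleus_mask(self, i: int) -> np.ndarray:
        return self.nucleus_labels == i + 1

    def tgn_mask(self, i: int) -> np.ndarray:
        return self.tgn_labels == i + 1


@dataclass
class FieldImage:
    """One imaged site: channel role -> 2D float array, plus identity."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    well_id: str = ""
    site_index: int = 0

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel arrays have mixed shapes: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        unknown = set(self.channels) - set(CHANNEL_ROLES)
        if unknown:
            raise ValueError(
                f"unknown channel roles {sorted(unknown)}; expected subset of {CHANNEL_ROLES}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def make_acquisition_layout(
    grid_n: int, spacing_um: float, omit_centre: bool
) -> list[tuple[float, float]]:
    """Site coordinates (x_um, y_um) of a square acquisition grid.

    The default potency-assay acquisition is 24 sites in a 5x5 square at
    330 µm pitch with the centre square left out.  Ordering is row-major.
    For even ``grid_n`` there is no unique central lattice point, so
    ``omit_centre`` is refused rather than guessed at.
    """
    if grid_n < 1:
        raise ValueError("grid_n must be >= 1")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    if omit_centre and grid_n % 2 == 0:
        raise ValueError(
            f"omit_centre is ambiguous for even grid_n={grid_n}: "
            "a square grid with an even edge has no unique centre site"
        )
    mid = grid_n // 2
    sites: list[tuple[float, float]] = []
    for row in range(grid_n):
        for col in range(grid_n):
            if omit_centre and grid_n % 2 == 1 and row == mid and col == mid:
                continue
            sites.append((col * spacing_um, row * spacing_um))
    return sites


def _disk_mask(shape: tuple[int, int], cx: float, cy: float, radius_px: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2


def _place_centres(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin_px: float,
    min_sep_px: float,
    max_tries_per_cell: int = 400,
) -> list[tuple[float, float]]:
    h, w = shape
    if n == 0:
        return []
    if w - 2 * margin_px <= 0 or h - 2 * margin_px <= 0:
        raise PlacementError(f"field too small for margin {margin_px:.1f} px; placed 0 of {n} cells")
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < n and tries < max_tries_per_cell * n:
        tries += 1
        x = rng.uniform(margin_px, w - margin_px)
        y = rng.uniform(margin_px, h - margin_px)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep_px**2 for cx, cy in centres):
            centres.append((x, y))
    if len(centres) < n:
        raise PlacementError(
            f"could not place {n} non-overlapping cells; achievable n_cells ~ {len(centres)}"
        )
    return centres


def generate_field(
    spec: FieldSpec,
    rng: np.random.Generator | None = None,
    well_id: str = "",
    site_index: int = 0,
) -> tuple[FieldImage, GroundTruth]:
    """Render one cultured-cell field and its exact ground truth.

    Identical ``(spec, seed)`` produce bit-identical output.  Pass ``rng`` to
    draw from an externally managed stream (used by :func:`generate_plate`).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = (spec.field_height_px, spec.field_width_px)
    px = spec.pixel_size_um
    cell_r = spec.cell_radius_um / px
    nuc_r = spec.nucleus_radius_um / px
    tgn_r = spec.tgn_radius_um / px

    centres = _place_centres(
        rng,
        spec.n_cells,
        shape,
        margin_px=cell_r + 2.0,
        min_sep_px=2 * cell_r + 3.0,
    )

    nucleus_lab = np.zeros(shape, dtype=np.int32)
    body_lab = np.zeros(shape, dtype=np.int32)
    tgn_lab = np.zeros(shape, dtype=np.int32)
    chan = {
        role: np.zeros(shape, dtype=np.float64)
        for role in ("nucleus", "cell_body", "tgn", "cargo")
    }
    inside_fu = np.zeros(spec.n_cells)
    outside_fu = np.zeros(spec.n_cells)

    frac = spec.cargo_inside_fraction
    for i, (cx, cy) in enumerate(centres):
        body = _disk_mask(shape, cx, cy, cell_r)
        nucleus = _disk_mask(shape, cx, cy, nuc_r)
        theta = rng.uniform(0, 2 * np.pi)
        tx = cx + spec.nucleus_radius_um / px * np.cos(theta)
        ty = cy + spec.nucleus_radius_um / px * np.sin(theta)
        tgn = _disk_mask(shape, tx, ty, tgn_r) & body
        outside_region = body & ~tgn

        body_lab[body] = i + 1
        nucleus_lab[nucleus] = i + 1
        tgn_lab[tgn] = i + 1

        chan["nucleus"][nucleus] += spec.nucleus_intensity
        chan["cell_body"][body] += spec.cellbody_intensity
        chan["tgn"][tgn] += spec.tgn_intensity

        fu_in = frac * spec.cargo_total_fu
        fu_out = (1.0 - frac) * spec.cargo_total_fu
        n_in = int(tgn.sum())
        n_out = int(outside_region.sum())
        if n_in > 0 and fu_in > 0:
            chan["cargo"][tgn] += fu_in / n_in
        else:
            fu_in = 0.0
        if n_out > 0 and fu_out > 0:
            chan["cargo"][outside_region] += fu_out / n_out
        else:
            fu_out = 0.0
        inside_fu[i] = fu_in
        outside_fu[i] = fu_out

    for role in chan:
        chan[role] += spec.background_level
        if spec.noise_sd > 0:
            chan[role] += rng.normal(0.0, spec.noise_sd, size=shape)
        np.maximum(chan[role], 0.0, out=chan[role])

    image = FieldImage(chan, pixel_size_um=px, well_id=well_id, site_index=site_index)
    truth = GroundTruth(
        cell_centres=centres,
        nucleus_labels=nucleus_lab,
        body_labels=body_lab,
        tgn_labels=tgn_lab,
        inside_fu=inside_fu,
        outside_fu=outside_fu,
    )
    return image, truth


def default_potency_layout(
    mois: list[float] | None = None,
    wells_per_moi: int = 2,
    n_sites: int = 1,
) -> PlateLayoutSpec:
    """The default plate: 16 KO-untreated + 8 WT-untreated control wells plus
    ``wells_per_moi`` treated wells at each requested MOI, with the 5x5 /
    24-site / 330 µm acquisition grid."""
    wells = [
        WellSpec(well_id=f"KO{i + 1:02d}", role="KO_untreated", n_sites=n_sites)
        for i in range(16)
    ]
    wells += [
        WellSpec(well_id=f"WT{i + 1:02d}", role="WT_untreated", n_sites=n_sites)
        for i in range(8)
    ]
    for moi in mois or []:
        for r in range(wells_per_moi):
            wells.append(
                WellSpec(
                    well_id=f"T{moi:.0e}_{r + 1}".replace("+", ""),
                    role="treated",
                    moi=moi,
                    n_sites=n_sites,
                )
            )
    return PlateLayoutSpec(wells=wells, grid_n=5, site_spacing_um=330.0, omit_centre=True)


def default_dose_response() -> dict[float, tuple[float, float]]:
    """MOI -> (cargo_inside_fraction, expected cells per site).

    A monotone dose->fraction mapping spanning MOI 1e3 to 1.6e7 vg/cell with
    cell-count attrition at the top doses, emulating the reference-range
    behaviour of the assay.  Callers supply their own table for real designs.
    """
    return {
        1e3: (0.839, 6.0),
        1e5: (0.828, 6.0),
        1e6: (0.820, 5.5),
        2e6: (0.810, 5.0),
        4e6: (0.790, 3.5),
        1.6e7: (0.766, 2.0),
    }


def well_rng(master_seed: int, well_id: str) -> np.random.Generator:
    """Per-well random stream: wells can be regenerated independently."""
    return np.random.default_rng([master_seed & 0x7FFFFFFF, zlib.crc32(well_id.encode())])


@dataclass
class SyntheticPlate:
    """All fields of one simulated plate, keyed by (well_id, site_index)."""

    layout: PlateLayoutSpec
    fields: dict[tuple[str, int], tuple[FieldImage, GroundTruth]]

    def wells(self) -> list[WellSpec]:
        return self.layout.wells


def generate_plate(
    layout: PlateLayoutSpec,
    ko_spec: FieldSpec,
    wt_spec: FieldSpec,
    dose_response: dict[float, tuple[float, float]],
    seed: int,
) -> SyntheticPlate:
    """Simulate a whole plate.

    Control wells draw their per-site cell count as Poisson around the control
    spec's ``n_cells``; treated wells look up (inside fraction, expected cell
    count) in ``dose_response`` by exact MOI.  Each well has an independent
    seeded stream derived from ``seed`` and the well id, so identical calls
    are bit-identical and single wells can be regenerated.
    """
    missing = {
        w.moi for w in layout.wells if w.role == "treated" and w.moi not in dose_response
    }
    if missing:
        raise ValueError(
            f"treated MOIs missing from dose_response table: {sorted(missing)}"
        )
    fields: dict[tuple[str, int], tuple[FieldImage, GroundTruth]] = {}
    for well in layout.wells:
        rng = well_rng(seed, well.well_id)
        if well.role == "KO_untreated":
            base, expected = ko_spec, float(ko_spec.n_cells)
        elif well.role == "WT_untreated":
            base, expected = wt_spec, float(wt_spec.n_cells)
        else:
            frac, expected = dose_response[well.moi]
            base = ko_spec.model_copy(update={"cargo_inside_fraction": frac})
        for site in range(well.n_sites):
            n = int(rng.poisson(expected))
            # a high Poisson draw can exceed what fits without overlap in the
            # field; back off deterministically rather than failing the plate
            while True:
                try:
                    site_spec = base.model_copy(update={"n_cells": n})
                    fields[(well.well_id, site)] = generate_field(
                        site_spec, rng=rng, well_id=well.well_id, site_index=site
                    )
                    break
                except PlacementError:
                    if n == 0:
                        raise
                    n -= 1
    return SyntheticPlate(layout=layout, fields=fields)


def generate_tissue_field(
    n_cells: int,
    enrichment: float,
    spheroid_areas_um2: list[float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    field_width_px: int = 384,
    field_height_px: int = 384,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    nucleus_radius_um: float = 4.0,
    ring_width_um: float = 3.0,
    background_level: float = 20.0,
    nucleus_intensity: float = 150.0,
    spheroid_intensity: float = 120.0,
) -> tuple[FieldImage, GroundTruth]:
    """Render a tissue-section field: perinuclear cargo rings plus a calbindin
    channel with planted circular spheroids of known areas.

    The cargo ring around each nucleus spans distances (0, ring_width_um] from
    the nucleus boundary (Euclidean distance to the nearest nucleus pixel) at
    intensity ``enrichment x background_level``; ``enrichment = 1`` therefore
    leaves the cargo channel statistically uniform.
    """
    if enrichment <= 0:
        raise ValueError("enrichment must be positive")
    spheroid_areas_um2 = list(spheroid_areas_um2 or [])
    rng = np.random.default_rng(seed)
    shape = (field_height_px, field_width_px)
    px = pixel_size_um
    nuc_r = nucleus_radius_um / px
    ring_w = ring_width_um / px

    centres = _place_centres(
        rng, n_cells, shape, margin_px=nuc_r + ring_w + 2.0,
        min_sep_px=2 * (nuc_r + ring_w) + 4.0,
    )
    nucleus_lab = np.zeros(shape, dtype=np.int32)
    for i, (cx, cy) in enumerate(centres):
        nucleus_lab[_disk_mask(shape, cx, cy, nuc_r)] = i + 1

    cargo = np.full(shape, float(background_level))
    if n_cells > 0:
        dist = ndimage.distance_transform_edt(nucleus_lab == 0)
        ring = (dist > 0) & (dist <= ring_w)
        cargo[ring] = enrichment * background_level

    nucleus_chan = np.full(shape, float(background_level))
    nucleus_chan[nucleus_lab > 0] += nucleus_intensity

    calbindin = np.full(shape, float(background_level))
    sph_rng = rng
    placed: list[tuple[float, float, float]] = []
    for area in spheroid_areas_um2:
        r_px = np.sqrt(area / np.pi) / px
        margin = r_px + 2.0
        if 2 * margin >= min(shape):
            raise PlacementError(f"spheroid of {area} µm² too large for the field")
        ok = False
        for _ in range(400):
            x = sph_rng.uniform(margin, field_width_px - margin)
            y = sph_rng.uniform(margin, field_height_px - margin)
            if all(
                (x - px0) ** 2 + (y - py0) ** 2 >= (r_px + r0 + 3.0) ** 2
                for px0, py0, r0 in placed
            ):
                placed.append((x, y, r_px))
                calbindin[_disk_mask(shape, x, y, r_px)] += spheroid_intensity
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place spheroid of {area} µm² without overlap"
            )

    channels = {"nucleus": nucleus_chan, "cargo": cargo, "calbindin": calbindin}
    if noise_sd > 0:
        for role in ("nucleus", "cargo", "calbindin"):
            channels[role] = np.maximum(
                channels[role] + rng.normal(0.0, noise_sd, size=shape), 0.0
            )

    image = FieldImage(channels, pixel_size_um=px, well_id="tissue", site_index=0)
    truth = GroundTruth(
        cell_centres=centres,
        nucleus_labels=nucleus_lab,
        body_labels=np.zeros(shape, dtype=np.int32),
        tgn_labels=np.zeros(shape, dtype=np.int32),
        inside_fu=np.zeros(n_cells),
        outside_fu=np.zeros(n_cells),
        enrichment=np.full(n_cells, float(enrichment)),
        spheroid_areas_um2=spheroid_areas_um2,
    )
    return image, truth
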