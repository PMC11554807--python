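"""Multi-parametric per-cell morphology/intensity profiling and KO-normalized
Z-score profiles (the matrix behind a per-MOI heatmap).

The default feature set has 33 named features: cell shape descriptors,
per-channel intensity statistics, TGN-specific morphology, and surrogates for
the proprietary high-content measures "roughness" (isoperimetric deficit,
perimeter²/(4π·area) − 1, which is 0 for a disk) and "homogeneity"
(1/(1 + CV) of the staining, 1 for perfectly uniform staining).  The neurite
outgrowth proxy is the morphological-skeleton length of the cell body outside
a dilated nucleus.  Missing features propagate as NaN, never as zero.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .segmentation import CompartmentAssignment, LabelledCells, MaskSet
from .synthetic import FieldImage

logger = logging.getLogger(__name__)

#: cells below this pixel area get NaN shape descriptors (degenerate regions)
MIN_SHAPE_PIXELS = 5
NUCLEUS_DILATION_UM = 1.0

SHAPE_FEATURES = (
    "area_um2", "perimeter_um", "equivalent_diameter_um",
    "eccentricity", "solidity", "extent", "roughness",
)
INTENSITY_CHANNELS = ("nucleus", "cell_body", "tgn", "cargo")
INTENSITY_STATS = ("mean", "median", "max", "integrated", "homogeneity")
TGN_FEATURES = ("tgn_area_um2", "tgn_fragment_count", "tgn_compactness")
OTHER_FEATURES = ("neurite_outgrowth_um", "cargo_inside_fu", "cargo_outside_fu")

FEATURE_NAMES: tuple[str, ...] = (
    SHAPE_FEATURES
    + tuple(f"{c}_{s}" for c in INTENSITY_CHANNELS for s in INTENSITY_STATS)
    + TGN_FEATURES
    + OTHER_FEATURES
)


def _homogeneity(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    sd = float(np.std(values))
    if mean == 0:
        return math.nan
    return 1.0 / (1.0 + sd / abs(mean))


def extract_features(
    body_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    tgn_mask: np.ndarray,
    channels: dict[str, np.ndarray],
    pixel_size_um: float,
    cargo_inside_fu: float = math.nan,
    cargo_outside_fu: float = math.nan,
) -> dict[str, float]:
    """Feature vector for a single cell. Areas and lengths in physical units."""
    if body_mask.sum() < 1:
        raise ValueError("cell region must contain at least one pixel")
    px = pixel_size_um
    feats: dict[str, float] = dict.fromkeys(FEATURE_NAMES, math.nan)

    props = measure.regionprops(body_mask.astype(np.uint8))[0]
    n_px = int(body_mask.sum())
    feats["area_um2"] = n_px * px**2
    if n_px >= MIN_SHAPE_PIXELS:
        # Crofton estimator: far less biased than pixel-boundary counting on
        # smooth shapes, keeping the isoperimetric roughness near 0 for disks
        perim_px = float(props.perimeter_crofton)
        feats["perimeter_um"] = perim_px * px
        feats["equivalent_diameter_um"] = float(props.equivalent_diameter_area) * px
        feats["eccentricity"] = float(props.eccentricity)
        feats["solidity"] = float(props.solidity)
        feats["extent"] = float(props.extent)
        if props.area > 0 and perim_px > 0:
            feats["roughness"] = perim_px**2 / (4 * np.pi * float(props.area)) - 1.0
    else:
        logger.info("degenerate %d-pixel cell: shape descriptors set to NaN", n_px)

    for role in INTENSITY_CHANNELS:
        if role not in channels:
            continue
        vals = channels[role][body_mask]
        feats[f"{role}_mean"] = float(np.mean(vals))
        feats[f"{role}_median"] = float(np.median(vals))
        feats[f"{role}_max"] = float(np.max(vals))
        feats[f"{role}_integrated"] = float(np.sum(vals))
        feats[f"{role}_homogeneity"] = _homogeneity(vals)

    tgn_in_cell = tgn_mask & body_mask
    n_tgn = int(tgn_in_cell.sum())
    feats["tgn_area_um2"] = n_tgn * px**2
    if n_tgn:
        tgn_lab = measure.label(tgn_in_cell, connectivity=2)
        feats["tgn_fragment_count"] = float(tgn_lab.max())
        tprops = measure.regionprops((tgn_in_cell).astype(np.uint8))[0]
        tperim = float(tprops.perimeter_crofton)
        if tperim > 0:
            feats["tgn_compactness"] = 4 * np.pi * n_tgn / tperim**2
    else:
        feats["tgn_fragment_count"] = 0.0

    dil_px = max(1, int(round(NUCLEUS_DILATION_UM / px)))
    cytoplasm = body_mask & ~morphology.dilation(nucleus_mask, morphology.disk(dil_px))
    skel = morphology.skeletonize(cytoplasm)
    feats["neurite_outgrowth_um"] = float(skel.sum()) * px

    feats["cargo_inside_fu"] = cargo_inside_fu
    feats["cargo_outside_fu"] = cargo_outside_fu
    return feats


def extract_field_features(
    field: FieldImage,
    cells: LabelledCells,
    masks: MaskSet,
    assignment: CompartmentAssignment | None = None,
    fu_inside: np.ndarray | None = None,
    fu_outside: np.ndarray | None = None,
) -> pd.DataFrame:
    """Feature table (one row per cell) for a segmented field."""
    rows = []
    for label in range(1, cells.n_cells + 1):
        body = cells.labels == label
        nucleus = cells.nucleus_labels == label
        fin = float(fu_inside[label - 1]) if fu_inside is not None else math.nan
        fout = float(fu_outside[label - 1]) if fu_outside is not None else math.nan
        feats = extract_features(
            body, nucleus, masks.tgn_mask, field.channels, field.pixel_size_um,
            cargo_inside_fu=fin, cargo_outside_fu=fout,
        )
        feats["cell_id"] = label
        feats["well_id"] = field.well_id
        feats["site_index"] = field.site_index
        rows.append(feats)
    cols = ["well_id", "site_index", "cell_id", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def per_well_feature_means(cell_features: pd.DataFrame) -> pd.DataFrame:
    """Mean feature vector per well (rows = wells), NaN-aware."""
    feat_cols = [c for c in FEATURE_NAMES if c in cell_features.columns]
    return cell_features.groupby("well_id")[feat_cols].mean()


def zscore_profile(
    condition_tables: dict[str, pd.DataFrame],
    ko_reference_table: pd.DataFrame,
    condition_order: list[str] | None = None,
) -> pd.DataFrame:
    """Condition-by-feature Z-score matrix against the untreated-KO wells.

    ``condition_tables`` maps a condition name (control role or MOI label) to
    its per-well feature means; ``ko_reference_table`` holds the untreated-KO
    per-well means (>= 2 wells).  Each entry is
    ``(condition mean − KO mean) / KO SD`` with sample SD across KO wells.
    A feature with zero KO SD is emitted as NaN with a warning.
    """
    if len(ko_reference_table) < 2:
        raise ValueError("KO reference needs >= 2 wells")
    ko_mean = ko_reference_table.mean()
    ko_sd = ko_reference_table.std(ddof=1)
    dead = ko_sd[ko_sd == 0].index.tolist()
    if dead:
        warnings.warn(
            f"features with zero KO SD emitted as missing: {dead}", stacklevel=2
        )
        ko_sd = ko_sd.replace(0.0, math.nan)
    order = condition_order or list(condition_tables)
    rows = {
        name: (condition_tables[name].mean() - ko_mean) / ko_sd for name in order
    }
    return pd.DataFrame(rows).T.loc[order]
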