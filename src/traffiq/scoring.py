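"""Per-cell cargo ratio, per-well summaries, control-anchored translocation
(percent rescue), cell-count Z-score toxicity QC, and the per-MOI potency
table.

The assay's core statistic is the per-cell ratio of cargo fluorescence inside
the TGN to cargo fluorescence outside it.  A plate's untreated knockout wells
anchor 0% translocation and its untreated wild-type wells 100%; every treated
well's mean ratio is mapped through the unique affine transform between those
anchors.  Toxicity is flagged when a well's cell count falls at or below 3
sample standard deviations under the knockout-control mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z_TOXICITY_CUTOFF = -3.0


class DegenerateControlsError(ValueError):
    """Plate controls cannot anchor the translocation scale."""


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell's compartmentalized cargo fluorescence."""

    cell_id: int
    well_id: str
    site_index: int
    fu_inside: float
    fu_outside: float

    @property
    def ratio(self) -> float:
        return cell_ratio(self.fu_inside, self.fu_outside)


@dataclass
class WellSummary:
    well_id: str
    role: str
    moi: float
    n_cells: int
    mean_ratio: float
    n_undefined_ratio: int = 0
    translocation_pct: float = math.nan
    cellcount_z: float = math.nan
    nontoxic: bool | None = None


def cell_ratio(fu_inside: float, fu_outside: float) -> float:
    """Cargo F.U. inside the TGN divided by F.U. outside.

    Undefined (NaN) when ``fu_outside`` is zero; such cells are excluded from
    well means but still counted.  Negative fluorescence is rejected.
    """
    if fu_inside < 0 or fu_outside < 0:
        raise ValueError(
            f"fluorescence must be non-negative, got ({fu_inside}, {fu_outside})"
        )
    if fu_outside == 0:
        logger.debug("undefined ratio: fu_outside = 0 (fu_inside=%s)", fu_inside)
        return math.nan
    return fu_inside / fu_outside


def well_summary(cells: list[CellRecord]) -> WellSummary:
    """Per-well mean of defined cell ratios; ``n_cells`` counts every
    segmented cell, defined ratio or not."""
    if not cells:
        return WellSummary(
            well_id="", role="", moi=0.0, n_cells=0, mean_ratio=math.nan
        )
    well_ids = {c.well_id for c in cells}
    if len(well_ids) > 1:
        raise ValueError(f"cells span multiple wells: {sorted(well_ids)}")
    ratios = [c.ratio for c in cells]
    defined = [r for r in ratios if not math.isnan(r)]
    n_undef = len(ratios) - len(defined)
    if n_undef:
        logger.info("well %s: %d cells with undefined ratio excluded from mean",
                    cells[0].well_id, n_undef)
    mean = float(np.mean(defined)) if defined else math.nan
    return WellSummary(
        well_id=cells[0].well_id,
        role="",
        moi=0.0,
        n_cells=len(cells),
        mean_ratio=mean,
        n_undefined_ratio=n_undef,
    )


def translocation(mean_ratio: float, ko_ref: float, wt_ref: float) -> float:
    """Percent rescue of the cargo distribution: the affine map sending the
    knockout-control mean ratio to 0% and the wild-type-control mean to 100%.

    Values outside [0, 100] are returned as-is (they diagnose control drift).
    """
    if ko_ref == wt_ref:
        raise DegenerateControlsError(
            "degenerate plate controls: KO and WT reference ratios are equal"
        )
    return 100.0 * (ko_ref - mean_ratio) / (ko_ref - wt_ref)


def cellcount_zscore(
    count: int, control_counts: list[int] | np.ndarray
) -> tuple[float, bool]:
    """Cell-count Z-score against the plate's untreated-KO control wells.

    Sample standard deviation (n-1).  Non-toxic iff z is strictly larger
    than -3; a well exactly at z = -3 is flagged toxic.
    """
    control_counts = np.asarray(control_counts, dtype=float)
    if control_counts.size < 2:
        raise ValueError("need >= 2 control wells for a cell-count Z-score")
    sd = float(np.std(control_counts, ddof=1))
    if sd == 0:
        raise ValueError("control cell counts have zero standard deviation")
    z = (float(count) - float(np.mean(control_counts))) / sd
    return z, z > Z_TOXICITY_CUTOFF


def score_plate(
    cells_by_well: dict[str, list[CellRecord]],
    roles: dict[str, str],
    mois: dict[str, float],
) -> pd.DataFrame:
    """Score every well of a plate against its own controls.

    Parameters
    ----------
    cells_by_well
        All segmented cells grouped by well id (wells with zero cells are
        allowed and summarized with NaN mean ratio).
    roles, mois
        Well id -> role (``KO_untreated`` / ``WT_untreated`` / ``treated``)
        and -> MOI (0 for untreated).

    Returns a per-well DataFrame with mean ratio, translocation percent,
    cell-count Z-score and the non-toxicity flag, ordered by role then id.
    """
    summaries: dict[str, WellSummary] = {}
    for well_id in roles:
        s = well_summary(cells_by_well.get(well_id, []))
        s.well_id = well_id
        s.role = roles[well_id]
        s.moi = mois.get(well_id, 0.0)
        summaries[well_id] = s

    ko = [s for s in summaries.values() if s.role == "KO_untreated"]
    wt = [s for s in summaries.values() if s.role == "WT_untreated"]
    if not ko or not wt:
        raise DegenerateControlsError(
            "plate must contain at least one KO_untreated and one WT_untreated well"
        )
    ko_defined = [s.mean_ratio for s in ko if not math.isnan(s.mean_ratio)]
    wt_defined = [s.mean_ratio for s in wt if not math.isnan(s.mean_ratio)]
    if len(ko_defined) < len(ko) or len(wt_defined) < len(wt):
        logger.info(
            "%d control well(s) without defined mean ratio excluded from references",
            len(ko) + len(wt) - len(ko_defined) - len(wt_defined),
        )
    if not ko_defined or not wt_defined:
        raise DegenerateControlsError("control wells yielded no defined cell ratios")
    ko_ref = float(np.mean(ko_defined))
    wt_ref = float(np.mean(wt_defined))
    control_counts = [s.n_cells for s in ko]

    for s in summaries.values():
        s.translocation_pct = translocation(s.mean_ratio, ko_ref, wt_ref)
        if not 0.0 <= s.translocation_pct <= 100.0:
            logger.info(
                "well %s translocation %.1f%% outside [0, 100]",
                s.well_id, s.translocation_pct,
            )
        s.cellcount_z, s.nontoxic = cellcount_zscore(s.n_cells, control_counts)

    order = {"KO_untreated": 0, "WT_untreated": 1, "treated": 2}
    rows = sorted(summaries.values(), key=lambda s: (order[s.role], s.moi, s.well_id))
    return pd.DataFrame(
        {
            "well_id": [s.well_id for s in rows],
            "role": [s.role for s in rows],
            "moi": [s.moi for s in rows],
            "n_cells": [s.n_cells for s in rows],
            "n_undefined_ratio": [s.n_undefined_ratio for s in rows],
            "mean_ratio": [s.mean_ratio for s in rows],
            "translocation_pct": [s.translocation_pct for s in rows],
            "cellcount_z": [s.cellcount_z for s in rows],
            "nontoxic": [s.nontoxic for s in rows],
        }
    )


def potency_table(well_df: pd.DataFrame) -> pd.DataFrame:
    """Per-MOI potency summary over a plate's treated wells.

    Rows are ordered by ascending MOI; the translocation SD is NaN for a
    single replicate well.  An empty frame is returned when the plate has no
    treated wells.
    """
    treated = well_df[well_df["role"] == "treated"]
    if treated.empty:
        return pd.DataFrame(
            columns=[
                "moi", "mean_translocation_pct", "sd_translocation_pct",
                "mean_cellcount_z", "n_wells", "n_cells",
            ]
        )
    rows = []
    for moi, grp in sorted(treated.groupby("moi"), key=lambda kv: kv[0]):
        t = grp["translocation_pct"].to_numpy(dtype=float)
        defined = t[~np.isnan(t)]
        if defined.size < len(t):
            logger.info(
                "MOI %g: %d well(s) without a defined mean ratio excluded",
                moi, len(t) - defined.size,
            )
        rows.append(
            {
                "moi": moi,
                "mean_translocation_pct": float(np.mean(defined)) if defined.size else math.nan,
                "sd_translocation_pct": float(np.std(defined, ddof=1)) if defined.size > 1 else math.nan,
                "mean_cellcount_z": float(grp["cellcount_z"].mean()),
                "n_wells": int(len(grp)),
                "n_cells": int(grp["n_cells"].sum()),
            }
        )
    return pd.DataFrame(rows)
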