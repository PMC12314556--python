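"""Nuclear:cytoplasmic localization analysis with cell-contact filtering.

Per cell, the nuclear:cytoplasmic intensity ratio of the labelled protein is
a proxy for its transcriptional activity. Cells are filtered to a window of
percent cell-cell contact (default the closed interval [45, 55]) to limit
contact-inhibition effects at either density extreme, aggregated to per-well
medians, expressed as percent of same-genotype vehicle wells, and finally
subjected to the 2-MAD well outlier rule across biological replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .features import remove_outlier_wells

log = logging.getLogger(__name__)

WELL_KEY = [
    "Metadata_Plate", "Metadata_Well", "Metadata_Genotype",
    "Metadata_Treatment", "Metadata_Concentration", "Metadata_Replicate",
]


def cell_ratio(nuclear_intensity: float, cytoplasmic_intensity: float) -> float:
    """Single-cell nuclear:cytoplasmic ratio; cytoplasm must be positive."""
    if cytoplasmic_intensity <= 0:
        raise ValidationError("cytoplasmic intensity must be > 0 for a ratio")
    return nuclear_intensity / cytoplasmic_intensity


def compute_ratios(cells: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Attach an ``nc_ratio`` column, excluding undetectable cells.

    Cells with nonpositive or missing intensity in either compartment have no
    detectable signal for a ratio; they are flagged and dropped, and their
    count returned (never silently ignored).
    """
    ok = (
        cells["nuclear_intensity"].gt(0)
        & cells["cytoplasmic_intensity"].gt(0)
        & cells["nuclear_intensity"].notna()
        & cells["cytoplasmic_intensity"].notna()
    )
    n_flagged = int((~ok).sum())
    out = cells[ok].copy()
    out["nc_ratio"] = out["nuclear_intensity"] / out["cytoplasmic_intensity"]
    if n_flagged:
        log.info("ratio computation excluded %d undetectable cells", n_flagged)
    return out, n_flagged


def contact_filter(cells: pd.DataFrame, low: float = 45.0, high: float = 55.0) -> pd.DataFrame:
    """Retain cells with ``low <= contact_percent <= high`` (closed interval)."""
    if not low < high:
        raise ValidationError("contact window requires low < high")
    kept = cells[(cells["contact_percent"] >= low) & (cells["contact_percent"] <= high)]
    log.info("contact filter retained %d/%d cells", len(kept), len(cells))
    return kept.copy()


@dataclass
class LocalizationReport:
    n_cells_in: int
    n_cells_flagged: int
    empty_wells: list[str] = field(default_factory=list)
    outlier_wells: list[str] = field(default_factory=list)


def well_summary(
    cells: pd.DataFrame,
    vehicle_label: str = "DMSO",
    vehicle_stat: str = "mean",
    outlier_group_cols=("Metadata_Genotype", "Metadata_Treatment", "Metadata_Concentration"),
) -> tuple[pd.DataFrame, LocalizationReport]:
    """Per-well median ratios normalized to same-genotype vehicle wells.

    Expects the contact filter to have been applied already. Per well the
    median cell ratio is computed; ``percent_of_vehicle`` divides it by the
    mean (or median, per ``vehicle_stat``) of the same genotype's vehicle
    well medians. The 2-MAD outlier rule then marks outlier wells across
    biological replicates within each treatment group; outliers are flagged
    in the ``outlier`` column and excluded wells listed in the report.
    """
    with_ratio, n_flagged = compute_ratios(cells)
    report = LocalizationReport(n_cells_in=len(cells), n_cells_flagged=n_flagged)
    if with_ratio.empty:
        raise ConfigurationError("no cells with computable ratios")

    summary = (
        with_ratio.groupby(WELL_KEY, sort=True)["nc_ratio"]
        .agg(median_ratio="median", n_cells_retained="size")
        .reset_index()
    )

    agg = {"mean": np.mean, "median": np.median}[vehicle_stat]
    out_frames = []
    for genotype, geno in summary.groupby("Metadata_Genotype", sort=True):
        veh = geno[geno["Metadata_Treatment"] == vehicle_label]
        if veh.empty:
            raise ConfigurationError(f"no vehicle wells for genotype {genotype!r}")
        baseline = float(agg(veh["median_ratio"].to_numpy()))
        geno = geno.copy()
        geno["percent_of_vehicle"] = 100.0 * geno["median_ratio"] / baseline
        out_frames.append(geno)
    summary = pd.concat(out_frames).reset_index(drop=True)

    group_labels = summary[list(outlier_group_cols)].astype(str).agg("|".join, axis=1)
    retained = remove_outlier_wells(summary["median_ratio"].to_numpy(), group_labels)
    summary["outlier"] = ~retained
    report.outlier_wells = (
        summary.loc[summary["outlier"], "Metadata_Plate"].astype(str)
        + ":" + summary.loc[summary["outlier"], "Metadata_Well"].astype(str)
    ).tolist()
    return summary, report


def dose_response(summary: pd.DataFrame, include_outliers: bool = False) -> pd.DataFrame:
    """Per treatment × concentration mean ± SD of percent-of-vehicle across wells."""
    df = summary if include_outliers else summary[~summary["outlier"]]
    return (
        df.groupby(["Metadata_Genotype", "Metadata_Treatment", "Metadata_Concentration"],
                   sort=True)["percent_of_vehicle"]
        .agg(mean_percent="mean", sd_percent="std", n_wells="size")
        .reset_index()
    )
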