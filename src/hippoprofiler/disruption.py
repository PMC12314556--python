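"""Modified robust Z' feature-disruption scoring and genotype-dependency adjustment.

The disruption score for one feature compares treated wells against the same
genotype's vehicle wells::

    z_mod = 1 - (MAD_treat + MAD_control) / |median_treat - median_control|

This is the classical Z'-factor with the scaling constant of 3 removed and
median/MAD replacing mean/SD. A feature is called *disrupted* when
``z_mod > 0``, i.e. when the median separation exceeds the summed robust
spreads. When the medians tie the score is undefined (NaN sentinel) and the
feature is not disrupted.

Dependency adjustment subtracts the knockout genotype's score from the
wild-type score (after clamping both from below); positive adjusted values
mark features whose disruption requires the knocked-out gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientReplicatesError, ReconciliationError
from .io import feature_columns
from .robust import mad

GROUP_KEY = ["Metadata_Genotype", "Metadata_Treatment", "Metadata_Concentration"]


@dataclass
class DisruptionScore:
    """One feature's modified robust Z' against its vehicle baseline."""

    feature: str
    z_mod: float  # NaN when the medians tie (undefined sentinel)
    disrupted: bool
    n_treat: int
    n_control: int
    median_treat: float
    median_control: float
    mad_treat: float
    mad_control: float
    genotype: str | None = None
    treatment: str | None = None
    concentration: float | None = None


def modified_z_prime(treat_values, control_values, feature: str = "") -> DisruptionScore:
    """Score one feature's treated arm against its control arm.

    Requires at least two values per arm. Returns all four intermediate
    robust statistics alongside the score; ``z_mod`` is NaN (and
    ``disrupted`` False) when the medians are identical.
    """
    t = np.asarray(treat_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise InsufficientReplicatesError(
            f"modified Z' needs >=2 values per arm (got {len(t)} treat, {len(c)} control)"
        )
    med_t, med_c = float(np.median(t)), float(np.median(c))
    mad_t, mad_c = mad(t), mad(c)
    delta = abs(med_t - med_c)
    z = np.nan if delta == 0.0 else 1.0 - (mad_t + mad_c) / delta
    disrupted = bool(np.isfinite(z) and z > 0.0)
    return DisruptionScore(
        feature=feature, z_mod=float(z), disrupted=disrupted,
        n_treat=len(t), n_control=len(c),
        median_treat=med_t, median_control=med_c,
        mad_treat=mad_t, mad_control=mad_c,
    )


def disruption_table(
    normalized_matrix: pd.DataFrame,
    vehicle_label: str = "DMSO",
) -> pd.DataFrame:
    """Score every (feature, genotype × treatment × concentration) group.

    Each treated group is compared against the *same genotype's* vehicle
    wells. Groups (or vehicle baselines) with fewer than 2 wells are skipped
    and listed in the returned frame's ``attrs['skipped_groups']``.
    """
    feats = feature_columns(normalized_matrix)
    rows: list[dict] = []
    skipped: list[tuple] = []
    for genotype, geno_df in normalized_matrix.groupby("Metadata_Genotype", sort=True):
        ctrl = geno_df[geno_df["Metadata_Treatment"] == vehicle_label]
        if len(ctrl) < 2:
            skipped.append((genotype, vehicle_label, None))
            continue
        C = ctrl[feats].to_numpy()
        med_c = np.median(C, axis=0)
        mad_c = mad(C, axis=0)
        treated = geno_df[geno_df["Metadata_Treatment"] != vehicle_label]
        for (treatment, conc), grp in treated.groupby(
            ["Metadata_Treatment", "Metadata_Concentration"], sort=True
        ):
            if len(grp) < 2:
                skipped.append((genotype, treatment, conc))
                continue
            T = grp[feats].to_numpy()
            med_t = np.median(T, axis=0)
            mad_t = mad(T, axis=0)
            delta = np.abs(med_t - med_c)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(delta > 0.0, 1.0 - (mad_t + mad_c) / delta, np.nan)
            for j, f in enumerate(feats):
                rows.append({
                    "feature": f,
                    "Metadata_Genotype": genotype,
                    "Metadata_Treatment": treatment,
                    "Metadata_Concentration": conc,
                    "z_mod": z[j],
                    "disrupted": bool(np.isfinite(z[j]) and z[j] > 0.0),
                    "n_treat": len(grp),
                    "n_control": len(ctrl),
                    "median_treat": med_t[j],
                    "median_control": med_c[j],
                    "mad_treat": mad_t[j],
                    "mad_control": mad_c[j],
                })
    table = pd.DataFrame(rows)
    table.attrs["skipped_groups"] = skipped
    return table


def percent_disrupted(table: pd.DataFrame, by=GROUP_KEY) -> pd.DataFrame:
    """Per group, 100 × (#disrupted) / (#scored features).

    Undefined-sentinel rows count as scored but never as disrupted.
    """
    by = list(by)
    out = (
        table.groupby(by, sort=True)
        .agg(n_features=("feature", "size"), n_disrupted=("disrupted", "sum"))
        .reset_index()
    )
    out["percent_disrupted"] = 100.0 * out["n_disrupted"] / out["n_features"]
    return out


def dependency_adjust(
    table_wt: pd.DataFrame,
    table_ko: pd.DataFrame,
    clamp_floor: float = -10.0,
    restrict_wt_positive: bool = True,
) -> pd.DataFrame:
    """Adjust disruption scores for genotype dependency (WT minus KO).

    Scores below ``clamp_floor`` — including undefined sentinels, which carry
    no separation information — are raised to the floor before subtraction so
    near-tie denominators cannot dominate. By default only features with
    discriminatory potential in wild type (``z_wt > 0``) are reported.
    Classification: ``dependent`` when adjusted > 0, else ``independent``.
    """
    key = ["feature", "Metadata_Treatment", "Metadata_Concentration"]
    wt = table_wt[key + ["z_mod"]].rename(columns={"z_mod": "z_wt"})
    ko = table_ko[key + ["z_mod"]].rename(columns={"z_mod": "z_ko"})
    merged = wt.merge(ko, on=key, how="outer", indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        missing = unmatched[key].head(20).to_dict("records")
        raise ReconciliationError(
            f"{len(unmatched)} (feature, treatment, concentration) keys "
            f"unmatched across genotypes; first few: {missing}"
        )
    merged = merged.drop(columns="_merge")

    def clamp(z):
        z = z.to_numpy(dtype=float)
        z = np.where(np.isfinite(z), z, clamp_floor)
        return np.maximum(z, clamp_floor)

    cw, ck = clamp(merged["z_wt"]), clamp(merged["z_ko"])
    merged["adjusted"] = cw - ck
    merged["classification"] = np.where(merged["adjusted"] > 0.0, "dependent", "independent")
    if restrict_wt_positive:
        merged = merged[merged["z_wt"] > 0.0].reset_index(drop=True)
    return merged


def disruption_pivot(table: pd.DataFrame, value: str = "z_mod") -> pd.DataFrame:
    """Heatmap-ready features × (genotype, treatment, concentration) pivot."""
    return table.pivot_table(
        index="feature",
        columns=GROUP_KEY,
        values=value,
        aggfunc="first",
        dropna=False,
    )
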