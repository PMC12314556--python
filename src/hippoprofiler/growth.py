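"""2D proliferation and spheroid growth quantification.

2D growth is summarized by fitting a logistic curve to each well's
confluency time series; the slope statistic is the curve's maximal
derivative ``L * k / 4``, normalized per genotype to vehicle wells with
negative rates clipped to zero. Spheroid tracks are first cleaned with a
per-time-point 2-MAD trim across like-treated wells (wells with more than
half their time-points trimmed are excluded), then growth is the day-7
(168 h) area over the 24-h area within each well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import ConfigurationError, ReconciliationError
from .robust import mad

log = logging.getLogger(__name__)

WELL_KEY = [
    "Metadata_Plate", "Metadata_Well", "Metadata_Genotype",
    "Metadata_Treatment", "Metadata_Concentration", "Metadata_Replicate",
]
TRIM_GROUP = ["Metadata_Genotype", "Metadata_Treatment", "Metadata_Concentration",
              "Metadata_Replicate"]


def logistic(t, L, k, t0):
    """Three-parameter logistic ``L / (1 + exp(-k (t - t0)))``."""
    return L / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t0)))


@dataclass
class GrowthFit:
    L: float        # plateau, in the series' units (e.g. % confluency)
    k: float        # rate, per hour
    t0: float       # midpoint, hours
    slope_stat: float  # maximal derivative L*k/4, units per hour
    fit_ok: bool


def fit_logistic(times, values) -> GrowthFit:
    """Bounded least-squares logistic fit with deterministic initialization.

    L starts at the series maximum, t0 at the time of half-maximum, and k at
    a log-linear pre-fit of the logit transform; bounds keep parameters in a
    physically sensible range. A constant series, or a failed fit, returns
    ``fit_ok=False`` with ``slope_stat`` taken from a straight-line fallback
    fit (slope of values against time).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 4:
        raise ConfigurationError("logistic fit needs >= 4 time-points")
    if np.ptp(v) == 0.0:
        return GrowthFit(L=float(v[0]), k=0.0, t0=float(np.median(t)),
                         slope_stat=0.0, fit_ok=False)
    trend = float(np.polyfit(t, v, 1)[0])
    if trend < 0:
        # a shrinking culture is outside the logistic model (k > 0); report
        # the negative straight-line rate so normalization clips it to 0
        return GrowthFit(L=float(v.max()), k=0.0, t0=float(np.median(t)),
                         slope_stat=trend, fit_ok=False)

    L0 = float(v.max())
    t0_0 = float(np.interp(L0 / 2.0, np.sort(v), t[np.argsort(v)]))
    # log-linear pre-fit of logit(v / L) where defined
    frac = np.clip(v / (1.05 * L0), 1e-6, 1 - 1e-6)
    slope_pre = np.polyfit(t, np.log(frac / (1 - frac)), 1)[0]
    k0 = float(np.clip(abs(slope_pre), 1e-3, 1.0))
    span = t[-1] - t[0]
    try:
        popt, _ = curve_fit(
            logistic, t, v,
            p0=[L0, k0, t0_0],
            bounds=([1e-9, 1e-4, t[0] - span], [10.0 * L0, 5.0, t[-1] + span]),
            maxfev=10000,
        )
        L, k, t0 = map(float, popt)
        return GrowthFit(L=L, k=k, t0=t0, slope_stat=L * k / 4.0, fit_ok=True)
    except (RuntimeError, ValueError):
        lin_slope = float(np.polyfit(t, v, 1)[0])
        log.warning("logistic fit failed; straight-line fallback slope %.4g", lin_slope)
        return GrowthFit(L=L0, k=0.0, t0=t0_0, slope_stat=lin_slope, fit_ok=False)


def fit_growth_table(tracks: pd.DataFrame, value_col: str = "confluency") -> pd.DataFrame:
    """Fit a logistic curve per well of a long-format track table."""
    rows = []
    for key, grp in tracks.groupby(WELL_KEY, sort=True):
        grp = grp.sort_values("time_h")
        fit = fit_logistic(grp["time_h"].to_numpy(), grp[value_col].to_numpy())
        rows.append({**dict(zip(WELL_KEY, key)), "L": fit.L, "k": fit.k,
                     "t0": fit.t0, "slope_stat": fit.slope_stat, "fit_ok": fit.fit_ok})
    return pd.DataFrame(rows)


def normalize_growth(fits: pd.DataFrame, vehicle_label: str = "DMSO") -> pd.DataFrame:
    """Normalize slope statistics to same-genotype vehicle wells, clipping at 0.

    A strictly decreasing series has a negative (fallback) slope statistic;
    after normalization those rates are adjusted to 0.
    """
    out_frames = []
    for genotype, geno in fits.groupby("Metadata_Genotype", sort=True):
        veh = geno[geno["Metadata_Treatment"] == vehicle_label]
        if veh.empty:
            raise ConfigurationError(f"no vehicle wells for genotype {genotype!r}")
        baseline = float(veh["slope_stat"].mean())
        if baseline <= 0:
            raise ConfigurationError(
                f"vehicle slope statistic for genotype {genotype!r} is not positive"
            )
        geno = geno.copy()
        geno["normalized_growth"] = np.maximum(geno["slope_stat"] / baseline, 0.0)
        out_frames.append(geno)
    return pd.concat(out_frames).reset_index(drop=True)


def trim_timepoints(tracks: pd.DataFrame, group_cols=TRIM_GROUP,
                    value_col: str = "area") -> pd.DataFrame:
    """Mask per-time-point artefact spikes with the 2-MAD rule.

    Within each group of like-treated wells, at each time-point, wells whose
    area deviates from the cross-well median by strictly more than two raw
    MADs are masked (``trimmed=True``). Time-points observed in fewer than 3
    wells are left untrimmed (logged). Wells with more than half their
    time-points trimmed are flagged ``excluded`` (strict: exactly half is
    retained).
    """
    group_cols = [c for c in group_cols if c in tracks.columns]
    out = tracks.copy()
    out["trimmed"] = False
    for gkey, grp in out.groupby(group_cols + ["time_h"], sort=False):
        if len(grp) < 3:
            log.debug("trim: group %r has %d wells (<3); untrimmed", gkey, len(grp))
            continue
        v = grp[value_col].to_numpy(dtype=float)
        med, spread = np.median(v), mad(v)
        out.loc[grp.index, "trimmed"] = np.abs(v - med) > 2.0 * spread
    frac = out.groupby(WELL_KEY, sort=False)["trimmed"].transform("mean")
    out["excluded"] = frac > 0.5
    return out


def spheroid_growth(
    tracks: pd.DataFrame,
    anchor_early: float = 24.0,
    anchor_late: float = 168.0,
    anchor_tol: float = 4.0,
    value_col: str = "area",
) -> pd.DataFrame:
    """Per-well growth = area at ~168 h over area at ~24 h.

    Operates on trimmed tracks (see :func:`trim_timepoints`); excluded wells
    and wells without an unmasked time-point within ``anchor_tol`` hours of
    either anchor are skipped and listed in ``attrs['skipped_wells']``.
    When a masked anchor forces use of a neighbouring time-point, the actual
    times used are recorded per well.
    """
    if "trimmed" not in tracks.columns:
        tracks = tracks.copy()
        tracks["trimmed"] = False
        tracks["excluded"] = False
    rows, skipped = [], []
    for key, grp in tracks.groupby(WELL_KEY, sort=True):
        well = f"{key[0]}:{key[1]}"
        if bool(grp["excluded"].any()):
            skipped.append((well, "excluded"))
            continue
        usable = grp[~grp["trimmed"]].sort_values("time_h")

        def pick(anchor):
            near = usable[np.abs(usable["time_h"] - anchor) <= anchor_tol]
            if near.empty:
                return None
            return near.iloc[int(np.argmin(np.abs(near["time_h"].to_numpy() - anchor)))]

        early, late = pick(anchor_early), pick(anchor_late)
        if early is None or late is None:
            skipped.append((well, "missing anchor time-point"))
            continue
        if early["time_h"] != anchor_early or late["time_h"] != anchor_late:
            log.info("well %s used anchors t=%s,%s h", well, early["time_h"], late["time_h"])
        rows.append({
            **dict(zip(WELL_KEY, key)),
            "t_early": float(early["time_h"]), "t_late": float(late["time_h"]),
            "area_early": float(early[value_col]), "area_late": float(late[value_col]),
            "growth": float(late[value_col]) / float(early[value_col]),
        })
    out = pd.DataFrame(rows)
    out.attrs["skipped_wells"] = skipped
    return out


def sensitivity(
    response_table: pd.DataFrame,
    reference_genotype: str = "WT",
    response_col: str = "normalized_growth",
) -> pd.DataFrame:
    """Percent growth-reduction relative to a reference genotype.

    Per well, ``response = 100 * (1 - normalized_growth)``; per treatment ×
    concentration, ``sensitivity = response - mean reference response``.
    Negative values mean reduced sensitivity (more growth on treatment)
    relative to the reference.
    """
    df = response_table.copy()
    df["response"] = 100.0 * (1.0 - df[response_col])
    ref = df[df["Metadata_Genotype"] == reference_genotype]
    if ref.empty:
        raise ReconciliationError(f"no wells for reference genotype {reference_genotype!r}")
    ref_mean = (
        ref.groupby(["Metadata_Treatment", "Metadata_Concentration"])["response"]
        .mean().rename("reference_response").reset_index()
    )
    merged = df.merge(ref_mean, on=["Metadata_Treatment", "Metadata_Concentration"],
                      how="left", indicator=True)
    missing = merged[merged["_merge"] != "both"]
    if len(missing):
        keys = missing[["Metadata_Treatment", "Metadata_Concentration"]].drop_duplicates()
        raise ReconciliationError(
            f"no reference wells for treatment cells: {keys.to_dict('records')}"
        )
    merged = merged.drop(columns="_merge")
    merged["sensitivity"] = merged["response"] - merged["reference_response"]
    return merged
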