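"""Feature curation, vehicle-control normalization, and the 2-MAD well rule.

Curation removes near-constant features and then greedily trims highly
correlated ones; normalization rescales every retained feature to robust
z-scores against vehicle (DMSO) wells of the wild-type genotype; the well
outlier rule drops wells more than two raw MADs from their group median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateOutputError, ValidationError
from .io import feature_columns, metadata_columns
from .robust import mad

log = logging.getLogger(__name__)


@dataclass
class CurationReport:
    """Accounting for a curation pass: every input feature is either retained
    or appears in exactly one dropped set."""

    n_input_features: int
    n_retained: int
    dropped_low_variance: list[str] = field(default_factory=list)
    #: feature -> the already-retained partner whose correlation triggered the drop
    dropped_correlated: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": f, "reason": "low_variance", "partner": ""}
                for f in self.dropped_low_variance]
        rows += [{"feature": f, "reason": "correlated", "partner": p}
                 for f, p in self.dropped_correlated.items()]
        return pd.DataFrame(rows, columns=["feature", "reason", "partner"])


def curate_features(
    matrix: pd.DataFrame,
    variance_threshold: float = 1e-8,
    correlation_threshold: float = 0.9,
) -> tuple[pd.DataFrame, CurationReport]:
    """Drop low-variance then highly correlated features.

    Correlation trimming is greedy and deterministic: while any retained pair
    exceeds the threshold in absolute Pearson correlation, the feature with
    the highest mean absolute correlation to the other retained features is
    dropped (ties broken by column order), and correlations are reassessed.

    Returns the curated matrix (metadata columns untouched) and a
    :class:`CurationReport`.
    """
    if len(matrix) < 2:
        raise ConfigurationError("curation requires at least 2 wells")
    if variance_threshold < 0:
        raise ValidationError("variance_threshold must be >= 0")
    if not (0 < correlation_threshold <= 1):
        raise ValidationError("correlation_threshold must be in (0, 1]")

    feats = feature_columns(matrix)
    variances = matrix[feats].var(axis=0, ddof=1)
    low_var = [f for f in feats if variances[f] < variance_threshold]
    kept = [f for f in feats if f not in set(low_var)]

    dropped_corr: dict[str, str] = {}
    if kept:
        corr = matrix[kept].corr().abs().fillna(0.0)
        np.fill_diagonal(corr.values, 0.0)
        while len(corr) > 1 and corr.values.max() > correlation_threshold:
            per_feature_max = corr.max(axis=1)
            offenders = per_feature_max[per_feature_max > correlation_threshold].index
            mean_corr = corr.loc[offenders].mean(axis=1)
            drop = mean_corr.idxmax()  # first occurrence wins ties: column order
            dropped_corr[drop] = corr.loc[drop].idxmax()
            corr = corr.drop(index=drop, columns=drop)
        kept = [f for f in kept if f not in dropped_corr]

    if not kept:
        raise DegenerateOutputError("curation dropped every feature")

    report = CurationReport(
        n_input_features=len(feats),
        n_retained=len(kept),
        dropped_low_variance=low_var,
        dropped_correlated=dropped_corr,
    )
    log.info(
        "curation: retained %d/%d features (%d low-variance, %d correlated dropped)",
        report.n_retained, report.n_input_features,
        len(low_var), len(dropped_corr),
    )
    curated = matrix[metadata_columns(matrix) + kept].copy()
    return curated, report


@dataclass
class NormalizationReport:
    n_control_wells: int
    dropped_zero_mad: list[str] = field(default_factory=list)


def normalize_to_control(
    matrix: pd.DataFrame,
    vehicle_label: str = "DMSO",
    control_genotype: str = "WT",
    per_plate: bool = True,
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Robust-z normalize features to vehicle-treated wild-type wells.

    Per feature (and per plate when ``per_plate``), output is
    ``(value - control_median) / control_MAD`` with the raw MAD. Features
    whose control MAD is zero on any plate carry no usable control spread and
    are dropped with a report.
    """
    is_control = (
        (matrix["Metadata_Treatment"] == vehicle_label)
        & (matrix["Metadata_Genotype"] == control_genotype)
    )
    if int(is_control.sum()) < 2:
        raise ConfigurationError(
            f"need >=2 vehicle control wells ({vehicle_label}, {control_genotype}); "
            f"found {int(is_control.sum())}"
        )

    feats = feature_columns(matrix)
    out = matrix.copy()
    zero_mad: set[str] = set()

    plates = matrix["Metadata_Plate"].unique() if per_plate else [None]
    for plate in plates:
        in_plate = (
            matrix["Metadata_Plate"] == plate if plate is not None
            else pd.Series(True, index=matrix.index)
        )
        ctrl = matrix.loc[is_control & in_plate, feats]
        if len(ctrl) < 2:
            raise ConfigurationError(
                f"plate {plate!r} has {len(ctrl)} vehicle control wells; need >=2"
            )
        med = ctrl.median(axis=0)
        spread = ctrl.apply(lambda c: mad(c.to_numpy()), axis=0)
        zero_mad.update(spread.index[spread == 0.0])
        safe = spread.replace(0.0, np.nan)
        out.loc[in_plate, feats] = (matrix.loc[in_plate, feats] - med) / safe

    keep = [f for f in feats if f not in zero_mad]
    if not keep:
        raise DegenerateOutputError("all features had zero control MAD")
    report = NormalizationReport(
        n_control_wells=int(is_control.sum()),
        dropped_zero_mad=sorted(zero_mad),
    )
    if zero_mad:
        log.info("normalization dropped %d zero-MAD features", len(zero_mad))
    return out[metadata_columns(matrix) + keep], report


def remove_outlier_wells(values, groups=None) -> np.ndarray:
    """Retention mask for the 2-MAD well outlier rule.

    Within each group, wells whose value deviates from the group median by
    strictly more than twice the raw group MAD are removed. The rule is
    applied once on the original group statistics (no iterative re-trimming).
    Groups with fewer than 3 wells pass through untouched (logged).

    Parameters
    ----------
    values : array-like of float, one summary value per well
    groups : array-like of group labels, optional (one group if omitted)

    Returns
    -------
    numpy boolean array, ``True`` for retained wells.
    """
    v = np.asarray(values, dtype=float)
    g = np.zeros(len(v)) if groups is None else np.asarray(groups)
    retained = np.ones(len(v), dtype=bool)
    for key in pd.unique(g):
        idx = np.flatnonzero(g == key)
        if len(idx) < 3:
            log.warning("outlier rule: group %r has %d wells (<3); retained as-is",
                        key, len(idx))
            continue
        med = np.median(v[idx])
        spread = mad(v[idx])
        retained[idx] = np.abs(v[idx] - med) <= 2.0 * spread
    return retained
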