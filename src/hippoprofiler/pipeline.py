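"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages: simulate (or load) → curate → normalize → distance/uniformity →
disruption → dependency → localization → growth. Each stage's output CSV is
hashed into ``manifest.txt`` together with the config hash, seed and package
version; re-running with the same config and seed reproduces the manifest
hashes byte-for-byte. Attrition (rows/features retained vs dropped) is
logged per stage because the filters discard large fractions of data by
design.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisParams, config_hash
from .disruption import dependency_adjust, disruption_table, percent_disrupted
from .exceptions import ConfigurationError, HippoProfilerError, PipelineStageError
from .features import curate_features, normalize_to_control
from .growth import fit_growth_table, normalize_growth, sensitivity, spheroid_growth, trim_timepoints
from .io import (read_cell_table, read_feature_matrix, read_growth_table,
                 write_feature_matrix)
from .localization import contact_filter, well_summary
from .profiling import distance_matrix, linkage_table, pca_trajectories, uniformity_scores
from .synthetic import (SyntheticConfig, generate_cell_table, generate_feature_matrix,
                        generate_growth_tracks, write_truth)

log = logging.getLogger(__name__)

ARTIFACTS = [
    "curated.csv", "normalized.csv", "distance.csv", "uniformity.csv",
    "disruption.csv", "dependency.csv", "localization.csv", "growth.csv",
]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(
    outdir,
    config: SyntheticConfig | None = None,
    params: AnalysisParams | None = None,
    feature_matrix_path=None,
    cell_table_path=None,
    growth_2d_path=None,
    growth_spheroid_path=None,
) -> Path:
    """Run every stage and write all artifacts plus a manifest.

    Inputs come either from a synthetic ``config`` or from existing CSV
    paths; missing paths are reported before any stage runs. Returns the
    artifact directory.
    """
    params = params or AnalysisParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paths = {
        "feature_matrix": feature_matrix_path, "cell_table": cell_table_path,
        "growth_2d": growth_2d_path, "growth_spheroid": growth_spheroid_path,
    }
    for name, p in paths.items():
        if p is not None and not Path(p).exists():
            raise ConfigurationError(f"input '{name}' does not exist: {p}")
    if config is None and any(p is None for p in paths.values()):
        raise ConfigurationError(
            "either a synthetic config or all four input paths must be given"
        )

    def stage(name, fn):
        try:
            return fn()
        except HippoProfilerError as exc:
            raise PipelineStageError(name, str(exc)) from exc

    # --- inputs -----------------------------------------------------------
    if feature_matrix_path is not None:
        matrix = stage("load", lambda: read_feature_matrix(feature_matrix_path))
        cells = stage("load", lambda: read_cell_table(cell_table_path))
        tracks_2d = stage("load", lambda: read_growth_table(growth_2d_path, "confluency"))
        tracks_sph = stage("load", lambda: read_growth_table(growth_spheroid_path, "area"))
    else:
        def simulate():
            m, truth_m = generate_feature_matrix(config)
            c, truth_c = generate_cell_table(config)
            g2, truth_2 = generate_growth_tracks(config, mode="2d")
            gs, truth_s = generate_growth_tracks(config, mode="spheroid")
            write_feature_matrix(m, outdir / "feature_matrix.csv")
            c.to_csv(outdir / "cell_table.csv", index=False)
            g2.to_csv(outdir / "growth_2d.csv", index=False)
            gs.to_csv(outdir / "growth_spheroid.csv", index=False)
            truth_m.outlier_timepoints = truth_s.outlier_timepoints
            truth_m.true_growth = truth_s.true_growth
            truth_m.true_well_ratio = truth_c.true_well_ratio
            write_truth(truth_m, outdir / "truth.txt")
            return m, c, g2, gs
        matrix, cells, tracks_2d, tracks_sph = stage("simulate", simulate)
    log.info("inputs: %d wells x %d columns; %d cells; %d 2D rows; %d spheroid rows",
             len(matrix), matrix.shape[1], len(cells), len(tracks_2d), len(tracks_sph))

    # --- feature pipeline -------------------------------------------------
    def curate():
        curated, report = curate_features(
            matrix, params.variance_threshold, params.correlation_threshold)
        curated.to_csv(outdir / "curated.csv", index=False)
        report.to_frame().to_csv(outdir / "curation_report.csv", index=False)
        return curated
    curated = stage("curate", curate)

    def normalize():
        normed, _ = normalize_to_control(
            curated, params.vehicle_label, params.wt_genotype)
        normed.to_csv(outdir / "normalized.csv", index=False)
        return normed
    normalized = stage("normalize", normalize)

    # --- profiling --------------------------------------------------------
    def profile():
        dist = distance_matrix(normalized)
        dist.to_csv(outdir / "distance.csv")
        linkage_table(dist).to_csv(outdir / "linkage.csv", index=False)
        _, traj = pca_trajectories(normalized, params.vehicle_label)
        traj.to_csv(outdir / "pca_trajectories.csv", index=False)
        meta = normalized[[c for c in normalized.columns if c.startswith("Metadata_")]]
        uni = uniformity_scores(dist, meta)
        uni.to_csv(outdir / "uniformity.csv", index=False)
        return dist
    stage("profile", profile)

    # --- disruption -------------------------------------------------------
    def disrupt():
        table = disruption_table(normalized, params.vehicle_label)
        table.to_csv(outdir / "disruption.csv", index=False)
        percent_disrupted(table).to_csv(outdir / "percent_disrupted.csv", index=False)
        return table
    table = stage("disrupt", disrupt)

    def dependency():
        wt = table[table["Metadata_Genotype"] == params.wt_genotype]
        ko = table[table["Metadata_Genotype"] == params.ko_genotype]
        dep = dependency_adjust(wt, ko, clamp_floor=params.clamp_floor)
        dep.to_csv(outdir / "dependency.csv", index=False)
    stage("dependency", dependency)

    # --- localization -----------------------------------------------------
    def localize():
        kept = contact_filter(cells, params.contact_low, params.contact_high)
        summary, _ = well_summary(kept, params.vehicle_label)
        summary.to_csv(outdir / "localization.csv", index=False)
    stage("localize", localize)

    # --- growth -----------------------------------------------------------
    def growth():
        fits = fit_growth_table(tracks_2d, value_col="confluency")
        normed = normalize_growth(fits, params.vehicle_label)
        sens = sensitivity(normed, params.wt_genotype)
        trimmed = trim_timepoints(tracks_sph, value_col="area")
        sph = spheroid_growth(trimmed, params.anchor_early, params.anchor_late,
                              params.anchor_tol)
        sph = sph.rename(columns={"growth": "spheroid_growth"})
        merged = normed.merge(
            sph[[*("Metadata_Plate", "Metadata_Well"), "spheroid_growth"]],
            on=["Metadata_Plate", "Metadata_Well"], how="left")
        merged["sensitivity"] = sens["sensitivity"]
        merged.to_csv(outdir / "growth.csv", index=False)
    stage("growth", growth)

    # --- manifest ---------------------------------------------------------
    lines = [
        f"version={__version__}",
        f"seed={'NA' if config is None else config.seed}",
        f"config_hash={config_hash(config, params)}",
    ]
    for name in ARTIFACTS:
        lines.append(f"sha256[{name}]={_sha256(outdir / name)}")
    (outdir / "manifest.txt").write_text("\n".join(lines) + "\n")
    log.info("pipeline complete: %d artifacts in %s", len(ARTIFACTS), outdir)
    return outdir


def read_manifest(outdir) -> dict[str, str]:
    out = {}
    for line in (Path(outdir) / "manifest.txt").read_text().splitlines():
        key, _, value = line.partition("=")
        out[key] = value
    return out
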