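"""Synthetic data with the measurement structure the analysis assumes.

Three generators emit the same CSV dialects the pipeline consumes, together
with a ground-truth object for recovery testing:

* :func:`generate_feature_matrix` — well × feature profiles with
  block-correlated baseline noise, planted treatment-disruption shifts that
  are present in the wild-type genotype and absent (or attenuated) for
  *dependent* features in the knockout, and occasional gross outlier wells.
* :func:`generate_cell_table` — per-cell nuclear/cytoplasmic intensities
  with a dose-dependent multiplicative reduction of the nuclear:cytoplasmic
  ratio, plus a percent cell-cell contact column uniform on [0, 100].
* :func:`generate_growth_tracks` — logistic growth tracks (spheroid areas
  or 2D confluency) with multiplicative noise and sporadic
  segmentation-artefact spikes.

All randomness derives from a single integer seed; identical (config, seed)
produce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .robust import NORMAL_MAD

__all__ = [
    "Treatment", "SyntheticConfig", "SyntheticTruth",
    "generate_feature_matrix", "generate_cell_table", "generate_growth_tracks",
    "write_truth", "read_truth", "dose_scale",
]


@dataclass(frozen=True)
class Treatment:
    label: str
    family: str  # "selective-TEAD" or "non-selective"
    concentrations: tuple[float, ...]  # µM


#: Inhibitor panel and dose grid mirroring the profiled compound classes:
#: three selective TEAD autopalmitoylation inhibitors and three classical
#: non-selective YAP/TAZ inhibitors, each at a 1:3 dilution triplet.
DEFAULT_TREATMENTS: tuple[Treatment, ...] = (
    Treatment("VT-107", "selective-TEAD", (1.1, 3.3, 10.0)),
    Treatment("K-975", "selective-TEAD", (1.1, 3.3, 10.0)),
    Treatment("IK-930", "selective-TEAD", (1.1, 3.3, 10.0)),
    Treatment("verteporfin", "non-selective", (1.1, 3.3, 10.0)),
    Treatment("lovastatin", "non-selective", (1.1, 3.3, 10.0)),
    Treatment("dasatinib", "non-selective", (1.1, 3.3, 10.0)),
)

DEFAULT_GROWTH_PARAMS = {
    # genotype -> (L [area units], k [/h], t0 [h]) for spheroid tracks
    "WT": (20000.0, 0.045, 84.0),
    "NF2_KO": (30000.0, 0.05, 80.0),
    "YAP_KO": (12000.0, 0.04, 90.0),
}
DEFAULT_GROWTH_PARAMS_2D = {
    # genotype -> (L [% confluency], k [/h], t0 [h]) for 2D tracks
    "WT": (90.0, 0.1, 36.0),
    "NF2_KO": (90.0, 0.11, 34.0),
    "YAP_KO": (90.0, 0.09, 38.0),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the profiled study design: two genotypes (wild type and
    a YAP knockout), six inhibitors at three doses, three biological
    replicate wells per condition (with four technical wells per biological
    replicate for the localization assay).
    """

    seed: int = 0
    n_features: int = 120
    n_blocks: int = 12
    block_rho: float = 0.95
    genotypes: tuple[str, ...] = ("WT", "YAP_KO")
    wt_genotype: str = "WT"
    ko_genotype: str = "YAP_KO"
    treatments: tuple[Treatment, ...] = DEFAULT_TREATMENTS
    vehicle_label: str = "DMSO"
    n_replicate_wells: int = 3
    n_technical_wells: int = 4
    plate: str = "P1"
    # feature-matrix effect structure
    effect_size: float = 6.0          # shift at top dose, in control-MAD units
    affected_fraction: float = 0.25   # fraction of features shifted per treatment
    dependent_fraction: float = 0.5   # affected features whose effect needs the KO'd gene
    ko_attenuation: float = 0.0       # residual effect multiplier in KO (0 = all-or-none)
    outlier_well_rate: float = 0.02
    outlier_shift: float = 25.0       # constant added to every feature of an outlier well
    # cell-table structure
    cells_per_well: int = 200
    intensity_scale: float = 1000.0   # arbitrary fluorescence units
    intensity_sigma: float = 0.35     # lognormal sigma of cytoplasmic intensity
    baseline_nc_ratio: float = 2.0    # vehicle nuclear:cytoplasmic median
    ratio_effect: float = 0.5         # multiplicative N:C reduction at top dose
    cell_ratio_sigma: float = 0.25    # cell-to-cell lognormal spread of the ratio
    well_ratio_sigma: float = 0.05    # well-to-well lognormal spread
    # growth tracks
    growth_params: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH_PARAMS))
    growth_params_2d: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH_PARAMS_2D))
    growth_inhibition: float = 0.5    # fractional k reduction at top dose (or per-genotype dict)
    growth_noise: float = 0.05        # lognormal sigma on areas
    outlier_timepoint_rate: float = 0.02
    spike_factor: float = 5.0
    spheroid_times: tuple[float, ...] = tuple(float(t) for t in range(12, 169, 12))
    times_2d: tuple[float, ...] = tuple(float(t) for t in range(0, 73, 4))

    def __post_init__(self):
        if self.n_replicate_wells < 1:
            raise ConfigurationError("n_replicate_wells must be >= 1")
        for name in ("affected_fraction", "dependent_fraction", "ko_attenuation",
                     "outlier_well_rate", "outlier_timepoint_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]; got {val}")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValidationError("block_rho must be in [0, 1)")
        if self.intensity_scale <= 0:
            raise ValidationError("intensity_scale must be > 0")
        if self.cells_per_well < 1:
            raise ValidationError("cells_per_well must be >= 1")
        if self.n_features < 1 or self.n_blocks < 1 or self.n_blocks > self.n_features:
            raise ValidationError("need 1 <= n_blocks <= n_features")
        for times in (self.spheroid_times, self.times_2d):
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValidationError("time grids must be strictly increasing")
        if self.wt_genotype not in self.genotypes:
            raise ConfigurationError("wt_genotype must be listed in genotypes")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside synthetic tables."""

    seed: int
    affected_features: dict[str, set[str]] = field(default_factory=dict)
    dependency_labels: dict[str, str] = field(default_factory=dict)  # only affected features
    outlier_wells: set[str] = field(default_factory=set)
    outlier_timepoints: set[tuple[str, float]] = field(default_factory=set)
    true_growth: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    true_well_ratio: dict[str, float] = field(default_factory=dict)


def dose_scale(concentration: float, concentrations: tuple[float, ...]) -> float:
    """Log-linear effect scaling across the configured dose range.

    Maps the lowest configured dose to 0.5 and the highest to 1.0 on a log
    scale (a single-dose treatment scales by 1.0), giving monotone dose
    trajectories without asserting a specific pharmacology.
    """
    cmin, cmax = min(concentrations), max(concentrations)
    if cmax == cmin:
        return 1.0
    t = (math.log(concentration) - math.log(cmin)) / (math.log(cmax) - math.log(cmin))
    return 0.5 + 0.5 * t


def _condition_grid(config: SyntheticConfig):
    """(treatment label, family, concentration) including the vehicle at dose 0."""
    conds = [(config.vehicle_label, "vehicle", 0.0)]
    for trt in config.treatments:
        for c in trt.concentrations:
            conds.append((trt.label, trt.family, float(c)))
    return conds


def _treatment_by_label(config: SyntheticConfig) -> dict[str, Treatment]:
    return {t.label: t for t in config.treatments}


def generate_feature_matrix(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Well × feature profiles with planted, genotype-dependent disruption.

    Baseline features are unit-variance with shared latent factors per block
    (loading sqrt(block_rho)), reproducing the redundant-feature structure
    that curation must remove. Treated wells receive a shift of
    ``effect_size × NORMAL_MAD × dose_scale`` on the treatment's affected
    features; in the knockout genotype, features labelled *dependent* receive
    the shift multiplied by ``ko_attenuation`` (0 by default, i.e. absent).
    Outlier wells get a large constant added to every feature.
    """
    if config.n_replicate_wells < 2:
        raise ConfigurationError("feature matrix generation needs >=2 replicate wells")
    rng = np.random.default_rng([config.seed, 1])
    features = [f"feat_{i:04d}" for i in range(config.n_features)]
    block_of = np.array([i * config.n_blocks // config.n_features
                         for i in range(config.n_features)])
    truth = SyntheticTruth(seed=config.seed)

    # Planted effect structure (drawn first so well-count changes do not
    # reshuffle which features carry signal).
    n_affected = int(round(config.affected_fraction * config.n_features))
    if config.effect_size != 0.0 and n_affected > 0:
        for trt in config.treatments:
            chosen = rng.choice(config.n_features, size=n_affected, replace=False)
            names = {features[i] for i in chosen}
            truth.affected_features[trt.label] = names
            for i in sorted(chosen):
                f = features[i]
                if f not in truth.dependency_labels:
                    truth.dependency_labels[f] = (
                        "dependent" if rng.random() < config.dependent_fraction
                        else "independent"
                    )
    else:
        for trt in config.treatments:
            truth.affected_features[trt.label] = set()

    conds = _condition_grid(config)
    meta_rows = []
    for genotype in config.genotypes:
        for label, family, conc in conds:
            for rep in range(1, config.n_replicate_wells + 1):
                meta_rows.append((config.plate, genotype, label, family, conc, rep))
    n_wells = len(meta_rows)

    latents = rng.standard_normal((n_wells, config.n_blocks))
    eps = rng.standard_normal((n_wells, config.n_features))
    X = (math.sqrt(config.block_rho) * latents[:, block_of]
         + math.sqrt(1.0 - config.block_rho) * eps)

    by_label = _treatment_by_label(config)
    feat_index = {f: j for j, f in enumerate(features)}
    for w, (_, genotype, label, _, conc, _) in enumerate(meta_rows):
        if label == config.vehicle_label or config.effect_size == 0.0:
            continue
        scale = dose_scale(conc, by_label[label].concentrations)
        for f in truth.affected_features[label]:
            factor = 1.0
            if genotype == config.ko_genotype and truth.dependency_labels[f] == "dependent":
                factor = config.ko_attenuation
            X[w, feat_index[f]] += config.effect_size * NORMAL_MAD * scale * factor

    outlier_draws = rng.random(n_wells)
    well_names = [f"W{w + 1:03d}" for w in range(n_wells)]
    for w in range(n_wells):
        if outlier_draws[w] < config.outlier_well_rate:
            X[w, :] += config.outlier_shift
            truth.outlier_wells.add(f"{config.plate}:{well_names[w]}")

    df = pd.DataFrame({
        "Metadata_Plate": [m[0] for m in meta_rows],
        "Metadata_Well": well_names,
        "Metadata_Genotype": [m[1] for m in meta_rows],
        "Metadata_Treatment": [m[2] for m in meta_rows],
        "Metadata_Family": [m[3] for m in meta_rows],
        "Metadata_Concentration": [m[4] for m in meta_rows],
        "Metadata_Replicate": [m[5] for m in meta_rows],
    })
    df = pd.concat([df, pd.DataFrame(X, columns=features)], axis=1)
    return df, truth


def generate_cell_table(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-cell intensities with a dose-dependent N:C ratio reduction.

    Cytoplasmic intensity is lognormal around ``intensity_scale``; the
    per-cell ratio is lognormal around a per-well level whose median equals
    ``baseline_nc_ratio × ratio_effect ** dose_scale`` (vehicle wells are at
    baseline). The true per-well median ratio is recorded in the truth
    object. Percent cell-cell contact is uniform on [0, 100].
    """
    rng = np.random.default_rng([config.seed, 2])
    truth = SyntheticTruth(seed=config.seed)
    by_label = _treatment_by_label(config)
    frames = []
    well_counter = 0
    for genotype in config.genotypes:
        for label, family, conc in _condition_grid(config):
            effect = 1.0
            if label != config.vehicle_label:
                effect = config.ratio_effect ** dose_scale(conc, by_label[label].concentrations)
            for rep in range(1, config.n_replicate_wells + 1):
                for _tech in range(config.n_technical_wells):
                    well_counter += 1
                    well = f"W{well_counter:04d}"
                    well_level = (config.baseline_nc_ratio * effect
                                  * math.exp(rng.normal(0.0, config.well_ratio_sigma)))
                    truth.true_well_ratio[f"{config.plate}:{well}"] = well_level
                    n = config.cells_per_well
                    cyt = config.intensity_scale * np.exp(
                        rng.normal(0.0, config.intensity_sigma, n))
                    ratio = well_level * np.exp(rng.normal(0.0, config.cell_ratio_sigma, n))
                    frames.append(pd.DataFrame({
                        "Metadata_Plate": config.plate,
                        "Metadata_Well": well,
                        "Metadata_Genotype": genotype,
                        "Metadata_Treatment": label,
                        "Metadata_Concentration": conc,
                        "Metadata_Replicate": rep,
                        "nuclear_intensity": cyt * ratio,
                        "cytoplasmic_intensity": cyt,
                        "contact_percent": rng.uniform(0.0, 100.0, n),
                    }))
    return pd.concat(frames, ignore_index=True), truth


def _growth_inhibition_for(config: SyntheticConfig, genotype: str) -> float:
    gi = config.growth_inhibition
    if isinstance(gi, dict):
        return float(gi.get(genotype, gi.get("default", 0.0)))
    return float(gi)


def generate_growth_tracks(
    config: SyntheticConfig, mode: str = "spheroid"
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Logistic growth tracks with artefact spikes.

    ``mode='spheroid'`` emits areas on a 12-h grid through 168 h (the 24-h
    and 168-h anchors are always present); ``mode='2d'`` emits % confluency
    on a 4-h grid through 72 h. Treatment reduces the logistic rate k by
    ``growth_inhibition × dose_scale``. Each observation is multiplied by
    lognormal noise; spike artefacts multiply single time-points by
    ``spike_factor`` and are recorded in the truth object.
    """
    if mode not in ("spheroid", "2d"):
        raise ValidationError(f"mode must be 'spheroid' or '2d'; got {mode!r}")
    times = np.array(config.spheroid_times if mode == "spheroid" else config.times_2d)
    params = config.growth_params if mode == "spheroid" else config.growth_params_2d
    value_col = "area" if mode == "spheroid" else "confluency"
    midpoints = [params.get(g, params.get(config.wt_genotype))[2] for g in config.genotypes]
    if sum(t < max(midpoints) for t in times) < 1 or len(times) < 4:
        raise ValidationError("time grid must have >=4 points spanning the logistic midpoint")

    rng = np.random.default_rng([config.seed, 3 if mode == "spheroid" else 4])
    truth = SyntheticTruth(seed=config.seed)
    by_label = _treatment_by_label(config)
    rows = []
    well_counter = 0
    for genotype in config.genotypes:
        L, k_base, t0 = params.get(genotype, params.get(config.wt_genotype))
        for label, family, conc in _condition_grid(config):
            k = k_base
            if label != config.vehicle_label:
                scale = dose_scale(conc, by_label[label].concentrations)
                k = k_base * max(0.0, 1.0 - _growth_inhibition_for(config, genotype) * scale)
            for rep in range(1, config.n_replicate_wells + 1):
                well_counter += 1
                well = f"W{well_counter:03d}"
                well_id = f"{config.plate}:{well}"
                truth.true_growth[well_id] = (L, k, t0)
                clean = L / (1.0 + np.exp(-k * (times - t0)))
                noise = np.exp(rng.normal(0.0, config.growth_noise, len(times)))
                values = clean * noise
                spikes = rng.random(len(times)) < config.outlier_timepoint_rate
                for j, t in enumerate(times):
                    if spikes[j]:
                        values[j] *= config.spike_factor
                        truth.outlier_timepoints.add((well_id, float(t)))
                for j, t in enumerate(times):
                    rows.append({
                        "Metadata_Plate": config.plate,
                        "Metadata_Well": well,
                        "Metadata_Genotype": genotype,
                        "Metadata_Treatment": label,
                        "Metadata_Family": family,
                        "Metadata_Concentration": conc,
                        "Metadata_Replicate": rep,
                        "time_h": float(t),
                        value_col: values[j],
                    })
    return pd.DataFrame(rows), truth


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize ground truth as a documented key-value text file."""
    lines = [f"# hippoprofiler synthetic truth v1", f"seed={truth.seed}"]
    for trt in sorted(truth.affected_features):
        feats = ",".join(sorted(truth.affected_features[trt]))
        lines.append(f"affected_features[{trt}]={feats}")
    for f in sorted(truth.dependency_labels):
        lines.append(f"dependency_label[{f}]={truth.dependency_labels[f]}")
    for w in sorted(truth.outlier_wells):
        lines.append(f"outlier_well={w}")
    for w, t in sorted(truth.outlier_timepoints):
        lines.append(f"outlier_timepoint={w},{t!r}")
    for w in sorted(truth.true_growth):
        L, k, t0 = truth.true_growth[w]
        lines.append(f"true_growth[{w}]={L!r},{k!r},{t0!r}")
    for w in sorted(truth.true_well_ratio):
        lines.append(f"true_well_ratio[{w}]={truth.true_well_ratio[w]!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth(path) -> SyntheticTruth:
    truth = SyntheticTruth(seed=0)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            if key == "seed":
                truth.seed = int(value)
            elif key.startswith("affected_features["):
                trt = key[len("affected_features["):-1]
                truth.affected_features[trt] = set(filter(None, value.split(",")))
            elif key.startswith("dependency_label["):
                truth.dependency_labels[key[len("dependency_label["):-1]] = value
            elif key == "outlier_well":
                truth.outlier_wells.add(value)
            elif key == "outlier_timepoint":
                well, _, t = value.rpartition(",")
                truth.outlier_timepoints.add((well, float(t)))
            elif key.startswith("true_growth["):
                well = key[len("true_growth["):-1]
                L, k, t0 = (float(x) for x in value.split(","))
                truth.true_growth[well] = (L, k, t0)
            elif key.startswith("true_well_ratio["):
                truth.true_well_ratio[key[len("true_well_ratio["):-1]] = float(value)
    return truth
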