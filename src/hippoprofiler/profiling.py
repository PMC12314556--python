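"""Well-level profile analytics: correlation distances, complete-linkage
clustering, PCA dose trajectories, and morphological uniformity.

Distances are ``1 - Pearson r`` computed across the retained feature set of a
pair of wells, so 0 means identical profile shape and 2 perfect
anti-correlation. Uniformity of a well is one minus its mean distance to the
other wells that received the same (genotype, treatment, concentration), so
larger values mean more uniform replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .exceptions import ConfigurationError, UndefinedDistanceError
from .io import feature_columns, well_ids

GROUP_KEY = ["Metadata_Genotype", "Metadata_Treatment", "Metadata_Concentration"]


def correlation_distance(profile_a, profile_b) -> float:
    """``1 - Pearson r`` between two feature vectors; range [0, 2]."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        raise UndefinedDistanceError("zero-variance profile has no correlation distance")
    r = np.corrcoef(a, b)[0, 1]
    return float(np.clip(1.0 - r, 0.0, 2.0))


def distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Square well × well correlation-distance matrix, labelled ``plate:well``."""
    feats = feature_columns(matrix)
    X = matrix[feats].to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0.0):
        bad = well_ids(matrix)[sd == 0.0].tolist()
        raise UndefinedDistanceError(f"zero-variance profile(s): {bad}")
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 2.0)
    ids = well_ids(matrix).tolist()
    return pd.DataFrame(D, index=ids, columns=ids)


def cluster_wells(dist: pd.DataFrame) -> np.ndarray:
    """Complete-linkage agglomerative clustering of a distance matrix.

    Returns the scipy linkage matrix (merge pairs, heights, cluster sizes);
    leaf order is deterministic given the input well order.
    """
    if len(dist) < 2:
        raise ConfigurationError("clustering requires >=2 wells")
    condensed = squareform(dist.to_numpy(), checks=False)
    return linkage(condensed, method="complete")


def linkage_table(dist: pd.DataFrame) -> pd.DataFrame:
    Z = cluster_wells(dist)
    return pd.DataFrame(Z, columns=["left", "right", "height", "size"])


def pca_trajectories(
    matrix: pd.DataFrame,
    vehicle_label: str = "DMSO",
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-component PCA embedding plus per-group dose-ordered centroid paths.

    The matrix is expected to be curated and vehicle-normalized (features
    already on a common robust-z scale), so no second scaling pass is
    applied. For each (genotype, treatment) the trajectory starts at that
    genotype's vehicle centroid (dose 0) and proceeds through concentration
    centroids in ascending dose order.
    """
    feats = feature_columns(matrix)
    if len(matrix) < n_components:
        raise ConfigurationError(
            f"PCA with {n_components} components needs >= that many wells"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(matrix[feats].to_numpy(dtype=float))
    comp_cols = [f"PC{i + 1}" for i in range(n_components)]
    embedding = matrix[[c for c in matrix.columns if c.startswith("Metadata_")]].copy()
    embedding[comp_cols] = scores
    embedding.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()

    traj_rows = []
    for genotype, geno_df in embedding.groupby("Metadata_Genotype", sort=True):
        veh = geno_df[geno_df["Metadata_Treatment"] == vehicle_label]
        veh_centroid = veh[comp_cols].mean() if len(veh) else None
        treated = geno_df[geno_df["Metadata_Treatment"] != vehicle_label]
        for treatment, trt_df in treated.groupby("Metadata_Treatment", sort=True):
            if veh_centroid is not None:
                traj_rows.append({
                    "Metadata_Genotype": genotype, "Metadata_Treatment": treatment,
                    "Metadata_Concentration": 0.0,
                    **{c: veh_centroid[c] for c in comp_cols},
                })
            for conc, cdf in sorted(
                trt_df.groupby("Metadata_Concentration", sort=True),
                key=lambda kv: kv[0],
            ):
                cent = cdf[comp_cols].mean()
                traj_rows.append({
                    "Metadata_Genotype": genotype, "Metadata_Treatment": treatment,
                    "Metadata_Concentration": float(conc),
                    **{c: cent[c] for c in comp_cols},
                })
    trajectories = pd.DataFrame(traj_rows)
    return embedding, trajectories


def uniformity_scores(
    dist: pd.DataFrame,
    metadata: pd.DataFrame,
    group_cols=GROUP_KEY,
) -> pd.DataFrame:
    """Per-well mean correlation distance to the other like-treated wells.

    ``metadata`` carries one row per well in the same order as ``dist``.
    Wells in singleton groups are omitted and listed in
    ``attrs['singleton_groups']``. ``uniformity = 1 - mean_like_distance``
    so that enhanced uniformity is numerically larger.
    """
    group_cols = list(group_cols)
    D = dist.to_numpy()
    meta = metadata.reset_index(drop=True)
    rows, singletons = [], []
    for key, grp in meta.groupby(group_cols, sort=True):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            singletons.append(key)
            continue
        sub = D[np.ix_(idx, idx)]
        mean_like = sub.sum(axis=1) / (len(idx) - 1)
        for i, row_i in enumerate(idx):
            rows.append({
                "well_id": dist.index[row_i],
                **dict(zip(group_cols, key if isinstance(key, tuple) else (key,))),
                "mean_like_distance": mean_like[i],
                "uniformity": 1.0 - mean_like[i],
            })
    out = pd.DataFrame(rows)
    out.attrs["singleton_groups"] = singletons
    return out


def compare_group_uniformity(
    dist: pd.DataFrame,
    wells_a: list[str],
    wells_b: list[str],
    n_permutations: int = 200,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value that group A is more uniform than B.

    The statistic is mean like-treated distance of B minus that of A (larger
    = A more uniform). Group memberships are permuted between A and B.
    """
    rng = np.random.default_rng(seed)
    D = dist.to_numpy()
    pos = {w: i for i, w in enumerate(dist.index)}
    ia = np.array([pos[w] for w in wells_a])
    ib = np.array([pos[w] for w in wells_b])

    def mean_like(idx):
        sub = D[np.ix_(idx, idx)]
        return sub.sum() / (len(idx) * (len(idx) - 1))

    observed = mean_like(ib) - mean_like(ia)
    pooled = np.concatenate([ia, ib])
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = mean_like(perm[len(ia):]) - mean_like(perm[:len(ia)])
        if stat >= observed:
            hits += 1
    return (1 + hits) / (1 + n_permutations)
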