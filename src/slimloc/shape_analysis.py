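"""Low-dimensional embedding of USV shape vectors and local-predictability analysis.

The embedding itself is delegated to UMAP (an established component, seeded for
reproducibility). The package's own statistic is the Local Prediction Error
(LPE): the RMSE of predicting a per-USV property from the mean of its k nearest
embedding neighbors, and the permutation-based explained variance

    sigma_E^2 = 100 * (1 - LPE(X) / mean_i LPE(X_perm,i))

with significance p = #(permuted LPE < original LPE) / N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n, 3)
    params: dict
    seed: int | None
    cluster_labels: np.ndarray | None = None


@dataclass
class LPEResult:
    lpe_original: float
    lpe_permuted: np.ndarray
    explained_variance: float  # percent; nan for a constant property
    p_value: float
    degenerate: bool = False


def embed_3d(
    vectors,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int | None = 0,
    standardize: bool = True,
) -> EmbeddingResult:
    """Embed shape vectors into 3D with UMAP.

    Components are z-scored beforehand by default (constant components are left
    at zero). Deterministic for a fixed seed.
    """
    import umap  # deferred: numba compilation makes this import expensive

    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or len(x) < 50:
        raise ValidationError("need a (n >= 50, d) matrix of shape vectors")
    if not np.all(np.isfinite(x)):
        raise ValidationError("shape vectors must be finite")
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    reducer = umap.UMAP(
        n_components=3, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = np.asarray(reducer.fit_transform(x), dtype=float)
    return EmbeddingResult(
        coordinates=coords,
        params={"n_neighbors": n_neighbors, "min_dist": min_dist,
                "standardize": standardize},
        seed=seed,
    )


def cluster(embedding: EmbeddingResult | np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means labels of the embedded points (k = 100 at full data scale)."""
    coords = embedding.coordinates if isinstance(embedding, EmbeddingResult) else np.asarray(embedding)
    if k > len(coords):
        raise ValidationError(f"k = {k} exceeds the number of points ({len(coords)})")
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(coords)
    if isinstance(embedding, EmbeddingResult):
        embedding.cluster_labels = labels
    return labels


def _neighbor_index(coords: np.ndarray, k_neighbors: int) -> np.ndarray:
    n = len(coords)
    if n <= k_neighbors:
        raise ValidationError("need more points than neighbors")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    return idx[:, 1:]  # self excluded


def local_prediction_error(
    embedding: EmbeddingResult | np.ndarray,
    prop,
    k_neighbors: int = 5,
    neighbor_index: np.ndarray | None = None,
) -> float:
    """RMSE of k-nearest-neighbor prediction of ``prop`` from the embedding.

    Each point's property is predicted as the mean over its ``k_neighbors``
    nearest neighbors (self excluded). Binary properties are expected coded 0/1.
    """
    coords = embedding.coordinates if isinstance(embedding, EmbeddingResult) else np.asarray(embedding)
    prop = np.asarray(prop, dtype=float)
    if not np.all(np.isfinite(prop)):
        raise ValidationError("property values must be finite")
    if len(prop) != len(coords):
        raise ValidationError("one property value per point required")
    idx = neighbor_index if neighbor_index is not None else _neighbor_index(coords, k_neighbors)
    pred = prop[idx].mean(axis=1)
    return float(np.sqrt(np.mean((prop - pred) ** 2)))


def explained_variance(
    embedding: EmbeddingResult | np.ndarray,
    prop,
    n_perm: int = 100,
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = None,
) -> LPEResult:
    """Permutation-based explained variance of a property in the embedding.

    Permutations shuffle the property values over points, keeping the spatial
    structure; p has resolution 1/n_perm. A constant property makes the ratio
    0/0 and is reported as degenerate with nan explained variance.
    """
    if n_perm < 10:
        raise ValidationError("n_perm must be at least 10")
    coords = embedding.coordinates if isinstance(embedding, EmbeddingResult) else np.asarray(embedding)
    prop = np.asarray(prop, dtype=float)
    rng = np.random.default_rng(rng)
    idx = _neighbor_index(coords, k_neighbors)
    lpe = local_prediction_error(coords, prop, k_neighbors, neighbor_index=idx)
    perms = np.empty(n_perm)
    for i in range(n_perm):
        perms[i] = local_prediction_error(
            coords, rng.permutation(prop), k_neighbors, neighbor_index=idx
        )
    mean_perm = perms.mean()
    if mean_perm == 0.0:
        return LPEResult(lpe, perms, float("nan"), 1.0, degenerate=True)
    var_e = 100.0 * (1.0 - lpe / mean_perm)
    p = float(np.sum(perms < lpe) / n_perm)
    return LPEResult(lpe, perms, var_e, p)
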